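import numpy as np
import pytest

from survtree.classification_eval import ClassifierSpec
from survtree.cohort_io import assemble_cohort
from survtree.greedy_hierarchy import PipelineConfig
from survtree.imbalance import BalanceSpec
from survtree.synthetic_cohort import SimulationConfig, simulate


@pytest.fixture(scope="session")
def small_sim():
    """Small planted cohort shared by read-only tests: 6 classes, strong effects."""
    config = SimulationConfig(
        n_genes=300,
        class_sizes={"LR": 30, "DR": 12, "LH": 12, "DH": 6, "LS": 30, "DS": 15},
        planted_per_class=3,
        effect_size=3.0,
        redundancy_copies=1,
        seed=11,
    )
    expr, clinical, truth = simulate(config)
    return config, expr, clinical, truth


@pytest.fixture(scope="session")
def small_cohort(small_sim):
    _, expr, clinical, _ = small_sim
    return assemble_cohort(expr, clinical)


@pytest.fixture()
def fast_config():
    """Cheap deterministic pipeline config for hierarchy-level tests."""
    return PipelineConfig(
        mrmr_max_k=5,
        balance=BalanceSpec(method="smote", seed=5),
        classifier=ClassifierSpec(kind="naive_bayes", seed=7),
        cv_k=5,
        seed=3,
    )
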