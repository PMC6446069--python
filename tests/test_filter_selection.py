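import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from survtree.cohort_io import assemble_cohort
from survtree.filter_selection import (
    Discretization,
    chi_square,
    filter_genes,
    fallback_scores,
    info_gain,
    mdl_discretize,
)
from survtree.synthetic_cohort import SimulationConfig, simulate


def _mdl_oracle_single_split(values, labels):
    """Exhaustive search over candidate cuts with explicit MDL acceptance check."""
    order = np.argsort(values, kind="stable")
    sv, sl = np.asarray(values, float)[order], np.asarray(labels, int)[order]
    n = len(sv)

    def H(lab):
        if len(lab) == 0:
            return 0.0
        p = np.bincount(lab, minlength=2) / len(lab)
        return float(-sum(q * math.log2(q) for q in p if q > 0))

    best = None
    for b in range(1, n):
        if sv[b] == sv[b - 1]:
            continue
        gain = H(sl) - (b / n) * H(sl[:b]) - ((n - b) / n) * H(sl[b:])
        if best is None or gain > best[0]:
            best = (gain, b)
    if best is None:
        return None
    gain, b = best
    k = lambda lab: len(set(lab.tolist()))
    delta = math.log2(3 ** k(sl) - 2) - (k(sl) * H(sl) - k(sl[:b]) * H(sl[:b]) - k(sl[b:]) * H(sl[b:]))
    if gain <= (math.log2(n - 1) + delta) / n:
        return None
    return (sv[b - 1] + sv[b]) / 2


def test_mdl_accepts_one_clean_split():
    values = np.array([1, 2, 3, 101, 102, 103.0])
    labels = np.array([0, 0, 0, 1, 1, 1])
    disc = mdl_discretize(values, labels)
    assert len(disc.cut_points) == 1
    assert 3 < disc.cut_points[0] < 101
    assert disc.cut_points[0] == _mdl_oracle_single_split(values, labels)


def test_mdl_pure_labels_and_constant_values_give_single_bin():
    v = np.array([1.0, 2.0, 3.0, 4.0])
    assert mdl_discretize(v, np.zeros(4, int)).cut_points == ()
    assert mdl_discretize(np.ones(4), np.array([0, 1, 0, 1])).cut_points == ()


@settings(max_examples=100, deadline=None)
@given(st.lists(st.tuples(st.floats(-50, 50), st.integers(0, 1)), min_size=4, max_size=40))
def test_mdl_first_split_matches_oracle(pairs):
    """The top-level accepted cut (or rejection) agrees with exhaustive search."""
    values = np.array([p[0] for p in pairs])
    labels = np.array([p[1] for p in pairs])
    expected = _mdl_oracle_single_split(values, labels)
    disc = mdl_discretize(values, labels)
    if expected is None:
        assert disc.cut_points == ()
    else:
        assert expected in disc.cut_points


def test_info_gain_perfect_separation_is_one_bit():
    v = np.array([1, 2, 3, 101, 102, 103.0])
    y = np.array([0, 0, 0, 1, 1, 1])
    assert info_gain(v, y) == pytest.approx(1.0)


def test_info_gain_two_bin_table_matches_entropy_formula():
    # bins x labels = [[8,2],[2,8]] at n=20 with balanced labels -> 1 - H(0.2)
    v = np.array([0.0] * 10 + [1.0] * 10)
    y = np.array([0] * 8 + [1] * 2 + [0] * 2 + [1] * 8)
    disc = Discretization((0.5,))
    expected = 1 - (-0.2 * math.log2(0.2) - 0.8 * math.log2(0.8))
    assert info_gain(v, y, disc) == pytest.approx(expected)


def test_info_gain_zero_for_class_independent_gene():
    rng = np.random.default_rng(0)
    v = rng.normal(size=100)
    y = rng.integers(0, 2, size=100)
    assert info_gain(v, y) == 0.0  # MDL rejects all splits


@settings(max_examples=50, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_info_gain_invariant_to_monotone_transform(seed):
    rng = np.random.default_rng(seed)
    v = rng.normal(size=30)
    y = (v + rng.normal(scale=0.5, size=30) > 0).astype(int)
    if y.min() == y.max():
        return
    assert info_gain(np.exp(v), y) == pytest.approx(info_gain(v, y))


def test_chi_square_closed_form_perfect_association():
    v = np.array([0.0] * 10 + [1.0] * 10)
    y = np.array([1] * 10 + [0] * 10)
    stat, p = chi_square(v, y, Discretization((0.5,)))
    assert stat == pytest.approx(20.0)  # n(ad-bc)^2 / row/col products
    assert p < 1e-4


def test_chi_square_independent_and_single_bin():
    v = np.array([0.0] * 10 + [1.0] * 10)
    y = np.array([0, 1] * 10)
    stat, p = chi_square(v, y, Discretization((0.5,)))
    assert stat == 0.0 and p == 1.0
    assert chi_square(v, y, Discretization(())) == (0.0, 1.0)


def test_chi_square_invariant_to_label_swap():
    rng = np.random.default_rng(3)
    v = rng.normal(size=40)
    y = rng.integers(0, 2, size=40)
    d = Discretization((0.0,))
    assert chi_square(v, y, d) == pytest.approx(chi_square(v, 1 - y, d))


@pytest.fixture(scope="module")
def dh_node(small_sim_module):
    config, expr, clinical, truth = small_sim_module
    cohort = assemble_cohort(expr, clinical)
    return cohort, truth


@pytest.fixture(scope="module")
def small_sim_module():
    config = SimulationConfig(
        n_genes=300,
        class_sizes={"LR": 30, "DR": 12, "LH": 12, "DH": 6, "LS": 30, "DS": 15},
        planted_per_class=3,
        effect_size=3.0,
        redundancy_copies=1,
        seed=11,
    )
    return (config,) + simulate(config)


def test_filter_recovers_planted_and_removes_nulls(dh_node):
    cohort, truth = dh_node
    y = cohort.binary_labels("DH")
    scores = filter_genes(cohort.expression.values, cohort.expression.gene_ids, y)
    retained = {s.gene_id for s in scores}
    assert set(truth.planted["DH"]) <= retained
    informative = {g for c in truth.planted for g in truth.planted[c]} | set(truth.duplicates)
    null_genes = set(cohort.expression.gene_ids) - informative
    assert len(retained & null_genes) / len(null_genes) < 0.05


def test_filter_null_false_positive_rate():
    cfg = SimulationConfig(
        n_genes=400, planted_per_class=1, redundancy_copies=0, effect_size=0.0,
        class_sizes={"LR": 60, "DH": 30}, seed=17,
    )
    expr, clinical, _ = simulate(cfg)
    cohort = assemble_cohort(expr, clinical)
    scores = filter_genes(expr.values, expr.gene_ids, cohort.binary_labels("DH"))
    assert len(scores) / expr.n_genes < 0.05


def test_single_planted_gene_ranks_first():
    cfg = SimulationConfig(
        n_genes=51, planted_per_class=1, redundancy_copies=0, effect_size=3.0,
        class_sizes={"LR": 40, "DH": 20}, seed=23,
    )
    expr, clinical, truth = simulate(cfg)
    cohort = assemble_cohort(expr, clinical)
    scores = filter_genes(expr.values, expr.gene_ids, cohort.binary_labels("DH"))
    assert scores[0].gene_id == truth.planted["DH"][0]


def test_filter_order_deterministic_and_bounded(dh_node):
    cohort, _ = dh_node
    y = cohort.binary_labels("DH")
    a = filter_genes(cohort.expression.values, cohort.expression.gene_ids, y)
    b = filter_genes(cohort.expression.values, cohort.expression.gene_ids, y)
    assert [s.gene_id for s in a] == [s.gene_id for s in b]
    h_y = -(lambda p: p * math.log2(p) + (1 - p) * math.log2(1 - p))(y.mean())
    for s in a:
        assert 0 <= s.info_gain_bits <= h_y + 1e-12


def test_fallback_scores_rank_by_chi2():
    rng = np.random.default_rng(1)
    expr = rng.normal(size=(20, 40))
    y = rng.integers(0, 2, size=40)
    out = fallback_scores(expr, [f"g{i}" for i in range(20)], y, k=5)
    assert len(out) == 5
    stats = [s.chi2_stat for s in out]
    assert stats == sorted(stats, reverse=True)
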