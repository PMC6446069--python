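"""Synthetic expression cohorts with planted class-specific markers.

The generator emulates the statistical structure the downstream pipeline assumes:
a normalized (roughly Gaussian) expression matrix in which each treatment-survival
class carries a handful of planted genes whose mean is shifted in that class only,
each planted gene optionally has noisy redundant copies (to exercise the mRMR
redundancy penalty), and the remaining genes are class-independent noise.
Clinical records are generated so that label derivation recovers the intended
class for every sample.
"""

from __future__ import annotations

import json
import logging
import pathlib
from dataclasses import dataclass, field, asdict

import numpy as np

from survtree.cohort_io import (
    CLASS_LABELS,
    ClinicalRecord,
    ExpressionMatrix,
)

logger = logging.getLogger(__name__)

#: Per-class sample counts of the motivating breast-cancer cohort.
DEFAULT_CLASS_SIZES = {"LR": 132, "DR": 19, "LH": 20, "DH": 6, "LS": 130, "DS": 40}

_THERAPY_FLAGS = {"R": "radio", "H": "hormone", "S": "surgery"}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort.

    effect_size is the planted mean shift in units of the within-gene standard
    deviation; redundancy_copies noisy duplicates are added per planted gene;
    genes not planted or duplicated are pure noise.
    """

    n_genes: int = 2000
    class_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_CLASS_SIZES))
    planted_per_class: int = 5
    effect_size: float = 3.0
    redundancy_copies: int = 2
    duplicate_noise_sd: float = 0.25
    baseline_mean_range: tuple[float, float] = (5.0, 12.0)
    baseline_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.class_sizes) - set(CLASS_LABELS)
        if unknown:
            raise ValueError(f"unknown class labels {sorted(unknown)}")
        if any(n <= 0 for n in self.class_sizes.values()):
            raise ValueError("class sizes must be positive")
        if self.n_genes <= 0 or self.planted_per_class < 0 or self.redundancy_copies < 0:
            raise ValueError("counts must be non-negative (n_genes positive)")
        needed = self.planted_per_class * len(self.class_sizes) * (1 + self.redundancy_copies)
        if needed > self.n_genes:
            raise ValueError(
                f"planted+duplicate genes ({needed}) exceed n_genes ({self.n_genes})"
            )
        if self.baseline_sd <= 0:
            raise ValueError("baseline_sd must be positive")
        lo, hi = self.baseline_mean_range
        if not lo <= hi:
            raise ValueError("baseline_mean_range must be a non-empty interval")


@dataclass
class GroundTruth:
    """Planted informative genes per class, duplicate provenance, and effects."""

    planted: dict[str, list[str]]
    duplicates: dict[str, str]  # duplicate gene id -> source planted gene id
    effect_size_per_class: dict[str, float]
    seed: int

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def _gene_name(i: int, width: int) -> str:
    return f"G{i:0{width}d}"


def simulate(
    config: SimulationConfig,
    effect_size_per_class: dict[str, float] | None = None,
) -> tuple[ExpressionMatrix, list[ClinicalRecord], GroundTruth]:
    """Generate (expression, clinical, ground truth) for the configured cohort.

    ``effect_size_per_class`` overrides the common ``config.effect_size`` with a
    per-class shift, which is how graded-separability cohorts are built.  Planted
    shifts alternate in sign across a class's genes so each class carries both
    up- and down-regulated markers.  Fixed seed gives bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    classes = [c for c in CLASS_LABELS if c in config.class_sizes]
    sizes = [config.class_sizes[c] for c in classes]
    n_samples = int(np.sum(sizes))
    effects = dict.fromkeys(classes, float(config.effect_size))
    if effect_size_per_class is not None:
        effects.update({c: float(v) for c, v in effect_size_per_class.items()})

    width = max(4, len(str(config.n_genes)))
    gene_ids = [_gene_name(i, width) for i in range(config.n_genes)]
    sample_ids = [f"S{j:04d}" for j in range(n_samples)]
    sample_class = np.repeat(np.arange(len(classes)), sizes)

    mu = rng.uniform(*config.baseline_mean_range, size=config.n_genes)
    values = mu[:, None] + rng.normal(0.0, config.baseline_sd, size=(config.n_genes, n_samples))

    # First planted_per_class*6 genes are the informative ones, then their copies;
    # assignment is deterministic so ground truth is reproducible by construction.
    planted: dict[str, list[str]] = {c: [] for c in classes}
    duplicates: dict[str, str] = {}
    gi = 0
    for ci, c in enumerate(classes):
        in_class = sample_class == ci
        for k in range(config.planted_per_class):
            sign = 1.0 if k % 2 == 0 else -1.0
            shift = sign * effects[c] * config.baseline_sd
            values[gi, in_class] += shift
            planted[c].append(gene_ids[gi])
            gi += 1
    for c in classes:
        for src in planted[c]:
            si = gene_ids.index(src)
            for _ in range(config.redundancy_copies):
                values[gi] = values[si] + rng.normal(0.0, config.duplicate_noise_sd, size=n_samples)
                duplicates[gene_ids[gi]] = src
                gi += 1

    expr = ExpressionMatrix(gene_ids, sample_ids, values)

    clinical: list[ClinicalRecord] = []
    for j, s in enumerate(sample_ids):
        label = classes[sample_class[j]]
        survival, therapy = label[0], label[1]
        flags = {"surgery": False, "hormone": False, "radio": False}
        flags[_THERAPY_FLAGS[therapy]] = True
        if survival == "L":
            vital, followup = "living", float(rng.uniform(60.0, 220.0))
        else:
            vital, followup = "deceased", float(rng.uniform(1.0, 59.0))
        clinical.append(
            ClinicalRecord(sample_id=s, vital_status=vital, followup_months=followup, **flags)
        )

    truth = GroundTruth(
        planted=planted,
        duplicates=duplicates,
        effect_size_per_class={c: effects[c] for c in classes},
        seed=config.seed,
    )
    return expr, clinical, truth


def write_fixture(
    expr: ExpressionMatrix,
    clinical: list[ClinicalRecord],
    truth: GroundTruth,
    outdir,
    overwrite: bool = False,
) -> dict[str, pathlib.Path]:
    """Write expression.tsv, clinical.tsv and ground_truth.json under outdir."""
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "clinical": outdir / "clinical.tsv",
        "ground_truth": outdir / "ground_truth.json",
    }
    clobber = [p for p in paths.values() if p.exists()]
    if clobber and not overwrite:
        raise FileExistsError(f"refusing to overwrite {clobber[0]} (pass overwrite=True)")

    # full repr precision so a write -> read round trip reproduces values exactly
    expr.to_frame().to_csv(paths["expression"], sep="\t", index_label="gene_symbol")
    with open(paths["clinical"], "w") as fh:
        fh.write("sample_id\tsurgery\thormone\tradio\tvital_status\tfollowup_months\n")
        for rec in clinical:
            fh.write(
                f"{rec.sample_id}\t{int(rec.surgery)}\t{int(rec.hormone)}\t{int(rec.radio)}"
                f"\t{rec.vital_status}\t{rec.followup_months!r}\n"
            )
    paths["ground_truth"].write_text(truth.to_json())
    logger.info("wrote fixture to %s", outdir)
    return paths
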