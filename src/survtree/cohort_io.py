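"""Cohort assembly: expression/clinical readers and treatment-survival class labels.

The six classes combine the single therapy a patient received — radiotherapy (R),
hormone therapy (H) or surgery (S) — with whether they survived the five-year
horizon (L living, D deceased): LR, DR, LH, DH, LS, DS.  Patients who received
more than one therapy (or none), and living patients censored before the horizon,
are excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Closed label set, in the fixed deterministic order used for tie-breaking.
CLASS_LABELS = ("DH", "DR", "LH", "DS", "LS", "LR")

#: Sentinel returned by :func:`derive_class` for records outside the study design.
EXCLUDED = "excluded"

_THERAPY_SUFFIX = {"surgery": "S", "hormone": "H", "radio": "R"}


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of normalized continuous expression values."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # shape (n_genes, n_samples)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains non-finite values")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self, gene_id: str) -> int:
        try:
            return self._gene_lookup[gene_id]
        except AttributeError:
            self._gene_lookup = {g: i for i, g in enumerate(self.gene_ids)}
            return self._gene_lookup[gene_id]

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        lookup = {s: j for j, s in enumerate(self.sample_ids)}
        cols = [lookup[s] for s in sample_ids]
        return ExpressionMatrix(list(self.gene_ids), list(sample_ids), self.values[:, cols])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class ClinicalRecord:
    """One patient's therapy flags, vital status and follow-up."""

    sample_id: str
    surgery: bool
    hormone: bool
    radio: bool
    vital_status: str  # "living" | "deceased"
    followup_months: float

    def __post_init__(self) -> None:
        if self.vital_status not in ("living", "deceased"):
            raise ValueError(f"invalid vital_status {self.vital_status!r}")
        if self.followup_months < 0:
            raise ValueError("followup_months must be >= 0")


@dataclass
class LabeledCohort:
    """Expression matrix restricted to labeled samples, plus the label map."""

    expression: ExpressionMatrix
    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(self.labels) - set(self.expression.sample_ids)
        if missing:
            raise ValueError(f"labeled samples without expression columns: {sorted(missing)[:5]}")

    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in CLASS_LABELS}
        for lab in self.labels.values():
            counts[lab] += 1
        return counts

    def samples_of(self, label: str) -> list[str]:
        return [s for s in self.expression.sample_ids if self.labels[s] == label]

    def subset(self, sample_ids: list[str]) -> "LabeledCohort":
        return LabeledCohort(
            self.expression.subset_samples(sample_ids),
            {s: self.labels[s] for s in sample_ids},
        )

    def binary_labels(self, positive_class: str) -> np.ndarray:
        """0/1 vector over expression.sample_ids with 1 = positive_class."""
        return np.array(
            [1 if self.labels[s] == positive_class else 0 for s in self.expression.sample_ids],
            dtype=int,
        )


def read_expression(path) -> ExpressionMatrix:
    """Read a tab-delimited expression file (first column gene symbol, header = sample ids).

    Gzip-compressed files are handled transparently.  Duplicate gene symbols keep
    the first occurrence with a warning; any non-numeric cell is an error naming
    the offending gene and sample.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    if df.empty or df.shape[1] == 0:
        raise ValueError(f"empty expression matrix in {path}")
    dup_mask = df.index.duplicated(keep="first")
    if dup_mask.any():
        dups = sorted(set(df.index[dup_mask]))
        logger.warning("dropping %d duplicated gene rows (keeping first): %s", dup_mask.sum(), dups[:5])
        df = df[~dup_mask]
    try:
        # numpy's astype parser is correctly rounded, so write -> read round-trips
        values = df.to_numpy().astype(float)
    except ValueError:
        coerced = df.apply(pd.to_numeric, errors="coerce")
        bad = np.argwhere(coerced.isna().to_numpy())
        g, s = coerced.index[bad[0, 0]], coerced.columns[bad[0, 1]]
        raise ValueError(f"non-numeric expression value for gene {g!r}, sample {s!r}") from None
    return ExpressionMatrix(list(df.index), list(df.columns), values)


def read_clinical(path) -> list[ClinicalRecord]:
    """Read the clinical TSV: sample_id, surgery, hormone, radio, vital_status, followup_months."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = ["sample_id", "surgery", "hormone", "radio", "vital_status", "followup_months"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"clinical file {path} missing columns: {missing}")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in clinical file")
    return [
        ClinicalRecord(
            sample_id=row.sample_id,
            surgery=bool(int(row.surgery)),
            hormone=bool(int(row.hormone)),
            radio=bool(int(row.radio)),
            vital_status=str(row.vital_status),
            followup_months=float(row.followup_months),
        )
        for row in df.itertuples(index=False)
    ]


def derive_class(record: ClinicalRecord, horizon_months: float = 60.0) -> str:
    """Map one clinical record to a treatment-survival label or the excluded sentinel.

    Rules: exactly one therapy flag must be set; survival part is L when follow-up
    reaches the horizon, D when the patient died before it; living patients
    censored before the horizon are excluded (their five-year status is unknown).
    """
    flags = [("surgery", record.surgery), ("hormone", record.hormone), ("radio", record.radio)]
    active = [name for name, on in flags if on]
    if len(active) != 1:
        return EXCLUDED
    therapy = _THERAPY_SUFFIX[active[0]]
    if record.followup_months >= horizon_months:
        survival = "L"
    elif record.vital_status == "deceased":
        survival = "D"
    else:  # living, censored before horizon
        return EXCLUDED
    return survival + therapy


def assemble_cohort(
    expr: ExpressionMatrix,
    clinical: list[ClinicalRecord],
    horizon_months: float = 60.0,
) -> LabeledCohort:
    """Join expression and clinical data into a labeled cohort.

    Samples must appear in both inputs and receive a non-excluded label; the
    per-class counts are logged.
    """
    expr_samples = set(expr.sample_ids)
    labels: dict[str, str] = {}
    n_no_expr = 0
    for rec in clinical:
        if rec.sample_id not in expr_samples:
            n_no_expr += 1
            continue
        label = derive_class(rec, horizon_months)
        if label != EXCLUDED:
            labels[rec.sample_id] = label
    if n_no_expr:
        logger.info("dropped %d clinical rows without expression columns", n_no_expr)
    if not labels:
        raise ValueError("no overlap between expression samples and labelable clinical records")
    kept = [s for s in expr.sample_ids if s in labels]
    cohort = LabeledCohort(expr.subset_samples(kept), {s: labels[s] for s in kept})
    counts = cohort.class_counts()
    logger.info("class counts: %s (total %d)", counts, len(kept))
    for c, n in counts.items():
        if n == 0:
            logger.warning("class %s has 0 samples", c)
    return cohort
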