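"""Filter feature selection: MDL discretization, information gain, chi-square.

Continuous expression values are discretized per gene with the Fayyad-Irani
minimum-description-length procedure against the binary (class vs rest) label;
information gain and the Pearson chi-square statistic are then computed on the
resulting bins.  A gene survives the filter when its information gain is positive
and its chi-square p-value is below alpha, which drops tens of thousands of genes
to the order of hundreds before the wrapper stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Discretization:
    """Sorted cut points defining len(cut_points)+1 bins; empty means one bin."""

    cut_points: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.cut_points, self.cut_points[1:])):
            raise ValueError("cut points must be strictly increasing")

    @property
    def n_bins(self) -> int:
        return len(self.cut_points) + 1

    def assign(self, values: np.ndarray) -> np.ndarray:
        """Bin index per value (0-based, left-open bins)."""
        return np.searchsorted(np.asarray(self.cut_points), values, side="left")


@dataclass(frozen=True)
class GeneScore:
    gene_id: str
    info_gain_bits: float
    chi2_stat: float
    chi2_pvalue: float


def _entropy_bits(counts: np.ndarray) -> float:
    """Shannon entropy in bits of a count vector; 0*log0 = 0."""
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


def _binary_entropy_from_cums(n: np.ndarray, k: np.ndarray) -> np.ndarray:
    """Vectorized binary entropy of groups with n samples, k positives."""
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n > 0, k / np.maximum(n, 1), 0.0)
        h = -np.where((p > 0) & (p < 1), p * np.log2(p) + (1 - p) * np.log2(1 - p), 0.0)
    return np.where(n > 0, h, 0.0)


def _mdlp_recurse(sv: np.ndarray, sl: np.ndarray, cuts: list[float]) -> None:
    """Recursive entropy-minimizing splits on value-sorted data, MDL-gated.

    sv: sorted values, sl: labels in the same order.  Appends accepted cut
    points (midpoints between adjacent distinct values) to cuts.
    """
    n = sv.size
    if n < 2:
        return
    pos_total = int(sl.sum())
    if pos_total == 0 or pos_total == n:
        return  # pure node: zero entropy, nothing to gain
    # candidate boundaries: between adjacent distinct values
    boundary = np.flatnonzero(sv[1:] > sv[:-1]) + 1  # split before index b
    if boundary.size == 0:
        return
    cum_pos = np.cumsum(sl)
    n1 = boundary.astype(float)
    k1 = cum_pos[boundary - 1].astype(float)
    n2 = n - n1
    k2 = pos_total - k1
    h = _binary_entropy_from_cums(np.array([n]), np.array([pos_total]))[0]
    h1 = _binary_entropy_from_cums(n1, k1)
    h2 = _binary_entropy_from_cums(n2, k2)
    cond = (n1 * h1 + n2 * h2) / n
    gain = h - cond
    best = int(np.argmin(cond))  # max gain; ties -> smallest cut value
    g = float(gain[best])
    b = int(boundary[best])
    # MDL acceptance: gain must exceed (log2(n-1) + delta) / n
    def _k(labels: np.ndarray) -> int:
        return int(labels.min() != labels.max()) + 1
    k_s, k_1, k_2 = _k(sl), _k(sl[:b]), _k(sl[b:])
    delta = np.log2(3.0**k_s - 2.0) - (k_s * h - k_1 * float(h1[best]) - k_2 * float(h2[best]))
    threshold = (np.log2(n - 1) + delta) / n
    if g <= threshold:
        return
    cuts.append(float((sv[b - 1] + sv[b]) / 2.0))
    _mdlp_recurse(sv[:b], sl[:b], cuts)
    _mdlp_recurse(sv[b:], sl[b:], cuts)


def mdl_discretize(values: np.ndarray, labels: np.ndarray) -> Discretization:
    """Fayyad-Irani supervised discretization of one gene against a binary label.

    Splits are accepted only when the information gain of the best binary split
    exceeds the MDL cost log2(N-1)/N + [log2(3^k - 2) - (k H(S) - k1 H(S1) -
    k2 H(S2))]/N; constant values or pure labels yield a single bin.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if values.size != labels.size or values.size < 2:
        raise ValueError("values and labels must have equal length >= 2")
    order = np.argsort(values, kind="stable")
    cuts: list[float] = []
    _mdlp_recurse(values[order], labels[order], cuts)
    return Discretization(tuple(sorted(cuts)))


def info_gain(
    values: np.ndarray,
    labels: np.ndarray,
    disc: Discretization | None = None,
) -> float:
    """Information gain H(Y) - H(Y|X_binned) in bits under MDL discretization."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if disc is None:
        disc = mdl_discretize(values, labels)
    if disc.n_bins == 1:
        return 0.0
    bins = disc.assign(values)
    h_y = _entropy_bits(np.bincount(labels))
    h_cond = 0.0
    n = labels.size
    for b in range(disc.n_bins):
        mask = bins == b
        nb = int(mask.sum())
        if nb:
            h_cond += (nb / n) * _entropy_bits(np.bincount(labels[mask]))
    return max(0.0, h_y - h_cond)


def chi_square(
    values: np.ndarray,
    labels: np.ndarray,
    disc: Discretization,
) -> tuple[float, float]:
    """Pearson chi-square of the bins x 2 label contingency table.

    df = n_bins - 1; a single-bin discretization carries no association and
    returns (0, 1).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if disc.n_bins == 1:
        return 0.0, 1.0
    bins = disc.assign(values)
    table = np.zeros((disc.n_bins, 2), dtype=float)
    for b, y in zip(bins, labels):
        table[b, y] += 1
    table = table[table.sum(axis=1) > 0]
    if table.shape[0] < 2 or np.any(table.sum(axis=0) == 0):
        return 0.0, 1.0
    stat, pvalue, _, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), float(pvalue)


def score_gene(gene_id: str, values: np.ndarray, labels: np.ndarray) -> GeneScore:
    disc = mdl_discretize(values, labels)
    ig = info_gain(values, labels, disc)
    stat, p = chi_square(values, labels, disc)
    return GeneScore(gene_id, ig, stat, p)


def filter_genes(
    expression: np.ndarray,
    gene_ids: list[str],
    labels: np.ndarray,
    alpha: float = 0.05,
) -> list[GeneScore]:
    """Score every gene against the binary label and keep the informative ones.

    Retention rule: info_gain > 0 AND chi-square p < alpha.  Output is sorted by
    information gain descending, ties broken by chi-square statistic descending
    then gene id, so the ranking is fully deterministic.
    """
    labels = np.asarray(labels, dtype=int)
    counts = np.bincount(labels, minlength=2)
    if counts.min() < 2:
        raise ValueError("need at least 2 samples per label value")
    retained = [
        s
        for gene_id, row in zip(gene_ids, np.asarray(expression, dtype=float))
        if (s := score_gene(gene_id, row, labels)).info_gain_bits > 0 and s.chi2_pvalue < alpha
    ]
    retained.sort(key=lambda s: (-s.info_gain_bits, -s.chi2_stat, s.gene_id))
    if not retained:
        logger.warning("filter retained zero genes")
    return retained


def fallback_scores(
    expression: np.ndarray,
    gene_ids: list[str],
    labels: np.ndarray,
    k: int = 10,
) -> list[GeneScore]:
    """Top-k genes by chi-square statistic, for nodes where the joint rule keeps none.

    Used only when the caller opts into a total pipeline (e.g. null-calibration
    runs); ranking falls back to chi2 stat desc, info gain desc, gene id.
    """
    labels = np.asarray(labels, dtype=int)
    scored = [score_gene(g, row, labels) for g, row in zip(gene_ids, np.asarray(expression, dtype=float))]
    scored.sort(key=lambda s: (-s.chi2_stat, -s.info_gain_bits, s.gene_id))
    return scored[:k]


def write_filter_scores(scores: list[GeneScore], retained_ids: set[str], path) -> None:
    """Write filter_scores TSV: gene_id, info_gain_bits, chi2_stat, chi2_pvalue, retained."""
    with open(path, "w") as fh:
        fh.write("gene_id\tinfo_gain_bits\tchi2_stat\tchi2_pvalue\tretained\n")
        for s in scores:
            fh.write(
                f"{s.gene_id}\t{s.info_gain_bits:.4f}\t{s.chi2_stat:.4f}"
                f"\t{s.chi2_pvalue:.4g}\t{int(s.gene_id in retained_ids)}\n"
            )
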