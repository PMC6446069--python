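"""Greedy minimum-redundancy-maximum-relevance ranking and wrapper prefix search.

The MID (mutual-information difference) form is used: the first gene maximizes
relevance I(g; Y); each later step maximizes I(g; Y) minus the mean mutual
information with the genes already selected.  A wrapper then scores every prefix
of the ranking by cross-validated accuracy and keeps the smallest prefix
attaining the maximum — the node's biomarker panel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from survtree.filter_selection import Discretization, mdl_discretize

logger = logging.getLogger(__name__)


@dataclass
class MrmrTrace:
    ordered_genes: list[str]
    relevance: dict[str, float]  # I(g; Y) in bits
    step_scores: list[float]  # MID objective at each greedy step


@dataclass
class WrapperResult:
    best_k: int
    cv_accuracy_by_k: list[tuple[int, float]]
    selected_genes: list[str]


def mutual_information_binned(x_bins: np.ndarray, y_bins: np.ndarray) -> float:
    """Plug-in mutual information (bits) between two discrete assignments."""
    x_bins = np.asarray(x_bins, dtype=int)
    y_bins = np.asarray(y_bins, dtype=int)
    n = x_bins.size
    joint = np.zeros((x_bins.max() + 1, y_bins.max() + 1), dtype=float)
    np.add.at(joint, (x_bins, y_bins), 1.0)
    joint /= n
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    mask = joint > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = joint * np.log2(joint / (px * py))
    return float(max(0.0, terms[mask].sum()))


def mutual_information(
    values: np.ndarray,
    labels: np.ndarray,
    disc: Discretization | None = None,
) -> float:
    """I(X; Y) in bits, with X binned by its label-supervised discretization."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if disc is None:
        disc = mdl_discretize(values, labels)
    return mutual_information_binned(disc.assign(values), labels)


def mrmr_rank(
    candidates: list[str],
    expression: np.ndarray,
    gene_ids: list[str],
    labels: np.ndarray,
    max_k: int,
    discretizations: dict[str, Discretization] | None = None,
) -> MrmrTrace:
    """Greedy MID ranking of candidate genes.

    ``candidates`` must come ordered by filter rank — ties in the objective are
    broken by that order, then gene id, so the trace is deterministic.  Each
    gene's bins come from its own label-supervised discretization (cached via
    ``discretizations`` when supplied); gene-gene MI uses those same bins.
    """
    if not candidates:
        raise ValueError("empty candidate set")
    labels = np.asarray(labels, dtype=int)
    lookup = {g: i for i, g in enumerate(gene_ids)}
    expression = np.asarray(expression, dtype=float)

    bins: dict[str, np.ndarray] = {}
    relevance: dict[str, float] = {}
    for g in candidates:
        row = expression[lookup[g]]
        disc = (discretizations or {}).get(g) or mdl_discretize(row, labels)
        bins[g] = disc.assign(row)
        relevance[g] = mutual_information_binned(bins[g], labels)

    filter_rank = {g: i for i, g in enumerate(candidates)}
    max_k = min(max_k, len(candidates))
    selected: list[str] = []
    step_scores: list[float] = []
    remaining = list(candidates)
    pair_mi: dict[tuple[str, str], float] = {}
    redundancy_sum = dict.fromkeys(candidates, 0.0)

    def pair(g: str, s: str) -> float:
        key = (g, s) if g < s else (s, g)
        if key not in pair_mi:
            pair_mi[key] = mutual_information_binned(bins[g], bins[s])
        return pair_mi[key]

    while len(selected) < max_k:
        best_g, best_obj = None, None
        for g in remaining:
            obj = relevance[g]
            if selected:
                obj -= redundancy_sum[g] / len(selected)
            if (
                best_obj is None
                or obj > best_obj
                or (obj == best_obj and (filter_rank[g], g) < (filter_rank[best_g], best_g))
            ):
                best_g, best_obj = g, obj
        selected.append(best_g)
        step_scores.append(float(best_obj))
        remaining.remove(best_g)
        for g in remaining:
            redundancy_sum[g] += pair(g, best_g)

    return MrmrTrace(ordered_genes=selected, relevance=relevance, step_scores=step_scores)


def wrapper_prefix_search(
    trace: MrmrTrace,
    evaluate_prefix,
) -> WrapperResult:
    """Score every prefix of the mRMR ordering and keep the smallest best one.

    ``evaluate_prefix(genes)`` must return a cross-validated accuracy; the caller
    binds the dataset, classifier and CV protocol.  best_k is the smallest k
    attaining the maximum accuracy (exact float comparison — CV accuracies are
    ratios of identical integer counts when they tie).
    """
    if not trace.ordered_genes:
        raise ValueError("empty mRMR trace")
    curve: list[tuple[int, float]] = []
    for k in range(1, len(trace.ordered_genes) + 1):
        acc = float(evaluate_prefix(trace.ordered_genes[:k]))
        curve.append((k, acc))
    best_acc = max(acc for _, acc in curve)
    best_k = min(k for k, acc in curve if acc == best_acc)
    return WrapperResult(
        best_k=best_k,
        cv_accuracy_by_k=curve,
        selected_genes=trace.ordered_genes[:best_k],
    )


def write_mrmr_trace(trace: MrmrTrace, path) -> None:
    with open(path, "w") as fh:
        fh.write("step\tgene\tobjective\n")
        for i, (g, v) in enumerate(zip(trace.ordered_genes, trace.step_scores), start=1):
            fh.write(f"{i}\t{g}\t{v:.4f}\n")


def write_wrapper_curve(result: WrapperResult, path) -> None:
    with open(path, "w") as fh:
        fh.write("k\tcv_accuracy\n")
        for k, acc in result.cv_accuracy_by_k:
            fh.write(f"{k}\t{acc:.4f}\n")
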