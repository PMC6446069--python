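"""Greedy one-vs-rest classification tree over the treatment-survival classes.

At every level the remaining classes are each evaluated one-vs-rest with the
full per-node pipeline (filter selection, mRMR ranking, wrapper prefix search,
balanced cross-validation); the best-classified class becomes the node, its
samples are removed, and the search repeats until two classes remain and a
plain binary leaf finishes the tree.  Six classes therefore yield exactly five
nodes, each with its own small biomarker panel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from survtree.classification_eval import (
    ClassifierSpec,
    ConfusionSummary,
    Metrics,
    cross_validate,
    make_classifier,
)
from survtree.cohort_io import CLASS_LABELS, LabeledCohort
from survtree.filter_selection import fallback_scores, filter_genes, mdl_discretize
from survtree.imbalance import BalanceSpec, balance_training
from survtree.mrmr_selection import MrmrTrace, WrapperResult, mrmr_rank, wrapper_prefix_search

logger = logging.getLogger(__name__)

_CLASS_ORDER = {c: i for i, c in enumerate(CLASS_LABELS)}


@dataclass
class PipelineConfig:
    """All knobs of the per-node pipeline and the greedy search.

    ``mode`` selects where feature selection happens: ``paper_faithful`` (the
    default) selects on all node samples before cross-validation, as in the
    motivating study; ``strict_nested`` repeats filter+mRMR inside every
    training fold, avoiding selection leakage at extra cost.  One global seed
    fans out deterministically to fold assignment, balancing and classifiers.
    """

    filter_alpha: float = 0.05
    mrmr_max_k: int = 30
    balance: BalanceSpec = field(default_factory=BalanceSpec)
    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)
    cv_k: int = 10
    mode: str = "paper_faithful"
    balance_before_cv: bool = False  # workbench-style: balance once, then CV
    on_empty_filter: str = "error"  # or "fallback": top-k by chi2 when rule keeps none
    fallback_k: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("paper_faithful", "strict_nested"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.on_empty_filter not in ("error", "fallback"):
            raise ValueError("on_empty_filter must be 'error' or 'fallback'")

    def node_seed(self, level: int, positive_class: str) -> int:
        return (self.seed * 7919 + level * 613 + _CLASS_ORDER[positive_class] * 31) % (2**31)


class EmptyFilterError(ValueError):
    """Raised when the filter retains no gene for a node's positive class."""


@dataclass
class NodeResult:
    node_index: int  # 1-based level in the tree
    positive_class: str
    rest_classes: list[str]
    is_leaf: bool
    selected_genes: list[str]
    metrics: Metrics
    confusion: ConfusionSummary
    candidate_table: dict[str, float]
    wrapper_curve: list[tuple[int, float]]
    mrmr_order: list[str]
    n_filtered: int
    filter_fallback: bool = False


@dataclass
class HierarchyModel:
    nodes: list[NodeResult]
    class_order: list[str]  # elimination order; last entry is the leaf pair "A|B"
    run_metadata: dict

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)


def _node_matrix(cohort: LabeledCohort, genes: list[str]) -> np.ndarray:
    rows = [cohort.expression.gene_index(g) for g in genes]
    return cohort.expression.values[rows].T  # samples x genes


def evaluate_node(
    cohort: LabeledCohort,
    positive_class: str,
    config: PipelineConfig,
    level: int = 1,
    is_leaf: bool = False,
) -> NodeResult:
    """Run the full pipeline for one candidate node: positive_class vs rest."""
    y = cohort.binary_labels(positive_class)
    if y.sum() < 2:
        raise ValueError(f"class {positive_class} has fewer than 2 samples")
    expr = cohort.expression
    seed = config.node_seed(level, positive_class)

    scores = filter_genes(expr.values, expr.gene_ids, y, alpha=config.filter_alpha)
    fallback = False
    if not scores:
        if config.on_empty_filter == "error":
            raise EmptyFilterError(
                f"filter retained no genes for class {positive_class} at level {level}"
            )
        fallback = True
        scores = fallback_scores(expr.values, expr.gene_ids, y, k=config.fallback_k)
        logger.warning(
            "class %s level %d: filter kept nothing; falling back to top-%d by chi2",
            positive_class, level, config.fallback_k,
        )
    candidates = [s.gene_id for s in scores]
    discs = {g: mdl_discretize(expr.values[expr.gene_index(g)], y) for g in candidates}
    trace = mrmr_rank(candidates, expr.values, expr.gene_ids, y, config.mrmr_max_k, discs)

    def evaluate_prefix(genes: list[str]) -> float:
        X = _node_matrix(cohort, genes)
        _, m = cross_validate(
            X, y, expr.sample_ids, config.classifier, config.balance,
            k=config.cv_k, seed=seed, balance_before_cv=config.balance_before_cv,
        )
        return m.accuracy

    wrapper = wrapper_prefix_search(trace, evaluate_prefix)

    if config.mode == "strict_nested":
        confusion, metrics = _nested_cv(cohort, y, config, seed)
    else:
        X = _node_matrix(cohort, wrapper.selected_genes)
        confusion, metrics = cross_validate(
            X, y, expr.sample_ids, config.classifier, config.balance,
            k=config.cv_k, seed=seed, balance_before_cv=config.balance_before_cv,
        )

    rest = sorted({c for c in cohort.labels.values() if c != positive_class})
    return NodeResult(
        node_index=level,
        positive_class=positive_class,
        rest_classes=rest,
        is_leaf=is_leaf,
        selected_genes=wrapper.selected_genes,
        metrics=metrics,
        confusion=confusion,
        candidate_table={},
        wrapper_curve=wrapper.cv_accuracy_by_k,
        mrmr_order=trace.ordered_genes,
        n_filtered=len(candidates),
        filter_fallback=fallback,
    )


def _nested_cv(
    cohort: LabeledCohort,
    y: np.ndarray,
    config: PipelineConfig,
    seed: int,
) -> tuple[ConfusionSummary, Metrics]:
    """Leakage-free evaluation: filter+mRMR+panel choice repeated per training fold."""
    from survtree.classification_eval import ConfusionSummary, compute_metrics, fit_predict, stratified_folds

    expr = cohort.expression
    folds = stratified_folds(y, config.cv_k, seed)
    predicted = np.full(y.size, -1, dtype=int)
    for fold in range(config.cv_k):
        test_mask = folds == fold
        if not test_mask.any():
            continue
        tr = ~test_mask
        Xtr_all = expr.values[:, tr]
        scores = filter_genes(Xtr_all, expr.gene_ids, y[tr], alpha=config.filter_alpha)
        if not scores:
            scores = fallback_scores(Xtr_all, expr.gene_ids, y[tr], k=config.fallback_k)
        candidates = [s.gene_id for s in scores]
        trace = mrmr_rank(candidates, Xtr_all, expr.gene_ids, y[tr], config.mrmr_max_k)

        def eval_prefix(genes: list[str]) -> float:
            rows = [expr.gene_index(g) for g in genes]
            _, m = cross_validate(
                expr.values[rows][:, tr].T, y[tr], [expr.sample_ids[i] for i in np.flatnonzero(tr)],
                config.classifier, config.balance, k=min(5, config.cv_k),
                seed=seed + 1 + fold,
            )
            return m.accuracy

        wrapper = wrapper_prefix_search(trace, eval_prefix)
        rows = [expr.gene_index(g) for g in wrapper.selected_genes]
        bt = balance_training(
            expr.values[rows][:, tr].T, y[tr], config.balance, seed=config.balance.seed + fold
        )
        predicted[test_mask] = fit_predict(
            config.classifier, bt.X, bt.y, expr.values[rows][:, test_mask].T, bt.sample_weight
        )
    tp = int(np.sum((predicted == 1) & (y == 1)))
    fp = int(np.sum((predicted == 1) & (y == 0)))
    tn = int(np.sum((predicted == 0) & (y == 0)))
    fn = int(np.sum((predicted == 0) & (y == 1)))
    confusion = ConfusionSummary(tp, fp, tn, fn, dict(zip(expr.sample_ids, predicted.tolist())))
    return confusion, compute_metrics(confusion)


def build_tree(cohort: LabeledCohort, config: PipelineConfig) -> HierarchyModel:
    """Greedy construction of the one-vs-rest hierarchy.

    At each level every remaining class is evaluated one-vs-rest; the class with
    the highest CV accuracy wins (ties: fewer selected genes, then the fixed
    order DH < DR < LH < DS < LS < LR).  The final two classes form a direct
    binary leaf whose positive label is the lexicographically smaller class.
    """
    present = [c for c in CLASS_LABELS if any(v == c for v in cohort.labels.values())]
    if len(present) < 3:
        raise ValueError("greedy hierarchy needs at least 3 classes")
    current = cohort
    remaining = list(present)
    nodes: list[NodeResult] = []
    order: list[str] = []
    level = 1

    while len(remaining) > 2:
        results: dict[str, NodeResult] = {}
        for c in remaining:
            res = evaluate_node(current, c, config, level=level)
            results[c] = res
            logger.info(
                "level %d candidate %s: accuracy %.4f with %d genes",
                level, c, res.metrics.accuracy, len(res.selected_genes),
            )
        winner = min(
            remaining,
            key=lambda c: (
                -results[c].metrics.accuracy,
                len(results[c].selected_genes),
                _CLASS_ORDER[c],
            ),
        )
        node = results[winner]
        node.candidate_table = {c: results[c].metrics.accuracy for c in remaining}
        nodes.append(node)
        order.append(winner)
        keep = [s for s in current.expression.sample_ids if current.labels[s] != winner]
        current = current.subset(keep)
        remaining.remove(winner)
        level += 1

    # binary leaf on the last two classes
    a, b = sorted(remaining)
    leaf = evaluate_node(current, a, config, level=level, is_leaf=True)
    leaf.candidate_table = {a: leaf.metrics.accuracy, b: leaf.metrics.accuracy}
    nodes.append(leaf)
    order.append(f"{a}|{b}")

    metadata = {
        "config": _config_dict(config),
        "class_order": order,
        "n_classes": len(present),
        "leaf_positive": a,
    }
    return HierarchyModel(nodes=nodes, class_order=order, run_metadata=metadata)


def _config_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    return d


def fit_cascade(model: HierarchyModel, cohort: LabeledCohort):
    """Refit each node's classifier on all its samples for deployment.

    Cross-validated models are fold-specific, so prediction uses classifiers
    refit on the full node data (balanced per the run's BalanceSpec) restricted
    to the node's selected panel.
    """
    config = model.run_metadata["config"]
    balance = BalanceSpec(**config["balance"])
    clf_spec = ClassifierSpec(**config["classifier"])
    fitted = []
    current = cohort
    for node in model.nodes:
        X = _node_matrix(current, node.selected_genes)
        y = current.binary_labels(node.positive_class)
        bt = balance_training(X, y, balance, seed=balance.seed)
        clf = make_classifier(clf_spec)
        if bt.sample_weight is not None:
            clf.fit(bt.X, bt.y, sample_weight=bt.sample_weight)
        else:
            clf.fit(bt.X, bt.y)
        fitted.append((node, clf))
        if not node.is_leaf:
            keep = [
                s for s in current.expression.sample_ids
                if current.labels[s] != node.positive_class
            ]
            current = current.subset(keep)
    return fitted


def predict_cascade(
    model: HierarchyModel,
    cohort: LabeledCohort,
    sample: dict[str, float],
    fitted=None,
) -> str:
    """Route one expression vector (gene id -> value) through the fitted tree.

    The first node whose classifier votes positive claims the sample; the leaf
    decides between the final two classes.  Missing panel genes are an error.
    """
    needed = sorted({g for node in model.nodes for g in node.selected_genes})
    missing = [g for g in needed if g not in sample]
    if missing:
        raise KeyError(f"sample is missing panel genes: {missing}")
    if fitted is None:
        fitted = fit_cascade(model, cohort)
    for node, clf in fitted:
        x = np.array([[sample[g] for g in node.selected_genes]])
        vote = int(clf.predict(x)[0])
        if node.is_leaf:
            other = [c for c in node.rest_classes][0]
            return node.positive_class if vote == 1 else other
        if vote == 1:
            return node.positive_class
    raise AssertionError("cascade must terminate at the leaf")
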