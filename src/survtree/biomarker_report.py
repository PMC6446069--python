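"""Post-hoc biomarker characterization and report writers.

For each node's gene panel this module reports the regulation direction of every
panel gene (up/down in the positive class relative to the rest, with Tukey
boxplot five-number summaries) and the class-conditional Pearson correlation
network among panel genes (edges kept at p < alpha, computed separately in the
positive-class samples and the rest so class-specific co-expression stands out).
"""

from __future__ import annotations

import json
import logging
import pathlib
from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

from survtree.cohort_io import LabeledCohort
from survtree.greedy_hierarchy import HierarchyModel, NodeResult

logger = logging.getLogger(__name__)


@dataclass
class BoxplotSummary:
    """Tukey five-number summary: whiskers clip at 1.5*IQR beyond the quartiles."""

    gene_id: str
    group: str  # "positive" | "rest"
    minimum: float
    q1: float
    median: float
    q3: float
    maximum: float
    outliers: list[float]


@dataclass
class CorrelationEdge:
    gene_a: str
    gene_b: str
    r: float
    pvalue: float
    group: str


def five_number_summary(gene_id: str, group: str, values: np.ndarray) -> BoxplotSummary:
    """Quartiles by linear interpolation; whisker min/max exclude 1.5*IQR outliers."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty group")
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inliers = values[(values >= lo) & (values <= hi)]
    outliers = sorted(values[(values < lo) | (values > hi)].tolist())
    return BoxplotSummary(
        gene_id, group,
        minimum=float(inliers.min()), q1=float(q1), median=float(med),
        q3=float(q3), maximum=float(inliers.max()), outliers=outliers,
    )


def regulation_direction(
    positive_values: np.ndarray,
    rest_values: np.ndarray,
    gene_id: str = "",
) -> tuple[str, BoxplotSummary, BoxplotSummary]:
    """Classify a panel gene as up-, down-regulated or flat in the positive class.

    Direction compares group medians (up when the positive-class median exceeds
    the rest median), mirroring how boxplot pairs are read.
    """
    pos = five_number_summary(gene_id, "positive", positive_values)
    rest = five_number_summary(gene_id, "rest", rest_values)
    if pos.median > rest.median:
        direction = "up"
    elif pos.median < rest.median:
        direction = "down"
    else:
        direction = "flat"
    return direction, pos, rest


def correlation_network(
    expression: np.ndarray,
    gene_ids: list[str],
    group: str,
    alpha: float = 0.05,
) -> list[CorrelationEdge]:
    """Significant Pearson edges among panel genes within one sample group.

    p-values come from the two-sided t transform t = r*sqrt((n-2)/(1-r^2));
    zero-variance genes are skipped with a warning.  Edges are returned with
    gene_a < gene_b so the network is order-independent.
    """
    expression = np.asarray(expression, dtype=float)
    n_genes, n_samples = expression.shape
    if n_samples < 3:
        raise ValueError("need at least 3 samples for a correlation network")
    if n_genes < 2:
        raise ValueError("need at least 2 genes")
    variable = [i for i in range(n_genes) if np.std(expression[i]) > 0]
    skipped = set(range(n_genes)) - set(variable)
    if skipped:
        logger.warning("skipping zero-variance genes: %s", [gene_ids[i] for i in sorted(skipped)])
    edges: list[CorrelationEdge] = []
    for ai in range(len(variable)):
        for bi in range(ai + 1, len(variable)):
            i, j = variable[ai], variable[bi]
            r, p = stats.pearsonr(expression[i], expression[j])
            if p < alpha:
                a, b = sorted((gene_ids[i], gene_ids[j]))
                edges.append(CorrelationEdge(a, b, float(r), float(p), group))
    return edges


def node_networks(
    cohort: LabeledCohort,
    node: NodeResult,
    alpha: float = 0.05,
) -> list[CorrelationEdge]:
    """Positive-class and rest networks for one node's panel, concatenated."""
    rows = [cohort.expression.gene_index(g) for g in node.selected_genes]
    pos_ids = cohort.samples_of(node.positive_class)
    rest_ids = [s for s in cohort.expression.sample_ids if cohort.labels[s] != node.positive_class]
    edges: list[CorrelationEdge] = []
    for group, ids in (("positive", pos_ids), ("rest", rest_ids)):
        if len(ids) < 3 or len(rows) < 2:
            continue
        sub = cohort.expression.subset_samples(ids)
        edges.extend(correlation_network(sub.values[rows], node.selected_genes, group, alpha))
    return edges


def _fmt(x: float) -> str:
    return f"{x:.4f}"


def model_to_dict(model: HierarchyModel) -> dict:
    nodes = []
    for node in model.nodes:
        d = asdict(node)
        d["confusion"] = {k: d["confusion"][k] for k in ("tp", "fp", "tn", "fn")}
        nodes.append(d)
    return {"nodes": nodes, "class_order": model.class_order, "run_metadata": model.run_metadata}


def write_reports(
    model: HierarchyModel,
    cohort: LabeledCohort,
    outdir,
    alpha: float = 0.05,
    sweep_table: dict[str, dict[str, float]] | None = None,
) -> dict[str, pathlib.Path]:
    """Write the full report bundle for a fitted hierarchy.

    Files: model.json (full machine-readable model), panels.tsv (one gene column
    per node), node_metrics.tsv, regulation.tsv, edges.tsv, links.txt
    (circos-style gene_a gene_b r), and comparison.tsv when a classifier sweep
    table is supplied.  All numeric cells use 4 decimals; reruns with the same
    seed are byte-identical.
    """
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, pathlib.Path] = {}

    paths["model"] = outdir / "model.json"
    paths["model"].write_text(json.dumps(model_to_dict(model), indent=2, sort_keys=True))

    # panels.tsv: node columns, genes listed downward
    paths["panels"] = outdir / "panels.tsv"
    headers = [
        f"node{n.node_index}_{n.positive_class if not n.is_leaf else '_vs_'.join([n.positive_class] + n.rest_classes)}"
        for n in model.nodes
    ]
    depth = max(len(n.selected_genes) for n in model.nodes)
    with open(paths["panels"], "w") as fh:
        fh.write("\t".join(headers) + "\n")
        for i in range(depth):
            row = [n.selected_genes[i] if i < len(n.selected_genes) else "" for n in model.nodes]
            fh.write("\t".join(row) + "\n")

    paths["node_metrics"] = outdir / "node_metrics.tsv"
    with open(paths["node_metrics"], "w") as fh:
        fh.write(
            "node\tpositive_class\tclassifier\taccuracy\tsensitivity\tspecificity\tf1"
            "\ttp\tfp\ttn\tfn\tn_genes\n"
        )
        kind = model.run_metadata["config"]["classifier"]["kind"]
        for n in model.nodes:
            m, c = n.metrics, n.confusion
            fh.write(
                f"{n.node_index}\t{n.positive_class}\t{kind}\t{_fmt(m.accuracy)}"
                f"\t{_fmt(m.sensitivity)}\t{_fmt(m.specificity)}\t{_fmt(m.f1)}"
                f"\t{c.tp}\t{c.fp}\t{c.tn}\t{c.fn}\t{len(n.selected_genes)}\n"
            )

    if sweep_table is not None:
        paths["comparison"] = outdir / "comparison.tsv"
        kinds = sorted({k for row in sweep_table.values() for k in row})
        with open(paths["comparison"], "w") as fh:
            fh.write("node\t" + "\t".join(kinds) + "\n")
            for node_name, row in sweep_table.items():
                fh.write(node_name + "\t" + "\t".join(_fmt(row[k]) for k in kinds) + "\n")

    # regulation + networks are computed on each node's own sample subset
    paths["regulation"] = outdir / "regulation.tsv"
    paths["edges"] = outdir / "edges.tsv"
    paths["links"] = outdir / "links.txt"
    current = cohort
    with open(paths["regulation"], "w") as reg, open(paths["edges"], "w") as edg, open(
        paths["links"], "w"
    ) as lnk:
        reg.write(
            "node\tgene\tdirection\tpositive_median\trest_median"
            "\tpos_min\tpos_q1\tpos_q3\tpos_max\trest_min\trest_q1\trest_q3\trest_max\n"
        )
        edg.write("node\tgroup\tgene_a\tgene_b\tr\tpvalue\n")
        for node in model.nodes:
            pos_ids = current.samples_of(node.positive_class)
            rest_ids = [
                s for s in current.expression.sample_ids
                if current.labels[s] != node.positive_class
            ]
            for g in node.selected_genes:
                gi = current.expression.gene_index(g)
                pos_vals = current.subset(pos_ids).expression.values[gi]
                rest_vals = current.subset(rest_ids).expression.values[gi]
                direction, ps, rs = regulation_direction(pos_vals, rest_vals, g)
                reg.write(
                    f"{node.node_index}\t{g}\t{direction}\t{_fmt(ps.median)}\t{_fmt(rs.median)}"
                    f"\t{_fmt(ps.minimum)}\t{_fmt(ps.q1)}\t{_fmt(ps.q3)}\t{_fmt(ps.maximum)}"
                    f"\t{_fmt(rs.minimum)}\t{_fmt(rs.q1)}\t{_fmt(rs.q3)}\t{_fmt(rs.maximum)}\n"
                )
            for e in node_networks(current, node, alpha):
                edg.write(
                    f"{node.node_index}\t{e.group}\t{e.gene_a}\t{e.gene_b}"
                    f"\t{_fmt(e.r)}\t{e.pvalue:.4g}\n"
                )
                if e.group == "positive":
                    lnk.write(f"{e.gene_a} {e.gene_b} {_fmt(e.r)}\n")
            if not node.is_leaf:
                current = current.subset(rest_ids)

    logger.info("wrote reports to %s", outdir)
    return paths
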