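#!/usr/bin/env python
"""Replication studies: elimination-order recovery and null calibration.

Part 1 replays the greedy search over 10 seeded cohorts with strictly graded
per-class effect sizes (equal class sizes so node accuracies are comparable)
and counts how often the elimination order tracks the effect-size ordering.
Part 2 runs the pipeline on a zero-effect cohort in leakage-free nested mode
and reports each node's accuracy deviation from the rest-class proportion in
binomial standard errors, plus the null correlation-edge retention rate.
Tables land under results/.
"""

import pathlib
import sys

import numpy as np

ROOT = pathlib.Path(__file__).resolve().parent.parent

from survtree.biomarker_report import correlation_network
from survtree.cohort_io import assemble_cohort
from survtree.greedy_hierarchy import build_tree
from survtree.presets import GRADED_EFFECTS, null_calibration_study, order_recovery_study
from survtree.synthetic_cohort import simulate


def order_study(seed: int, out: pathlib.Path) -> None:
    expected = sorted(GRADED_EFFECTS, key=lambda c: -GRADED_EFFECTS[c])[:4]
    rows, matches = [], 0
    for rep in range(10):
        sim, pipe = order_recovery_study(seed * 1000 + rep)
        expr, clinical, _ = simulate(sim, effect_size_per_class=GRADED_EFFECTS)
        model = build_tree(assemble_cohort(expr, clinical), pipe)
        ok = model.class_order[:4] == expected
        matches += ok
        rows.append((rep, " ".join(model.class_order), int(ok)))
    with open(out / "order_recovery.tsv", "w") as fh:
        fh.write("replicate\telimination_order\tmatches_effect_ordering\n")
        for r in rows:
            fh.write("\t".join(map(str, r)) + "\n")
    print(f"order recovery: {matches}/10 replicates match {' > '.join(expected)}")


def null_study(seed: int, out: pathlib.Path) -> None:
    sim, pipe = null_calibration_study(seed)
    expr, clinical, _ = simulate(sim)
    cohort = assemble_cohort(expr, clinical)
    model = build_tree(cohort, pipe)
    remaining = dict(cohort.class_counts())
    with open(out / "null_calibration.tsv", "w") as fh:
        fh.write("node\tpositive_class\taccuracy\trest_proportion\tz\n")
        for node in model.nodes:
            total = sum(remaining.values())
            p0 = (total - remaining[node.positive_class]) / total
            se = np.sqrt(p0 * (1 - p0) / total)
            z = (node.metrics.accuracy - p0) / se
            fh.write(
                f"{node.node_index}\t{node.positive_class}\t{node.metrics.accuracy:.4f}"
                f"\t{p0:.4f}\t{z:+.2f}\n"
            )
            print(f"  null node {node.node_index} [{node.positive_class}]: "
                  f"accuracy {node.metrics.accuracy:.4f} vs baseline {p0:.4f} (z={z:+.2f})")
            if not node.is_leaf:
                remaining.pop(node.positive_class)

    rng = np.random.default_rng(seed + 50_000)
    retained = total_pairs = 0
    for _ in range(50):
        noise = rng.normal(size=(10, 40))
        retained += len(correlation_network(noise, [f"g{i}" for i in range(10)], "rest"))
        total_pairs += 45
    print(f"  null edge retention at alpha 0.05: {retained / total_pairs:.4f} "
          f"({retained}/{total_pairs} pairs)")


def main(seed: int = 1) -> None:
    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    order_study(seed, out)
    null_study(seed, out)
    print(f"tables under {out}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
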