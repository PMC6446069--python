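import numpy as np
import pytest

from survtree.filter_selection import mdl_discretize
from survtree.mrmr_selection import (
    mrmr_rank,
    mutual_information,
    mutual_information_binned,
    wrapper_prefix_search,
)


def brute_force_mid_oracle(candidates, expression, gene_ids, labels, max_k):
    """Independent greedy MID reimplementation used as the oracle.

    Recomputes relevance and redundancy from scratch with its own MI routine
    (direct double loop over the joint table) and applies the same tie rule
    (filter rank, then gene id).
    """
    lookup = {g: i for i, g in enumerate(gene_ids)}

    def mi(xb, yb):
        n = len(xb)
        total = 0.0
        for xv in set(xb.tolist()):
            for yv in set(yb.tolist()):
                pxy = sum(1 for a, b in zip(xb, yb) if a == xv and b == yv) / n
                if pxy == 0:
                    continue
                px = sum(1 for a in xb if a == xv) / n
                py = sum(1 for b in yb if b == yv) / n
                total += pxy * np.log2(pxy / (px * py))
        return max(0.0, total)

    bins = {g: mdl_discretize(expression[lookup[g]], labels).assign(expression[lookup[g]])
            for g in candidates}
    relevance = {g: mi(bins[g], labels) for g in candidates}
    rank = {g: i for i, g in enumerate(candidates)}
    selected, scores = [], []
    remaining = list(candidates)
    while len(selected) < min(max_k, len(candidates)):
        best, best_obj = None, None
        for g in remaining:
            obj = relevance[g]
            if selected:
                obj -= sum(mi(bins[g], bins[s]) for s in selected) / len(selected)
            if best_obj is None or obj > best_obj or (
                obj == best_obj and (rank[g], g) < (rank[best], best)
            ):
                best, best_obj = g, obj
        selected.append(best)
        scores.append(best_obj)
        remaining.remove(best)
    return selected, scores


def _random_instance(rng, n_genes, n_samples):
    y = rng.integers(0, 2, size=n_samples)
    while y.min() == y.max():
        y = rng.integers(0, 2, size=n_samples)
    strength = rng.uniform(0, 2.5, size=n_genes)
    expr = y[None, :] * strength[:, None] + rng.normal(size=(n_genes, n_samples))
    genes = [f"g{i}" for i in range(n_genes)]
    return genes, expr, y


@pytest.mark.parametrize("seed", range(12))
def test_mrmr_matches_brute_force_oracle(seed):
    rng = np.random.default_rng(seed)
    genes, expr, y = _random_instance(rng, rng.integers(3, 11), rng.integers(12, 50))
    trace = mrmr_rank(genes, expr, genes, y, max_k=len(genes))
    oracle_order, oracle_scores = brute_force_mid_oracle(genes, expr, genes, y, len(genes))
    assert trace.ordered_genes == oracle_order
    assert trace.step_scores == pytest.approx(oracle_scores)


def test_first_selected_gene_maximizes_relevance():
    rng = np.random.default_rng(42)
    genes, expr, y = _random_instance(rng, 8, 40)
    trace = mrmr_rank(genes, expr, genes, y, max_k=3)
    best = max(trace.relevance, key=lambda g: (trace.relevance[g], -genes.index(g)))
    assert trace.relevance[trace.ordered_genes[0]] == max(trace.relevance.values())
    assert trace.ordered_genes[0] == best or trace.relevance[best] == trace.relevance[trace.ordered_genes[0]]


def test_noisy_copy_deferred_behind_independent_gene():
    """With A, A' = noisy copy of A, and independent informative B: order starts A, B."""
    rng = np.random.default_rng(0)
    n = 60
    y = np.array([0] * 30 + [1] * 30)
    A = y * 2.0 + rng.normal(0, 1, n)
    Ap = A + rng.normal(0, 0.3, n)
    B = y * 1.5 + rng.normal(0, 1, n)
    genes = ["A", "Ap", "B"]
    trace = mrmr_rank(genes, np.vstack([A, Ap, B]), genes, y, max_k=3)
    assert trace.ordered_genes[:2] == ["A", "B"]


def test_pure_relevance_ranking_selects_more_duplicates_than_mrmr():
    """One strong gene with three near-copies: relevance ranking stacks the copies,
    mRMR spreads across the independent (weaker) sources instead."""
    rng = np.random.default_rng(7)
    n = 120
    y = np.array([0] * 60 + [1] * 60)
    strong = y * 3.0 + rng.normal(0, 1, n)
    rows = [strong] + [strong + rng.normal(0, 0.15, n) for _ in range(3)]
    genes = ["src0", "dup0_0", "dup0_1", "dup0_2"]
    dup_names = set(genes[1:])
    for i, s in enumerate((2.2, 2.0), start=1):
        rows.append(y * s + rng.normal(0, 1, n))
        genes.append(f"src{i}")
    expr = np.vstack(rows)
    trace = mrmr_rank(genes, expr, genes, y, max_k=3)
    by_relevance = sorted(genes, key=lambda g: -trace.relevance[g])[:3]
    mrmr_dupes = len(set(trace.ordered_genes[:3]) & dup_names)
    relevance_dupes = len(set(by_relevance) & dup_names)
    assert relevance_dupes >= 2  # the copy cluster dominates pure relevance
    assert mrmr_dupes < relevance_dupes  # redundancy penalty spreads across sources


def test_mutual_information_identities():
    rng = np.random.default_rng(1)
    x = rng.integers(0, 2, size=347)
    # self-information: MI(X; X) = H(X)
    p = x.mean()
    h = -(p * np.log2(p) + (1 - p) * np.log2(1 - p))
    assert mutual_information_binned(x, x) == pytest.approx(h)
    # relabeling bins leaves MI unchanged
    y = rng.integers(0, 2, size=347)
    assert mutual_information_binned(1 - x, y) == pytest.approx(mutual_information_binned(x, y))
    # independent variables: plug-in MI is small at n=347
    assert mutual_information_binned(x, y) < 0.02


def test_mutual_information_continuous_independent_is_near_zero():
    rng = np.random.default_rng(2)
    v = rng.normal(size=347)
    y = rng.integers(0, 2, size=347)
    assert mutual_information(v, y) < 0.02


def test_wrapper_smallest_k_at_max():
    from survtree.mrmr_selection import MrmrTrace

    trace = MrmrTrace(ordered_genes=list("abcdef"), relevance={}, step_scores=[0] * 6)
    curve = {1: 0.7, 2: 0.8, 3: 0.9, 4: 0.95, 5: 0.95, 6: 0.95}
    result = wrapper_prefix_search(trace, lambda genes: curve[len(genes)])
    assert result.best_k == 4  # plateau from k=4 onward
    assert result.selected_genes == list("abcd")
    assert result.cv_accuracy_by_k == [(k, curve[k]) for k in range(1, 7)]


def test_wrapper_single_gene_and_max_k_one():
    from survtree.mrmr_selection import MrmrTrace

    trace = MrmrTrace(ordered_genes=["a"], relevance={"a": 1.0}, step_scores=[1.0])
    result = wrapper_prefix_search(trace, lambda genes: 1.0)
    assert result.best_k == 1 and result.selected_genes == ["a"]


def test_perfectly_separating_gene_gives_best_k_one(small_cohort):
    """A planted, perfectly separating gene should win at k=1 in a real CV wrapper."""
    import survtree.classification_eval as ce
    from survtree.imbalance import BalanceSpec
    from survtree.mrmr_selection import MrmrTrace

    cohort = small_cohort
    y = cohort.binary_labels("DH")
    sep = np.where(y == 1, 10.0, 0.0) + np.random.default_rng(0).normal(0, 0.1, y.size)
    noise = np.random.default_rng(1).normal(size=y.size)
    expr = np.vstack([sep, noise])
    trace = MrmrTrace(ordered_genes=["sep", "noise"], relevance={}, step_scores=[0, 0])

    def eval_prefix(genes):
        rows = [0 if g == "sep" else 1 for g in genes]
        _, m = ce.cross_validate(
            expr[rows].T, y, cohort.expression.sample_ids,
            ce.ClassifierSpec(kind="naive_bayes"), BalanceSpec(method="none"), k=5, seed=0,
        )
        return m.accuracy

    assert wrapper_prefix_search(trace, eval_prefix).best_k == 1


def test_empty_candidates_error():
    with pytest.raises(ValueError):
        mrmr_rank([], np.zeros((0, 5)), [], np.array([0, 1, 0, 1, 1]), max_k=1)
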