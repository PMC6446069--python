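# Methods

## Class definition and cohort assembly

A patient enters the cohort only if exactly one of the three therapy flags
(surgery, hormone, radio) is set; patients with combined therapies (or none,
e.g. chemotherapy-only) are excluded. The survival part of the label uses a
fixed 60-month horizon: `L` when follow-up reaches 60 months (regardless of
later death), `D` when the patient died before 60 months. Living patients
censored before the horizon carry no 5-year status and are excluded — the
censoring rule is this package's choice; treating censored patients as living
would systematically inflate the L classes. Expression values are used as
provided (the intended inputs are already-normalized matrices); no
re-normalization is applied.

## Synthetic cohorts

The generator emulates normalized (log-scale) microarray intensities: gene *g*
has baseline Normal(μ_g, σ) with μ_g ~ Uniform(5, 12) and σ = 1 by default.
Each class owns `planted_per_class` genes whose mean is shifted by
`effect_size·σ` in that class only, with the sign alternating gene by gene so
both up- and down-regulated markers exist. Every planted gene gets
`redundancy_copies` noisy duplicates (source + Normal(0, 0.25σ), giving
source–copy correlation > 0.9); the duplicates exist specifically to probe
mRMR's redundancy handling. Clinical records are generated consistently with
the class label (living → follow-up ≥ 60 months, deceased → < 60, one therapy
flag), so label derivation round-trips exactly. Defaults follow the
motivating cohort's design: six classes of 132/19/20/6/130/40 samples and,
for the main study, 2,000 genes with 5 planted markers + 2 duplicates per
class at effect size 3.

What the generator does **not** model: batch effects, missingness, heavy
tails, gene–gene correlation beyond the planted duplicates, and survival-time
distributions beyond the horizon constraint. Passing tests therefore
demonstrate correctness of the machinery under the assumed location-shift
model, not performance on real cohorts.

## Filter selection

Discretization is Fayyad–Irani MDL partitioning: recursive entropy-minimizing
binary splits, each accepted only when its information gain exceeds
(log₂(N−1) + Δ)/N with Δ = log₂(3^k − 2) − [k·H(S) − k₁·H(S₁) − k₂·H(S₂)].
Entropies are base-2 with 0·log0 ≡ 0; ties in split gain resolve to the
smallest cut value, making the procedure deterministic. A gene is retained
when IG > 0 (equivalently, MDL accepts at least one split) **and** the χ²
p-value of its bins × label table is below α = 0.05 — the intersection of the
two filter scores; df = n_bins − 1, no multiple-testing correction (matching
the practice of the motivating analysis). Retained genes are ordered by IG,
then χ² statistic, then gene id.

By default filter selection (and the wrapper) runs on **all samples of the
node before cross-validation**, reproducing the protocol of the motivating
study; this leaks selection information into the CV estimate and is the reason
`strict_nested` mode exists, which repeats filter + mRMR + prefix choice
inside every training fold. Honest-generalization questions (e.g. the null
calibration study) must use `strict_nested`.

When the joint retention rule keeps nothing (a real possibility under the
null), the default is an error naming the class; `on_empty_filter="fallback"`
instead keeps the top-k genes by χ² statistic so that no-signal studies remain
total. The fallback is flagged in the node result.

## mRMR and the wrapper

The MID (difference) form is used: step 1 picks argmax I(g;Y); step t picks
argmax I(g;Y) − (1/|S|)·Σ_{s∈S} I(g;s). MI is the plug-in estimate on binned
data; every gene uses its own label-supervised discretization, also for
gene–gene MI (cached, deterministic). Ties break by filter rank then gene id.
The quotient (MIQ) form was rejected because it is ill-conditioned when
redundancy approaches zero. `max_k` (default 30) caps the ranking; the
packaged studies use 6–12 because their panels saturate far below that.

The wrapper scores every prefix of the ranking by the node's cross-validated
accuracy and returns the **smallest k attaining the maximum** — a parsimony
rule: the panel is the smallest gene set that classifies as well as any
longer prefix. Consequence: a panel is *sufficient*, not *complete*. When a
class's planted markers are individually strong (effect 3σ), CV accuracy
reaches 1.0 with 1–4 genes and the remaining markers — individually
informative but conditionally redundant — are excluded by design. Likewise, a
noisy duplicate whose estimated relevance exceeds its source's (a coin flip at
n = 347 when the copy noise is 0.25σ) can represent that marker in the panel;
mRMR's redundancy penalty prevents co-selection of source *and* copy, not
substitution of one for the other. Recovering the complete planted set would
require an anti-parsimony stopping rule, which would contradict the panel-size
efficiency argument this pipeline exists to make.

## Class balancing

Three methods, applied to the training portion of each fold only (test folds
never contain synthetic or duplicated samples): SMOTE (synthetic point =
x + u·(nn − x), u ~ U(0,1), nn among the k = 5 nearest minority neighbours,
k auto-reduced with a warning for classes smaller than 6, as the 6-sample DH
class forces); random oversampling with replacement; cost-sensitive weighting
(default cost: 1 for the majority, majority/minority for the minority, which
equalizes total class weight). `target_ratio` (default 1.0) sets the
minority/majority ratio after augmentation. A `balance_before_cv` mode
balances once before CV to mirror workbench-style protocols; it is optimistic
(synthetic points derived from test samples leak into training) and off by
default.

## Cross-validation and metrics

Stratified 10-fold CV with a custom round-robin fold assigner that tolerates
classes smaller than k (at most one minority sample per fold; folds without a
positive test sample contribute negatives only — sklearn's splitter refuses
such classes). Fold assignment is seeded independently of the classifier seed.
Pooled predictions over the folds give the confusion counts; accuracy,
sensitivity, specificity, precision and F1 follow the usual formulas, with
0/0 reported as 0 and flagged `undefined` so tabular reports stay numeric.
Backends: random forest (100 trees, √p features — the study default), Gaussian
naive Bayes, and SVMs (linear, poly-3, RBF; C = 1, γ = 1/p), all seeded and
sample-weight aware. The packaged studies shrink the forest to 60 trees —
ample for panels of ≤ 8 features.

## Greedy hierarchy

Node selection is by CV accuracy alone; ties break by smaller panel, then the
fixed class order DH < DR < LH < DS < LS < LR (the deterministic tie rule is
this package's addition). The greedy search re-runs the complete per-node
pipeline for every candidate at every level. The final two classes are a
plain binary leaf whose positive label is the lexicographically smaller class.
For deployment, `predict_cascade` refits each node's classifier on all its
samples (CV models are fold-specific) and routes a sample to the first node
voting positive.

Note that comparing one-vs-rest accuracies across classes of different sizes
favours small classes (their rest-proportion baseline is higher); the
order-recovery study therefore uses equal class sizes so that accuracy
ordering reflects effect-size ordering.

## Packaged studies (presets)

* **Planted recovery** — 2,000 genes, study class sizes, effect 3σ, 5 planted
  + 2 duplicates per class; RF(60 trees), SMOTE in-fold, wrapper cap 8.
  Expected outcome: five nodes, per-node CV accuracy ≥ 0.95 (observed 1.0),
  parsimonious panels as discussed above.
* **Order recovery** — six equal classes (60 samples each), graded effects
  2.4/2.0/1.6/1.2/0.8/0.4σ, naive Bayes nodes, 10 replicates: the elimination
  order should follow the effect grading in most replicates (observed 8–9/10).
* **Null calibration** — effect 0 everywhere, balancing off, `strict_nested`
  selection, naive Bayes. Rationale: the study asks whether held-out accuracy
  is honest under no signal, which requires leakage-free selection and a
  classifier whose predictions collapse to the class prior (a forest emits
  occasional overfit positives under the null, depressing accuracy below
  baseline for reasons unrelated to protocol honesty). Observed: every node
  within 1.7 binomial SE of its rest-class proportion; null correlation edges
  retained at ≈ 5% as designed.

Problem sizes (gene counts in the hundreds-to-thousands, 60-tree forests,
wrapper caps 6–12) are desk-scale choices that preserve every statistical
property at a few minutes per full run; the generator's `--full-scale` preset
reproduces the motivating 24,368-gene dimensionality.

## Determinism

One global seed fans out (via fixed multiplicative hashing) to the simulator,
fold assignment, balancing and classifier seeds; identical configuration gives
bit-identical models and byte-identical report files. All report numerics are
written with 4 decimals.

## Known limitations

Whole-cohort filter selection in the default mode overstates CV accuracy on
weak signals (use `strict_nested` to quantify); panels are minimal sufficient
sets, not exhaustive marker lists; χ² and correlation p-values are unadjusted
for multiplicity by design; the leaf's metrics depend on the positive-label
convention (lexicographically smaller class); accuracies of one-vs-rest nodes
with different class sizes are not directly comparable.
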