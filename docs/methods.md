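# Methods

## Problem and model

The package classifies genes as disease-associated or not, using only
*functional-enrichment* features: a gene `g` is represented by how strongly
its direct interaction-network neighborhood `G` is enriched for each
annotation term (GO-style BP/CC/MF terms and pathway gene sets).  For a
universe of `N` genes, a term annotating `M` of them, `n = |G|` and
`m = |G ∩ term|`, the feature is

    ES(g, term) = −log10 P(X ≥ m),    X ~ Hypergeometric(N, M, n),

the upper-tail (over-representation) p-value on a −log10 scale.  The tail
is inclusive (`k` runs from `m`), the summation limit is effectively
`min(n, M)` (higher terms are zero), and the score is capped at 300 so
underflowed p-values stay finite.  Genes with an empty neighborhood get an
all-zero row; the gene itself is excluded from its own neighborhood (a
flag re-includes it for sensitivity analysis).  `N` is the size of the
loaded universe, never a hard-coded human gene count.  The scores are
*features*, not inferences, so no multiple-testing correction is applied
and no term-size filter is imposed by default.

A feature-selection cascade then distils these columns:

1. **Boruta** (all-relevant filtering).  Each iteration appends one
   freshly row-permuted shadow copy per active feature, fits a random
   forest (class-balanced weights) on originals + shadows, and records a
   hit for every feature whose importance exceeds the maximum shadow
   importance (the reference percentile is configurable).  Hits are
   tested two-sidedly against Binomial(t, 0.5) with Bonferroni correction
   over the *total* feature count; significantly-above features are
   confirmed, significantly-below rejected and dropped.  Remaining
   tentatives are resolved by comparing their median importance with the
   median best-shadow importance: those below are rejected, those above
   keep weak (tentative) support — only the binomial test confirms, and
   only confirmed features continue downstream.
2. **mRMR** ranking of the confirmed features: scores are discretized
   into three bins at mean ± t·σ (t = 1, sample σ), mutual information is
   the plug-in estimate in bits, and the greedy MID criterion
   `I(f; y) − mean_{s∈S} I(f; s)` picks features one by one (MIQ is a
   config option; ties break to the smaller column index).  The label is
   used as-is.
3. **IFS**: nested prefixes of the ranking (step 5, plus the final
   partial prefix) are evaluated by stratified 10-fold cross-validation
   of a CART (Gini, unlimited depth) tree.  Inside each training fold
   only, SMOTE brings the minority class to exact parity with the
   majority: each synthetic row interpolates a minority sample toward one
   of its k = 5 nearest minority neighbors with a Uniform(0,1) weight.
   Confusion counts are pooled over folds (a single matrix keeps MCC
   well-defined with rare positives; per-fold averaging is a config
   choice away) and summarized as ACC, SN, SP, precision, F1 and MCC,
   with zero-denominator ratios defined as 0.  The best prefix maximizes
   F1, ties to the smaller prefix.
4. **Rules**: the final tree is trained on all samples (same SMOTE
   balancing) with the best prefix; each leaf becomes an IF–THEN rule
   whose per-feature conditions are tightened to single lower/upper
   bounds.  Rule supports are counted on the real (non-synthetic)
   samples so they are interpretable; rules are mutually exclusive and
   exhaustive by construction and reproduce the tree's predictions
   exactly.

## Boruta importance measure

The default importance is the z-score of out-of-bag permutation
importance: for each tree, balanced accuracy on its out-of-bag samples is
compared with the balanced accuracy after permuting one column; the
z-score is the mean drop across trees over its standard error (Breiman
scaling).  Two properties motivated this over impurity-decrease
importance (which remains available as `importance="impurity"`):

* impurity importance is computed in-sample, so on a fixed dataset a
  noise feature with a chance correlation to the labels persistently
  outranks the re-randomized shadows, and the binomial test will confirm
  it — the null calibration of the whole filter collapses.  Out-of-bag
  evaluation scores such features near zero.
* balanced accuracy matches the class-balanced training weights; with
  ~10:1 imbalance a plain accuracy drop can *reward* corrupting
  minority-informative columns.

Power scales with the square root of the tree count (the z-score is a
t-statistic) while shadow z-scores stay near a standard-normal maximum,
so the tree count should grow with the number of features: package
defaults are 500 trees and up to 100 iterations; the bundled evaluations
use 250 trees for the ~90-feature synthetic study conditions and 100
trees for the 20-feature calibration scenario.  A floor of five shadow
columns (recycling source columns before permuting) keeps the max-shadow
reference meaningful late in a run, when most features have been
rejected.

## Synthetic data: what it emulates, and what it does not

The generator stands in for the real inputs (a disease-gene catalog, an
interaction network, GO/pathway annotation): a universe of `n_genes`
(default 500) with uniformly sampled, overlapping term gene sets (90
terms: 40 BP, 20 CC, 20 MF, 10 pathway; sizes uniform on 10–30), an
Erdős–Rényi background network with edge probability
`mean_degree/(n_genes−1)` (default mean degree 8, a typical
high-confidence interactome density), 50 planted positive genes and 3
causal BP terms.  Each positive gene is assigned one *driver* causal
term; every background edge incident to it is rewired, with probability
`effect_strength` (default 0.9), so its far endpoint is a uniform draw
from the driver term's gene set.  Planting through edges (not by
annotating the positives directly) matters because the features score
the *neighbor* set; assigning a single driver term per gene (rather than
drawing from the union of causal terms) is what creates genuine
term-level neighborhood enrichment — spreading a degree-8 neighborhood
over three term sets leaves every single term barely enriched.  With
`effect_strength = 0` no rewiring happens and positives follow exactly
the background law, giving a clean null.

Deliberately not emulated: the GO DAG (no term–subterm propagation),
degree heterogeneity (scale-free hubs), STRING channel sub-scores, and
identifier mapping.  Passing recovery tests therefore show that the
cascade detects term-level neighborhood enrichment at realistic sparsity
and imbalance — not that it would rank any particular biology on real
databases, where term correlation structure is far richer.

## Numerical and design choices

* Hypergeometric tails come from the scipy survival function
  (`sf(m−1)`), tested against exact enumeration over all draws for small
  universes; p-values are clipped at 1e−320 before the log.
* Mutual information uses log base 2; any base gives the same ranking.
* Seed handling: one global seed fans out to per-stage seeds through
  `numpy.random.SeedSequence`; identical seeds give byte-identical
  artifacts, including the written datasets.
* SMOTE is applied strictly inside training folds; the held-out fold
  never contains synthetic rows.  Whether to oversample before or inside
  cross-validation is a genuinely open choice; oversampling first leaks
  interpolated copies of test points into training, so the in-fold
  placement is used even though it can depress headline metrics
  slightly.
* If Boruta confirms nothing (typical on null data), the model ranks the
  full feature set with mRMR so the downstream stages stay well-defined;
  the result is flagged (`boruta_fallback`).
* Degenerate inputs: single-class labels, classes smaller than the fold
  count, matrices without features, p-values outside (0, 1] and
  inconsistent universes all raise informative errors rather than
  propagating NaNs.

## Evaluation protocol and problem sizes

The bundled evaluation (test suite and `scripts/acceptance.py`) runs the
full cascade on the default study conditions over five replicate seeds,
plus five null replicates with the effect removed, and reports medians:
best cross-validated F1 ≈ 0.9, causal-term recall 1.0, and null
median |MCC| ≈ 0.1.  The study-scale operating point (SN 0.683,
SP 0.908, precision 0.378 at 1330 positives / 16338 negatives) is used
as *input* to verify the metric implementations reproduce the associated
ACC 0.891, F1 0.486 and MCC 0.455 from reconstructed confusion counts.

## Known limitations

* Boruta on strongly correlated features splits importance between the
  correlates; with permutation importance this is conservative (a
  redundant feature can be missed), which the mRMR stage partly offsets
  but cannot undo.
* The plug-in MI estimator is biased upward at small sample sizes; with
  three bins and n ≥ a few hundred this does not change rankings
  materially.
* Rule supports on real samples can be (0, 0) for leaves created purely
  by synthetic balancing points; such rules are kept (they are part of
  the tree) but carry no data support.
* The end-to-end F1 on synthetic data is not comparable to the
  study-scale F1: the synthetic signal is planted and strong, while real
  disease-gene labels are noisy and the feature space is ~200× larger.
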