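# Methods

## Problem setting

`tcrscreen` implements a case/control analysis of TCRβ repertoires (AIRR-seq
clonotype tables) aimed at disease classification from small marker panels.
The pipeline has five stages:

1. **Repertoire loading** — clonotype tables are canonicalized to
   `CDR3_V_J` keys with V collapsed to the gene family (`TRBV12-3*01 →
   TRBV12`) and J stripped of its allele. Rows with non-productive
   rearrangements (explicit flag, stop codon `*`, or frame-shift `_` in the
   junction) are excluded by default; duplicate keys are merged by summing
   template counts. Presence of a clonotype in a sample means its canonical
   key occurs with count ≥ 1.
2. **Diversity indexing** — six indices per sample (natural log throughout):
   Shannon H′ = −Σ pᵢ ln pᵢ, Simpson Σpᵢ², inverse Simpson 1/Σpᵢ²,
   clonality 1 − H′/ln n, V–J usage entropy (Hvj), and the singleton ratio
   n₁/(n−1). Frequencies are template-count weighted.
3. **Association screening** — Fisher's exact test on per-clonotype 2×2
   presence tables over the training split, filtered at a descending cutoff
   ladder (0.1, 10⁻², 10⁻³, 10⁻⁴) with nested result sets.
4. **Classification** — a 14-model bank (logistic, LDA, linear/polynomial
   SVM, Gaussian naive Bayes, decision tree, kNN, random forest, GBDT, a
   subsampled/regularized boosting variant, AdaBoost, bagging, a single
   hidden-layer MLP, calibrated linear SVM) evaluated on any of three feature
   views: the six indices, two-dimensional counts (total clonotypes,
   associated clonotypes present), or the 0/1 presence matrix over screened
   keys.
5. **Panel reduction** — L1-logistic paths, recursive feature elimination
   with cross-validation (RFECV, step 1), and greedy one-by-one backward
   exclusion that keeps cross-validated AUC within a tolerance of the running
   best.

## Statistical choices and conventions

* **Fisher's exact test.** Two-sided by default (sum of hypergeometric
  probabilities of all tables at the fixed margins whose probability does not
  exceed the observed one); a `case_enriched` upper-tail alternative is
  available. No multiple-testing correction is applied — the cutoff ladder is
  the error-control mechanism. Screening is strict (`p < cutoff`), except
  that a cutoff of 1 returns every observed key. Results sort by ascending
  p-value with lexicographic tie-breaks for determinism. P-values are
  memoized by table cell counts (margins are fixed cohort-wide), which makes
  screening tens of thousands of keys essentially free.
* **Diversity edge cases.** For a single-clonotype repertoire, clonality and
  singleton ratio return 0 (the formulas divide by zero; 0 is the
  no-information value). The singleton ratio keeps its published n−1
  denominator — it can exceed 1 (two singletons give 2/1) — with an optional
  `denominator="n"` switch. Hvj weights V–J pairs by template counts, not by
  clonotype multiplicity, consistent with the other indices.
* **Classification.** Case is the positive class everywhere; sensitivity is
  case recall. Scale-sensitive models (logistic, SVMs, kNN, MLP, calibrated
  SVM) are wrapped in a standardizer fitted on the training split only.
  Hard labels use a threshold of 0.5 on probabilities or 0 on decision
  values; AUC uses the continuous scores. `roc_auc` equals the Mann–Whitney
  statistic with ties counted ½. All models carry fixed seeds, making every
  evaluation bit-reproducible. The boosting variant labelled
  `xgboost_like` is gradient boosting with subsampling and a deeper,
  faster-learning configuration; it is deliberately not tied to any specific
  boosting library.
* **Leakage guard.** The associated key set is always screened on the
  training split; test-split features are built against that same list.

## Panel reduction

* **Cross-validation.** Stratified 5-fold with a fixed shuffling seed,
  *repeated* (3 repeats in RFECV and Lasso paths, 10 in the exclusion loop).
  The repeats are a numerical-precision choice: AUC measured on ~9-sample
  folds is heavily quantized, and exact score ties would otherwise dominate
  RFECV's smallest-dimension-at-the-maximum tie rule and blind the
  tolerance-0 exclusion loop to removals with true CV drops of ~0.01. The
  exclusion loop compares near-equivalent small panels, hence its finer
  estimate.
* **RFECV** eliminates one feature per iteration and returns the smallest
  dimension attaining the maximum mean CV score (fewer biomarkers win ties).
* **Backward exclusion** greedily drops the feature whose removal least
  harms (or most helps) train-CV AUC and accepts removals while the score
  stays within `tolerance` (default 0) of the running best; ties between
  candidate removals break lexicographically. The full exclusion trace is
  recorded.
* **Lasso** is an L1-penalized logistic regression; the coefficient path is
  recorded over a 21-point log-spaced grid of inverse-regularization values,
  with the operating point chosen by cross-validated accuracy unless a
  strength is given.

## Synthetic cohorts

The generator emulates the shape of a small balanced case/control AIRR-seq
study so that every stage is testable with known ground truth. Defaults: 44
training samples (22/22) and 30 test samples (15/15); ~1,000 clonotypes per
sample (±10% uniform jitter); a 5,000-clonotype shared public pool; 12
planted associated clonotypes present in a sample with probability 0.7
(cases) vs 0.05 (controls); 30% singletons; 30 V families and 13 J genes
with Dirichlet-drawn usage.

* **Clone sizes** follow a Zipf law over within-sample rank (exponent 1.1),
  after which the number of count-1 clonotypes is adjusted to exactly the
  configured singleton fraction. This yields realistic clonality values
  without fitting real data.
* **Cross-sample sharing** is deliberately much steeper than the clone-size
  law. Each pool clonotype has an independent per-sample presence
  probability q_r = min(1, (r/r₀)^−6): a core of near-ubiquitous public
  clonotypes and a sharply decaying sharing tail, with r₀ calibrated so
  expected public draws match the configured private fraction (0.2).
  This mirrors the public/private dichotomy of real repertoires and keeps
  the number of intermediate-prevalence clonotypes — the only ones on which
  a presence test can fire by chance — small: the analytic expected number
  of false screening hits at cutoff 0.01 is ≈ 1 per cohort. Top-k weighted
  sampling was rejected because it pins an O(rank)-wide fuzzy inclusion
  boundary at the per-sample draw count, flooding the test with
  intermediate-prevalence keys.
* **Planted clones** carry one fixed `CDR3_V_J` identity cohort-wide and are
  included per sample by independent Bernoulli draws at the phenotype's
  incidence.
* Everything derives from one `numpy` Generator seed; identical seeds give
  byte-identical output trees.

**What the generator does not model:** V(D)J recombination statistics,
biophysical CDR3 composition, sequencing-depth variation, batch effects, or
abundance differences of shared clones between groups. Passing tests
therefore demonstrate correctness of the statistical machinery and
recoverability of presence/absence signal at the study's scale — not
performance on real repertoires, where effect sizes are smaller and
confounding is real.

## Benchmark scales

The recovery benchmark (also recomputed by `scripts/acceptance.py`) runs the
full pipeline on default-configuration cohorts: screening at cutoff 0.01,
the nine-model presence-matrix bank, and RFECV (AdaBoost) followed by
backward exclusion with an SVM evaluator. The test suite uses 20 seeded
replicates; the acceptance script uses 5 cohorts per run, a size chosen to
keep a full from-scratch reproduction at desk scale. Typical results:
~11.8/12 planted clonotypes recovered with ~1 false key, presence-matrix
AUCs ≈ 0.99, and 2–5-marker core panels holding held-out AUC within a few
points of the full screened panel.

## Known limitations

* The greedy exclusion loop inherits the variance of small-cohort CV: on a
  minority of seeds it prunes past the reliable panel size (test AUC drops
  ~0.1) or refuses to prune below 6–7 features. This is intrinsic to
  tolerance-0 greedy selection at n = 44, not an implementation artifact.
* Fisher screening treats samples as exchangeable; systematic
  presence/absence structure (batch, depth) in real data would inflate
  discoveries.
* The two-sided test is the default even though disease-associated markers
  are typically case-enriched; the `case_enriched` alternative roughly
  halves p-values for such markers.
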