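# Methods

## The stemness index

The index is a one-class logistic regression (OCLR) signature. Let `X`
be a genes × samples training matrix in TPM-like units containing both
pluripotent samples (ESC/iPSC-like) and their differentiated
progenitors. Each gene row is centered by its mean across **all**
training samples; the penalised one-class log-likelihood

    L(w) = (1/n) Σᵢ [ sᵢ − log(1 + exp(sᵢ)) ] − (λ₂/2)·‖w‖²,  sᵢ = w·xᵢ

is then maximised over the **pluripotent columns only**. Each summand is
`−softplus(−sᵢ)`, so `L` is concave, strictly concave for λ₂ > 0, and
equal to −log 2 at w = 0. Computed via `logaddexp`, it is stable for
arbitrarily large |sᵢ|.

Why two sample classes when the regression is "one-class": if the
per-gene means are taken over exactly the samples that are fitted, the
class mean is identically zero, the gradient at w = 0 —
`(1/2n) Σ xᵢ` — vanishes, and concavity makes w = 0 the global maximum;
nothing can be learned. The differentiated progenitors serve purely as
the centering reference that gives the pluripotent class a non-zero mean
direction. `train_signature` enforces this split (and warns if asked to
fit without a reference class).

**Optimisation.** Deterministic damped Newton ascent from w = 0. The
Hessian `−(X D Xᵀ/n + λ₂ I)` (D the logistic curvature) is inverted via
the Woodbury identity, so only an n × n system is solved per step —
cheap when genes ≫ training samples, and necessary in practice: raw
TPM magnitudes make the gradient's Lipschitz constant of order 10⁴, so
first-order ascent with a safe fixed step needs ~10⁵ iterations while
Newton converges in ~10–15. Armijo backtracking (c = 10⁻⁴, halving)
keeps the objective trace monotonically non-decreasing. Convergence:
gradient max-norm < 10⁻⁶ (default), max 10 000 iterations; the
`converged` flag records the outcome. No randomness anywhere; the
`seed` argument exists only for interface symmetry. Defaults λ₂ = 1, no
L1 term, no intercept (scoring is rank-based, so an intercept would be
inert anyway). Zero-variance genes end at weight 0 and are retained —
harmless under rank scoring.

## Scoring

A sample's raw score is the Spearman correlation (average ranks for
ties) between the signature weights and the sample's expression over the
genes present in both; at least 3 shared genes are required, and
`intersect_signature` reports signature coverage (warning below 50%).
Expression is **not** re-centered or renormalised before scoring: ranks
make the score invariant to any strictly increasing per-sample
transform, which is the contract the tests assert at 10⁻¹² precision.
Samples with zero expression variance across the shared genes have no
defined rank correlation and are reported as missing, never silently
dropped.

Raw scores are min-max rescaled to [0, 1] within a rescaling cohort, so
the scale is cohort-relative. The scope is an explicit choice
(`all` pooled, the default, vs `per-tissue`); raw scores are always
emitted so users can re-scope without re-scoring. Whether
sample-filtering (e.g. removing transformed cell lines) happens before
or after rescaling changes the [0, 1] anchors but not the raw scores;
both orders are expressible (`filter_tissue_details` then score, or
score then filter) and the pooled default assumes filtering first.

## Statistical battery

* Per-group correlation screen: Pearson r per tissue between stemness
  and a numeric covariate (age in years, a marker gene's TPM, or a
  gene-set mean signal), two-sided p from the exact t transform with
  n − 2 df. Groups with fewer than `min_n` = 50 complete samples are
  skipped and listed, not tested. Benjamini–Hochberg correction is
  applied once per analysis family, across the tissues actually tested.
* Gene-set signals are arithmetic means of TPM over the set's genes
  present in the matrix (coverage-warned below 50%); a singleton set is
  exactly the marker signal.
* Group comparisons: two groups get a two-sided two-sample t-test —
  Welch by default, since equal variances are rarely defensible across
  biological groups; a `pooled` flag restores the classic form. Three
  or more groups get Kruskal–Wallis with tie correction.
* `derive_proliferation_set` reconstructs a proliferation list as the
  top 1% (configurable) of genes most positively correlated with a
  proliferation marker (PCNA-style) across samples; the normal workflow
  consumes a curated GMT instead.

## Covariate model

Per tissue, ordinary least squares of stemness on age plus
treatment-coded dummies for sex, Hardy death code and region. Hardy
codes are opaque categoricals (no ordinal structure is assumed).
Reference level = most frequent (lexicographic tie-break), recorded in
the output. A categorical with fewer than two observed levels in a
tissue is dropped and recorded (`dropped_covariates`); rows missing a
retained covariate are dropped (complete-case). Rank-deficient designs
raise, naming the aliased columns. With one response per tissue,
variance-moderation machinery (limma-style empirical Bayes) would be
inert, so plain OLS with t-based inference is used deliberately.

The summary reports `alpha` (stemness change per year) and
`log2fc = log2(ŷ(75)/ŷ(25))`, the model-predicted stemness ratio between
ages 75 and 25 at reference covariate levels — defined only when both
predictions are positive, flagged otherwise. This is one specific,
documented fold-change convention; stemness is fitted on its [0, 1]
scale, untransformed. With age as the sole regressor, sign(alpha)
equals the sign of the marginal Pearson r (algebraic identity, tested).

## Cross-tissue structure

Per subject and tissue, stemness is averaged over replicate samples;
tissues are then correlated pairwise over the subjects observed in both
(pairwise-complete, not listwise). Pairs with overlap below
`min_overlap` = 10 are masked but their n is always reported; the
default is a display-stability choice, as per-square correlations on a
handful of shared subjects are meaningless. Sex-specific tissues can be
excluded up front (they cannot overlap in subjects across sexes). The
display ordering is unweighted average-linkage clustering on 1 − r,
implemented directly with a lexicographic tie-break on cluster names so
the order is deterministic and invariant to input permutation (scipy's
linkage is the cross-check oracle in the tests, not the implementation).

## Synthetic cohorts

The generator emulates the structure the analysis assumes, with one
global seed expanded into CRC-keyed substreams (gene baselines, subject
pool, one per tissue), so adding a tissue never perturbs the others.

* **Expression**: log-normal. Gene g in sample j has
  `log x = base_g + slope_g·ℓ_j + ε`, `ε ~ N(0, noise_sd)`,
  `base_g ~ N(2, 1)`; `slope_g` is `signature_effect` (1.5) on the 100
  signature genes, `coupling_prolif` (+0.5) on the 50 proliferation
  genes (one of which is named MKI67), `coupling_senesc` (−0.5) on the
  50 senescence genes, 0 on background genes. `noise_sd` = 0.3.
* **Latent stemness** of sample j (subject s, tissue t):
  `ℓ = β_t·(age_s − 50) + sex_eff·[male] + region_eff + λ_t·u_s + N(0, 0.8)`
  with subject factor `u_s ~ N(0,1)`.
* **Study panel** (defaults): 10 tissues × 300 samples over a shared
  pool of 450 subjects (ages uniform over the six decade bins, mapped to
  midpoints 25…75 so the binning path is exercised end-to-end). Eight
  tissues decline at β = −0.02/yr — one of them, `brain_like`, with
  shared-factor loading 0 so its cross-tissue row is flat — one
  single-sex `uterus_like` tissue rises at +0.02/yr, and `null_like` has
  β = 0. These rates give per-tissue score–age correlations of ~|0.3| at
  n = 300. Two tissues carry 2–3 regions with distinct offsets so the
  region covariate is non-trivial.
* **Training cohort**: 50 pluripotent + 100 progenitor samples;
  signature genes shifted up by `signature_effect` in the pluripotent
  class only.
* `sex_age_confound` (default 0) tilts P(male) linearly in age within
  the subject pool, creating the sex-by-age imbalance used to test
  confounder adjustment. That test regresses the generator's *latent*
  stemness on age ± sex, because the latent variable is on the same
  scale as the generative β; the observed [0, 1] score is a
  cohort-dependent monotone rescaling, so comparing its slope to β
  would mix units.
* Default `n_genes` = 1200 — a desk-scale stand-in for the ~12k-gene
  matrices of real signature workflows; the signature-recovery check
  uses 2000 genes / 100 signature genes / 50 stem samples.

What the generator does **not** emulate: empirical gene–gene correlation
networks, library-size or batch artifacts, count noise (values are
continuous log-normal), non-linear age trends, and cell-type
composition shifts — the usual mechanism behind bulk stemness signals.
Passing tests therefore validate the statistical machinery and its
directional recovery under the stated generative model, not biological
conclusions on real tissue data.

## Numerical conventions and edge cases

* Duplicate gene rows on input collapse by mean (order-independent);
  duplicate sample ids are an error.
* Age bins map 20-29→25 … 70-79→75; any other bin-shaped label is an
  error, literal ages pass through.
* All-equal raw scores raise a degenerate-cohort error rather than
  emitting an arbitrary rescaling.
* BH adjustment requires p ∈ (0, 1]; exact-fit p = 0 values from
  degenerate OLS fits are clipped to 10⁻³⁰⁰ before correction.
* Missing covariate values: rows are dropped, covariates only when
  entirely uninformative (< 2 observed levels).
* Problem sizes in the validation suite (n_genes 300–2000, 100
  simulation repetitions for recovery/calibration checks) were chosen
  as the smallest scales at which the stochastic assertions have
  comfortable Monte-Carlo margins.
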