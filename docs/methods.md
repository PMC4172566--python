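# Methods

`drugclf` treats a cancer drug as a binary classifier: a mapping from
measurable cellular markers (here, gene expression) to a kill / no-kill
decision. The package implements the three analyses this framing suggests and
a synthetic-data generator that reproduces the statistical structure those
analyses assume.

## The regularized GLM engine

All three analyses share one model family. Given standardized predictors
`x` (z-scored per feature on the training data), weights `β`, and intercept
`b`, the linear predictor `z = x·β + b` is passed through an inverse link
matched to the response:

* **bernoulli** (logistic link) for binary outcomes — is this cell cancerous,
  is this line basal-like; predictions are probabilities in (0, 1);
* **gaussian** (identity link) for continuous outcomes — chemosensitivity
  measured as −log(GI50), where larger means the line is killed at a lower
  concentration.

Fitting minimizes the penalized negative log-likelihood

    bernoulli:  Σᵢ [log(1 + exp(zᵢ)) − yᵢ zᵢ] + λ·P(β)
    gaussian:   ½ Σᵢ (yᵢ − zᵢ)² + λ·P(β)

with `P(β) = Σ|βₖ|` (L1, sparsity-inducing, performs gene selection) or
`Σβₖ²` (L2, dense shrinkage). The intercept is never penalized. The single-cell
classifier (Part I) uses L2, because with only ~45 candidate genes many may
carry signal; the chemosensitivity models (Part II) use L1, because only a
small fraction of hundreds-to-thousands of genes should predict any one drug;
the two-feature drug-pair classifier (Part III) is unpenalized, because two
features cannot meaningfully overfit 40+ samples.

Solvers: L2 and unpenalized bernoulli fits use a damped Newton iteration
written for this package (bounded iterations, so perfectly separable data
terminates with large finite weights rather than diverging); L1 bernoulli fits
use scikit-learn's saga solver followed by an active-set Newton polish within
the orthant fixed by the saga signs; gaussian fits use scikit-learn's Lasso,
a closed-form SVD ridge solution, and ordinary least squares. Convergence
targets are ~1e-9 on the gradient/objective; the test suite checks every
penalty/family combination against an independent grid-search + Nelder–Mead
minimization of the same objective on small instances (tolerance 1e-3).

**Standardization.** Predictors are z-scored on the training split; the
constants are stored in the model and re-applied at prediction time.
Coefficient magnitudes are therefore comparable across genes, which is what
makes "rank genes by |weight|" meaningful. Constant (zero-variance) features
are detected exactly (zero range) and forced to zero weight.

**Penalty-strength selection.** Candidates form a 50-point logarithmic grid
from λ_max — the smallest strength at which every L1 weight is exactly zero,
`max_k |x_k · (y − ȳ)|` on the standardized design — down to 10⁻⁴ λ_max; the
same anchor is reused as a scale for L2 grids, which have no finite zeroing
point. K-fold cross-validation (stratified for binary responses, fold
assignment a deterministic function of the seed) picks the candidate with the
smallest mean held-out deviance; exact ties go to the stronger penalty. The
deviance paths are computed with warm-started solvers (Newton continuation for
L2-logistic, `lasso_path` for L1-gaussian, an SVD sweep for ridge), which is
what makes the permutation analyses below affordable.

## Part I — discriminating cancer from healthy single cells

Accuracy is estimated with *nested* 10-fold cross-validation: inner 10-fold CV
selects λ using the training split only; outer folds give every cell exactly
one score from a model that never saw it. Pooled out-of-fold scores yield an
ROC curve (thresholds swept over the unique score values) and its trapezoidal
AUC, which with half-credit ties equals the Mann–Whitney U statistic divided
by n₁·n₀ — 1 for a perfect classifier, 0.5 for a random one.

The *shuffle control* estimates the chance level by rerunning the entire
nested-CV procedure on label-permuted data (default 100 permutations) and
summarizing the null AUC distribution (mean, 2.5/97.5 percentiles).

Two learning curves quantify data requirements:

* **gene-count curve** — inside each outer training fold, a full-gene model
  ranks genes by |weight|; the design is restricted to the top k and the
  nested CV, including λ re-selection, rerun on the restriction. Ranking
  inside the fold keeps the held-out cells out of the gene selection.
* **cell-count curve** — for each training-set size, 100 iterations draw a
  class-balanced random training subset (size/2 per class, following the
  "two cancerous, two healthy" balance of the smallest case) and measure AUC
  on all held-out cells. Subsets too small for stratified inner CV (fewer than
  two cells per class) fall back to λ = 10⁻² λ_max, the geometric middle of
  the candidate grid, since no cross-validated choice exists at n = 2. Within
  an iteration the top-k refits reuse the λ selected on that subset's
  full-gene fit; re-selecting λ per k inside a 100-iteration subsample loop
  would multiply the cost without changing the qualitative curve, and at the
  subset sizes of interest the selection is noise-dominated anyway.

Confidence intervals are percentile bootstraps (1000 resamples): over cells
(resampling score/label pairs) for pooled-AUC quantities, over iteration AUCs
for subsample curves. The curves' `chance_auc` column is a score-permutation
null (labels permuted against the pooled out-of-fold scores, 100 permutations)
— a cheap per-k chance level; the full pipeline-level null remains the
shuffle-control operation.

## Part II — drugs as classifiers of expression

For each drug, sensitivity across the panel is modelled as an L1-penalized
gaussian GLM of expression. Lines missing that drug's measurement are dropped
for that drug only; at least 10 measured lines are required. Accuracy is
leave-one-out CV R² = 1 − SSE/SST on the held-out predictions (negative when
the model predicts worse than the mean), with λ re-selected inside every
training set of n−1 lines so the held-out line never influences model
selection. The R²-vs-gene-count table restricts each training set to its own
top-k genes and re-predicts; its CI is a percentile bootstrap over per-line
squared errors.

The two-gene sensitivity heatmap takes the two largest-|weight| genes from a
fit on *all* data (a descriptive choice, deliberately not cross-validated),
and interpolates the observed (expression, expression, sensitivity) triples
onto a regular grid: piecewise-linear interpolation inside the convex hull of
the observations, nearest-observation fill outside — the behaviour of the
classic scattered-data `griddata` routine. Interpolation, not smoothing: the
surface passes through the observed points.

## Part III — compound classifiers from drug pairs

Two drugs' sensitivity profiles (measured columns, or predictions from their
Part-II models — the default, since the framework defines a drug's behaviour
through its marker dependence) become the two features of an unpenalized
bernoulli GLM discriminating basal-like from luminal lines. Each candidate
pair is scored by 100 rounds of stratified 90/10 subsampling: fit on the 90%,
AUC on the held-out 10%; the pair AUC is the mean over rounds with a
percentile-bootstrap CI, and single-drug AUCs are computed on the identical
splits. Test splits that lose a class are redrawn (cap 1000, count recorded).

`search_pairs` evaluates all D(D−1)/2 unordered pairs. One shared set of
splits (drawn from the search seed) serves every pair, making pair and
single-drug AUCs directly comparable across the ranked table and the search
exactly symmetric in (A, B). Per round, all pairs are fitted simultaneously by
a batched Newton solver; per-round AUCs use the rank-based Mann–Whitney form,
which the tests pin to the trapezoidal ROC integral.

No multiple-comparison correction is applied across pairs by default; the
search is a screen, not an inference. Benjamini–Hochberg q-values over
permutation p-values are available as an opt-in, and `max_pair_auc_null`
exposes the permutation null of the *maximum* pair AUC so users can see the
selection effect directly (on pure-noise panels the best of many pairs sits
well above 0.5).

## Synthetic data

The generator provides the two dataset shapes the analyses expect, with known
ground truth for recovery tests.

**Single-cell sets** (default 45 genes, 90 + 90 cells, mirroring the
~45-gene, <200-cell single-cell PCR scale): gaussian log-expression with
per-gene baselines; a chosen number of informative genes (default 10) shifted
between populations by `effect_size` pooled SDs; optional assay-floor dropout
(a value is replaced by 0 with probability `dropout_rate`), mimicking
below-detection measurements. Default effect size 1.5 SD gives a strong but
imperfect classifier, the regime the analyses are designed for.

**Cell-line panels** (default 45 lines, 74 drugs, 500 genes — the printed
panel shape, with the gene count held at a desk-runnable scale): lines carry
two latent factors u and v; 20 genes load on u, 20 on v, the rest are
independent noise. The subtype label ("basal-like", the more aggressive
population) is u > 0. Each drug's sensitivity is a `support_size`-sparse
(default 5) linear combination of genes plus N(0, noise_sd²) noise (default
0.5, roughly a quarter of the typical signal SD). Optional pure-noise drugs
have empty support. The optional *complementary pair* plants two drugs
reading u+v and u−v through two near-noiseless marker genes: each drug alone
sees the subtype factor u diluted by v, but together they recover u — a
constructive guarantee that the pair classifies better than either drug
alone, mirroring the boosting intuition.

What the generator does **not** emulate: count noise and library-size effects
of sequencing assays, batch structure, nonlinear gene–drug relationships, and
drug–drug pharmacological interaction. Tests passing on this generator
demonstrate that the estimation machinery is correct under the model's own
assumptions, not that real tumors satisfy those assumptions.

## Numerical and design notes

* All randomness descends from one user seed through `numpy.SeedSequence`
  spawning; rerunning with the same inputs and seed reproduces every output,
  and generated datasets are byte-identical across runs.
* Ranking ties break by input column order; zero-weight features sort last.
* ROC ties receive half credit (Mann–Whitney convention).
* Probabilities are clipped to [1e-12, 1 − 1e-12] so log-losses stay finite.
* Exact support recovery by the lasso is only expected where the classical
  irrepresentable/low-correlation conditions hold. The recovery tests
  therefore use two-gene noise-free drugs (clean recovery at 45 lines × 500
  genes); for the default 5-gene drugs at this sample size the lasso provably
  keeps a few tiny compensating coefficients at the cross-validated λ, so
  recovery of larger supports is tested by ranking (planted genes in the top
  2× support size) rather than by exact active sets.
* Problem sizes in the test suite (e.g. 80-cell shuffle-control sets,
  12-drug pair-search panels, 120-gene panels in unit tests) are desk-scale
  choices that preserve each analysis's qualitative regime while keeping a
  full run of the suite comfortable on a laptop; the acceptance script runs
  the Part-I analyses at the full 45-gene / 180-cell shape.

## Limitations

Results on particular experimental datasets (a colon single-cell panel, a
breast cancer cell-line panel, specific named drugs and gene pairs) depend on
external data the package does not ship; the loaders accept such data as
plain matrices, but the package's tested guarantees are the analytic and
synthetic ones above. Sequential treatment scheduling, pharmacological synergy modelling,
and ≥3-drug cocktails are out of scope.
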