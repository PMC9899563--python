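# Methods

## Scope

`prognet` compares nine prognostic modelling approaches for post-treatment
depression outcomes under an external-validation protocol: four weighted
sum-score models (three network-centrality weightings plus one factor
weighting), cross-validated elastic-net and unpenalised regressions on
unweighted sum scores or individual items, and a null model. Every
approach is fitted separately for the continuous follow-up depressive
total and for remission (total ≤ 10), giving 18 fitted models per run.
Treatment-specific (differential) prediction, bootstrapped edge stability,
multi-factor measurement models and decision-curve analysis are out of
scope.

## Synthetic cohorts

Real patient-level trial data of this kind cannot be redistributed, so
all analyses run on synthetic multi-study cohorts with the structure the
methods assume.

* **Latent structure.** Each patient draws a severity factor
  f ~ N(μ_s, 1); the 32 baseline variables are latent Gaussians
  x_i = λ_i f + e_i with unit marginal variance. Residual covariance is
  derived from a configurable sparse partial-correlation matrix (unit-
  diagonal precision Ω = I − P, inverted, rescaled), so true conditional
  dependence beyond the factor exists for the network models to find. The
  default residual network links six substantively related symptom pairs
  (e.g. sleep/fatigue, worry/generalised anxiety) at partial correlations
  0.15–0.25.
* **Ordinal items.** Depressive items (0–3) and anxiety subscales (0–4)
  are produced by thresholding the latents at fixed standard-normal
  quantile cut-points (default marginals 0.35/0.35/0.20/0.10 and
  0.40/0.25/0.15/0.12/0.08); auxiliary totals are linearly mapped,
  rounded and clipped to their ranges. This matches the graphical-model
  treatment of items as coarsened continuous variables.
* **Between-study heterogeneity.** Each study's factor mean is shifted by
  a draw from N(0, 0.15²); *test* studies receive an extra fixed shift
  (+0.55 SD), reproducing the characteristic external-validation
  situation of a more severe test sample. On the default fixture the
  follow-up total runs ≈ 3 points higher in the test studies and the
  remission rate drops from ≈ 48% (train) to ≈ 37% (test), which is what
  makes the null model's external R² negative.
* **Outcome.** Follow-up total = 12.5 + 6·f − 0.25·support + 0.5·life
  events + 0.15·alcohol + N(0, 11²), rounded and clipped to 0–63. The
  noise SD of 11 was chosen so that most outcome variance is *not*
  explained by baseline severity (external R² around 0.2–0.3 at default
  sizes) — prognostic signal in primary-care depression is known to be
  modest, and a generator whose outcome were mostly predictable would
  make the model comparison trivially easy.
* **Sizes.** The default fixture has 3 training studies of 575 and 3 test
  studies of 300 patients, matching the cohort scale the protocol
  targets; default per-cell missingness is 0.8%, the order of magnitude
  seen in trial baseline data.

What the generator does **not** emulate: item-level response styles,
floor/ceiling artefacts beyond thresholding, missingness that depends on
severity (MNAR), treatment assignment, and within-study clustering beyond
the single mean shift. Passing tests therefore demonstrate correctness of
the machinery and behaviour of the estimators under the assumed
data-generating process — not expected performance on any real cohort.

## Missing data

Baseline variables with a missing fraction strictly below 30% are imputed
by an iterative random-forest scheme: mean initialisation, then each
incomplete variable regressed on all others (plus one-hot study
indicators, so between-study mean differences inform the fills), cycling
until the relative sum of squared changes in the imputed values increases
(the previous iterate is then kept) or an iteration cap is reached.
Ordinal variables are rounded to their valid range at the end. Variables
at or above the 30% bound are left untouched and flagged. Training-set
outcomes may be imputed (configurable); **test-set outcomes are never
imputed** — test patients without outcomes are excluded and counted. The
forest size (default 100 trees) trades accuracy for runtime; pipeline
runs in this repository use 25 trees, which changes recovered values by
far less than their ±0.5 rounding granularity.

## Fused graphical lasso

Per-study correlation matrices S_k (variables standardized within study)
enter the objective

n_k-weighted Gaussian log-likelihood + λ₁·L1 (off-diagonal) + λ₂·L1 on
all pairwise between-study precision differences,

solved by ADMM. The Θ-step is a per-study eigen-decomposition; the
consensus step is the exact proximal operator of the combined penalty,
computed elementwise: the pure fusion problem over the K study values is
solved in closed form for K ≤ 2 and, for K > 2, exactly by enumerating
the 2^(K−1) contiguous partitions of the sorted values (the optimum is
order-preserving and constant on its fused groups, so evaluating the
exact objective over all candidates is exact); soft-thresholding is
applied afterwards, which commutes with the fusion step. Numerical
choices: step parameter 1.0 with residual-balancing adaptation, tolerance
1e−6 on scaled primal/dual residuals, iteration cap 5000;
non-convergence raises with the residuals. The sparse consensus iterate
is returned (falling back to the smooth iterate if thresholding ever
leaves it non-positive-definite). The fused network is the across-study
mean of per-study partial correlations −θ_ij/√(θ_ii θ_jj).

Because the likelihood term carries the raw n_k weights, penalty values
are on the *total* (not per-sample) scale: λ₁ = 10 on studies of n ≈ 500
corresponds to a per-sample penalty of ≈ 0.02. The library defaults
follow the common per-sample-style grids (λ₁ ∈ [0.01, 1], λ₂ ∈
{0, …, 0.5}); pipeline runs in this repository pass grids scaled to their
sample sizes so that the estimated networks are genuinely sparse.
Penalties are selected by patient-level cross-validation stratified by
study, scoring held-out Gaussian log-likelihood; a single-pair grid
short-circuits the search, which the internal-cross-validation protocol
exploits to keep nested re-estimation affordable.

The three auxiliary totals are included as network nodes (32 nodes in
total) so that the centrality weightings cover every predictor the
weighted-sum models use.

## Centrality and factor weights

* EI1: signed row sum of the fused network; EI2 adds the edge-weighted
  one-step influence of neighbours, back-edges included (the standard
  expected-influence formulation).
* Communities: Walktrap on absolute edge weights, walk length 4, cut at
  maximum modularity. PC uses absolute strengths per community; PR is the
  inverse Herfindahl index of a node's normalised absolute edge weights
  (its effective number of connections) — the cited literature gives no
  formula, so this operationalisation is isolated behind one function.
  Zero-strength nodes get PC = PR = 0. The weight is √(PC·PR).
* CFA: one-factor maximum-likelihood fit (factor variance 1) on the
  pooled within-study-standardized training data, L-BFGS-B with analytic
  gradient from a leading-eigenvector start; residual variances are
  floored at 1e−6 and a fit touching the floor is flagged as a Heywood
  case. Sign convention: majority of loadings positive.
* All weight vectors are min-max rescaled to [0, 1] **within each
  instrument block** (21 depressive items; 8 anxiety subscales; the 3
  auxiliary totals), so each instrument spans the full weight range. Two
  consequences are accepted and handled explicitly: (i) the
  lowest-centrality auxiliary total always receives weight exactly 0 —
  its predictor column is constant and is dropped from the regression
  with a zero coefficient (a zero weight *is* exclusion); (ii) if
  Walktrap returns a single community, PC ≡ 0 makes the PC/PR weight
  constant, and the affected block falls back to the participation ratio
  alone, with a warning.

## Models and evaluation

Models 1–4 enter the weighted sums (and weighted auxiliary totals) into
OLS (continuous) or logistic (remission) regressions on their natural
scale. Elastic-net models standardize predictors internally, search an
(α, λ) grid by study-stratified 10-fold cross-validation (per-α λ-paths
auto-scaled from the data; minimum mean held-out MSE or deviance;
first-minimum tie-break), refit on the full training data and
back-transform coefficients. The null model stores the training outcome
mean or remission proportion.

R² is computed against the *evaluation set's own* outcome mean, so a
mis-centred constant prediction goes negative; the null model's R² is
always computed by this formula (it is ≤ 0 by construction, with equality
only when the stored training mean equals the evaluation mean).
Internal cross-validation re-runs the entire pipeline — penalty
selection, network, CFA, elastic-net tuning, final fits — inside each
training fold, pools the held-out predictions, and computes each metric
once on the pooled vector (stable for R², unlike per-fold averaging).
Calibration bins keep a trailing partial bin flagged rather than merging
it, preserving the fixed-size contract for all full bins. Predicted
scores are rounded half-up before severity categorisation (0–13 / 14–19 /
20–28 / 29–63).

Leakage control: weights, imputation models and hyperparameters are
derived from training studies only; the pipeline hashes the test tables
before and after fitting and fails if they changed, and a regression test
verifies that perturbing the test studies leaves every training-derived
weight and coefficient bit-identical.

## Determinism and problem sizes

Every stochastic stage (generation, missingness, imputation forests, fold
assignments, saga solver) draws its seed deterministically from the
single master seed, so a run is a pure function of its configuration.
Repository runs (tests and `scripts/acceptance.py`) use the default
fixture with fixed network penalties (λ₁ = 10, λ₂ = 5 on the total-scale
objective), a compact elastic-net grid (α ∈ {0.5, 1.0}, 15-value λ path,
4 folds), 25-tree imputation forests and 5-fold internal cross-validation
— sizes chosen so a full comparison completes in a few minutes on one
workstation; all grids widen to the library defaults by configuration.

## Known limitations

* Pearson correlations of ordinal items feed the FGL (no polychoric
  option); with 4-category items this attenuates edges somewhat.
* The elastic-net λ grid is searched per α on per-α paths, so the
  selected (α, λ) pair is only optimal over the constructed grid.
* Single imputation only — imputation uncertainty is not propagated.
* The PR formula is one reasonable reading of "participation ratio";
  alternatives exist in the literature.
* CFA assumes a single factor for all 32 variables; on data with strong
  multidimensionality the loadings (and hence model 4's weights) are a
  projection, not a description.
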