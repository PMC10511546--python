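# Methods

## The model and the question

Brain-age prediction treats chronological age as the regression target and
regional structural-MRI morphometry as the predictors, fitted in typically
developing subjects. The scientific question this package is organised
around is comparative: does the *meso-scale organisation* of cortical
morphometry — captured per subject as a morphometric similarity network
(MSN) — predict age in late childhood/adolescence better than the simple
regional features it is built from? The pipeline therefore trains and
evaluates ten models side by side (seven single morphometric features, all
features concatenated, MSN nodal strength, MSN edge weights) under one
shared protocol, and then screens the resulting brain-age delta
(Δ = predicted − actual age) for nuisance associations.

## Morphometric similarity networks

For each subject the 68 Desikan-Killiany regions each carry 7 features
(surface area, curvature index, folding index, Gaussian and mean
curvature, cortical thickness, cortical volume). Each feature is z-scored
across the 68 regions (population SD), making the 7-vector "feature
profile" of every region scale-free; the MSN edge between two regions is
the Pearson correlation of their profiles (n = 7 points per correlation —
small by design; edges are used as features, not as individually tested
effects). The matrix is kept unthresholded by default. Density
thresholding retains the top round-half-even(d · 2278) edges by absolute
weight with deterministic tie-breaking (|w| descending, then row, then
column index), so edge sets are nested across densities. Normalised nodal
strength is the sum of a node's surviving edge weights divided by its
degree (= its mean edge weight when unthresholded); global strength is the
mean nodal strength. A zero-variance regional profile (possible only in
degenerate synthetic input) is a hard error rather than a silent NaN edge.

## Synthetic cohort generator

The generator stands in for a 17-site public developmental release and is
the package's test bed. What it emulates:

* **Demographics** — ages from a truncated normal on [6.5, 16.9] whose
  *parent* parameters are solved numerically so the realised (truncated)
  mean/SD hit the configured 12.4 / 2.5 years; ~79% male; IQ ~N(110, 15²)
  with ~6% missing.
* **Morphometry** — value = (baseline + age trend + latent factor +
  subject offset + site offset) × site scale + iid noise. Baselines vary
  by region; per-feature linear age slopes default to strongest on
  cortical thickness (−0.035 mm/yr, 0.35 noise-SD/yr) and volume, and
  essentially zero on the curvature features. A per-subject, per-feature
  offset shared across regions models stable individual differences; it is
  what bounds attainable prediction accuracy (for thickness,
  0.06 mm ÷ 0.035 mm/yr ≈ 1.7 yr irreducible error, i.e. test R² in the
  0.3–0.6 range at these cohort sizes).
* **Age-varying coupling** — a rank-1 latent factor with region loadings
  that rotate with age, u(a) = λ·(cos θ·U₀ + sin θ·U₁),
  θ = 0.08 rad/yr × (a − 12.4), score g ~ N(1, 0.5²). Loadings concentrate
  on thickness and volume (λ = 0.8 noise-SD) and are near zero on the
  curvature features (λ = 0.1). This makes the inter-regional correlation
  structure — and hence MSN edges — drift with age while keeping
  curvature-type feature sets age-null. A uniform loading across features
  was rejected at design time because it leaked age signal into every
  feature set and made edges outperform thickness, inverting the intended
  regime (thickness strongest, edges intermediate, curvature null).
* **QA metrics** — six site-batched spatial quality scalars with QAP-style
  names (cnr, efc, fber, fwhm, qi1, snr) and realistic orientations (efc,
  fwhm, qi1: higher is worse). ~4% of subjects are deliberately degraded
  on 2–4 metrics by 3 within-site SD to exercise the QC filter.

What it does **not** emulate: cortical geometry, spatially structured
noise, scanner-specific covariance of QA metrics, non-Gaussian feature
distributions, or site-by-age confounding. Passing tests therefore show
the *pipeline* behaves correctly under a known generative model, not that
the substantive findings transfer to any real cohort.

## Quality control and harmonisation

QA metrics are z-scored within site (population SD by default; ddof
configurable since the convention is not fixed by any authority),
re-signed so larger z = better quality, failed at z < −1.5, and subjects
failing ≥ 2 of the 6 metrics are excluded. Which metrics are
higher-is-worse is declared in config metadata, not guessed from data.

Harmonisation is ComBat: per morphometric feature, the subjects × regions
matrix is standardised under a pooled model containing site intercepts and
age (so age-related variation is protected), per-site location and scale
are estimated per region, shrunk by parametric empirical Bayes (normal
prior on locations, inverse-gamma on scale variances, moment-matched,
iterated to 1e−4), and the data back-transformed. `eb=False` keeps the raw
per-site estimates — exact for closed-form tests (two sites differing by a
pure additive offset are equalised to numerical precision). The EB path is
verified against the Bioconductor reference implementation on a frozen
synthetic fixture to < 1e−5 (`tests/data/combat_sva_reference.csv`).
Harmonisation is fitted on all QC-included subjects before any split, so
corrected data feed both the MSN and single-feature models identically.

## Splitting

Stratified under-sampling: ages are binned at 0.5-year width, bins below
9.0 years merged (thin lower tail; the boundary's openness is
configurable, default [min, 9.0)), and the training cohort
(⌊0.75 n⌋ subjects) is drawn with equal per-bin quotas allocated
round-robin one slot per pass, so bins smaller than their quota contribute
everything and the deficit flows to bins that still have members; the
remainder is the test cohort. This reproduces the canonical sizes
327 → 245/82 and, after the simple-random 5:1 internal refinement,
245 → 204/41 (floor rounding on the larger part). One consequence used in
the tests: the train and test cohorts have systematically different age
means (training is flattened, test keeps the mode), which biases null-model
predicted R² negative — visible in the negative R² cells of
under-regularised models and in the Δ-vs-age bias.

## Kernel regressors

Both regressors standardise feature columns by training mean/SD and use
laplacedot exp(−σ‖x−x′‖) or rbfdot exp(−σ‖x−x′‖²). The bandwidth defaults
to the median heuristic (σ = 1/median pairwise squared distance for rbfdot,
unsquared for laplacedot, over ≤ 200 training rows); no marginal-likelihood
optimisation is attempted (out of scope).

* **GPR** — posterior-mean prediction with dual weights
  α = (K + σₙ²I)⁻¹(y − ȳ) via Cholesky, σₙ² = 1e−3 by default plus 1e−8
  jitter; predictions add back the training mean. `refit_targets` reuses
  the Cholesky factor when only y changes — this makes training-label
  permutation nulls ~100× cheaper, since the Gram matrix depends only
  on X.
* **RVR** — Tipping-style sparse Bayesian regression over the kernel
  basis: iterate γᵢ = 1 − αᵢΣᵢᵢ, αᵢ ← γᵢ/μᵢ², σ² ← ‖y − Φμ‖²/(n − Σγ) to
  relative tolerance 1e−6 or 1000 iterations, pruning basis functions with
  αᵢ > 1e9; all pruned = degenerate model = error. On cohort-scale data
  with informative features RVR typically retains everything and drives
  σ² → 0, i.e. it interpolates (train R² ≈ 1.0 with much lower validation
  R²) — the classic overfit signature this study design exposes via
  internal validation. The analysis drivers cap RVR at 200 iterations
  (`--rvr-max-iter`) as their working problem size; the library default
  remains 1000.

## Evaluation and inference

Predicted R² = 1 − MSE(pred, obs)/MSE(obs, mean), with the normalising
mean taken from the evaluation cohort itself (so 0 is exactly "predicting
that cohort's mean"; a training-mean baseline is a config switch). MAE is
in years. Per feature set, the algorithm × kernel cell with the best
*validation* R² is selected (ties: lower MAE, then GPR before RVR,
laplacedot before rbfdot), retrained on the full training cohort, and
scored exactly once on the held-out test cohort (the run manifest counts
test-cohort evaluations to prove this).

Robustness: the whole split→train→test cycle is repeated over fresh
stratified partitions (library default 20; release preset 100) giving a
mean and percentile 2.5/97.5 interval of test R². Significance: training
ages are permuted, the model retrained, and scored on the untouched test
cohort against true ages; p = (1 + #{null R² ≥ observed})/(1 + n_perm)
(add-one, never exactly zero), observed statistic = the mean resampled R²,
Bonferroni α = 0.005 over the ten models. Note the arithmetic consequence
of scaling down: with 49 permutations the smallest attainable p is
1/50 = 0.02 > 0.005, so formal Bonferroni significance requires the
release-scale 1000 permutations; the scaled runs still rank models
correctly and the calibration of the p-values themselves is tested
separately (null p-values uniform by KS at α = 0.01 over 200
mini-experiments).

## Delta and bias screens

Δ is **signed** (predicted − actual): the observed negative Δ-age
correlation (regression to the mean: young over-aged, old under-aged) only
exists with sign, and it is why every covariate screen controls for actual
age. EFC and IQ use first-order partial correlations (Pearson, and the
same formula on ranks for Spearman; p from the t transform with n − 3 df),
with pairwise deletion of missing IQ and the per-test n reported; sex uses
OLS Δ ~ sex + age (male = 1) and reports the sex coefficient's t. The
screen-wide Bonferroni threshold is 0.05/60 = 0.000833 (10 models × [2
covariates × 2 methods + 1 sex test] + the Δ-age screens in the same
family); the denominator is exposed in config.

## Numerical and design choices

* Population SD (ddof = 0) everywhere a z-score is formed within a group;
  sample SD (ddof = 1) for ComBat's per-site variance estimates (matching
  the reference implementation).
* Round-half-even for edge counts at a density; floor for split sizes on
  the larger partition.
* Degenerate inputs raise with the offending site/metric/region/subject
  named: zero-SD QA metric, < 2 subjects per site, constant feature across
  regions, constant regional profile, zero-degree node, constant observed
  ages, single-sex cohorts.
* All randomness flows from one seed per run through spawned seed
  sequences (generator, split, internal split, resampling, permutation);
  reruns are byte-identical.
* Problem sizes in the test-suite and acceptance runs (cohorts of 80–500,
  20 partitions, 49–99 permutations, 50-seed replications) are the
  package's working scale; the `paper_scale_config()` preset carries the
  release-scale settings (100 partitions, 1000 permutations).

## Known limitations

* The generator's linear-plus-rotation age model cannot represent
  developmental milestones or nonlinear growth curves beyond its quadratic
  term; recovery tests compare against the injected cohort-level trend
  (including the realised latent-factor drift), not against a universal
  constant.
* GPR with a fixed small noise variance overfits age-null feature sets,
  giving systematically negative (not zero-centred) null R² under this
  split design; conclusions about null features should rest on the
  permutation test, which is calibrated, rather than on the sign of a
  single R².
* RVR's σ² → 0 interpolation makes its selection-stage validation scores
  sensitive to the iteration cap; the cap is surfaced as a parameter and
  recorded in run manifests.
* Partial correlations are first-order only (one control variable), which
  is all the screens require.
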