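# Methods

## Calibrated age transform

The regression target is not age itself but F(age), piecewise
logarithmic below an adult anchor *A* and linear above it, continuous
with matching one-sided derivatives 1/(A+1) at the anchor and zero at
age = A. Clock CpGs change roughly an order of magnitude faster before
age twenty than after; the log branch linearizes that childhood phase so
a single linear model can serve both children and adults. The domain is
age > −1 year, which keeps cord-blood samples annotated with small
negative gestational offsets valid. *A* defaults to 20 years and is a
parameter of every model; predictions are mapped back to years with the
exact inverse, so the transform introduces no approximation error
(round-trip error is at machine precision, ~1e−14 over (−1, 120]).

## Preselection

Within each cell-type stratum (annotation column configurable,
default `tissue`), every probe's Pearson correlation with F(age) is
computed pairwise-complete over non-missing betas; the top `k_pos`
positively and `k_neg` negatively correlated probes per stratum are
pooled across strata, together with the `k_null` probes whose pooled
correlation is least significant (largest t-test p). The null set is a
deliberate control: probes the penalty ought to discard, letting tests
verify sparsity is real. Defaults are k_pos = k_neg = 1000 and
k_null = 500. Strata with fewer than 3 aged samples are skipped with a
warning; zero-variance probes get r = 0, p = 1; ties in the rankings are
broken lexicographically by probe ID, so selection is deterministic.

## Elastic-net fit

The solver minimizes
(1/2n)·Σ(yᵢ − b₀ − xᵢᵀb)² + λ[α‖b‖₁ + ((1−α)/2)‖b‖₂²]
with predictors standardized internally (population SD; zero-variance
columns left centered so they can only receive zero weight) and
coefficients returned on the beta scale. Coordinate descent is delegated
to scikit-learn's `ElasticNet`, whose objective matches this
parameterization exactly; correctness is checked independently against
the OLS normal equations (λ = 0), the analytic all-zero threshold λmax,
the univariate soft-threshold closed form, and a hand-written KKT
(subgradient stationarity) residual, which is below 1e−12 at returned
solutions. α defaults to 0.5; λ is selected from a 100-point geometric
grid spanning [λmax, 1e−4·λmax] by K-fold cross-validation (default 10
folds, minimum mean squared error, tie broken toward the larger λ).
Fold assignment is governed by a recorded seed, so training is
bit-reproducible. Missing training betas are imputed with the probe's
training mean before fitting; the means of the fitted support are stored
in the model for prediction-time imputation. CV path solutions use a
warm-started tolerance of 1e−5 (only the error curve is needed); the
final refit uses 1e−12.

## Prediction

DNAm age is F⁻¹(b₀ + Σ wⱼβⱼ). Missing or absent clock probes are imputed
with the stored training means; each sample's imputed fraction is
reported and samples above `max_missing_frac` (default 0.2) are flagged
`too_many_imputed` rather than dropped or crashed — the estimate is
still returned but should be excluded downstream. Models loaded from
bare coefficient files carry no means and raise if imputation would be
required. Prediction is invariant to probe order and to extra unweighted
probes, and applying a clock to its own training matrix reproduces the
logged training metrics exactly.

## Age acceleration

Acceleration is the residual, in years, from a least-squares polynomial
(degree 1 by default; degree 2 optional for cohorts spanning wide age
ranges) of DNAm age on age fitted through controls only, so control-mean
acceleration is zero by construction. Covariate-adjusted analysis is OLS
of DNAm age on any of {age, age², pdl, disease indicator} with two-sided
t-test p-values and no multiple-testing correction (single prespecified
models). Rank-deficient designs raise with the collinear columns named.
Note the residual depends on the control reference: published per-sample
accelerations computed against an unpublished control fit will not be
exactly reproducible from (age, DNAm age) pairs alone.

## Group comparison

`kruskal_wallis` wraps the tie-corrected rank statistic with the
chi-square approximation (k − 1 df) used in conventional reporting; the
all-values-identical degenerate case returns (H, p) = (0, 1). Tests
cross-check it against a first-principles rank-sum oracle and against
the normal-approximation two-group rank-sum test, which agrees with the
chi-square tail to well under 0.005 for tie-free groups of n ≥ 10.

## Ex vivo bookkeeping

Population doubling uses the printed laboratory constant 3.32 rather
than the exact 1/log10(2) = 3.3219…, reproducing lab spreadsheets
bit-for-bit (~0.06% low per doubling); `exact=True` switches constants.
Cumulative PD is the running sum, and a harvest below the seed count
yields a negative per-passage PD as the formula dictates. The trend
analysis is an ordinary least-squares slope (years per doubling) with
its Pearson correlation; at least 3 passages and non-constant PD are
required.

## Synthetic data generator

Causal probes follow E[β] = logistic(a + b·z) with z = F(age) +
disease_offset·1[case] + tissue offset, a ~ U(−1, 1), |b| ~ U(0.25, 0.6)
with alternating signs, plus truncated Gaussian noise on the beta scale
(default SD 0.03, the residual scale typical of array replicates); null
probes have age-independent means U(0.05, 0.95). Because the mean is
logistic, a noiseless causal probe is an exact monotone function of z
(Spearman ρ = ±1, and Pearson r = ±1 on the logit scale) but not exactly
linear in z on the beta scale. The disease offset lives on the
transformed-age scale, so its effect in years shrinks with age —
matching the empirical pattern that progeroid acceleration is clearest
in young donors. Two overlapping manifests emulate the 450K/EPIC
universe with a configurable privately-held probe fraction. The passage
series drifts causal-probe logits linearly in cumulative PD and draws
harvest counts to hit a target per-passage doubling; probe parameters
are drawn from a stream keyed only by the generator seed, so a clock
trained on cross-sectional data from a `SyntheticSpec` applies directly
to the passage series built from the same spec object.

What the generator does **not** emulate: probe-specific noise
heteroscedasticity (real betas are beta-distributed with U-shaped
variance), batch and chip effects, correlated CpG blocks, cell-type
composition mixtures, and detection failures. Passing recovery tests
therefore demonstrates the estimator machinery is correct, not that it
would attain the same accuracy on real arrays.

## Experiment sizes and numerical choices

The standard recovery experiment (tests and `scripts/acceptance.py`)
uses 400 samples (300 train / 100 held out), 50 causal + 450 null
probes, ages uniform on (0, 90) and noise SD 0.03, with preselection
k_pos = k_neg = k_null = 100 — large enough that held-out correlation
≥ 0.95 and ≥ 80% support recovery are clearly resolvable, small enough
to run in seconds. Acceleration simulations use n = 44–60 with a +5-year
planted offset (the magnitude of progeroid acceleration reported in
young cohorts); the ex vivo series uses 20 passages of ~1 doubling with
drift 0.05 transformed units per doubling, i.e. ~0.1 year per doubling
for neonatal cells, the scale observed in cultured fibroblasts.

## Known limitations

- No IDAT/normalization layer: the toolkit starts at beta matrices.
- The chi-square approximation for Kruskal–Wallis is used even at the
  small group sizes of the worked example, matching conventional
  reporting; exact permutation is not implemented.
- Confidence intervals on predicted DNAm age are out of scope.
- The published 391-CpG coefficient set is not bundled; the coefficient
  file format loads such a table when supplied, but without training
  means those models cannot impute missing probes.
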