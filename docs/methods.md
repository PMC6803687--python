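# Methods

## Problem and model

`dynconn` quantifies how *dynamic* the functional coupling between pairs of
large-scale brain networks is, and whether that dynamicity covaries with
personality. A "node" is a network time course (one column of a T × K
matrix); a "connection" is an unordered node pair, so K = 15 nodes give
K(K−1)/2 = 105 connections.

### Time-varying connectivity: DCC-GARCH

Sliding-window correlation trades temporal resolution for stability. The
dynamic conditional correlation (DCC) model instead yields a conditional
correlation estimate at every timepoint, in three steps per pair:

1. **ARIMA detrending.** Each node series is pre-whitened with an ARIMA
   fit (default order (1,0,1), exact maximum likelihood through the
   statsmodels state-space filter) so the volatility model sees
   approximately mean-zero innovations. A regression-based
   Hannan–Rissanen fit is available (`arima_method="hannan_rissanen"`);
   on near-white signals it is statistically equivalent and about 3×
   faster, and the large simulated-cohort studies below use it.
   Non-convergent fits fall back to mean removal with a logged warning.
2. **GARCH(1,1) standardization.** For each detrended series,
   y_t = σ_t ε_t with σ²_t = ω + α y²_{t−1} + β σ²_{t−1}, ω > 0,
   α ≥ 0, β ≥ 0, α + β < 1, estimated by Gaussian quasi-maximum
   likelihood. ω is profiled out by **variance targeting**
   (ω = v̂ (1 − α − β), v̂ the sample variance): the free-ω likelihood has
   a flat near-unit-root ridge (β → 1, ω → 0) on low-volatility series
   that derails generic optimizers, and targeting removes it without
   changing the optimum in well-identified cases. Free-ω estimation
   remains available via `variance_targeting=False`. Standardized
   residuals ε̂_t = y_t/σ̂_t feed the correlation stage.
3. **DCC(1,1) recursion.** For each pair of standardized residual series,
   Q_t = (1 − a − b) Q̄ + a ε_{t−1} ε′_{t−1} + b Q_{t−1}, with Q̄ the
   sample correlation matrix of the pair and Q_0 = Q̄, rescaled to
   R_t = diag(Q_t)^{−1/2} Q_t diag(Q_t)^{−1/2}. (a, b) are estimated by
   Gaussian quasi-maximum likelihood under a, b ≥ 0, a + b < 1. The
   off-diagonal of R_t is the connectivity estimate, at the full temporal
   resolution of the input.

Estimation is two-stage (GARCH per node once, then every pair), pairwise
rather than joint 15-dimensional: the pairwise model is faithful to the
two-series formulation, estimable at T = 4,800, and embarrassingly
parallel over pairs. Optimization uses SLSQP with box bounds and the
stationarity constraint, starting at (ω, α, β) = (0.1 v̂, 0.05, 0.90) and
(a, b) = (0.05, 0.90), with up to three jittered restarts before a fit is
declared failed; failed GARCH fits degrade to constant variance and failed
DCC fits freeze the correlation at Q̄ (both flagged, never raised, so one
bad pair cannot abort a subject). Conditional correlations are clamped to
|ρ| ≤ 1 − 10⁻⁶ before any log or variance operation. The 4 runs of a
subject are concatenated before fitting; the per-half consistency check
(`session_consistency`) covers the session-split question separately.

### Non-stationarity: the excursion T-index

For a conditional-correlation series ρ_t, an **excursion** is the segment
between two consecutive crossings of the full-series median, with length τ
(timepoints between crossings) and magnitude h (peak |ρ_t − median| within
the segment). The T-index is

    T = (1/N) Σᵢ hᵢ τᵢ

over the N complete excursions: large when the connection departs from its
median often, far, or for long, and invariant to the median level itself
and to the direction of departure. Conventions (each deterministic, chosen
where a discrete series leaves room):

- crossings sit at the later sample of an opposite-sign pair; no
  sub-sample interpolation;
- a sample exactly on the median is itself a crossing (it terminates the
  running excursion);
- a segment that never leaves the median (h = 0; e.g. a constant series)
  is not an excursion;
- partial segments before the first and after the last crossing are
  discarded;
- N = 0 ⇒ T = 0 (the 0/0 case: a series with no complete excursion is
  maximally stationary);
- τ is measured in timepoints by default; passing the TR re-expresses it
  in seconds, a pure rescaling that cannot affect rank-based or linear
  inference.

A brute-force sample-by-sample scanner implementing the same conventions
serves as the test oracle for the vectorized implementation.

### Trait association

Subjects are split 75/25 (train n = ⌊0.75 n⌋; 613/205 at n = 818) by
re-drawing random partitions until no connection's train-vs-test T-index
distributions differ by Mann–Whitney U at α = 0.05 (at most 1,000
re-draws, then an error naming the worst-matched connection). The
"sampling with replacement" phrasing of matched splitting is read as
re-drawing candidate partitions — duplicating subjects across sets would
leak train information into test. Per connection, ordinary least squares
regresses the train T-index on the five NEO-FFI traits plus age, sex
(0/1), education, handedness (R = 1, L = −1, both = 0) and intelligence;
any full-rank coding gives identical trait inference. Trait p-values are
Benjamini–Hochberg adjusted across the family of connections within each
trait (a pooled single-family option exists). Effect sizes are absolute
partial correlations obtained from the t-statistic identity
r² = t²/(t² + df), which ties them exactly to the reported coefficients.
Generalization is scored on the untouched test set by

    RRMSE = RMSE(observed, predicted) / mean(observed),

classed excellent < 0.1 ≤ good < 0.2 ≤ fair < 0.3 ≤ poor. The
normalization by the mean observed value is our reading of "relative"
RMSE; since T > 0 with mean well away from zero, it is well defined
(non-positive means raise). Missing T cells drop the subject from that
connection's model only.

## Synthetic cohort

The generator emulates the structure the analysis assumes, not fMRI
physics: it starts at the node-time-series level. Per subject it draws
independent Gaussian innovations and mixes them with the time-varying
Cholesky factor of a latent correlation matrix that is constant for
stationary pairs and sinusoidal, ρ(t) = ρ0 + A sin(2πt/P + φ), for
dynamic pairs (defaults ρ0 = 0.3, A = 0.25, P = 300 timepoints; φ uniform
per subject and pair). Default dimensions are 15 nodes and 4 runs × 1,200
timepoints (TR 0.72 s). The default pair layout uses node-disjoint 2×2
blocks, which keeps the latent matrix positive definite by construction;
arbitrary layouts are validated by attempting the Cholesky factorization
at every timepoint. Optional GARCH(1,1) volatility can modulate each
node.

Phenotypes are truncated normals (resampled into range, not clipped, to
avoid boundary atoms). Because truncation shrinks the SD and shifts the
mean, the parent normal is moment-matched (a one-time two-moment root
solve per distribution) so that the *realized* truncated moments equal
the configured targets; where no truncated normal can reach the target
(education's printed 14.9 ± 1.8 on [11, 17] exceeds the family's SD
ceiling) the naive parent is used. The five NEO-FFI traits use the
published cohort-level means, SDs and ranges (e.g. conscientiousness 34.5 ± 5.9,
range 12–48); age 28.7 ± 3.7 [22, 37] years and education 14.9 ± 1.8
[11, 17] years likewise; sex and handedness are categorical draws at the
cohort frequencies. The intelligence score (16.5 ± 4.9, range 4–24, a
matrix-reasoning-style scale) and the head-motion RMS (log-normal, median
0.07 mm) have no published distribution here and are invented, plausible
defaults. Covariates are generated independent of traits; a
`covariate_trait_corr` knob introduces age–trait confounding for
sensitivity tests.

**Planted effects.** A planted effect targets the |partial correlation|
between one trait and one dynamic connection's T-index. It acts on the
fluctuation amplitude — A_s = A(1 + g·sign·z_s) with z_s the subject's
standardized trait score — never on the mean level ρ0, because the
T-index is median-invariant by construction. The slope g is calibrated
from T ≈ κA + noise: g = [m/√(1−m²)]·ν, where m is the target magnitude
and ν the noise-to-signal ratio σ_noise/(κA) of the *estimated* T-index,
which was measured by simulation: ν ≈ 0.18 at T = 1,200 under the default
dynamics, scaling as 1/√T; ν ≈ 0.10 for the planted-effect study
condition below. These constants are properties of the full estimation
chain (ARIMA + GARCH + DCC + excursion scan), not of the generator alone.

**What the generator does not emulate:** hemodynamic autocorrelation and
low-pass structure, scanner drift, head motion artefacts, non-sinusoidal
or state-switching dynamics, inter-subject variability in ρ0 or P, and
any spatial structure. Passing tests therefore demonstrate that the
estimator chain recovers what it assumes, not that real resting-state
data satisfy those assumptions.

## Study conditions used by the tests and the acceptance script

Problem sizes are chosen so each study answers its question at desk
scale:

- **Discrimination** (dynamic vs stationary T-indices, AUC > 0.9): 20
  subjects at the full default dimensions (15 nodes, 4,800 timepoints).
- **Planted-effect recovery**: 600 subjects, 10 nodes, 2 runs × 1,200
  timepoints, four node-disjoint dynamic pairs carrying negative
  conscientiousness effects at magnitudes 0.111/0.125/0.130/0.157 (the
  empirically reported effect-size range; planting several connections
  mirrors real edge-wise findings and gives the study adequate detection
  power — a single connection at r ≈ 0.13 is borderline at train
  n = 450 after FDR), plus one stationary pair
  (`planted_effect_cohort`). The dynamics for this condition are stronger
  and faster (ρ0 = 0.5, A = 0.45, P = 150) than the cohort default so
  that the between-subject CV of the estimated T-index (≈ 0.15) matches
  the regime implied by empirically reported RRMSE values (0.14–0.20):
  with the default gentle dynamics at T = 2,400 the estimation noise
  alone would push every RRMSE into the "fair/poor" bands regardless of
  model quality. Generalization (RRMSE band) is assessed on the
  recovered planted connections — a false-positive connection has no
  true model for RRMSE to score.
- **GARCH recovery**: (ω, α, β) = (0.05, 0.10, 0.85), T = 5,000, median
  over 50 seeds.
- **DCC tracking**: the default sinusoid over T = 4,800, requiring
  corr(ρ̂_t, ρ(t)) > 0.5.
- **FDR control**: 1,000 global-null families of 105 GLM trait tests
  (batched closed-form OLS p-values, validated against the package GLM).

## Known limitations

- The DCC quasi-likelihood assumes Gaussian innovations; heavy-tailed
  drives would need a Student-t extension, which is out of scope.
- Pairwise DCC ignores cross-pair constraints; the assembled 15 × 15
  "matrix" of pairwise estimates need not be positive definite at every t.
- The excursion statistic has no built-in null: T is used as a raw
  dependent variable, as intended, and surrogate-based significance of
  individual T values is out of scope.
- The planted-effect calibration constants are condition-specific
  (`effect_noise_ratio`); configurations far from the calibrated
  conditions will realize somewhat different effect magnitudes.
- BH adjustment is monotone but not idempotent; re-adjusting adjusted
  values can only inflate them.
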