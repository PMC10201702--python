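# Methods

## Model

A balanced panel of strictly positive densities X_it (unit i = 1..N, year
t = 1..T) is viewed through the time-varying factor decomposition
X_it = δ_it μ_t: a single common trend μ_t and unit-specific transition
coefficients δ_it. Convergence of the panel means δ_it → δ for every unit;
club convergence means δ_it → δ_c within subsets. Since μ_t and δ_it are
not separately observed, the common factor is removed by normalising with
the cross-sectional mean:

- relative transition parameter: h_it = X_it / (N⁻¹ Σ_i X_it),
- cross-sectional transition variance: H_t = N⁻¹ Σ_i (h_it − 1)².

Under full convergence h_it → 1 and H_t → 0. The mean of h over units is
identically 1 at every t (asserted to 1e-12 relative tolerance).

## The log-t test

The trimmed regression

    y_t = log(H_1/H_t) − 2 log(log t) = α + β log t + ν_t,
    t = ⌊rT⌋+1, …, T

is estimated by OLS. Conventions and numerical choices:

- Time is indexed 1..T; H_1 is the variance of the *untrimmed* first
  period, not of the first retained one. ⌊rT⌋ is a floor. The trim r
  defaults to 0.3 (the annual-data convention) and must satisfy ⌊rT⌋ ≥ 1 so
  that t = 1 (where log log t is undefined) is never retained; T ≥ 10 and
  at least 5 retained observations are required.
- Under convergence at rate a (H_t ∝ t^(−2a)(log t)^(−2)), y_t is exactly
  affine in log t with slope β = 2a; this closed form is the analytic
  checkpoint used in the tests.
- Inference: Bartlett-kernel (Newey–West) long-run variance on the OLS
  residuals, lag truncation ⌊4 (T_reg/100)^(2/9)⌋ with T_reg the retained
  length, no small-sample correction; the bandwidth is a config knob and is
  echoed in every result. The decision is one-sided: convergence is
  rejected iff t = β̂/se(β̂) is strictly below the critical value, −1.65
  (5%) by default; t exactly at the threshold does not reject.
- Degenerate variances: H_t ≤ 1e-24 is treated as an exact zero (the
  machine-noise floor of h − 1 ≈ 1e-12, squared). A zero inside the
  retained window means the cross-section has already converged exactly:
  the result carries the +inf t-statistic sentinel, converged = true, and
  NaN coefficients. The converse knife-edge — H_1 = 0 with positive later
  variances, a cross-section that coincided at t = 1 and then fanned out —
  is reported with the −inf sentinel (maximal rejection).

## Preprocessing

The estimator/pipeline default is to test log densities after per-unit
Hodrick–Prescott smoothing with λ = 400, the conventional pre-step for
annual panels: the log keeps proportional (not absolute) gaps, and the
smoothing removes business-cycle-scale noise that would otherwise
contaminate H_t at short T. Levels mode and no smoothing remain available
(`transform="levels"`, `hp_lambda=None`), and the transform actually used
is recorded in `TransitionPaths.source_transform` and in every report.
Smoothing is always applied to the per-unit series before Eq.-style
normalisation, never to H. Note two consequences of log mode: the test is
invariant to a common *multiplicative* trend only in levels mode, and a
change of measurement units shifts every log series by a constant, so
panels should be scaled so that all logs are positive — a cross-sectional
mean of logs ≤ 0 raises a degenerate-cross-section error naming the year
(rescale, e.g. per 100,000 instead of per 10,000, to resolve it).

`hp_smooth` solves the penalized least-squares system (I + λ D′D)τ = y
(D = second differences) directly with a sparse LU factorization, applied
to all rows of a panel with a single solve; it is checked in the tests
against both a dense solve and statsmodels' `hpfilter`. A line is a fixed
point for any λ.

## Club clustering

With full-sample convergence rejected, clubs are identified by the
standard four steps, every knob exposed in `ClubConfig`:

1. **Ordering.** Units are sorted by the mean of the final half of the
   (transformed) series, decreasing; the final-window mean (rather than the
   last observation) is robust to terminal-year noise, and the window
   fraction is configurable. Ties break lexicographically by unit id, so
   the procedure is fully deterministic.
2. **Core group.** Prefixes of the ordering of length k = 2, 3, … are
   tested; the core is the prefix maximizing the log-t t-statistic among
   prefixes with t > −1.65. If no prefix starting at the top qualifies, the
   top unit is set aside and the scan restarts; an empty core (no
   converging pair at all) classifies the whole remainder divergent.
3. **Sieve.** Each remaining unit is added, alone, to the core and joins
   the provisional club if the augmented t-statistic exceeds the criterion
   c\* (default 0, a conservative choice for short panels). If the
   assembled club then fails its own log-t test, c\* is raised in 0.05
   steps and the sieve repeats; since the admission set shrinks as c\*
   grows, the club falls back to the core in the worst case, so every
   reported club passes its own test.
4. **Recursion and merging.** The formed club is removed and steps 1–3
   repeat on the remainder; leftover singletons are divergent by definition
   (a club needs ≥ 2 members). Finally adjacent clubs (by rank) whose union
   passes the log-t test are merged, restarting the scan after every merge,
   so reported clubs are "strong"; every attempt is recorded in
   `merge_log`. Clubs are numbered 1, 2, … by decreasing final-window mean
   *raw* density, the high-density-first convention.

The partition (clubs + divergent set) is validated to be disjoint and
exhaustive after assembly.

## Synthetic data generator

`simulate_panel` draws panels from the canonical semiparametric DGP:
μ_t = μ₀(1+g)^(t−1) and, for a unit of club c,

    δ_it = δ_c + σ_i ξ_it / (log(t+1) · (t+1)^α),   ξ_it ~ N(0, 1) iid,

with σ_i = `noise_sigma` · δ_c (noise proportional to the club level).
This form is chosen because it makes β = 2α an analytic checkpoint for the
log-t slope. Draws that would make δ (hence the density) non-positive are
resampled, not truncated, preserving the Gaussian shape; the resample count
is recorded on the truth object. Divergent units follow deterministic
log-linear trends fanning outward from the club range — even-indexed fans
start above the top club and drift up (slopes +5%, +7%, … per year),
odd-indexed fans start below the bottom club and drift down (−2%, −3.5%,
…) — so no fan shares a long-run relative path with any club or any other
fan, and power statements about them are clean.

Defaults are the study conditions the package is validated under: 204
units in three clubs of 110/66/28 converging to 21, 7 and 2 per 10,000
population (the high club's limit matches the ~21/10k level reported for
high-density countries; the lower two straddle the universal-coverage
threshold gap), T = 30 annual periods from 1990, 3% yearly common growth,
α = 0.5, and 10% relative initial noise. Everything is reproducible from
the config seed.

What the generator does *not* emulate: measurement error correlated over
time or across neighbouring countries, policy breaks and wars (jumps in
δ_it), cross-unit noise correlation, population-weighting, or calibration
to the empirical moments of any real extract. Monte-Carlo results under
this DGP therefore validate the *method's* size, power and club recovery
under a clean factor structure; they do not guarantee the same accuracy on
real data, where the transform/smoothing choices and borderline units can
move club boundaries.

## Monte-Carlo problem sizes

The validation suite uses: size — one club, N = 50, T = 30, 500
replicates, rejection ≤ 10% (one-sided nominal 5% plus Monte-Carlo slack);
power — two clubs with limits 2:1 at μ₀ = 10 (keeping all logs safely
positive), N = 25+25, 500 replicates, rejection ≥ 95%; club recovery — the
default 110/66/28 panel plus 4 fans, 100 replicates, adjusted-Rand
agreement with the generating labels ≥ 0.9 and all fans flagged divergent
in ≥ 90% of replicates. Observed behaviour is comfortably inside all three
bands (0% size, 100% power, 100% recovery at these seeds).

## Elasticity arithmetic

`growth_elasticity(o, d) = o/d` (rounded to 2 decimals) turns two
percentage growths into an implied elasticity. `project_index` projects an
index level after a relative driver change; the default is the *linear*
first-order approximation baseline·(1 + ε·Δ), the convention in the
descriptive arithmetic this mirrors, while the exact constant-elasticity
form baseline·(1+Δ)^ε is available via `form="loglinear"` — for a doubling
at ε = 0.23 the two give 68.4 vs 65.2 from a baseline of 55.6, so the
choice matters and both are exposed. `fit_loglinear_haq` is an ordinary
cross-sectional OLS of ln(index) on log densities with classical standard
errors and adjusted R²; omitting the second cadre gives the bivariate fit.
Reports round coefficients and t-statistics to 3 decimals.

## Limitations

- The log-t test is asymptotic in both N and T; at very short T (close to
  the minimum of 10 years) the HAC variance is noisy and club boundaries
  are sensitive to the trim and bandwidth.
- The clustering outcome on real data depends on the preprocessing
  configuration (levels vs logs, smoothing weight, sieve criterion); exact
  club compositions published elsewhere may not reproduce under different
  unstated settings — which is why every report echoes its full
  configuration.
- Log mode requires all cross-sectional log means to be positive; panels
  containing densities below one unit must be rescaled first.
- No population weighting, no missing-data handling (panels must be
  balanced), no conditional-convergence covariates, and no spatial
  dependence modelling.
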