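# Methods

This note records the models, conventions and numerical choices behind the
package, and what the synthetic cohort does and does not establish about
real data.

## Trial conventions

A trial is the CoP position in cm on the medio-lateral (ML, x) and
antero-posterior (AP, y) axes, nominally 50 Hz × 60 s. The half-open
sampling convention is used: a standard trial has N = rate × duration =
3000 samples at t = 0, 0.02, …, 59.98 s and duration N/rate = 60 s. This
makes mean velocity = total path / 60 s an exact identity on standard
trials, which is also how published velocity values relate to published
path lengths (77.52 cm → 1.29 cm/s, 111.60 cm → 1.86 cm/s, and so on).

Files are plain delimited text (comma or tab, decimal point), two columns
(ML, AP) or three (time, ML, AP). When a time column is present the rate
is inferred from the median step and steps must be uniform to a relative
1e-3. No filtering, detrending or mean removal is applied before metric
computation; any pre-acquisition settling is assumed excluded from the
file (an optional leading-trim parameter exists, default 0 s).

## Time-domain variables

Positional variability uses the sample SD (n−1). At N = 3000 the
population/sample distinction is below 0.02 %, far below any reported
precision; the sample form is the conventional reading of a reported
"standard deviation". Mean velocity is defined through the total path, not
per-axis averages — this is the definition under which published velocity
equals published total path / 60 s in every table row of the source
protocol family.

## Sway areas

**PCA ellipse.** s₀ denotes the square roots of the eigenvalues of the
2×2 sample covariance (principal-axis SDs, units cm), and 1.96·s₀ is a
*semi*-axis, giving area π·1.96²·√(λ₁λ₂). The alternative full-axis
reading would divide areas by 4 and is grossly incompatible with
published sway areas, which sit within a few percent of the semi-axis
value. A fully degenerate cloud yields a zero-area ellipse with a warning
rather than an exception (a measurable, if extreme, outcome).

**Fourier outline (FAO).** The [0, 2π) circle about the cloud centroid is
split into 100 equal angular bins; the farthest sample per non-empty bin
is kept (ties broken by first occurrence; empty bins are skipped). A
truncated Fourier series with a constant term, r(φ) = A₀ + Σ_{m≤20}
(A_m cos mφ + B_m sin mφ), is fitted by ordinary least squares. The
constant term is required — a pure sinusoid sum cannot represent a closed
outline with nonzero mean radius. The angle entered into the fit is the
extreme point's own polar angle (closer to the data than the bin centre;
the difference is below one bin width, and the bin-centre variant is
selectable). Area follows from Parseval: ½∫r²dφ = πA₀² + (π/2)Σ(A_m²+B_m²).
The fitted radius is validated on a 1000-point grid; a negative radius
anywhere raises an error naming the offending angle, since the "area"
formula would silently count negative lobes positively.

Consequences worth knowing: the outline area is exactly invariant under
translation and under rotations by whole bin widths, but only approximately
(≈0.5 % at 100 bins) under generic rotations, because the bins are fixed in
the lab frame. The PCA area is exactly invariant under all rigid motions.

## Higuchi fractal dimension

For lag k (samples) and offset m = 1..k, the normalized curve length is

    L_m(k) = [ Σ_{i=1..n_m} |x(m+ik) − x(m+(i−1)k)| ] · (N−1)/(n_m·k),
    n_m = ⌊(N−m)/k⌋,       L(k) = (1/k) · mean_m L_m(k).

L(k) ∝ k^(−D) with D the fractal dimension: a straight line gives
L(k) = (N−1)/k exactly (D = 1), uncorrelated noise D → 2, and
fractional-Brownian-type traces D = 2 − H. D is estimated as −slope of an
unweighted least-squares line of ln L(k) on ln k.

CoP log-log curves show two regimes, so the regression runs separately
over lags with k/fs in [0, 0.3] s (short) and [0.8, 12] s (long),
boundaries inclusive, excluding the transition region between. The default
lag grid is every integer lag in the short window (k = 1..15 at 50 Hz)
plus ~25 log-spaced integer lags across the long window (k = 40..600) —
dense where lags are cheap, log-spaced where the regression lives on a log
axis. Lags are capped at ⌊(N−1)/4⌋ so each offset contributes at least
four increments. A constant series produces all-zero lengths and the fit
refuses with a specific error.

## Reliability statistics

ICC(2,1) — two-way random-effects, absolute agreement, single measures —
is computed from the two-way ANOVA mean squares (rows = subjects,
columns = sessions), with the Shrout–Fleiss approximate F interval using
Satterthwaite degrees of freedom. The implementation agrees with
pingouin's ICC(A,1) to 1e-9 and its simulated 95 % CI coverage is 93–97 %
for true ICC ∈ {0.5, 0.8, 0.95} and n ∈ {15, 26}. For strongly negative
estimates the Satterthwaite df collapses toward zero and the F quantiles
diverge; the affected bound is then reported as vacuous (−1 or 1) rather
than NaN. Note the point estimate itself can fall below −1 for tiny, noisy
cohorts (the ICC(2,1) estimator is not bounded below by −1 at small n);
the interval is widened to contain it.

Two "SEM"s circulate in the reliability literature. Reported tables of
this protocol family print SD/√n (the standard error of the mean) in
parentheses — verifiable from the printed numbers, e.g. 0.1/√26 = 0.02 and
17.55/√15 = 4.53 — while the methods-level SEM is the standard error of
measurement SD_pooled·√(1−ICC) with SD_pooled = √((SD₁²+SD₂²)/2). Both are
emitted as separate, labelled columns; nothing is guessed.

Romberg quotients pair the firm-surface conditions (FO, FC) by default
(the compliant pair is selectable) and use the per-subject mean of ratios,
not the ratio of means — a per-subject quantity is required for the
reported RQ standard deviations to exist. Session 1 is used so the
quotient describes a single test occasion.

Cells (condition × group) with fewer than 3 complete subjects are skipped
with a warning; subjects missing one session are excluded from that
condition only, and every exclusion is logged and attached to the output
table. No multiple-testing adjustment is applied: each variable's ICC is
reported raw.

## Synthetic cohorts

The generator emulates the *statistical* structure the reliability
analysis assumes, not stance biomechanics:

- **Scale model.** Each subject j draws u_j ~ N(0, σ_subject²) and each
  session s draws v_js ~ N(0, σ_session²), both on the log scale; the trial
  sway scale is base_group × mult_condition × exp(u_j + v_js). Log-normal
  effects keep scales positive and make the designed ICC exact on the log
  metric: ICC_design = σ_subject²/(σ_subject² + σ_session²). Defaults
  σ_subject = 0.2, σ_session = 0.1 give ICC_design = 0.8, inside the
  good-to-excellent range typical of this protocol.
- **Cohort defaults.** Two groups of 26 ("young", base ML/AP scales
  0.44/0.51 cm) and 15 ("elderly", 0.57/0.62 cm) subjects — the sizes and
  firm-surface sway magnitudes of the cohorts this package is modelled
  on — with condition multipliers FO 1.0 < FC 1.2 < CO 1.5 < CC 2.7
  reflecting sensory-condition difficulty. 2 sessions × 4 conditions gives
  328 trials.
- **Trace model.** Per axis, the default trace is leaky-integrated
  fractional Gaussian noise: an exact Davies–Harte fGn sample (Hurst
  H = 0.85) passed through x_i = e^(−θΔt)·x_{i−1} + g_i with leak
  θ = 1 /s. The leak is what makes the trace behave like stance: pure fBm
  wanders unboundedly, which both misrepresents postural control and
  produces star-shaped point clouds whose extreme-radius function defeats
  a 20-harmonic outline fit. With the leak, short-lag roughness (FD ≈ 2−H)
  is preserved, the long-lag curve-length slope drifts toward 2 as position
  decorrelates — the empirical two-regime shape — and mean velocity at a
  0.44 cm scale is ≈1.4 cm/s, in the observed range. A stationary OU
  process and an OU+fBm mixture are available alternatives; OU's θ controls
  velocity at fixed scale.
- **Standardization.** Traces are standardized to zero mean and unit
  sample SD before scaling, so each trial's realized positional SD equals
  its drawn scale exactly. This makes the log positional SD carry the
  designed variance components without attenuation — recovery tests then
  measure the estimator, not generator shot noise. Axes are independent by
  default; a correlation parameter exists to exercise the PCA-vs-FAO gap.
- **Determinism.** All randomness flows from one seed through spawned
  child generators; identical configs give bitwise-identical cohorts.

What passing tests on synthetic cohorts do *not* show: robustness to
sensor drift, filtering artefacts, non-Gaussian heavy-tailed sway,
session-by-condition interactions, or true biomechanical dynamics
(inverted-pendulum control, foam mechanics). The generator's role is to
give known ground truth, not realism beyond the features listed above.

## Numerical and degenerate-input choices

- Outline fitting requires ≥ 2·m_max + 1 polar samples; fewer raises an
  error suggesting a lower m_max. Fewer than 3 non-empty angular bins is a
  degenerate outline (e.g. a perfectly collinear cloud).
- A trial whose metrics fail (typically an invalid outline, ~0.7 % of
  default synthetic trials) is excluded from the metrics table with a
  logged error; the run continues and the affected subject drops out of
  that condition's reliability cell only.
- ICC requires n ≥ 3 subjects and nonzero total variance. mse = 0
  (duplicated sessions) short-circuits to ICC = 1 with a collapsed
  interval.
- Romberg quotients refuse non-positive eyes-open values, naming the
  subject.
- Report tables round to 2 decimals; CSV outputs keep full precision.

## Problem sizes used in checks

Oracle and recovery checks run at sizes chosen to make their tolerances
meaningful on one CPU: brute-force Higuchi agreement on 50 series of
N ≤ 500; fGn fractal-dimension recovery as the median over 50 seeds of
N = 3000 traces; ICC calibration with 500 replicate 26×2 cohorts (1000 for
the coverage grid); end-to-end recovery on one full default cohort (328
trials of N = 3000).
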