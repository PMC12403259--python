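# Methods

This note documents the statistical procedures implemented in `normcheck`,
the conventions adopted where several exist, and the limits of what the
package's simulations can show.

## Test statistics and p-values

All thirteen statistics are computed from their defining formulas on the
raw data; every one is location–scale invariant, so each null distribution
depends only on the sample size n.

**Moment conventions.** Central moments `μ̂2, μ̂3, μ̂4` use divisor n.
Sample skewness is `μ̂3/μ̂2^{3/2}` and raw kurtosis `μ̂4/μ̂2²` (3 under
normality). Plotting positions `p_(i) = Φ((x_(i) − x̄)/s)` standardize with
the unbiased SD (divisor n − 1); the Gel–Miao–Gastwirth numerator `s_n`
uses the maximum-likelihood SD (divisor n), which together with the
`√(π/2)` factor in `J_n` keeps the ratio centred at 1 under normality.

**Shapiro–Wilk.** The exact weight vector needs the inverse covariance
matrix of normal order statistics, which is impractical to form; the
implementation uses Royston's polynomial approximation (Blom scores with
corrected extreme weights, normalized so `Σaᵢ² = 1`) and Royston's
normalizing transformation for the p-value — exact at n = 3, a
log-gamma-type transform for 4 ≤ n ≤ 11, lognormal beyond. Valid for
3 ≤ n ≤ 5000.

**Shapiro–Francia.** The statistic is the squared correlation between the
sorted data and Blom scores `Φ⁻¹((i − 3/8)/(n + 1/4))` (the squared form is
what ranges in (0, 1] and what the standard implementations compute), with
Royston's SF-specific lognormal p-value transform.

**EDF tests.** Lilliefors uses the Dallal–Wilcoxon analytic p-value
approximation (with the Stephens polynomial form when p > 0.1); the
Cramér–von Mises p-value comes from piecewise exponential tail formulas for
the modified statistic `Z = W(1 + 0.5/n)`; Anderson–Darling applies the
small-sample modification `A* = AD(1 + 0.75/n + 2.25/n²)` before its
piecewise formulas. These are the conventions of the widely used R
implementations, and they were validated against that family to 1e−6 on
pinned fixtures. `p_(i)` is clamped to `[1e−12, 1 − 1e−12]` before
logarithms.

**Moment tests.** JB, AJB, DAP, and RJB are upper-tailed against χ² with
2 df; DAS and DAK are two-sided standard normal after the D'Agostino
normalizing transformations. The DAS constant is
`c = 3(n² + 27n − 70)(n+1)(n+3) / ((n−2)(n+5)(n+7)(n+9))`, the only sign
convention for which `w² = −1 + √(2(c−1))` is real at practical n.
AJB uses the exact finite-sample moments `Var(√b1) = 6(n−2)/((n+1)(n+3))`,
`E(b2) = 3(n−1)/(n+1)`, `Var(b2) = 24n(n−2)(n−3)/((n+1)²(n+3)(n+5))`.

**GMG p-value.** The ratio test is *directed*: heavy tails push
`R = s_n/J_n` above 1. The default p-value is the upper tail of a
Student-t with n degrees of freedom applied to
`√n(R − 1)/√((π − 3)/2)`. This choice was made on calibration evidence:
across n = 20…200 it reproduces the mildly liberal finite-sample size
profile (≈ 0.062 at n = 20 decaying toward 0.05) that the two-sided
asymptotic normal (available via `gmg_test(..., method="normal")`) does
not — the normal form is near-exact in size and correspondingly less
powerful. A simulated-null calibrated mode is available for both (pass a
`NullTable`). Known residual: against strongly leptokurtic alternatives at
moderate n the directed-t convention yields slightly higher power (by
roughly +0.015 at n = 50, excess kurtosis 9) than some other
implementations of this test; no analytic convention we examined matches
both the size profile and that power value simultaneously.

**Pearson chi-square.** `k = ⌈2 n^0.4⌉` classes equiprobable under the
fitted normal (mean, unbiased SD), statistic `Σ(Oᵢ − Eᵢ)²/Eᵢ` with
`Eᵢ = n/k`, p-value from χ² with `k − 3` df (two estimated parameters plus
the usual constraint). Requires n ≥ 20 in the public API.

**Sample-size domains.** SW 3–5000, SF 5–5000, LF ≥ 4, CVM ≥ 4, AD ≥ 7,
JB ≥ 3, AJB ≥ 4 (its `n − 3` factor vanishes at n = 3), DAS ≥ 9, DAK ≥ 5,
DAP ≥ 20, GMG ≥ 10, RJB ≥ 4, PCHI ≥ 20. Zero-variance samples raise a
typed degenerate-input error from every test; NaN/Inf are rejected at
`Sample` construction. Ties are handled naturally through Φ — no
jittering.

## Fleishman power-method generator

Non-normal data are generated as `Y = a + bZ + cZ² + dZ³` with Z standard
normal and `a = −c`, so Y has mean 0. The classical three-equation system
(variance, third moment, fourth cumulant as polynomials in b, c, d) is
solved by Newton–Raphson with the analytic Jacobian, start
`(b, c, d) = (1, 0.1·sign(γ₁), 0.01)`, tolerance 1e−10 on the residual
norm, at most 200 iterations, with a coarse multi-start grid as fallback.
The skewness/kurtosis components of the system are exact on the
unit-variance manifold where all solutions live. Coefficients for `−γ₁`
are the sign-flip `(a, c) → (−a, −c)` of those for `+γ₁`, so mirrored
scenarios have identical power.

**Kurtosis conventions.** Scenario grids index alternatives by a
"kurtosis" number. Under the default `excess_reproduction` convention that
number is passed to the solver directly as excess kurtosis; under `raw` it
is the raw kurtosis and the solver target is the number minus 3. The
default was fixed by calibration: simulated power values over the full
scenario grids agree with the reference study's published tables only
under the excess reading (e.g. symmetric data with tabulated kurtosis 9 at
n = 50 give all thirteen tests power within ~0.01 of the published row),
whereas the raw reading makes slight-deviation scenarios nearly
undetectable and makes tabulated kurtosis 1 unattainable by any
distribution once skewness is moderate. Both conventions are exposed.

**Feasibility.** Every distribution satisfies raw kurtosis ≥ skewness² + 1,
and the power method's attainable region is narrower (lower boundary
approximately `γ₂ ≥ −1.2264 + 1.6410 γ₁²`). `feasible()` is implemented as
solve-and-check; scenario cells outside the region are *flagged*
(`status="infeasible"`) and never generated — in particular the entire
skewness-4 grid with kurtosis values 1–9 is infeasible under either
convention, and the package reports it as such rather than simulating
something else.

## Monte Carlo engine

Default 10,000 replications per cell at nominal α = 0.05 (override with
`--reps` for quick runs), samples drawn per (test, scenario) cell from an
independent stream derived from the master seed and a cell key, so any
cell is reproducible in isolation and whole studies are bit-identical
under a fixed seed. `common_samples=True` switches to common random
numbers across tests within a cell (variance reduction for between-test
contrasts). Rejection proportions carry the binomial standard error
`√(p(1−p)/reps)`; the conventional adequacy band for empirical size is
[0.045, 0.055]. Negative-skew grids are mirrored from positive skew by
default (`status="mirrored"`), reflecting the generator's exact symmetry.

The size/power studies in the test suite use the study-scale problem sizes
(10,000 replications, n up to 200); the full acceptance layer runs in
under a minute on one core because every test statistic is evaluated as a
vectorized kernel over the whole replication matrix.

## Recommendation checklist

The checklist grid is indexed by sample-size anchors {20, 30, 40, 50, 80,
100, 200}, kurtosis bands [1, 2], (2, 4], (4, 9] (raw kurtosis of the
data, closed on the right), and skewness classes anchored at 0 (symmetric),
0.75 (moderately skewed), and 4 (highly skewed). Since real data never sit
on an anchor, classification cuts at the midpoints 0.375 and 2.375 of
|skewness|; a sample's n maps to the largest anchor ≤ n. Outside the
domain (n < 20, kurtosis outside [1, 9]) the checklist refuses with an
explicit message instead of extrapolating. `assess` composes
moments → classification → recommendation → tests, optionally with the
full 13-test panel; it reports every p-value and decision rather than a
single verdict, because panel disagreement is itself informative.

## What the synthetic data do and do not show

The generator reproduces a *specific* family of alternatives: unimodal
cubic transforms of a normal with prescribed third and fourth moments.
Real heavy-tailed or skewed health data (costs, lengths of stay, biomarker
concentrations) can differ in ways the first four moments do not capture —
multimodality, point masses, censoring, discreteness — so passing power
figures here bound what to expect only for moment-style departures.
Accuracy of the generated shape also degrades exactly at the feasibility
boundary, where the solver's Jacobian becomes ill-conditioned. Two further
limitations: the checklist's skewness cutoffs are an interpolation between
the study anchors, not estimated boundaries; and for tests whose p-values
rely on asymptotic approximations (AJB, RJB, GMG, DAP) the simulated-null
calibrated mode is the more accurate — if less conventional — choice at
small n.
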