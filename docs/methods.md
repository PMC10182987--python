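# Methods

This note documents the models and procedures implemented in `riveryield`,
the choices made where the design was genuinely open, and what the
synthetic test bed does and does not demonstrate.

## Rating-curve load estimation

Instantaneous load on a sampled day is L = 86400·Q·C (gC day⁻¹ from Q in
m³ s⁻¹ and C in mgC L⁻¹; inputs flagged as ft³ s⁻¹ are converted by
0.0283168). Same-day flow and concentration records are paired; multiple
samples on one day are averaged before the load is formed (the source
datasets do not prescribe a rule; averaging is the symmetric choice).
Nonpositive flows or concentrations cannot enter a log model and are
dropped with a logged warning. Stations with fewer than 12 paired
observations — the minimum for a stable nine-model comparison — are
carried to output with a null load and a reason code, never silently
dropped.

Nine candidate models regress ln L on subsets of {lnQ, lnQ², sin(2π·dtime),
cos(2π·dtime), dtime, dtime²}. Both covariates are centered with the
decorrelating center c = mean + Σ(x−mean)³ / (2Σ(x−mean)²), the LOADEST
convention, which zeroes the sample covariance of (x−c) with (x−c)² and so
stabilizes the linear/quadratic pairs; when the covariate is constant the
cubic correction is 0/0 and the center is defined as the common value.
Decimal time is year + (day_of_year − 0.5)/days_in_year.

Fitting is maximum likelihood, which for uncensored records is ordinary
least squares with the ML variance s² = RSS/n. The reference FORTRAN
implementation uses adjusted maximum likelihood (AMLE), whose difference
from plain MLE for uncensored data is O(1/n); the estimator-calibration
test (mean relative bias of the annual load below 2% at n = 100,
σ = 0.5) bounds the practical consequence. The retransformation from the
ln scale uses the lognormal correction exp(s²/2), isolated in
`bias_correction_factor` so an exact small-sample variant can be swapped
in. Model selection minimizes AIC = −2·loglik + 2(p+1), where p counts
the regression coefficients and the +1 the variance; ties break toward the
smaller model id (the candidate list is ordered by complexity). A
rank-deficient design (e.g. the seasonal model on samples that all share
one day-of-year) marks that candidate failed and removes it from
selection. R² is computed on the ln-load scale — the scale the regression
is fit on — and reported in percent; it is invariant to flow-unit
rescaling because centering absorbs multiplicative constants into the
intercept.

The station load is the arithmetic mean of predicted daily loads over the
whole flow record (a whole-record mean, not per-calendar-year means, which
the output period field lets users revisit), converted to kgC yr⁻¹ by
× 365.25/1000.

## Drainage topology

Each catchment unit names its downstream unit; ocean outlets and closed
basins are terminal sentinels, with "closed" additionally flagged on the
unit so the link column stays a pure parent pointer. Corrections to
defective links are an explicit input table — in the real workflow such
repairs come from visual inspection of flowlines, which cannot be
automated here — applied before validation; residual cycles or dangling
links are hard failures naming the offending units. Upstream sets and
accumulated drainage areas are computed by one linear-time traversal, but
correctness is defined set-theoretically (area of every unit whose
downstream walk passes through the target, target included) and tested
against brute-force path-walk oracles.

A station's own unit is included in its drainage area (matching the
additivity identity and gauge convention), except in headwater units,
where the reported gauge area replaces the whole-unit area because the
gauge controls only a fraction of the unit; a headwater station without a
reported area falls back to the derived area with a logged overestimation
warning, and the output flags whether each area is derived or reported.
Closed basins and all units draining into them are excluded from yield
accounting on the assumption that endorheic water and carbon cycles do
not interact with other basins.

## Leveling and yield allocation

Level 1 stations have no gauge downstream; the level of any station is
1 + the number of stations strictly below it on its flow path. Every unit
is assigned to the first station on its downstream walk — a station's own
unit belongs to that station's (upstream) region — and units with no
station below them, or inside a closed drainage, are no-data with a
reason code (`downstream_of_outlet` when a gauge exists upstream of them,
else `no_station`). Two stations on one unit are rejected; co-located
gauges must be merged beforehand.

The yield of the region ending at station s is
Y = (F_s − ΣF_up)/(A_s − ΣA_up) over s's immediate upstream stations,
F/A when there are none. Negative yields are legitimate net removal and
flow through to the output table. Regions with non-positive incremental
area or a missing upstream load are flagged (invalid/incomplete) and emit
no yield. The default granularity is one yield per region; a per-level
pooling mode (all same-level regions of one drainage tree share the
incremental-area-weighted mean) is available because the alternative
reading — one value per level within a basin — also appears in the
workflow this package systematizes. Both modes satisfy the telescoping
identity ΣY·ΔA = F_s. POC and DOC are processed as independent layers over
the same network, each with its own station subset; exact-zero yields are
tallied separately from positive ones so the "greater than zero" class is
unambiguous.

## Validation procedures

The drainage-area check regresses derived on reported areas
(`scipy.stats.linregress`), to be read against the 1:1 line. The
inversed-load check selects pairs where an upstream gauge with ≤20
observations sits under a downstream gauge with ≥30, computes
F_down·(A_up/A_down) as the area-scaled upstream load, and reports the
Pearson correlation and regression slope of estimated versus inversed
loads. Pairing uses immediate upstream stations by default (consistent
with the leveling structure); an any-ancestor mode exists because the
qualifying relation could also be read as unrestricted reachability.
Correlation is computed on untransformed loads, with a log-scale option.

## Synthetic test bed

The generator emulates: a drainage forest (uniform random attachment with
a child cap, so acyclic by construction) with lognormal unit areas whose
default parameters (log-sd 1.0, log-mean ln 104 − 0.5) give a mean of
~104 km², matching the hydrologic-unit population scale the analysis
targets; seasonal lognormal daily flows (defaults: log-mean 3.0 ≈ 20 m³/s,
log-sd 0.8, seasonal amplitude 0.5 in the log — free choices at realistic
gauged-stream magnitudes, since no distributional facts are prescribed);
concentrations back-computed from a ln-load that follows a chosen
rating-curve model exactly, so σ = 0 records are recovered to machine
precision by refitting; and a Gaussian per-unit true-yield field (default
mean 5,000, sd 3,000 kgC km⁻² yr⁻¹, giving mostly-gaining units with a
few percent net-removal) whose induced station loads are exactly
mass-balanced, honoring headwater partial areas. Station records can be
rescaled so the expected rating-curve estimate matches the induced truth,
which is what makes end-to-end closure testable.

It does not emulate: spatial geometry, correlated or autoregressive
flows, censored ("<" detection-limit) concentrations, observation periods
that differ across stations, or any real-basin heterogeneity. Passing
tests therefore demonstrate the correctness of the algorithms under the
stated statistical assumptions, not the accuracy of loads or yields on
real gauge records.

## Problem sizes and numerics

The recovery study uses 50 stations (seasonal model, 200 samples,
σ = 0.2); calibration uses 500 stations (100 samples, σ = 0.5, two-year
flow records); traversal oracles run on 100 random forests of up to 1,000
units — sizes at which the Monte-Carlo standard errors are comfortably
inside the asserted bounds. Mass-balance identities are asserted at 1e-9
relative, coefficient round-trips at 1e-8; exact-arithmetic rules
(filters, exclusions, counts) are asserted bit-exactly. All generators
take explicit seeds; identical seed means byte-identical CSV output.

## Known limitations

- Plain MLE with exp(s²/2) rather than the exact AMLE g-function
  correction; the difference is O(1/n) and bounded by the calibration test.
- Loads estimated over different observation periods are combined in the
  yield equation as-is, uncorrected for temporal mismatch.
- No uncertainty intervals on loads or yields.
- The whole-record mean load is the only averaging mode implemented.
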