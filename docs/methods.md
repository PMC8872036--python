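# Methods

This note documents the models implemented in `terpflux`, the defaults
and conventions chosen where the underlying methodology leaves freedom,
and what the synthetic-data tests do and do not demonstrate about real
field data.

## Chamber flux model

Dynamic enclosures are treated as well-mixed, steady-state flow reactors:
the emission of the enclosed vegetation equals the purge flow times the
outlet-minus-inlet concentration difference, per footprint area (surface
chambers) or per dry leaf mass (branch chambers). Assumptions: purge flow
large enough that chamber residence time is short relative to the 2 h
sample integration; no wall losses (an optional multiplicative correction
for adsorptive monoterpene/sesquiterpene losses exists but defaults to
off, since reported rates in this measurement tradition are usually
uncorrected and therefore possibly biased low by ~20–30 %); timestamps
mark the **end** of each integration period.

Negative concentration differences are physically meaningful (deposition)
or analytical noise; they are retained and flagged
(`deposition_or_noise`) rather than clipped, because the downstream
log-space fit must be able to exclude them explicitly and report the
exclusion count.

Defaults: purge flow Q = 1500 L h⁻¹ (25 L min⁻¹); surface chamber
footprint S = 0.04909 m², a circular base read as 25 cm **diameter** (the
base dimension could also be read as a radius or side length; diameter is
the conventional reading for a "25 cm" circular chamber collar and is
configurable).

## Carbon-basis units and censoring

Mixing ratios (pptv) convert to carbon mass concentrations via the ideal
gas law with R = 8.314 J mol⁻¹ K⁻¹ and atomic masses C = 12.011,
H = 1.008. The pressure/temperature basis of the conversion is exposed as
configuration (defaults: 96.0 kPa, the station pressure of a ~720 m
elevation site, and the measured air temperature where available, else
298.15 K), since conversion bases are rarely stated in field reports and
should not be silently guessed.

Below-LOQ values (default LOQ 2 pptv) are summarized by the half-LOQ
substitution convention: censored entries are replaced by LOQ/2 before
mean, sd, min and max; the quantification frequency is the percentage of
entries at or above the LOQ. The sd is computed after substitution — a
convention, not an unbiased estimator for censored data; for quantities
where censoring dominates, a likelihood-based censored estimator would be
preferable and is out of scope here.

## Standardization

Isoprene standardization uses the classical leaf-level light and
temperature activity factors with their canonical published constants
(α = 0.0027 (μmol m⁻² s⁻¹)⁻¹, c_L1 = 1.066, c_T1 = 95 kJ mol⁻¹,
c_T2 = 230 kJ mol⁻¹, T_M = 314 K, T_s = 303.15 K). The projection is the
**ratio form** ER_std = ER·[C_T(T_std)C_L(PAR_std)]/[C_T(T)C_L(PAR)], so
an observation already at standard conditions is returned unchanged even
though C_T(303.15) ≈ 0.963 ≠ 1; this also makes
standardize ∘ destandardize an exact identity, which is property-tested.
The standard temperature is taken as 303.15 K (exactly 30 °C). PAR = 0
makes the isoprene ratio undefined (C_L = 0) and raises rather than
returning infinity; callers flag and exclude such records.

Monoterpene emission is modelled as storage-pool release, exponential in
temperature with β = 0.09 K⁻¹.

## MEGAN2.1 temperature activity

γ_T is implemented in Kelvin throughout; 0.00831 kJ mol⁻¹ K⁻¹ is the
molar gas constant and 297/313 K are the empirical anchors. The closed
form is the standard CT1 = 95 / CT2 = 200 parameterization

    γ_T = E_opt·200·e^{95x}/(200 − 95(1 − e^{200x})).

Structural identities are tested exactly: the maximum sits at
T_opt(T10) = 313 + 0.6(T10 − 297) with value E_opt(T10) = 2e^{0.08(T10−297)},
and the reference evaluation γ_T(303, 297) is checked against a 50-digit
symbolic recomputation to 1e-9. Exponential overflow for |x| large is
guarded by returning the correct limits (0 in both directions).

C_CE calibration: C_CE = 1/γ_T at standard conditions, defaulting to
T = 303 K, T10 = 297 K (the MEGAN convention; only the γ-scaled-to-unity
requirement is fundamental, so both are configurable). Warming ratios
100·γ_T(T+Δ, T10′)/γ_T(T, T10) expose a `t10_policy` — the 10-day mean
either tracks the warming (`tracking`, default, the steady-state climate
reading) or stays fixed (a transient heat-wave reading). The exact
procedure behind published MEGAN warming-increase ranges is typically
under-specified, so no target value is asserted for this operation.

## Emission–temperature response

Normalization divides each enclosure's fluxes by that enclosure's mean
emission over the reference bin [19, 21) °C. Enclosures without positive
reference coverage cannot be normalized and are dropped with a logged
warning. Temperature bins are half-open [center − w/2, center + w/2) with
w = 2 °C by default, consistent with a "20 ± 1 °C" reference bin.

The fit is ordinary least squares of ln E_norm on (T − 20) over the
**raw normalized records**, not the binned means — binning is retained
for display counts only. Non-positive normalized values are excluded from
the log fit and counted. The daytime restriction (10:00–20:00 local) is
applied by default since nighttime isoprene emission is light-limited and
would bias a temperature-only fit. The intercept is retained as a
diagnostic (≈ 0 by construction of the normalization).

"X % increase with Δ warming" is reported as *final emission = X % of
baseline*, i.e. 100·exp(â·Δ). A pair of printed percentages at Δ = 3 and
Δ = 4 is mutually consistent with a single exponential only under this
reading (both imply â ≈ 0.19 °C⁻¹), whereas the additive
("baseline + X %") reading is not; that consistency check fixed the
convention here.

The MEGAN comparison tabulates both curves normalized to 1 at 20 °C for a
given T10 (default 284.15 K ≈ 11 °C, an Arctic midsummer mean). It is a
plotting/tabulation aid; no closeness statistic is asserted, because the
observed fit is an extrapolating exponential while γ_T levels off above
~30 °C and the two genuinely diverge there.

## Ambient series QC

Detector drift correction uses the CFC-11 and CFC-113 peak areas as an
internal reference: each is normalized by its campaign median, the two
are combined by geometric mean (neither tracer takes precedence), the
proxy is smoothed by a 24 h running median, and analyte values are
multiplied by its reciprocal. Consequences of the median reference:
corrected values sit on the *campaign-median sensitivity* scale (a
planted linear 20 % decay is removed to within the trend CI, while the
corrected level equals truth × median sensitivity). The smoothing window
and reference statistic are conventions — campaign reports rarely state
their exact scheme — and are configurable.

Aggregation windows are local-time (Alaska standard time, UTC−9) hour
intervals, half-open [start, end): daytime 10:00–20:00, midday
11:00–14:00, nighttime 23:00–05:00 (wrapping midnight). Conservation is
exact and tested: the count-weighted mean of hourly means equals the
overall mean, and the daytime window mean equals the count-weighted mean
of hourly means for hours 10–19.

Instrument intercomparison pairs samples nearest-neighbor within 15 min
and reports OLS slope/intercept and Pearson r. Event enhancement is the
ratio of event-window to background-window means. Oxidation-product
ratios (e.g. MVK/MACR) are means of per-sample ratios over pairs with
both compounds quantified; the small positive bias of a ratio of noisy
lognormals is documented and tolerated in tests. Balloon-profile
filtering discards samples strictly below the flight blank (equality
retained).

## Synthetic data: what it emulates, and what it does not

The generator plants: (i) chamber mass balance exact to machine precision
at zero noise (the mass-balance oracle); (ii) an exponential isoprene
temperature response with per-enclosure lognormal biomass scaling (what
normalization must remove) and multiplicative lognormal measurement noise
(CV default 0.15, matching typical 16–25 % analytical uncertainty;
lognormal because concentrations are positive and GC errors are
multiplicative); (iii) weak exponential monoterpene emission; (iv)
midnight-sun diurnal forcing — temperature and PAR both peaking near
local solar noon (~14:00 AST; chamber air tracks radiation through
greenhouse heating) with PAR clipped at a 2 % nocturnal floor; (v)
ambient drift, censoring and event structure as described above.

For the emission–temperature study the generator switches to a stratified
(Latin-hypercube style) temperature draw over 2–32 °C at fixed
near-saturating light: marginally uniform, but guaranteeing every
enclosure covers the 19–21 °C reference bin so that no enclosure drops
out of normalization by sampling accident.

Not emulated: leaf-vs-air temperature decoupling, chamber microclimate
and radiative transfer, turbulence, boundary-layer dynamics, instrument
peak-fitting artifacts, and serial correlation of weather beyond a
per-day temperature offset. Passing tests therefore demonstrate the
correctness of the computational chain under the stated statistical
model, not the field accuracy of the measurements themselves.

## Problem sizes and runtime choices

The standard study configuration is 10 surface enclosures × 60 daytime
samples (600 isoprene records) at noise CV 0.15 — enough that the 95 % CI
on â has half-width ≈ 0.002 °C⁻¹. Coverage of the planted coefficient by
the 95 % CI is checked over 50 independent seeds (expected ≥ 90 %
coverage; the log-space noise is exactly normal, so nominal coverage
holds). Ambient scenarios use 30 days at 2 h resolution. The full test
suite runs in a few seconds on one CPU.

## Known limitations

* The censored sd is a substitution convention, not an estimator.
* Drift correction assumes the CFC areas share the analytes' sensitivity
  drift exactly and have negligible atmospheric variability.
* The exponential fit weights all normalized records equally; enclosures
  with more records influence â more.
* No leveling-off detection above 30 °C: the exponential is extrapolated,
  and disagreement with the saturating γ_T there is expected.
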