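# Methods

## Problem

Shelf bottom waters of the northwest Atlantic (central Scotian Shelf) have
lost dissolved oxygen for decades. Whether that matters to a fish or
invertebrate depends on where the ambient concentration sits relative to the
species' oxygen thresholds — preferred, critical, median lethal (LC50), and
no-survival levels — and, for warming scenarios, relative to its thermal
envelope. `shelfvuln` implements that comparison as a pipeline with four
stages: envelope normalization, trend projection, threshold crossing, and
scenario-based suitability classification.

## Species envelopes

An envelope is one species × life stage, with per-source records for each
variable. Oxygen carries four categories as (min, max) pairs in mg/L;
temperature and salinity carry total range, preferred range, intolerant and
lethal bounds; depth carries total range, mean and preferred; pH carries
exposure levels with coded responses (0 no impact / 1 decrease / 2
increase). Three representation rules matter downstream:

- **Absent ≠ zero.** Blank file cells become `None`; a stored 0.0 is a real
  concentration (the American oyster's LC50 of 0 mg/L). Lookups on absent
  categories raise a `DataDeficientError` rather than returning a default.
- **Sources are never merged away.** Conflicting literature values are kept
  as separate per-source records; consumers choose the union span
  (`span_across_sources`) or the per-source view. A record carrying only an
  upper bound (common for maximum thermal limits) contributes a degenerate
  interval to the span.
- **Single-valued categories** store the one known value in the min slot
  and return it for both bounds.

The packaged fixture holds the threshold values printed in the study's main
text for nine species (wolffish, cod, salmon adult and post-smolt, witch
flounder, snow crab, a spionid polychaete, American oyster, blue crab). The
cod LC50 upper bound of 2.4 mg/L is *inferred* — it is the upper end of the
printed demersal LC50 span (0.9–2.4 mg/L), not a species-specific printed
value — and is flagged `provenance = inferred` in the table and explained
in the sidecar. The full 54-species compilation is deliberately not
reproduced.

## Oxygen units and solubility

All computation happens in mg/L. Fixed-constant conversions use the O₂
molar mass 31.9988 g/mol and 1.42905 mg per mL of O₂ gas (molar mass over
the real-gas molar volume 22.392 L/mol). Percent saturation and per-kg
conversions are state-dependent and require (T, S, P); requesting them
without conditions is an error, mirroring the fact that the original
compilation needed archived salinity data for such conversions.

Solubility is the Garcia–Gordon refit of the Benson–Krause data (volumetric
coefficient set, mL/L × 1.42905), valid for T ∈ [−2, 40] °C, S ∈ [0, 42];
this is the same fit family behind the USGS conversion tables the source
compilation used. Seawater density for per-kg conversions is the UNESCO
EOS-80 surface polynomial (TEOS-10/`gsw` is not assumed to be installed;
at surface pressure the two agree to well within every tolerance used
here). The test suite cross-checks the implementation against an
independently coded per-mass (µmol/kg) coefficient set plus density;
the two published fits agree to 0.014% over T ∈ [0, 30], S ∈ [0, 36].
A nonzero pressure applies the exponential partial-molar-volume correction
(32 cm³/mol); the default — and everything the analysis uses — is surface
pressure.

The solubility-driven deoxygenation percentage is
100·(1 − C\*(T+ΔT, S+ΔS)/C\*(T, S)). For the scenario baseline the analysis
uses (9.0 °C, 34.5): the source study never prints its baseline, and this
choice is the config default because it lands the +6 °C/+0.5 reduction on
the printed 12% after rounding. Sensitivity is mild: ±3 °C on the baseline
moves the rounded percentage by ≤1 point.

## Time-series statistics

- **Outlier screen:** median ± k·MAD with raw (unscaled) MAD and k = 5 by
  default (≈3.4 σ for Gaussian data, <0.1% false removals). The source
  record's QC rule is unpublished; this is a standard robust screen.
- **Summaries:** sample (n−1) standard deviation throughout. The
  high-frequency σ is computed on the full screened sub-daily series; an
  optional harmonic-removal step is *not* applied by default since the
  original σ = 0.36 mg/L is consistent with the raw screened record.
- **Detrending:** OLS line removal; the residual σ uses n−2 degrees of
  freedom so an exact line yields σ = 0. High-frequency and interannual σ
  are separate fields and are never pooled.
- **Depth interpolation** between bracketing stations is linear in depth
  and refuses to extrapolate.

## Trend projection and crossing years

The observed trend −1.06 µmol/L/yr converts to −0.033919 mg/L/yr and is
anchored at (2014.0, 4.32 mg/L) — the midpoint of the Nov 2011–Apr 2015
mooring record and the interpolated 150 m mean. Variability enters as a
lowered start: the crossing of threshold *θ* under band offset *b* solves

    a − b + s·(t − t₀) = θ  →  t = t₀ + (θ − a + b)/s

with a = 4.32, s = −0.033919, b ∈ {0, 2×0.36, 2×0.71}. If a − b ≤ θ the
threshold is already met ("already"); a non-declining trend above the
threshold "never" crosses. Years round to nearest by default (floor/ceil
by flag); with these settings the fractional years 2047.3, 2026.1, 2036.1
and 2056.7 round to the published 2047, 2026, 2036 and 2057. The upper
bound of a threshold range is the default crossing target (first onset of
stress); the lower bound gives the full-loss year. The anchor is a config
parameter: 2014.0 is adopted because it reproduces the published years
exactly, though a 2015 anchor would shift each year by at most one.

## Scenarios and suitability

Scenario I derives its oxygen loss (≈12%) from solubility under ΔT = +6 °C,
ΔS = +0.5; Scenario II prescribes 21% from source-water deoxygenation;
Scenario III combines them. The default combination rule is **additive**
(12 + 21 = 33%), matching the published combined figure; the physically
motivated multiplicative rule (30.5%) is available behind a flag and is
documented as a deliberate discrepancy — the two differ by the compounding
term, and applying I then II sequentially equals the multiplicative path.

`apply_scenario` shifts means (T additively, O₂ multiplicatively by
1 − ΔO₂/100) and carries every σ over unchanged: future variability is
assumed to equal present variability.

Suitability classifies temperature and oxygen independently (no
interaction or metabolic-index coupling). Classes are ordered enums:

- temperature: within preferred < above preferred < above the range of
  some sources < above the range of all sources (per-source exceedance is
  also reported, since upper thermal limits differ between sources);
- oxygen: above critical < at-or-below critical (mean ≤ critical upper
  bound — a mean inside the critical range counts as "at" the level) <
  below LC50 < below no-survival.

Band qualifiers re-classify at mean + 2σ_T (warm edge) and mean − 2σ_O₂
(using the larger of the high-frequency and interannual σ) and flag only a
strictly worse outcome, so variability can worsen but never improve a
verdict. `SiteState` carries a temperature σ alongside the two oxygen σs
because thermal variability at shallow sites is what pushes borderline
sites over preferred limits.

## Synthetic data

The pod generator produces value(t) = mean + A·cos(2π·doy/365.25) + AR(1)
noise at a configurable sampling interval (default hourly, 3.4 years,
matching the observing period). AR(1) innovations are scaled by
√(1 − φ²) so the *stationary* sd equals the requested `noise_sd`
(default φ = 0.9 at hourly sampling, a decorrelation time of ~10 h). The
annual generator is a line plus iid Gaussian noise (default 38 years,
σ = 0.71 mg/L, slope −0.0339 mg/L/yr, central value 5.7 mg/L). Defaults
mirror the observed record's statistics.

What a green recovery test establishes — and what it does not: the
generators are unbiased and correctly scaled, verified by aggregate
recovery over 100 seeds and per-draw recovery within two sampling standard
deviations. At n = 38 the residual σ estimate has a relative sampling sd of
1/√(2·36) ≈ 11.8%, so *no* generator can put ≳95% of single draws within
15% of the true σ; per-draw tolerances in the suite follow the sampling
theory instead. The generators do not emulate event-scale intrusions,
multi-variable covariance, or gaps, so tests exercise the statistical
pathway, not real-data QC pathology.

## Numerical choices and edge cases

- Projection is floored at 0 mg/L; crossings are solved closed-form and
  verified against a monthly brute-force scan (within one month on 200
  randomized cases).
- Union of per-source oxygen records: category-wise min of minima / max of
  maxima; if one source reports only a minimum and another only a smaller
  maximum, the pair is widened rather than rejected.
- A combined scenario loss above 100% clamps with a warning; future O₂ is
  floored at 0.
- Validation errors name the species and the offending category; schema
  errors name the missing column.

## Known limitations

- The cod LC50 crossing "as early as 2028 under interannual variability"
  depends on the supplement-only species-specific LC50 and is therefore
  only bounded (trend-only crossing after 2065), not reproduced to the year.
- The default site states for the assessment pipeline are synthetic
  stand-ins (plausible shelf values with the right depth ordering), since
  the per-site mooring statistics are unpublished; real site tables can be
  supplied via `--sites`.
- Only linear trends are supported; no probabilistic exceedance model
  beyond the ±2σ construction.
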