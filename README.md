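# shelfvuln

Species climate-vulnerability assessment for shelf bottom waters.

`shelfvuln` is for marine ecologists and climate-impact analysts who have
literature-derived species tolerance data (oxygen thresholds, thermal
ranges) and observed bottom-water conditions, and want to answer two
questions quantitatively:

1. **When** does a declining oxygen trend reach each species' thresholds —
   and how much sooner once natural variability is accounted for?
2. **Which** species keep suitable temperature and oxygen conditions under
   future warming/deoxygenation scenarios?

## The model

Bottom oxygen is modelled as a linear multidecadal decline anchored at an
observed mean state, O₂(t) = a + s·(t − t₀), with the central Scotian Shelf
defaults s = −1.06 µmol L⁻¹ yr⁻¹ (−0.0339 mg L⁻¹ yr⁻¹ via the O₂ molar
mass 31.9988 g mol⁻¹) and (t₀, a) = (2014.0, 4.32 mg L⁻¹), the interpolated
150 m mooring mean. Natural variability enters as ±2σ bands: a
high-frequency σ = 0.36 mg L⁻¹ from near-hourly mooring records, and an
interannual σ = 0.71 mg L⁻¹ from a detrended 38-year annual anomaly series.
The first possible encounter with a species threshold θ under band offset
b = 2σ is the closed-form crossing year

    t = t₀ + (θ − a + b) / s,

reported as "already" when a − b ≤ θ. Future scenarios perturb an observed
site state by (ΔT, ΔS, ΔO₂%): a solubility-driven oxygen loss computed from
the Garcia–Gordon (Benson–Krause) saturation fit, a prescribed source-water
deoxygenation, or their (additive, by default) combination — with
present-day variability carried over unchanged. Species suitability is then
classified independently for temperature and oxygen against the envelope
categories, with ±2σ qualifiers.

## Worked example

```python
from shelfvuln import (OxygenQuantity, TrendSpec, VariabilityBands,
                       crossing_table, load_main_text_envelopes)
from shelfvuln.config import crossing_frame

envs = [e for e in load_main_text_envelopes()
        if e.key.latin_name in ("Gadus morhua", "Glyptocephalus cynoglossus")]
trend = TrendSpec.from_quantity(OxygenQuantity(-1.06, "umol_per_L"),
                                anchor_year=2014.0, anchor_value=4.32)
rows = crossing_table(envs, trend, VariabilityBands.from_sigmas(0.36, 0.71),
                      categories=("critical", "no_survival"))
print(crossing_frame(rows).dropna(subset=["threshold_mg_per_L"]).to_string(index=False))
```

prints

```
                latin_name  life_stage    category  threshold_mg_per_L       mode  status  fractional_year  crossing_year
              Gadus morhua       adult    critical                3.19    ia_band already      2014.000000         2014.0
              Gadus morhua       adult    critical                3.19    hf_band crosses      2026.087717         2026.0
Glyptocephalus cynoglossus unspecified no_survival                2.15    ia_band crosses      2036.111678         2036.0
              Gadus morhua       adult    critical                3.19 trend_only crosses      2047.314929         2047.0
Glyptocephalus cynoglossus unspecified no_survival                2.15    hf_band crosses      2056.749245         2057.0
Glyptocephalus cynoglossus unspecified no_survival                2.15 trend_only crosses      2077.976456         2078.0
```

Read: on the trend alone, Atlantic cod's critical oxygen level
(upper bound 3.19 mg/L) is reached in 2047; with the high-frequency ±2σ
band the first encounter moves to 2026, and under the larger interannual
band the level is met already at the anchor state. Witch flounder's
no-survival level (2.15 mg/L) is first met in 2036 (interannual) and 2057
(high-frequency).

The same pipelines are exposed on the command line:

```sh
shelfvuln convert 1.06 umol_per_L mg_per_L        # 0.0339187 mg_per_L
shelfvuln project --out out/                      # crossing timetable + files
shelfvuln assess --out out/                       # scenario suitability verdicts
shelfvuln simulate --kind pod --seed 1 --out pod.csv
shelfvuln report --out out/                       # both, plus scenario summary
```

## Data

A packaged fixture (`shelfvuln/data/main_text_thresholds.csv` with a JSON
units sidecar) carries the published headline thresholds for nine species;
`load_envelopes` reads any table in the same one-row-per
species × life stage × source layout, with a header map for other dialects.
Blank cells are *absent* (never zero); multi-source values are kept
per-source. The cod LC50 upper bound (2.4 mg/L) is flagged as inferred from
the published demersal span — see `docs/methods.md`.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
recomputes the headline crossing years from scratch — loading the packaged
envelope fixture, converting the trend slope, and solving the crossings for
the cod critical, cod median-lethal, and witch flounder no-survival
thresholds under each variability band — and writes them as JSON.
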