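"""Run configuration and the two composed pipelines.

``run_timetable`` chains unit conversion → trend construction → threshold
crossing into the species oxygen-loss timetable; ``run_assessment`` builds
the future scenarios, applies them to site states, and classifies species
suitability. All defaults mirror the study parameterization: trend
−1.06 µmol/L/yr anchored at (2014.0, 4.32 mg/L), variability bands
2×0.36 and 2×0.71 mg/L, additive scenario combination, nearest-year
rounding.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import units
from .envelopes import SpeciesEnvelope, load_envelopes, load_main_text_envelopes
from .projection import CrossingResult, TrendSpec, VariabilityBands, crossing_table
from .scenarios import (
    Scenario,
    SuitabilityVerdict,
    apply_scenario,
    assess,
    build_solubility_scenario,
    build_source_water_scenario,
    combine,
)
from .tsstats import SiteState

__all__ = [
    "RunConfig",
    "DEFAULT_SITES",
    "default_scenarios",
    "run_timetable",
    "run_assessment",
    "read_sites",
    "write_sites",
    "crossing_frame",
    "verdict_frame",
]

#: Synthetic stand-ins for the three mooring sites used in the assessment.
#: Means and sigmas are plausible shelf bottom-water values chosen so the
#: depth ordering (warmer/less oxygenated at depth in the future state) is
#: respected; they are NOT the (unpublished) observed pod statistics.
DEFAULT_SITES: tuple[SiteState, ...] = (
    SiteState(site_id="SYN-POD-060", depth=60.0, mean_T=3.73, mean_S=31.5,
              mean_O2=9.0, sd_hf=0.50, sd_ia=0.71, sd_T=1.00),
    SiteState(site_id="SYN-POD-115", depth=115.0, mean_T=4.50, mean_S=32.5,
              mean_O2=7.0, sd_hf=0.40, sd_ia=0.71, sd_T=0.80),
    SiteState(site_id="SYN-POD-160", depth=160.0, mean_T=4.60, mean_S=34.0,
              mean_O2=4.76, sd_hf=0.36, sd_ia=0.71, sd_T=0.50),
)


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run needs; defaults follow the study."""

    envelope_table: str | None = None  # None -> packaged fixture
    sites_table: str | None = None  # None -> synthetic default sites
    trend_value: float = -1.06
    trend_unit: str = "umol_per_L"
    anchor_year: float = 2014.0
    anchor_value: float = 4.32  # mg/L
    sigma_hf: float = 0.36  # mg/L, mooring high-frequency
    sigma_ia: float = 0.71  # mg/L, detrended interannual
    categories: tuple[str, ...] = ("preferred", "critical", "lc50", "no_survival")
    bound: str = "upper"
    rounding: str = "nearest"
    scenario_baseline_T: float = 9.0
    scenario_baseline_S: float = 34.5
    scenario_dT: float = 6.0
    scenario_dS: float = 0.5
    scenario_source_water_pct: float = 21.0
    combine_rule: str = "additive"
    outdir: str | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "categories" in raw:
            raw["categories"] = tuple(raw["categories"])
        return cls(**raw)

    def trend(self) -> TrendSpec:
        return TrendSpec.from_quantity(
            units.OxygenQuantity(self.trend_value, units.OxygenUnit(self.trend_unit)),
            anchor_year=self.anchor_year,
            anchor_value=self.anchor_value,
        )

    def bands(self) -> VariabilityBands:
        return VariabilityBands.from_sigmas(self.sigma_hf, self.sigma_ia)

    def envelopes(self) -> list[SpeciesEnvelope]:
        if self.envelope_table is None:
            return load_main_text_envelopes()
        return load_envelopes(self.envelope_table)

    def sites(self) -> list[SiteState]:
        if self.sites_table is None:
            return list(DEFAULT_SITES)
        return read_sites(self.sites_table)


def default_scenarios(config: RunConfig) -> dict[str, Scenario]:
    """The three standard scenarios: solubility, source water, combined."""
    s1 = build_solubility_scenario(
        units.WaterConditions(config.scenario_baseline_T, config.scenario_baseline_S),
        config.scenario_dT,
        config.scenario_dS,
        label="I",
    )
    s2 = build_source_water_scenario(config.scenario_source_water_pct, label="II")
    s3 = combine(s1, s2, rule=config.combine_rule, label="III")
    return {"I": s1, "II": s2, "III": s3}


# ---------------------------------------------------------------------------
# Site-state tables

_SITE_COLUMNS = [
    "site_id", "depth", "mean_T", "mean_S", "mean_O2", "sd_hf", "sd_ia", "sd_T",
]


def read_sites(path: str | Path) -> list[SiteState]:
    df = pd.read_csv(path)
    missing = set(_SITE_COLUMNS[:2]) - set(df.columns)
    if missing:
        raise ValueError(f"sites table missing columns: {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        kwargs = {
            c: (None if c not in df.columns or pd.isna(row[c]) else float(row[c]))
            for c in _SITE_COLUMNS[1:]
        }
        out.append(SiteState(site_id=str(row["site_id"]), **kwargs))
    return out


def write_sites(sites: list[SiteState], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        [{c: getattr(s, c) for c in _SITE_COLUMNS} for s in sites]
    ).to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# Result tables

def crossing_frame(rows: list[CrossingResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "latin_name": r.species_key.latin_name if r.species_key else None,
                "life_stage": r.species_key.life_stage if r.species_key else None,
                "category": r.threshold_category,
                "threshold_mg_per_L": r.threshold_value,
                "mode": r.mode,
                "status": r.status.value,
                "fractional_year": r.fractional_year,
                "crossing_year": r.crossing_year,
            }
            for r in rows
        ]
    )


def verdict_frame(rows: list[SuitabilityVerdict]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "latin_name": v.species_key.latin_name,
                "life_stage": v.species_key.life_stage,
                "site_id": v.site_id,
                "scenario": v.scenario,
                "temperature_class": v.temperature_class.name.lower()
                if v.temperature_class is not None
                else "data_deficient",
                "oxygen_class": v.oxygen_class.name.lower()
                if v.oxygen_class is not None
                else "data_deficient",
                "temperature_variability_flag": v.temperature_variability_flag,
                "oxygen_variability_flag": v.oxygen_variability_flag,
            }
            for v in rows
        ]
    )


# ---------------------------------------------------------------------------
# Pipelines

def _write_outputs(df: pd.DataFrame, outdir: str | Path, stem: str, summary: str) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    df.to_csv(outdir / f"{stem}.csv", index=False)
    (outdir / f"{stem}.json").write_text(
        json.dumps(df.where(df.notna(), None).to_dict(orient="records"), indent=1)
    )
    (outdir / f"{stem}_summary.txt").write_text(summary)


def run_timetable(config: RunConfig) -> list[CrossingResult]:
    """Species threshold-crossing timetable under the configured trend."""
    envelopes = config.envelopes()
    trend = config.trend()
    bands = config.bands()
    rows = crossing_table(
        envelopes, trend, bands,
        categories=config.categories, bound=config.bound, rounding=config.rounding,
    )
    if config.outdir:
        df = crossing_frame(rows)
        summary = [
            "Threshold-crossing timetable",
            f"trend: {config.trend_value} {config.trend_unit}/yr "
            f"(= {trend.slope:.6f} mg/L/yr), anchor ({trend.anchor_year}, "
            f"{trend.anchor_value} mg/L)",
            f"bands: 2x{config.sigma_hf} (high-frequency), 2x{config.sigma_ia} "
            "(interannual) mg/L",
            f"rounding: {config.rounding}; threshold bound: {config.bound}",
            "",
            df.to_string(index=False),
            "",
        ]
        _write_outputs(df, config.outdir, "crossing_table", "\n".join(summary))
    return rows


def run_assessment(config: RunConfig) -> list[SuitabilityVerdict]:
    """Suitability verdicts for every species × site under the combined scenario."""
    envelopes = config.envelopes()
    sites = config.sites()
    scenario = default_scenarios(config)["III"]
    verdicts = []
    for site in sites:
        future = apply_scenario(scenario, site)
        for env in envelopes:
            verdicts.append(assess(env, future))
    if config.outdir:
        df = verdict_frame(verdicts)
        summary = [
            "Habitat suitability under the combined future scenario",
            f"scenario III: dT=+{scenario.dT} degC, dS=+{scenario.dS}, "
            f"dO2=-{scenario.dO2_pct:.1f}% ({config.combine_rule})",
            "",
            df.to_string(index=False),
            "",
        ]
        _write_outputs(df, config.outdir, "assessment", "\n".join(summary))
    return verdicts
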