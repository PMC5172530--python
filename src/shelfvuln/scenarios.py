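"""Future bottom-water scenarios and species habitat-suitability assessment.

A scenario is a (ΔT, ΔS, ΔO₂%) perturbation of an observed site state. The
solubility mechanism derives its oxygen loss from the reduction of oxygen
saturation under warming/salinification; the source-water mechanism carries
a prescribed percentage (deoxygenation of the off-shelf water mass feeding
the shelf bottom); a combined scenario stacks both. Present-day variability
(±2σ) is assumed to persist unchanged around the shifted means.

Suitability treats temperature and oxygen independently (no interaction
effects): the site mean is classified against the species envelope, and a
variability qualifier flags cases where the ±2σ band — not the mean —
triggers a worse class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import IntEnum

from . import units
from .envelopes import DataDeficientError, SpeciesEnvelope, get_threshold, span_across_sources
from .tsstats import SiteState

__all__ = [
    "Scenario",
    "FutureSiteState",
    "TemperatureClass",
    "OxygenClass",
    "SuitabilityVerdict",
    "build_solubility_scenario",
    "build_source_water_scenario",
    "combine",
    "apply_scenario",
    "assess",
]


@dataclass(frozen=True)
class Scenario:
    """A future perturbation: warming ΔT, salinification ΔS, oxygen loss %."""

    label: str
    dT: float = 0.0
    dS: float = 0.0
    dO2_pct: float = 0.0
    mechanism: str = "source_water"  # solubility | source_water | combined
    parents: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (0.0 <= self.dO2_pct <= 100.0):
            raise ValueError("dO2_pct must lie in [0, 100]")
        if self.mechanism not in ("solubility", "source_water", "combined"):
            raise ValueError(f"unknown mechanism {self.mechanism!r}")


@dataclass(frozen=True)
class FutureSiteState(SiteState):
    """A site state after a scenario shift; variability carried over."""

    scenario: str = ""
    provenance: tuple[str, ...] = ()


class TemperatureClass(IntEnum):
    """Ordered thermal suitability (larger is worse)."""

    WITHIN_PREFERRED = 0
    ABOVE_PREFERRED = 1
    ABOVE_RANGE_SOME_SOURCE = 2
    ABOVE_RANGE_ALL_SOURCES = 3


class OxygenClass(IntEnum):
    """Ordered oxygen suitability (larger is worse)."""

    ABOVE_CRITICAL = 0
    AT_OR_BELOW_CRITICAL = 1
    BELOW_LC50 = 2
    BELOW_NO_SURVIVAL = 3


@dataclass(frozen=True)
class SuitabilityVerdict:
    species_key: object
    site_id: str
    scenario: str
    temperature_class: TemperatureClass | None  # None = data deficient
    oxygen_class: OxygenClass | None
    temperature_band_class: TemperatureClass | None
    oxygen_band_class: OxygenClass | None
    temperature_variability_flag: bool
    oxygen_variability_flag: bool
    per_source_range_exceeded: tuple[tuple[str | None, bool], ...] = ()


def build_solubility_scenario(
    baseline: units.WaterConditions, dT: float, dS: float, label: str = "I"
) -> Scenario:
    """Scenario whose oxygen loss is the solubility reduction for (ΔT, ΔS)."""
    pct = units.solubility_reduction_pct(baseline, dT, dS)
    return Scenario(label=label, dT=dT, dS=dS, dO2_pct=pct, mechanism="solubility")


def build_source_water_scenario(dO2_pct: float, label: str = "II") -> Scenario:
    """Scenario with a prescribed oxygen loss from source-water deoxygenation."""
    return Scenario(label=label, dO2_pct=dO2_pct, mechanism="source_water")


def combine(a: Scenario, b: Scenario, rule: str = "additive", label: str | None = None) -> Scenario:
    """Combine two scenarios: ΔT and ΔS sum; oxygen loss per ``rule``.

    ``additive`` simply sums the percentages (the convention behind a
    12% + 21% = 33% combined loss); ``multiplicative`` compounds the two
    survival fractions, 100·(1 − (1−a/100)(1−b/100)). A combined loss over
    100% is clamped with a warning.
    """
    if rule == "additive":
        pct = a.dO2_pct + b.dO2_pct
    elif rule == "multiplicative":
        pct = 100.0 * (1.0 - (1.0 - a.dO2_pct / 100.0) * (1.0 - b.dO2_pct / 100.0))
    else:
        raise ValueError(f"unknown combination rule {rule!r}")
    if pct > 100.0:
        warnings.warn("combined oxygen reduction exceeds 100%; clamping", stacklevel=2)
        pct = 100.0
    return Scenario(
        label=label or f"{a.label}+{b.label}",
        dT=a.dT + b.dT,
        dS=a.dS + b.dS,
        dO2_pct=pct,
        mechanism="combined",
        parents=(a.label, b.label),
    )


def apply_scenario(scn: Scenario, site: SiteState) -> FutureSiteState:
    """Shift a site state by a scenario; variability magnitudes unchanged.

    Future mean T = mean T + ΔT; future mean O₂ = mean O₂ × (1 − ΔO₂%/100).
    Observed ranges are shifted with the means (temperature) or scaled with
    the mean (oxygen), and the σ fields are carried over verbatim — the
    assumption that future variability looks like today's.
    """
    if site.mean_T is None or site.mean_O2 is None:
        raise ValueError("site state must carry mean temperature and oxygen")
    o2_factor = 1.0 - scn.dO2_pct / 100.0
    new_range_T = (
        (site.range_T[0] + scn.dT, site.range_T[1] + scn.dT) if site.range_T else None
    )
    new_range_O2 = (
        (site.range_O2[0] * o2_factor, site.range_O2[1] * o2_factor)
        if site.range_O2
        else None
    )
    return FutureSiteState(
        site_id=site.site_id,
        depth=site.depth,
        mean_T=site.mean_T + scn.dT,
        mean_S=(site.mean_S + scn.dS) if site.mean_S is not None else None,
        mean_O2=max(0.0, site.mean_O2 * o2_factor),
        sd_hf=site.sd_hf,
        sd_ia=site.sd_ia,
        sd_T=site.sd_T,
        range_T=new_range_T,
        range_O2=new_range_O2,
        scenario=scn.label,
        provenance=(
            f"mean_T = observed + {scn.dT}",
            f"mean_O2 = observed x {o2_factor:.4f}",
            "sd_hf, sd_ia, sd_T carried over unchanged",
        ),
    )


def _classify_temperature(
    env: SpeciesEnvelope, temp: float
) -> tuple[TemperatureClass, tuple[tuple[str | None, bool], ...]]:
    per_source: tuple[tuple[str | None, bool], ...] = ()
    try:
        span = span_across_sources(env, "temperature_range")
        per_source = tuple((s, temp > hi) for s, _, hi in span.per_source)
    except DataDeficientError:
        span = None
    if span is not None and any(flag for _, flag in per_source):
        if all(flag for _, flag in per_source):
            return TemperatureClass.ABOVE_RANGE_ALL_SOURCES, per_source
        return TemperatureClass.ABOVE_RANGE_SOME_SOURCE, per_source
    try:
        pref_max = get_threshold(env, "temperature_preferred", "upper")
    except DataDeficientError:
        if span is None:
            raise
        pref_max = None
    if pref_max is not None and temp > pref_max:
        return TemperatureClass.ABOVE_PREFERRED, per_source
    return TemperatureClass.WITHIN_PREFERRED, per_source


def _classify_oxygen(env: SpeciesEnvelope, o2: float) -> OxygenClass:
    def bound(category: str) -> float | None:
        try:
            return get_threshold(env, category, "upper")
        except DataDeficientError:
            return None

    ns, lc, crit = bound("no_survival"), bound("lc50"), bound("critical")
    if ns is None and lc is None and crit is None:
        raise DataDeficientError(
            f"{env.key.latin_name}: no oxygen threshold categories"
        )
    if ns is not None and o2 < ns:
        return OxygenClass.BELOW_NO_SURVIVAL
    if lc is not None and o2 < lc:
        return OxygenClass.BELOW_LC50
    if crit is not None and o2 <= crit:
        return OxygenClass.AT_OR_BELOW_CRITICAL
    return OxygenClass.ABOVE_CRITICAL


def assess(env: SpeciesEnvelope, site: SiteState) -> SuitabilityVerdict:
    """Classify a species' thermal and oxygen suitability at a site.

    Mean-based classes come from the site means; band classes re-classify
    at mean + 2σ_T (warm edge) and mean − 2σ (low-oxygen edge, using the
    larger of the high-frequency and interannual σ). The variability flags
    are set only when the band class is strictly worse than the mean class.
    Missing envelope blocks yield ``None`` classes (data deficient).
    """
    t_class = t_band = None
    per_source: tuple[tuple[str | None, bool], ...] = ()
    if site.mean_T is not None:
        try:
            t_class, per_source = _classify_temperature(env, site.mean_T)
            if site.sd_T:
                t_band, _ = _classify_temperature(env, site.mean_T + 2.0 * site.sd_T)
                t_band = max(t_class, t_band)
        except DataDeficientError:
            pass
    o_class = o_band = None
    if site.mean_O2 is not None:
        try:
            o_class = _classify_oxygen(env, site.mean_O2)
            sigma = max(site.sd_hf or 0.0, site.sd_ia or 0.0)
            if sigma:
                o_band = _classify_oxygen(env, max(0.0, site.mean_O2 - 2.0 * sigma))
                o_band = max(o_class, o_band)
        except DataDeficientError:
            pass
    return SuitabilityVerdict(
        species_key=env.key,
        site_id=site.site_id,
        scenario=getattr(site, "scenario", ""),
        temperature_class=t_class,
        oxygen_class=o_class,
        temperature_band_class=t_band,
        oxygen_band_class=o_band,
        temperature_variability_flag=(
            t_band is not None and t_class is not None and t_band > t_class
        ),
        oxygen_variability_flag=(
            o_band is not None and o_class is not None and o_band > o_class
        ),
        per_source_range_exceeded=per_source,
    )
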