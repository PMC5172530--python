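"""Linear trend projection and species threshold-crossing years.

A multidecadal linear oxygen decline, anchored at an observed mean state,
is extended forward and intersected with species oxygen thresholds. Natural
variability enters as ±2σ offsets of the trend start: a high-frequency band
(mooring σ) and an interannual band (detrended annual-anomaly σ). The
crossing year under an offset of 2σ answers "how soon could the species
first encounter this threshold given observed variability".
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

from . import units
from .envelopes import DataDeficientError, SpeciesEnvelope, SpeciesKey, get_threshold

__all__ = [
    "TrendSpec",
    "VariabilityBands",
    "CrossingStatus",
    "CrossingResult",
    "project",
    "crossing_year",
    "crossing_table",
]


@dataclass(frozen=True)
class TrendSpec:
    """A linear concentration trend anchored at (year, value), in mg/L."""

    slope: float  # mg/L per year, signed
    anchor_year: float
    anchor_value: float  # mg/L

    def __post_init__(self) -> None:
        if not math.isfinite(self.slope):
            raise ValueError("slope must be finite")
        if self.anchor_value < 0:
            raise ValueError("anchor_value must be >= 0")

    @classmethod
    def from_quantity(
        cls,
        slope: units.OxygenQuantity,
        anchor_year: float,
        anchor_value: float,
        conditions: units.WaterConditions | None = None,
    ) -> "TrendSpec":
        """Build a trend from a slope in any oxygen unit (converted to mg/L)."""
        mg = units.convert(slope, units.OxygenUnit.MG_PER_L, conditions)
        return cls(slope=mg.value, anchor_year=anchor_year, anchor_value=anchor_value)


@dataclass(frozen=True)
class VariabilityBands:
    """±2σ offsets in mg/L: high-frequency (mooring) and interannual."""

    two_sigma_hf: float
    two_sigma_ia: float

    def __post_init__(self) -> None:
        if self.two_sigma_hf < 0 or self.two_sigma_ia < 0:
            raise ValueError("band offsets must be >= 0")

    @classmethod
    def from_sigmas(cls, sigma_hf: float, sigma_ia: float) -> "VariabilityBands":
        return cls(two_sigma_hf=2.0 * sigma_hf, two_sigma_ia=2.0 * sigma_ia)


class CrossingStatus(str, Enum):
    CROSSES = "crosses"
    ALREADY = "already"  # offset start is at or below the threshold today
    NEVER = "never"  # non-declining trend above the threshold
    DATA_DEFICIENT = "data_deficient"


#: Variability modes: trend only, or trend start lowered by one of the bands.
MODES = ("trend_only", "hf_band", "ia_band")


@dataclass(frozen=True)
class CrossingResult:
    species_key: SpeciesKey | None
    threshold_category: str
    threshold_value: float | None
    mode: str
    status: CrossingStatus
    fractional_year: float | None
    crossing_year: int | None

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")


def project(trend: TrendSpec, year: float) -> float:
    """Concentration (mg/L) on the extended trend line, floored at 0."""
    if year < trend.anchor_year:
        raise ValueError("projection year precedes the trend anchor")
    return max(0.0, trend.anchor_value + trend.slope * (year - trend.anchor_year))


def _round_year(t: float, rounding: str) -> int:
    if rounding == "nearest":
        return int(math.floor(t + 0.5))
    if rounding == "floor":
        return int(math.floor(t))
    if rounding == "ceil":
        return int(math.ceil(t))
    raise ValueError(f"unknown rounding mode {rounding!r}")


def crossing_year(
    trend: TrendSpec,
    threshold: float,
    band_offset: float = 0.0,
    rounding: str = "nearest",
    species_key: SpeciesKey | None = None,
    category: str = "",
    mode: str = "trend_only",
) -> CrossingResult:
    """Closed-form year at which the (offset) trend reaches a threshold.

    Solves ``anchor_value − band_offset + slope·(t − anchor_year) =
    threshold``. Reports ``already`` when the offset start is at or below
    the threshold, and ``never`` for a non-declining trend that starts
    above it.
    """
    if band_offset < 0:
        raise ValueError("band_offset must be >= 0")
    start = trend.anchor_value - band_offset
    if start <= threshold:
        return CrossingResult(
            species_key, category, threshold, mode,
            CrossingStatus.ALREADY, trend.anchor_year, int(round(trend.anchor_year)),
        )
    if trend.slope >= 0:
        return CrossingResult(
            species_key, category, threshold, mode,
            CrossingStatus.NEVER, None, None,
        )
    t = trend.anchor_year + (threshold - start) / trend.slope
    return CrossingResult(
        species_key, category, threshold, mode,
        CrossingStatus.CROSSES, t, _round_year(t, rounding),
    )


_DEFAULT_CATEGORIES = ("preferred", "critical", "lc50", "no_survival")


def crossing_table(
    envelopes: list[SpeciesEnvelope],
    trend: TrendSpec,
    bands: VariabilityBands,
    categories: tuple[str, ...] = _DEFAULT_CATEGORIES,
    bound: str = "upper",
    rounding: str = "nearest",
) -> list[CrossingResult]:
    """Crossing years for every species × oxygen category × variability mode.

    The upper bound of a threshold range is the default (first onset of
    stress); pass ``bound="lower"`` for the full-loss year. Data-deficient
    categories are reported as explicit rows, never dropped silently. Rows
    are ordered soonest-first (``already`` first, then by fractional year,
    with ``never`` and data-deficient rows last).
    """
    offsets = {
        "trend_only": 0.0,
        "hf_band": bands.two_sigma_hf,
        "ia_band": bands.two_sigma_ia,
    }
    rows: list[CrossingResult] = []
    for env in envelopes:
        for category in categories:
            try:
                threshold = get_threshold(env, category, bound)
            except DataDeficientError:
                for mode in MODES:
                    rows.append(
                        CrossingResult(
                            env.key, category, None, mode,
                            CrossingStatus.DATA_DEFICIENT, None, None,
                        )
                    )
                continue
            for mode, offset in offsets.items():
                rows.append(
                    crossing_year(
                        trend, threshold, offset, rounding,
                        species_key=env.key, category=category, mode=mode,
                    )
                )

    def sort_key(r: CrossingResult) -> float:
        if r.status is CrossingStatus.ALREADY:
            return trend.anchor_year
        if r.status is CrossingStatus.CROSSES:
            return r.fractional_year
        return math.inf

    return sorted(rows, key=sort_key)
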