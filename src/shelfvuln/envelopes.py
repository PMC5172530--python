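"""Species environmental envelopes: data model, delimited-text I/O, fixture.

A species envelope collects the literature-derived tolerated and preferred
ranges of one species × life stage across dissolved oxygen, temperature,
salinity, depth and pH. Oxygen carries four threshold categories — preferred,
critical, median lethal (LC50), and no-survival — each as a (min, max) pair
in mg/L; temperature and salinity carry total range, preferred range,
intolerant and lethal bounds; depth carries total range, mean and preferred.

Multiple literature sources for the same species are never merged away:
every per-source record is retained, and consumers choose between the union
span and the per-source view. Absent data is an empty cell on disk and
``None`` in memory — 0.0 is a legal concentration (an oyster LC50 of 0 mg/L
means no oxygen requirement for median survival).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum, IntEnum
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "HabitatZone",
    "SpeciesKey",
    "OxygenThresholds",
    "TemperatureEnvelope",
    "SalinityEnvelope",
    "DepthEnvelope",
    "PhResponse",
    "PhResponseCode",
    "SpeciesEnvelope",
    "SourceSpan",
    "SchemaError",
    "EnvelopeValidationError",
    "DataDeficientError",
    "CRITERIA_CODES",
    "load_envelopes",
    "write_envelopes",
    "get_threshold",
    "span_across_sources",
    "main_text_fixture_path",
    "load_main_text_envelopes",
    "fixture_metadata",
]

#: Inclusion-criteria vocabulary: bycatch, baitfish, commercial fishery,
#: predator/prey of commercial species, endangered, ecosystem energy
#: transfer, invasive, special concern, threatened, vagrant.
CRITERIA_CODES = frozenset(
    {"BC", "BF", "CF", "CFP", "E", "EET", "IS", "SC", "T", "VS"}
)


class SchemaError(ValueError):
    """An input table is missing a mandatory column or has a bad header."""


class EnvelopeValidationError(ValueError):
    """An envelope violates an invariant (e.g. category min > max)."""


class DataDeficientError(LookupError):
    """The requested category has no data — distinct from a value of zero."""


class HabitatZone(str, Enum):
    """Vertical habitat zone: water column, near-bottom, on-bottom, in-sediment."""

    PELAGIC = "pelagic"
    DEMERSAL = "demersal"
    BENTHIC = "benthic"
    INFAUNAL = "infaunal"


class PhResponseCode(IntEnum):
    NO_IMPACT = 0
    DECREASE = 1
    INCREASE = 2


@dataclass(frozen=True)
class SpeciesKey:
    latin_name: str
    common_name: str
    life_stage: str = "unspecified"
    habitat_zone: HabitatZone = HabitatZone.DEMERSAL

    def __post_init__(self) -> None:
        if not self.latin_name:
            raise EnvelopeValidationError("latin_name must be non-empty")
        object.__setattr__(self, "habitat_zone", HabitatZone(self.habitat_zone))


# (category, (field for lower bound, field for upper bound)) used both for
# validation and for threshold lookup.
_OXYGEN_CATEGORIES = {
    "preferred": ("preferred_min", "preferred_max"),
    "critical": ("critical_min", "critical_max"),
    "lc50": ("lc50_min", "lc50_max"),
    "no_survival": ("no_survival_min", "no_survival_max"),
}
_TS_CATEGORIES = {
    "range": ("range_min", "range_max"),
    "preferred": ("preferred_min", "preferred_max"),
    "intolerant": ("intolerant_low", "intolerant_high"),
    "lethal": ("lethal_low", "lethal_high"),
}
_DEPTH_CATEGORIES = {
    "range": ("range_min", "range_max"),
    "mean": ("mean", "mean"),
    "preferred": ("preferred_min", "preferred_max"),
}


def _check_pairs(record, categories: dict, label: str, *, nonnegative: bool) -> None:
    for cat, (lo_f, hi_f) in categories.items():
        lo = getattr(record, lo_f)
        hi = getattr(record, hi_f)
        for v in (lo, hi):
            if v is not None and nonnegative and v < 0:
                raise EnvelopeValidationError(
                    f"{label} {cat}: negative value {v}"
                )
        if lo is not None and hi is not None and lo > hi:
            raise EnvelopeValidationError(
                f"{label} {cat}: min {lo} > max {hi}"
            )


@dataclass(frozen=True)
class OxygenThresholds:
    """Oxygen threshold categories in mg/L; ``None`` marks absent data.

    For the preferred category a single known value is stored as
    ``preferred_min`` (only the minimum preferred concentration is known).
    """

    preferred_min: float | None = None
    preferred_max: float | None = None
    critical_min: float | None = None
    critical_max: float | None = None
    lc50_min: float | None = None
    lc50_max: float | None = None
    no_survival_min: float | None = None
    no_survival_max: float | None = None
    source_id: str | None = None

    def __post_init__(self) -> None:
        _check_pairs(self, _OXYGEN_CATEGORIES, "oxygen", nonnegative=True)


@dataclass(frozen=True)
class TemperatureEnvelope:
    """One source's temperature categories in °C."""

    range_min: float | None = None
    range_max: float | None = None
    preferred_min: float | None = None
    preferred_max: float | None = None
    intolerant_low: float | None = None
    intolerant_high: float | None = None
    lethal_low: float | None = None
    lethal_high: float | None = None
    source_id: str | None = None

    def __post_init__(self) -> None:
        _check_pairs(self, _TS_CATEGORIES, "temperature", nonnegative=False)
        # preferred range must sit inside the total range when both known
        if (
            self.preferred_min is not None
            and self.range_min is not None
            and self.preferred_min < self.range_min
        ) or (
            self.preferred_max is not None
            and self.range_max is not None
            and self.preferred_max > self.range_max
        ):
            raise EnvelopeValidationError(
                "temperature preferred range outside total range"
            )


@dataclass(frozen=True)
class SalinityEnvelope:
    range_min: float | None = None
    range_max: float | None = None
    preferred_min: float | None = None
    preferred_max: float | None = None
    intolerant_low: float | None = None
    intolerant_high: float | None = None
    lethal_low: float | None = None
    lethal_high: float | None = None
    source_id: str | None = None

    def __post_init__(self) -> None:
        _check_pairs(self, _TS_CATEGORIES, "salinity", nonnegative=True)


@dataclass(frozen=True)
class DepthEnvelope:
    range_min: float | None = None
    range_max: float | None = None
    mean: float | None = None
    preferred_min: float | None = None
    preferred_max: float | None = None
    source_id: str | None = None

    def __post_init__(self) -> None:
        _check_pairs(self, _DEPTH_CATEGORIES, "depth", nonnegative=True)


@dataclass(frozen=True)
class PhResponse:
    """A pH exposure level and the coded response observed at it."""

    ph_level: float
    response_code: PhResponseCode
    response_variable: str = ""
    evidence: str = "experimental"
    source_id: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.ph_level < 14.0):
            raise EnvelopeValidationError(f"ph_level {self.ph_level} outside (0, 14)")
        object.__setattr__(
            self, "response_code", PhResponseCode(self.response_code)
        )
        if self.evidence not in ("experimental", "observational"):
            raise EnvelopeValidationError(
                f"evidence {self.evidence!r} must be experimental|observational"
            )


@dataclass(frozen=True)
class SpeciesEnvelope:
    """All envelope blocks for one species × life stage.

    ``oxygen`` is the union across sources (category-wise min of minima and
    max of maxima); ``oxygen_records`` keeps the per-source thresholds.
    """

    key: SpeciesKey
    oxygen: OxygenThresholds | None = None
    oxygen_records: tuple[OxygenThresholds, ...] = ()
    temperature: tuple[TemperatureEnvelope, ...] = ()
    salinity: tuple[SalinityEnvelope, ...] = ()
    depth: tuple[DepthEnvelope, ...] = ()
    ph: tuple[PhResponse, ...] = ()
    criteria: frozenset[str] = frozenset()
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = set(self.criteria) - CRITERIA_CODES
        if bad:
            raise EnvelopeValidationError(
                f"{self.key.latin_name}: unknown criteria codes {sorted(bad)}"
            )
        if not (
            self.oxygen_records
            or self.temperature
            or self.salinity
            or self.depth
            or self.ph
        ):
            raise EnvelopeValidationError(
                f"{self.key.latin_name}: envelope has no data blocks"
            )


@dataclass(frozen=True)
class SourceSpan:
    """Union span of a category across sources, with the per-source bounds."""

    lower: float
    upper: float
    per_source: tuple[tuple[str | None, float, float], ...]


# ---------------------------------------------------------------------------
# Delimited-text I/O

_ID_COLUMNS = ["latin_name", "common_name", "life_stage", "habitat_zone", "source_id"]
_OXY_COLUMNS = [f"oxygen_{f}" for pair in _OXYGEN_CATEGORIES.values() for f in pair]
_TEMP_COLUMNS = [f"temperature_{f}" for pair in _TS_CATEGORIES.values() for f in pair]
_SAL_COLUMNS = [f"salinity_{f}" for pair in _TS_CATEGORIES.values() for f in pair]
_DEPTH_COLUMNS = [
    "depth_range_min",
    "depth_range_max",
    "depth_mean",
    "depth_preferred_min",
    "depth_preferred_max",
]
_PH_COLUMNS = ["ph_level", "ph_response_code", "ph_response_variable", "ph_evidence"]
_META_COLUMNS = ["criteria", "provenance"]

COLUMNS = (
    _ID_COLUMNS
    + _META_COLUMNS
    + _OXY_COLUMNS
    + _TEMP_COLUMNS
    + _SAL_COLUMNS
    + _DEPTH_COLUMNS
    + _PH_COLUMNS
)

#: Units per column family, emitted to the machine-readable sidecar.
COLUMN_UNITS = {
    "oxygen": "mg/L",
    "temperature": "degC",
    "salinity": "practical salinity",
    "depth": "m",
    "ph": "pH units",
}


def _parse_float(cell, column: str, species: str) -> float | None:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)) or cell is pd.NA:
        return None
    text = str(cell).strip()
    if text == "":
        return None
    try:
        return float(text)
    except ValueError as exc:
        raise EnvelopeValidationError(
            f"{species}: column {column} value {text!r} is not numeric"
        ) from exc


def _row_block(row, prefix: str, fields_: tuple, species: str) -> dict | None:
    vals = {
        f: _parse_float(row.get(f"{prefix}_{f}"), f"{prefix}_{f}", species)
        for f in fields_
    }
    if all(v is None for v in vals.values()):
        return None
    return vals


def load_envelopes(
    table_path: str | Path, header_map: dict[str, str] | None = None
) -> list[SpeciesEnvelope]:
    """Read a species-envelope table (one row per species × life stage × source).

    Blank cells become absent values, never zero. ``header_map`` renames
    alternative column dialects onto the canonical snake-cased names before
    validation. Raises :class:`SchemaError` for missing mandatory columns
    and :class:`EnvelopeValidationError` (naming species and category) for
    invariant violations.
    """
    table_path = Path(table_path)
    df = pd.read_csv(table_path, dtype="string")
    if header_map:
        df = df.rename(columns=header_map)
    for col in _ID_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing mandatory column: {col}")

    envelopes: list[SpeciesEnvelope] = []
    grouped = df.groupby(["latin_name", "life_stage"], sort=False, dropna=False)
    for (latin, stage), rows in grouped:
        species = f"{latin} ({stage})"
        first = rows.iloc[0]
        key = SpeciesKey(
            latin_name=str(latin),
            common_name=str(first["common_name"]),
            life_stage="unspecified" if pd.isna(stage) or stage == "" else str(stage),
            habitat_zone=HabitatZone(str(first["habitat_zone"])),
        )
        oxy_records: list[OxygenThresholds] = []
        temp_records: list[TemperatureEnvelope] = []
        sal_records: list[SalinityEnvelope] = []
        depth_records: list[DepthEnvelope] = []
        ph_records: list[PhResponse] = []
        criteria: set[str] = set()
        provenance: dict[str, str] = {}
        for _, row in rows.iterrows():
            source = None if pd.isna(row["source_id"]) else str(row["source_id"])
            if "provenance" in row.index and not pd.isna(row.get("provenance")):
                provenance[source or ""] = str(row["provenance"])
            if "criteria" in row.index and not pd.isna(row.get("criteria")):
                criteria |= {
                    c.strip()
                    for c in str(row["criteria"]).split(";")
                    if c.strip()
                }
            try:
                oxy_fields = tuple(
                    f for pair in _OXYGEN_CATEGORIES.values() for f in pair
                )
                block = _row_block(row, "oxygen", oxy_fields, species)
                if block is not None:
                    oxy_records.append(OxygenThresholds(**block, source_id=source))
                ts_fields = tuple(f for pair in _TS_CATEGORIES.values() for f in pair)
                block = _row_block(row, "temperature", ts_fields, species)
                if block is not None:
                    temp_records.append(TemperatureEnvelope(**block, source_id=source))
                block = _row_block(row, "salinity", ts_fields, species)
                if block is not None:
                    sal_records.append(SalinityEnvelope(**block, source_id=source))
                depth_fields = ("range_min", "range_max", "mean", "preferred_min", "preferred_max")
                block = _row_block(row, "depth", depth_fields, species)
                if block is not None:
                    depth_records.append(DepthEnvelope(**block, source_id=source))
                ph_level = _parse_float(row.get("ph_level"), "ph_level", species)
                if ph_level is not None:
                    code = _parse_float(
                        row.get("ph_response_code"), "ph_response_code", species
                    )
                    ph_records.append(
                        PhResponse(
                            ph_level=ph_level,
                            response_code=PhResponseCode(int(code or 0)),
                            response_variable=str(row.get("ph_response_variable") or ""),
                            evidence=str(row.get("ph_evidence") or "experimental"),
                            source_id=source,
                        )
                    )
            except EnvelopeValidationError as exc:
                raise EnvelopeValidationError(f"{species}: {exc}") from exc
        try:
            envelopes.append(
                SpeciesEnvelope(
                    key=key,
                    oxygen=_merge_oxygen(oxy_records),
                    oxygen_records=tuple(oxy_records),
                    temperature=tuple(temp_records),
                    salinity=tuple(sal_records),
                    depth=tuple(depth_records),
                    ph=tuple(ph_records),
                    criteria=frozenset(criteria),
                    provenance=provenance,
                )
            )
        except EnvelopeValidationError as exc:
            raise EnvelopeValidationError(f"{species}: {exc}") from exc
    return envelopes


def _merge_oxygen(records: list[OxygenThresholds]) -> OxygenThresholds | None:
    """Union across sources: category-wise min of minima, max of maxima."""
    if not records:
        return None
    merged: dict[str, float | None] = {}
    for lo_f, hi_f in _OXYGEN_CATEGORIES.values():
        los = [getattr(r, lo_f) for r in records if getattr(r, lo_f) is not None]
        his = [getattr(r, hi_f) for r in records if getattr(r, hi_f) is not None]
        merged[lo_f] = min(los) if los else None
        merged[hi_f] = max(his) if his else None
    # a union of valid per-source records can still invert a pair when one
    # source reports only a min and another only a (smaller) max; widen
    for lo_f, hi_f in _OXYGEN_CATEGORIES.values():
        lo, hi = merged[lo_f], merged[hi_f]
        if lo is not None and hi is not None and lo > hi:
            merged[lo_f], merged[hi_f] = hi, lo
    return OxygenThresholds(**merged)


def write_envelopes(
    envelopes: list[SpeciesEnvelope],
    table_path: str | Path,
    write_sidecar: bool = True,
) -> Path:
    """Write envelopes back to delimited text, one row per source record.

    Preserves absent-vs-zero: absent values become empty cells. A
    machine-readable units sidecar is written next to the table.
    """
    table_path = Path(table_path)
    rows = []
    for env in envelopes:
        by_source: dict[str | None, dict] = {}

        def row_for(source: str | None) -> dict:
            if source not in by_source:
                by_source[source] = {
                    "latin_name": env.key.latin_name,
                    "common_name": env.key.common_name,
                    "life_stage": env.key.life_stage,
                    "habitat_zone": env.key.habitat_zone.value,
                    "source_id": source,
                    "criteria": ";".join(sorted(env.criteria)) or None,
                    "provenance": env.provenance.get(source or "") or None,
                }
            return by_source[source]

        for rec in env.oxygen_records:
            row = row_for(rec.source_id)
            for f in (x for pair in _OXYGEN_CATEGORIES.values() for x in pair):
                row[f"oxygen_{f}"] = getattr(rec, f)
        for rec in env.temperature:
            row = row_for(rec.source_id)
            for f in (x for pair in _TS_CATEGORIES.values() for x in pair):
                row[f"temperature_{f}"] = getattr(rec, f)
        for rec in env.salinity:
            row = row_for(rec.source_id)
            for f in (x for pair in _TS_CATEGORIES.values() for x in pair):
                row[f"salinity_{f}"] = getattr(rec, f)
        for rec in env.depth:
            row = row_for(rec.source_id)
            for f in ("range_min", "range_max", "mean", "preferred_min", "preferred_max"):
                row[f"depth_{f}"] = getattr(rec, f)
        for rec in env.ph:
            row = row_for(rec.source_id)
            row["ph_level"] = rec.ph_level
            row["ph_response_code"] = int(rec.response_code)
            row["ph_response_variable"] = rec.response_variable or None
            row["ph_evidence"] = rec.evidence
        rows.extend(by_source.values())
    df = pd.DataFrame(rows, columns=COLUMNS)
    df.to_csv(table_path, index=False)
    if write_sidecar:
        sidecar = table_path.with_suffix(".meta.json")
        sidecar.write_text(
            json.dumps({"units": COLUMN_UNITS, "columns": COLUMNS}, indent=1)
        )
    return table_path


# ---------------------------------------------------------------------------
# Threshold lookup

def _category_records(env: SpeciesEnvelope, category: str):
    """Resolve a category name to (records, lower-field, upper-field)."""
    if category in _OXYGEN_CATEGORIES:
        lo_f, hi_f = _OXYGEN_CATEGORIES[category]
        return env.oxygen_records, lo_f, hi_f
    for prefix, records, cats in (
        ("temperature", env.temperature, _TS_CATEGORIES),
        ("salinity", env.salinity, _TS_CATEGORIES),
        ("depth", env.depth, _DEPTH_CATEGORIES),
    ):
        if category.startswith(prefix + "_"):
            cat = category[len(prefix) + 1 :]
            if cat not in cats:
                raise KeyError(f"unknown category {category!r}")
            lo_f, hi_f = cats[cat]
            return records, lo_f, hi_f
    if category == "ph":
        return env.ph, "ph_level", "ph_level"
    raise KeyError(f"unknown category {category!r}")


def get_threshold(env: SpeciesEnvelope, category: str, bound: str) -> float:
    """Look up one bound of a category, spanning sources.

    ``bound`` is ``"lower"`` or ``"upper"``. For single-valued categories
    both bounds return that value. Raises :class:`DataDeficientError` when
    the category carries no data — deliberately distinguishable from a
    legitimate threshold of 0.
    """
    if bound not in ("lower", "upper"):
        raise ValueError("bound must be 'lower' or 'upper'")
    records, lo_f, hi_f = _category_records(env, category)
    want, other = (lo_f, hi_f) if bound == "lower" else (hi_f, lo_f)
    values = [getattr(r, want) for r in records if getattr(r, want) is not None]
    if not values:  # single-valued records: both bounds return the one value
        values = [getattr(r, other) for r in records if getattr(r, other) is not None]
    if not values:
        raise DataDeficientError(
            f"{env.key.latin_name} ({env.key.life_stage}): no data for {category}"
        )
    return min(values) if bound == "lower" else max(values)


def span_across_sources(env: SpeciesEnvelope, category: str) -> SourceSpan:
    """Union span of a category over sources plus the per-source intervals.

    A record carrying only one bound contributes a degenerate interval, so
    two sources reporting upper thermal limits of 10 and 13 °C span
    [10, 13] with per-source bounds [10, 10] and [13, 13].
    """
    records, lo_f, hi_f = _category_records(env, category)
    per_source = []
    for r in records:
        lo = getattr(r, lo_f)
        hi = getattr(r, hi_f)
        if lo is None and hi is None:
            continue
        lo_eff = lo if lo is not None else hi
        hi_eff = hi if hi is not None else lo
        per_source.append((r.source_id, float(lo_eff), float(hi_eff)))
    if not per_source:
        raise DataDeficientError(
            f"{env.key.latin_name} ({env.key.life_stage}): no sources for {category}"
        )
    return SourceSpan(
        lower=min(lo for _, lo, _ in per_source),
        upper=max(hi for _, _, hi in per_source),
        per_source=tuple(per_source),
    )


# ---------------------------------------------------------------------------
# Packaged fixture: the threshold values printed in the study's main text

def main_text_fixture_path() -> Path:
    """Path of the packaged main-text thresholds table."""
    return Path(
        resources.files("shelfvuln").joinpath("data/main_text_thresholds.csv")
    )


def load_main_text_envelopes() -> list[SpeciesEnvelope]:
    """Load the packaged envelope fixture (main-text threshold subset)."""
    return load_envelopes(main_text_fixture_path())


def fixture_metadata() -> dict:
    """Sidecar metadata of the packaged fixture (units, aggregates, notes)."""
    path = resources.files("shelfvuln").joinpath("data/main_text_thresholds.meta.json")
    return json.loads(path.read_text())
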