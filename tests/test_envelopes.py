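"""Species envelope data model, I/O round trips, and the packaged fixture."""

import pandas as pd
import pytest

from shelfvuln.envelopes import (
    _DEPTH_CATEGORIES,
    _OXYGEN_CATEGORIES,
    _TS_CATEGORIES,
    COLUMNS,
    DataDeficientError,
    EnvelopeValidationError,
    HabitatZone,
    OxygenThresholds,
    PhResponse,
    SchemaError,
    SpeciesKey,
    TemperatureEnvelope,
    fixture_metadata,
    get_threshold,
    load_envelopes,
    load_main_text_envelopes,
    span_across_sources,
    write_envelopes,
)


def _table(tmp_path, rows, columns=COLUMNS, name="table.csv"):
    path = tmp_path / name
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)
    return path


class TestLoad:
    def test_cod_critical_row(self, tmp_path):
        path = _table(
            tmp_path,
            [
                {
                    "latin_name": "Gadus morhua",
                    "common_name": "Atlantic cod",
                    "life_stage": "adult",
                    "habitat_zone": "demersal",
                    "source_id": "r1",
                    "oxygen_critical_min": 2.9,
                    "oxygen_critical_max": 3.19,
                }
            ],
        )
        (env,) = load_envelopes(path)
        assert env.oxygen.critical_min == 2.9
        assert env.oxygen.critical_max == 3.19

    def test_empty_table_with_valid_header(self, tmp_path):
        assert load_envelopes(_table(tmp_path, [])) == []

    def test_inverted_bounds_name_species_and_category(self, tmp_path):
        path = _table(
            tmp_path,
            [
                {
                    "latin_name": "Gadus morhua",
                    "common_name": "Atlantic cod",
                    "life_stage": "adult",
                    "habitat_zone": "demersal",
                    "source_id": "r1",
                    "oxygen_critical_min": 3.19,
                    "oxygen_critical_max": 2.9,
                }
            ],
        )
        with pytest.raises(EnvelopeValidationError, match="Gadus morhua.*critical"):
            load_envelopes(path)

    def test_missing_mandatory_column_names_it(self, tmp_path):
        cols = [c for c in COLUMNS if c != "habitat_zone"]
        path = _table(tmp_path, [], columns=cols)
        with pytest.raises(SchemaError, match="habitat_zone"):
            load_envelopes(path)

    def test_blank_cells_are_absent_not_zero(self, tmp_path):
        path = _table(
            tmp_path,
            [
                {
                    "latin_name": "Crassostrea virginica",
                    "common_name": "American oyster",
                    "life_stage": "unspecified",
                    "habitat_zone": "benthic",
                    "source_id": "r1",
                    "oxygen_lc50_min": 0.0,
                }
            ],
        )
        (env,) = load_envelopes(path)
        assert env.oxygen.lc50_min == 0.0  # a legal zero
        assert env.oxygen.critical_min is None  # absent, not zero

    def test_header_map_dialect(self, tmp_path):
        cols = ["species", "common", "stage", "zone", "ref", "o2_crit_lo", "o2_crit_hi"]
        path = tmp_path / "alt.csv"
        pd.DataFrame(
            [["Gadus morhua", "Atlantic cod", "adult", "demersal", "r1", 2.9, 3.19]],
            columns=cols,
        ).to_csv(path, index=False)
        header_map = {
            "species": "latin_name",
            "common": "common_name",
            "stage": "life_stage",
            "zone": "habitat_zone",
            "ref": "source_id",
            "o2_crit_lo": "oxygen_critical_min",
            "o2_crit_hi": "oxygen_critical_max",
        }
        (env,) = load_envelopes(path, header_map=header_map)
        assert env.oxygen.critical_max == 3.19


class TestRoundTrip:
    def test_fixture_round_trips_exactly(self, tmp_path, envelopes):
        """write → load reproduces every numeric cell and absent/zero state."""
        out = tmp_path / "rt.csv"
        write_envelopes(envelopes, out)
        reloaded = load_envelopes(out)
        assert len(reloaded) == len(envelopes)
        for a, b in zip(
            sorted(envelopes, key=lambda e: (e.key.latin_name, e.key.life_stage)),
            sorted(reloaded, key=lambda e: (e.key.latin_name, e.key.life_stage)),
        ):
            assert a.key == b.key
            assert a.oxygen == b.oxygen
            assert set(a.oxygen_records) == set(b.oxygen_records)
            assert set(a.temperature) == set(b.temperature)
            assert a.criteria == b.criteria
            assert a.provenance == b.provenance

    def test_round_trip_preserves_zero_vs_absent(self, tmp_path, by_species):
        oyster = by_species[("Crassostrea virginica", "unspecified")]
        out = tmp_path / "oyster.csv"
        write_envelopes([oyster], out)
        (back,) = load_envelopes(out)
        assert back.oxygen.lc50_min == 0.0
        assert back.oxygen.lc50_max is None


class TestGetThreshold:
    @pytest.mark.parametrize(
        "species,stage,category,bound,expected",
        [
            ("Anarhichas lupus", "adult", "critical", "upper", 6.64),
            ("Anarhichas lupus", "adult", "critical", "lower", 5.69),
            ("Chionoecetes opilio", "unspecified", "temperature_range", "lower", -1.0),
            ("Chionoecetes opilio", "unspecified", "temperature_range", "upper", 4.0),
            ("Gadus morhua", "adult", "lc50", "upper", 2.4),
            ("Salmo salar", "post-smolt", "critical", "upper", 4.82),
            ("Salmo salar", "post-smolt", "critical", "lower", 4.82),
            ("Streblospio benedicti", "unspecified", "critical", "upper", 0.57),
        ],
    )
    def test_fixture_lookups(self, by_species, species, stage, category, bound, expected):
        env = by_species[(species, stage)]
        assert get_threshold(env, category, bound) == pytest.approx(expected)

    def test_absent_category_is_data_deficient(self, by_species):
        env = by_species[("Gadus morhua", "adult")]
        with pytest.raises(DataDeficientError):
            get_threshold(env, "ph", "upper")


class TestSpanAcrossSources:
    def test_wolffish_thermal_upper_limits(self, by_species):
        span = span_across_sources(
            by_species[("Anarhichas lupus", "adult")], "temperature_range"
        )
        assert span.upper == 13.0
        assert sorted(hi for _, _, hi in span.per_source) == [10.0, 13.0]

    def test_single_source_span_equals_source(self, by_species):
        span = span_across_sources(
            by_species[("Chionoecetes opilio", "unspecified")], "temperature_range"
        )
        assert (span.lower, span.upper) == (-1.0, 4.0)
        assert len(span.per_source) == 1

    def test_synthetic_three_source_hull(self):
        env_key = SpeciesKey("Testus testus", "test fish", "adult", "demersal")
        from shelfvuln.envelopes import SpeciesEnvelope

        env = SpeciesEnvelope(
            key=env_key,
            temperature=tuple(
                TemperatureEnvelope(range_min=lo, range_max=hi, source_id=s)
                for s, lo, hi in [("a", 5, 7), ("b", 6, 8), ("c", 7, 9)]
            ),
        )
        span = span_across_sources(env, "temperature_range")
        assert (span.lower, span.upper) == (5.0, 9.0)

    def test_no_sources_is_data_deficient(self, by_species):
        with pytest.raises(DataDeficientError):
            span_across_sources(by_species[("Salmo salar", "adult")], "salinity_range")


class TestFixtureContents:
    """The packaged fixture carries every threshold printed in the main text."""

    def test_printed_thresholds_present(self, by_species):
        checks = [
            (("Anarhichas lupus", "adult"), "critical", (5.69, 6.64)),
            (("Salmo salar", "adult"), "critical", (4.0, 5.0)),
            (("Salmo salar", "post-smolt"), "critical", (4.82, 4.82)),
            (("Gadus morhua", "adult"), "critical", (2.9, 3.19)),
            (("Glyptocephalus cynoglossus", "unspecified"), "no_survival", (0.97, 2.15)),
            (("Chionoecetes opilio", "unspecified"), "temperature_range", (-1.0, 4.0)),
            (("Streblospio benedicti", "unspecified"), "critical", (0.57, 0.57)),
            (("Crassostrea virginica", "unspecified"), "lc50", (0.0, 0.0)),
            (("Callinectes sapidus", "juvenile"), "lc50", (4.08, 6.44)),
        ]
        for key, category, (lo, hi) in checks:
            env = by_species[key]
            assert get_threshold(env, category, "lower") == pytest.approx(lo)
            assert get_threshold(env, category, "upper") == pytest.approx(hi)
        wolf = span_across_sources(
            by_species[("Anarhichas lupus", "adult")], "temperature_range"
        )
        assert {hi for _, _, hi in wolf.per_source} == {10.0, 13.0}

    def test_demersal_lc50_span_in_sidecar(self, by_species):
        meta = fixture_metadata()
        assert meta["aggregates"]["demersal_lc50_span_mg_per_L"] == [0.9, 2.4]
        # upper end of that span is the inferred cod LC50, flagged as such
        cod = by_species[("Gadus morhua", "adult")]
        assert cod.oxygen.lc50_max == 2.4
        assert "inferred" in cod.provenance.values()

    def test_every_category_pair_ordered(self, envelopes):
        """min ≤ max for every present category pair, across all records."""
        for env in envelopes:
            records = list(env.oxygen_records) + list(env.temperature) + list(
                env.salinity
            ) + list(env.depth)
            for rec in records:
                cats = (
                    _OXYGEN_CATEGORIES
                    if isinstance(rec, OxygenThresholds)
                    else _DEPTH_CATEGORIES
                    if hasattr(rec, "mean")
                    else _TS_CATEGORIES
                )
                for lo_f, hi_f in cats.values():
                    lo, hi = getattr(rec, lo_f), getattr(rec, hi_f)
                    if lo is not None and hi is not None:
                        assert lo <= hi

    def test_fixture_is_a_subset_not_the_full_compilation(self, envelopes):
        """Only the main-text subset ships; the 54-species tables do not."""
        assert len({e.key.latin_name for e in envelopes}) < 54


class TestTypeInvariants:
    def test_habitat_zone_vocabulary(self):
        with pytest.raises(ValueError):
            SpeciesKey("Gadus morhua", "cod", "adult", "abyssal")
        assert SpeciesKey("Gadus morhua", "cod").habitat_zone is HabitatZone.DEMERSAL

    def test_empty_latin_name_rejected(self):
        with pytest.raises(EnvelopeValidationError):
            SpeciesKey("", "cod")

    def test_negative_oxygen_rejected(self):
        with pytest.raises(EnvelopeValidationError):
            OxygenThresholds(critical_min=-0.1)

    def test_preferred_outside_total_range_rejected(self):
        with pytest.raises(EnvelopeValidationError):
            TemperatureEnvelope(range_min=0.0, range_max=10.0, preferred_max=12.0)

    def test_ph_response_codes(self):
        r = PhResponse(ph_level=7.7, response_code=1, response_variable="calcification")
        assert r.response_code.name == "DECREASE"
        with pytest.raises(EnvelopeValidationError):
            PhResponse(ph_level=15.0, response_code=0)
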