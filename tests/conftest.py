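import pytest

from shelfvuln import (
    OxygenQuantity,
    TrendSpec,
    VariabilityBands,
    load_main_text_envelopes,
)


@pytest.fixture(scope="session")
def envelopes():
    """Packaged main-text threshold fixture."""
    return load_main_text_envelopes()


@pytest.fixture(scope="session")
def by_species(envelopes):
    return {(e.key.latin_name, e.key.life_stage): e for e in envelopes}


@pytest.fixture(scope="session")
def trend():
    """The observed 150 m trend: −1.06 µmol/L/yr anchored at (2014.0, 4.32 mg/L)."""
    return TrendSpec.from_quantity(
        OxygenQuantity(-1.06, "umol_per_L"), anchor_year=2014.0, anchor_value=4.32
    )


@pytest.fixture(scope="session")
def bands():
    """±2σ offsets: high-frequency σ = 0.36 mg/L, interannual σ = 0.71 mg/L."""
    return VariabilityBands.from_sigmas(0.36, 0.71)
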