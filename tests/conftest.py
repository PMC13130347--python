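from __future__ import annotations

import pytest

from covergap.model import (
    AnalysisConfig,
    IncidencePair,
    PartCategory,
    ProtectionLevel,
    Species,
    ThreatCategory,
)


def make_species(
    sid: str,
    endemic: bool = False,
    threat: str = "NONE",
    protection: str = "NONE",
    parts=("II",),
) -> Species:
    return Species(
        species_id=sid,
        name=f"Species {sid}",
        family="Fam",
        genus="Gen",
        is_endemic=endemic,
        threat_category=ThreatCategory(threat),
        protection_level=ProtectionLevel(protection),
        part_categories=frozenset(PartCategory(p) for p in parts),
    )


@pytest.fixture
def config() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture
def toy_pairs():
    """Three incidences: species A in cells 1 and 2, species B in cell 1."""
    return [IncidencePair("A", 1), IncidencePair("B", 1), IncidencePair("A", 2)]


@pytest.fixture
def toy_species():
    return [
        make_species("A", endemic=True, threat="CR", parts=("I", "III")),
        make_species("B", threat="VU", parts=("II", "III")),
        make_species("C", protection="II", parts=("III",)),
    ]


@pytest.fixture(scope="session")
def small_landscape():
    """A small but fully featured synthetic landscape shared across tests."""
    from covergap.synthetic import SyntheticSpec, gen_landscape

    spec = SyntheticSpec(
        n_species=30, n_rows=8, n_cols=8, reserve_fraction=0.25, seed=11
    )
    return spec, gen_landscape(spec)
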