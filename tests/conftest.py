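import pytest
from hypothesis import settings

from netweaver import Dataset, LocalTableBackend, RawTable

settings.register_profile("repeatable", derandomize=True, database=None)
settings.load_profile("repeatable")

ORGANISM = "Synthetica exempli"


@pytest.fixture
def toy_backend():
    """Small offline resolver: two core symbols, a stale alias, five targets."""
    mapping = [
        ("esg", "FBcore001", "esg", "CG0001"),
        ("cic", "FBcore002", "cic", "CG0002"),
        ("OLD1", "FB1", "symA", "ALT1"),
        ("t1", "FB_t1", "t1", ""),
        ("t2", "FB_t2", "t2", ""),
        ("t3", "FB_t3", "t3", ""),
        ("t4", "FB_t4", "t4", ""),
    ]
    interactions = [
        ("FB_t1", "FBcore001", "genetic"),
        ("FB_t2", "FB_t3", "physical"),
        ("FB_t3", "FB_t2", "physical"),  # reverse duplicate of the line above
    ]
    return LocalTableBackend(ORGANISM, mapping, interactions)


@pytest.fixture
def identity_backend():
    """Resolver in which every identifier and symbol maps to itself."""
    names = ["A", "B", "C"] + [f"t{i}" for i in range(1, 10)]
    return LocalTableBackend(ORGANISM, [(n, n, n, "") for n in names])


def make_dataset(core, targets, name=None, technique="DamID"):
    return Dataset(
        name=name or f"{core}_ds",
        organism=ORGANISM,
        core_symbol=core,
        technique=technique,
        identifiers=tuple(targets),
    )


@pytest.fixture
def toy_table():
    return RawTable(
        headers=("gene", "r1", "r2", "r3", "signal"),
        rows=(
            ("g1", "x", "x", "x", "3.0"),
            ("g2", "x", "", "x", "1.0"),
            ("g3", "x", "x", "x", "2.0"),
            ("g1", "x", "x", "x", "9.0"),
        ),
    )
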