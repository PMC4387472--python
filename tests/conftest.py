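"""Shared fixtures: simulated libraries and centromeres reused across tests."""

import pytest

from cennest import (
    SimConfig,
    TEFamily,
    curate_elements,
    library_from_families,
    simulate_centromere,
    simulate_library,
)
from cennest.synthetic_centromere import ground_truth_hits


@pytest.fixture(scope="session")
def toy_library():
    """Hand-built 3-family library with known structure."""
    ltr = "ACGTGGTACCAT" * 25  # 300 bp LTR
    internal = "TTGACCATGGCA" * 100  # 1200 bp internal
    tir = "ACGTACGTACGTAA"
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    tir_rc = "".join(comp[b] for b in reversed(tir))
    return library_from_families(
        [
            TEFamily(
                name="GYPSY1",
                te_class="I",
                superfamily="Ty3-gypsy",
                consensus=ltr + internal + ltr,
                ltr_span=((0, 300), (1500, 1800)),
                tsd_length=5,
            ),
            TEFamily(
                name="MULE1",
                te_class="II",
                superfamily="Mutator",
                consensus=tir + "GATTACA" * 60 + tir_rc,
                tir_length=14,
                tsd_length=9,
            ),
            TEFamily(
                name="HEL1",
                te_class="II",
                superfamily="Helitron",
                consensus="CATTCGGA" * 60,
                tsd_length=0,
            ),
        ]
    )


@pytest.fixture(scope="session")
def sim_library():
    return simulate_library(10, seed=3)


@pytest.fixture(scope="session")
def small_truth(sim_library):
    """Mutation-free simulated centromere with a moderate nesting load."""
    cfg = SimConfig(
        backbone_length=150_000,
        n_insertions=40,
        seed=5,
        nesting_bias=0.5,
        solo_ltr_prob=0.15,
        mutation_rate_per_age_unit=0.0,
    )
    return simulate_centromere(sim_library, cfg)


@pytest.fixture(scope="session")
def small_elements(small_truth, sim_library):
    hits = ground_truth_hits(small_truth)
    return curate_elements(small_truth.sequence, hits, sim_library)
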