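"""Shared fixtures: small synthetic datasets generated at test time."""

from __future__ import annotations

import pytest

from abikit.proteome_io import PhageRecord, Protein, ProteomeSet
from abikit.synthetic_data import ProteomeSimSpec, gen_proteomes


@pytest.fixture(scope="session")
def small_planted():
    """A small planted-family proteome set: 2 clusters x 2 phages,
    6 core families, 10% substitutions.  Cheap enough for unit tests."""
    spec = ProteomeSimSpec(
        n_clusters=2,
        phages_per_cluster=2,
        core_families=6,
        shared_families=1,
        singleton_fraction=0.2,
        substitution_rate=0.1,
        length_mean=80.0,
        length_sd=15.0,
        seed=11,
    )
    return gen_proteomes(spec)


@pytest.fixture()
def toy_proteome_set():
    """Two phages with hand-written tiny proteomes."""
    phages = [PhageRecord("A", "Fam1", "", "GenX"), PhageRecord("B", "Fam1", "", "")]
    proteins = [
        Protein("A|p1", "A", "MKVLAATTRW"),
        Protein("A|p2", "A", "GGHHIIKKLL"),
        Protein("B|p1", "B", "MKVLAATTRW"),
    ]
    return ProteomeSet(proteins, phages)
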