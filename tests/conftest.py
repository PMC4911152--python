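"""Shared fixtures: tiny hand-built databases and scaled-down scenarios."""

from __future__ import annotations

import numpy as np
import pytest

from markereval.insilico_pcr import PrimerPair
from markereval.refdb import RefDB, RefRecord
from markereval.synthetic_data import MarkerProfile, QualityModel
from markereval.taxonomy import Lineage
from markereval.workflow import MarkerConfig, RunConfig


def lineage(order="Poales", family="Poaceae", genus="Poa", species="Poa pratensis"):
    return Lineage(kingdom="Plantae", phylum="Tracheophyta", order=order,
                   family=family, genus=genus, species=species)


@pytest.fixture
def poa_lineage():
    return lineage()


@pytest.fixture
def small_refdb():
    """Four references, three species in two genera of one family."""
    db = RefDB(marker="rbcL")
    seqs = {
        "R1": ("ACGTACGTACGTACGTACGTACGTACGTACGT", lineage(species="Poa pratensis")),
        "R2": ("ACGTACGTACGTACGTACGTACGTACGTACGA", lineage(species="Poa annua")),
        "R3": ("TTTTACGTACGTACGTACGTACGTACGTACGT",
               lineage(genus="Carex", species="Carex aquatilis",
                       family="Cyperaceae")),
        "R4": ("ACGTACGTACGTACGTACGTACGTACGTACGT", lineage(species="Poa pratensis")),
    }
    for rid, (seq, lin) in seqs.items():
        db.add(RefRecord(id=rid, marker="rbcL", sequence=seq, lineage=lin))
    return db


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def tiny_marker(name: str, length: int, d_species: float = 0.1,
                primers: PrimerPair | None = None, **kwargs) -> MarkerProfile:
    primers = primers or PrimerPair("ATGCGTCAAGGCTTACGTGA", "TGCACGTTAGCCATGGATCA")
    return MarkerProfile(name=name, amplicon_length=length, primers=primers,
                         d_species=d_species, d_genus=min(1.0, 3 * d_species + 0.05),
                         **kwargs)


def tiny_reads_config(seed: int = 0, **overrides) -> RunConfig:
    """A minutes-scale two-marker scenario for workflow tests."""
    m1 = MarkerConfig(
        profile=tiny_marker("alpha", 150,
                            primers=PrimerPair("ATGCGTCAAGGCTTACGTGA",
                                               "TGCACGTTAGCCATGGATCA")),
        merge_mode="overlap", contamination_fraction=0.2,
        quality=QualityModel(36, 36, read_sd=3.0))
    m2 = MarkerConfig(
        profile=tiny_marker("beta", 230,
                            primers=PrimerPair("GGCAAGTCTTACGCATGGTA",
                                               "CATGCGATTGGAACCTAGCA")),
        merge_mode="concat", contamination_fraction=0.0,
        quality=QualityModel(36, 36, read_sd=3.0))
    defaults = dict(seed=seed, n_orders=2, n_families_per_order=1,
                    n_genera_per_family=2, n_species_per_genus=2,
                    n_instances=3, n_replicates=2, n_species_per_instance=4,
                    reads_per_sample=80, read_length=100, error_rate=0.001,
                    presence_min_per_sample=5, presence_min_total=20,
                    n_contaminants=5, contaminant_length=300,
                    markers=(m1, m2))
    defaults.update(overrides)
    return RunConfig(**defaults)
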