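"""Ground-truthed synthetic inputs for the marker-evaluation pipeline.

Emulates the statistical structure of a multi-marker plant eDNA study:
a nested taxonomy, per-marker reference databases with planted
inter-rank divergence, coverage gaps and duplicate (indistinguishable)
amplicons, mixed-template soil communities, and error-bearing paired-end
reads with non-target (fungal-like) contamination.  Every random draw is
recorded so downstream metrics can be checked against exact truth.

Sequences evolve under a star-like hierarchical substitution model: each
daughter lineage mutates independently from its ancestor at half the
planted expected pairwise distance, so congeneric species show an expected
p-distance close to ``d_species`` (2r(1−r) + 2r²/3 with r = d/2).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .insilico_pcr import PrimerPair
from .iupac import IUPAC_SETS, reverse_complement
from .refdb import RefDB, RefRecord
from .reads_pipeline import Read, ReadSet
from .taxonomy import Lineage

_BASES = np.array(["A", "C", "G", "T"])
_BASE_IDX = {b: i for i, b in enumerate(_BASES)}


class SyntheticError(ValueError):
    pass


def substream(seed: int, *keys: str | int) -> np.random.Generator:
    """Derive an independent, reproducible RNG substream from (seed, keys).

    Each pipeline stage draws from its own named substream so any stage
    can be re-run in isolation.
    """
    ints = [int(seed) & 0x7FFFFFFF]
    for k in keys:
        ints.append(zlib.crc32(str(k).encode()) & 0x7FFFFFFF)
    return np.random.default_rng(ints)


# ---------------------------------------------------------------- taxonomy

@dataclass
class Taxonomy:
    """A strictly nested synthetic taxonomy (kingdom/phylum fixed)."""

    species: list[Lineage]

    def species_keys(self) -> list[str]:
        return [s.species for s in self.species]

    def by_genus(self) -> dict[str, list[Lineage]]:
        out: dict[str, list[Lineage]] = {}
        for s in self.species:
            out.setdefault(s.genus, []).append(s)
        return out

    def lineage_of(self, species_name: str) -> Lineage:
        for s in self.species:
            if s.species == species_name:
                return s
        raise KeyError(species_name)


def generate_taxonomy(
    n_orders: int,
    n_families_per_order: int,
    n_genera_per_family: int,
    n_species_per_genus: int,
    seed: int = 0,
    kingdom: str = "Plantae",
    phylum: str = "Tracheophyta",
) -> Taxonomy:
    """Deterministically named nested taxonomy; the seed permutes species
    epithets (leaf naming) without changing the tree shape."""
    for n in (n_orders, n_families_per_order, n_genera_per_family, n_species_per_genus):
        if n < 1:
            raise SyntheticError("all taxonomy counts must be >= 1")
    rng = substream(seed, "taxonomy")
    species: list[Lineage] = []
    for o in range(1, n_orders + 1):
        order = f"Ord{o:02d}"
        for f in range(1, n_families_per_order + 1):
            family = f"Fam{o:02d}_{f:02d}"
            for g in range(1, n_genera_per_family + 1):
                genus = f"Gen{o:02d}_{f:02d}_{g:02d}"
                epithets = rng.permutation(np.arange(1, 100))[:n_species_per_genus]
                for e in sorted(int(x) for x in epithets):
                    species.append(
                        Lineage(kingdom=kingdom, phylum=phylum, order=order,
                                family=family, genus=genus,
                                species=f"{genus} sp{e:02d}")
                    )
    return Taxonomy(species=species)


# ---------------------------------------------------------------- sequences

def random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def mutate_sequence(seq: str, rate: float, rng: np.random.Generator | int) -> str:
    """Per-site independent substitution at ``rate``; the replacement base
    is drawn uniformly from the three alternatives.  Non-ACGT characters
    are left untouched."""
    if not 0 <= rate <= 1:
        raise SyntheticError("rate must be in [0, 1]")
    if isinstance(rng, (int, np.integer)):
        rng = substream(int(rng), "mutate")
    if rate == 0 or not seq:
        return seq
    arr = np.array(list(seq))
    idx = np.array([_BASE_IDX.get(c, -1) for c in arr])
    hit = (rng.random(len(arr)) < rate) & (idx >= 0)
    shifts = rng.integers(1, 4, size=len(arr))
    new_idx = (idx + shifts) % 4
    arr[hit] = _BASES[new_idx[hit]]
    return "".join(arr)


def concrete_primer_site(primer: str, rng: np.random.Generator) -> str:
    """Realise a degenerate primer as a concrete binding site."""
    return "".join(
        c if c in "ACGT" else sorted(IUPAC_SETS[c])[rng.integers(0, len(IUPAC_SETS[c]))]
        for c in primer.upper().replace("U", "T")
    )


def random_primer_pair(rng: np.random.Generator, length: int = 20,
                       max_mismatch: int = 2) -> PrimerPair:
    return PrimerPair(forward=random_sequence(length, rng),
                      reverse=random_sequence(length, rng),
                      max_mismatch=max_mismatch)


# ---------------------------------------------------------------- references

@dataclass(frozen=True)
class MarkerProfile:
    """Planted characteristics of one marker's reference set.

    Distances are expected pairwise p-distances: between congeneric
    species (``d_species``), between confamilial genus ancestors
    (``d_genus``) and within species (``d_intra``).
    ``coverage_gap_rate`` is the per-species probability of lacking any
    reference; ``duplicate_amplicon_rate`` the per-congeneric-pair
    probability of byte-identical amplicons (a planted resolution failure).
    """

    name: str
    amplicon_length: int
    primers: PrimerPair
    d_species: float = 0.05
    d_genus: float = 0.15
    d_intra: float = 0.0
    coverage_gap_rate: float = 0.0
    duplicate_amplicon_rate: float = 0.0
    n_seqs_per_species: int = 1
    flank_length: int = 15

    def __post_init__(self) -> None:
        if not (0 <= self.d_intra < self.d_species < self.d_genus <= 1):
            raise SyntheticError("require 0 <= d_intra < d_species < d_genus <= 1")
        for r in (self.coverage_gap_rate, self.duplicate_amplicon_rate):
            if not 0 <= r <= 1:
                raise SyntheticError("rates must be in [0, 1]")
        min_len = 1
        if self.amplicon_length < min_len:
            raise SyntheticError("amplicon_length must be positive")


@dataclass
class ReferenceTruth:
    """Exact record of every planted feature of the reference databases."""

    #: canonical amplicon insert per (marker, species name)
    amplicons: dict[tuple[str, str], str] = field(default_factory=dict)
    #: species omitted from each marker's database
    gaps: dict[str, set[str]] = field(default_factory=dict)
    #: congeneric species pairs given byte-identical amplicons, per marker
    duplicates: dict[str, list[tuple[str, str]]] = field(default_factory=dict)

    def species_with_refs(self, marker: str, taxonomy: Taxonomy) -> set[str]:
        return {s.species for s in taxonomy.species} - self.gaps.get(marker, set())


def generate_references(
    taxonomy: Taxonomy,
    profiles: Iterable[MarkerProfile],
    seed: int = 0,
) -> tuple[dict[str, RefDB], ReferenceTruth]:
    """Build per-marker reference databases with planted structure.

    Family ancestors are random; genus ancestors mutate at d_genus/2,
    species at d_species/2, intra-species replicates at d_intra/2 — so
    the planted rates are expected *pairwise* distances.  Primer binding
    sites and random flanks are added intact around each insert.  Coverage
    gaps and duplicate amplicons are drawn per profile and recorded
    exactly in the returned truth tables.
    """
    dbs: dict[str, RefDB] = {}
    truth = ReferenceTruth()
    by_family: dict[str, list[Lineage]] = {}
    for s in taxonomy.species:
        by_family.setdefault(s.family, []).append(s)

    for profile in profiles:
        marker = profile.name
        rng = substream(seed, "references", marker)
        fwd_site = concrete_primer_site(profile.primers.forward, rng)
        rev_site = reverse_complement(concrete_primer_site(profile.primers.reverse, rng))
        db = RefDB(marker=marker)
        truth.gaps[marker] = set()
        truth.duplicates[marker] = []
        counter = 0
        for family in sorted(by_family):
            ancestor = random_sequence(profile.amplicon_length, rng)
            genera: dict[str, list[Lineage]] = {}
            for s in by_family[family]:
                genera.setdefault(s.genus, []).append(s)
            for genus in sorted(genera):
                genus_anc = mutate_sequence(ancestor, profile.d_genus / 2, rng)
                members = sorted(genera[genus], key=lambda s: s.species)
                inserts = {
                    s.species: mutate_sequence(genus_anc, profile.d_species / 2, rng)
                    for s in members
                }
                # planted duplicate amplicons: disjoint congeneric pairs
                for a, b in zip(members[::2], members[1::2]):
                    if rng.random() < profile.duplicate_amplicon_rate:
                        inserts[b.species] = inserts[a.species]
                        truth.duplicates[marker].append((a.species, b.species))
                for s in members:
                    insert = inserts[s.species]
                    truth.amplicons[(marker, s.species)] = insert
                    if rng.random() < profile.coverage_gap_rate:
                        truth.gaps[marker].add(s.species)
                        continue
                    for rep in range(profile.n_seqs_per_species):
                        variant = (insert if profile.d_intra == 0
                                   else mutate_sequence(insert, profile.d_intra / 2, rng))
                        counter += 1
                        seq = (random_sequence(profile.flank_length, rng)
                               + fwd_site + variant + rev_site
                               + random_sequence(profile.flank_length, rng))
                        db.add(RefRecord(id=f"{marker.upper()}{counter:05d}",
                                         marker=marker, sequence=seq, lineage=s))
        dbs[marker] = db
    return dbs, truth


def generate_contaminants(
    n: int, length: int, seed: int = 0, kingdom: str = "Fungi"
) -> RefDB:
    """Non-target reference pool (fungal/bryophyte-like random sequences)."""
    rng = substream(seed, "contaminants")
    db = RefDB(marker="contaminant")
    for i in range(1, n + 1):
        lineage = Lineage(kingdom=kingdom, phylum=f"{kingdom}Phy01",
                          order=f"{kingdom}Ord{(i - 1) % 5 + 1:02d}",
                          family=f"{kingdom}Fam{i:02d}",
                          genus=f"{kingdom}Gen{i:02d}",
                          species=f"{kingdom}Gen{i:02d} sp01")
        db.add(RefRecord(id=f"CONT{i:05d}", marker="contaminant",
                         sequence=random_sequence(length, rng), lineage=lineage))
    return db


# ---------------------------------------------------------------- community

@dataclass
class CommunityTruth:
    """Known per-sample composition of the simulated soil community."""

    #: sample id -> species name -> template count
    samples: dict[str, dict[str, int]]
    #: sample id -> sampling instance (pooling of replicates)
    pooling: dict[str, str]
    #: fraction of each marker's reads drawn from the non-target pool
    contamination_fraction: float | Mapping[str, float] = 0.0
    #: per-marker recovery multiplier (amplification efficiency)
    marker_multipliers: dict[str, float] = field(default_factory=dict)

    def contamination_for(self, marker: str) -> float:
        c = self.contamination_fraction
        return float(c.get(marker, 0.0)) if isinstance(c, Mapping) else float(c)


def generate_community(
    taxonomy: Taxonomy,
    n_instances: int = 12,
    n_replicates: int = 3,
    n_species_per_instance: int = 10,
    reads_per_sample: int = 250,
    contamination_fraction: float | Mapping[str, float] = 0.1,
    marker_multipliers: Mapping[str, float] | None = None,
    seed: int = 0,
) -> CommunityTruth:
    """Draw per-instance species pools and per-replicate template counts.

    Each sampling instance holds a random species pool; each of its
    replicate samples draws template counts from a symmetric Dirichlet-
    multinomial over that pool, emulating uneven mixed-template eDNA.
    """
    rng = substream(seed, "community")
    all_species = taxonomy.species_keys()
    if n_species_per_instance > len(all_species):
        raise SyntheticError("n_species_per_instance exceeds taxonomy size")
    samples: dict[str, dict[str, int]] = {}
    pooling: dict[str, str] = {}
    for inst in range(1, n_instances + 1):
        instance = f"I{inst:02d}"
        pool = [all_species[i] for i in
                rng.choice(len(all_species), size=n_species_per_instance, replace=False)]
        for rep in range(1, n_replicates + 1):
            sample = f"{instance}_R{rep}"
            weights = rng.dirichlet(np.ones(len(pool)))
            counts = rng.multinomial(reads_per_sample, weights)
            samples[sample] = {sp: int(c) for sp, c in zip(pool, counts) if c > 0}
            pooling[sample] = instance
    return CommunityTruth(samples=samples, pooling=pooling,
                          contamination_fraction=contamination_fraction,
                          marker_multipliers=dict(marker_multipliers or {}))


# ---------------------------------------------------------------- reads

@dataclass(frozen=True)
class QualityModel:
    """Phred quality profile: constant or linear 3' decay, plus an optional
    per-read quality offset (sd ``read_sd``) emulating whole-read quality
    variation so that mean-quality filtering removes a realistic tail."""

    q_start: int = 38
    q_end: int = 38
    read_sd: float = 0.0

    def profile(self, length: int, offset: float = 0.0) -> np.ndarray:
        if length <= 1 or self.q_start == self.q_end:
            base = np.full(length, float(self.q_start))
        else:
            base = np.linspace(self.q_start, self.q_end, length)
        return np.clip(np.round(base + offset), 2, 41).astype(np.int16)


@dataclass
class ReadCollection:
    """Paired read sets per (sample, marker) plus per-read provenance."""

    pairs: dict[tuple[str, str], tuple[ReadSet, ReadSet]]
    provenance: pd.DataFrame  # sample, marker, read_id, source, is_contaminant


def generate_reads(
    community: CommunityTruth,
    truth: ReferenceTruth,
    markers: Iterable[str],
    read_length: int = 250,
    error_rate: float = 0.003,
    quality: QualityModel = QualityModel(),
    contaminant_db: RefDB | None = None,
    contaminant_template_length: int | None = None,
    seed: int = 0,
) -> ReadCollection:
    """Simulate paired-end amplicon reads per sample and marker.

    Target reads are drawn from the truth amplicons proportional to
    template counts times the marker's recovery multiplier; contaminant
    reads (fraction per marker) come from the non-target pool.  Mates
    cover the two amplicon ends; substitution errors are applied at
    ``error_rate`` per base.
    """
    markers = list(markers)
    known = {sp for (m, sp) in truth.amplicons}
    for sample, comp in community.samples.items():
        unknown = set(comp) - known
        if unknown:
            raise SyntheticError(f"sample {sample}: unknown taxa {sorted(unknown)}")
    pairs: dict[tuple[str, str], tuple[ReadSet, ReadSet]] = {}
    prov_rows = []
    for marker in markers:
        mult = community.marker_multipliers.get(marker, 1.0)
        contam = community.contamination_for(marker)
        for sample, comp in community.samples.items():
            rng = substream(seed, "reads", marker, sample)
            fwd = ReadSet(sample_id=sample, marker=marker)
            rev = ReadSet(sample_id=sample, marker=marker)
            n_total = int(round(sum(comp.values()) * mult))
            if n_total <= 0:
                pairs[(sample, marker)] = (fwd, rev)
                continue
            n_contam = int(rng.binomial(n_total, contam)) if contam > 0 else 0
            n_target = n_total - n_contam
            species = sorted(comp)
            weights = np.array([comp[sp] for sp in species], dtype=float)
            weights /= weights.sum()
            # deterministic largest-remainder allocation: read counts stay
            # exactly proportional to template counts (up to rounding)
            if n_target > 0:
                ideal = weights * n_target
                draws = np.floor(ideal).astype(int)
                short = n_target - int(draws.sum())
                if short > 0:
                    order_idx = np.argsort(-(ideal - draws), kind="stable")
                    draws[order_idx[:short]] += 1
            else:
                draws = np.zeros(len(species), int)
            templates: list[tuple[str, str, bool]] = []
            for sp, k in zip(species, draws):
                tmpl = truth.amplicons[(marker, sp)]
                templates.extend([(sp, tmpl, False)] * int(k))
            if n_contam > 0:
                if contaminant_db is None or len(contaminant_db) == 0:
                    raise SyntheticError("contamination requested but no contaminant pool given")
                picks = rng.integers(0, len(contaminant_db), size=n_contam)
                for p in picks:
                    rec = contaminant_db.records[int(p)]
                    tmpl = rec.sequence
                    if contaminant_template_length is not None:
                        # same primers amplify the non-target pool, so its
                        # products share the marker's amplicon size
                        tmpl = tmpl[:contaminant_template_length]
                    templates.append((rec.id, tmpl, True))
            order = rng.permutation(len(templates))
            for ridx, t in enumerate(order):
                source, tmpl, is_contam = templates[int(t)]
                f_seq = tmpl[:read_length]
                r_seq = reverse_complement(tmpl[-read_length:] if len(tmpl) > read_length else tmpl)
                if error_rate > 0:
                    f_seq = mutate_sequence(f_seq, error_rate, rng)
                    r_seq = mutate_sequence(r_seq, error_rate, rng)
                offset = rng.normal(0.0, quality.read_sd) if quality.read_sd > 0 else 0.0
                fwd.reads.append(Read(f_seq, quality.profile(len(f_seq), offset)))
                rev.reads.append(Read(r_seq, quality.profile(len(r_seq), offset)))
                prov_rows.append((sample, marker, f"{sample}|{marker}|{ridx}",
                                  source, is_contam))
            pairs[(sample, marker)] = (fwd, rev)
    prov = pd.DataFrame(prov_rows,
                        columns=["sample", "marker", "read_id", "source", "is_contaminant"])
    return ReadCollection(pairs=pairs, provenance=prov)
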