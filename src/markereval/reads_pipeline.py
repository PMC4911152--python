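"""In-situ read processing: merging, filtering, dereplication, clustering.

Contract-level stand-ins for the standard amplicon toolchain: paired-end
assembly (overlap scan with quality-aware consensus), mean-quality and
length filtering, exact dereplication with an abundance threshold in place
of full denoising, greedy centroid OTU clustering at a percent-identity
radius, a low-stringency target-group screen, and the presence filters
(per-sample minimum and per-OTU total minimum) applied before analysis.
Per-stage read counts are logged for recovery analysis.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .alignment import DEFAULT_SCORING, pairwise_identity
from .iupac import reverse_complement
from .refdb import RefDB
from .taxassign import SearchParams, seeded_search
from .taxonomy import Lineage


class PipelineError(ValueError):
    pass


@dataclass
class Read:
    sequence: str
    quality: np.ndarray  # phred scores, same length as sequence

    def __post_init__(self) -> None:
        self.quality = np.asarray(self.quality, dtype=np.int16)
        if len(self.quality) != len(self.sequence):
            raise PipelineError("quality length must equal sequence length")


@dataclass
class ReadSet:
    sample_id: str
    marker: str
    reads: list[Read] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.reads)


@dataclass
class OTU:
    centroid: str
    members: list[str] = field(default_factory=list)  # unique sequences incl. centroid


@dataclass
class OTUTable:
    """Centroid sequences with per-sample member read counts."""

    identity_threshold: float
    otus: list[OTU] = field(default_factory=list)
    counts: pd.DataFrame | None = None  # rows: otu index, columns: sample ids

    def __len__(self) -> int:
        return len(self.otus)


class StageLog:
    """Ordered per-sample read counts at each pipeline stage."""

    def __init__(self) -> None:
        self.stages: list[tuple[str, dict[str, int]]] = []

    def append(self, stage: str, per_sample_counts: dict[str, int]) -> None:
        self.stages.append((stage, dict(per_sample_counts)))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({name: counts for name, counts in self.stages})
        return df[[name for name, _ in self.stages]]

    def is_monotone(self) -> bool:
        df = self.to_frame().fillna(0)
        arr = df.to_numpy()
        return bool((np.diff(arr, axis=1) <= 0).all())


def load_fastq(path: str | Path, sample_id: str, marker: str) -> ReadSet:
    reads = [
        Read(str(rec.seq).upper(), np.asarray(rec.letter_annotations["phred_quality"]))
        for rec in SeqIO.parse(str(path), "fastq")
    ]
    return ReadSet(sample_id=sample_id, marker=marker, reads=reads)


def merge_pairs(
    fwd: ReadSet,
    rev: ReadSet,
    min_overlap: int = 20,
    max_mismatch_rate: float = 0.1,
) -> tuple[ReadSet, int]:
    """Assemble index-paired mates by overlap; returns (merged set, n failed).

    The reverse mate is reverse-complemented and slid against the forward
    read; the longest overlap of at least ``min_overlap`` whose mismatch
    rate does not exceed ``max_mismatch_rate`` is accepted.  Disagreeing
    overlap positions are resolved in favour of the higher-quality base
    (forward wins on quality ties).
    """
    if len(fwd) != len(rev):
        raise PipelineError(
            f"mate count mismatch: {len(fwd)} forward vs {len(rev)} reverse"
        )
    merged = ReadSet(sample_id=fwd.sample_id, marker=fwd.marker)
    failures = 0
    for f, r in zip(fwd.reads, rev.reads):
        rc_seq = reverse_complement(r.sequence)
        rc_q = r.quality[::-1]
        best = None
        max_l = min(len(f.sequence), len(rc_seq))
        fa = np.frombuffer(f.sequence.encode(), dtype=np.uint8)
        ra = np.frombuffer(rc_seq.encode(), dtype=np.uint8)
        for L in range(max_l, min_overlap - 1, -1):
            mism = int(np.count_nonzero(fa[len(fa) - L:] != ra[:L]))
            if mism / L <= max_mismatch_rate:
                best = L
                break
        if best is None:
            failures += 1
            continue
        L = best
        seq = list(f.sequence[:-L] or "")
        qual = list(f.quality[:-L] if L < len(f.sequence) else [])
        for k in range(L):
            fb = f.sequence[len(f.sequence) - L + k]
            fq = int(f.quality[len(f.sequence) - L + k])
            rb = rc_seq[k]
            rq = int(rc_q[k])
            if fb == rb:
                seq.append(fb)
                qual.append(max(fq, rq))
            elif fq >= rq:
                seq.append(fb)
                qual.append(fq)
            else:
                seq.append(rb)
                qual.append(rq)
        seq.extend(rc_seq[L:])
        qual.extend(rc_q[L:])
        merged.reads.append(Read("".join(seq), np.asarray(qual)))
    return merged, failures


#: spacer used when long-marker mates cannot overlap; N never mismatches
CONCAT_SPACER = "N" * 10


def concat_pairs(fwd: ReadSet, rev: ReadSet, spacer: str = CONCAT_SPACER) -> ReadSet:
    """Join non-overlapping mates as fwd + spacer + revcomp(rev).

    Mirrors concatenation of long-marker paired ends; the all-N spacer is
    neutral in identity computations (N matches every base).
    """
    if len(fwd) != len(rev):
        raise PipelineError("mate count mismatch")
    out = ReadSet(sample_id=fwd.sample_id, marker=fwd.marker)
    spacer_q = np.full(len(spacer), 2, dtype=np.int16)
    for f, r in zip(fwd.reads, rev.reads):
        seq = f.sequence + spacer + reverse_complement(r.sequence)
        qual = np.concatenate([f.quality, spacer_q, r.quality[::-1]])
        out.reads.append(Read(seq, qual))
    return out


def quality_filter(
    reads: ReadSet, min_mean_q: float = 25.0, min_len: int = 50, max_len: int = 10_000
) -> ReadSet:
    """Keep reads with mean phred >= ``min_mean_q`` and length within bounds."""
    if min_len > max_len:
        raise PipelineError("min_len must not exceed max_len")
    kept = [
        r
        for r in reads.reads
        if min_len <= len(r.sequence) <= max_len and float(np.mean(r.quality)) >= min_mean_q
    ]
    return ReadSet(sample_id=reads.sample_id, marker=reads.marker, reads=kept)


def dereplicate(
    sequences: Iterable[str], min_abundance: int = 2
) -> list[tuple[str, int]]:
    """Collapse exact duplicates and drop rare uniques.

    Returns (sequence, abundance) sorted by abundance descending with
    lexicographic tie-break, a simplified stand-in for read denoising.
    """
    counts = Counter(sequences)
    uniques = [(s, n) for s, n in counts.items() if n >= min_abundance]
    uniques.sort(key=lambda x: (-x[1], x[0]))
    return uniques


def cluster_otus(
    uniques: Sequence[tuple[str, int]],
    identity_threshold: float = 98.0,
    scoring: tuple[int, int, int] = DEFAULT_SCORING,
) -> OTUTable:
    """Greedy centroid clustering at a percent-identity radius.

    Input must be abundance-sorted; each unique joins the first existing
    centroid (in founding order) with global-alignment identity (terminal
    gaps excluded) at or above the threshold, otherwise it founds a new
    centroid.  Centroids are therefore mutually below the threshold at
    founding time.
    """
    table = OTUTable(identity_threshold=identity_threshold)
    for seq, _ in uniques:
        placed = False
        for otu in table.otus:
            if pairwise_identity(seq, otu.centroid, scoring) >= identity_threshold:
                otu.members.append(seq)
                placed = True
                break
        if not placed:
            table.otus.append(OTU(centroid=seq, members=[seq]))
    return table


def otu_counts(
    table: OTUTable, per_sample_sequences: dict[str, Iterable[str]]
) -> pd.DataFrame:
    """Per-sample read counts for each OTU (rows: OTU index, cols: samples).

    Reads whose sequence is not among the clustered uniques (e.g. removed
    by the abundance threshold) are ignored.
    """
    member_to_otu = {
        m: i for i, otu in enumerate(table.otus) for m in otu.members
    }
    samples = sorted(per_sample_sequences)
    counts = np.zeros((len(table.otus), len(samples)), dtype=int)
    for j, sample in enumerate(samples):
        for seq in per_sample_sequences[sample]:
            i = member_to_otu.get(seq)
            if i is not None:
                counts[i, j] += 1
    df = pd.DataFrame(counts, columns=samples)
    table.counts = df
    return df


def screen_target_group(
    table: OTUTable,
    screen_db: RefDB,
    params: SearchParams,
    is_target: Callable[[Lineage], bool],
) -> OTUTable:
    """Keep OTUs whose best passing low-stringency hit is in the target group.

    OTUs with no passing hit at all are removed together with the
    non-target ones (they cannot be attributed to the target group).
    """
    if len(screen_db) == 0:
        raise PipelineError("screen database is empty")
    kept_idx = []
    for i, otu in enumerate(table.otus):
        hits = seeded_search(otu.centroid, screen_db, params)
        if hits and is_target(hits[0].lineage):
            kept_idx.append(i)
    out = OTUTable(identity_threshold=table.identity_threshold,
                   otus=[table.otus[i] for i in kept_idx])
    if table.counts is not None:
        out.counts = table.counts.iloc[kept_idx].reset_index(drop=True)
    return out


def apply_presence_filters(
    counts: pd.DataFrame, min_per_sample: int = 10, min_total: int = 100
) -> pd.DataFrame:
    """Zero per-sample counts below ``min_per_sample``; drop rows whose
    total (after zeroing) is below ``min_total``.

    Both thresholds are inclusive ("a minimum of N" means >= N survives).
    Idempotent by construction.
    """
    if (counts.to_numpy() < 0).any():
        raise PipelineError("counts must be non-negative")
    zeroed = counts.where(counts >= min_per_sample, 0)
    return zeroed[zeroed.sum(axis=1) >= min_total]
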