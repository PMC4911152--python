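"""In-silico PCR: degenerate primer site location and mock-amplicon cropping.

Reference sequences are cropped to the region a primer pair would amplify,
producing mock reads with known taxonomy.  Primer matching is ungapped and
exhaustive on both strands, with a configurable mismatch tolerance; of all
valid forward/reverse site pairs the shortest product is taken, mimicking
the dominant PCR product.  Primers are trimmed from the emitted amplicon by
default so mock reads are comparable to primer-trimmed HTS reads.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .iupac import encode, reverse_complement
from .refdb import RefDB, RefRecord
from .taxonomy import Lineage, format_lineage, parse_lineage


class PrimerError(ValueError):
    pass


@dataclass(frozen=True)
class PrimerPair:
    """Forward and reverse primers, both written 5'→3' on their own strands."""

    forward: str
    reverse: str
    max_mismatch: int = 2

    def __post_init__(self) -> None:
        if not self.forward or not self.reverse:
            raise PrimerError("primers must be non-empty")
        if self.max_mismatch < 0 or self.max_mismatch >= min(len(self.forward), len(self.reverse)):
            raise PrimerError("max_mismatch must be in [0, primer length)")
        encode(self.forward)
        encode(self.reverse)


@dataclass(frozen=True)
class PrimerSite:
    offset: int  # 0-based start on the forward strand of the scanned sequence
    strand: str  # '+' or '-'
    n_mismatch: int


@dataclass(frozen=True)
class MockAmplicon:
    """A reference cropped to its amplified insert, with truth lineage."""

    source_id: str
    marker: str
    sequence: str
    truth: Lineage


def _mismatch_profile(seq_masks: np.ndarray, primer_masks: np.ndarray) -> np.ndarray:
    """Mismatch count of the primer at every ungapped offset (vectorised)."""
    n, m = len(seq_masks), len(primer_masks)
    if n < m:
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(seq_masks, m)
    return ((windows & primer_masks) == 0).sum(axis=1)


def find_primer_site(seq: str, primer: str, max_mismatch: int) -> PrimerSite | None:
    """Best ungapped primer site on either strand, or ``None``.

    Exhaustive scan; returns the site with fewest mismatches not exceeding
    ``max_mismatch``.  Ties are broken in favour of the forward strand,
    then the smallest offset.
    """
    if len(seq) < len(primer):
        raise PrimerError("sequence shorter than primer")
    es = encode(seq)
    ep = encode(primer)
    best: PrimerSite | None = None
    for strand, masks in (("+", ep), ("-", encode(reverse_complement(primer)))):
        prof = _mismatch_profile(es, masks)
        if prof.size == 0:
            continue
        off = int(prof.argmin())
        mm = int(prof[off])
        if mm <= max_mismatch and (best is None or mm < best.n_mismatch):
            best = PrimerSite(offset=off, strand=strand, n_mismatch=mm)
    return best


def _sites(seq_masks: np.ndarray, primer_masks: np.ndarray, max_mismatch: int) -> list[tuple[int, int]]:
    prof = _mismatch_profile(seq_masks, primer_masks)
    return [(int(i), int(prof[i])) for i in np.nonzero(prof <= max_mismatch)[0]]


def _crop(seq: str, primers: PrimerPair, trim_primers: bool) -> str | None | str:
    """Find the shortest valid product on the given orientation.

    Returns the insert (or full product) string, or the string reason for
    failure ("forward"/"reverse").
    """
    es = encode(seq)
    fwd = encode(primers.forward)
    rev_rc = encode(reverse_complement(primers.reverse))
    fsites = _sites(es, fwd, primers.max_mismatch)
    if not fsites:
        return "forward"
    rsites = _sites(es, rev_rc, primers.max_mismatch)
    best = None  # (insert_len, f_start, r_start)
    for f_start, _ in fsites:
        f_end = f_start + len(primers.forward)
        for r_start, _ in rsites:
            if r_start < f_end:
                continue
            cand = (r_start - f_end, f_start, r_start)
            if best is None or cand < best:
                best = cand
    if best is None:
        return "reverse"
    _, f_start, r_start = best
    if trim_primers:
        insert = seq[f_start + len(primers.forward): r_start]
    else:
        insert = seq[f_start: r_start + len(primers.reverse)]
    return insert if insert else "reverse"


def extract_amplicons(
    db: RefDB, primers: PrimerPair, trim_primers: bool = True
) -> tuple[list[MockAmplicon], pd.DataFrame]:
    """Crop each reference to its amplicon; skipped records are logged.

    The forward orientation of each record is tried first; records in
    reverse orientation are handled by reverse-complementing.  The skip log
    has columns ``record_id`` and ``reason``.
    """
    amplicons: list[MockAmplicon] = []
    skips: list[tuple[str, str]] = []
    for rec in db.records:
        result = None
        reasons = []
        for seq in (rec.sequence, reverse_complement(rec.sequence)):
            out = _crop(seq, primers, trim_primers)
            if out not in ("forward", "reverse"):
                result = out
                break
            reasons.append(out)
        if result is None:
            reason = ("forward primer not found" if set(reasons) == {"forward"}
                      else "reverse primer not found")
            skips.append((rec.id, reason))
            continue
        amplicons.append(
            MockAmplicon(source_id=rec.id, marker=db.marker, sequence=result, truth=rec.lineage)
        )
    log = pd.DataFrame(skips, columns=["record_id", "reason"])
    return amplicons, log


def write_amplicon_fasta(amplicons: list[MockAmplicon], path: str | Path,
                         delimiter: str = ";") -> None:
    recs = [
        SeqRecord(Seq(a.sequence), id=a.source_id,
                  description=format_lineage(a.truth, delimiter))
        for a in amplicons
    ]
    SeqIO.write(recs, str(path), "fasta")


def load_amplicon_fasta(path: str | Path, marker: str, delimiter: str = ";") -> list[MockAmplicon]:
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        truth = parse_lineage(rec.description.split(None, 1)[1], delimiter) \
            if " " in rec.description else Lineage()
        out.append(MockAmplicon(source_id=rec.id, marker=marker,
                                sequence=str(rec.seq).upper(), truth=truth))
    return out


def amplicon_refdb(amplicons: list[MockAmplicon], marker: str) -> RefDB:
    """Build a searchable reference database from mock amplicons."""
    db = RefDB(marker=marker)
    for a in amplicons:
        db.add(RefRecord(id=a.source_id, marker=marker, sequence=a.sequence, lineage=a.truth))
    return db
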