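"""Reference sequence databases with taxonomic lineages, and coverage summaries.

A reference database is a per-marker collection of sequences, each bound to
a six-rank lineage carried in the FASTA header::

    >KX1234 Plantae;Tracheophyta;Poales;Poaceae;Poa;Poa pratensis
    ACGT...

Coverage of a target taxa list is summarised per rank (order, family,
genus, species) the way barcode-database audits tabulate it, together with
the sequence-to-species ratio of the database itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .iupac import AlphabetError, normalize
from .taxonomy import RANKS, Lineage, format_lineage, parse_lineage, species_key

COVERAGE_RANKS: tuple[str, ...] = ("order", "family", "genus", "species")


class RefDBError(ValueError):
    pass


@dataclass(frozen=True)
class RefRecord:
    """One reference sequence bound to its lineage."""

    id: str
    marker: str
    sequence: str
    lineage: Lineage

    def __post_init__(self) -> None:
        if not self.sequence:
            raise RefDBError(f"record {self.id!r}: empty sequence")
        try:
            object.__setattr__(self, "sequence", normalize(self.sequence))
        except AlphabetError as exc:
            raise RefDBError(f"record {self.id!r}: {exc}") from None


@dataclass
class RefDB:
    """A marker-specific reference database with unique record ids."""

    marker: str
    records: list[RefRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._index: dict[str, RefRecord] = {}
        for rec in self.records:
            if rec.id in self._index:
                raise RefDBError(f"duplicate record id {rec.id!r} in {self.marker} database")
            self._index[rec.id] = rec

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, rec_id: str) -> RefRecord:
        return self._index[rec_id]

    def __contains__(self, rec_id: str) -> bool:
        return rec_id in self._index

    def add(self, rec: RefRecord) -> None:
        if rec.id in self._index:
            raise RefDBError(f"duplicate record id {rec.id!r} in {self.marker} database")
        self.records.append(rec)
        self._index[rec.id] = rec

    def species(self) -> set[str]:
        """Distinct known species keys in the database."""
        out = set()
        for rec in self.records:
            key = species_key(rec.lineage)
            if key is not None:
                out.add(key.lower())
        return out


@dataclass(frozen=True)
class CoverageTable:
    """Per-rank coverage of a target taxa list plus the seq:species ratio."""

    rows: pd.DataFrame  # index: rank; columns: n_target, n_covered, percent
    seq_to_species_ratio: float

    def to_tsv(self, path: str | Path) -> None:
        df = self.rows.reset_index().rename(columns={"index": "rank"})
        with open(path, "w") as fh:
            df.to_csv(fh, sep="\t", index=False, float_format="%.4f")
            fh.write(f"# seq_to_species_ratio\t{self.seq_to_species_ratio:.4f}\n")


def load_reference_fasta(path: str | Path, marker: str, delimiter: str = ";") -> RefDB:
    """Load a reference FASTA whose headers carry ``id lineage-string``.

    Sequences are uppercased and U converted to T.  Duplicate ids and
    non-IUPAC characters raise :class:`RefDBError` naming the record.
    """
    db = RefDB(marker=marker)
    for rec in SeqIO.parse(str(path), "fasta"):
        lineage = parse_lineage(rec.description.split(None, 1)[1], delimiter) \
            if " " in rec.description else Lineage()
        db.add(RefRecord(id=rec.id, marker=marker, sequence=str(rec.seq), lineage=lineage))
    return db


def write_reference_fasta(db: RefDB, path: str | Path, delimiter: str = ";") -> None:
    recs = [
        SeqRecord(Seq(r.sequence), id=r.id,
                  description=format_lineage(r.lineage, delimiter))
        for r in db.records
    ]
    SeqIO.write(recs, str(path), "fasta")


def load_targets_tsv(path: str | Path) -> list[Lineage]:
    """Read a target taxa list: TSV with one column per rank."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [r for r in RANKS if r not in df.columns]
    if missing:
        raise RefDBError(f"targets file missing rank columns: {missing}")
    return [
        Lineage(**{r: (row[r].strip() or "UNKNOWN") for r in RANKS})
        for _, row in df.iterrows()
    ]


def write_targets_tsv(targets: list[Lineage], path: str | Path) -> None:
    df = pd.DataFrame([t.as_tuple() for t in targets], columns=list(RANKS))
    df.to_csv(path, sep="\t", index=False)


def _matches_through(record: Lineage, target: Lineage, rank: str) -> bool:
    """Case-insensitive match at ``rank`` and all coarser reported ranks."""
    for r in COVERAGE_RANKS:
        if not target.is_known(r):
            return False
        if record.at(r).lower() != target.at(r).lower():
            return False
        if r == rank:
            return True
    return False


def coverage_summary(db: RefDB, targets: list[Lineage]) -> CoverageTable:
    """Summarise database coverage of a target taxa list per rank.

    A target taxon is covered at rank *r* iff at least one record's lineage
    matches it (exact, case-insensitive) at *r* and at every coarser
    reported rank.  The seq:species ratio is the number of records divided
    by the number of distinct species in the database.
    """
    if not targets:
        raise RefDBError("target list is empty")
    record_lineages = [r.lineage for r in db.records]
    rows = {}
    for rank in COVERAGE_RANKS:
        idx = COVERAGE_RANKS.index(rank)
        target_taxa = {
            tuple(t.at(r).lower() for r in COVERAGE_RANKS[: idx + 1]): t
            for t in targets
            if all(t.is_known(r) for r in COVERAGE_RANKS[: idx + 1])
        }
        n_target = len(target_taxa)
        n_cov = sum(
            1
            for t in target_taxa.values()
            if any(_matches_through(rl, t, rank) for rl in record_lineages)
        )
        pct = 100.0 * n_cov / n_target if n_target else float("nan")
        rows[rank] = {"n_target": n_target, "n_covered": n_cov, "percent": pct}
    n_species = len(db.species())
    if n_species == 0:
        warnings.warn(f"{db.marker}: no species-labelled records; seq:species ratio undefined")
        ratio = float("nan")
    else:
        ratio = len(db) / n_species
    frame = pd.DataFrame.from_dict(rows, orient="index").astype(
        {"n_target": int, "n_covered": int, "percent": float}
    )
    return CoverageTable(rows=frame, seq_to_species_ratio=ratio)
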