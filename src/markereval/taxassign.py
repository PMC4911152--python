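"""Seeded similarity search and consensus taxonomy assignment.

A contract-level stand-in for a megaBLAST-style workflow: candidate
references must share at least one exact word with the query (either
strand), candidates are locally aligned with gapped extension, and hits
are gated on identity, E-value (Karlin–Altschul approximation) and aligned
query fraction.  The taxonomy of all hits tying for top score is
consolidated rank by rank; any disagreement yields ``AMBIGUOUS`` at that
rank and all finer ranks.  Outcomes against known truth are classified as
correct / incorrect / ambiguous / no_match.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .alignment import DEFAULT_SCORING, LocalAlignment, local_align
from .iupac import reverse_complement
from .refdb import RefDB
from .taxonomy import AMBIGUOUS, RANKS, UNKNOWN, Lineage

OUTCOMES = ("correct", "incorrect", "ambiguous", "no_match")


class SearchError(ValueError):
    pass


@dataclass(frozen=True)
class SearchParams:
    """Thresholds for the seeded search.

    ``ks_lambda`` and ``ks_k`` are Karlin–Altschul constants for the
    +1/−1 match/mismatch scoring, used only to gate hits on an
    approximate E-value = k·m·n·exp(−lambda·score).
    """

    word_size: int = 28
    min_identity: float = 98.0
    max_evalue: float = 1e-20
    ks_lambda: float = 1.33
    ks_k: float = 0.621
    min_align_fraction: float = 0.8

    def __post_init__(self) -> None:
        if self.word_size < 4:
            raise SearchError("word_size must be >= 4")
        if not (0 < self.min_identity <= 100):
            raise SearchError("min_identity must be in (0, 100]")
        if self.max_evalue <= 0:
            raise SearchError("max_evalue must be positive")


#: High-stringency search for the long marker class (full-length barcodes).
HIGH_STRINGENCY_LONG = SearchParams(word_size=28, min_identity=98.0, max_evalue=1e-20)
#: High-stringency search for short markers (small word size, relaxed E).
HIGH_STRINGENCY_SHORT = SearchParams(word_size=12, min_identity=98.0, max_evalue=0.1)
#: Low-stringency screen used to separate target from non-target groups.
LOW_STRINGENCY = SearchParams(word_size=12, min_identity=70.0, max_evalue=0.1,
                              min_align_fraction=0.5)


@dataclass(frozen=True)
class Hit:
    ref_id: str
    score: int
    identity: float
    evalue: float
    lineage: Lineage


@dataclass
class AssignmentResult:
    query_id: str
    consensus: Lineage
    n_tied_top: int
    hits: list[Hit] = field(default_factory=list)
    outcome_per_rank: dict[str, str] = field(default_factory=dict)

    @property
    def no_match(self) -> bool:
        return self.n_tied_top == 0


def _words(seq: str, k: int) -> set[str]:
    return {seq[i: i + k] for i in range(len(seq) - k + 1)}


def seeded_search(
    query: str,
    db: RefDB,
    params: SearchParams,
    scoring: tuple[int, int, int] = DEFAULT_SCORING,
) -> list[Hit]:
    """Rank references matching the query under the given thresholds.

    Candidate references share at least one exact word of ``word_size``
    with the query on either strand; each candidate is Smith–Waterman
    aligned (the better of the two query strands is kept, forward on ties)
    and gated on identity, E-value and aligned query fraction.  Hits are
    sorted by score descending with ties kept in database order.
    """
    if len(query) < params.word_size:
        raise SearchError(
            f"query length {len(query)} shorter than word size {params.word_size}"
        )
    query = query.upper()
    rc_query = reverse_complement(query)
    k = params.word_size
    qwords = _words(query, k) | _words(rc_query, k)
    db_len = sum(len(r.sequence) for r in db.records)
    hits: list[Hit] = []
    for rec in db.records:
        ref = rec.sequence
        if not any(ref[i: i + k] in qwords for i in range(len(ref) - k + 1)):
            continue
        best: LocalAlignment | None = None
        for strand_query in (query, rc_query):
            aln = local_align(strand_query, ref, scoring)
            if aln is not None and (best is None or aln.score > best.score):
                best = aln
        if best is None:
            continue
        evalue = params.ks_k * len(query) * db_len * math.exp(-params.ks_lambda * best.score)
        if (
            best.identity >= params.min_identity
            and evalue <= params.max_evalue
            and best.query_fraction(len(query)) >= params.min_align_fraction
        ):
            hits.append(Hit(ref_id=rec.id, score=best.score, identity=best.identity,
                            evalue=evalue, lineage=rec.lineage))
    hits.sort(key=lambda h: -h.score)  # stable: ties keep database order
    return hits


def top_tied_hits(hits: Sequence[Hit]) -> list[Hit]:
    if not hits:
        return []
    top = hits[0].score
    return [h for h in hits if h.score == top]


def consolidate_taxonomy(hits: Sequence[Hit]) -> Lineage:
    """Per-rank consensus of tied top hits; conflicts become ``AMBIGUOUS``.

    At each rank all tied hits must carry the identical value (including
    all-``UNKNOWN``); any mixture yields ``AMBIGUOUS``, which then
    propagates to every finer rank.
    """
    if not hits:
        raise SearchError("cannot consolidate an empty hit set")
    values: dict[str, str] = {}
    ambiguous = False
    for rank in RANKS:
        if not ambiguous:
            names = {h.lineage.at(rank) for h in hits}
            if len(names) > 1:
                ambiguous = True
        values[rank] = AMBIGUOUS if ambiguous else hits[0].lineage.at(rank)
    # Lineage's binomial invariant cannot be violated: either both
    # genus/species copied from one hit, or species is AMBIGUOUS.
    return Lineage(**values)


def classify_against_truth(result: AssignmentResult, truth: Lineage, rank: str) -> str:
    """Outcome of one assignment at one rank versus the known lineage."""
    if truth.at(rank) in (UNKNOWN, AMBIGUOUS):
        raise SearchError(f"truth is not known at rank {rank!r}")
    if result.no_match:
        return "no_match"
    assigned = result.consensus.at(rank)
    if assigned in (AMBIGUOUS, UNKNOWN):
        return "ambiguous"
    return "correct" if assigned.lower() == truth.at(rank).lower() else "incorrect"


def assign_query(
    query_id: str,
    sequence: str,
    db: RefDB,
    params: SearchParams,
    truth: Lineage | None = None,
    ranks: Iterable[str] = ("genus", "species"),
    scoring: tuple[int, int, int] = DEFAULT_SCORING,
    exclude_self: bool = False,
) -> AssignmentResult:
    """Search, consolidate and (when truth is given) classify one query.

    ``exclude_self`` removes the hit whose ref_id equals ``query_id``
    (leave-one-out evaluation); the default leave-in mode mirrors searching
    database-derived mock reads against the full database.
    """
    hits = seeded_search(sequence, db, params, scoring)
    if exclude_self:
        hits = [h for h in hits if h.ref_id != query_id]
    tied = top_tied_hits(hits)
    if tied:
        consensus = consolidate_taxonomy(tied)
    else:
        consensus = Lineage()
    result = AssignmentResult(query_id=query_id, consensus=consensus,
                              n_tied_top=len(tied), hits=hits)
    if truth is not None:
        for rank in ranks:
            if truth.at(rank) not in (UNKNOWN, AMBIGUOUS):
                result.outcome_per_rank[rank] = classify_against_truth(result, truth, rank)
    return result


def accuracy_summary(
    results: Sequence[AssignmentResult], ranks: Iterable[str] = ("genus", "species")
) -> pd.DataFrame:
    """Per-rank proportions of correct / incorrect / ambiguous / no_match.

    Only results classified at a rank contribute to that rank's
    denominator; proportions sum to 1 per rank.
    """
    results = list(results)
    if not results:
        raise SearchError("no assignment results to summarise")
    rows = {}
    for rank in ranks:
        classified = [r.outcome_per_rank[rank] for r in results if rank in r.outcome_per_rank]
        if not classified:
            continue
        n = len(classified)
        counts = {o: classified.count(o) for o in OUTCOMES}
        row = {o: counts[o] / n for o in OUTCOMES}
        row.update({f"n_{o}": counts[o] for o in OUTCOMES})
        row["n"] = n
        rows[rank] = row
    if not rows:
        raise SearchError("no results carried truth at the requested ranks")
    return pd.DataFrame.from_dict(rows, orient="index")


def params_for_marker(amplicon_length: int, long_marker_cutoff: int = 200) -> SearchParams:
    """High-stringency preset chosen by marker length class."""
    return HIGH_STRINGENCY_LONG if amplicon_length >= long_marker_cutoff else HIGH_STRINGENCY_SHORT
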