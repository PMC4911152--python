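"""Pairwise sequence alignment primitives.

Needleman–Wunsch global alignment and Smith–Waterman local alignment under
linear gap scoring, with fully deterministic traceback (ties prefer
diagonal, then up, then left) so that every downstream distance and
identity value is reproducible bit-for-bit.  IUPAC ambiguity codes are
compared by degeneracy-set intersection: overlapping sets score as a match.

The dynamic-programming fills are numba-compiled; sequences enter as
uint8 degeneracy-mask arrays (see :mod:`markereval.iupac`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .iupac import encode, iupac_match

GAP = "-"

#: default scoring: +1 match, -1 mismatch, -2 gap
DEFAULT_SCORING: tuple[int, int, int] = (1, -1, -2)

_DIAG, _UP, _LEFT, _STOP = 0, 1, 2, 3


class AlignmentError(ValueError):
    pass


@njit(cache=True)
def _nw_fill(a, b, match, mismatch, gap):  # pragma: no cover - numba
    n, m = a.shape[0], b.shape[0]
    H = np.empty((n + 1, m + 1), np.int64)
    P = np.empty((n + 1, m + 1), np.int8)
    H[0, 0] = 0
    P[0, 0] = _STOP
    for j in range(1, m + 1):
        H[0, j] = gap * j
        P[0, j] = _LEFT
    for i in range(1, n + 1):
        H[i, 0] = gap * i
        P[i, 0] = _UP
        for j in range(1, m + 1):
            s = match if (a[i - 1] & b[j - 1]) != 0 else mismatch
            d = H[i - 1, j - 1] + s
            u = H[i - 1, j] + gap
            l = H[i, j - 1] + gap
            best = d
            ptr = _DIAG
            if u > best:
                best = u
                ptr = _UP
            if l > best:
                best = l
                ptr = _LEFT
            H[i, j] = best
            P[i, j] = ptr
    return H, P


@njit(cache=True)
def _sw_fill(a, b, match, mismatch, gap):  # pragma: no cover - numba
    n, m = a.shape[0], b.shape[0]
    H = np.zeros((n + 1, m + 1), np.int64)
    P = np.full((n + 1, m + 1), _STOP, np.int8)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if (a[i - 1] & b[j - 1]) != 0 else mismatch
            d = H[i - 1, j - 1] + s
            u = H[i - 1, j] + gap
            l = H[i, j - 1] + gap
            v = d
            ptr = _DIAG
            if u > v:
                v = u
                ptr = _UP
            if l > v:
                v = l
                ptr = _LEFT
            if v <= 0:
                v = 0
                ptr = _STOP
            H[i, j] = v
            P[i, j] = ptr
            if v > best:  # strict: first occurrence in row-major order wins
                best = v
                bi = i
                bj = j
    return H, P, best, bi, bj


@njit(cache=True)
def _sw_score(a, b, match, mismatch, gap):  # pragma: no cover - numba
    """Best local score only (no matrices kept) — used for oracle scans."""
    n, m = a.shape[0], b.shape[0]
    prev = np.zeros(m + 1, np.int64)
    cur = np.zeros(m + 1, np.int64)
    best = 0
    for i in range(1, n + 1):
        cur[0] = 0
        for j in range(1, m + 1):
            s = match if (a[i - 1] & b[j - 1]) != 0 else mismatch
            v = prev[j - 1] + s
            u = prev[j] + gap
            l = cur[j - 1] + gap
            if u > v:
                v = u
            if l > v:
                v = l
            if v < 0:
                v = 0
            cur[j] = v
            if v > best:
                best = v
        prev, cur = cur, prev
    return best


@dataclass(frozen=True)
class GlobalAlignment:
    aligned_a: str
    aligned_b: str
    score: int

    def __iter__(self):
        return iter((self.aligned_a, self.aligned_b))


@dataclass(frozen=True)
class LocalAlignment:
    """A Smith–Waterman local alignment of query against reference."""

    aligned_query: str
    aligned_ref: str
    score: int
    query_start: int
    query_end: int  # half-open
    ref_start: int
    ref_end: int

    @property
    def identity(self) -> float:
        """Percent identical columns over all alignment columns."""
        cols = len(self.aligned_query)
        if cols == 0:
            return 0.0
        matches = _count_matches(self.aligned_query, self.aligned_ref)
        return 100.0 * matches / cols

    def query_fraction(self, query_length: int) -> float:
        return (self.query_end - self.query_start) / query_length


def _count_matches(aln_a: str, aln_b: str) -> int:
    n = 0
    for x, y in zip(aln_a, aln_b):
        if x != GAP and y != GAP and iupac_match(x, y):
            n += 1
    return n


def global_align(
    a: str, b: str, scoring: tuple[int, int, int] = DEFAULT_SCORING
) -> GlobalAlignment:
    """Optimal global alignment under linear gap scoring.

    Traceback ties are resolved diagonal > up > left, so the result is a
    deterministic function of the inputs.
    """
    if not a or not b:
        raise AlignmentError("cannot align an empty sequence")
    match, mismatch, gap = scoring
    ea, eb = encode(a), encode(b)
    H, P = _nw_fill(ea, eb, match, mismatch, gap)
    i, j = len(a), len(b)
    out_a: list[str] = []
    out_b: list[str] = []
    while i > 0 or j > 0:
        p = P[i, j]
        if p == _DIAG:
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i -= 1
            j -= 1
        elif p == _UP:
            out_a.append(a[i - 1])
            out_b.append(GAP)
            i -= 1
        else:
            out_a.append(GAP)
            out_b.append(b[j - 1])
            j -= 1
    return GlobalAlignment("".join(reversed(out_a)), "".join(reversed(out_b)), int(H[-1, -1]))


def local_align(
    query: str, ref: str, scoring: tuple[int, int, int] = DEFAULT_SCORING
) -> LocalAlignment | None:
    """Best Smith–Waterman local alignment; ``None`` when the best score is 0.

    The traceback starts at the first (row-major) maximal cell and follows
    the same diagonal > up > left preference as the global aligner.
    """
    if not query or not ref:
        raise AlignmentError("cannot align an empty sequence")
    match, mismatch, gap = scoring
    eq, er = encode(query), encode(ref)
    H, P, best, bi, bj = _sw_fill(eq, er, match, mismatch, gap)
    if best <= 0:
        return None
    i, j = int(bi), int(bj)
    qe, re_ = i, j
    out_q: list[str] = []
    out_r: list[str] = []
    while H[i, j] > 0 and P[i, j] != _STOP:
        p = P[i, j]
        if p == _DIAG:
            out_q.append(query[i - 1])
            out_r.append(ref[j - 1])
            i -= 1
            j -= 1
        elif p == _UP:
            out_q.append(query[i - 1])
            out_r.append(GAP)
            i -= 1
        else:
            out_q.append(GAP)
            out_r.append(ref[j - 1])
            j -= 1
    return LocalAlignment(
        "".join(reversed(out_q)),
        "".join(reversed(out_r)),
        int(best),
        i,
        qe,
        j,
        re_,
    )


def local_score(query: str, ref: str, scoring: tuple[int, int, int] = DEFAULT_SCORING) -> int:
    """Best local alignment score only (memory-light)."""
    match, mismatch, gap = scoring
    return int(_sw_score(encode(query), encode(ref), match, mismatch, gap))


def p_distance(aligned_a: str, aligned_b: str) -> float:
    """Uncorrected pairwise distance with pairwise deletion of gap columns.

    Returns (#differing sites) / (#sites where both sequences have a
    non-gap base).  IUPAC codes whose degeneracy sets overlap count as
    identical sites.
    """
    if len(aligned_a) != len(aligned_b):
        raise AlignmentError("aligned sequences must have equal length")
    comparable = 0
    diffs = 0
    for x, y in zip(aligned_a, aligned_b):
        if x == GAP or y == GAP:
            continue
        comparable += 1
        if not iupac_match(x, y):
            diffs += 1
    if comparable == 0:
        raise AlignmentError("no overlap: zero comparable (gap-free) columns")
    return diffs / comparable


def pairwise_identity(
    a: str, b: str, scoring: tuple[int, int, int] = DEFAULT_SCORING
) -> float:
    """Percent identity of the global alignment, excluding terminal gaps.

    Identity = matches / alignment columns, where columns inside terminal
    gap runs (overhangs at either end of the alignment) are excluded and
    internal gap columns count against identity.  This is the criterion
    used for greedy OTU clustering, tolerant of length variation.
    """
    aln = global_align(a, b, scoring)
    qa, qb = aln.aligned_a, aln.aligned_b
    start = 0
    end = len(qa)
    while start < end and (qa[start] == GAP or qb[start] == GAP):
        start += 1
    while end > start and (qa[end - 1] == GAP or qb[end - 1] == GAP):
        end -= 1
    cols = end - start
    if cols <= 0:
        return 0.0
    matches = _count_matches(qa[start:end], qb[start:end])
    return 100.0 * matches / cols
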