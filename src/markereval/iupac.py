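"""IUPAC nucleotide alphabet: degeneracy masks, matching, reverse complement.

Bases are represented internally as 4-bit masks (A=1, C=2, G=4, T=8), so a
degenerate code is the OR of its set and two codes are compatible iff their
masks intersect.
"""

from __future__ import annotations

import numpy as np

_BASE_BITS = {"A": 1, "C": 2, "G": 4, "T": 8}

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "U": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

IUPAC_MASKS: dict[str, int] = {
    code: sum(_BASE_BITS[b] for b in bases) for code, bases in IUPAC_SETS.items()
}

_COMPLEMENT = {
    "A": "T", "T": "A", "U": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}
_COMP_TABLE = str.maketrans({**_COMPLEMENT, **{k.lower(): v for k, v in _COMPLEMENT.items()}})

# mask -> mask lookup for complementing encoded arrays
_MASK_COMPLEMENT = np.zeros(16, dtype=np.uint8)
for code, m in IUPAC_MASKS.items():
    if code != "U":
        _MASK_COMPLEMENT[m] = IUPAC_MASKS[_COMPLEMENT[code]]


class AlphabetError(ValueError):
    """Raised when a sequence contains a character outside the IUPAC alphabet."""


def iupac_match(base: str, code: str) -> bool:
    """True iff ``base`` lies in the degeneracy set of ``code``.

    Both arguments may be degenerate; the test is set intersection.
    """
    try:
        return bool(IUPAC_MASKS[base.upper()] & IUPAC_MASKS[code.upper()])
    except KeyError as exc:
        raise AlphabetError(f"non-IUPAC character {exc.args[0]!r}") from None


def validate_sequence(seq: str, context: str = "sequence") -> None:
    bad = set(seq.upper()) - IUPAC_MASKS.keys()
    if bad:
        raise AlphabetError(f"{context} contains non-IUPAC characters: {sorted(bad)}")


def normalize(seq: str) -> str:
    """Uppercase and convert RNA-style U to T (validates the alphabet)."""
    s = seq.upper().replace("U", "T")
    validate_sequence(s)
    return s


def reverse_complement(seq: str) -> str:
    validate_sequence(seq)
    return seq.translate(_COMP_TABLE)[::-1]


_ENCODE_TABLE = np.zeros(128, dtype=np.uint8)
for code, m in IUPAC_MASKS.items():
    _ENCODE_TABLE[ord(code)] = m
    _ENCODE_TABLE[ord(code.lower())] = m


def encode(seq: str) -> np.ndarray:
    """Encode a sequence as a uint8 array of degeneracy masks."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    if raw.max(initial=0) > 127:
        validate_sequence(seq)
    out = _ENCODE_TABLE[raw]
    if (out == 0).any():
        validate_sequence(seq)  # raises with a useful message
    return out


def complement_masks(masks: np.ndarray) -> np.ndarray:
    return _MASK_COMPLEMENT[masks]
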