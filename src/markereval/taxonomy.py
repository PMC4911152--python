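"""Fixed-rank taxonomic lineages.

A lineage is a complete path over the fixed hierarchy
kingdom > phylum > order > family > genus > species.  Every rank is
always present; a rank whose name is not known carries the ``UNKNOWN``
token, and consensus building may set a rank to ``AMBIGUOUS`` when
equally supported references disagree.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

RANKS: tuple[str, ...] = ("kingdom", "phylum", "order", "family", "genus", "species")

#: Token for a rank whose taxon name is not recorded.
UNKNOWN = "UNKNOWN"
#: Token set by consensus building when tied references disagree at a rank.
AMBIGUOUS = "AMBIGUOUS"


class LineageError(ValueError):
    """Raised for malformed lineage strings or invalid rank access."""


@dataclass(frozen=True)
class Lineage:
    """A complete six-rank taxonomic path.

    Invariants: all ranks present (``UNKNOWN`` fills gaps) and, when both
    genus and species are known, the species binomial's first token equals
    the genus name.
    """

    kingdom: str = UNKNOWN
    phylum: str = UNKNOWN
    order: str = UNKNOWN
    family: str = UNKNOWN
    genus: str = UNKNOWN
    species: str = UNKNOWN

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not isinstance(v, str) or not v:
                raise LineageError(f"rank {f.name!r} must be a non-empty string, got {v!r}")
        if self.genus not in (UNKNOWN, AMBIGUOUS) and self.species not in (UNKNOWN, AMBIGUOUS):
            first = self.species.split()[0]
            if first != self.genus:
                raise LineageError(
                    f"species {self.species!r} does not start with genus {self.genus!r}"
                )

    def at(self, rank: str) -> str:
        if rank not in RANKS:
            raise LineageError(f"unknown rank {rank!r}")
        return getattr(self, rank)

    def is_known(self, rank: str) -> bool:
        return self.at(rank) not in (UNKNOWN, AMBIGUOUS)

    def as_tuple(self) -> tuple[str, ...]:
        return tuple(getattr(self, r) for r in RANKS)

    def replace(self, **changes: str) -> "Lineage":
        vals = {r: getattr(self, r) for r in RANKS}
        vals.update(changes)
        return Lineage(**vals)

    def __str__(self) -> str:
        return format_lineage(self)


def parse_lineage(header_field: str, delimiter: str = ";") -> Lineage:
    """Parse a delimited six-field lineage string.

    Empty fields map to :data:`UNKNOWN`; surrounding whitespace is trimmed.

    Raises
    ------
    LineageError
        If the string does not contain exactly six fields.
    """
    parts = [p.strip() for p in header_field.split(delimiter)]
    if len(parts) != len(RANKS):
        raise LineageError(
            f"expected {len(RANKS)} {delimiter!r}-separated ranks, "
            f"got {len(parts)} in {header_field!r}"
        )
    return Lineage(**{r: (p if p else UNKNOWN) for r, p in zip(RANKS, parts)})


def format_lineage(lineage: Lineage, delimiter: str = ";") -> str:
    """Inverse of :func:`parse_lineage` (UNKNOWN rendered as empty field)."""
    return delimiter.join("" if v == UNKNOWN else v for v in lineage.as_tuple())


def species_key(lineage: Lineage) -> str | None:
    """Canonical species identifier: the first two tokens of the binomial.

    Collapses infraspecific names (subspecies, varieties) onto the parent
    species.  Returns ``None`` when the species rank is not known.
    """
    if not lineage.is_known("species"):
        return None
    toks = lineage.species.split()
    return " ".join(toks[:2]) if len(toks) >= 2 else toks[0]
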