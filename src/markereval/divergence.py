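"""Sequence divergence among species: p-distance matrices and barcode gaps.

Mean interspecific uncorrected p-distances are computed over all
cross-species sequence pairs after pairwise global alignment (pairwise
deletion of gap columns), and each species' nearest-neighbour distance
(NND) — its minimum interspecific distance — is extracted from the matrix.
Large NNDs indicate good species discrimination at a marker.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .alignment import DEFAULT_SCORING, global_align, p_distance
from .insilico_pcr import MockAmplicon
from .taxonomy import species_key

__all__ = [
    "group_by_species",
    "species_distance_matrix",
    "nearest_neighbour_distances",
    "restrict_to_shared_species",
    "p_distance",
    "global_align",
]


class DivergenceError(ValueError):
    pass


def group_by_species(amplicons: Iterable[MockAmplicon]) -> dict[str, list[str]]:
    """Group amplicon sequences by canonical species key (known species only)."""
    groups: dict[str, list[str]] = defaultdict(list)
    for a in amplicons:
        key = species_key(a.truth)
        if key is not None:
            groups[key].append(a.sequence)
    return dict(groups)


def species_distance_matrix(
    groups: Mapping[str, list[str]],
    scoring: tuple[int, int, int] = DEFAULT_SCORING,
) -> DistanceMatrix:
    """Mean interspecific p-distance between every pair of species.

    Entry (i, j) is the mean uncorrected p-distance over all cross-species
    sequence pairs, each pair globally aligned first.
    """
    species = sorted(groups)
    if len(species) < 2:
        raise DivergenceError("need at least 2 species for a distance matrix")
    for sp in species:
        if not groups[sp]:
            raise DivergenceError(f"species {sp!r} has no sequences")
    n = len(species)
    mat = np.zeros((n, n), dtype=float)
    for i, j in combinations(range(n), 2):
        dists = [
            p_distance(*global_align(a, b, scoring))
            for a in groups[species[i]]
            for b in groups[species[j]]
        ]
        mat[i, j] = mat[j, i] = float(np.mean(dists))
    return DistanceMatrix(mat, ids=species)


def nearest_neighbour_distances(m: DistanceMatrix) -> pd.DataFrame:
    """Per-species minimum off-diagonal distance and its nearest neighbour.

    Ties are broken by the lexicographically first neighbour.  Returns a
    DataFrame with columns ``species``, ``nnd``, ``neighbour``.
    """
    ids = list(m.ids)
    if len(ids) < 2:
        raise DivergenceError("need at least 2 species")
    data = np.asarray(m.data)
    rows = []
    for i, sp in enumerate(ids):
        off = [(data[i, j], ids[j]) for j in range(len(ids)) if j != i]
        nnd = min(d for d, _ in off)
        neighbour = min(name for d, name in off if d == nnd)
        rows.append((sp, nnd, neighbour))
    return pd.DataFrame(rows, columns=["species", "nnd", "neighbour"])


def raw_pair_nnd(groups: Mapping[str, list[str]],
                 scoring: tuple[int, int, int] = DEFAULT_SCORING) -> pd.DataFrame:
    """NND over raw sequence pairs (minimum instead of species-mean).

    Alternative mode: per species, the minimum p-distance over all of its
    sequences against every sequence of every other species.
    """
    species = sorted(groups)
    if len(species) < 2:
        raise DivergenceError("need at least 2 species")
    cache: dict[tuple[int, int], float] = {}
    for i, j in combinations(range(len(species)), 2):
        cache[(i, j)] = min(
            p_distance(*global_align(a, b, scoring))
            for a in groups[species[i]]
            for b in groups[species[j]]
        )
    rows = []
    for i, sp in enumerate(species):
        cand = [
            (cache[(min(i, j), max(i, j))], species[j])
            for j in range(len(species)) if j != i
        ]
        nnd = min(d for d, _ in cand)
        neighbour = min(name for d, name in cand if d == nnd)
        rows.append((sp, nnd, neighbour))
    return pd.DataFrame(rows, columns=["species", "nnd", "neighbour"])


def restrict_to_shared_species(per_marker_species: Mapping[str, set[str]]) -> set[str]:
    """Species present in every marker's set (intersection across markers)."""
    if not per_marker_species:
        raise DivergenceError("need at least one marker")
    sets = list(per_marker_species.values())
    shared = set(sets[0]).intersection(*sets[1:])
    if not shared:
        warnings.warn("no species shared across all markers")
    return shared


def write_distance_matrix_tsv(m: DistanceMatrix, path: str | Path) -> None:
    pd.DataFrame(np.asarray(m.data), index=list(m.ids), columns=list(m.ids)).to_csv(
        path, sep="\t", float_format="%.6f"
    )


def write_nnd_tsv(nnd: pd.DataFrame, path: str | Path) -> None:
    nnd.to_csv(path, sep="\t", index=False, float_format="%.6f")
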