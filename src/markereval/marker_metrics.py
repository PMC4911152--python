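"""Marker comparison metrics: recovery, specificity, resolution, richness,
and compositional dispersion.

The dispersion analysis follows the classic beta-dispersion recipe:
presence/absence taxon sets per marker are compared by Jaccard
dissimilarity, embedded by principal coordinates analysis (classical
scaling with negative-eigenvalue axes retained separately), and each
marker's distance to the spatial (geometric) median of its group is
measured with the squared-difference correction for non-Euclidean input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import eigh

from .reads_pipeline import StageLog


class MetricsError(ValueError):
    pass


def median_absolute_deviation(values: np.ndarray) -> float:
    """Unscaled MAD: median of absolute deviations from the median."""
    v = np.asarray(values, dtype=float)
    return float(np.median(np.abs(v - np.median(v))))


def recovery_by_stage(log: StageLog) -> pd.DataFrame:
    """Median and MAD of per-sample read counts at each pipeline stage."""
    df = log.to_frame()
    if df.empty:
        raise MetricsError("stage log is empty")
    rows = {
        stage: {
            "median": float(np.median(df[stage].dropna())),
            "mad": median_absolute_deviation(df[stage].dropna().to_numpy()),
            "n_samples": int(df[stage].notna().sum()),
        }
        for stage in df.columns
    }
    return pd.DataFrame.from_dict(rows, orient="index")


def specificity_per_sample(groups: Mapping[str, Sequence[bool]]) -> pd.Series:
    """Proportion of assigned reads per sample that are NOT the target group.

    ``groups`` maps sample id to a per-read boolean vector (True = target
    group, e.g. vascular plant).  Samples with zero assigned reads are
    excluded with a warning.
    """
    out = {}
    for sample, flags in groups.items():
        flags = list(flags)
        if not flags:
            warnings.warn(f"sample {sample!r} has no assigned reads; excluded")
            continue
        out[sample] = 1.0 - sum(flags) / len(flags)
    return pd.Series(out, dtype=float).sort_index()


def resolution_profile(assignments: pd.DataFrame) -> pd.DataFrame:
    """Proportion of order-assigned reads left unassigned at finer ranks.

    ``assignments`` needs boolean columns ``order_assigned``,
    ``family_resolved``, ``genus_resolved``, ``species_resolved`` and a
    ``sample`` column; a read counts as resolved at a rank only when it
    received an unambiguous name there (AMBIGUOUS counts as unassigned).
    Samples without order-assigned reads are excluded with a warning.
    """
    required = {"sample", "order_assigned", "family_resolved", "genus_resolved",
                "species_resolved"}
    missing = required - set(assignments.columns)
    if missing:
        raise MetricsError(f"assignments missing columns: {sorted(missing)}")
    rows = {}
    for sample, grp in assignments.groupby("sample"):
        base = grp[grp["order_assigned"]]
        n = len(base)
        if n == 0:
            warnings.warn(f"sample {sample!r} has no order-assigned reads; excluded")
            continue
        rows[sample] = {
            "n_order_assigned": n,
            "unassigned_family": 1.0 - base["family_resolved"].sum() / n,
            "unassigned_genus": 1.0 - base["genus_resolved"].sum() / n,
            "unassigned_species": 1.0 - base["species_resolved"].sum() / n,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def jaccard_dissimilarity(a: set, b: set) -> float:
    """1 − |a ∩ b| / |a ∪ b|; errors when both sets are empty."""
    union = a | b
    if not union:
        raise MetricsError("Jaccard dissimilarity undefined for two empty sets")
    return 1.0 - len(a & b) / len(union)


@dataclass(frozen=True)
class PCoAResult:
    """Classical-scaling embedding of a dissimilarity matrix.

    ``positive`` holds coordinates on axes with positive eigenvalues,
    ``negative`` the (real-valued) coordinates on negative-eigenvalue
    axes, kept separately for corrected distance computations on
    non-Euclidean input.
    """

    positive: np.ndarray  # (n, p)
    negative: np.ndarray  # (n, q)
    eigenvalues: np.ndarray  # all retained eigenvalues, descending


def pcoa_embed(d: np.ndarray, tol: float = 1e-10) -> PCoAResult:
    """Principal coordinates analysis via the double-centred Gram matrix.

    Axes with |eigenvalue| below ``tol`` (relative to the largest) are
    dropped; negative-eigenvalue axes are retained separately.
    """
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise MetricsError("dissimilarity matrix must be square")
    if not np.allclose(d, d.T, atol=1e-12):
        raise MetricsError("dissimilarity matrix must be symmetric")
    n = d.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (d ** 2) @ J
    evals, evecs = eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    scale = max(abs(evals).max(initial=0.0), 1.0)
    keep = np.abs(evals) > tol * scale
    evals, evecs = evals[keep], evecs[:, keep]
    coords = evecs * np.sqrt(np.abs(evals))
    pos = coords[:, evals > 0]
    neg = coords[:, evals < 0]
    return PCoAResult(positive=pos, negative=neg, eigenvalues=evals)


def spatial_median(
    points: np.ndarray, tol: float = 1e-9, max_iter: int = 1000
) -> np.ndarray:
    """Geometric median by iteratively re-weighted averaging (Weiszfeld).

    Minimises the summed Euclidean distance to the points; an iterate that
    coincides with a data point is checked for optimality via the
    modified-Weiszfeld condition and nudged along the descent direction
    otherwise.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] == 0:
        raise MetricsError("need at least one point")
    if pts.shape[0] == 1:
        return pts[0].copy()
    x = pts.mean(axis=0)
    for _ in range(max_iter):
        diff = pts - x
        dist = np.linalg.norm(diff, axis=1)
        at_point = dist < 1e-14
        if at_point.any():
            # modified Weiszfeld (Vardi–Zhang): treat the coincident point
            # separately and test the optimality condition
            mask = ~at_point
            if not mask.any():
                return x
            w = 1.0 / dist[mask]
            r_vec = (pts[mask] * w[:, None]).sum(axis=0) - x * w.sum()
            r = np.linalg.norm(r_vec)
            if r <= 1.0:  # coincident point is the median
                return x
            t = (pts[mask] * w[:, None]).sum(axis=0) / w.sum()
            step = max(0.0, 1.0 - 1.0 / r)
            x_new = (1.0 - step) * x + step * t
        else:
            w = 1.0 / dist
            x_new = (pts * w[:, None]).sum(axis=0) / w.sum()
        if np.linalg.norm(x_new - x) < tol:
            return x_new
        x = x_new
    return x


@dataclass(frozen=True)
class DispersionResult:
    """Per group: marker PCoA coordinates, spatial median, distances."""

    distances: pd.DataFrame  # rows: group, columns: marker
    eigenvalues: dict[str, np.ndarray]


def dispersion_distances(
    composition_sets: Mapping[str, Mapping[str, set]]
) -> DispersionResult:
    """Distance of each marker to its group's spatial median in PCoA space.

    ``composition_sets`` maps group id (sampling instance) to
    {marker: taxon set}.  Per group, the Jaccard matrix among markers is
    embedded by PCoA; one spatial median is found over all retained axes
    jointly (a separate median per axis sign would be non-unique whenever
    a subspace is one-dimensional with an even point count), and each
    marker's corrected distance is sqrt(max(0, d_pos² − d_neg²)) where the
    two parts split the squared distance to the median by eigenvalue sign.
    Groups with fewer than two markers are skipped with a warning.
    """
    rows: dict[str, dict[str, float]] = {}
    eigs: dict[str, np.ndarray] = {}
    for group, marker_sets in composition_sets.items():
        markers = sorted(marker_sets)
        if len(markers) < 2:
            warnings.warn(f"group {group!r} has fewer than 2 markers; skipped")
            continue
        n = len(markers)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = jaccard_dissimilarity(
                    marker_sets[markers[i]], marker_sets[markers[j]]
                )
        emb = pcoa_embed(d)
        eigs[group] = emb.eigenvalues
        p = emb.positive.shape[1]
        coords = np.hstack([emb.positive, emb.negative])
        med = spatial_median(coords) if coords.shape[1] else np.zeros(0)
        out = {}
        for i, m in enumerate(markers):
            diff = coords[i] - med if med.size else np.zeros(0)
            d_pos2 = float(np.sum(diff[:p] ** 2))
            d_neg2 = float(np.sum(diff[p:] ** 2))
            out[m] = float(np.sqrt(max(0.0, d_pos2 - d_neg2)))
        rows[group] = out
    return DispersionResult(distances=pd.DataFrame.from_dict(rows, orient="index").sort_index(),
                            eigenvalues=eigs)


def cumulative_richness(
    sample_sets: Mapping[str, set], pooling: Mapping[str, str]
) -> tuple[pd.Series, int]:
    """Union taxon richness within pools plus the grand total.

    ``pooling`` maps every sample id to its pool (sampling instance);
    returns (per-pool richness Series, total richness across all pools).
    """
    missing = set(sample_sets) - set(pooling)
    if missing:
        raise MetricsError(f"samples missing from pooling map: {sorted(missing)}")
    pools: dict[str, set] = {}
    for sample, taxa in sample_sets.items():
        pools.setdefault(pooling[sample], set()).update(taxa)
    per_pool = pd.Series({p: len(s) for p, s in pools.items()}, dtype=int).sort_index()
    total = len(set().union(*pools.values())) if pools else 0
    return per_pool, total
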