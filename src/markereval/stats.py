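"""Blocked significance tests for marker comparisons.

Complete-block designs throughout: the Friedman rank sum test (with post
hoc pairwise Wilcoxon signed-rank tests, Holm-adjusted) for non-parametric
comparisons blocked by species or by soil sample, and randomized-block
ANOVA with post hoc Tukey HSD for means.  Pairwise outcomes are summarised
as compact letter displays: treatments that are not significantly
different share at least one letter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, product

import numpy as np
import pandas as pd
from scipy import stats as sps


class StatsError(ValueError):
    pass


@dataclass
class BlockedData:
    """A complete blocks × treatments value matrix."""

    values: np.ndarray  # shape (n_blocks, n_treatments)
    blocks: list[str]
    treatments: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise StatsError("values must be a 2-D blocks × treatments matrix")
        b, k = self.values.shape
        if b < 2 or k < 2:
            raise StatsError("need at least 2 blocks and 2 treatments")
        if b != len(self.blocks) or k != len(self.treatments):
            raise StatsError("label lengths do not match the value matrix")
        if np.isnan(self.values).any():
            raise StatsError("complete blocks required (no missing cells)")

    @classmethod
    def from_long(
        cls,
        df: pd.DataFrame,
        block: str = "block",
        treatment: str = "treatment",
        value: str = "value",
        drop_incomplete: bool = True,
    ) -> "BlockedData":
        """Pivot a long table; incomplete blocks are dropped (or rejected)."""
        wide = df.pivot_table(index=block, columns=treatment, values=value,
                              aggfunc="mean")
        if drop_incomplete:
            wide = wide.dropna(axis=0)
        return cls(values=wide.to_numpy(),
                   blocks=[str(x) for x in wide.index],
                   treatments=[str(x) for x in wide.columns])


@dataclass
class TestResult:
    statistic: float
    p_value: float
    df: tuple | None = None
    pairwise: pd.DataFrame | None = None  # adjusted p-values
    pairwise_raw: pd.DataFrame | None = None
    letters: dict[str, str] | None = None
    extra: dict = field(default_factory=dict)


def _within_block_ranks(values: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(sps.rankdata, 1, values)


def friedman_test(d: BlockedData) -> TestResult:
    """Friedman rank sum test on a complete block design.

    Within-block midranks, chi-square approximation with the standard tie
    correction, k − 1 degrees of freedom.  With no rank variation at all
    the statistic is 0 and p = 1.
    """
    b, k = d.values.shape
    ranks = _within_block_ranks(d.values)
    col_sums = ranks.sum(axis=0)
    stat = 12.0 / (b * k * (k + 1)) * np.sum(col_sums ** 2) - 3.0 * b * (k + 1)
    # tie correction: counts of tied groups within each block
    ties = 0.0
    for row in d.values:
        _, counts = np.unique(row, return_counts=True)
        ties += float(np.sum(counts ** 3 - counts))
    correction = 1.0 - ties / (b * k * (k ** 2 - 1))
    if correction <= 0:
        return TestResult(statistic=0.0, p_value=1.0, df=(k - 1,))
    stat /= correction
    stat = max(stat, 0.0)
    return TestResult(statistic=float(stat),
                      p_value=float(sps.chi2.sf(stat, k - 1)),
                      df=(k - 1,))


def _signed_rank_w(diffs: np.ndarray) -> tuple[float, np.ndarray]:
    """W+ (sum of positive midranks) and the midranks of |d| (zeros dropped)."""
    d = diffs[diffs != 0]
    if d.size == 0:
        raise StatsError("all differences are zero")
    ranks = sps.rankdata(np.abs(d))
    return float(ranks[d > 0].sum()), ranks


def wilcoxon_signed_rank(
    paired: list[tuple[float, float]] | np.ndarray, exact_cutoff: int = 12
) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired values.

    Zero differences are dropped and midranks used for tied magnitudes.
    For n <= ``exact_cutoff`` the p-value is exact by enumeration of all
    2^n sign patterns; otherwise a normal approximation with tie-corrected
    variance and continuity correction is used.
    """
    arr = np.asarray(paired, dtype=float)
    diffs = arr[:, 0] - arr[:, 1] if arr.ndim == 2 else arr
    w_obs, ranks = _signed_rank_w(diffs)
    n = ranks.size
    if n <= exact_cutoff:
        # distribution of W+ over all 2^n sign patterns
        w_values = []
        for signs in product((0.0, 1.0), repeat=n):
            w_values.append(float(np.dot(signs, ranks)))
        w_values = np.asarray(w_values)
        p_le = float(np.mean(w_values <= w_obs + 1e-12))
        p_ge = float(np.mean(w_values >= w_obs - 1e-12))
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return TestResult(statistic=w_obs, p_value=p, extra={"n": n, "method": "exact"})
    mean = n * (n + 1) / 4.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(counts ** 3 - counts)) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var <= 0:
        raise StatsError("degenerate variance in Wilcoxon approximation")
    delta = w_obs - mean
    cc = 0.5 * np.sign(delta) if delta != 0 else 0.0
    z = (delta - cc) / np.sqrt(var)
    p = min(1.0, 2.0 * float(sps.norm.sf(abs(z))))
    return TestResult(statistic=w_obs, p_value=p, extra={"n": n, "method": "normal", "z": float(z)})


def holm_adjust(pvals: np.ndarray) -> np.ndarray:
    """Holm step-down adjustment (monotone, >= raw p-values)."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank_idx, i in enumerate(order):
        val = min(1.0, (m - rank_idx) * p[i])
        running = max(running, val)
        adj[i] = running
    return adj


def friedman_with_posthoc(d: BlockedData, alpha: float = 0.05) -> TestResult:
    """Friedman test plus Holm-adjusted pairwise Wilcoxon signed-rank tests
    and a compact letter display."""
    res = friedman_test(d)
    k = len(d.treatments)
    pairs = list(combinations(range(k), 2))
    raw = []
    for i, j in pairs:
        try:
            raw.append(wilcoxon_signed_rank(
                np.stack([d.values[:, i], d.values[:, j]], axis=1)).p_value)
        except StatsError:  # identical columns: no evidence of difference
            raw.append(1.0)
    adj = holm_adjust(np.asarray(raw))
    res.pairwise_raw = _pair_matrix(raw, pairs, d.treatments)
    res.pairwise = _pair_matrix(adj, pairs, d.treatments)
    res.letters = compact_letter_display(res.pairwise, alpha)
    return res


def _pair_matrix(pvals, pairs, labels) -> pd.DataFrame:
    k = len(labels)
    m = np.ones((k, k))
    for p, (i, j) in zip(pvals, pairs):
        m[i, j] = m[j, i] = p
    return pd.DataFrame(m, index=labels, columns=labels)


def blocked_anova_tukey(d: BlockedData, alpha: float = 0.05) -> TestResult:
    """Randomized block ANOVA (treatment + block, no interaction) with
    Tukey HSD post hoc comparisons on treatment means.

    The F statistic tests the treatment effect against the residual mean
    square with (k−1, (b−1)(k−1)) degrees of freedom; Tukey p-values use
    the studentized range with the blocked model's error df.
    """
    y = d.values
    b, k = y.shape
    df_err = (b - 1) * (k - 1)
    if df_err <= 0:
        raise StatsError("zero error degrees of freedom")
    grand = y.mean()
    treat_means = y.mean(axis=0)
    block_means = y.mean(axis=1)
    ss_treat = b * float(np.sum((treat_means - grand) ** 2))
    ss_block = k * float(np.sum((block_means - grand) ** 2))
    ss_total = float(np.sum((y - grand) ** 2))
    ss_err = ss_total - ss_treat - ss_block
    ms_treat = ss_treat / (k - 1)
    ms_err = max(ss_err / df_err, 0.0)
    if ms_err == 0.0:
        f = np.inf if ms_treat > 0 else 0.0
        p = 0.0 if ms_treat > 0 else 1.0
    else:
        f = ms_treat / ms_err
        p = float(sps.f.sf(f, k - 1, df_err))
    res = TestResult(statistic=float(f), p_value=p, df=(k - 1, df_err),
                     extra={"ss_treat": ss_treat, "ss_block": ss_block,
                            "ss_error": ss_err, "ms_error": ms_err,
                            "treatment_means": dict(zip(d.treatments, treat_means))})
    pairs = list(combinations(range(k), 2))
    pvals = []
    se = np.sqrt(ms_err / b) if ms_err > 0 else 0.0
    for i, j in pairs:
        if se == 0.0:
            pvals.append(0.0 if treat_means[i] != treat_means[j] else 1.0)
            continue
        q = abs(treat_means[i] - treat_means[j]) / se
        pvals.append(float(sps.studentized_range.sf(q, k, df_err)))
    res.pairwise_raw = _pair_matrix(pvals, pairs, d.treatments)
    res.pairwise = res.pairwise_raw  # Tukey p-values are already family-wise
    res.letters = compact_letter_display(res.pairwise, alpha)
    return res


def compact_letter_display(pairwise_p: pd.DataFrame, alpha: float = 0.05) -> dict[str, str]:
    """Letter codes from a symmetric matrix of (adjusted) pairwise p-values.

    Treatments that are not significantly different share at least one
    letter; significantly different pairs share none.  Greedy assignment
    in treatment order, letters alphabetical by group creation.
    """
    labels = list(pairwise_p.index)
    p = pairwise_p.to_numpy()
    n = len(labels)
    differ = p < alpha
    groups: list[set[int]] = []
    for t in range(n):
        placed = False
        for g in groups:
            if all(not differ[t, m] for m in g):
                g.add(t)
                placed = True
        if not placed:
            g = {t}
            for other in range(n):
                if other != t and all(not differ[other, m] for m in g):
                    g.add(other)
            groups.append(g)
    # coverage: every non-significant pair must share a group
    for i, j in combinations(range(n), 2):
        if not differ[i, j] and not any(i in g and j in g for g in groups):
            g = {i, j}
            for other in range(n):
                if other not in g and all(not differ[other, m] for m in g):
                    g.add(other)
            groups.append(g)
    letters = {t: "" for t in range(n)}
    for idx, g in enumerate(groups):
        letter = chr(ord("a") + idx) if idx < 26 else f"z{idx}"
        for t in sorted(g):
            letters[t] += letter
    return {labels[t]: letters[t] for t in range(n)}
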