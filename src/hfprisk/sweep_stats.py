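"""Per-threshold group statistics: means, intervals, effect sizes, rank tests.

For each footprint threshold t we compare the two labelled species groups
(low-risk vs high-risk, or uplisted vs not-uplisted) on the extent of range
above t and on its change between epochs. Each threshold gets group means
with 95% bands, Cohen's d and a one-sided rank-sum p-value; the effect
profile locates the threshold of largest |d|.

The rank test is the two-sample (unpaired) rank-sum form: the groups are
independent sets of species, so a paired signed-rank construction does not
apply.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .risk_transitions import HIGH_RISK, LOW_RISK

EXACT_MAX_N = 12  # exact enumeration of rank-sum null up to this pooled size

__all__ = [
    "GroupSweep",
    "group_sweep",
    "cohens_d",
    "rank_test",
    "effect_profile",
    "bootstrap_halfwidth",
]


@dataclass
class GroupSweep:
    """Per-threshold two-group summaries for extents and deltas.

    ``table`` has one row per threshold with columns
    ``t, mean_<stat>_<group>, half_<stat>_<group>, n_<group>,
    d_<stat>, p_<stat>`` for stat in {extent, delta}; d and the one-sided
    p are oriented as group_b minus group_a (default high-risk minus
    low-risk).
    """

    group_a: str
    group_b: str
    table: pd.DataFrame


def cohens_d(group_a: np.ndarray, group_b: np.ndarray) -> float:
    """Standardized mean difference (A minus B) with pooled SD.

    Returns NaN (flagged non-finite) when the pooled SD is zero.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    na, nb = a.size, b.size
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if pooled_var == 0:
        return float("nan")
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var))


def rank_test(group_a, group_b, alternative: str = "greater") -> float:
    """One-sided two-sample rank-sum p-value (A vs B).

    ``alternative='greater'`` tests whether A tends to exceed B. Exact
    enumeration of all group assignments when the pooled size is at most
    12; otherwise the normal approximation with tie correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    if np.unique(pooled).size == 1:
        raise ValueError("all values tied across both groups")
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    if a.size + b.size <= EXACT_MAX_N:
        return _exact_rank_test(a, b, alternative)
    res = stats.mannwhitneyu(a, b, alternative=alternative, method="asymptotic")
    return float(res.pvalue)


def _exact_rank_test(a: np.ndarray, b: np.ndarray, alternative: str) -> float:
    """Enumerate every split of the pooled sample into groups of these sizes."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n = pooled.size
    na = a.size
    observed = ranks[:na].sum()
    sums = np.array([ranks[list(idx)].sum() for idx in combinations(range(n), na)])
    if alternative == "greater":
        return float((sums >= observed - 1e-9).mean())
    return float((sums <= observed + 1e-9).mean())


def bootstrap_halfwidth(
    values: np.ndarray, n_boot: int = 1000, seed: int = 0
) -> float:
    """Half-width of a 95% bootstrap percentile interval for the mean."""
    rng = np.random.default_rng(seed)
    v = np.asarray(values, dtype=float)
    means = rng.choice(v, size=(n_boot, v.size), replace=True).mean(axis=1)
    lo, hi = np.percentile(means, [2.5, 97.5])
    return float((hi - lo) / 2)


def _halfwidth(v: np.ndarray) -> float:
    if v.size < 2:
        return float("nan")  # undefined for a single observation
    return float(1.96 * v.std(ddof=1) / np.sqrt(v.size))


def group_sweep(
    extent_changes: pd.DataFrame,
    labels: pd.DataFrame,
    group_a: str = LOW_RISK,
    group_b: str = HIGH_RISK,
    label_column: str = "risk_class",
    alternative: str = "greater",
) -> GroupSweep:
    """Aggregate the long extent/delta table into per-threshold group curves.

    ``extent_changes`` columns: species_id, t, extent93, extent09, delta.
    ``labels`` columns: species_id plus ``label_column``. d and p compare
    group_b against group_a (one-sided, default "group_b greater").
    """
    merged = extent_changes.merge(
        labels[["species_id", label_column]], on="species_id", how="inner"
    )
    if merged.empty:
        raise ValueError("no labelled species in the extent table")
    rows = []
    for t, sub in merged.groupby("t", sort=True):
        va = sub[sub[label_column] == group_a]
        vb = sub[sub[label_column] == group_b]
        if len(va) == 0 or len(vb) == 0:
            raise ValueError(f"a group is empty at threshold {t}")
        row: dict = {"t": int(t), f"n_{group_a}": len(va), f"n_{group_b}": len(vb)}
        stats_cols = (
            ("extent", "extent09"),
            ("extent93", "extent93"),
            ("delta", "delta"),
        )
        for stat, col in stats_cols:
            a = va[col].to_numpy()
            b = vb[col].to_numpy()
            row[f"mean_{stat}_{group_a}"] = a.mean()
            row[f"mean_{stat}_{group_b}"] = b.mean()
            row[f"half_{stat}_{group_a}"] = _halfwidth(a)
            row[f"half_{stat}_{group_b}"] = _halfwidth(b)
            # d undefined (NaN) for singleton groups, like the half-widths
            row[f"d_{stat}"] = (
                cohens_d(b, a) if min(a.size, b.size) >= 2 else float("nan")
            )
            try:
                row[f"p_{stat}"] = rank_test(b, a, alternative=alternative)
            except ValueError:
                row[f"p_{stat}"] = float("nan")
        rows.append(row)
    return GroupSweep(group_a=group_a, group_b=group_b, table=pd.DataFrame(rows))


def effect_profile(sweep: GroupSweep) -> tuple[int, int]:
    """Thresholds with the largest |Cohen's d| for extent and for delta.

    Ties break toward the lowest threshold. Raises if d is non-finite at
    every threshold.
    """
    peaks = []
    for stat in ("extent", "delta"):
        d = sweep.table[f"d_{stat}"].to_numpy(dtype=float)
        ts = sweep.table["t"].to_numpy()
        finite = np.isfinite(d)
        if not finite.any():
            raise ValueError(f"Cohen's d non-finite at every threshold for {stat}")
        absd = np.where(finite, np.abs(d), -np.inf)
        peaks.append(int(ts[int(np.argmax(absd))]))
    return peaks[0], peaks[1]
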