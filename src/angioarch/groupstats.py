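"""Per-architecture aggregation of DOA/DOC and nonparametric comparison.

Samples arrive as a tidy table with one row per (architecture,
replicate, statistic) triple.  Groups are summarized by mean and
standard error, and compared with the Kruskal-Wallis omnibus test
followed by Dunn's pairwise post-hoc z-tests on mean ranks, flagged at
the 0.05 and 0.005 cutoffs.

With very small groups (the study uses n = 3 per architecture) the
chi-square approximation to the Kruskal-Wallis statistic is badly
conservative, so for small total samples the omnibus p-value is taken
from the exact permutation distribution of H.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupSummary",
    "KruskalDunnResult",
    "summarize_groups",
    "kruskal_dunn",
]

#: Use the exact permutation null when the partition count is below this.
_EXACT_LIMIT = 50_000


@dataclass(frozen=True)
class GroupSummary:
    """Per-architecture mean and SEM for one statistic."""

    table: pd.DataFrame  # columns: architecture, statistic, n, mean, sem


@dataclass(frozen=True)
class KruskalDunnResult:
    statistic: float  # tie-corrected Kruskal-Wallis H
    p_omnibus: float
    method: str  # "exact" or "chi-square"
    pairwise: pd.DataFrame  # group_a, group_b, z, p, p_adj, sig_05, sig_005
    n_excluded: int  # non-finite values dropped before testing


def summarize_groups(table: pd.DataFrame) -> GroupSummary:
    """Mean and SEM (sd/sqrt(n)) per architecture per statistic.

    Non-finite (sentinel) values are excluded.  A single-value group
    reports its value as the mean and an undefined (NaN) SEM.
    """
    t = _validate_table(table)
    t = t[np.isfinite(t["value"])]
    rows = []
    for (arch, stat), grp in t.groupby(["architecture", "statistic"], sort=True):
        v = grp["value"].to_numpy(dtype=float)
        sem = float(np.std(v, ddof=1) / math.sqrt(len(v))) if len(v) > 1 else float("nan")
        rows.append(
            {"architecture": arch, "statistic": stat, "n": len(v),
             "mean": float(v.mean()), "sem": sem}
        )
    return GroupSummary(pd.DataFrame(rows))


def kruskal_dunn(
    table: pd.DataFrame,
    statistic: str | None = None,
    alpha: float = 0.05,
    adjust: str | None = None,
) -> KruskalDunnResult:
    """Kruskal-Wallis omnibus test plus Dunn's pairwise post-hoc tests.

    Parameters
    ----------
    table : tidy table (architecture, replicate, statistic, value).
    statistic : restrict to one statistic name (required if the table
        carries several).
    adjust : ``None`` for raw Dunn p-values (the study reports raw
        cutoffs) or ``"holm"`` for step-down Holm adjustment.

    Identical values across all groups give a zero statistic and
    p = 1 by convention.
    """
    t = _validate_table(table)
    if statistic is not None:
        t = t[t["statistic"] == statistic]
    elif t["statistic"].nunique() > 1:
        raise ValueError("table holds several statistics; pass statistic=...")
    finite = np.isfinite(t["value"])
    n_excluded = int((~finite).sum())
    if n_excluded:
        warnings.warn(
            f"excluding {n_excluded} non-finite sentinel value(s) from testing",
            stacklevel=2,
        )
    t = t[finite]
    names = sorted(t["architecture"].unique())
    groups = [t.loc[t["architecture"] == g, "value"].to_numpy(float) for g in names]
    if len(groups) < 3:
        raise ValueError("omnibus test needs at least 3 groups")

    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        pairwise = _dunn(groups, names, adjust, degenerate=True)
        return KruskalDunnResult(0.0, 1.0, "degenerate", pairwise, n_excluded)

    H = _kruskal_h(groups)
    sizes = tuple(len(g) for g in groups)
    n_part = _n_partitions(sizes)
    if n_part <= _EXACT_LIMIT:
        p = _exact_kruskal_p(groups, H)
        method = "exact"
    else:
        p = float(stats.chi2.sf(H, len(groups) - 1))
        method = "chi-square"
    pairwise = _dunn(groups, names, adjust)
    return KruskalDunnResult(float(H), p, method, pairwise, n_excluded)


def _validate_table(table: pd.DataFrame) -> pd.DataFrame:
    required = {"architecture", "statistic", "value"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"table is missing columns: {sorted(missing)}")
    return table


def _kruskal_h(groups: list[np.ndarray]) -> float:
    """Tie-corrected Kruskal-Wallis H."""
    pooled = np.concatenate(groups)
    ranks = stats.rankdata(pooled)
    N = len(pooled)
    start = 0
    ssum = 0.0
    for g in groups:
        r = ranks[start : start + len(g)]
        start += len(g)
        ssum += r.sum() ** 2 / len(g)
    H = 12.0 / (N * (N + 1)) * ssum - 3.0 * (N + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - np.sum(counts**3 - counts) / (N**3 - N)
    return H / tie if tie > 0 else 0.0


def _n_partitions(sizes: tuple[int, ...]) -> float:
    n = sum(sizes)
    out = math.factorial(n)
    for s in sizes:
        out //= math.factorial(s)
    return out


@lru_cache(maxsize=8)
def _partition_labels(sizes: tuple[int, ...]) -> np.ndarray:
    """All assignments of positions 0..N-1 to groups, as label arrays."""
    n = sum(sizes)
    labels = []

    def rec(remaining: frozenset, gi: int, current: np.ndarray) -> None:
        if gi == len(sizes):
            labels.append(current.copy())
            return
        for combo in itertools.combinations(sorted(remaining), sizes[gi]):
            current[list(combo)] = gi
            rec(remaining - set(combo), gi + 1, current)

    rec(frozenset(range(n)), 0, np.zeros(n, dtype=np.int8))
    return np.array(labels)


def _exact_kruskal_p(groups: list[np.ndarray], H_obs: float) -> float:
    """Exact permutation p-value of H over all group assignments."""
    sizes = tuple(len(g) for g in groups)
    pooled = np.concatenate(groups)
    ranks = stats.rankdata(pooled)
    N = len(pooled)
    labels = _partition_labels(sizes)  # (n_part, N)
    ssum = np.zeros(len(labels))
    for gi, s in enumerate(sizes):
        sel = labels == gi
        ssum += (ranks[None, :] * sel).sum(axis=1) ** 2 / s
    H_all = 12.0 / (N * (N + 1)) * ssum - 3.0 * (N + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - np.sum(counts**3 - counts) / (N**3 - N)
    if tie > 0:
        H_all = H_all / tie
    return float(np.mean(H_all >= H_obs - 1e-9))


def _dunn(
    groups: list[np.ndarray],
    names: list[str],
    adjust: str | None,
    degenerate: bool = False,
) -> pd.DataFrame:
    """Dunn's pairwise z-tests on mean ranks with tie correction."""
    pooled = np.concatenate(groups)
    ranks = stats.rankdata(pooled)
    N = len(pooled)
    mean_ranks = []
    start = 0
    for g in groups:
        mean_ranks.append(ranks[start : start + len(g)].mean())
        start += len(g)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (12.0 * (N - 1))
    var_base = N * (N + 1) / 12.0 - tie_term
    rows = []
    for i, j in itertools.combinations(range(len(groups)), 2):
        if degenerate or var_base <= 0:
            z, p = 0.0, 1.0
        else:
            se = math.sqrt(var_base * (1.0 / len(groups[i]) + 1.0 / len(groups[j])))
            z = abs(mean_ranks[i] - mean_ranks[j]) / se
            p = float(2.0 * stats.norm.sf(z))
        rows.append({"group_a": names[i], "group_b": names[j], "z": z, "p": p})
    df = pd.DataFrame(rows)
    if adjust is None:
        df["p_adj"] = df["p"]
    elif adjust == "holm":
        df["p_adj"] = _holm(df["p"].to_numpy())
    else:
        raise ValueError("adjust must be None or 'holm'")
    df["sig_05"] = df["p_adj"] < 0.05
    df["sig_005"] = df["p_adj"] < 0.005
    return df


def _holm(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj
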