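"""Population-level statistics over classified trajectories.

Aggregates per-trajectory apparent diffusion coefficients (whole-trajectory
D1-4) and motion-mode categories into the standard single-molecule-tracking
population outputs: mode fractions (Brownian / confined / mixed, with
directed and unclassified reported separately), median apparent D overall
and per category, across-experiment dispersion, long-format distribution
exports for violin plots, and two-sample Mann-Whitney U comparisons.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

REPORTED_CATEGORIES = ("brownian", "confined", "mixed")


@dataclass
class PopulationSummary:
    """Mode fractions and median apparent diffusion coefficients."""

    n_trajectories: int
    median_D_all: float
    median_D_by_mode: dict[str, float]
    fraction_by_mode: dict[str, float]          # over the three reported categories
    fraction_other: dict[str, float] = field(default_factory=dict)  # directed/unclassified
    fraction_sd: dict[str, float] = field(default_factory=dict)     # across experiments


def summarize(table: pd.DataFrame, group_by: str | None = None) -> PopulationSummary:
    """Summarize a per-trajectory results table.

    ``table`` needs columns ``D`` (whole-trajectory apparent D1-4, um^2/s)
    and ``category``; optionally a ``group_by`` column naming the independent
    experiment each trajectory came from, in which case mode-fraction SDs
    are computed across experiments (the error bars of fraction histograms).
    Fractions are reported over {brownian, confined, mixed}; directed and
    unclassified trajectories are counted separately.
    """
    if len(table) == 0:
        raise ValueError("empty trajectory table")
    if group_by is not None:
        for name, grp in table.groupby(group_by):
            if len(grp) == 0:
                raise ValueError(f"empty experiment group {name!r}")
    D = table["D"].to_numpy(dtype=float)
    cats = table["category"].astype(str)
    n = len(table)
    in_report = cats.isin(REPORTED_CATEGORIES)
    n_report = int(in_report.sum())
    fraction_by_mode = {
        c: float((cats == c).sum()) / n_report if n_report else math.nan
        for c in REPORTED_CATEGORIES
    }
    other = {c: float((cats == c).sum()) / n
             for c in sorted(set(cats) - set(REPORTED_CATEGORIES))}
    median_by = {c: float(np.median(D[(cats == c).to_numpy()]))
                 for c in sorted(set(cats)) if (cats == c).any()}
    fraction_sd: dict[str, float] = {}
    if group_by is not None and table[group_by].nunique() > 1:
        per_exp = []
        for _, grp in table.groupby(group_by):
            gc = grp["category"].astype(str)
            m = int(gc.isin(REPORTED_CATEGORIES).sum())
            per_exp.append({c: (gc == c).sum() / m if m else math.nan
                            for c in REPORTED_CATEGORIES})
        for c in REPORTED_CATEGORIES:
            fraction_sd[c] = float(np.std([e[c] for e in per_exp], ddof=1))
    return PopulationSummary(
        n_trajectories=n,
        median_D_all=float(np.median(D)),
        median_D_by_mode=median_by,
        fraction_by_mode=fraction_by_mode,
        fraction_other=other,
        fraction_sd=fraction_sd,
    )


def mann_whitney(group_a, group_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test (rank-sum with average ranks).

    Returns ``(U_a, p)`` where ``U_a`` is the U statistic of the first
    group. The null distribution is obtained by exact enumeration of rank
    assignments when the smaller group has at most 8 observations and the
    total arrangement count is modest; otherwise the normal approximation
    with tie correction is used. If every value is tied across both groups
    the test is undefined and p = 1 is returned with a warning.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    n_a, n_b = len(a), len(b)
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values tied across both groups; p set to 1")
        return n_a * n_b / 2.0, 1.0
    ranks = rankdata(pooled)
    r_a = float(ranks[:n_a].sum())
    u_a = r_a - n_a * (n_a + 1) / 2.0

    n_small = min(n_a, n_b)
    if n_small <= 8 and math.comb(n_a + n_b, n_small) <= 200_000:
        # exact permutation null: U for every way of assigning n_a ranks
        base = n_a * (n_a + 1) / 2.0
        us = np.array([sum(c) - base for c in combinations(ranks, n_a)])
        p_low = float(np.mean(us <= u_a + 1e-9))
        p_high = float(np.mean(us >= u_a - 1e-9))
        p = min(1.0, 2.0 * min(p_low, p_high))
        return u_a, p
    # normal approximation with tie correction
    mu = n_a * n_b / 2.0
    nt = n_a + n_b
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (nt * (nt - 1))
    sigma2 = n_a * n_b / 12.0 * (nt + 1 - tie_term)
    if sigma2 <= 0:
        warnings.warn("degenerate variance in Mann-Whitney; p set to 1")
        return u_a, 1.0
    from scipy.stats import norm

    z = (u_a - mu - 0.5 * np.sign(u_a - mu)) / math.sqrt(sigma2)  # continuity corr.
    p = min(1.0, 2.0 * float(norm.sf(abs(z))))
    return u_a, p


def export_distribution(values_by_group: dict[str, np.ndarray], target: int = 1000,
                        seed: int = 0) -> pd.DataFrame:
    """Long-format (group, value) table for violin plots.

    When a group holds more than ``target`` values, a seeded subsample of
    exactly ``target`` is exported (the convention used for 1000-trajectory
    violins); smaller groups are exported whole. Group medians are annotated
    in a ``group_median`` column.
    """
    rng = np.random.default_rng(seed)
    frames = []
    for group, values in values_by_group.items():
        v = np.asarray(values, dtype=float)
        if len(v) > target:
            v = v[rng.choice(len(v), size=target, replace=False)]
        frames.append(pd.DataFrame({
            "group": group, "value": v, "group_median": float(np.median(v)),
        }))
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["group", "value", "group_median"])
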