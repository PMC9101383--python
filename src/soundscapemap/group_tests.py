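"""Nonparametric between-cluster tests on index descriptors.

Because per-site descriptor samples are small and often non-normal
(checked with the Shapiro-Wilk test), between-cluster differences are
assessed with rank tests: the two-sided Wilcoxon-Mann-Whitney test for
two clusters and the Kruskal-Wallis test for three or more, both at
alpha = 0.05.  p-values are reported per index without multiple-testing
correction (a Holm adjustment is available but off by default), matching
the raw per-index reporting convention of soundscape surveys.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cluster import ClusterSolution
from .descriptors import FeatureMatrix

__all__ = ["TestResult", "shapiro_wilk", "wilcoxon_mann_whitney",
           "kruskal_wallis", "compare_clusters"]

ALPHA = 0.05


class DegenerateDataError(ValueError):
    """Input with zero variance where a test requires spread."""


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str                      # shapiro_wilk | wmw | kruskal_wallis
    n_per_group: tuple[int, ...]
    alpha: float = ALPHA

    @property
    def decision(self) -> str:
        return "rejected" if self.p_value < self.alpha else "failed_to_reject"


def shapiro_wilk(x) -> TestResult:
    """Shapiro-Wilk normality test (Royston approximation via scipy)."""
    x = np.asarray(x, dtype=float)
    if not 3 <= x.size <= 5000:
        raise ValueError(f"Shapiro-Wilk requires 3 <= n <= 5000, got {x.size}")
    if np.ptp(x) == 0:
        raise DegenerateDataError("constant sample: normality test undefined")
    w, p = stats.shapiro(x)
    return TestResult(float(w), float(p), "shapiro_wilk", (x.size,))


def wilcoxon_mann_whitney(x, y, mode: str = "auto") -> TestResult:
    """Two-sided rank-sum test for two independent samples.

    ``auto`` uses the exact null distribution (full enumeration of rank
    assignments) when n_x + n_y <= 20 and there are no ties, else the
    normal approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
    if mode == "auto":
        mode = "exact" if (x.size + y.size <= 20 and not has_ties) else "normal_approx"
    if mode == "exact":
        if has_ties:
            raise ValueError("exact WMW p-value is undefined with ties")
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    elif mode == "normal_approx":
        res = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic", use_continuity=True)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return TestResult(float(res.statistic), float(min(res.pvalue, 1.0)),
                      "wmw", (x.size, y.size))


def kruskal_wallis(groups) -> TestResult:
    """Kruskal-Wallis H test with tie correction; chi-square p, df = g - 1."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis needs at least 2 groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("all groups must be non-empty")
    if sum(g.size for g in groups) < 3:
        raise ValueError("need at least 3 observations in total")
    all_vals = np.concatenate(groups)
    if np.ptp(all_vals) == 0:
        # all observations tied: H = 0 by the tie-corrected convention
        return TestResult(0.0, 1.0, "kruskal_wallis",
                          tuple(g.size for g in groups))
    h, p = stats.kruskal(*groups)
    return TestResult(float(h), float(p), "kruskal_wallis",
                      tuple(g.size for g in groups))


def compare_clusters(
    fm: FeatureMatrix,
    solution: ClusterSolution,
    descriptor: str = "mean",
    holm: bool = False,
) -> pd.DataFrame:
    """Per-index between-cluster test of one descriptor's site values.

    Dispatches to WMW for two clusters and Kruskal-Wallis otherwise.
    Returns a report with columns index, method, statistic, p_value,
    outcome — one row per index.  Indices whose values are identical in
    every site are flagged and skipped.
    """
    labels = pd.Series(solution.labels, index=solution.site_ids)
    labels = labels.reindex(fm.site_ids)
    if labels.isna().any():
        raise ValueError("cluster solution does not cover all sites")
    ks = sorted(labels.unique())
    if len(ks) < 2:
        raise ValueError("need at least 2 clusters to compare")
    cols = [c for c in fm.data.columns if c.endswith(f"_{descriptor}")]
    if not cols:
        raise ValueError(f"descriptor {descriptor!r} not present in matrix")
    rows = []
    for col in cols:
        index_name = col.rsplit("_", 1)[0]
        groups = [fm.data.loc[labels == k, col].to_numpy() for k in ks]
        if np.ptp(np.concatenate(groups)) == 0:
            rows.append({"index": index_name, "method": "skipped",
                         "statistic": np.nan, "p_value": np.nan,
                         "outcome": "degenerate"})
            continue
        if len(ks) == 2:
            res = wilcoxon_mann_whitney(groups[0], groups[1])
        else:
            res = kruskal_wallis(groups)
        rows.append({"index": index_name, "method": res.method,
                     "statistic": res.statistic, "p_value": res.p_value,
                     "outcome": res.decision})
    report = pd.DataFrame(rows)
    if holm:
        mask = report["p_value"].notna()
        p = report.loc[mask, "p_value"].to_numpy()
        order = np.argsort(p)
        m = p.size
        adj = np.empty(m)
        running = 0.0
        for rank, i in enumerate(order):
            running = max(running, (m - rank) * p[i])
            adj[i] = min(running, 1.0)
        report.loc[mask, "p_value_holm"] = adj
        report.loc[mask, "outcome"] = np.where(adj < ALPHA, "rejected",
                                               "failed_to_reject")
    return report
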