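"""Inter-method agreement statistics for airway measurements.

Reliability between measurement methods (e.g. manual tracing, automatic
thresholding, AI segmentation) is quantified with the intraclass
correlation coefficient from a two-way mixed-effects model — ICC(3,1),
single-rater consistency::

    ICC(3,1) = (MS_subjects - MS_error) / (MS_subjects + (k - 1) MS_error)

with the conventional reliability bands: > 0.75 good, > 0.90 excellent.
Location differences are tested nonparametrically: Mann-Whitney U between
two methods, Kruskal-Wallis H among three or more, both with midrank tie
handling.  The U statistic is reported in the min-U convention; its p-value
is exact (full enumeration) when both samples have at most 8 observations,
and a tie-corrected normal approximation otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

EXACT_MAX_N = 8


@dataclass
class MeasurementTable:
    """An ``n_subjects x k_methods`` matrix of one metric."""

    subjects: list
    methods: list
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n, k = self.values.shape
        if n != len(self.subjects) or k != len(self.methods):
            raise ValueError("values shape does not match subjects x methods")
        if n < 2 or k < 2:
            raise ValueError("need at least 2 subjects and 2 methods")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("missing or non-finite cells are not allowed")

    @classmethod
    def from_long(cls, df: pd.DataFrame, subject="subject", method="method",
                  value="value") -> "MeasurementTable":
        wide = df.pivot(index=subject, columns=method, values=value)
        if wide.isna().any().any():
            raise ValueError("incomplete subject x method table")
        return cls(list(wide.index), list(wide.columns), wide.to_numpy())

    def to_long(self) -> pd.DataFrame:
        rows = [
            {"subject": s, "method": m, "value": self.values[i, j]}
            for i, s in enumerate(self.subjects)
            for j, m in enumerate(self.methods)
        ]
        return pd.DataFrame(rows)

    def column(self, method) -> np.ndarray:
        return self.values[:, self.methods.index(method)]

    def pair(self, m1, m2) -> "MeasurementTable":
        j1, j2 = self.methods.index(m1), self.methods.index(m2)
        return MeasurementTable(self.subjects, [m1, m2],
                                self.values[:, [j1, j2]])


# ---------------------------------------------------------------------------
# ICC
# ---------------------------------------------------------------------------

def icc_two_way_mixed(t: MeasurementTable) -> float:
    """ICC(3,1): single-rater consistency from the two-way ANOVA mean squares."""
    x = t.values
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    denom = ms_rows + (k - 1) * ms_err
    if denom <= 0:
        raise ZeroDivisionError("zero total variance: ICC undefined")
    return float((ms_rows - ms_err) / denom)


def classify_reliability(icc: float) -> str:
    """Reliability band: > 0.90 excellent, > 0.75 good, else below_good."""
    if not np.isfinite(icc):
        raise ValueError("ICC must be finite")
    if icc > 0.90:
        return "excellent"
    if icc > 0.75:
        return "good"
    return "below_good"


# ---------------------------------------------------------------------------
# Rank tests
# ---------------------------------------------------------------------------

def _tie_term(pooled: np.ndarray) -> float:
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Mann-Whitney U test (two-sided), min-U convention, midrank ties.

    Exact p by full enumeration of group assignments when both samples have
    at most 8 observations; otherwise a tie-corrected normal approximation
    (no continuity correction, so that for two groups the Kruskal-Wallis
    chi-square p coincides: H = z^2).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = len(x), len(y)
    if n == 0 or m == 0:
        raise ValueError("empty sample")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    r_x = ranks[:n].sum()
    u_x = r_x - n * (n + 1) / 2.0
    u_y = n * m - u_x
    u = min(u_x, u_y)

    if n <= EXACT_MAX_N and m <= EXACT_MAX_N:
        p = _exact_min_u_p(pooled, n, u)
    else:
        big_n = n + m
        tie = _tie_term(pooled)
        var = n * m / 12.0 * ((big_n + 1) - tie / (big_n * (big_n - 1)))
        if var <= 0:
            return float(u), 1.0
        z = (u_x - n * m / 2.0) / np.sqrt(var)
        p = 2.0 * stats.norm.sf(abs(z))
    return float(u), float(min(p, 1.0))


def _exact_min_u_p(pooled: np.ndarray, n: int, u_obs: float) -> float:
    """P(min(U_x, U_y) <= observed) over all equally likely group splits."""
    big_n = len(pooled)
    ranks = stats.rankdata(pooled)
    m = big_n - n
    total = comb(big_n, n)
    count = 0
    for idx in combinations(range(big_n), n):
        r = ranks[list(idx)].sum()
        ux = r - n * (n + 1) / 2.0
        if min(ux, n * m - ux) <= u_obs + 1e-9:
            count += 1
    return count / total


def kruskal_wallis(groups) -> tuple[float, float]:
    """Kruskal-Wallis H with midrank tie correction; chi-square p, g-1 df."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty group")
    pooled = np.concatenate(groups)
    big_n = len(pooled)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    ranks = stats.rankdata(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + len(g)].sum()
        h += r * r / len(g)
        start += len(g)
    h = 12.0 / (big_n * (big_n + 1)) * h - 3.0 * (big_n + 1)
    correction = 1.0 - _tie_term(pooled) / (big_n**3 - big_n)
    h /= correction
    p = float(stats.chi2.sf(h, len(groups) - 1))
    return float(h), p


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------

def compare_methods(tables: dict, alpha: float = 0.05) -> dict:
    """Full agreement report over one table per metric.

    For every metric: per-method summary statistics, the location test
    (Mann-Whitney U for 2 methods, Kruskal-Wallis for 3 or more, plus all
    pairwise U tests), ICC(3,1) overall and per method pair, and
    significance flags at ``alpha``.
    """
    report = {}
    for metric, t in tables.items():
        summary = pd.DataFrame({
            "method": t.methods,
            "mean": t.values.mean(axis=0),
            "median": np.median(t.values, axis=0),
            "min": t.values.min(axis=0),
            "max": t.values.max(axis=0),
            "sd": t.values.std(axis=0, ddof=1),
        })
        entry = {"summary": summary, "icc_form": "ICC(3,1) consistency"}

        pairwise = []
        for m1, m2 in combinations(t.methods, 2):
            u, p = mann_whitney_u(t.column(m1), t.column(m2))
            icc_pair = icc_two_way_mixed(t.pair(m1, m2))
            pairwise.append({
                "method_a": m1, "method_b": m2, "U": u, "p": p,
                "significant": p < alpha, "icc": icc_pair,
                "reliability": classify_reliability(icc_pair),
            })
        entry["pairwise"] = pd.DataFrame(pairwise)

        if len(t.methods) >= 3:
            h, p = kruskal_wallis([t.column(m) for m in t.methods])
            entry["kruskal_wallis"] = {"H": h, "p": p, "significant": p < alpha}

        icc_all = icc_two_way_mixed(t)
        entry["icc"] = icc_all
        entry["reliability"] = classify_reliability(icc_all)
        report[metric] = entry
    return report


def report_to_text(report: dict, alpha: float = 0.05) -> str:
    """Human-readable rendering of a :func:`compare_methods` report."""
    lines = []
    for metric, entry in report.items():
        lines.append(f"=== {metric} ===")
        lines.append(entry["summary"].to_string(index=False))
        lines.append(f"ICC ({entry['icc_form']}): {entry['icc']:.3f} "
                     f"[{entry['reliability']}]")
        if "kruskal_wallis" in entry:
            kw = entry["kruskal_wallis"]
            lines.append(f"Kruskal-Wallis H = {kw['H']:.3f}, p = {kw['p']:.4f}"
                         f"{' *' if kw['significant'] else ''}")
        lines.append(entry["pairwise"].to_string(index=False))
        lines.append("")
    return "\n".join(lines)
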