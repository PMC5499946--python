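"""Distribution construction, pairwise testing and robustness analysis.

Degree distributions (discrete) are compared with a chi-squared test of
homogeneity on pooled per-group counts; betweenness distributions
(continuous) with the two-sample Kolmogorov-Smirnov test on pooled raw
values.  Significance is controlled with a Bonferroni correction sized to
the full set of pairwise comparisons (3200 in the reference analysis, i.e.
alpha = 0.05 -> 1.5625e-5).  Robustness across biological replicates is
summarised by the coefficient of variation of log10 betweenness, compared
across groups with one-way ANOVA plus Tukey's HSD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupedSample",
    "ComparisonResult",
    "CVResult",
    "binned_distribution",
    "compare_degree",
    "compare_bc",
    "bonferroni_threshold",
    "cv_analysis",
]


@dataclass
class GroupedSample:
    """Per-cell values for one group (genotype x cell type), split by
    biological replicate.  Replicate sizes may differ."""

    label: str
    replicates: list[np.ndarray]

    def __post_init__(self) -> None:
        if not self.replicates:
            raise ValueError(f"group {self.label!r} needs >= 1 replicate")
        self.replicates = [np.asarray(r, dtype=float) for r in self.replicates]

    @property
    def pooled(self) -> np.ndarray:
        return np.concatenate(self.replicates)


@dataclass
class ComparisonResult:
    group_a: str
    group_b: str
    test: str
    statistic: float
    p_value: float
    alpha: float | None = None

    @property
    def significant(self) -> bool | None:
        if self.alpha is None:
            return None
        return self.p_value <= self.alpha


@dataclass
class CVResult:
    label: str
    replicate_cvs: np.ndarray
    mean_cv: float
    sd_cv: float
    distinct: bool = False


def binned_distribution(sample: GroupedSample, bins) -> pd.DataFrame:
    """Mean +- sd of per-replicate normalized bin frequencies.

    Each replicate is binned and normalized to frequencies summing to 1;
    the mean and sample sd across replicates are reported per bin.
    """
    bins = np.asarray(bins, dtype=float)
    if bins.ndim != 1 or len(bins) < 2 or (np.diff(bins) <= 0).any():
        raise ValueError("bins must be a monotone 1D edge array")
    freqs = []
    for i, rep in enumerate(sample.replicates):
        if rep.size == 0:
            raise ValueError(f"group {sample.label!r} replicate {i} is empty")
        counts, _ = np.histogram(rep, bins=bins)
        total = counts.sum()
        if total == 0:
            raise ValueError(
                f"group {sample.label!r} replicate {i} has no values in bins"
            )
        freqs.append(counts / total)
    freqs = np.array(freqs)
    ddof = 1 if len(freqs) > 1 else 0
    return pd.DataFrame(
        {
            "bin_left": bins[:-1],
            "bin_right": bins[1:],
            "mean_freq": freqs.mean(axis=0),
            "sd_freq": freqs.std(axis=0, ddof=ddof) if ddof else np.zeros(len(bins) - 1),
        }
    )


def _degree_contingency(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """2 x K table of pooled degree counts over the union of observed
    degree values, with expected-count-below-5 categories merged into their
    nearest neighbor for test validity."""
    cats = np.union1d(np.unique(a), np.unique(b))
    table = np.array(
        [[(a == c).sum() for c in cats], [(b == c).sum() for c in cats]],
        dtype=float,
    )
    # iteratively merge the category with the smallest expected count
    while table.shape[1] > 2:
        col_tot = table.sum(axis=0)
        row_tot = table.sum(axis=1)
        expected = np.outer(row_tot, col_tot) / table.sum()
        worst = int(expected.min(axis=0).argmin())
        if expected[:, worst].min() >= 5:
            break
        neighbor = worst - 1 if worst > 0 else worst + 1
        table[:, neighbor] += table[:, worst]
        table = np.delete(table, worst, axis=1)
    if table.shape[1] < 2:
        raise ValueError("fewer than 2 degree categories after pooling")
    if (table.sum(axis=0) == 0).any():
        raise ValueError("empty degree category could not be resolved")
    return table


def compare_degree(
    a: GroupedSample, b: GroupedSample, alpha: float | None = None
) -> ComparisonResult:
    """Chi-squared test of homogeneity between two pooled degree
    distributions."""
    xa, xb = a.pooled, b.pooled
    if np.unique(np.concatenate([xa, xb])).size < 2:
        raise ValueError("need >= 2 distinct degree values across the groups")
    table = _degree_contingency(xa, xb)
    if np.array_equal(table[0] / table[0].sum(), table[1] / table[1].sum()):
        stat, p = 0.0, 1.0
    else:
        stat, p, _, _ = sps.chi2_contingency(table, correction=False)
    return ComparisonResult(a.label, b.label, "chi_squared", float(stat), float(p), alpha)


def compare_bc(
    a: GroupedSample, b: GroupedSample, alpha: float | None = None
) -> ComparisonResult:
    """Two-sample Kolmogorov-Smirnov test on pooled raw betweenness values
    (asymptotic p-value)."""
    xa, xb = a.pooled, b.pooled
    if xa.size < 2 or xb.size < 2:
        raise ValueError("need >= 2 values per pooled group")
    res = sps.ks_2samp(xa, xb, method="asymp")
    return ComparisonResult(
        a.label, b.label, "ks_2samp", float(res.statistic), float(res.pvalue), alpha
    )


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Corrected per-comparison significance level alpha / m."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def replicate_cv(values: np.ndarray) -> float:
    """Coefficient of variation sd/mean (sample sd, n-1) of one replicate's
    log10 betweenness values."""
    values = np.asarray(values, dtype=float)
    mean = values.mean()
    if mean == 0:
        raise ZeroDivisionError("mean of log10 BC is 0; CV undefined")
    return float(values.std(ddof=1) / mean)


def cv_analysis(
    groups: list[GroupedSample], alpha: float = 0.01
) -> tuple[list[CVResult], float, pd.DataFrame]:
    """Robustness analysis of betweenness across replicates.

    Each group's replicates hold raw BC values of one cell type; they are
    log10-transformed (zeros dropped), summarised as per-replicate CVs, and
    compared across groups with one-way ANOVA plus Tukey's HSD.  A group is
    flagged ``distinct`` when it differs from every other group at the
    stated level.  Returns (per-group CV results, ANOVA p, Tukey table).
    """
    from .topology import log10_transform

    if len(groups) < 2 or any(len(g.replicates) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 replicates each")
    results = []
    for g in groups:
        cvs = []
        for i, rep in enumerate(g.replicates):
            logged, _ = log10_transform(rep)
            try:
                cvs.append(replicate_cv(logged))
            except ZeroDivisionError:
                warnings.warn(
                    f"group {g.label!r} replicate {i}: mean log10 BC is 0; "
                    "CV excluded",
                    stacklevel=2,
                )
        cvs = np.asarray(cvs)
        results.append(
            CVResult(g.label, cvs, float(cvs.mean()), float(cvs.std(ddof=1)))
        )

    all_cvs = [r.replicate_cvs for r in results]
    flat = np.concatenate(all_cvs)
    degenerate = np.ptp(flat) == 0  # no variation anywhere: trivially null
    anova_p = 1.0 if degenerate else float(sps.f_oneway(*all_cvs).pvalue)

    tukey = None if degenerate else sps.tukey_hsd(*all_cvs)
    rows = []
    k = len(results)
    for i in range(k):
        for j in range(i + 1, k):
            stat = 0.0 if degenerate else float(tukey.statistic[i, j])
            p = 1.0 if degenerate else float(tukey.pvalue[i, j])
            rows.append(
                {
                    "group_a": results[i].label,
                    "group_b": results[j].label,
                    "statistic": stat,
                    "p_value": p,
                    "significant": p <= alpha,
                }
            )
    tukey_df = pd.DataFrame(rows)
    for i, r in enumerate(results):
        others = tukey_df[
            (tukey_df["group_a"] == r.label) | (tukey_df["group_b"] == r.label)
        ]
        r.distinct = bool(len(others)) and bool(others["significant"].all())
    return results, anova_p, tukey_df
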