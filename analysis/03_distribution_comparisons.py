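"""Epidermal distribution comparisons and robustness analysis.

For each condition, pools the three replicates per epidermal cell type,
compares trichoblast vs atrichoblast degree (chi-squared) and betweenness
(Kolmogorov-Smirnov) at the Bonferroni-corrected level alpha = 0.05/3200,
and runs the coefficient-of-variation robustness analysis of log10 BC
across conditions.  Writes comparisons.csv and cv_analysis.csv.
"""

from pathlib import Path

import pandas as pd

from organtopo import stats, topology

ROOT = Path(__file__).resolve().parent.parent / "results"
measures = pd.read_csv(ROOT / "measures.csv")
reported = topology.report_central(measures)
reported["condition"] = reported["organ"].str.rsplit("_rep", n=1).str[0]
corrected = stats.bonferroni_threshold(0.05, 3200)


def grouped(condition, cell_type, column):
    sub = reported[
        (reported.condition == condition) & (reported.cell_type == cell_type)
    ]
    reps = [g[column].to_numpy() for _, g in sub.groupby("organ")]
    return stats.GroupedSample(f"{condition}:{cell_type}", reps)


rows = []
for condition in sorted(reported["condition"].unique()):
    tri_deg = grouped(condition, "trichoblast", "degree")
    atr_deg = grouped(condition, "atrichoblast", "degree")
    tri_bc = grouped(condition, "trichoblast", "bc")
    atr_bc = grouped(condition, "atrichoblast", "bc")
    for result in (
        stats.compare_degree(tri_deg, atr_deg, alpha=corrected),
        stats.compare_bc(tri_bc, atr_bc, alpha=corrected),
    ):
        rows.append(
            {
                "condition": condition,
                "test": result.test,
                "statistic": result.statistic,
                "p_value": result.p_value,
                "significant": result.significant,
            }
        )
comparisons = pd.DataFrame(rows)
comparisons.to_csv(ROOT / "comparisons.csv", index=False)
print(comparisons.to_string(index=False))

# robustness: CV of log10 BC per epidermal cell type across conditions
cv_rows = []
for cell_type in ("trichoblast", "atrichoblast"):
    groups = [
        grouped(condition, cell_type, "bc")
        for condition in sorted(reported["condition"].unique())
    ]
    results, anova_p, tukey = stats.cv_analysis(groups)
    for r in results:
        cv_rows.append(
            {
                "cell_type": cell_type,
                "group": r.label,
                "mean_cv": r.mean_cv,
                "sd_cv": r.sd_cv,
                "distinct": r.distinct,
                "anova_p": anova_p,
            }
        )
cv = pd.DataFrame(cv_rows)
cv.to_csv(ROOT / "cv_analysis.csv", index=False)
print(cv.round(4).to_string(index=False))
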