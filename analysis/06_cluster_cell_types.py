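"""Clustering of cell-type groups by distribution-test distances.

Builds the pairwise distance matrix over every (condition x cell type)
group — chi-squared statistic for degree, KS statistic for betweenness —
and cuts the average-linkage dendrogram at three clusters.  Writes
cluster assignments and Newick dendrograms under results/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from organtopo import stats, topology
from organtopo.infoclust import cluster_groups, distribution_distance_matrix

ROOT = Path(__file__).resolve().parent.parent / "results"
measures = pd.read_csv(ROOT / "measures.csv")
reported = topology.report_central(measures)
reported["condition"] = reported["organ"].str.rsplit("_rep", n=1).str[0]

for measure in ("degree", "bc"):
    groups = []
    for (condition, cell_type), sub in reported.groupby(["condition", "cell_type"]):
        reps = [g[measure].to_numpy() for _, g in sub.groupby("organ")]
        groups.append(stats.GroupedSample(f"{condition}:{cell_type}", reps))
    matrix, labels = distribution_distance_matrix(groups, measure=measure)
    assignments, _, newick = cluster_groups(matrix, labels, k=3)
    out = pd.DataFrame({"group": labels, "cluster": assignments})
    out.to_csv(ROOT / f"clusters_{measure}.csv", index=False)
    (ROOT / f"dendrogram_{measure}.nwk").write_text(newick + "\n")
    np.savetxt(
        ROOT / f"distance_matrix_{measure}.csv", matrix, delimiter=",",
        header=",".join(labels), comments="",
    )
    print(f"{measure}:")
    print(out.sort_values("cluster").to_string(index=False))
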