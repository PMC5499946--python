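"""End-to-end orchestration: generate/ingest -> filter -> buffer -> measure
-> compare -> mutual information -> cluster, with deterministic seeding.

The pipeline mirrors the reference workflow: three biological replicates
per condition, small-interface filtering at 2 square microns, a two-hop
boundary buffer, per-cell-type degree (chi-squared) and betweenness (KS)
comparisons at the Bonferroni-corrected level, an MI panel and a
distribution-distance clustering.  Replicates use seed, seed+1, seed+2.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import extraction, infoclust, stats, synthetic, topology
from .graph import EPIDERMAL_TYPES

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    input_mode: str = "synthetic"  # synthetic | edge_list
    edge_list_paths: tuple[str, ...] = ()
    annotation_paths: tuple[str, ...] = ()
    conduit_mode: bool = False
    organ_scale: str = "default"  # default | toy
    n_replicates: int = 3
    filter_threshold_um2: float = 2.0
    buffer_depth: int = 2
    alpha: float = 0.05
    m_comparisons: int = 3200
    mi_k: int = 3
    cluster_k: int = 3
    linkage: str = "average"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.input_mode not in ("synthetic", "edge_list"):
            raise ValueError(f"unknown input_mode {self.input_mode!r}")
        if self.filter_threshold_um2 <= 0 or self.buffer_depth < 0:
            raise ValueError("thresholds must be positive")


def _load_replicates(config: RunConfig) -> list:
    if config.input_mode == "synthetic":
        spec_fn = (
            synthetic.default_spec if config.organ_scale == "default" else synthetic.toy_spec
        )
        return [
            synthetic.generate_organ(
                spec_fn(conduit_mode=config.conduit_mode, seed=config.seed + i)
            )
            for i in range(config.n_replicates)
        ]
    if not config.edge_list_paths:
        raise FileNotFoundError("edge_list mode needs edge_list_paths")
    if len(config.annotation_paths) != len(config.edge_list_paths):
        raise FileNotFoundError(
            "every edge list needs a matching annotation file"
        )
    graphs = []
    for epath, apath in zip(config.edge_list_paths, config.annotation_paths):
        g = extraction.read_edge_list(epath)
        ann = extraction.read_annotation(apath)
        graphs.append(extraction.annotate_graph(g, ann))
    return graphs


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Run the full analysis; writes CSV/Newick artifacts under ``out_dir``
    and returns the result bundle in memory.

    Deterministic given the config (including seed).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"config: {json.dumps(asdict(config), default=list)}"]

    graphs = _load_replicates(config)
    log.append(f"loaded {len(graphs)} replicate networks")

    tables = []
    for i, g in enumerate(graphs):
        filtered, n_removed = extraction.filter_small_interfaces(
            g, config.filter_threshold_um2
        )
        buffered = extraction.mark_buffer(filtered, config.buffer_depth)
        table = topology.measure_table(buffered, measures=("degree", "bc", "wbc"))
        table.insert(0, "replicate", i)
        tables.append(table)
        log.append(
            f"replicate {i}: {g.number_of_nodes()} cells, "
            f"{g.number_of_edges()} interfaces, {n_removed} filtered"
        )
    measures = pd.concat(tables, ignore_index=True)
    measures.to_csv(out_dir / "measures.csv", index=False)

    reported = topology.report_central(measures)
    corrected = stats.bonferroni_threshold(config.alpha, config.m_comparisons)

    def grouped(cell_type: str, column: str) -> stats.GroupedSample:
        reps = [
            reported.loc[
                (reported["replicate"] == i) & (reported["cell_type"] == cell_type),
                column,
            ].to_numpy()
            for i in range(len(graphs))
        ]
        return stats.GroupedSample(cell_type, reps)

    comparisons = []
    tri_deg, atr_deg = grouped("trichoblast", "degree"), grouped("atrichoblast", "degree")
    tri_bc, atr_bc = grouped("trichoblast", "bc"), grouped("atrichoblast", "bc")
    comparisons.append(stats.compare_degree(tri_deg, atr_deg, alpha=corrected))
    comparisons.append(stats.compare_bc(tri_bc, atr_bc, alpha=corrected))
    comp_df = pd.DataFrame(
        [
            {
                "group_a": c.group_a,
                "group_b": c.group_b,
                "test": c.test,
                "statistic": c.statistic,
                "p_value": c.p_value,
                "corrected_alpha": c.alpha,
                "significant": c.significant,
            }
            for c in comparisons
        ]
    )
    comp_df.to_csv(out_dir / "comparisons.csv", index=False)
    log.append(f"corrected alpha = {corrected}")

    mi = infoclust.mi_panel(
        reported[reported["cell_type"].isin(EPIDERMAL_TYPES)],
        by="cell_type",
        k=config.mi_k,
        seed=config.seed,
    )
    mi.to_csv(out_dir / "mi.csv", index=False)

    cell_types = sorted(
        t for t in reported["cell_type"].unique() if t != "unassigned"
    )
    bc_groups = [grouped(t, "bc") for t in cell_types]
    matrix, labels = infoclust.distribution_distance_matrix(bc_groups, measure="bc")
    k = min(config.cluster_k, len(labels))
    assignments, _, newick = infoclust.cluster_groups(
        matrix, labels, k=k, method=config.linkage
    )
    pd.DataFrame({"group": labels, "cluster": assignments}).to_csv(
        out_dir / "clusters.csv", index=False
    )
    (out_dir / "dendrogram.nwk").write_text(newick + "\n")
    np.savetxt(out_dir / "distance_matrix.csv", matrix, delimiter=",")

    (out_dir / "run.log").write_text("\n".join(log) + "\n")
    return {
        "measures": measures,
        "comparisons": comp_df,
        "mi": mi,
        "distance_matrix": matrix,
        "cluster_labels": labels,
        "clusters": assignments,
        "newick": newick,
        "corrected_alpha": corrected,
        "log": log,
    }
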