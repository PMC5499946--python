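"""Node and edge topological measures with organ-network normalizations.

Betweenness centralities are computed over unordered node pairs and
normalized by the pair counts 2/((N-1)(N-2)) for nodes and 2/(N(N-1)) for
edges, where N is the whole-network node count (buffered and vascular cells
are always part of the computation; they are only dropped at reporting
time).  Shortest-path ties use standard Brandes fractional counting.

The heavy lifting is delegated to igraph's C implementation; equivalence
with brute-force path enumeration is enforced by the test suite.
"""

from __future__ import annotations

import warnings

import igraph as ig
import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "degree",
    "node_betweenness",
    "edge_betweenness",
    "weighted_node_betweenness",
    "current_flow_edge_betweenness",
    "log10_transform",
    "measure_table",
    "edge_measure_table",
    "report_central",
]


def _to_igraph(graph: nx.Graph):
    nodes = list(graph.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    edges = [(index[a], index[b]) for a, b in graph.edges]
    g = ig.Graph(n=len(nodes), edges=edges, directed=False)
    return g, nodes


def _check_connected(graph: nx.Graph) -> None:
    if graph.number_of_nodes() and not nx.is_connected(graph):
        warnings.warn(
            "graph is disconnected; betweenness computed per component with "
            "whole-graph N in the normalization",
            stacklevel=3,
        )


def degree(graph: nx.Graph) -> dict[int, int]:
    """Incident edge count per cell."""
    return dict(graph.degree())


def node_betweenness(graph: nx.Graph, weight: str | None = None) -> dict[int, float]:
    """Normalized node betweenness centrality, BC(v) in [0, 1].

    BC(v) = sum over unordered pairs s != v != t of sigma_st(v)/sigma_st,
    multiplied by 2/((N-1)(N-2)).
    """
    n = graph.number_of_nodes()
    if n < 3:
        raise ValueError(f"node betweenness needs N >= 3 (N = {n})")
    _check_connected(graph)
    g, nodes = _to_igraph(graph)
    weights = _edge_lengths(graph) if weight else None
    raw = g.betweenness(weights=weights)
    norm = 2.0 / ((n - 1) * (n - 2))
    return {node: raw[i] * norm for i, node in enumerate(nodes)}


def weighted_node_betweenness(graph: nx.Graph) -> dict[int, float]:
    """Betweenness over minimum-total-length paths with edge length equal to
    the reciprocal of shared wall area, so large interfaces make short
    steps; normalized like the unweighted measure."""
    return node_betweenness(graph, weight="area_um2")


def _edge_lengths(graph: nx.Graph) -> list[float]:
    lengths = []
    for a, b, data in graph.edges(data=True):
        area = data.get("area_um2")
        if area is None or not area > 0:
            raise ValueError(f"edge ({a}, {b}) needs positive area, got {area!r}")
        lengths.append(1.0 / area)
    return lengths


def edge_betweenness(graph: nx.Graph) -> dict[tuple[int, int], float]:
    """Normalized edge betweenness centrality, in [0, 1]:
    raw unordered-pair betweenness times 2/(N(N-1))."""
    n = graph.number_of_nodes()
    if n < 2:
        raise ValueError(f"edge betweenness needs N >= 2 (N = {n})")
    _check_connected(graph)
    g, nodes = _to_igraph(graph)
    raw = g.edge_betweenness()
    norm = 2.0 / (n * (n - 1))
    out = {}
    for eidx, (i, j) in enumerate(g.get_edgelist()):
        a, b = nodes[i], nodes[j]
        key = (a, b) if a <= b else (b, a)
        out[key] = raw[eidx] * norm
    return out


def current_flow_edge_betweenness(graph: nx.Graph) -> dict[tuple[int, int], float]:
    """Current-flow (random-walk) edge betweenness, normalized by
    2/(N(N-1)).  On trees this coincides with shortest-path edge
    betweenness, since all flow follows the unique path.

    Disconnected graphs are handled per component (with a warning), keeping
    the whole-graph N in the normalization.
    """
    n = graph.number_of_nodes()
    if n < 2:
        raise ValueError(f"edge betweenness needs N >= 2 (N = {n})")
    norm = 2.0 / (n * (n - 1))
    out: dict[tuple[int, int], float] = {}
    components = list(nx.connected_components(graph))
    if len(components) > 1:
        warnings.warn(
            "graph is disconnected; current-flow betweenness computed per "
            "component",
            stacklevel=2,
        )
    for comp in components:
        sub = graph.subgraph(comp)
        if sub.number_of_edges() == 0:
            continue
        if sub.number_of_nodes() == 2:
            raw = {tuple(sub.edges)[0]: 0.5}
        else:
            raw = nx.edge_current_flow_betweenness_centrality(
                sub, normalized=False, weight=None
            )
        # networkx's unnormalized values are half the unordered-pair flow sum
        for (a, b), v in raw.items():
            key = (a, b) if a <= b else (b, a)
            out[key] = 2.0 * v * norm
    return out


def log10_transform(values) -> tuple[np.ndarray, int]:
    """log10 of positive betweenness values.

    Zero entries are excluded (returned count reports how many); negative
    values are an error.  The transform is what makes BC summaries
    approximately normal for mean/sd statistics.
    """
    arr = np.asarray(list(values), dtype=float)
    if (arr < 0).any():
        raise ValueError("betweenness values must be nonnegative")
    n_excluded = int((arr == 0).sum())
    return np.log10(arr[arr > 0]), n_excluded


def measure_table(
    graph: nx.Graph,
    measures: tuple[str, ...] = ("degree", "bc"),
) -> pd.DataFrame:
    """Per-cell measure table joined to cell type and flags.

    ``measures`` may include ``degree``, ``bc``, ``wbc``; ``log10_bc`` is
    derived from ``bc`` (NaN where bc = 0).
    """
    rows = {
        "cell_id": list(graph.nodes),
        "cell_type": [graph.nodes[n].get("cell_type", "unassigned") for n in graph.nodes],
        "boundary": [bool(graph.nodes[n].get("boundary", False)) for n in graph.nodes],
        "buffer": [bool(graph.nodes[n].get("buffer", False)) for n in graph.nodes],
        "area_um2": [graph.nodes[n].get("area_um2", np.nan) for n in graph.nodes],
        "volume_um3": [graph.nodes[n].get("volume_um3", np.nan) for n in graph.nodes],
    }
    df = pd.DataFrame(rows)
    if "degree" in measures:
        deg = degree(graph)
        df["degree"] = [deg[n] for n in graph.nodes]
    if "bc" in measures:
        bc = node_betweenness(graph)
        df["bc"] = [bc[n] for n in graph.nodes]
        with np.errstate(divide="ignore"):
            df["log10_bc"] = np.where(df["bc"] > 0, np.log10(df["bc"]), np.nan)
    if "wbc" in measures:
        wbc = weighted_node_betweenness(graph)
        df["wbc"] = [wbc[n] for n in graph.nodes]
    return df


def edge_measure_table(
    graph: nx.Graph, measures: tuple[str, ...] = ("ebc",)
) -> pd.DataFrame:
    """Per-edge measure table: interface area plus edge betweenness
    (``ebc``) and optionally its current-flow variant (``rwbc``)."""
    keys = [(a, b) if a <= b else (b, a) for a, b in graph.edges]
    df = pd.DataFrame(
        {
            "cell_id_1": [k[0] for k in keys],
            "cell_id_2": [k[1] for k in keys],
            "area_um2": [graph.edges[k]["area_um2"] for k in keys],
        }
    )
    if "ebc" in measures:
        ebc = edge_betweenness(graph)
        df["ebc"] = [ebc[k] for k in keys]
    if "rwbc" in measures:
        rwbc = current_flow_edge_betweenness(graph)
        df["rwbc"] = [rwbc.get(k, 0.0) for k in keys]
    return df


def report_central(table: pd.DataFrame) -> pd.DataFrame:
    """Reporting mask: drop buffered cells (boundary artifacts) and
    vascular cells (sporadic segmentation errors in real data); the
    underlying measure values are untouched."""
    out = table[(~table["buffer"]) & (table["cell_type"] != "vasculature")]
    if out.empty:
        warnings.warn("all cells buffered: reported table is empty", stacklevel=2)
    return out.copy()
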