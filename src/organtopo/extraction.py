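"""Network extraction and exchange formats.

Builds annotated cell graphs from labeled 3D volumes (6-connectivity face
adjacency with physical face areas) or from MorphoGraphX-style edge-list
text exports, applies the small-interface filter and the boundary buffer,
and reads/writes edge lists, annotation tables and attribute heat maps.
"""

from __future__ import annotations

import csv
import warnings
from collections import deque
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .graph import ANNOTATION_TYPES, add_interface

__all__ = [
    "LabeledVolume",
    "extract_adjacency",
    "filter_small_interfaces",
    "mark_buffer",
    "read_edge_list",
    "write_edge_list",
    "read_annotation",
    "write_annotation",
    "annotate_graph",
    "write_heatmap",
    "read_heatmap",
]


@dataclass
class LabeledVolume:
    """Integer-labeled 3D volume in (z, y, x) axis order.

    ``voxel_um`` is (dz, dy, dx).  Labels in ``excluded_labels`` (background
    plus computationally removed segments such as air spaces) contribute to
    cells' exterior surface rather than to edges.
    """

    labels: np.ndarray
    voxel_um: tuple[float, float, float]
    excluded_labels: frozenset[int] = field(default_factory=lambda: frozenset({0}))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D array")
        if min(self.voxel_um) <= 0:
            raise ValueError(f"voxel dimensions must be positive: {self.voxel_um}")
        self.excluded_labels = frozenset(self.excluded_labels) | {0}


def extract_adjacency(volume: LabeledVolume) -> nx.Graph:
    """Face-adjacency cell graph of a labeled volume.

    One node per non-excluded label; an edge wherever two labels share at
    least one voxel face, with area equal to the summed physical face area
    (6-connectivity only: diagonal contacts are not shared walls).
    """
    labels = volume.labels
    dz, dy, dx = volume.voxel_um
    excluded = np.fromiter(volume.excluded_labels, dtype=labels.dtype)

    keep = np.unique(labels)
    keep = keep[~np.isin(keep, excluded)]
    if keep.size < 2:
        raise ValueError(
            f"need at least 2 non-excluded labels, found {keep.size}"
        )

    graph = nx.Graph()
    graph.add_nodes_from(int(v) for v in keep)

    face_area = {0: dy * dx, 1: dz * dx, 2: dz * dy}
    accum: dict[tuple[int, int], float] = {}
    for axis, area in face_area.items():
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[axis] = slice(None, -1)
        sl_b[axis] = slice(1, None)
        a = labels[tuple(sl_a)].ravel()
        b = labels[tuple(sl_b)].ravel()
        mask = (a != b) & ~np.isin(a, excluded) & ~np.isin(b, excluded)
        if not mask.any():
            continue
        lo = np.minimum(a[mask], b[mask])
        hi = np.maximum(a[mask], b[mask])
        pairs, counts = np.unique(np.stack([lo, hi], axis=1), axis=0, return_counts=True)
        for (u, v), c in zip(pairs, counts):
            key = (int(u), int(v))
            accum[key] = accum.get(key, 0.0) + float(c) * area

    for (u, v), a_um2 in accum.items():
        add_interface(graph, u, v, a_um2)
    return graph


def filter_small_interfaces(
    graph: nx.Graph, threshold_um2: float = 2.0
) -> tuple[nx.Graph, int]:
    """Remove edges with shared wall area strictly below the threshold,
    except edges with a vascular endpoint (the filter targets segmentation
    artifacts, and vascular interfaces are legitimately small).

    Returns (filtered graph, number of edges removed); nodes are never
    removed.
    """
    if not threshold_um2 > 0:
        raise ValueError("threshold_um2 must be > 0")
    out = graph.copy()
    doomed = [
        (a, b)
        for a, b, data in graph.edges(data=True)
        if data["area_um2"] < threshold_um2
        and graph.nodes[a].get("cell_type") != "vasculature"
        and graph.nodes[b].get("cell_type") != "vasculature"
    ]
    out.remove_edges_from(doomed)
    return out, len(doomed)


def mark_buffer(graph: nx.Graph, depth: int = 2) -> nx.Graph:
    """Flag every cell within ``depth`` graph hops of a boundary cell.

    Buffered cells stay in the graph (centrality is computed on the full
    network); reporting operations exclude them.  Returns a copy.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    out = graph.copy()
    sources = [n for n, d in out.nodes(data=True) if d.get("boundary")]
    nx.set_node_attributes(out, False, "buffer")
    if not sources:
        if depth > 0:
            warnings.warn(
                "no boundary cells flagged; buffer marking is a no-op",
                stacklevel=2,
            )
        return out
    # multi-source BFS over graph hops
    dist = {s: 0 for s in sources}
    frontier = deque(sources)
    while frontier:
        u = frontier.popleft()
        if dist[u] == depth:
            continue
        for v in out[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                frontier.append(v)
    for n in dist:
        out.nodes[n]["buffer"] = True
    return out


# ---------------------------------------------------------------------------
# Exchange formats
# ---------------------------------------------------------------------------


def read_edge_list(path) -> nx.Graph:
    """Read a whitespace/tab-delimited edge list: cell_id_1 cell_id_2 area_um2.

    Lines beginning with ``#`` are ignored.  Duplicate pairs, malformed
    lines and non-positive areas raise with the offending line number.
    """
    graph = nx.Graph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 'id1 id2 area', got {line!r}"
                )
            try:
                a, b = int(parts[0]), int(parts[1])
                area = float(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            if graph.has_edge(a, b):
                raise ValueError(
                    f"{path}:{lineno}: duplicate edge ({a}, {b})"
                )
            try:
                add_interface(graph, a, b, area)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    return graph


def write_edge_list(graph: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        fh.write("# cell_id_1 cell_id_2 area_um2\n")
        for a, b, data in sorted(graph.edges(data=True)):
            fh.write(f"{a}\t{b}\t{data['area_um2']!r}\n")


def read_annotation(path) -> pd.DataFrame:
    """Read an annotation CSV with columns cell_id, cell_type, boundary."""
    df = pd.read_csv(path)
    required = {"cell_id", "cell_type"}
    if not required.issubset(df.columns):
        raise ValueError(f"annotation must have columns {sorted(required)}")
    bad = set(df["cell_type"]) - set(ANNOTATION_TYPES)
    if bad:
        raise ValueError(
            f"unknown cell_type values {sorted(bad)}; "
            f"allowed: {list(ANNOTATION_TYPES)}"
        )
    if "boundary" not in df.columns:
        df["boundary"] = False
    df["cell_id"] = df["cell_id"].astype(int)
    df["boundary"] = df["boundary"].astype(bool)
    return df[["cell_id", "cell_type", "boundary"]]


def write_annotation(graph: nx.Graph, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["cell_id", "cell_type", "boundary"])
        for n in sorted(graph.nodes):
            d = graph.nodes[n]
            w.writerow(
                [n, d.get("cell_type", "unassigned"), bool(d.get("boundary", False))]
            )


def annotate_graph(graph: nx.Graph, annotation: pd.DataFrame) -> nx.Graph:
    """Attach cell_type and boundary flags from an annotation table.

    Every node must be covered (possibly as ``unassigned``)."""
    out = graph.copy()
    ann = annotation.set_index("cell_id")
    for n in out.nodes:
        if n in ann.index:
            out.nodes[n]["cell_type"] = ann.at[n, "cell_type"]
            out.nodes[n]["boundary"] = bool(ann.at[n, "boundary"])
        else:
            out.nodes[n].setdefault("cell_type", "unassigned")
            out.nodes[n].setdefault("boundary", False)
        out.nodes[n].setdefault("buffer", False)
    return out


def write_heatmap(values: dict[int, float], path) -> None:
    """Write a per-cell attribute map as two-column text (cell_id, value),
    consumable as a MorphoGraphX heat map."""
    with open(path, "w") as fh:
        for cid in sorted(values):
            fh.write(f"{cid}\t{values[cid]!r}\n")


def read_heatmap(path) -> dict[int, float]:
    out: dict[int, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cid, val = line.split()
            out[int(cid)] = float(val)
    return out
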