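"""Cellular connectivity graphs.

A cell graph is an undirected :class:`networkx.Graph` in which nodes are
cells (opaque positive-integer ids) and edges are shared wall interfaces.
Node attributes: ``cell_type``, ``boundary`` (cell touches the sample cut),
``buffer`` (excluded from reporting), ``area_um2``, ``volume_um3``.
Edge attribute: ``area_um2``, the shared wall area in square microns.
"""

from __future__ import annotations

import networkx as nx

#: Cell types of the hypocotyl, epidermis outward-in.
CELL_TYPES = (
    "trichoblast",
    "atrichoblast",
    "outer_cortex",
    "inner_cortex",
    "endodermis",
    "vasculature",
)

EPIDERMAL_TYPES = ("trichoblast", "atrichoblast")

#: Valid annotation labels (graph nodes may be unannotated).
ANNOTATION_TYPES = CELL_TYPES + ("unassigned",)


class CellGraphError(ValueError):
    """Raised when a cell graph violates its structural invariants."""


def new_cell_graph() -> nx.Graph:
    return nx.Graph()


def add_interface(graph: nx.Graph, a: int, b: int, area_um2: float) -> None:
    """Add the shared-wall edge (a, b); rejects self-loops, duplicates and
    non-positive areas."""
    if a == b:
        raise CellGraphError(f"self-loop on cell {a}")
    if graph.has_edge(a, b):
        raise CellGraphError(f"duplicate interface between cells {a} and {b}")
    if not area_um2 > 0:
        raise CellGraphError(
            f"interface ({a}, {b}) has non-positive area {area_um2}"
        )
    graph.add_edge(a, b, area_um2=float(area_um2))


def validate(graph: nx.Graph) -> None:
    """Check the cell-graph invariants, raising :class:`CellGraphError`."""
    for a, b, data in graph.edges(data=True):
        if a == b:
            raise CellGraphError(f"self-loop on cell {a}")
        area = data.get("area_um2")
        if area is None or not area > 0:
            raise CellGraphError(f"edge ({a}, {b}) has invalid area {area!r}")


def is_vascular(graph: nx.Graph, node: int) -> bool:
    return graph.nodes[node].get("cell_type") == "vasculature"
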