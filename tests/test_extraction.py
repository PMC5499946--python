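"""Adjacency extraction against a naive face-scan oracle, interface
filtering, boundary buffering and exchange-format round trips."""

import itertools

import networkx as nx
import numpy as np
import pytest

from organtopo import extraction
from organtopo.extraction import (
    LabeledVolume,
    extract_adjacency,
    filter_small_interfaces,
    mark_buffer,
    read_annotation,
    read_edge_list,
    read_heatmap,
    write_annotation,
    write_edge_list,
    write_heatmap,
)


def face_scan_oracle(volume):
    """O(voxels x 6) brute force: walk every voxel, inspect its 6 face
    neighbors and sum physical face areas per label pair."""
    labels = volume.labels
    dz, dy, dx = volume.voxel_um
    face = {(1, 0, 0): dy * dx, (0, 1, 0): dz * dx, (0, 0, 1): dz * dy}
    areas = {}
    nz, ny, nxv = labels.shape
    for z in range(nz):
        for y in range(ny):
            for x in range(nxv):
                a = labels[z, y, x]
                if a in volume.excluded_labels:
                    continue
                for (oz, oy, ox), fa in face.items():
                    z2, y2, x2 = z + oz, y + oy, x + ox
                    if z2 >= nz or y2 >= ny or x2 >= nxv:
                        continue
                    b = labels[z2, y2, x2]
                    if b in volume.excluded_labels or a == b:
                        continue
                    key = (min(a, b), max(a, b))
                    areas[key] = areas.get(key, 0.0) + fa
    return areas


def test_single_shared_face():
    vol = LabeledVolume(np.array([[[1, 2]]]), (1.0, 1.0, 1.0))
    g = extract_adjacency(vol)
    assert g.edges[1, 2]["area_um2"] == pytest.approx(1.0)


def test_slab_face_area_sums_voxel_faces():
    # two 2x2x1 slabs sharing a 2x2 face at 0.5 um voxels: 4 x 0.25 um^2
    labels = np.zeros((2, 2, 2), dtype=int)
    labels[:, :, 0] = 1
    labels[:, :, 1] = 2
    g = extract_adjacency(LabeledVolume(labels, (0.5, 0.5, 0.5)))
    assert g.edges[1, 2]["area_um2"] == pytest.approx(1.0)


def test_diagonal_contact_is_not_an_edge():
    # labels 1 and 2 touch only along a voxel edge: 6-connectivity sees no
    # shared wall
    labels = np.array([[[1, 0], [0, 2]]])
    g = extract_adjacency(LabeledVolume(labels, (1.0, 1.0, 1.0)))
    assert set(g.nodes) == {1, 2}
    assert g.number_of_edges() == 0


def test_excluded_labels_do_not_form_edges():
    labels = np.array([[[1, 9, 2]]])
    g = extract_adjacency(
        LabeledVolume(labels, (1.0, 1.0, 1.0), excluded_labels=frozenset({0, 9}))
    )
    assert set(g.nodes) == {1, 2}
    assert g.number_of_edges() == 0


def test_extraction_matches_face_scan_oracle(rng):
    for _ in range(15):
        shape = tuple(rng.integers(2, 8, size=3))
        labels = rng.integers(0, 5, size=shape)
        voxel = tuple(float(v) for v in rng.uniform(0.2, 2.0, size=3))
        vol = LabeledVolume(labels, voxel)
        oracle = face_scan_oracle(vol)
        if len(np.setdiff1d(np.unique(labels), [0])) < 2:
            continue
        g = extract_adjacency(vol)
        extracted = {
            tuple(sorted(e)): g.edges[e]["area_um2"] for e in g.edges
        }
        assert set(extracted) == set(oracle)
        for e, area in oracle.items():
            assert extracted[e] == pytest.approx(area, rel=1e-12)


def test_nonpositive_voxel_and_single_label_rejected():
    with pytest.raises(ValueError):
        LabeledVolume(np.ones((2, 2, 2), dtype=int), (1.0, 0.0, 1.0))
    with pytest.raises(ValueError):
        extract_adjacency(LabeledVolume(np.ones((2, 2, 2), dtype=int), (1, 1, 1)))


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------


def _typed_graph(edges):
    g = nx.Graph()
    for (a, ta), (b, tb), area in edges:
        g.add_node(a, cell_type=ta)
        g.add_node(b, cell_type=tb)
        g.add_edge(a, b, area_um2=area)
    return g


def test_filter_small_interfaces_rules():
    g = _typed_graph(
        [
            ((1, "trichoblast"), (2, "atrichoblast"), 1.9),
            ((3, "outer_cortex"), (4, "outer_cortex"), 2.0),
            ((5, "vasculature"), (6, "endodermis"), 0.5),
        ]
    )
    out, removed = filter_small_interfaces(g, 2.0)
    assert removed == 1
    assert not out.has_edge(1, 2)  # below threshold: removed
    assert out.has_edge(3, 4)  # exactly at threshold: retained
    assert out.has_edge(5, 6)  # vasculature-incident: exempt
    assert set(out.nodes) == set(g.nodes)  # nodes never removed


def test_filter_is_idempotent(toy_organ):
    once, n1 = filter_small_interfaces(toy_organ, 2.0)
    twice, n2 = filter_small_interfaces(once, 2.0)
    assert n2 == 0
    assert set(once.edges) == set(twice.edges)


def test_filter_rejects_nonpositive_threshold(toy_organ):
    with pytest.raises(ValueError):
        filter_small_interfaces(toy_organ, 0.0)


# ---------------------------------------------------------------------------
# Buffering
# ---------------------------------------------------------------------------


def _path_with_boundary():
    g = nx.path_graph([1, 2, 3, 4, 5])
    nx.set_node_attributes(g, False, "boundary")
    g.nodes[1]["boundary"] = True
    return g


def test_buffer_bfs_depths():
    g = _path_with_boundary()
    flagged = {
        n for n, d in mark_buffer(g, depth=2).nodes(data=True) if d["buffer"]
    }
    assert flagged == {1, 2, 3}
    flagged0 = {
        n for n, d in mark_buffer(g, depth=0).nodes(data=True) if d["buffer"]
    }
    assert flagged0 == {1}
    all_flagged = {
        n for n, d in mark_buffer(g, depth=10).nodes(data=True) if d["buffer"]
    }
    assert all_flagged == set(g.nodes)


def test_buffer_monotone_in_depth(toy_organ):
    previous = set()
    for depth in range(4):
        flagged = {
            n
            for n, d in mark_buffer(toy_organ, depth).nodes(data=True)
            if d["buffer"]
        }
        assert previous <= flagged
        previous = flagged


def test_buffer_without_boundary_warns():
    g = nx.path_graph(3)
    nx.set_node_attributes(g, False, "boundary")
    with pytest.warns(UserWarning):
        out = mark_buffer(g, depth=2)
    assert not any(d["buffer"] for _, d in out.nodes(data=True))


# ---------------------------------------------------------------------------
# Exchange formats
# ---------------------------------------------------------------------------


def test_edge_list_round_trip(tmp_path, toy_organ):
    path = tmp_path / "edges.txt"
    write_edge_list(toy_organ, path)
    back = read_edge_list(path)
    canon = lambda g: {tuple(sorted(e)) for e in g.edges}
    assert canon(back) == canon(toy_organ)
    for a, b in toy_organ.edges:
        assert back.edges[a, b]["area_um2"] == toy_organ.edges[a, b]["area_um2"]


def test_edge_list_parses_comments_and_reports_line_numbers(tmp_path):
    path = tmp_path / "edges.txt"
    path.write_text("# comment\n12 47 3.25\n")
    g = read_edge_list(path)
    assert g.edges[12, 47]["area_um2"] == 3.25

    path.write_text("1 2 1.0\n1 2 2.0\n")
    with pytest.raises(ValueError, match=":2"):
        read_edge_list(path)
    path.write_text("1 2 1.0\nbogus line here now\n")
    with pytest.raises(ValueError, match=":2"):
        read_edge_list(path)
    path.write_text("1 2 -1.0\n")
    with pytest.raises(ValueError, match=":1"):
        read_edge_list(path)


def test_annotation_round_trip_and_validation(tmp_path, toy_organ):
    path = tmp_path / "ann.csv"
    write_annotation(toy_organ, path)
    ann = read_annotation(path)
    assert len(ann) == toy_organ.number_of_nodes()
    lookup = dict(zip(ann["cell_id"], ann["cell_type"]))
    for n, d in toy_organ.nodes(data=True):
        assert lookup[n] == d["cell_type"]

    path.write_text("cell_id,cell_type,boundary\n1,hair,False\n")
    with pytest.raises(ValueError, match="hair"):
        read_annotation(path)


def test_heatmap_round_trip(tmp_path, toy_organ):
    from organtopo import topology

    bc = topology.node_betweenness(toy_organ)
    path = tmp_path / "bc.txt"
    write_heatmap(bc, path)
    back = read_heatmap(path)
    assert back == bc
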