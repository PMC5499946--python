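"""Synthetic organ generator: architecture invariants, rasterization round
trips, artifact injection and the signal channel."""

from dataclasses import replace

import networkx as nx
import numpy as np
import pytest

import organtopo as ot
from organtopo.synthetic import OrganSpec, OrganSpecError, RingSpec


def _mean_degree(graph, cell_type):
    deg = dict(graph.degree())
    vals = [
        deg[n] for n, d in graph.nodes(data=True) if d["cell_type"] == cell_type
    ]
    return np.mean(vals)


def test_generated_organ_is_connected_with_positive_areas(toy_organ):
    assert nx.is_connected(toy_organ)
    assert all(d["area_um2"] > 0 for _, _, d in toy_organ.edges(data=True))


def test_trichoblast_degree_exceeds_atrichoblast(toy_organ, default_organ):
    for g in (toy_organ, default_organ):
        assert _mean_degree(g, "trichoblast") > _mean_degree(g, "atrichoblast")


def test_epidermal_degree_below_cortical(default_organ):
    epidermal = np.mean(
        [_mean_degree(default_organ, t) for t in ("trichoblast", "atrichoblast")]
    )
    assert epidermal < _mean_degree(default_organ, "outer_cortex")
    assert epidermal < _mean_degree(default_organ, "inner_cortex")


def test_boundary_flags_on_axial_ends(toy_organ):
    for n, d in toy_organ.nodes(data=True):
        assert d["boundary"] == (d["axial"] in (0, _file_len(toy_organ, n) - 1))


def _file_len(graph, node):
    d = graph.nodes[node]
    return (
        max(
            dd["axial"]
            for _, dd in graph.nodes(data=True)
            if dd["ring"] == d["ring"] and dd["file"] == d["file"]
        )
        + 1
    )


def test_conduit_mode_reduces_atrichoblast_axial_count():
    on = ot.generate_organ(ot.toy_spec(conduit_mode=True, seed=3))
    off = ot.generate_organ(ot.toy_spec(conduit_mode=False, seed=3))
    count = lambda g, t: sum(d["cell_type"] == t for _, d in g.nodes(data=True))
    assert count(on, "atrichoblast") == count(off, "atrichoblast") // 2
    assert count(on, "trichoblast") == count(off, "trichoblast")


def test_replicates_are_topologically_distinct():
    g1 = ot.generate_organ(ot.toy_spec(seed=1))
    g2 = ot.generate_organ(ot.toy_spec(seed=2))
    assert {tuple(sorted(e)) for e in g1.edges} != {
        tuple(sorted(e)) for e in g2.edges
    }


def test_generation_is_deterministic_per_seed():
    a = ot.generate_organ(ot.toy_spec(seed=5))
    b = ot.generate_organ(ot.toy_spec(seed=5))
    assert {tuple(sorted(e)) for e in a.edges} == {tuple(sorted(e)) for e in b.edges}
    for e in a.edges:
        assert a.edges[e]["area_um2"] == b.edges[e]["area_um2"]


def test_spec_validation():
    ring = RingSpec("vasculature", 4, 4)
    epi = RingSpec("epidermis", 8, 4)
    with pytest.raises(OrganSpecError):
        OrganSpec(rings=(ring,))  # fewer than 2 rings
    with pytest.raises(OrganSpecError):
        OrganSpec(rings=(ring, RingSpec("epidermis", 7, 4)))  # cannot tile
    with pytest.raises(OrganSpecError):
        OrganSpec(rings=(epi, ring))  # epidermis must be outermost
    with pytest.raises(OrganSpecError):
        RingSpec("endodermis", 0, 4)
    with pytest.raises(OrganSpecError):
        OrganSpec(rings=(ring, epi), organ_length_um=-1.0)


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------


def _edge_sets(a, b):
    canon = lambda g: {tuple(sorted(e)) for e in g.edges}
    return canon(a), canon(b)


def test_rasterize_extract_round_trip_exact():
    # unstaggered lattices round-trip exactly at fine voxels
    spec = OrganSpec(
        rings=(
            RingSpec("vasculature", 2, 2, thickness_um=10.0),
            RingSpec("epidermis", 4, 2, thickness_um=10.0),
        ),
        organ_length_um=20.0,
        seed=1,
        axial_jitter=0.0,
    )
    generated = ot.generate_organ(spec)
    extracted = ot.extract_adjacency(ot.rasterize_organ(spec, (0.25, 0.25, 0.25)))
    assert set(extracted.nodes) == set(generated.nodes)
    ea, eb = _edge_sets(extracted, generated)
    assert ea == eb


def test_rasterize_extract_round_trip_toy_scale():
    spec = replace(ot.toy_spec(seed=2), axial_jitter=0.0)
    generated = ot.generate_organ(spec)
    extracted = ot.extract_adjacency(ot.rasterize_organ(spec, (0.5, 0.25, 0.25)))
    assert set(extracted.nodes) == set(generated.nodes)
    ea, eb = _edge_sets(extracted, generated)
    assert ea == eb


def test_rasterize_staggered_misses_only_slivers():
    # staggered cell boundaries create sub-voxel sliver interfaces that the
    # rasterization cannot resolve, but it must never invent contacts
    spec = ot.toy_spec(seed=2)
    generated = ot.generate_organ(spec)
    extracted = ot.extract_adjacency(ot.rasterize_organ(spec, (0.5, 0.25, 0.25)))
    ea, eb = _edge_sets(extracted, generated)
    assert ea <= eb


def test_rasterize_single_cell_plus_background():
    spec = OrganSpec(
        rings=(
            RingSpec("vasculature", 1, 1, thickness_um=5.0),
            RingSpec("epidermis", 2, 1, thickness_um=5.0),
        ),
        organ_length_um=5.0,
        seed=0,
    )
    vol = ot.rasterize_organ(spec, (0.5, 0.5, 0.5))
    assert set(np.unique(vol.labels)) == {0, 1, 2, 3}


def test_rasterize_too_coarse_names_a_cell():
    spec = ot.toy_spec(seed=0)
    with pytest.raises(ValueError, match="cell"):
        ot.rasterize_organ(spec, (40.0, 40.0, 40.0))


# ---------------------------------------------------------------------------
# Artifacts
# ---------------------------------------------------------------------------


def test_inject_artifacts_zero_rate_is_identity(toy_organ):
    out = ot.inject_artifacts(toy_organ, rate=0.0, max_area_um2=1.9, seed=0)
    assert _edge_sets(out, toy_organ)[0] == _edge_sets(out, toy_organ)[1]


def test_inject_artifacts_count_arithmetic(toy_organ):
    e0 = toy_organ.number_of_edges()
    out = ot.inject_artifacts(toy_organ, rate=0.1, max_area_um2=1.9, seed=0)
    assert out.number_of_edges() == e0 + round(0.1 * e0)


def test_filter_restores_injected_graph_exactly(toy_organ):
    injected = ot.inject_artifacts(toy_organ, rate=0.1, max_area_um2=1.9, seed=7)
    restored, removed = ot.filter_small_interfaces(injected, 2.0)
    ea, eb = _edge_sets(restored, toy_organ)
    assert ea == eb
    assert removed == injected.number_of_edges() - toy_organ.number_of_edges()


def test_artifacts_avoid_vasculature(toy_organ):
    injected = ot.inject_artifacts(toy_organ, rate=0.2, max_area_um2=1.0, seed=1)
    new_edges = _edge_sets(injected, toy_organ)[0] - _edge_sets(injected, toy_organ)[1]
    for a, b in new_edges:
        assert injected.nodes[a]["cell_type"] != "vasculature"
        assert injected.nodes[b]["cell_type"] != "vasculature"


# ---------------------------------------------------------------------------
# Signal channel
# ---------------------------------------------------------------------------


def test_signal_volume_noise_free_equals_type_means():
    spec = ot.toy_spec(seed=4)
    graph = ot.generate_organ(spec)
    vol = ot.rasterize_organ(spec, (1.0, 0.5, 0.5))
    annotation = {n: d["cell_type"] for n, d in graph.nodes(data=True)}
    means = {t: float(i + 1) for i, t in enumerate(ot.CELL_TYPES)}
    sig = ot.generate_signal_volume(vol, annotation, means, noise_sd=0.0)
    for cid in (1, graph.number_of_nodes() // 2, graph.number_of_nodes()):
        expected = means[annotation[cid]]
        assert np.all(sig[vol.labels == cid] == expected)
    assert np.all(sig[vol.labels == 0] == 0.0)


def test_signal_volume_missing_type_errors():
    spec = ot.toy_spec(seed=4)
    graph = ot.generate_organ(spec)
    vol = ot.rasterize_organ(spec, (1.0, 0.5, 0.5))
    annotation = {n: d["cell_type"] for n, d in graph.nodes(data=True)}
    with pytest.raises(KeyError):
        ot.generate_signal_volume(vol, annotation, {"trichoblast": 1.0})
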