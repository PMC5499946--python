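"""Synthetic hypocotyl generator.

Emulates the cellular architecture of the unexpanded plant embryonic stem:
a radially symmetric stack of concentric cell-type rings (vasculature core,
endodermis, cortical layers, epidermis) in which every ring is tiled by
circumferential cell files and every file by axial cells.  The epidermal
ring alternates trichoblast and atrichoblast files, with each trichoblast
file straddling the junction of two underlying cortical files (giving
trichoblasts their higher degree) and each atrichoblast file sitting over a
single cortical file.

Epidermal files are laid out with half the axial cell count of the internal
layers, so that in the null organ both epidermal cell types share the same
axial-conduit role and their betweenness distributions are statistically
indistinguishable even though trichoblast degree is higher — mirroring the
field observation that local connectivity does not by itself set path
length.  ``conduit_mode`` then produces a low-path-length atrichoblast
conduit by halving the number of atrichoblast cells along the axis once
more (longer cells mean fewer hops along the organ), so shortest paths
along the organ concentrate on atrichoblast files and their betweenness
rises sharply.  Interior cell boundaries along every file are randomly
staggered, which is what makes replicate organs (seed, seed+1, seed+2)
topologically distinct.

Geometry is idealised: cells are annular sectors, interface areas are drawn
from per-ring lognormal models, and per-cell wall area / volume carry a
lognormal size jitter.  Nothing here attempts to reproduce real ecotype
geometry quantitatively.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .graph import add_interface

__all__ = [
    "RingSpec",
    "OrganSpec",
    "OrganSpecError",
    "toy_spec",
    "default_spec",
    "generate_organ",
    "rasterize_organ",
    "generate_signal_volume",
    "inject_artifacts",
]


class OrganSpecError(ValueError):
    """Raised when an organ specification cannot tile a cylinder."""


@dataclass(frozen=True)
class RingSpec:
    """One concentric ring of the organ.

    ``cell_type`` is a single internal cell type, or ``"epidermis"`` for the
    outermost ring, which is split into alternating trichoblast (even file
    index) and atrichoblast (odd) files.  ``n_axial`` is the number of cells
    per file along the organ axis; for the epidermal ring it applies to
    trichoblast files (atrichoblast files follow it, or half of it when the
    conduit is switched on).  ``interface_area_mean_um2`` and
    ``interface_area_cv`` parameterise the lognormal model for interface
    areas of edges within this ring (between-ring edges pool the two rings'
    parameters).
    """

    cell_type: str
    n_files: int
    n_axial: int
    interface_area_mean_um2: float = 30.0
    interface_area_cv: float = 0.3
    thickness_um: float = 15.0

    def __post_init__(self) -> None:
        if self.n_files < 1 or self.n_axial < 1:
            raise OrganSpecError(
                f"ring {self.cell_type!r}: file/axial counts must be >= 1"
            )
        if not self.interface_area_mean_um2 > 0:
            raise OrganSpecError("interface_area_mean_um2 must be > 0")
        if self.interface_area_cv < 0:
            raise OrganSpecError("interface_area_cv must be >= 0")
        if not self.thickness_um > 0:
            raise OrganSpecError("thickness_um must be > 0")


@dataclass(frozen=True)
class OrganSpec:
    """Parametric description of a synthetic cylindrical organ.

    ``rings`` are ordered innermost (vasculature core) to outermost
    (epidermis).  The epidermal ring must carry twice as many files as the
    ring directly beneath it so that trichoblast files can bridge two
    cortical files; any other ratio cannot tile the cylinder.
    """

    rings: tuple[RingSpec, ...]
    organ_length_um: float = 300.0
    conduit_mode: bool = False
    artifact_rate: float = 0.0
    seed: int = 0
    size_jitter_cv: float = 0.1
    #: relative jitter of interior cell boundaries along a file (< 0.5);
    #: 0 gives an unstaggered lattice whose rasterization round-trips exactly
    axial_jitter: float = 0.3

    def __post_init__(self) -> None:
        object.__setattr__(self, "rings", tuple(self.rings))
        if len(self.rings) < 2:
            raise OrganSpecError("an organ needs at least 2 rings")
        if not self.organ_length_um > 0:
            raise OrganSpecError("organ_length_um must be > 0")
        if not 0.0 <= self.artifact_rate <= 1.0:
            raise OrganSpecError("artifact_rate must lie in [0, 1]")
        if not 0.0 <= self.axial_jitter < 0.5:
            raise OrganSpecError("axial_jitter must lie in [0, 0.5)")
        n_epi = sum(r.cell_type == "epidermis" for r in self.rings)
        if n_epi != 1 or self.rings[-1].cell_type != "epidermis":
            raise OrganSpecError(
                "exactly one ring must be epidermal and it must be outermost"
            )
        epi, inner = self.rings[-1], self.rings[-2]
        if epi.n_files != 2 * inner.n_files:
            raise OrganSpecError(
                "the epidermal ring must have exactly twice the files of the "
                f"ring beneath it ({epi.n_files} vs {inner.n_files}): "
                "trichoblast files cannot tile over cortical junctions"
            )

    @property
    def radii_um(self) -> np.ndarray:
        """Ring boundary radii, innermost boundary 0."""
        return np.concatenate(
            [[0.0], np.cumsum([r.thickness_um for r in self.rings])]
        )


def toy_spec(conduit_mode: bool = False, seed: int = 0) -> OrganSpec:
    """Small (~700 cell) organ for fast tests.

    Axial counts are kept high enough that central epidermal cells survive
    the default two-hop boundary buffer even in conduit mode."""
    return OrganSpec(
        rings=(
            RingSpec("vasculature", 4, 32, 6.0, 0.8, 12.0),
            RingSpec("endodermis", 6, 32, 45.0, 0.3, 12.0),
            RingSpec("outer_cortex", 6, 32, 60.0, 0.3, 15.0),
            RingSpec("epidermis", 12, 16, 30.0, 0.3, 10.0),
        ),
        organ_length_um=150.0,
        conduit_mode=conduit_mode,
        seed=seed,
    )


def default_spec(conduit_mode: bool = False, seed: int = 0) -> OrganSpec:
    """Organ on the order of a real hypocotyl network (~2000 cells)."""
    return OrganSpec(
        rings=(
            RingSpec("vasculature", 8, 60, 6.0, 0.8, 20.0),
            RingSpec("endodermis", 10, 60, 45.0, 0.3, 12.0),
            RingSpec("inner_cortex", 10, 60, 70.0, 0.3, 18.0),
            RingSpec("outer_cortex", 12, 60, 60.0, 0.3, 18.0),
            RingSpec("epidermis", 24, 30, 30.0, 0.3, 10.0),
        ),
        organ_length_um=300.0,
        conduit_mode=conduit_mode,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Lattice construction
# ---------------------------------------------------------------------------

_EPS = 1e-9


@dataclass
class _File:
    """One circumferential cell file: an angular sector tiled axially.

    ``z_bounds`` are the n_axial + 1 normalized axial cell boundaries
    (0 = organ base, 1 = tip), jittered off the uniform grid.
    """

    ring: int
    index: int
    cell_type: str
    theta0: float  # angular interval in turns, [theta0, theta1)
    theta1: float
    z_bounds: np.ndarray
    cell_ids: list[int] = field(default_factory=list)

    @property
    def n_axial(self) -> int:
        return len(self.z_bounds) - 1

    def z_interval(self, a: int) -> tuple[float, float]:
        return float(self.z_bounds[a]), float(self.z_bounds[a + 1])


def _z_bounds(n_axial: int, jitter: float, rng: np.random.Generator) -> np.ndarray:
    bounds = np.arange(n_axial + 1, dtype=float)
    if n_axial > 1 and jitter > 0:
        bounds[1:-1] += rng.uniform(-jitter, jitter, n_axial - 1)
    return bounds / n_axial


def _build_files(spec: OrganSpec) -> list[list[_File]]:
    """Lay out every ring's files: angular sectors plus jittered axial
    boundaries.

    Each internal ring tiles [0, 1) in equal sectors with a random angular
    phase (real cell layers are not angularly registered, and generic
    phases keep file-boundary rays of adjacent rings from coinciding).  The
    epidermal ring is registered to the ring beneath it, shifted by half an
    epidermal file width, so that each even (trichoblast) file straddles a
    cortical file junction and each odd (atrichoblast) file sits inside a
    single cortical sector.  The layout is a pure function of the spec
    (seed included), shared by the graph generator and the rasterizer.
    """
    rng = np.random.default_rng([spec.seed, 0])
    per_ring: list[list[_File]] = []
    ring_phase = 0.0
    for r, ring in enumerate(spec.rings):
        files: list[_File] = []
        if ring.cell_type == "epidermis":
            n = ring.n_files
            phase = ring_phase - 0.5 / n
            for f in range(n):
                ctype = "trichoblast" if f % 2 == 0 else "atrichoblast"
                if ctype == "atrichoblast" and spec.conduit_mode:
                    n_axial = max(1, ring.n_axial // 2)
                else:
                    n_axial = ring.n_axial
                files.append(
                    _File(
                        r, f, ctype, phase + f / n, phase + (f + 1) / n,
                        _z_bounds(n_axial, spec.axial_jitter, rng),
                    )
                )
        else:
            n = ring.n_files
            ring_phase = rng.uniform(0.0, 1.0) if r > 0 else 0.0
            for f in range(n):
                files.append(
                    _File(
                        r, f, ring.cell_type, ring_phase + f / n,
                        ring_phase + (f + 1) / n,
                        _z_bounds(ring.n_axial, spec.axial_jitter, rng),
                    )
                )
        per_ring.append(files)
    _assign_cell_ids(per_ring)
    return per_ring


def _assign_cell_ids(per_ring: list[list[_File]]) -> None:
    """Sequential 1-based cell ids, identical between the graph generator
    and the rasterizer (label 0 stays reserved for background)."""
    next_id = 1
    for files in per_ring:
        for fl in files:
            fl.cell_ids = list(range(next_id, next_id + fl.n_axial))
            next_id += fl.n_axial


def _circular_overlap(a: _File, b: _File) -> bool:
    """True when the two angular sectors overlap with positive measure."""
    for shift in (-1.0, 0.0, 1.0):
        lo = max(a.theta0, b.theta0 + shift)
        hi = min(a.theta1, b.theta1 + shift)
        if hi - lo > _EPS:
            return True
    return False


def _axial_pairs(fa: _File, fb: _File):
    """Index pairs (i, j) of cells in the two files whose axial intervals
    overlap with positive length (two-pointer sweep)."""
    i = j = 0
    while i < fa.n_axial and j < fb.n_axial:
        lo_i, hi_i = fa.z_interval(i)
        lo_j, hi_j = fb.z_interval(j)
        if min(hi_i, hi_j) - max(lo_i, lo_j) > _EPS:
            yield i, j
        if hi_i <= hi_j:
            i += 1
        else:
            j += 1


def _interface_area_params(ra: RingSpec, rb: RingSpec) -> tuple[float, float]:
    if ra is rb:
        return ra.interface_area_mean_um2, ra.interface_area_cv
    mean = math.sqrt(ra.interface_area_mean_um2 * rb.interface_area_mean_um2)
    cv = 0.5 * (ra.interface_area_cv + rb.interface_area_cv)
    return mean, cv


def _lognormal(rng: np.random.Generator, mean: float, cv: float, size: int):
    if cv == 0:
        return np.full(size, mean)
    sigma2 = math.log1p(cv * cv)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, math.sqrt(sigma2), size)


def generate_organ(spec: OrganSpec) -> nx.Graph:
    """Generate the annotated cell graph of a synthetic organ.

    Nodes carry ``cell_type``, ``ring``, ``file``, ``axial``, ``boundary``
    (first/last axial layer), ``buffer`` (initially False), ``area_um2`` and
    ``volume_um3``; edges carry positive ``area_um2`` drawn from the
    per-ring lognormal interface model.  The returned graph is connected.
    """
    rng = np.random.default_rng([spec.seed, 1])
    per_ring = _build_files(spec)
    radii = spec.radii_um
    graph = nx.Graph()

    for r, files in enumerate(per_ring):
        r_in, r_out = radii[r], radii[r + 1]
        r_mid = 0.5 * (r_in + r_out)
        thickness = r_out - r_in
        for fl in files:
            width = (fl.theta1 - fl.theta0) * 2.0 * math.pi * max(r_mid, 1.0)
            jitter = _lognormal(rng, 1.0, spec.size_jitter_cv, fl.n_axial)
            for a, cid in enumerate(fl.cell_ids):
                z0, z1 = fl.z_interval(a)
                length = (z1 - z0) * spec.organ_length_um
                area = 2.0 * (
                    width * length + width * thickness + length * thickness
                )
                volume = width * length * thickness
                graph.add_node(
                    cid,
                    cell_type=fl.cell_type,
                    ring=r,
                    file=fl.index,
                    axial=a,
                    boundary=(a == 0 or a == fl.n_axial - 1),
                    buffer=False,
                    area_um2=float(area * jitter[a]),
                    volume_um3=float(volume * jitter[a] ** 1.5),
                )

    edges: list[tuple[int, int]] = []
    edge_params: list[tuple[float, float]] = []

    def connect(fa: _File, fb: _File, pairs) -> None:
        params = _interface_area_params(spec.rings[fa.ring], spec.rings[fb.ring])
        for i, j in pairs:
            edges.append((fa.cell_ids[i], fb.cell_ids[j]))
            edge_params.append(params)

    for r, files in enumerate(per_ring):
        # axial neighbours within each file
        for fl in files:
            params = _interface_area_params(spec.rings[r], spec.rings[r])
            for a in range(fl.n_axial - 1):
                edges.append((fl.cell_ids[a], fl.cell_ids[a + 1]))
                edge_params.append(params)
        # circumferential neighbours between adjacent files of the ring
        # (a 2-file ring touches on two walls but forms a single interface)
        n = len(files)
        if n > 1:
            for f in range(n if n > 2 else 1):
                fa, fb = files[f], files[(f + 1) % n]
                connect(fa, fb, _axial_pairs(fa, fb))
        # radial neighbours with the next ring outward
        if r + 1 < len(per_ring):
            for fa in files:
                for fb in per_ring[r + 1]:
                    if _circular_overlap(fa, fb):
                        connect(fa, fb, _axial_pairs(fa, fb))

    # one draw per edge, a single pass through the generator
    means = np.array([p[0] for p in edge_params])
    cvs = np.array([p[1] for p in edge_params])
    sigma2 = np.log1p(cvs * cvs)
    mu = np.log(means) - sigma2 / 2.0
    areas = np.exp(rng.normal(mu, np.sqrt(sigma2)))

    for (a, b), area in zip(edges, areas):
        add_interface(graph, a, b, area)

    if not nx.is_connected(graph):
        raise OrganSpecError("generated organ graph is not connected")
    return graph


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------


def rasterize_organ(spec: OrganSpec, voxel_um: tuple[float, float, float]):
    """Rasterize the organ into a labeled volume (z, y, x axis order).

    Returns a :class:`organtopo.extraction.LabeledVolume` whose labels match
    the node ids of :func:`generate_organ` on the same spec; label 0 is the
    exterior background.  The face-adjacency graph of the rasterization
    equals the generated graph up to interface-area discretization (oblique
    file boundaries can leave single-voxel-face corner contacts, removed by
    the standard small-interface filter).
    """
    from .extraction import LabeledVolume

    dz, dy, dx = voxel_um
    if min(dz, dy, dx) <= 0:
        raise ValueError("voxel dimensions must be positive")
    per_ring = _build_files(spec)
    radii = spec.radii_um
    r_outer = radii[-1]
    length = spec.organ_length_um

    nz = max(1, int(round(length / dz)))
    ny = max(1, int(round(2 * r_outer / dy)))
    nxv = max(1, int(round(2 * r_outer / dx)))
    zc = (np.arange(nz) + 0.5) * dz
    yc = (np.arange(ny) + 0.5) * dy - r_outer
    xc = (np.arange(nxv) + 0.5) * dx - r_outer

    yy, xx = np.meshgrid(yc, xc, indexing="ij")
    rr = np.hypot(yy, xx)
    theta = (np.arctan2(yy, xx) / (2.0 * math.pi)) % 1.0
    ring_of = np.searchsorted(radii[1:-1], rr, side="right")
    inside = rr < r_outer

    labels = np.zeros((nz, ny, nxv), dtype=np.int32)
    z_frac = zc / length  # axial position of each slab, in (0, 1)

    for r, files in enumerate(per_ring):
        mask = inside & (ring_of == r)
        if not mask.any():
            continue
        n = len(files)
        phase = files[0].theta0  # uniform tiling: file f starts at phase + f/n
        fidx = np.floor(((theta[mask] - phase) % 1.0) * n).astype(int) % n
        ys, xs = np.nonzero(mask)
        for f in range(n):
            fl = files[f]
            sel = fidx == f
            if not sel.any():
                continue
            a_of_z = np.clip(
                np.searchsorted(fl.z_bounds, z_frac, side="right") - 1,
                0,
                fl.n_axial - 1,
            )
            ids = np.asarray(fl.cell_ids, dtype=np.int32)[a_of_z]
            labels[:, ys[sel], xs[sel]] = ids[:, None]

    present = np.unique(labels)
    all_ids = {
        cid for files in per_ring for fl in files for cid in fl.cell_ids
    }
    missing = sorted(all_ids - set(int(v) for v in present))
    if missing:
        raise ValueError(
            f"voxel size {voxel_um} too coarse: cell {missing[0]} "
            f"(and {len(missing) - 1} others) received no voxels"
        )
    return LabeledVolume(labels=labels, voxel_um=(dz, dy, dx))


def generate_signal_volume(
    volume,
    annotation: dict[int, str],
    per_type_mean: dict[str, float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Synthetic fluorescence channel for a labeled volume.

    Every voxel of a cell draws from Normal(per_type_mean[cell_type],
    noise_sd), truncated at 0; background voxels are 0.  Stands in for a
    fluorescein imaging channel.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if any(v < 0 for v in per_type_mean.values()):
        raise ValueError("per_type_mean values must be nonnegative")
    rng = np.random.default_rng(seed)
    labels = volume.labels
    signal = np.zeros(labels.shape, dtype=float)
    for cid in np.unique(labels):
        cid = int(cid)
        if cid in volume.excluded_labels:
            continue
        ctype = annotation.get(cid)
        if ctype is None or ctype not in per_type_mean:
            raise KeyError(f"cell {cid} ({ctype!r}) missing from per_type_mean")
        mask = labels == cid
        vals = np.full(int(mask.sum()), float(per_type_mean[ctype]))
        if noise_sd > 0:
            vals = rng.normal(vals, noise_sd)
        signal[mask] = np.clip(vals, 0.0, None)
    return signal


def inject_artifacts(
    graph: nx.Graph, rate: float, max_area_um2: float, seed: int = 0
) -> nx.Graph:
    """Add spurious small edges mimicking segmentation artifacts.

    ``round(rate * E)`` edges are added between randomly chosen non-adjacent,
    non-vascular cell pairs, with areas uniform in (0, max_area_um2).
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0, 1]")
    if not 0.0 < max_area_um2 < 2.0:
        raise ValueError("max_area_um2 must lie in (0, 2)")
    out = graph.copy()
    n_new = int(round(rate * graph.number_of_edges()))
    if n_new == 0:
        return out
    rng = np.random.default_rng(seed)
    candidates = [
        n for n, d in graph.nodes(data=True) if d.get("cell_type") != "vasculature"
    ]
    added = 0
    while added < n_new:
        a, b = rng.choice(candidates, size=2, replace=False)
        a, b = int(a), int(b)
        if out.has_edge(a, b):
            continue
        add_interface(out, a, b, float(rng.uniform(0.0, max_area_um2)))
        added += 1
    return out
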