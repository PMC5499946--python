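# Methods

## The network model

A tissue is represented as an undirected graph: one node per cell, one edge
per shared wall interface, with the interface area in µm² as the edge
attribute. Node attributes carry the cell-type annotation (trichoblast,
atrichoblast, outer/inner cortex, endodermis, vasculature, or unassigned),
a `boundary` flag for cells at the imaging cut, a `buffer` flag, and the
cell's wall area (µm²) and volume (µm³). All graph invariants (no
self-loops, no duplicate interfaces, strictly positive areas) are enforced
at construction.

### Extraction from labeled volumes

`extract_adjacency` walks a 3D integer-labeled volume in (z, y, x) order
and connects two labels wherever they share at least one voxel face
(6-connectivity; diagonal voxel contacts are not physical shared walls).
The edge area is the sum of the physical areas of the shared faces
(dy·dx, dz·dx, dz·dy by orientation), so it is exact for the given
segmentation rather than an approximation. Labels in `excluded_labels`
(background, air spaces) never form edges; faces against them count toward
a cell's exterior surface only. The implementation is vectorized over
whole label planes; its equivalence to a naive per-voxel face scan is
asserted on randomized volumes in the test suite.

### Interface filtering

Interfaces below 2 µm² are removed (strict `<`, so an area of exactly
2 µm² survives) **unless either endpoint is vascular** — tiny interfaces
elsewhere are overwhelmingly segmentation artifacts, while vascular
interfaces are legitimately small. The threshold is a parameter;
2 µm² is the default everywhere. Filtering removes edges only, never
nodes, and is idempotent.

### Boundary buffering

Cells within `depth` graph hops (multi-source BFS) of a boundary-flagged
cell are marked as buffer cells. They remain in the network for every
centrality computation — deleting them would change the centralities of
retained cells, which the test suite demonstrates — and are excluded only
at reporting time (`report_central`), together with vascular cells, whose
quantitative values are unreliable in real segmentations. The default
depth is 2 hops; hop-based rather than micron-based depth was chosen
because the buffer is a topological device.

## Topological measures

Let N be the number of nodes in the whole network (buffer and vasculature
included). For a node v, BC(v) = Σ_{s≠v≠t} σ_st(v)/σ_st over unordered
pairs, multiplied by 2/((N−1)(N−2)), so a star center scores exactly 1.
Edge BC is normalized by 2/(N(N−1)). Ties among equal-length shortest
paths use standard Brandes fractional counting. No density normalization
is applied beyond these pair-count factors. Weighted BC uses edge length =
1/area, so larger interfaces make shorter steps; the same node
normalization is applied. For mean/sd summaries, BC is log₁₀-transformed;
cells with BC = 0 are excluded from the transformed set (no pseudo-count),
with the excluded count reported.

Betweenness is computed by igraph's C implementation behind the module
surface; the tests pin it to a brute-force all-pairs shortest-path
enumeration (1e-12 agreement on hundreds of random graphs) and to closed
forms (star, path, cycle). Current-flow ("random walk") edge betweenness
is provided as a separate, clearly named measure via networkx's solver;
its unnormalized output is half the unordered-pair flow sum, which is
corrected before applying 2/(N(N−1)), making it coincide with
shortest-path edge BC on trees. On disconnected inputs, betweenness is
computed per component with the whole-graph N kept in the normalization
(the stated formula), with a warning.

## Statistics

Degree distributions (discrete) are compared with a chi-squared test of
homogeneity on cells pooled across the replicates of each group; the
category set is the union of observed degree values, and categories with
expected counts below 5 are merged into their nearest neighbour for test
validity. BC distributions (continuous) are compared with the two-sample
Kolmogorov–Smirnov test on pooled raw values (asymptotic p). Significance
is Bonferroni-controlled at α/m with m = 3200 pairwise comparisons by
default (0.05/3200 = 1.5625×10⁻⁵); m is a parameter since the appropriate
comparison count depends on the study design. Binned distribution plots
report the mean ± sample sd of per-replicate normalized frequencies.

Robustness across replicates is summarized by the coefficient of variation
CV = sd/mean (sample sd, n−1) of log₁₀ BC per replicate. CV is computed
literally as sd/mean: log₁₀ BC means are negative, so raw CVs are negative
and their magnitude is what plots show. Groups are compared by one-way
ANOVA on replicate CVs plus Tukey's HSD; a group is flagged *distinct*
when it differs from every other group at the stated level. When all CVs
are identical the ANOVA is degenerate and p = 1 is reported.

## Mutual information

MI is reported in bits. Estimators: Kraskov–Stögbauer–Grassberger (KSG,
algorithm 1, Chebyshev metric, k = 3 by default) for
continuous–continuous; the Ross kNN estimator for discrete–continuous
(per-class k is capped at the class size minus one; singleton classes are
excluded); the plug-in entropy sum for discrete–discrete. A deterministic
1e-10-scale jitter breaks ties before tree queries, seeded so repeated
calls agree. kNN estimates are noisy and may come out slightly negative;
they are reported as-is, with an optional floor at zero — silent clipping
would hide estimator bias. The KSG estimator recovers the closed-form
Gaussian MI (−½log₂(1−ρ²)) within 0.05 bits at n = 10⁴ for ρ ∈ {0, 0.5,
0.9}, and cross-checks against scikit-learn's independent implementation.

## Distribution-distance clustering

The distance between two groups is the test statistic of their
distribution comparison (chi-squared value for degree, KS statistic for
BC); the matrix is symmetric with a zero diagonal but is not assumed
metric. Groups are clustered by average linkage (UPGMA) on the precomputed
matrix and cut at k = 3 clusters by default; dendrograms export as Newick
text. A `--distance inverse` switch replaces each statistic by its
reciprocal for compatibility with an alternative reading in which
*similar* groups are maximally distant; the direct statistic is the
default because it makes similar groups close.

## Transport quantification

Per-cell tracer concentration = total signal inside the cell ÷ (voxel
count × voxel volume), i.e. volume-normalized internal signal. By
construction Σ(concentration × cell volume) over cells equals the total
labeled signal exactly (asserted to 1e-9 relative). Concentrations are
mean-normalized over the pooled comparison set (both epidermal cell types
of a genotype pooled across replicates), so the pooled mean is 1 and
normalization is idempotent. The atrichoblast–trichoblast differential is
tested with Welch's t-test at α = 0.001 (a pooled-variance option exists);
a warning is emitted below 40 cells per type, the protocol target for
this assay.

## The synthetic organ generator

The generator emulates the cellular architecture of an unexpanded
hypocotyl as a cylinder of concentric rings — vasculature core,
endodermis, inner and outer cortex, epidermis — each tiled by `n_files`
circumferential cell files, each file by `n_axial` cells. Edges connect
axial neighbours within a file, circumferentially adjacent files within a
ring, and radially adjacent rings, with adjacency decided by positive
overlap of the cells' angular sectors and axial intervals. Default scale
is ~3000 cells (a real organ's order of magnitude); a ~700-cell toy preset
keeps tests fast.

Design choices that matter:

- **Trichoblast bridging.** The epidermal ring carries twice the files of
  the ring beneath it, alternating trichoblast/atrichoblast, phase-shifted
  by half a file so each trichoblast file straddles a cortical file
  junction (radial contact with two files) while each atrichoblast file
  sits over one. This reproduces the trichoblast > atrichoblast degree
  differential by construction (~1.3× at the default spec). Other
  file-count ratios cannot tile the cylinder under this rule and are
  rejected.
- **Random ring phases.** Each internal ring receives a random angular
  phase (the epidermis stays registered to the ring beneath it). Real cell
  layers are not angularly registered, and generic phases keep
  file-boundary rays of adjacent rings from coinciding — which is also
  what makes the rasterization's face-adjacency graph match the generated
  graph instead of acquiring staircase corner contacts.
- **Staggered axial boundaries.** Interior cell boundaries along each file
  are jittered by up to 30% of a cell height (`axial_jitter`). This is
  what makes replicate organs (seed, seed+1, seed+2) topologically
  distinct rather than identical lattices; setting it to 0 yields an
  unstaggered lattice whose rasterize→extract round trip is exact.
- **Epidermal axial cell length.** Epidermal files carry half the axial
  cell count of internal rings (epidermal cells are axially longer), so in
  the null organ both epidermal cell types share the same axial-conduit
  role and their BC distributions are statistically indistinguishable at
  the corrected level, despite the degree differential — the analogue of
  the field observation that local connectivity does not by itself set
  path length. In a fully regular lattice with equal cell lengths
  everywhere, the trichoblasts' doubled cortical attachment wins enough
  shortest-path tie-shares to shift their BC by a detectable ~2×; giving
  the epidermis a shared axial through-traffic role drowns that local
  term. This is a deliberate modeling device, not a quantitative claim
  about real cell lengths.
- **Conduit mode.** `conduit_mode=True` halves the atrichoblast axial
  count once more. Atrichoblast files then form the organ's fastest axial
  route and their BC rises by orders of magnitude (KS D ≈ 0.99 against
  trichoblasts), the generator's analogue of the epidermal conduit. The
  mechanism — axial cell length — is one plausible choice; the anatomical
  cause of the real effect (cell length, file continuity, or junction
  geometry) is not established, and the generator makes no claim there.
- **Interface areas** are drawn lognormally per interface class with means
  ordered cortex > endodermis > epidermis > vasculature (cortical cells
  are largest) and CV 0.3 (0.8 for the heterogeneous vasculature, whose
  mean of 6 µm² deliberately places a tail below the 2 µm² filter
  threshold — those edges must survive filtering via the vasculature
  exemption). Non-vascular means sit far enough above 2 µm² that a
  sub-threshold draw is vanishingly rare, so artifact filtering restores
  an artifact-injected organ exactly.
- **Cell geometry.** Per-cell wall area and volume follow from the annular
  sector dimensions with a shared lognormal size jitter (CV 0.1), applied
  to area and, at power 1.5, to volume — so area and volume are strongly
  mutually informative while neither carries information about BC beyond
  cell type, matching the qualitative MI pattern the pipeline should
  recover.
- **Artifacts.** `inject_artifacts` adds `round(rate × E)` spurious edges
  between random non-adjacent, non-vascular pairs with areas uniform in
  (0, max_area); with max_area < 2 µm² the standard filter removes all of
  them, restoring the original edge set exactly.

### Rasterization

`rasterize_organ` assigns each voxel of a Cartesian (z, y, x) grid to a
cell by its cylindrical coordinates, sharing the exact file layout
(including jittered boundaries and ring phases) with the graph generator,
with label 0 as exterior background. Any cell receiving zero voxels raises
an error naming it. Discretization caveats: with `axial_jitter = 0` and
generic ring phases the face-adjacency graph of the rasterization equals
the generated graph exactly at fine voxels (asserted in tests); with
staggered boundaries, interface slivers thinner than a voxel may be
missed — the rasterization never *invents* contacts, which is the asserted
direction.

### What the generator does and does not emulate

It reproduces: radial ring organization, cell files, the trichoblast
bridging rule and degree differential, replicate-to-replicate topological
noise, a filterable artifact model, boundary layers, and a controllable
epidermal BC contrast. It does not attempt: real ecotype geometry or
interface-area calibration, growth or mechanics, realistic vasculature
anatomy (the synthetic vasculature is an ordinary innermost ring, and the
generated organ's BC maximum sits in the epidermal conduit rather than
the vascular core), or mutant-specific architectures beyond the
conduit/no-conduit and axial-count knobs. Tests passing on synthetic
organs therefore validate the *pipeline* — extraction, normalization,
statistics, clustering — not any quantitative claim about real tissue.

## Problem sizes and numerical conventions

Default analyses use ~3000-cell organs in biological triplicate; oracle
checks use 5–30-node random graphs (200 of them) and ≤10³-voxel random
volumes (100); null calibrations use 10³ simulated pairs; MI accuracy uses
n = 10⁴ Gaussian samples. Angular/axial interval overlap uses a 1e-9
tolerance so touching intervals do not connect. Replicates derive from
consecutive seeds (seed, seed+1, seed+2); a single integer seed drives
layout, interface areas and signal noise through separate documented
streams. All tabular outputs are CSV; dendrograms are Newick; heat maps
are two-column text consumable by MorphoGraphX.

## Known limitations

- The KS test's asymptotic p-values are used (as is conventional); at very
  small group sizes the exact test would differ.
- The chi-squared category-merging rule (nearest neighbour, expected < 5)
  is one standard choice; results can differ slightly from other pooling
  rules when degree supports are sparse.
- The Ross discrete–continuous MI estimator excludes singleton classes,
  which biases the estimate slightly downward for very sparse discrete
  variables.
- `quantify_concentration` requires non-negative integer labels (bincount
  semantics), consistent with the exchange formats.
- The conduit-off indistinguishability of epidermal BC holds at the
  default spec's scale and replicate structure; a much larger organ (or
  many more replicates) would eventually resolve the residual ~2× local
  tie-share asymmetry of the bridging rule, as any consistent test
  eventually resolves any fixed structural difference.
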