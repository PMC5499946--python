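"""Mutual information between cell features, and clustering of groups by
distribution-test distances.

Mutual information is reported in bits of Shannon entropy and estimated
nonparametrically: the Kraskov-Stoegbauer-Grassberger (KSG) kNN estimator
for continuous-continuous pairs, the Ross kNN estimator for
discrete-continuous pairs, and the plug-in entropy sum for
discrete-discrete pairs.  kNN estimates are noisy and may come out slightly
negative; they are reported as-is unless floored at zero on request.

Group-level distribution similarity uses the pairwise test statistic
(chi-squared for degree, Kolmogorov-Smirnov for betweenness) as a distance,
clustered by average-linkage (UPGMA) agglomeration on the precomputed
matrix, with Newick dendrogram export.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial import cKDTree
from scipy.spatial.distance import squareform
from scipy.special import digamma

from .stats import GroupedSample, compare_bc, compare_degree

__all__ = [
    "mutual_information",
    "mi_panel",
    "distribution_distance_matrix",
    "cluster_groups",
]

_LN2 = np.log(2.0)


def _jitter(x: np.ndarray, seed: int) -> np.ndarray:
    """Break ties in continuous samples with tiny deterministic noise
    (standard practice for kNN MI estimators)."""
    rng = np.random.default_rng(seed)
    scale = 1e-10 * max(np.std(x), 1.0)
    return x + rng.normal(0.0, scale, x.shape)


def _ksg_mi(x: np.ndarray, y: np.ndarray, k: int, seed: int) -> float:
    """KSG estimator (algorithm 1), Chebyshev metric, result in nats."""
    n = len(x)
    x = _jitter(x.astype(float), seed)
    y = _jitter(y.astype(float), seed + 1)
    xy = np.column_stack([x, y])
    tree_xy = cKDTree(xy)
    # distance to the k-th neighbour in the joint space (excluding self)
    eps = tree_xy.query(xy, k=k + 1, p=np.inf)[0][:, -1]
    tree_x = cKDTree(x[:, None])
    tree_y = cKDTree(y[:, None])
    r = eps - 1e-15  # strictly-within-eps counts, as in KSG algorithm 1
    nx_ = tree_x.query_ball_point(x[:, None], r=r, p=np.inf, return_length=True) - 1
    ny_ = tree_y.query_ball_point(y[:, None], r=r, p=np.inf, return_length=True) - 1
    return float(
        digamma(k) + digamma(n) - np.mean(digamma(nx_ + 1) + digamma(ny_ + 1))
    )


def _ross_mi(d: np.ndarray, c: np.ndarray, k: int, seed: int) -> float:
    """Ross estimator for MI between a discrete and a continuous variable,
    in nats.  Classes smaller than k+1 fall back to a per-class k; singleton
    classes are excluded from the average."""
    c = _jitter(c.astype(float), seed)
    n = len(c)
    tree_all = cKDTree(c[:, None])
    psi_terms = []
    weights = []
    for val in np.unique(d):
        mask = d == val
        n_c = int(mask.sum())
        if n_c < 2:
            continue
        k_c = min(k, n_c - 1)
        sub = c[mask]
        tree_c = cKDTree(sub[:, None])
        dist = tree_c.query(sub[:, None], k=k_c + 1, p=np.inf)[0][:, -1]
        m = tree_all.query_ball_point(
            sub[:, None], r=dist, p=np.inf, return_length=True
        ) - 1
        psi_terms.append(np.sum(digamma(k_c) - digamma(n_c) - digamma(m)))
        weights.append(n_c)
    n_used = sum(weights)
    if n_used == 0:
        raise ValueError("all discrete classes are singletons")
    return float(np.sum(psi_terms) / n_used + digamma(n))


def _plugin_mi(x: np.ndarray, y: np.ndarray) -> float:
    """Plug-in MI for two discrete variables, in nats."""
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    joint = np.zeros((xi.max() + 1, yi.max() + 1))
    np.add.at(joint, (xi, yi), 1.0)
    joint /= joint.sum()
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float(np.sum(joint[nz] * np.log(joint[nz] / (px @ py)[nz])))


def mutual_information(
    x,
    y,
    kind_x: str = "continuous",
    kind_y: str = "continuous",
    k: int = 3,
    floor_at_zero: bool = False,
    seed: int = 0,
) -> float:
    """Estimated mutual information between paired samples, in bits.

    ``kind_x``/``kind_y`` select the estimator: KSG for two continuous
    variables, Ross for a discrete-continuous pair, plug-in for two
    discrete variables.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D arrays of equal length")
    if not (np.isfinite(x.astype(float)).all() and np.isfinite(y.astype(float)).all()):
        raise ValueError("x and y must not contain missing/non-finite values")
    for kind in (kind_x, kind_y):
        if kind not in ("continuous", "discrete"):
            raise ValueError(f"unknown variable kind {kind!r}")
    n = len(x)
    if kind_x == "continuous" or kind_y == "continuous":
        if k >= n:
            raise ValueError(f"k = {k} must be < n = {n}")
        if k < 1:
            raise ValueError("k must be >= 1")

    if kind_x == "continuous" and kind_y == "continuous":
        mi = _ksg_mi(x, y, k, seed) / _LN2
    elif kind_x == "discrete" and kind_y == "discrete":
        mi = _plugin_mi(x, y) / _LN2
    elif kind_x == "discrete":
        mi = _ross_mi(x, y.astype(float), k, seed) / _LN2
    else:
        mi = _ross_mi(y, x.astype(float), k, seed) / _LN2
    if floor_at_zero:
        mi = max(mi, 0.0)
    return mi


#: Feature pairs of the MI panel, with variable kinds.
MI_PAIRS = (
    ("area_um2", "volume_um3", "continuous", "continuous"),
    ("area_um2", "degree", "continuous", "discrete"),
    ("degree", "bc", "discrete", "continuous"),
    ("area_um2", "bc", "continuous", "continuous"),
    ("volume_um3", "bc", "continuous", "continuous"),
)


def mi_panel(
    features: pd.DataFrame,
    by: str | None = "cell_type",
    k: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """MI between geometric (area, volume) and topological (degree, bc)
    per-cell features, per cell-type group.

    Warns below n = 20 cells per estimate.
    """
    import warnings

    required = {"area_um2", "volume_um3", "degree", "bc"}
    if not required.issubset(features.columns):
        raise ValueError(f"features must have columns {sorted(required)}")
    groups = (
        [(None, features)] if by is None else list(features.groupby(by, sort=True))
    )
    rows = []
    for label, df in groups:
        if len(df) < 20:
            warnings.warn(
                f"group {label!r}: only {len(df)} cells for MI estimation",
                stacklevel=2,
            )
        for fx, fy, kx, ky in MI_PAIRS:
            rows.append(
                {
                    "group": label,
                    "feature_x": fx,
                    "feature_y": fy,
                    "mi_bits": mutual_information(
                        df[fx].to_numpy(), df[fy].to_numpy(), kx, ky, k=k, seed=seed
                    ),
                    "n": len(df),
                }
            )
    return pd.DataFrame(rows)


def distribution_distance_matrix(
    groups: list[GroupedSample],
    measure: str = "bc",
    inverse: bool = False,
) -> tuple[np.ndarray, list[str]]:
    """Pairwise distribution-test distance matrix over groups.

    Entry (i, j) is the chi-squared statistic (``measure="degree"``) or the
    KS statistic (``measure="bc"``) between groups i and j; the diagonal is
    zero.  ``inverse=True`` uses the reciprocal statistic instead (an
    alternative reading in which similar groups are maximally distant).
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    if measure not in ("degree", "bc"):
        raise ValueError("measure must be 'degree' or 'bc'")
    compare = compare_degree if measure == "degree" else compare_bc
    k = len(groups)
    mat = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            stat = compare(groups[i], groups[j]).statistic
            if inverse:
                stat = np.inf if stat == 0 else 1.0 / stat
            mat[i, j] = mat[j, i] = stat
    return mat, [g.label for g in groups]


def cluster_groups(
    matrix: np.ndarray,
    labels: list[str],
    k: int = 3,
    method: str = "average",
) -> tuple[np.ndarray, np.ndarray, str]:
    """Agglomerative clustering of groups on a precomputed distance matrix.

    Returns (cluster labels for a k-cluster cut, scipy linkage matrix,
    Newick dendrogram text).  Deterministic given the matrix and linkage
    method.
    """
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    if matrix.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if n != len(labels):
        raise ValueError("labels must match the matrix size")
    if not np.allclose(matrix, matrix.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(matrix), 0.0):
        raise ValueError("distance matrix must have a zero diagonal")
    if k > n:
        raise ValueError(f"k = {k} exceeds the number of groups ({n})")
    z = linkage(squareform(matrix, checks=False), method=method)
    assignments = fcluster(z, t=k, criterion="maxclust")
    newick = _linkage_to_newick(z, labels)
    return assignments, z, newick


def _linkage_to_newick(z: np.ndarray, labels: list[str]) -> str:
    from skbio.tree import TreeNode

    tree = TreeNode.from_linkage_matrix(z, labels)
    return str(tree).strip()
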