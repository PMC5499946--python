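"""Per-cell tracer concentration from a co-registered signal channel.

Quantifies the steady-state distribution of a small fluorescent tracer
(fluorescein) in a segmented organ: per-cell concentration is the total
signal inside the cell divided by the cell's physical volume; values are
mean-normalized over the pooled comparison set, and the atrichoblast vs
trichoblast differential is tested with a two-sample t-test (Welch by
default) at alpha = 0.001.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from .extraction import LabeledVolume
from .stats import ComparisonResult

__all__ = ["quantify_concentration", "mean_normalize", "compare_cell_types"]


def quantify_concentration(
    volume: LabeledVolume, signal: np.ndarray
) -> pd.DataFrame:
    """Per-cell tracer concentration (signal per cubic micron).

    concentration = sum of signal over the cell's voxels divided by
    (voxel count x voxel volume); background/excluded labels are skipped.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.shape != volume.labels.shape:
        raise ValueError(
            f"signal shape {signal.shape} != labels shape {volume.labels.shape}"
        )
    dz, dy, dx = volume.voxel_um
    voxel_volume = dz * dy * dx
    labels = volume.labels.ravel()
    flat = signal.ravel()
    ids = np.unique(labels)
    ids = ids[~np.isin(ids, list(volume.excluded_labels))]
    if ids.size == 0:
        raise ValueError("no labeled cells in the volume")
    all_sums = np.bincount(labels, weights=flat)
    all_counts = np.bincount(labels)
    sums = all_sums[ids]
    counts = all_counts[ids]
    return pd.DataFrame(
        {
            "cell_id": ids.astype(int),
            "n_voxels": counts,
            "volume_um3": counts * voxel_volume,
            "raw_concentration": sums / (counts * voxel_volume),
        }
    )


def mean_normalize(values, pool_mask=None) -> np.ndarray:
    """Divide values by the mean of the pooled comparison set.

    ``pool_mask`` selects the cells defining the mean (default: all); the
    pooled mean of the output is 1.  Idempotent: normalizing an already
    normalized set is the identity.
    """
    values = np.asarray(values, dtype=float)
    mask = np.ones(len(values), dtype=bool) if pool_mask is None else np.asarray(pool_mask, dtype=bool)
    mean = values[mask].mean()
    if mean == 0:
        raise ValueError("pool mean is 0; normalization undefined")
    return values / mean


def compare_cell_types(
    table: pd.DataFrame,
    type_a: str = "atrichoblast",
    type_b: str = "trichoblast",
    value_column: str = "normalized_concentration",
    alpha: float = 0.001,
    equal_var: bool = False,
    min_cells: int = 40,
) -> ComparisonResult:
    """Two-sample t-test of normalized concentration between two cell
    types (Welch's by default).  Warns below the protocol target of 40
    segmented cells per type."""
    for t in (type_a, type_b):
        if not (table["cell_type"] == t).any():
            raise ValueError(f"cell type {t!r} absent from the table")
    xa = table.loc[table["cell_type"] == type_a, value_column].to_numpy()
    xb = table.loc[table["cell_type"] == type_b, value_column].to_numpy()
    if len(xa) < 2 or len(xb) < 2:
        raise ValueError("need >= 2 cells per type")
    if min(len(xa), len(xb)) < min_cells:
        warnings.warn(
            f"fewer than {min_cells} cells per type "
            f"({type_a}: {len(xa)}, {type_b}: {len(xb)})",
            stacklevel=2,
        )
    res = sps.ttest_ind(xa, xb, equal_var=equal_var)
    return ComparisonResult(
        type_a, type_b, "t_test", float(res.statistic), float(res.pvalue), alpha
    )
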