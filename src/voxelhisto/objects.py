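"""Within-cluster marker-object statistics.

Once significant clusters are known at map resolution, the
high-resolution binary images are revisited: connected marker objects
(e.g. amyloid plaques) are labeled, assigned to clusters, and their
counts and sizes are tabulated per individual so that count differences
can be tested and size tables exported for mixed-model analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

__all__ = [
    "label_objects",
    "objects_in_cluster",
    "compare_counts",
    "export_size_table",
    "upsample_mask",
    "CountComparison",
]

MEMBERSHIP_RULES = ("centroid", "any_overlap", "majority")


def label_objects(binary_volume: np.ndarray, mode: str = "planewise") -> tuple[np.ndarray, int]:
    """Label connected marker objects in a binary image or volume.

    ``planewise`` (the default) computes 2D connected components
    independently per coronal slice (axis 0 of a 3D volume), matching the
    convention that objects are defined within the sectioning plane;
    ``volumetric`` uses full 3D connectivity.  2D inputs are treated as a
    single slice.  Returns (labels, n_objects) with labels unique across
    slices.
    """
    vol = np.asarray(binary_volume) > 0
    if mode not in ("planewise", "volumetric"):
        raise ValueError(f"unknown mode {mode!r}")
    if vol.ndim == 2 or mode == "volumetric":
        structure = np.ones((3,) * vol.ndim)
        labels, n = ndimage.label(vol, structure=structure)
        return labels.astype(np.int32), int(n)
    if vol.ndim != 3:
        raise ValueError("expected a 2D image or 3D volume")
    labels = np.zeros(vol.shape, dtype=np.int32)
    offset = 0
    structure = np.ones((3, 3))
    for z in range(vol.shape[0]):
        lab, n = ndimage.label(vol[z], structure=structure)
        labels[z] = np.where(lab > 0, lab + offset, 0)
        offset += n
    return labels, offset


def upsample_mask(mask: np.ndarray, bin_window, target_shape) -> np.ndarray:
    """Nearest-neighbor upsampling of a map-resolution mask to image grid.

    Each map voxel is replicated over its bin window and the result is
    cropped to the (possibly non-divisible) target shape.
    """
    mask = np.asarray(mask)
    if np.isscalar(bin_window):
        bin_window = (int(bin_window),) * mask.ndim
    out = mask
    for ax, w in enumerate(bin_window):
        out = np.repeat(out, w, axis=ax)
    return out[tuple(slice(0, s) for s in target_shape)]


def objects_in_cluster(
    labeled: np.ndarray,
    cluster_mask_highres: np.ndarray,
    individual: str = "",
    group: str = "",
    rule: str = "centroid",
) -> pd.DataFrame:
    """Tabulate labeled objects lying within a high-resolution cluster mask.

    ``cluster_mask_highres`` is either boolean (one cluster) or an
    integer map of cluster ids (0 = outside).  Membership rules:
    ``centroid`` (default) assigns an object to the cluster containing
    its centroid voxel; ``any_overlap`` to the cluster covering most of
    the overlapping voxels provided at least one overlaps; ``majority``
    requires more than half the object's voxels inside one cluster.

    Returns a tidy table (individual, group, cluster, object, size,
    centroid coordinates); objects outside every cluster are dropped.
    """
    if rule not in MEMBERSHIP_RULES:
        raise ValueError(f"rule must be one of {MEMBERSHIP_RULES}")
    labeled = np.asarray(labeled)
    cmask = np.asarray(cluster_mask_highres)
    if cmask.shape != labeled.shape:
        raise ValueError("cluster mask must be at image resolution")
    cmask = cmask.astype(np.int32)
    n = int(labeled.max())
    cols = {"individual": [], "group": [], "cluster": [], "object": [], "size": []}
    cent_cols = [f"centroid_{ax}" for ax in range(labeled.ndim)]
    for c in cent_cols:
        cols[c] = []
    if n == 0:
        return pd.DataFrame(cols)
    ids = np.arange(1, n + 1)
    sizes = ndimage.sum_labels(labeled > 0, labeled, ids)
    centroids = np.asarray(ndimage.center_of_mass(labeled > 0, labeled, ids))
    if centroids.ndim == 1:
        centroids = centroids[None, :]
    for k, oid in enumerate(ids):
        if rule == "centroid":
            vox = tuple(int(round(x)) for x in centroids[k])
            vox = tuple(min(max(v, 0), s - 1) for v, s in zip(vox, labeled.shape))
            cluster = int(cmask[vox])
        else:
            members = labeled == oid
            overlap = cmask[members]
            inside = overlap[overlap > 0]
            if inside.size == 0:
                cluster = 0
            else:
                vals, cnts = np.unique(inside, return_counts=True)
                best = int(vals[np.argmax(cnts)])
                if rule == "majority" and cnts.max() <= members.sum() / 2:
                    cluster = 0
                else:
                    cluster = best
        if cluster == 0:
            continue
        cols["individual"].append(individual)
        cols["group"].append(group)
        cols["cluster"].append(cluster)
        cols["object"].append(int(oid))
        cols["size"].append(int(sizes[k]))
        for ax, c in enumerate(cent_cols):
            cols[c].append(float(centroids[k, ax]))
    return pd.DataFrame(cols)


@dataclass
class CountComparison:
    """Two-sample comparison of per-individual object counts."""

    t: float
    p: float
    df: float
    mean_a: float
    mean_b: float
    percent_change: float


def compare_counts(counts_a, counts_b) -> CountComparison:
    """Pooled two-sample t test on per-individual counts.

    ``percent_change`` is 100 * (mean_b - mean_a) / mean_a; it is NaN
    (with a warning) when the first group's mean is zero.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two individuals per group")
    from .inference import tstat_map

    sm = tstat_map(a[:, None], b[:, None])
    ma, mb = float(a.mean()), float(b.mean())
    if ma == 0:
        warnings.warn("mean of first group is zero: percent change undefined",
                      stacklevel=2)
        pct = float("nan")
    else:
        pct = 100.0 * (mb - ma) / ma
    return CountComparison(t=float(sm.t_values[0]), p=float(sm.p_values[0]),
                           df=sm.df, mean_a=ma, mean_b=mb, percent_change=pct)


def export_size_table(object_table: pd.DataFrame, path) -> None:
    """Write the tidy per-object size table as CSV.

    The output (individual, group, cluster, size per row) is the input
    expected by hierarchical / mixed-model size analyses in any
    statistics package.
    """
    if len(object_table) == 0:
        raise ValueError("object table is empty")
    cols = [c for c in ("individual", "group", "cluster", "object", "size")
            if c in object_table.columns]
    object_table[cols].to_csv(path, index=False)
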