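"""Voxel-wise group comparison and cluster inference on parametric maps.

A two-sample t statistic is computed at every map voxel, suprathreshold
voxels (p below the cluster-forming level) are grouped into sign-separated
connected components, and family-wise error is controlled with
nonparametric cluster-mass inference: group labels are permuted, the
maximum cluster mass (sum of |T| over a component) is recorded per
permutation, and the observed clusters are referred to that empirical
maximum-statistic distribution.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage, stats

__all__ = [
    "StatMap",
    "Cluster",
    "PermutationNull",
    "tstat_map",
    "extract_clusters",
    "permutation_null",
    "significant_clusters",
    "corrected_p_value",
    "f1_detection",
    "true_cluster_mask",
    "detection_mask",
]


@dataclass
class StatMap:
    """Voxel-wise two-sample t statistics and two-tailed p values."""

    t_values: np.ndarray
    p_values: np.ndarray
    df: float
    group_sizes: tuple[int, int]


@dataclass
class Cluster:
    """Sign-homogeneous connected suprathreshold component.

    ``voxels`` is a (k, ndim) integer array of member coordinates; the
    mass is the sum of |T| over members.
    """

    voxels: np.ndarray
    sign: int
    mass: float
    corrected_p: float | None = None

    @property
    def size(self) -> int:
        return int(self.voxels.shape[0])


@dataclass
class PermutationNull:
    """Empirical distribution of the maximum cluster mass under relabeling."""

    max_masses: np.ndarray
    alpha: float

    @property
    def n_perm(self) -> int:
        return int(len(self.max_masses))

    @property
    def threshold(self) -> float:
        """Empirical (1 - alpha) quantile of the maximum-mass distribution."""
        return float(np.quantile(self.max_masses, 1.0 - self.alpha))


def _stack(maps) -> np.ndarray:
    arrs = [m.grid if hasattr(m, "grid") else np.asarray(m, dtype=float) for m in maps]
    return np.stack([np.asarray(a, dtype=float) for a in arrs])


def tstat_map(maps_a, maps_b, equal_var: bool = True) -> StatMap:
    """Voxel-wise two-tailed two-sample Student t test (a minus b).

    The default is the classical pooled-variance statistic with
    df = n_a + n_b - 2; ``equal_var=False`` switches to Welch.  Voxels
    where both groups are constant and equal get t = 0, p = 1.
    """
    a = _stack(maps_a)
    b = _stack(maps_b)
    if a.shape[1:] != b.shape[1:]:
        raise ValueError(f"map shape mismatch: {a.shape[1:]} vs {b.shape[1:]}")
    na, nb = a.shape[0], b.shape[0]
    if na < 2 or nb < 2:
        raise ValueError("need at least two maps per group")
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    va, vb = a.var(axis=0, ddof=1), b.var(axis=0, ddof=1)
    diff = ma - mb
    with np.errstate(divide="ignore", invalid="ignore"):
        if equal_var:
            df = float(na + nb - 2)
            sp2 = ((na - 1) * va + (nb - 1) * vb) / df
            se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
            t = diff / se
            dfmap = df
        else:
            qa, qb = va / na, vb / nb
            se = np.sqrt(qa + qb)
            t = diff / se
            with np.errstate(divide="ignore", invalid="ignore"):
                dfmap = (qa + qb) ** 2 / (qa ** 2 / (na - 1) + qb ** 2 / (nb - 1))
            dfmap = np.where(np.isfinite(dfmap), dfmap, float(na + nb - 2))
    degenerate = (se == 0) & (diff == 0)
    t = np.where(degenerate, 0.0, t)
    p = 2.0 * stats.t.sf(np.abs(t), dfmap)
    p = np.where(degenerate, 1.0, p)
    return StatMap(t_values=t, p_values=p,
                   df=float(na + nb - 2) if equal_var else float(np.mean(dfmap)),
                   group_sizes=(na, nb))


def _structure(ndim: int, connectivity: int | None) -> np.ndarray:
    """Default: full connectivity (8 neighbors in 2D, 26 in 3D)."""
    if connectivity is None:
        connectivity = ndim
    return ndimage.generate_binary_structure(ndim, connectivity)


def extract_clusters(
    stat_map: StatMap,
    alpha_cluster_forming: float = 0.05,
    connectivity: int | None = None,
) -> list[Cluster]:
    """Sign-separated connected components of suprathreshold voxels."""
    t, p = stat_map.t_values, stat_map.p_values
    structure = _structure(t.ndim, connectivity)
    out: list[Cluster] = []
    for sign in (1, -1):
        mask = (p < alpha_cluster_forming) & ((t > 0) if sign > 0 else (t < 0))
        labels, n = ndimage.label(mask, structure=structure)
        for k in range(1, n + 1):
            vox = np.argwhere(labels == k)
            mass = float(np.abs(t[labels == k]).sum())
            out.append(Cluster(voxels=vox, sign=sign, mass=mass))
    return out


def _max_mass(maps: np.ndarray, is_a: np.ndarray, alpha: float,
              connectivity: int | None) -> float:
    sm = tstat_map(maps[is_a], maps[~is_a])
    clusters = extract_clusters(sm, alpha, connectivity)
    return max((c.mass for c in clusters), default=0.0)


def permutation_null(
    maps,
    labels,
    n_perm: int = 100,
    alpha: float = 0.05,
    alpha_cluster_forming: float = 0.05,
    connectivity: int | None = None,
    rng: np.random.Generator | None = None,
) -> PermutationNull:
    """Maximum cluster-mass distribution under group-label permutation.

    Labels are permuted preserving group sizes; for each permutation the
    t map and its clusters are recomputed and the largest cluster mass
    recorded (0 when no cluster forms).  If fewer distinct label
    assignments exist than ``n_perm``, all of them are enumerated
    instead.  The observed labeling is not included in the null set.
    """
    stack = _stack(maps)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError("exactly two groups required")
    if n_perm < 20:
        raise ValueError("n_perm must be >= 20")
    rng = np.random.default_rng() if rng is None else rng
    n = len(labels)
    na = int((labels == uniq[0]).sum())
    n_distinct = math.comb(n, na)
    masses = []
    if n_distinct <= n_perm:
        for combo in itertools.combinations(range(n), na):
            is_a = np.zeros(n, dtype=bool)
            is_a[list(combo)] = True
            masses.append(_max_mass(stack, is_a, alpha_cluster_forming, connectivity))
    else:
        for _ in range(n_perm):
            perm = rng.permutation(n)
            is_a = np.zeros(n, dtype=bool)
            is_a[perm[:na]] = True
            masses.append(_max_mass(stack, is_a, alpha_cluster_forming, connectivity))
    return PermutationNull(max_masses=np.asarray(masses, dtype=float), alpha=alpha)


def corrected_p_value(mass: float, null: PermutationNull) -> float:
    """Permutation p with the +1 convention: (1 + #{null >= m}) / (1 + B)."""
    return float((1 + int((null.max_masses >= mass).sum())) / (1 + null.n_perm))


def significant_clusters(clusters, null: PermutationNull,
                         alpha: float | None = None) -> list[Cluster]:
    """Clusters whose permutation-corrected p falls below alpha."""
    alpha = null.alpha if alpha is None else alpha
    out = []
    for c in clusters:
        p = corrected_p_value(c.mass, null)
        if p < alpha:
            out.append(replace(c, corrected_p=p))
    return out


def detection_mask(shape, clusters) -> np.ndarray:
    """Binary map-resolution mask of the voxels covered by the clusters."""
    mask = np.zeros(shape, dtype=bool)
    for c in clusters:
        mask[tuple(c.voxels.T)] = True
    return mask


def f1_detection(detected_mask: np.ndarray, truth_mask: np.ndarray,
                 empty_value: float = 1.0) -> float:
    """Voxel-wise F1 = 2TP / (2TP + FP + FN) between detection and truth."""
    d = np.asarray(detected_mask, dtype=bool)
    t = np.asarray(truth_mask, dtype=bool)
    if d.shape != t.shape:
        raise ValueError("mask shapes differ")
    tp = int((d & t).sum())
    fp = int((d & ~t).sum())
    fn = int((~d & t).sum())
    if tp == fp == fn == 0:
        return float(empty_value)
    return 2.0 * tp / (2.0 * tp + fp + fn)


def true_cluster_mask(shape, clusters, bin_window, min_fraction: float = 0.5) -> np.ndarray:
    """Map-resolution ground-truth mask from full-resolution cluster specs.

    A binned voxel is true iff more than ``min_fraction`` of its source
    voxels lie inside a true cluster rectangle.
    """
    from .maps import bin_image

    full = np.zeros(shape, dtype=np.float64)
    for c in clusters:
        full[c.slices] = 1.0
    return bin_image(full, bin_window) > min_fraction
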