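"""Parametric marker-load maps from high-resolution binary images.

Three estimators turn a binary segmented image into a low-resolution
continuous map of the local marker load (fraction of tissue occupied by
the marker):

``binning``
    window mean over non-overlapping ``bin_window`` blocks;
``voronoi_binning``
    each connected foreground object is reduced to its centroid, the
    plane is partitioned into Voronoi cells of the centroids, every pixel
    of a cell carries load = object area / cell area; the resulting image
    is then binned;
``gaussian_binning``
    Gaussian kernel smoothing of the binary image followed by binning.

The Gaussian kernel standard deviation is the one free parameter that
controls the bias-variance trade-off of the load estimate.  It is chosen
by minimizing an out-of-bag bootstrap estimate of the squared error of
the smoothed-map sample mean: bootstrap samples of individuals are drawn
with replacement, and each individual's raw binary image is compared with
the mean smoothed map of the bootstrap samples that left it out.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.fft as sfft
from scipy import ndimage

__all__ = [
    "ParametricMap",
    "BootstrapErrorCurve",
    "bin_image",
    "gaussian_smooth",
    "voronoi_load",
    "estimate_map",
    "bootstrap_error",
    "select_kernel",
    "default_sigma_grid",
]

ESTIMATORS = ("binning", "voronoi_binning", "gaussian_binning")


@dataclass
class ParametricMap:
    """Low-resolution marker-load map with its provenance."""

    grid: np.ndarray
    bin_window: tuple[int, ...]
    estimator: str
    sigma: float | None = None
    source_id: str | None = None


@dataclass
class BootstrapErrorCurve:
    """Bootstrap error per candidate kernel sd, per group.

    ``errors`` has shape (n_groups, n_sigmas); ``selected_sigma`` is the
    argmin of the across-group mean, ties broken toward the smaller sd.
    """

    sigmas: np.ndarray
    errors: np.ndarray
    n_bootstrap: int
    selected_sigma: float

    @property
    def mean_errors(self) -> np.ndarray:
        return self.errors.mean(axis=0)

    def to_frame(self):
        import pandas as pd

        rows = [
            {"sigma": float(s), "group": g, "error": float(self.errors[g, i])}
            for g in range(self.errors.shape[0])
            for i, s in enumerate(self.sigmas)
        ]
        return pd.DataFrame(rows)


def default_sigma_grid(n: int = 10, lo: float = 2.0, hi: float = 64.0) -> np.ndarray:
    """Geometric grid of candidate kernel standard deviations (pixels)."""
    return np.geomspace(lo, hi, n)


def bin_image(image: np.ndarray, bin_window: tuple[int, ...] | int) -> np.ndarray:
    """Window-mean downsampling to shape ``ceil(shape / bin_window)``.

    Boundary windows smaller than the full window average over their
    actual voxel count, so no tissue is discarded.
    """
    image = np.asarray(image)
    if np.isscalar(bin_window):
        bin_window = (int(bin_window),) * image.ndim
    if len(bin_window) != image.ndim:
        raise ValueError("bin_window rank must match image rank")
    # binary/8-bit inputs: float32 window sums (< 2^24) are exact and
    # halve the memory traffic; float inputs keep their precision
    work = np.float32 if image.dtype.itemsize <= 1 else \
        image.dtype if np.issubdtype(image.dtype, np.floating) else np.float64
    out = image.astype(work, copy=False)
    for ax, w in enumerate(bin_window):
        if w <= 0:
            raise ValueError("bin window dims must be positive")
        if w > image.shape[ax]:
            raise ValueError(
                f"bin window {w} larger than image extent {image.shape[ax]} on axis {ax}")
        starts = np.arange(0, out.shape[ax], w)
        sums = np.add.reduceat(out, starts, axis=ax)
        counts = np.minimum(starts + w, out.shape[ax]) - starts
        shape = [1] * out.ndim
        shape[ax] = len(counts)
        out = sums / counts.reshape(shape)
    return out


def gaussian_smooth(
    image: np.ndarray,
    sigma: float | Sequence[float],
    mask: np.ndarray | None = None,
    truncate: float = 4.0,
) -> np.ndarray:
    """Unit-sum Gaussian kernel smoothing.

    Without a mask the image is zero-padded at the border.  With a mask,
    the smoothed image is renormalized by the smoothed mask so that load
    values remain unbiased near the mask boundary; voxels outside the
    mask are set to zero.
    """
    image = np.asarray(image, dtype=np.float64)
    if np.any(np.asarray(sigma) <= 0):
        raise ValueError("sigma must be > 0")
    if mask is None:
        return ndimage.gaussian_filter(image, sigma, mode="constant", cval=0.0,
                                       truncate=truncate)
    m = np.asarray(mask, dtype=np.float64)
    num = ndimage.gaussian_filter(image * m, sigma, mode="constant", cval=0.0,
                                  truncate=truncate)
    den = ndimage.gaussian_filter(m, sigma, mode="constant", cval=0.0,
                                  truncate=truncate)
    out = np.zeros_like(num)
    inside = m > 0
    out[inside] = num[inside] / den[inside]
    return out


def voronoi_load(image: np.ndarray, connectivity: int | None = None) -> np.ndarray:
    """Voronoi-tessellation marker-load estimate of a binary image.

    Connected foreground objects are reduced to their centroids (rounded
    to the nearest pixel); every pixel is assigned to the cell of its
    nearest centroid (exact Euclidean feature transform) and carries
    load = object foreground area / cell area.  An empty image yields an
    all-zero map; a single object yields one cell spanning the image.
    """
    image = np.asarray(image)
    binary = image > 0
    structure = np.ones((3,) * binary.ndim) if connectivity is None else \
        ndimage.generate_binary_structure(binary.ndim, connectivity)
    labels, n = ndimage.label(binary, structure=structure)
    if n == 0:
        return np.zeros(binary.shape, dtype=np.float64)
    # sizes and centroids via label-indexed bincounts over foreground only
    flat = labels.ravel()
    fg = np.flatnonzero(flat)
    fg_labels = flat[fg]
    sizes = np.bincount(fg_labels, minlength=n + 1)[1:].astype(np.float64)
    coords = np.unravel_index(fg, binary.shape)
    centroids = np.column_stack([
        np.bincount(fg_labels, weights=c, minlength=n + 1)[1:] / sizes
        for c in coords
    ])
    cidx = tuple(
        np.clip(np.round(centroids[:, ax]).astype(np.intp), 0, binary.shape[ax] - 1)
        for ax in range(binary.ndim)
    )
    seed_img = np.zeros(binary.shape, dtype=bool)
    seed_img[cidx] = True
    nearest = ndimage.distance_transform_edt(~seed_img, return_distances=False,
                                             return_indices=True)
    flat_nearest = np.ravel_multi_index(tuple(nearest), binary.shape)
    lut = np.zeros(binary.size, dtype=np.intp)
    lut[np.ravel_multi_index(cidx, binary.shape)] = np.arange(n)
    obj = lut[flat_nearest]
    cell_sizes = np.bincount(obj.ravel(), minlength=n)
    load = (sizes[obj] / cell_sizes[obj]).reshape(binary.shape)
    return load


def estimate_map(
    image: np.ndarray,
    estimator: str,
    bin_window: tuple[int, ...] | int,
    sigma: float | Sequence[float] | None = None,
    mask: np.ndarray | None = None,
    source_id: str | None = None,
) -> ParametricMap:
    """Build a parametric map with the requested estimator."""
    if estimator not in ESTIMATORS:
        raise ValueError(f"estimator must be one of {ESTIMATORS}")
    if estimator == "binning":
        grid = bin_image(image, bin_window)
    elif estimator == "voronoi_binning":
        grid = bin_image(voronoi_load(image), bin_window)
    else:
        if sigma is None:
            raise ValueError("gaussian_binning requires sigma")
        grid = bin_image(gaussian_smooth(image, sigma, mask=mask), bin_window)
    if np.isscalar(bin_window):
        bin_window = (int(bin_window),) * np.asarray(image).ndim
    return ParametricMap(grid=grid, bin_window=tuple(bin_window), estimator=estimator,
                         sigma=None if sigma is None else float(np.max(sigma)),
                         source_id=source_id)


class FFTSmoother:
    """Zero-padded FFT evaluation of sampled-Gaussian smoothing for 2D stacks.

    Produces the same result as ``scipy.ndimage.gaussian_filter`` with
    ``mode='constant'`` (same sampled, truncated kernel) but reuses the
    forward transforms of the images across kernel widths, which makes
    sweeping a bandwidth grid over a cohort affordable.  Padding is
    chosen per kernel width so the circular convolution equals the linear
    one exactly.
    """

    def __init__(self, images: Sequence[np.ndarray], truncate: float = 4.0,
                 dtype=np.float32, max_sigma: float | None = None):
        self.images = [np.asarray(im) for im in images]
        self.shape = self.images[0].shape
        if any(im.shape != self.shape for im in self.images):
            raise ValueError("all images must share one shape")
        if len(self.shape) != 2:
            raise ValueError("FFTSmoother is 2D-only")
        self.truncate = truncate
        self.dtype = dtype
        # One pad for the whole bandwidth sweep keeps the forward
        # transforms shared; a pad larger than strictly needed is exact.
        self._min_pad = self._pad_for(max_sigma) if max_sigma else (0, 0)
        self._spectra: dict[tuple[int, int], list[np.ndarray]] = {}

    def _kernel1d(self, sigma: float) -> np.ndarray:
        r = int(self.truncate * sigma + 0.5)
        x = np.arange(-r, r + 1, dtype=np.float64)
        k = np.exp(-0.5 * (x / sigma) ** 2)
        return k / k.sum()

    def _pad_for(self, sigma: float) -> tuple[int, int]:
        r = int(self.truncate * sigma + 0.5)
        return (sfft.next_fast_len(self.shape[0] + 2 * r, real=True),
                sfft.next_fast_len(self.shape[1] + 2 * r, real=True))

    def _forward(self, pad: tuple[int, int]) -> list[np.ndarray]:
        if pad not in self._spectra:
            self._spectra[pad] = [
                sfft.rfft2(im.astype(self.dtype), s=pad) for im in self.images
            ]
        return self._spectra[pad]

    def smooth_stack(self, sigma: float) -> np.ndarray:
        """Smoothed images as a (T, n_pixels) stack (row-major flattened)."""
        need = self._pad_for(sigma)
        pad = (max(need[0], self._min_pad[0]), max(need[1], self._min_pad[1]))
        spectra = self._forward(pad)
        k = self._kernel1d(sigma)
        r = (len(k) - 1) // 2
        w = []
        for ax in range(2):
            k1 = np.zeros(pad[ax])
            k1[: len(k)] = k
            k1 = np.roll(k1, -r)
            w.append(sfft.rfft(k1) if ax == 1 else sfft.fft(k1))
        transfer = (w[0][:, None].astype(spectra[0].dtype)
                    * w[1][None, :].astype(spectra[0].dtype))
        h, wd = self.shape
        out = np.empty((len(spectra), h * wd), dtype=self.dtype)
        buf = np.empty_like(transfer)
        for i, f in enumerate(spectra):
            np.multiply(f, transfer, out=buf)
            s = sfft.irfft2(buf, s=pad, overwrite_x=True)
            out[i] = s[:h, :wd].reshape(-1)
        return out


def _bootstrap_counts(samples: np.ndarray, n: int) -> np.ndarray:
    counts = np.zeros((samples.shape[0], n), dtype=np.float64)
    for b, s in enumerate(samples):
        counts[b] = np.bincount(s, minlength=n)
    return counts


def bootstrap_error(
    images: Sequence[np.ndarray],
    sigma: float,
    n_bootstrap: int = 1000,
    rng: np.random.Generator | None = None,
    mask: np.ndarray | None = None,
    samples: np.ndarray | None = None,
    smoothed: np.ndarray | None = None,
    raw_stack: np.ndarray | None = None,
    stride: int = 1,
) -> float:
    """Out-of-bag bootstrap error of the smoothed-map sample mean.

    ``B`` bootstrap samples of the ``T`` individuals are drawn with
    replacement.  For each individual ``j``, the voxel-mean squared
    difference between the mean smoothed map of each sample not
    containing ``j`` and ``j``'s raw binary image is averaged; the result
    is averaged over individuals.  Individuals contained in every sample
    are skipped (reducing ``T``); if no individual has an out-of-bag
    sample a ``ValueError`` is raised.

    The computation regroups the voxel sums into Gram matrices of the
    smoothed images, which is algebraically identical to materializing
    every bootstrap mean.  ``samples`` (B, T) and ``smoothed`` (T, n) may
    be supplied to share work across a bandwidth grid; ``stride`` > 1
    subsamples the voxel sum for speed on very large volumes (off by
    default: the error is evaluated at full voxel resolution as
    defined).
    """
    t = len(images)
    if t < 2:
        raise ValueError("need at least two images")
    if samples is None:
        if n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")
        rng = np.random.default_rng() if rng is None else rng
        samples = rng.integers(0, t, size=(n_bootstrap, t))
    if smoothed is None:
        smoothed = np.stack([
            gaussian_smooth(im, sigma).reshape(-1) for im in images
        ])
    if raw_stack is None:
        raw_stack = np.stack([np.asarray(im, dtype=smoothed.dtype).reshape(-1)
                              for im in images])
    raw = raw_stack
    if mask is not None:
        keep = np.asarray(mask).reshape(-1) > 0
        smoothed = smoothed[:, keep]
        raw = raw[:, keep]
    if stride > 1:
        smoothed = smoothed[:, ::stride]
        raw = raw[:, ::stride]
    n = raw.shape[1]
    gram = (smoothed @ smoothed.T).astype(np.float64) / n
    cross = (smoothed @ raw.T).astype(np.float64) / n
    msq = np.einsum("ij,ij->i", raw, raw).astype(np.float64) / n
    counts = _bootstrap_counts(np.asarray(samples), t) / t
    per_j = []
    for j in range(t):
        oob = counts[:, j] == 0
        if not oob.any():
            continue
        c = counts[oob]
        e = np.einsum("bi,ik,bk->b", c, gram, c) - 2.0 * (c @ cross[:, j]) + msq[j]
        per_j.append(float(e.mean()))
    if not per_j:
        raise ValueError("no out-of-bag samples: increase n_bootstrap")
    return float(np.mean(per_j))


def select_kernel(
    groups: Sequence[Sequence[np.ndarray]],
    sigmas: Sequence[float] | None = None,
    n_bootstrap: int = 1000,
    rng: np.random.Generator | None = None,
    mask: np.ndarray | None = None,
    stride: int = 1,
) -> BootstrapErrorCurve:
    """Choose the Gaussian kernel sd minimizing the mean bootstrap error.

    The bootstrap error is computed for each experimental group
    separately (each group gets one set of bootstrap samples, shared
    across the bandwidth grid) and the selected sd is the argmin of the
    across-group mean curve, ties broken toward the smaller sd.
    """
    if len(groups) < 1:
        raise ValueError("need at least one group")
    sigmas = default_sigma_grid() if sigmas is None else np.sort(np.asarray(sigmas, float))
    if len(sigmas) < 2:
        raise ValueError("need at least two candidate sigmas")
    rng = np.random.default_rng() if rng is None else rng
    errors = np.zeros((len(groups), len(sigmas)))
    for g, images in enumerate(groups):
        t = len(images)
        samples = rng.integers(0, t, size=(n_bootstrap, t))
        use_fft = np.asarray(images[0]).ndim == 2 and mask is None
        smoother = FFTSmoother(images, max_sigma=float(sigmas[-1])) if use_fft else None
        for i, s in enumerate(sigmas):
            smoothed = smoother.smooth_stack(s) if smoother is not None else None
            errors[g, i] = bootstrap_error(images, s, rng=rng, mask=mask,
                                           samples=samples, smoothed=smoothed,
                                           stride=stride)
    mean = errors.mean(axis=0)
    selected = float(sigmas[int(np.argmin(mean))])
    return BootstrapErrorCurve(sigmas=np.asarray(sigmas, float), errors=errors,
                               n_bootstrap=int(n_bootstrap), selected_sigma=selected)
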