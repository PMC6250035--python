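"""Small plotting helpers (error curves, detection overlays)."""

from __future__ import annotations

import numpy as np


def plot_error_curve(curve, ax=None, log: bool = True):
    """Plot per-group bootstrap error curves and mark the selected sd."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for g in range(curve.errors.shape[0]):
        ax.plot(curve.sigmas, curve.errors[g], marker="o", label=f"group {g}")
    ax.plot(curve.sigmas, curve.mean_errors, color="k", lw=2, label="mean")
    ax.axvline(curve.selected_sigma, ls="--", color="b")
    if log:
        ax.set_xscale("log")
    ax.set_xlabel("Gaussian kernel sd (voxels)")
    ax.set_ylabel("bootstrap error")
    ax.legend()
    return ax


def plot_detection(t_values: np.ndarray, detected: np.ndarray, truth=None, ax=None):
    """Show a t map with detected (and optionally true) cluster outlines."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    im = ax.imshow(t_values, cmap="coolwarm")
    ax.contour(detected.astype(float), levels=[0.5], colors="k", linewidths=1)
    if truth is not None:
        ax.contour(np.asarray(truth, dtype=float), levels=[0.5], colors="g",
                   linewidths=1, linestyles="--")
    plt.colorbar(im, ax=ax, label="T")
    return ax
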