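"""Run-configuration parsing for the command-line interface."""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .simulate import ClusterSpec, RadiusModel, SimulationConfig, default_cluster_layout

__all__ = ["simulation_config_from_dict", "parse_sigma_grid"]


def simulation_config_from_dict(d: dict) -> SimulationConfig:
    """Build a SimulationConfig from a (YAML/JSON) mapping.

    Recognized keys: image_shape, basal_expected_count, n_per_group,
    seed, radius {mean, sd, truncation}, clusters (list of {origin,
    size, multiplier} or the string "default").
    """
    shape = tuple(int(x) for x in d.get("image_shape", (2560, 2560)))
    if len(shape) != 2:
        raise ValueError("image_shape must have two entries")
    rm = d.get("radius", {})
    radius_model = RadiusModel(
        mean_radius=float(rm.get("mean", 7.0)),
        sd_radius=float(rm.get("sd", 2.0)),
        truncation_rule=rm.get("truncation", "resample_nonpositive"),
    )
    clusters_cfg = d.get("clusters", "default")
    if clusters_cfg == "default" or clusters_cfg is None:
        clusters = default_cluster_layout(shape)
    else:
        clusters = tuple(
            ClusterSpec(origin=tuple(int(x) for x in c["origin"]),
                        size=tuple(int(x) for x in c["size"]),
                        multiplier=float(c["multiplier"]))
            for c in clusters_cfg
        )
    return SimulationConfig(
        image_shape=shape,
        radius_model=radius_model,
        basal_expected_count=float(d.get("basal_expected_count", 40.0)),
        clusters=clusters,
        n_per_group=int(d.get("n_per_group", 10)),
        seed=d.get("seed"),
    )


def parse_sigma_grid(spec: str | Sequence[float]) -> np.ndarray:
    """Parse "lo:hi:n" (geometric) or a comma-separated list of sds."""
    if not isinstance(spec, str):
        return np.sort(np.asarray(list(spec), dtype=float))
    if ":" in spec:
        lo, hi, n = spec.split(":")
        return np.geomspace(float(lo), float(hi), int(n))
    return np.sort(np.array([float(x) for x in spec.split(",") if x.strip()]))
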