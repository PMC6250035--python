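"""Image and table I/O.

Binary marker images travel as PNG/TIFF (2D) or NIfTI / TIFF stacks
(3D); parametric maps and truth maps as float32 TIFF or NIfTI.  The
format is picked from the file extension.  Cohort outputs carry a
manifest CSV (file, individual, group, seed, checksum) and a provenance
JSON sufficient to re-run the stage.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

__all__ = [
    "read_image",
    "write_image",
    "sha256sum",
    "write_provenance",
    "load_config_file",
]

_NIFTI_SUFFIXES = (".nii", ".nii.gz")


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return name.endswith(".nii") or name.endswith(".nii.gz")


def read_image(path, binary: bool = False) -> np.ndarray:
    """Read a 2D image or 3D volume; ``binary=True`` maps values >0 to 1."""
    path = Path(path)
    suffix = path.suffix.lower()
    if _is_nifti(path):
        import nibabel as nib

        arr = np.asanyarray(nib.load(str(path)).dataobj)
    elif suffix in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(str(path))
    elif suffix == ".png":
        from PIL import Image

        arr = np.asarray(Image.open(path))
    else:
        raise ValueError(f"unsupported image format: {path.name}")
    if binary:
        arr = (arr > 0).astype(np.uint8)
    return arr


def write_image(path, array: np.ndarray, voxel_size=None) -> Path:
    """Write an array; binary images as 8-bit, maps as float32.

    ``voxel_size`` (per-axis physical size) is stored in the NIfTI affine
    when that format is used; other formats carry it in the manifest.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = np.asarray(array)
    if _is_nifti(path):
        import nibabel as nib

        affine = np.eye(4)
        if voxel_size is not None:
            for i, v in enumerate(np.atleast_1d(voxel_size)[: 3]):
                affine[i, i] = float(v)
        data = arr.astype(np.uint8) if arr.dtype == bool else \
            arr.astype(np.float32) if np.issubdtype(arr.dtype, np.floating) else arr
        nib.save(nib.Nifti1Image(data, affine), str(path))
    elif path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        data = arr.astype(np.float32) if np.issubdtype(arr.dtype, np.floating) \
            else arr.astype(np.uint8)
        tifffile.imwrite(str(path), data)
    elif path.suffix.lower() == ".png":
        from PIL import Image

        if arr.ndim != 2:
            raise ValueError("PNG supports 2D images only")
        if arr.dtype == bool or (np.issubdtype(arr.dtype, np.integer) and arr.max(initial=0) <= 1):
            data = (arr.astype(np.uint8) * 255)
        else:
            data = arr.astype(np.uint8)
        Image.fromarray(data).save(path)
    else:
        raise ValueError(f"unsupported image format: {path.name}")
    return path


def sha256sum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_provenance(outdir, stage: str, params: dict) -> Path:
    """Machine-readable record of the parameters that produced a stage."""
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    payload = {"stage": stage, "voxelhisto_version": __version__, "params": params}
    path = outdir / "provenance.json"
    path.write_text(json.dumps(payload, indent=2, default=str) + "\n")
    return path


def load_config_file(path) -> dict:
    """Load a JSON or YAML run configuration."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    import yaml

    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must contain a mapping")
    return data
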