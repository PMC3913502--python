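"""Single-file array container for grids, scalar volumes and tensor fields.

The container is a NumPy ``.npz`` archive holding grid metadata
(``n``, ``h``, ``origin``) plus named component arrays.  Scalar volumes
store one array ``values``; tensor fields store the six components
``sxx, syy, szz, sxy, sxz, syz``.

Label volumes (e.g. segmentations exported from NIfTI) can be turned into
tensor fields through a label -> conductivity table.
"""

from __future__ import annotations

from typing import Dict, Union

import numpy as np

from .grid import RegularGrid, ScalarVolume, TensorField

__all__ = ["save_volume", "load_volume", "label_volume_to_tensor_field",
           "load_nifti_labels"]

_TENSOR_KEYS = ("sxx", "syy", "szz", "sxy", "sxz", "syz")


def _grid_meta(grid: RegularGrid) -> Dict[str, np.ndarray]:
    return {
        "n": np.array(grid.shape, dtype=np.int64),
        "h": grid.spacing,
        "origin": np.array(grid.origin),
    }


def save_volume(path, obj: Union[ScalarVolume, TensorField]) -> None:
    if isinstance(obj, ScalarVolume):
        np.savez(path, kind="scalar", values=obj.values, **_grid_meta(obj.grid))
    elif isinstance(obj, TensorField):
        comps = {k: getattr(obj, k) for k in _TENSOR_KEYS}
        np.savez(path, kind="tensor", **comps, **_grid_meta(obj.grid))
    else:
        raise TypeError(f"cannot save object of type {type(obj).__name__}")


def load_volume(path) -> Union[ScalarVolume, TensorField]:
    with np.load(path, allow_pickle=False) as data:
        n = data["n"]
        h = data["h"]
        origin = data["origin"]
        grid = RegularGrid(int(n[0]), int(n[1]), int(n[2]),
                           float(h[0]), float(h[1]), float(h[2]),
                           origin=tuple(origin))
        kind = str(data["kind"])
        if kind == "scalar":
            return ScalarVolume(grid, data["values"])
        if kind == "tensor":
            return TensorField(grid, *(data[k] for k in _TENSOR_KEYS))
    raise ValueError(f"unrecognized container kind {kind!r}")


def label_volume_to_tensor_field(grid: RegularGrid, labels: np.ndarray,
                                 table: Dict[int, float],
                                 default: float = 1e-10) -> TensorField:
    """Isotropic tensor field from an integer label volume and a
    label -> conductivity (S/m) table; unknown labels get ``default``."""
    labels = np.asarray(labels)
    if labels.shape != grid.shape:
        raise ValueError("label volume shape does not match the grid")
    values = np.full(grid.shape, default, dtype=float)
    for label, cond in table.items():
        values[labels == label] = cond
    return TensorField.isotropic(grid, values)


def load_nifti_labels(path) -> np.ndarray:
    """Optional NIfTI import of a label volume (requires nibabel)."""
    try:
        import nibabel as nib
    except ImportError as exc:  # pragma: no cover
        raise ImportError("NIfTI import requires the optional nibabel package") from exc
    return np.asanyarray(nib.load(str(path)).dataobj)
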