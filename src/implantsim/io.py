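"""Tabular serialization of ground truth, artifacts, and metrics.

Everything is plain text: TSV tables with a JSON provenance sidecar, plus
optional NIfTI rasterization of sparse voxel tables.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .ctsim import VoxelArtifact
from .depth import DepthArray
from .gridfit import FittedArray

__all__ = [
    "fitted_array_table",
    "depth_array_table",
    "artifact_table",
    "write_tsv",
    "write_provenance",
    "rasterize_to_nifti",
]


def fitted_array_table(fitted: FittedArray) -> pd.DataFrame:
    model = fitted.model
    idx = np.flatnonzero(model.reported_mask)
    rows, cols = np.divmod(idx, model.n_cols)
    coords = fitted.coords[idx]
    normals = fitted.normals[idx]
    return pd.DataFrame(
        {
            "electrode": np.arange(len(idx)),
            "row": rows,
            "col": cols,
            "x": coords[:, 0],
            "y": coords[:, 1],
            "z": coords[:, 2],
            "nx": normals[:, 0],
            "ny": normals[:, 1],
            "nz": normals[:, 2],
            "surface_distance": fitted.surface_distances[idx],
        }
    )


def depth_array_table(array: DepthArray) -> pd.DataFrame:
    """Contact table; contact index 1 is the deepest (target) contact."""
    c = array.contact_coords
    return pd.DataFrame(
        {
            "contact": np.arange(1, len(c) + 1),
            "x": c[:, 0],
            "y": c[:, 1],
            "z": c[:, 2],
            "curved": array.curved,
        }
    )


def artifact_table(artifacts: list[VoxelArtifact]) -> pd.DataFrame:
    from .ctsim import merge_artifacts

    return merge_artifacts(artifacts)


def write_tsv(table: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False, float_format="%.6f")
    return path


def write_provenance(info: dict, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(info, indent=2, default=_jsonify) + "\n")
    return path


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)!r}")


def rasterize_to_nifti(table: pd.DataFrame, path, spacing_mm: float = 0.5):
    """Rasterize a sparse voxel table to a NIfTI volume on its bounding box
    (0.5 mm isotropic, identity orientation; offset recorded in the affine)."""
    import nibabel as nib

    xyz = table[["x", "y", "z"]].to_numpy()
    lo = xyz.min(axis=0)
    ijk = np.round((xyz - lo) / spacing_mm).astype(int)
    shape = ijk.max(axis=0) + 1
    vol = np.zeros(shape, dtype=np.float32)
    np.maximum.at(vol, (ijk[:, 0], ijk[:, 1], ijk[:, 2]), table["intensity"].to_numpy())
    affine = np.diag([spacing_mm, spacing_mm, spacing_mm, 1.0])
    affine[:3, 3] = lo
    img = nib.Nifti1Image(vol, affine)
    nib.save(img, str(path))
    return img
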