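"""NIfTI and table I/O for volumes, parcellations, profiles and loadings.

Conventions
-----------
* Internal arrays are float64; scalar volumes are written to disk as
  float32 and label/mask volumes as int16 (standard neuroimaging sizes).
* NaN voxels encountered on load are replaced by 0 and counted; the
  count is logged (NaN never propagates into the pipeline).
* No resampling or reorientation is ever performed: a geometry mismatch
  against a reference grid is an error, not a silent fix.
* Tables are plain TSV read/written with pandas.
"""

from __future__ import annotations

import logging
import os
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import GeometryError, ParameterError
from .grids import AFFINE_ATOL, AtlasParcellation, VolumeGrid

log = logging.getLogger(__name__)


def _check_reference(shape, affine, reference: VolumeGrid | None,
                     path: str | os.PathLike) -> None:
    if reference is None:
        return
    if tuple(shape) != tuple(reference.shape):
        raise GeometryError(
            f"{path}: shape {tuple(shape)} does not match reference "
            f"shape {tuple(reference.shape)}"
        )
    if not np.allclose(affine, reference.affine, atol=AFFINE_ATOL, rtol=0.0):
        raise GeometryError(
            f"{path}: affine differs from reference by more than "
            f"{AFFINE_ATOL} per entry"
        )


def load_volume(path: str | os.PathLike,
                reference: VolumeGrid | None = None,
                space_tag: str = "") -> VolumeGrid:
    """Load a 3-D NIfTI volume, sanitising NaN to 0.

    Parameters
    ----------
    path:
        NIfTI-1/2 file (``.nii`` or ``.nii.gz``).
    reference:
        If given, the loaded geometry must match it (shape exactly,
        affine within ``1e-4`` per entry) or a GeometryError is raised.
    """
    if not os.path.exists(path):
        raise IOError(f"no such volume: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ParameterError(f"{path}: expected a 3-D volume, "
                             f"got shape {data.shape}")
    n_nan = int(np.isnan(data).sum())
    if n_nan:
        log.warning("%s: replaced %d NaN voxels with 0", path, n_nan)
        data = np.nan_to_num(data, nan=0.0)
    affine = np.asarray(img.affine, dtype=np.float64)
    _check_reference(data.shape, affine, reference, path)
    return VolumeGrid(data=data, affine=affine, space_tag=space_tag)


def save_volume(vol: VolumeGrid, path: str | os.PathLike,
                dtype: type = np.float32) -> str:
    """Write a volume as NIfTI; float32 by default, int16 for labels."""
    parent = os.path.dirname(os.path.abspath(path))
    if not os.path.isdir(parent):
        raise IOError(f"parent directory does not exist: {parent}")
    img = nib.Nifti1Image(vol.data.astype(dtype), vol.affine)
    nib.save(img, str(path))
    return str(path)


def load_volumes(paths: Sequence[str | os.PathLike],
                 reference: VolumeGrid | None = None) -> list[VolumeGrid]:
    """Load several volumes onto one shared geometry (first file sets it)."""
    vols: list[VolumeGrid] = []
    ref = reference
    for p in paths:
        v = load_volume(p, reference=ref)
        if ref is None:
            ref = v
        vols.append(v)
    return vols


def save_component_maps(maps: Sequence[VolumeGrid],
                        path: str | os.PathLike) -> str:
    """Stack K component maps into one 4-D NIfTI file."""
    if not maps:
        raise ParameterError("no component maps to save")
    from .grids import require_same_geometry
    ref = require_same_geometry(maps, "save_component_maps")
    stack = np.stack([m.data for m in maps], axis=-1).astype(np.float32)
    nib.save(nib.Nifti1Image(stack, ref.affine), str(path))
    return str(path)


def load_component_maps(path: str | os.PathLike,
                        reference: VolumeGrid | None = None
                        ) -> list[VolumeGrid]:
    """Load a 4-D NIfTI file as a list of K 3-D component maps."""
    if not os.path.exists(path):
        raise IOError(f"no such volume: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4:
        raise ParameterError(f"{path}: expected a 4-D component stack")
    n_nan = int(np.isnan(data).sum())
    if n_nan:
        log.warning("%s: replaced %d NaN voxels with 0", path, n_nan)
        data = np.nan_to_num(data, nan=0.0)
    affine = np.asarray(img.affine, dtype=np.float64)
    _check_reference(data.shape[:3], affine, reference, path)
    return [VolumeGrid(data=data[..., k], affine=affine)
            for k in range(data.shape[3])]


def load_atlas(label_path: str | os.PathLike,
               names_path: str | os.PathLike,
               reference: VolumeGrid | None = None) -> AtlasParcellation:
    """Load an integer parcellation plus its region lookup TSV.

    The TSV must have columns ``region_id`` and ``region_name``.
    """
    grid = load_volume(label_path, reference=reference)
    table = pd.read_csv(names_path, sep="\t")
    for col in ("region_id", "region_name"):
        if col not in table.columns:
            raise ParameterError(f"{names_path}: missing column '{col}'")
    names = {int(r.region_id): str(r.region_name)
             for r in table.itertuples()}
    labels = np.round(grid.data).astype(np.int32)
    return AtlasParcellation(labels=labels, region_names=names, grid=grid)


def save_atlas(atlas: AtlasParcellation,
               label_path: str | os.PathLike,
               names_path: str | os.PathLike) -> None:
    label_vol = atlas.grid.with_data(atlas.labels.astype(np.float64))
    save_volume(label_vol, label_path, dtype=np.int16)
    table = pd.DataFrame(
        {"region_id": sorted(atlas.region_names),
         "region_name": [atlas.region_names[i]
                         for i in sorted(atlas.region_names)]}
    )
    table.to_csv(names_path, sep="\t", index=False)


def save_profile_table(table: pd.DataFrame, path: str | os.PathLike) -> str:
    """Write a region-profile table as TSV with stable float formatting."""
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return str(path)


def load_profile_table(path: str | os.PathLike) -> pd.DataFrame:
    if not os.path.exists(path):
        raise IOError(f"no such table: {path}")
    return pd.read_csv(path, sep="\t")
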