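"""Core spatial containers: scalar volumes and integer parcellations.

Every map handled by the pipeline — lesion masks, tract probability
fields, disconnection maps, fMRI contrasts, t-maps — is a
:class:`VolumeGrid`: a 3-D scalar field plus a 4x4 voxel-to-world affine.
All cross-volume operations require a single shared geometry; mismatches
raise :class:`~disconnectome.errors.GeometryError` rather than being
silently resampled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .errors import GeometryError, ParameterError

#: absolute tolerance per affine entry when comparing geometries (mm)
AFFINE_ATOL = 1e-4


@dataclass
class VolumeGrid:
    """A 3-D scalar field with voxel-to-world affine.

    Parameters
    ----------
    data:
        3-D array of scalar values; stored as float64 internally.
    affine:
        4x4 invertible voxel-to-world transform in mm.
    space_tag:
        Free-text label of the reference space, e.g. ``"MNI152-2mm"``
        or ``"synthetic-32"``.
    """

    data: np.ndarray
    affine: np.ndarray
    space_tag: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 3:
            raise ParameterError(
                f"volume data must be 3-D, got {self.data.ndim}-D"
            )
        if min(self.data.shape) < 1:
            raise ParameterError(f"degenerate shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise ParameterError("affine must be 4x4")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ParameterError("affine is not invertible")
        if np.isnan(self.data).any():
            raise ParameterError(
                "NaN values in volume data; sanitize at load time"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths in mm (norm of the affine columns)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def with_data(self, data: np.ndarray) -> "VolumeGrid":
        """New volume on the same grid carrying different values."""
        return VolumeGrid(data=data, affine=self.affine.copy(),
                          space_tag=self.space_tag)

    def same_geometry(self, other: "VolumeGrid") -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=AFFINE_ATOL, rtol=0.0
        )


def require_same_geometry(grids: Iterable[VolumeGrid],
                          context: str = "operation") -> VolumeGrid:
    """Check that all grids share one geometry; return the reference.

    Raises :class:`GeometryError` naming both shapes on mismatch.
    """
    grids = list(grids)
    if not grids:
        raise ParameterError(f"{context}: no volumes given")
    ref = grids[0]
    for g in grids[1:]:
        if not ref.same_geometry(g):
            raise GeometryError(
                f"{context}: geometry mismatch — shape {ref.shape} / "
                f"affine\n{ref.affine}\nvs shape {g.shape} / "
                f"affine\n{g.affine}"
            )
    return ref


@dataclass
class AtlasParcellation:
    """Integer-labelled parcellation sharing a :class:`VolumeGrid` geometry.

    ``labels`` uses 0 for background and 1..R for region ids; every id in
    that range must appear in ``region_names``.
    """

    labels: np.ndarray
    region_names: Mapping[int, str]
    grid: VolumeGrid = field(repr=False)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ParameterError("atlas labels must be 3-D")
        if self.labels.shape != self.grid.shape:
            raise GeometryError(
                f"atlas labels shape {self.labels.shape} does not match "
                f"grid shape {self.grid.shape}"
            )
        if not np.issubdtype(self.labels.dtype, np.integer):
            lab = np.asarray(self.labels)
            if not np.allclose(lab, np.round(lab)):
                raise ParameterError("atlas labels must be integers")
            self.labels = np.round(lab).astype(np.int32)
        if self.labels.min() < 0:
            raise ParameterError("atlas labels must be nonnegative")
        r = max(self.region_names, default=0)
        if r < 2:
            raise ParameterError("parcellation needs at least 2 regions")
        if int(self.labels.max()) > r:
            raise ParameterError(
                f"label {int(self.labels.max())} exceeds the lookup "
                f"table's largest region id {r}"
            )
        missing = [i for i in range(1, r + 1)
                   if i not in self.region_names]
        if missing:
            raise ParameterError(
                f"region ids missing from the lookup table: {missing[:10]}"
            )

    @property
    def n_regions(self) -> int:
        """Number of regions declared in the lookup table (some may be
        empty in the label volume)."""
        return max(self.region_names)

    @property
    def region_ids(self) -> np.ndarray:
        return np.arange(1, self.n_regions + 1)
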