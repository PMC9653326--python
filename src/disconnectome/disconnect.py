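"""Turn binary lesions into voxelwise disconnection probability maps.

A lesion "hits" a tract when any lesioned voxel lies on the tract's
core, i.e. where the tract probability exceeds ``hit_threshold``
(default 0.5). The patient's disconnection map is then the voxelwise
maximum of the hit tracts' probability fields — disconnection stays a
probability in [0, 1] and a lesion touching no tract yields an all-zero
map. This is a desk-scale emulation of probabilistic disconnectome
construction; it does not reproduce tractography-based maps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np

from .errors import ParameterError
from .grids import VolumeGrid, require_same_geometry

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .synthetic import TractSystem


@dataclass
class LesionMask:
    """Binary mask of lesioned tissue (1 = lesioned) for one patient."""

    mask: VolumeGrid
    patient_id: str

    def __post_init__(self) -> None:
        vals = np.unique(self.mask.data)
        if not np.isin(vals, (0.0, 1.0)).all():
            raise ParameterError(
                f"{self.patient_id}: lesion mask must be binary, "
                f"found values {vals[:5]}"
            )
        if not self.mask.data.any():
            raise ParameterError(f"{self.patient_id}: empty lesion mask")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.data.sum())


@dataclass
class DisconnectionMap:
    """Per-voxel probability in [0, 1] that white matter is disconnected."""

    probmap: VolumeGrid
    patient_id: str

    def __post_init__(self) -> None:
        d = self.probmap.data
        if d.min() < 0.0 or d.max() > 1.0:
            raise ParameterError(
                f"{self.patient_id}: disconnection values outside [0, 1]"
            )


def lesion_to_disconnection(lesion: LesionMask,
                            tracts: "TractSystem",
                            hit_threshold: float = 0.5) -> DisconnectionMap:
    """Disconnection map of one lesion against a tract system.

    A tract is hit iff some lesion voxel has tract probability above
    ``hit_threshold``; the output is the voxelwise max over hit tracts.
    """
    if not 0.0 < hit_threshold < 1.0:
        raise ParameterError(
            f"hit_threshold must be in (0, 1), got {hit_threshold}"
        )
    grid = require_same_geometry(
        [lesion.mask, *tracts.tracts], "lesion_to_disconnection"
    )
    inside = lesion.mask.data > 0
    prob = np.zeros(grid.shape)
    for tract in tracts.tracts:
        if (tract.data[inside] > hit_threshold).any():
            np.maximum(prob, tract.data, out=prob)
    return DisconnectionMap(probmap=grid.with_data(prob),
                            patient_id=lesion.patient_id)


def batch_disconnect(lesions: Sequence[LesionMask],
                     tracts: "TractSystem",
                     hit_threshold: float = 0.5) -> list[DisconnectionMap]:
    """Order-preserving :func:`lesion_to_disconnection` over a cohort."""
    if len(lesions) == 0:
        raise ParameterError("batch_disconnect: empty lesion list")
    out: list[DisconnectionMap] = []
    for lesion in lesions:
        try:
            out.append(lesion_to_disconnection(lesion, tracts,
                                               hit_threshold))
        except Exception as exc:
            raise type(exc)(
                f"patient {lesion.patient_id}: {exc}"
            ) from exc
    return out
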