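"""Principal-component decomposition of patient disconnection maps.

The cohort's disconnection maps form a patients x voxels matrix
(restricted to an analysis mask); PCA with voxelwise mean removal and
no variance scaling yields spatial component maps ordered by explained
variance. The retained number K is the smallest for which the
cumulative explained-variance fraction exceeds a threshold (default
0.99); an explicit ``k_override`` supports exact-K workflows. Component
sign and scale are arbitrary — everything downstream must be invariant
to flipping any component's sign.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.decomposition import PCA

from .disconnect import DisconnectionMap
from .errors import DegenerateDataError, ParameterError
from .grids import VolumeGrid, require_same_geometry


@dataclass
class ComponentSet:
    """K principal-component spatial maps with explained variance."""

    maps: list[VolumeGrid]
    explained_var: np.ndarray
    cum_var: np.ndarray
    mean_map: VolumeGrid
    mask: VolumeGrid = field(repr=False)
    set_tag: str = "original"

    def __post_init__(self) -> None:
        self.explained_var = np.asarray(self.explained_var, float)
        self.cum_var = np.asarray(self.cum_var, float)
        if np.any(np.diff(self.explained_var) > 1e-12):
            raise ParameterError("explained_var must be non-increasing")
        if np.any(np.diff(self.cum_var) < -1e-12):
            raise ParameterError("cum_var must be non-decreasing")
        if self.cum_var[-1] > 1.0 + 1e-9:
            raise ParameterError("cumulative variance exceeds 1")

    @property
    def n_components(self) -> int:
        return len(self.maps)


def _as_grids(maps: Sequence[DisconnectionMap | VolumeGrid]
              ) -> list[VolumeGrid]:
    return [m.probmap if isinstance(m, DisconnectionMap) else m
            for m in maps]


def fit_components(disconnection_maps: Sequence[DisconnectionMap | VolumeGrid],
                   variance_threshold: float = 0.99,
                   analysis_mask: VolumeGrid | None = None,
                   k_override: int | None = None,
                   set_tag: str = "original") -> ComponentSet:
    """PCA of a cohort of disconnection maps.

    Parameters
    ----------
    disconnection_maps:
        At least 3 maps sharing one geometry.
    variance_threshold:
        Fraction in (0, 1); K is the smallest count of leading
        components whose cumulative explained variance exceeds it.
    analysis_mask:
        Binary volume restricting the voxels entering the PCA; defaults
        to voxels nonzero in at least one patient.
    k_override:
        Fix K explicitly instead of deriving it from the threshold.
    """
    grids = _as_grids(disconnection_maps)
    if len(grids) < 3:
        raise ParameterError(
            f"need >= 3 disconnection maps, got {len(grids)}"
        )
    if not 0.0 < variance_threshold < 1.0:
        raise ParameterError("variance_threshold must be in (0, 1)")
    ref = require_same_geometry(
        grids if analysis_mask is None else [*grids, analysis_mask],
        "fit_components",
    )
    stack = np.stack([g.data for g in grids])  # patients x grid
    if analysis_mask is not None:
        mask = analysis_mask.data > 0
    else:
        mask = np.any(stack != 0, axis=0)
    if not mask.any():
        raise DegenerateDataError("all-zero data matrix: no voxel has "
                                  "signal in any patient")
    x = stack[:, mask]
    if not x.any():
        raise DegenerateDataError("analysis mask contains no signal")

    pca = PCA(svd_solver="full")
    pca.fit(x)
    evr = pca.explained_variance_ratio_
    cum = np.cumsum(evr)
    if k_override is not None:
        if not 1 <= k_override <= len(evr):
            raise ParameterError(
                f"k_override {k_override} outside 1..{len(evr)}"
            )
        k = k_override
    else:
        above = np.nonzero(cum > variance_threshold)[0]
        k = int(above[0]) + 1 if len(above) else len(evr)

    maps = []
    for axis in pca.components_[:k]:
        vol = np.zeros(ref.shape)
        vol[mask] = axis
        maps.append(ref.with_data(vol))
    mean_vol = np.zeros(ref.shape)
    mean_vol[mask] = pca.mean_
    return ComponentSet(
        maps=maps,
        explained_var=evr[:k],
        cum_var=cum[:k],
        mean_map=ref.with_data(mean_vol),
        mask=ref.with_data(mask.astype(float)),
        set_tag=set_tag,
    )


def split_sets(disconnection_maps: Sequence[DisconnectionMap | VolumeGrid],
               seed: int,
               variance_threshold: float = 0.99,
               k_override: int | None = None
               ) -> tuple[ComponentSet, ComponentSet]:
    """Random seeded patient halving into original/replication sets.

    Both halves are fitted with the same analysis mask (voxels nonzero
    in at least one patient of the full cohort) and the same threshold,
    so their component maps live on a common voxel support.
    """
    grids = _as_grids(disconnection_maps)
    if len(grids) < 6:
        raise ParameterError(
            f"need >= 6 maps to form two component sets, got {len(grids)}"
        )
    ref = require_same_geometry(grids, "split_sets")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(grids))
    half = len(grids) // 2
    shared = np.any(np.stack([g.data for g in grids]) != 0, axis=0)
    shared_mask = ref.with_data(shared.astype(float))
    first = [disconnection_maps[i] for i in order[:half]]
    second = [disconnection_maps[i] for i in order[half:]]
    original = fit_components(first, variance_threshold,
                              analysis_mask=shared_mask,
                              k_override=k_override, set_tag="original")
    replication = fit_components(second, variance_threshold,
                                 analysis_mask=shared_mask,
                                 k_override=k_override,
                                 set_tag="replication")
    return original, replication
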