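"""Group-level t-maps and atlas region profiles.

The group map is a voxelwise one-sample Student t statistic across
subjects, computed on the signal mask (voxels with nonzero value in
every subject) and Bonferroni-thresholded over that mask, keeping only
significant *positive* activations. Any scalar map can be reduced to a
region profile — the vector of its mean value per atlas region — which
is the common space for decoding and patient-level correlations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateDataError, GeometryError, ParameterError
from .grids import AtlasParcellation, VolumeGrid, require_same_geometry

log = logging.getLogger(__name__)


@dataclass
class TMap:
    """Voxelwise one-sample t statistics over a signal mask."""

    tvals: VolumeGrid
    n_subjects: int
    signal_mask: VolumeGrid = field(repr=False)
    n_mask_voxels: int = 0
    alpha: float = 0.05
    zero_variance_mask: VolumeGrid | None = field(default=None, repr=False)

    @property
    def df(self) -> int:
        return self.n_subjects - 1


@dataclass
class RegionProfile:
    """Mean map value per atlas region (map units)."""

    values: np.ndarray
    region_ids: np.ndarray
    source_tag: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.region_ids = np.asarray(self.region_ids, dtype=np.int64)
        if len(self.values) != len(self.region_ids):
            raise ParameterError("values and region_ids length mismatch")

    @property
    def n_regions(self) -> int:
        return len(self.values)

    def aligned_with(self, other: "RegionProfile") -> bool:
        return (self.n_regions == other.n_regions
                and (self.region_ids == other.region_ids).all())


def group_tmap(subject_maps: Sequence[VolumeGrid],
               alpha: float = 0.05) -> TMap:
    """One-sample t statistic per voxel across subjects.

    The signal mask is the set of voxels nonzero in *every* subject;
    t = mean / (sd / sqrt(n)) with the n-1 standard-deviation
    denominator. Voxels with zero across-subject variance get t = 0 and
    are flagged in ``zero_variance_mask``.
    """
    if len(subject_maps) < 2:
        raise ParameterError(
            f"need >= 2 subject maps, got {len(subject_maps)}"
        )
    ref = require_same_geometry(subject_maps, "group_tmap")
    stack = np.stack([m.data for m in subject_maps])
    mask = np.all(stack != 0, axis=0)
    if not mask.any():
        raise DegenerateDataError(
            "empty signal mask: no voxel has signal in all subjects"
        )
    n = stack.shape[0]
    vals = stack[:, mask]
    mean = vals.mean(axis=0)
    sd = vals.std(axis=0, ddof=1)
    zerovar = sd == 0
    t = np.zeros_like(mean)
    nz = ~zerovar
    t[nz] = mean[nz] / (sd[nz] / np.sqrt(n))

    tvol = np.zeros(ref.shape)
    tvol[mask] = t
    zv_vol = np.zeros(ref.shape)
    zv_vol[mask] = zerovar.astype(float)
    return TMap(
        tvals=ref.with_data(tvol),
        n_subjects=n,
        signal_mask=ref.with_data(mask.astype(float)),
        n_mask_voxels=int(mask.sum()),
        alpha=alpha,
        zero_variance_mask=ref.with_data(zv_vol),
    )


def bonferroni_critical_t(df: int, alpha: float,
                          n_tests: int, two_sided: bool = False) -> float:
    """Critical t for a Bonferroni-corrected voxelwise threshold."""
    p = alpha / n_tests
    if two_sided:
        p = p / 2.0
    return float(stats.t.isf(p, df))


def threshold_bonferroni(tmap: TMap, two_sided: bool = False) -> VolumeGrid:
    """Keep only significant positive t values, Bonferroni over the mask.

    A voxel survives when its Student-t p-value (one-sided positive
    tail by default; two-sided behind the flag) is below
    ``alpha / n_mask_voxels`` *and* its t is positive. Everything else
    is set to 0, so the output's nonzero voxels are a sub-field of the
    input t-map.
    """
    if tmap.n_mask_voxels < 1:
        raise ParameterError("t-map has an empty signal mask")
    t = tmap.tvals.data
    mask = tmap.signal_mask.data > 0
    p_thresh = tmap.alpha / tmap.n_mask_voxels
    if two_sided:
        p = 2.0 * stats.t.sf(np.abs(t[mask]), tmap.df)
    else:
        p = stats.t.sf(t[mask], tmap.df)
    keep = (p < p_thresh) & (t[mask] > 0)
    out = np.zeros(tmap.tvals.shape)
    vals = np.zeros(mask.sum())
    vals[keep] = t[mask][keep]
    out[mask] = vals
    return tmap.tvals.with_data(out)


def region_profile(vol: VolumeGrid, atlas: AtlasParcellation,
                   source_tag: str = "") -> RegionProfile:
    """Mean map value per atlas region.

    Regions with zero voxels are dropped from the profile with a logged
    warning; an atlas whose regions are all empty is degenerate.
    """
    if not vol.same_geometry(atlas.grid):
        raise GeometryError(
            f"region_profile: map shape {vol.shape} does not match atlas "
            f"shape {atlas.grid.shape}"
        )
    labels = atlas.labels.ravel()
    r_max = atlas.n_regions
    counts = np.bincount(labels, minlength=r_max + 1)[1:r_max + 1]
    sums = np.bincount(labels, weights=vol.data.ravel(),
                       minlength=r_max + 1)[1:r_max + 1]
    present = counts > 0
    if not present.any():
        raise DegenerateDataError("every atlas region is empty")
    if not present.all():
        empty = np.nonzero(~present)[0] + 1
        log.warning("dropping %d empty atlas regions: %s",
                    len(empty), empty[:10].tolist())
    values = sums[present] / counts[present]
    ids = np.arange(1, r_max + 1)[present]
    return RegionProfile(values=values, region_ids=ids,
                         source_tag=source_tag)
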