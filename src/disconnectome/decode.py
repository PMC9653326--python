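"""Decode an activation profile as a mixture of component profiles.

Ordinary least squares (with intercept) of the fMRI region profile on
the K component region profiles. The reported "loadings" are
standardized coefficients — raw coefficient x predictor sd / dependent
sd — which makes the downstream voxel regression scale-free and the
whole decode invariant to rescaling the fMRI map by any positive
constant. A permutation test (shuffling the dependent profile across
regions) guards interpretation of individual loadings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import (AlignmentError, CollinearityError, ParameterError,
                     UnderdeterminedError)
from .fmri_group import RegionProfile

#: condition number above which the component design is rejected
MAX_CONDITION = 1e8


@dataclass
class LoadingVector:
    """Standardized regression loadings of K components."""

    loadings: np.ndarray
    raw_coefs: np.ndarray
    intercept: float
    r_squared: float
    k_used: int
    n_regions: int

    def __post_init__(self) -> None:
        self.loadings = np.asarray(self.loadings, dtype=np.float64)
        self.raw_coefs = np.asarray(self.raw_coefs, dtype=np.float64)
        if len(self.loadings) != self.k_used:
            raise ParameterError("loading length differs from k_used")
        if not -1e-10 <= self.r_squared <= 1.0 + 1e-10:
            raise ParameterError(f"r_squared {self.r_squared} outside [0,1]")
        self.r_squared = float(min(max(self.r_squared, 0.0), 1.0))


def _design(fmri: RegionProfile,
            component_profiles: Sequence[RegionProfile]
            ) -> tuple[np.ndarray, np.ndarray]:
    k = len(component_profiles)
    if k < 1:
        raise ParameterError("no component profiles given")
    for i, cp in enumerate(component_profiles):
        if not fmri.aligned_with(cp):
            raise AlignmentError(
                f"component profile {i} is not aligned with the fMRI "
                f"profile (region ids or order differ)"
            )
    r = fmri.n_regions
    if r <= k + 1:
        raise UnderdeterminedError(
            f"{r} regions cannot constrain {k} components plus intercept"
        )
    x = np.column_stack([cp.values for cp in component_profiles])
    y = fmri.values.astype(np.float64)
    dead = np.nonzero(np.ptp(x, axis=0) == 0)[0]
    if len(dead):
        raise CollinearityError(
            f"component profile(s) {dead.tolist()} have zero variance "
            f"across regions"
        )
    return x, y


def decode_profile(fmri: RegionProfile,
                   component_profiles: Sequence[RegionProfile]
                   ) -> LoadingVector:
    """OLS decode of the fMRI profile on component profiles.

    Returns standardized loadings, raw coefficients, intercept and the
    ordinary coefficient of determination.
    """
    x, y = _design(fmri, component_profiles)
    k = x.shape[1]
    sx = x.std(axis=0, ddof=1)
    sy = y.std(ddof=1)

    zx = (x - x.mean(axis=0)) / sx
    cond = np.linalg.cond(zx)
    if cond > MAX_CONDITION:
        raise CollinearityError(
            f"design condition number {cond:.3g} exceeds {MAX_CONDITION:.0e};"
            " use fewer components or a finer parcellation"
        )

    design = np.column_stack([np.ones(len(y)), x])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    intercept, raw = float(coef[0]), coef[1:]
    fitted = design @ coef
    ss_res = float(((y - fitted) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        raise CollinearityError("fMRI profile has zero variance")
    r2 = 1.0 - ss_res / ss_tot
    loadings = raw * sx / sy
    return LoadingVector(loadings=loadings, raw_coefs=raw,
                         intercept=intercept, r_squared=r2,
                         k_used=k, n_regions=len(y))


def permute_loading_significance(fmri: RegionProfile,
                                 component_profiles: Sequence[RegionProfile],
                                 n_perm: int = 999,
                                 seed: int = 0) -> np.ndarray:
    """Permutation p-value per component loading.

    The dependent profile is permuted across regions and the regression
    refitted; p = (1 + #{|beta*_perm| >= |beta*_obs|}) / (1 + n_perm) on
    the standardized coefficients, making the p-values invariant to
    component sign flips.
    """
    if n_perm < 99:
        raise ParameterError(f"n_perm must be >= 99, got {n_perm}")
    x, y = _design(fmri, component_profiles)
    sx = x.std(axis=0, ddof=1)
    sy = y.std(ddof=1)
    if sy == 0:
        raise CollinearityError("fMRI profile has zero variance")
    zx = (x - x.mean(axis=0)) / sx
    zy = (y - y.mean()) / sy
    # standardized betas == OLS of zy on centred-standardized zx
    hat = np.linalg.pinv(zx)  # K x R
    obs = np.abs(hat @ zy)

    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(zy) for _ in range(n_perm)], axis=1)
    betas = np.abs(hat @ perms)  # K x n_perm
    exceed = (betas >= obs[:, None]).sum(axis=1)
    return (1.0 + exceed) / (1.0 + n_perm)
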