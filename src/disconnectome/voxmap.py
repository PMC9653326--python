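"""Loading-driven voxelwise regression with max-statistic permutation FWE.

At every voxel the K component-map values are regressed on the K
decoded loadings (simple regression across components, df = K - 2); the
slope t statistic says how strongly that voxel's white matter tracks
the decoded activation mixture. Family-wise inference permutes the
loading vector's entries, records the maximum |t| over the analysis
mask per permutation, and converts observed |t| to corrected p-values —
the max-statistic analogue of permutation tools such as FSL randomise
for a single fixed covariate. The test is two-sided on |t| because
component signs are arbitrary.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .decode import LoadingVector
from .errors import DegenerateDataError, ParameterError
from .grids import VolumeGrid, require_same_geometry

#: perfect-fit voxels get |t| capped here before ranking
T_CAP = 1e6


@dataclass
class VoxelPermResult:
    """Observed t-map with FWE-corrected p-values and significance mask."""

    tmap: VolumeGrid
    pmap_fwe: VolumeGrid
    sig_mask: VolumeGrid
    analysis_mask: VolumeGrid = field(repr=False)
    n_perm: int = 0
    alpha: float = 0.05
    seed: int = 0
    exact: bool = False


def _coerce_loadings(loadings: LoadingVector | np.ndarray) -> np.ndarray:
    vec = loadings.loadings if isinstance(loadings, LoadingVector) \
        else np.asarray(loadings, dtype=np.float64)
    return np.asarray(vec, dtype=np.float64)


def _mask_and_matrix(component_maps: Sequence[VolumeGrid]
                     ) -> tuple[VolumeGrid, np.ndarray, np.ndarray]:
    ref = require_same_geometry(component_maps, "voxel_regression")
    stack = np.stack([m.data for m in component_maps])  # K x grid
    mask = stack.var(axis=0) > 0
    if not mask.any():
        raise DegenerateDataError(
            "no voxel varies across the component maps"
        )
    return ref, mask, stack[:, mask]  # K x V


def _slope_tstats(matrix: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Slope t statistic of each column of ``matrix`` regressed on ``x``.

    ``matrix`` is K x V (component values per voxel), ``x`` length K.
    Perfect fits are capped at +-T_CAP instead of emitting infinities.
    """
    k = len(x)
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx == 0:
        raise ParameterError("loading vector is constant; slope undefined")
    sxy = xc @ matrix  # V
    yc = matrix - matrix.mean(axis=0)
    syy = (yc ** 2).sum(axis=0)
    ss_res = np.maximum(syy - sxy ** 2 / sxx, 0.0)
    df = k - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(ss_res / (df * sxx))
        t = np.where(se > 0, (sxy / sxx) / se,
                     np.sign(sxy) * T_CAP)
    return np.clip(t, -T_CAP, T_CAP)


def voxel_regression(component_maps: Sequence[VolumeGrid],
                     loadings: LoadingVector | np.ndarray) -> VolumeGrid:
    """Per-voxel slope t statistics of component values on loadings.

    The analysis mask is the set of voxels with nonzero variance across
    the K component maps; all other voxels are 0 in the output.
    """
    x = _coerce_loadings(loadings)
    if len(component_maps) < 3:
        raise ParameterError(
            f"need >= 3 component maps for df >= 1, got "
            f"{len(component_maps)}"
        )
    if len(x) != len(component_maps):
        raise ParameterError(
            f"{len(x)} loadings for {len(component_maps)} component maps"
        )
    ref, mask, matrix = _mask_and_matrix(component_maps)
    out = np.zeros(ref.shape)
    out[mask] = _slope_tstats(matrix, x)
    return ref.with_data(out)


def _null_permutations(x: np.ndarray, n_perm: int,
                       seed: int) -> tuple[np.ndarray, bool]:
    """Null loading vectors: exact enumeration or distinct random draws.

    Returns (perms, exact). For exact tests the identity permutation is
    excluded from the returned array; the p-value formula adds it back.
    """
    k = len(x)
    total = math.factorial(k)
    if total <= n_perm:
        perms = np.array([p for p in itertools.permutations(range(k))])
        ident = np.arange(k)
        keep = ~(perms == ident).all(axis=1)
        return x[perms[keep]], True
    rng = np.random.default_rng(seed)
    if total <= 50 * n_perm:
        # small permutation space: sample distinct permutations
        seen: set[tuple[int, ...]] = set()
        rows = []
        while len(rows) < n_perm:
            p = tuple(rng.permutation(k))
            if p not in seen:
                seen.add(p)
                rows.append(p)
        return x[np.array(rows)], False
    idx = np.stack([rng.permutation(k) for _ in range(n_perm)])
    return x[idx], False


def permutation_fwe(component_maps: Sequence[VolumeGrid],
                    loadings: LoadingVector | np.ndarray,
                    n_perm: int = 1000,
                    alpha: float = 0.05,
                    seed: int = 0,
                    chunk: int = 256) -> VoxelPermResult:
    """Max-|t| permutation FWE correction of the voxelwise regression.

    The null relabels the loading vector (entries permuted without
    replacement); when K! <= n_perm every distinct permutation is
    enumerated and the test is exact. pmap_fwe(v) =
    (1 + #{max|t|_perm >= |t_obs(v)|}) / (1 + n_null).
    """
    x = _coerce_loadings(loadings)
    if n_perm < 99:
        raise ParameterError(f"n_perm must be >= 99, got {n_perm}")
    if not 0.0 < alpha < 1.0:
        raise ParameterError("alpha must be in (0, 1)")
    if len(component_maps) < 3:
        raise ParameterError("need >= 3 component maps")
    if len(x) != len(component_maps):
        raise ParameterError("loadings/component count mismatch")

    ref, mask, matrix = _mask_and_matrix(component_maps)
    t_obs = _slope_tstats(matrix, x)

    perms, exact = _null_permutations(x, n_perm, seed)
    n_null = len(perms)
    max_t = np.empty(n_null)
    for lo in range(0, n_null, chunk):
        block = perms[lo:lo + chunk]
        xc = block - block.mean(axis=1, keepdims=True)
        sxx = (xc ** 2).sum(axis=1)  # identical across perms
        sxy = xc @ matrix  # B x V
        yc = matrix - matrix.mean(axis=0)
        syy = (yc ** 2).sum(axis=0)
        ss_res = np.maximum(syy[None, :] - sxy ** 2 / sxx[:, None], 0.0)
        df = len(x) - 2
        with np.errstate(divide="ignore", invalid="ignore"):
            se = np.sqrt(ss_res / (df * sxx[:, None]))
            t = np.where(se > 0, (sxy / sxx[:, None]) / se,
                         np.sign(sxy) * T_CAP)
        max_t[lo:lo + chunk] = np.abs(np.clip(t, -T_CAP, T_CAP)).max(axis=1)

    sorted_max = np.sort(max_t)
    exceed = n_null - np.searchsorted(sorted_max, np.abs(t_obs),
                                      side="left")
    p_masked = (1.0 + exceed) / (1.0 + n_null)

    pvol = np.ones(ref.shape)
    pvol[mask] = p_masked
    sig = np.zeros(ref.shape)
    sig[mask] = (p_masked < alpha).astype(float)
    tvol = np.zeros(ref.shape)
    tvol[mask] = t_obs
    return VoxelPermResult(
        tmap=ref.with_data(tvol),
        pmap_fwe=ref.with_data(pvol),
        sig_mask=ref.with_data(sig),
        analysis_mask=ref.with_data(mask.astype(float)),
        n_perm=n_null,
        alpha=alpha,
        seed=seed,
        exact=exact,
    )


def replication_correlation(map_a: VolumeGrid, map_b: VolumeGrid,
                            mask: VolumeGrid) -> float:
    """Pearson r between two unthresholded t-maps over a mask."""
    require_same_geometry([map_a, map_b, mask], "replication_correlation")
    m = mask.data > 0
    if m.sum() < 3:
        raise ParameterError("mask must contain >= 3 voxels")
    a = map_a.data[m]
    b = map_b.data[m]
    if a.std() == 0 or b.std() == 0:
        raise DegenerateDataError(
            "a map has zero variance over the mask; correlation undefined"
        )
    return float(stats.pearsonr(a, b).statistic)
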