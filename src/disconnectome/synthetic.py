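"""Synthetic brains with known ground truth.

The generators here stand in for the two data sources the pipeline was
designed around — a large cohort of stroke lesions with derived
disconnection maps, and a group fMRI sample — so that every downstream
stage has a recovery test against known truth:

* tube-shaped tract probability fields along random smooth polylines
  (Gaussian cross-section, peak-normalised to 1);
* binary ellipsoid lesions of varied size and location;
* a nearest-seed (Voronoi) volumetric parcellation;
* per-subject activation maps equal to a known linear combination of
  component spatial maps plus i.i.d. Gaussian voxel noise.

All generators are pure functions of their parameters and an explicit
integer seed; no global RNG state is used.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.spatial import cKDTree

from .disconnect import LesionMask
from .errors import ParameterError
from .grids import AtlasParcellation, VolumeGrid

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .components import ComponentSet

#: tract probabilities below this are truncated to exactly 0, so that
#: "outside all tracts" is a well-defined voxel set
TRACT_FLOOR = 0.01


@dataclass
class TractSystem:
    """A set of tract probability fields sharing one grid."""

    tracts: list[VolumeGrid]
    names: list[str]
    seed: int

    def __post_init__(self) -> None:
        if len(self.tracts) != len(self.names):
            raise ParameterError("one name per tract required")
        for name, t in zip(self.names, self.tracts):
            if t.data.min() < 0.0 or t.data.max() > 1.0:
                raise ParameterError(f"tract {name}: values outside [0, 1]")
            if not (t.data > 0.5).any():
                raise ParameterError(f"tract {name}: no core voxel (> 0.5)")

    @property
    def n_tracts(self) -> int:
        return len(self.tracts)

    def support(self) -> np.ndarray:
        """Boolean union of all tract supports (probability > 0)."""
        out = np.zeros(self.tracts[0].shape, dtype=bool)
        for t in self.tracts:
            out |= t.data > 0
        return out


@dataclass
class SyntheticTruth:
    """Ground truth behind a batch of synthetic subject maps."""

    true_loadings: np.ndarray
    noise_sd: float
    n_subjects: int
    seed: int

    def __post_init__(self) -> None:
        self.true_loadings = np.asarray(self.true_loadings, dtype=np.float64)
        if self.n_subjects < 2:
            raise ParameterError("n_subjects must be >= 2")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")


def make_grid(n: int) -> VolumeGrid:
    """Zero-filled isotropic n^3 grid with 2 mm voxels."""
    if n < 8:
        raise ParameterError(f"grid edge must be >= 8 voxels, got {n}")
    affine = np.diag([2.0, 2.0, 2.0, 1.0])
    return VolumeGrid(data=np.zeros((n, n, n)), affine=affine,
                      space_tag=f"synthetic-{n}")


def _random_polyline(rng: np.random.Generator, n: int) -> np.ndarray:
    """Dense sample of a smooth random curve spanning >= half the grid."""
    axis = int(rng.integers(0, 3))
    n_ctrl = 4
    along = np.linspace(rng.uniform(0, 0.15 * n),
                        rng.uniform(0.85 * n, n - 1), n_ctrl)
    ctrl = np.empty((n_ctrl, 3))
    ctrl[:, axis] = along
    for ax in range(3):
        if ax == axis:
            continue
        base = rng.uniform(0.25 * n, 0.75 * n)
        ctrl[:, ax] = base + rng.normal(0.0, n / 10.0, size=n_ctrl)
    ctrl = np.clip(ctrl, 1.0, n - 2.0)
    t = np.linspace(0.0, 1.0, n_ctrl)
    spline = CubicSpline(t, ctrl, axis=0)
    # ~4 samples per voxel of arc length keeps the tube bead-free
    return spline(np.linspace(0.0, 1.0, 8 * n))


def simulate_tracts(grid: VolumeGrid, n_tracts: int,
                    seed: int) -> TractSystem:
    """Tube-shaped tract probability fields on ``grid``.

    Each tract follows a random smooth polyline spanning at least half
    the grid, with Gaussian cross-section of sigma ~1.2-2 voxels (core
    radius roughly 2-4 voxels). Fields are peak-normalised to 1 and
    floored to 0 below :data:`TRACT_FLOOR`.
    """
    if n_tracts < 1:
        raise ParameterError("n_tracts must be >= 1")
    n = grid.shape[0]
    rng = np.random.default_rng(seed)
    idx = np.indices(grid.shape).reshape(3, -1).T.astype(np.float64)
    tracts, names = [], []
    for k in range(n_tracts):
        curve = _random_polyline(rng, n)
        sigma = rng.uniform(1.2, 2.0)
        dist, _ = cKDTree(curve).query(idx, k=1)
        prob = np.exp(-dist ** 2 / (2.0 * sigma ** 2)).reshape(grid.shape)
        prob /= prob.max()
        prob[prob < TRACT_FLOOR] = 0.0
        tracts.append(grid.with_data(prob))
        names.append(f"tract_{k:02d}")
    return TractSystem(tracts=tracts, names=names, seed=seed)


def simulate_lesions(grid: VolumeGrid, n_patients: int, seed: int,
                     radius_range: tuple[float, float] = (2.0, 5.0)
                     ) -> list[LesionMask]:
    """Random binary ellipsoid lesions.

    Each lesion has a random centre inside the grid's interior and
    random semi-axes drawn uniformly from ``radius_range`` (voxels).
    """
    if n_patients < 1:
        raise ParameterError("n_patients must be >= 1")
    r_min, r_max = radius_range
    n = grid.shape[0]
    if not (1.0 <= r_min <= r_max <= n / 3.0):
        raise ParameterError(
            f"radius_range {radius_range} must satisfy "
            f"1 <= min <= max <= {n / 3:.1f} (grid edge / 3)"
        )
    rng = np.random.default_rng(seed)
    ii, jj, kk = np.indices(grid.shape).astype(np.float64)
    lesions = []
    for p in range(n_patients):
        centre = rng.uniform(r_min, n - 1 - r_min, size=3)
        semi = rng.uniform(r_min, r_max, size=3)
        mask = (((ii - centre[0]) / semi[0]) ** 2
                + ((jj - centre[1]) / semi[1]) ** 2
                + ((kk - centre[2]) / semi[2]) ** 2) <= 1.0
        lesions.append(LesionMask(mask=grid.with_data(mask.astype(float)),
                                  patient_id=f"P{p:04d}"))
    return lesions


def simulate_atlas(grid: VolumeGrid, n_regions: int,
                   seed: int) -> AtlasParcellation:
    """Nearest-seed (Voronoi) parcellation covering the whole grid."""
    if n_regions < 2:
        raise ParameterError("n_regions must be >= 2")
    rng = np.random.default_rng(seed)
    n = grid.shape[0]
    seeds = rng.uniform(0, n - 1, size=(n_regions, 3))
    idx = np.indices(grid.shape).reshape(3, -1).T.astype(np.float64)
    _, owner = cKDTree(seeds).query(idx, k=1)
    labels = (owner + 1).astype(np.int32).reshape(grid.shape)
    names = {r: f"region_{r:03d}" for r in range(1, n_regions + 1)}
    return AtlasParcellation(labels=labels, region_names=names, grid=grid)


def simulate_subject_maps(components: "ComponentSet",
                          truth: SyntheticTruth,
                          grid: VolumeGrid) -> list[VolumeGrid]:
    """Subject activation maps embedding a known loading vector.

    Each subject map is ``sum_k true_loadings[k] * component_map_k``
    plus i.i.d. Gaussian(0, noise_sd) voxel noise, so the group mean
    converges to the loading-weighted component sum.
    """
    if len(truth.true_loadings) != components.n_components:
        raise ParameterError(
            f"{len(truth.true_loadings)} loadings for "
            f"{components.n_components} components"
        )
    signal = np.zeros(grid.shape)
    for w, comp in zip(truth.true_loadings, components.maps):
        signal += w * comp.data
    rng = np.random.default_rng(truth.seed)
    maps = []
    for _ in range(truth.n_subjects):
        noise = (rng.normal(0.0, truth.noise_sd, size=grid.shape)
                 if truth.noise_sd > 0 else 0.0)
        maps.append(grid.with_data(signal + noise))
    return maps


def simulate_subject_maps_from_field(field_map: VolumeGrid,
                                     n_subjects: int,
                                     noise_sd: float,
                                     seed: int) -> list[VolumeGrid]:
    """Subject maps whose group mean is an arbitrary spatial field.

    Used by the tract-truth fixture: activation generated from a chosen
    tract field exercises the voxel-mapping stage against spatial truth
    rather than component-space truth.
    """
    if n_subjects < 2:
        raise ParameterError("n_subjects must be >= 2")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_subjects):
        noise = (rng.normal(0.0, noise_sd, size=field_map.shape)
                 if noise_sd > 0 else 0.0)
        out.append(field_map.with_data(field_map.data + noise))
    return out


def write_fixture(out_dir: str | os.PathLike, *, grid_size: int = 32,
                  n_tracts: int = 5, n_patients: int = 60,
                  n_regions: int = 120, n_subjects: int = 24,
                  noise_sd: float = 0.5, seed: int = 0,
                  variance_threshold: float = 0.99) -> dict:
    """Write a complete synthetic study to ``out_dir``.

    Produces tracts/, lesions/, subjects/, atlas.nii.gz + atlas.tsv and
    truth.json (true loadings, seeds, noise level). Returns the truth
    dictionary. Subject maps are built in component space from the
    cohort's own fitted components, so decoding has an exact target.
    """
    from .components import fit_components
    from .disconnect import batch_disconnect
    from .io_nifti import save_atlas, save_volume

    out_dir = str(out_dir)
    for sub in ("tracts", "lesions", "subjects"):
        os.makedirs(os.path.join(out_dir, sub), exist_ok=True)

    grid = make_grid(grid_size)
    tracts = simulate_tracts(grid, n_tracts, seed=seed)
    lesions = simulate_lesions(grid, n_patients, seed=seed + 1)
    atlas = simulate_atlas(grid, n_regions, seed=seed + 2)
    disc = batch_disconnect(lesions, tracts)
    comps = fit_components(disc, variance_threshold=variance_threshold)

    rng = np.random.default_rng(seed + 3)
    loadings = rng.normal(0.0, 1.0, size=comps.n_components)
    # scale the embedded activation so its peak sits well above the
    # subject noise floor, as in a robust task contrast
    signal = sum(w * m.data for w, m in zip(loadings, comps.maps))
    peak = np.abs(signal).max()
    if peak > 0:
        loadings *= max(5.0, 10.0 * noise_sd) / peak
    truth = SyntheticTruth(true_loadings=loadings, noise_sd=noise_sd,
                           n_subjects=n_subjects, seed=seed + 4)
    subjects = simulate_subject_maps(comps, truth, grid)

    for name, t in zip(tracts.names, tracts.tracts):
        save_volume(t, os.path.join(out_dir, "tracts", f"{name}.nii.gz"))
    for les in lesions:
        save_volume(les.mask,
                    os.path.join(out_dir, "lesions",
                                 f"{les.patient_id}.nii.gz"),
                    dtype=np.int16)
    for s, vol in enumerate(subjects):
        save_volume(vol, os.path.join(out_dir, "subjects",
                                      f"S{s:04d}.nii.gz"))
    save_atlas(atlas, os.path.join(out_dir, "atlas.nii.gz"),
               os.path.join(out_dir, "atlas.tsv"))

    truth_doc = {
        "grid_size": grid_size,
        "n_tracts": n_tracts,
        "n_patients": n_patients,
        "n_regions": n_regions,
        "n_subjects": n_subjects,
        "n_components": int(comps.n_components),
        "noise_sd": noise_sd,
        "seed": seed,
        "subject_seed": truth.seed,
        "variance_threshold": variance_threshold,
        "true_loadings": [float(x) for x in loadings],
    }
    with open(os.path.join(out_dir, "truth.json"), "w") as fh:
        json.dump(truth_doc, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return truth_doc
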