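# Methods

## Model and assumptions

The pipeline treats three quantities as living on one voxel grid: a
patient's **disconnection probability map**, a **component spatial
map** from PCA of the cohort's disconnection maps, and the group
**activation t-map**. All cross-volume operations require a single
shared geometry (shape and 4×4 affine, compared entry-wise at 1e-4);
no resampling or reorientation is ever performed — a mismatch is an
error. Volumes are float64 in memory and written as float32 NIfTI
(int16 for masks and label volumes). NaN voxels encountered on load
become 0 with a logged count.

### Disconnection construction

A lesion "hits" a tract when at least one lesioned voxel lies on the
tract's core, i.e. where the tract probability exceeds the
`hit_threshold` (default 0.5 — the tube's core rather than its tails).
The disconnection map is the voxelwise **maximum** over hit tracts, not
the sum, so values remain probabilities in [0, 1]; a lesion that hits
no tract yields the all-zero map and is later excluded from
correlation analyses as undefined. This construction is monotone: a
larger lesion can only increase disconnection. It is a desk-scale
emulation of probabilistic disconnectome construction, not a
reproduction of tractography-based maps.

### Components

PCA is fitted on the patients × voxels matrix restricted to an
analysis mask (default: voxels nonzero in at least one patient), with
voxelwise mean removal and **no variance scaling** — the maps share
units (probabilities), so whitening would distort the spatial
structure. K is the smallest count with cumulative explained variance
above `variance_threshold` (default 0.99); `k_override` fixes K for
exact-K workflows. Component sign and scale are arbitrary, and the
pipeline is built so results do not depend on them (see Invariances).
Original/replication component pairs come from a seeded random halving
of the cohort, both halves fitted on the shared mask. How a
replication set is best constructed is genuinely open; halving is the
package's choice because it guarantees independent patients.

### Group t-map

One-sample t = m̄/(s/√n) per voxel (s with the n−1 denominator) over
the signal mask — voxels nonzero in *every* subject. Zero-variance
voxels get t = 0 and a flag rather than ±inf. Thresholding keeps
voxels with one-sided positive-tail p < α/n_mask and t > 0. Sidedness
before the positivity filter is not canonical; one-sided is the
default because only positive activation is of interest, and a
two-sided variant sits behind a flag.

### Decoding

OLS of the activation's region profile on the K component region
profiles plus intercept, at region (not voxel) level — region profiles
are the common representation in which activation and disconnection
are compared. Loadings are standardized coefficients
(raw × predictor sd / dependent sd): they are scale-free, which makes
the downstream voxel regression invariant to rescaling the fMRI map.
Raw coefficients and the intercept are also reported. Guards: R > K+1
regions, no zero-variance predictor (exact, via the range of the
column), and design condition number ≤ 1e8 (region averaging can
collapse PCA profiles to near-collinearity). A permutation test on the
loadings shuffles the dependent profile across regions,
p = (1+#{|β*ₚₑᵣₘ| ≥ |β*ₒᵦₛ|})/(1+n_perm), computed on |β*| so it is
sign-flip invariant.

### Voxelwise mapping and FWE

At each voxel in the analysis mask (voxels with nonzero variance
across the K component maps), the K component values are regressed on
the K loadings; the slope t (df = K−2, intercept included) measures
how strongly that voxel's white matter tracks the decoded mixture.
Perfect-fit voxels are capped at |t| = 1e6 before ranking — order is
preserved, infinities never propagate. The family-wise null permutes
the **entries of the loading vector** (the design rows): loadings are
a fixed covariate, not symmetric errors, so sign-flipping nulls do not
apply. When K! ≤ n_perm all K! permutations are enumerated and the
test is exact (the identity is folded into the +1 of the p-value
formula); for moderate spaces (K! ≤ 50·n_perm) distinct permutations
are sampled without replacement; otherwise independent random
permutations are drawn. The maximum |t| over the mask per permutation
gives pmap_fwe(v) = (1+#{max|t|ₚₑᵣₘ ≥ |t(v)|})/(1+n_null); the test is
two-sided on |t| because component signs are arbitrary. Max-statistic
FWE at α = 0.05 is this package's explicit choice of correction; no
TFCE or cluster inference. Replication between two component sets is
the Pearson r of the two *unthresholded* t-maps over the intersection
of their masks.

### Typical lesion

Pearson r between each patient's disconnection region profile and the
activation region profile (one observation per region). Patients whose
profile has zero variance (no tract hit) are flagged undefined and
excluded with bookkeeping, never silently dropped. "Pure lesions" are
r > `effect_threshold` (default 0.5, a large effect); the criterion is
one-sided — a lesion anticorrelated with activation is not a pure
lesion of the network. The top patient is the argmax of r, ties
resolved to the lowest patient id and logged; their mask is exported
as the typical lesion.

## Invariances

Exact, tested properties:

* decode R², loadings (up to matching sign) and loading p-values are
  invariant to flipping any component's sign;
* standardized loadings, and therefore the entire voxel stage
  (bit-identical pmap_fwe given the same seed), are invariant to
  rescaling the fMRI map by any c > 0;
* a **global** joint sign flip of all component maps and loadings
  reproduces the voxel t-map and pmap_fwe bit-exactly;
* pure_fraction is invariant to rescaling and monotone non-increasing
  in the effect threshold.

Flipping a *single* component's map and loading jointly reflects one
(x, y) point of the voxelwise regression through the origin; with an
intercept this shifts the per-voxel means and provably changes the
slope t, so only the family-wise calibration (not the t values) is
preserved, and the suite checks that approximately. This is an
inherent property of the with-intercept regression, not an
implementation artifact.

## Synthetic data: what it emulates and what it does not

Generators are pure functions of (parameters, seed): tube-shaped tract
probability fields (Gaussian cross-section, σ ~1.2–2 voxels ≈ core
radius 2–4 voxels, peak-normalised to 1, truncated to exactly 0 below
0.01 so "outside all tracts" is a well-defined voxel set); binary
ellipsoid lesions with semi-axes drawn from `radius_range` (default
2–5 voxels) centred anywhere in the grid interior; a nearest-seed
Voronoi parcellation; and subject activation maps equal to a known
loading-weighted component sum plus i.i.d. Gaussian voxel noise.
Fixture loadings are scaled so the activation peak is
max(5, 10·noise_sd) — a robust task contrast whose strongest voxels
survive whole-volume Bonferroni, as real group reading maps do.

What passing tests on these data show: linear-algebra correctness
(component recovery, decoding, permutation calibration) and spatial
recovery when truth is a single tract. What they do not show: realism
of vascular lesion shapes, tractography-quality disconnection maps,
spatially correlated fMRI noise, or the population diversity of a
four-figure stroke cohort — synthetic pure-lesion rates are therefore
far higher than clinical ones.

## Problem sizes and numerical choices

The default test and acceptance runs use 16³–24³ grids, 3–8 tracts,
20–200 patients, 40–120 regions, 48 subjects, and 199–999
permutations; the spatial-truth study uses 50 seeds at 24³/8
tracts/200 patients with n_perm = 499, chosen as the smallest cohort
at which the decoded white matter reliably reaches FWE significance.
The permutation engine processes permutations in chunks of 256 to
bound memory. Degenerate inputs (all-zero cohorts, empty signal masks,
constant profiles) raise typed errors (`DegenerateDataError`,
`CollinearityError`, ...) rather than NaN.

## Known limitations

* The disconnection construction is max-over-hit-tracts on synthetic
  tubes; published disconnectome maps come from streamline
  tractography in large healthy cohorts.
* Region profiles use a single volumetric parcellation; surface
  atlases (GIFTI/CIFTI) are out of scope.
* No spatial smoothing, registration, or first-level GLM — inputs are
  assumed already normalised contrast maps on one grid.
* Max-|t| FWE is the only correction offered; cluster-extent and TFCE
  inference are deliberately excluded.
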