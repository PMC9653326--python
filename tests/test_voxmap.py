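"""Voxelwise regression and max-statistic permutation inference."""

import itertools

import numpy as np
import pytest
from scipy import stats

import disconnectome as dc


def maps_from_matrix(grid, matrix):
    """K component maps whose flattened values are the rows of matrix."""
    return [grid.with_data(row.reshape(grid.shape)) for row in matrix]


def slope_t_reference(y, x):
    """Textbook simple-regression slope t, one voxel at a time."""
    res = stats.linregress(x, y)
    if res.stderr == 0:
        return np.sign(res.slope) * 1e6
    return res.slope / res.stderr


def brute_force_fwe(matrix, x):
    """Exhaustive max-|t| permutation test via nested loops."""
    k, n_vox = matrix.shape
    t_obs = np.array([slope_t_reference(matrix[:, v], x)
                      for v in range(n_vox)])
    max_ts = []
    for perm in itertools.permutations(range(k)):
        xp = x[list(perm)]
        ts = [abs(slope_t_reference(matrix[:, v], xp))
              for v in range(n_vox)]
        max_ts.append(max(ts))
    max_ts = np.array(max_ts)
    p = np.array([(max_ts >= abs(t)).sum() / len(max_ts) for t in t_obs])
    return t_obs, p


@pytest.fixture
def grid8():
    return dc.make_grid(8)


def test_tstats_match_per_voxel_reference(grid8):
    rng = np.random.default_rng(20)
    k = 8
    matrix = rng.normal(size=(k, 8 ** 3))
    x = rng.normal(size=k)
    got = dc.voxel_regression(maps_from_matrix(grid8, matrix), x)
    flat = got.data.ravel()
    check = rng.choice(8 ** 3, size=50, replace=False)
    for v in check:
        assert np.isclose(flat[v], slope_t_reference(matrix[:, v], x),
                          atol=1e-8)


def test_perfect_fit_voxel_capped(grid8):
    rng = np.random.default_rng(21)
    x = np.array([0.5, -1.0, 2.0, 0.1])
    matrix = rng.normal(size=(4, 8 ** 3))
    matrix[:, 0] = 2.0 * x  # exact linear voxel
    got = dc.voxel_regression(maps_from_matrix(grid8, matrix), x)
    assert got.data.ravel()[0] == 1e6


def test_pairing_invariance(grid8):
    """Permuting maps together with loadings leaves the t-map fixed."""
    rng = np.random.default_rng(22)
    k = 6
    matrix = rng.normal(size=(k, 8 ** 3))
    x = rng.normal(size=k)
    order = rng.permutation(k)
    a = dc.voxel_regression(maps_from_matrix(grid8, matrix), x)
    b = dc.voxel_regression(maps_from_matrix(grid8, matrix[order]),
                            x[order])
    assert np.allclose(a.data, b.data)


def test_constant_voxels_masked_not_divided(grid8):
    rng = np.random.default_rng(23)
    matrix = rng.normal(size=(5, 8 ** 3))
    matrix[:, 7] = 3.14  # constant across components
    x = rng.normal(size=5)
    got = dc.voxel_regression(maps_from_matrix(grid8, matrix), x)
    assert got.data.ravel()[7] == 0.0


def test_needs_three_maps(grid8):
    rng = np.random.default_rng(24)
    maps = maps_from_matrix(grid8, rng.normal(size=(2, 8 ** 3)))
    with pytest.raises(dc.ParameterError):
        dc.voxel_regression(maps, np.array([1.0, 2.0]))


class TestPermutationFWE:
    def test_exact_enumeration_matches_brute_force(self, grid8):
        """K=4 gives 24 permutations: exhaustive oracle, voxel for voxel."""
        rng = np.random.default_rng(25)
        matrix = rng.normal(size=(4, 8 ** 3))
        x = np.array([1.0, -0.5, 0.25, 2.0])
        result = dc.permutation_fwe(maps_from_matrix(grid8, matrix), x,
                                    n_perm=999, seed=0)
        assert result.exact
        t_ref, p_ref = brute_force_fwe(matrix, x)
        assert np.allclose(result.tmap.data.ravel(), t_ref, atol=1e-8)
        assert np.allclose(result.pmap_fwe.data.ravel(), p_ref)

    def test_determinism(self, grid8):
        rng = np.random.default_rng(26)
        matrix = rng.normal(size=(10, 8 ** 3))
        x = rng.normal(size=10)
        maps = maps_from_matrix(grid8, matrix)
        a = dc.permutation_fwe(maps, x, n_perm=199, seed=7)
        b = dc.permutation_fwe(maps, x, n_perm=199, seed=7)
        assert np.array_equal(a.pmap_fwe.data, b.pmap_fwe.data)

    def test_p_floor_and_monotonicity(self, grid8):
        rng = np.random.default_rng(27)
        matrix = rng.normal(size=(10, 8 ** 3))
        x = rng.normal(size=10)
        res = dc.permutation_fwe(maps_from_matrix(grid8, matrix), x,
                                 n_perm=199, seed=1)
        mask = res.analysis_mask.data > 0
        p = res.pmap_fwe.data[mask]
        t = np.abs(res.tmap.data[mask])
        assert (p >= 1.0 / (res.n_perm + 1) - 1e-12).all()
        order = np.argsort(t)
        assert (np.diff(p[order]) <= 1e-12).all()

    def test_sig_mask_consistent_with_pmap(self, grid8):
        rng = np.random.default_rng(28)
        matrix = rng.normal(size=(8, 8 ** 3))
        matrix[:, :20] += 5.0 * rng.normal(size=8)[:, None]
        x = rng.normal(size=8)
        res = dc.permutation_fwe(maps_from_matrix(grid8, matrix), x,
                                 n_perm=299, seed=2, alpha=0.1)
        mask = res.analysis_mask.data > 0
        expect = (res.pmap_fwe.data < 0.1) & mask
        assert np.array_equal(res.sig_mask.data > 0, expect)

    def test_global_sign_flip_is_exact_invariance(self, grid8):
        """Negating every map AND every loading reproduces t and p exactly
        (each (loading, value) pair reflects through the origin jointly).
        """
        rng = np.random.default_rng(29)
        k = 6
        matrix = rng.normal(size=(k, 8 ** 3))
        x = rng.normal(size=k)
        a = dc.permutation_fwe(maps_from_matrix(grid8, matrix), x,
                               n_perm=199, seed=5)
        b = dc.permutation_fwe(maps_from_matrix(grid8, -matrix), -x,
                               n_perm=199, seed=5)
        assert np.array_equal(a.tmap.data, b.tmap.data)
        assert np.array_equal(a.pmap_fwe.data, b.pmap_fwe.data)

    def test_single_sign_flip_preserves_calibration(self, grid8):
        """Negating one component (map and loading together) shifts the
        per-voxel means, so t changes — but the family-wise calibration
        of the strongest effect must be preserved.
        """
        rng = np.random.default_rng(33)
        k = 8
        matrix = rng.normal(size=(k, 8 ** 3))
        x = rng.normal(size=k)
        matrix[:, :10] += 4.0 * x[:, None]
        m2 = matrix.copy()
        m2[2] *= -1
        x2 = x.copy()
        x2[2] *= -1
        res_a = dc.permutation_fwe(maps_from_matrix(grid8, matrix), x,
                                   n_perm=299, seed=5)
        res_b = dc.permutation_fwe(maps_from_matrix(grid8, m2), x2,
                                   n_perm=299, seed=5)
        assert np.isclose(res_a.pmap_fwe.data.min(),
                          res_b.pmap_fwe.data.min(), atol=0.05)

    def test_n_perm_floor(self, grid8):
        rng = np.random.default_rng(30)
        maps = maps_from_matrix(grid8, rng.normal(size=(5, 8 ** 3)))
        with pytest.raises(dc.ParameterError):
            dc.permutation_fwe(maps, rng.normal(size=5), n_perm=50)


class TestReplicationCorrelation:
    def test_identity_and_negation(self, grid8):
        rng = np.random.default_rng(31)
        vol = grid8.with_data(rng.normal(size=grid8.shape))
        mask = grid8.with_data(np.ones(grid8.shape))
        assert dc.replication_correlation(vol, vol, mask) == \
            pytest.approx(1.0)
        neg = vol.with_data(-vol.data)
        assert dc.replication_correlation(vol, neg, mask) == \
            pytest.approx(-1.0)

    def test_shared_signal_mixture_matches_analytic_r(self, grid24):
        """a = s + e1, b = s + e2 ⇒ r ≈ var(s)/(var(s)+var(e))."""
        rng = np.random.default_rng(32)
        shape = grid24.shape
        s = rng.normal(0, 2.0, size=shape)
        a = grid24.with_data(s + rng.normal(0, 1.0, size=shape))
        b = grid24.with_data(s + rng.normal(0, 1.0, size=shape))
        mask = grid24.with_data(np.ones(shape))
        r = dc.replication_correlation(a, b, mask)
        assert np.isclose(r, 4.0 / 5.0, atol=0.02)

    def test_degenerate_map_rejected(self, grid8):
        flat = grid8.with_data(np.ones(grid8.shape))
        other = grid8.with_data(np.arange(8 ** 3, dtype=float)
                                .reshape(grid8.shape))
        mask = grid8.with_data(np.ones(grid8.shape))
        with pytest.raises(dc.DegenerateDataError):
            dc.replication_correlation(flat, other, mask)
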