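"""Shared synthetic fixtures: small seeded brains with known truth."""

import numpy as np
import pytest

import disconnectome as dc


@pytest.fixture(scope="session")
def grid16():
    return dc.make_grid(16)


@pytest.fixture(scope="session")
def grid24():
    return dc.make_grid(24)


@pytest.fixture(scope="session")
def tracts16(grid16):
    return dc.simulate_tracts(grid16, n_tracts=3, seed=11)


@pytest.fixture(scope="session")
def lesions16(grid16):
    return dc.simulate_lesions(grid16, n_patients=25, seed=12)


@pytest.fixture(scope="session")
def disc16(lesions16, tracts16):
    return dc.batch_disconnect(lesions16, tracts16)


@pytest.fixture(scope="session")
def atlas16(grid16):
    return dc.simulate_atlas(grid16, n_regions=40, seed=13)


@pytest.fixture(scope="session")
def cohort24(grid24):
    """Richer cohort for decode/voxmap/typical-lesion tests."""
    tracts = dc.simulate_tracts(grid24, n_tracts=5, seed=21)
    lesions = dc.simulate_lesions(grid24, n_patients=50, seed=22)
    disc = dc.batch_disconnect(lesions, tracts)
    comps = dc.fit_components(disc)
    atlas = dc.simulate_atlas(grid24, n_regions=120, seed=23)
    return dict(grid=grid24, tracts=tracts, lesions=lesions, disc=disc,
                comps=comps, atlas=atlas)


def rank3_maps(grid, n_patients=12, seed=5):
    """Noiseless patient maps spanning exactly a 3-D pattern subspace.

    Patterns are orthogonalised disjoint-support fields in [0, 1];
    mixing weights keep every map a valid probability field.
    """
    rng = np.random.default_rng(seed)
    n = grid.shape[0]
    patterns = []
    for k in range(3):
        p = np.zeros(grid.shape)
        lo, hi = k * n // 3, (k + 1) * n // 3
        p[lo:hi] = rng.uniform(0.2, 1.0, size=(hi - lo, n, n))
        patterns.append(p)
    maps = []
    for _ in range(n_patients):
        w = rng.uniform(0.1, 1.0, size=3)
        data = sum(wk * pk for wk, pk in zip(w, patterns))
        maps.append(grid.with_data(data / data.max()))
    return maps, patterns
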