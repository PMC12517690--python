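import numpy as np
import pytest

import pulvigrad as pg


@pytest.fixture(scope="session")
def small_domain():
    """Bilateral blob of ~200 voxels with 4 nuclei."""
    domain, nuc_idx = pg.make_voxel_domain(200, nuclei=4, voxel_size=2.0,
                                           seed=1)
    return domain, nuc_idx


@pytest.fixture(scope="session")
def parcels100():
    return pg.make_parcel_set(100, 7, seed=1)


@pytest.fixture(scope="session")
def planted_bundle():
    """Planted two-axis study at the package's toy scale (snr 10)."""
    from pulvigrad.synth import make_ground_truth_bundle

    return make_ground_truth_bundle(
        n_voxels=600, n_parcels=100, k=2, snr=10.0, seed=1
    )


@pytest.fixture(scope="session")
def sa_field_500():
    """A 500-point smooth field with its coordinates and distance matrix."""
    domain, _ = pg.make_voxel_domain(1000, 4, 2.0, seed=3)
    coords = domain.coords[domain.mask("right")]
    D = pg.pairwise_distances(coords)
    y = pg.make_sa_field(coords, correlation_length=8.0, seed=7)
    return coords, D, y


def pearson_abs(a, b):
    return abs(np.corrcoef(np.ravel(a), np.ravel(b))[0, 1])
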