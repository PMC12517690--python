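"""Generator contracts: determinism, geometry, planted-structure identities."""

import numpy as np
import pytest

import pulvigrad as pg
from pulvigrad.synth import (
    make_parcel_set,
    make_receptor_maps,
    make_sa_field,
    make_structural_counts,
    make_timeseries,
    make_voxel_domain,
    plant_cortical_connectivity,
    plant_pulvinar_connectivity,
)


class TestVoxelDomain:
    def test_construction_mirrored_and_partitioned(self, small_domain):
        domain, nuc_idx = small_domain
        assert domain.n_voxels == 200
        left = domain.coords[domain.mask("left")]
        right = domain.coords[domain.mask("right")]
        # left is the x-mirror of (the first half of) right
        flipped = right[: len(left)] * np.array([-1, 1, 1])
        assert np.allclose(np.sort(flipped, axis=0), np.sort(left, axis=0))
        # 4 nonempty nucleus labels
        labels, counts = np.unique(domain.nucleus_label, return_counts=True)
        assert len(labels) == 4 and counts.min() >= 1

    def test_nuclei_are_voronoi_contiguous(self, small_domain):
        # every voxel is nearest to its own nucleus centroid -> convex cells
        domain, nuc_idx = small_domain
        m = domain.mask("right")
        coords, idx = domain.coords[m], nuc_idx[m]
        centroids = np.array([coords[idx == k].mean(axis=0)
                              for k in np.unique(idx)])
        d = np.linalg.norm(coords[:, None] - centroids[None], axis=2)
        assert np.array_equal(np.argmin(d, axis=1), idx)

    def test_single_voxel_domain(self):
        domain, _ = make_voxel_domain(1, nuclei=1, voxel_size=2.0, seed=0)
        assert domain.n_voxels == 1
        assert len(set(domain.nucleus_label)) == 1

    def test_deterministic(self):
        a, _ = make_voxel_domain(120, 3, 2.0, seed=7)
        b, _ = make_voxel_domain(120, 3, 2.0, seed=7)
        assert np.array_equal(a.coords, b.coords)
        assert np.array_equal(a.nucleus_label, b.nucleus_label)

    @pytest.mark.parametrize("n,nuclei", [(0, 1), (5, 0), (3, 4)])
    def test_invalid_counts_rejected(self, n, nuclei):
        with pytest.raises(ValueError):
            make_voxel_domain(n, nuclei)


class TestParcelSet:
    def test_every_network_nonempty(self, parcels100):
        assert parcels100.n_parcels == 100
        labels, counts = np.unique(parcels100.network_label,
                                   return_counts=True)
        assert len(labels) == 7 and counts.min() >= 1

    def test_one_parcel_per_network(self):
        p = make_parcel_set(7, 7, seed=2)
        assert len(np.unique(p.network_label)) == 7

    def test_deterministic(self):
        a = make_parcel_set(50, 7, seed=3)
        b = make_parcel_set(50, 7, seed=3)
        assert np.array_equal(a.centroids, b.centroids)

    def test_mirror_index_crosses_hemispheres(self, parcels100):
        idx = parcels100.mirror_index()
        assert np.all(parcels100.hemisphere[idx] != parcels100.hemisphere)
        # mirroring twice is the identity
        assert np.array_equal(idx[idx], np.arange(parcels100.n_parcels))

    def test_too_many_networks_rejected(self):
        with pytest.raises(ValueError):
            make_parcel_set(5, 6)


class TestPlantedCorticalConnectivity:
    def test_rank1_plus_diagonal_spectral_identity(self, parcels100):
        # C is exactly w g g^T with the diagonal overwritten to 1; removing
        # that diagonal shift leaves a rank-1 matrix whose leading
        # eigenvector is g itself
        c, g = plant_cortical_connectivity(parcels100, k=1, weights=[3.0],
                                           noise_sd=0.0, seed=0)
        low_rank = c - np.diag(1.0 - 3.0 * g[:, 0] ** 2)
        assert np.allclose(low_rank, 3.0 * np.outer(g[:, 0], g[:, 0]),
                           atol=1e-12)
        lam, vec = np.linalg.eigh(low_rank)
        lead = vec[:, np.argmax(np.abs(lam))]
        assert abs(np.corrcoef(lead, g[:, 0])[0, 1]) > 1 - 1e-10

    def test_top2_eigvecs_span_planted(self, parcels100):
        # independent dense eigendecomposition oracle
        weights = np.array([3.0, 1.0])
        c, g = plant_cortical_connectivity(parcels100, k=2, weights=weights,
                                           noise_sd=0.0, seed=0)
        low_rank = c - np.diag(1.0 - (g**2 * weights).sum(axis=1))
        lam, vec = np.linalg.eigh(low_rank)
        top2 = vec[:, np.argsort(lam)[-2:]]
        proj = top2 @ (top2.T @ g)
        assert np.allclose(proj, g, atol=1e-8)

    def test_symmetric_with_unit_diagonal(self, parcels100):
        c, _ = plant_cortical_connectivity(parcels100, k=2, noise_sd=0.1,
                                           seed=1)
        assert np.allclose(c, c.T)
        assert np.allclose(np.diag(c), 1.0)

    def test_bad_weights_rejected(self, parcels100):
        with pytest.raises(ValueError):
            plant_cortical_connectivity(parcels100, k=2, weights=[1.0, 2.0])


class TestPlantedPulvinarConnectivity:
    def test_axes_centred_orthonormal(self, planted_bundle):
        axes = planted_bundle["ground_truth"].planted_axes
        assert np.allclose(axes.mean(axis=0), 0.0, atol=1e-10)
        assert np.allclose(axes.T @ axes, np.eye(axes.shape[1]), atol=1e-10)

    def test_identical_coordinates_identical_profiles(self, parcels100):
        domain, _ = make_voxel_domain(40, 2, 2.0, seed=0)
        _, g = plant_cortical_connectivity(parcels100, k=1, weights=[3.0],
                                           noise_sd=0.0)
        w, _ = plant_pulvinar_connectivity(domain, parcels100, g,
                                           np.array([[1.0, 0, 0]]),
                                           snr=np.inf)
        # mirror voxels share the mirrored-coordinate value -> equal profiles
        left = domain.mask("left")
        right = domain.mask("right")
        assert np.allclose(w[left], w[right][: left.sum()])

    def test_snr_must_be_positive(self, small_domain, parcels100):
        domain, _ = small_domain
        _, g = plant_cortical_connectivity(parcels100, k=1, weights=[3.0])
        with pytest.raises(ValueError):
            plant_pulvinar_connectivity(domain, parcels100, g,
                                        np.array([[1.0, 0, 0]]), snr=0.0)

    def test_dependent_axes_rejected(self, small_domain, parcels100):
        domain, _ = small_domain
        _, g = plant_cortical_connectivity(parcels100, k=2,
                                           weights=[3.0, 1.0])
        dirs = np.array([[1.0, 0, 0], [2.0, 0, 0]])
        with pytest.raises(ValueError):
            plant_pulvinar_connectivity(domain, parcels100, g, dirs)


class TestTimeseries:
    def test_sample_correlations_converge_to_target(self):
        rng = np.random.default_rng(0)
        target = 0.6 * rng.uniform(-1, 1, size=(20, 10))
        target /= np.maximum(1.0, np.linalg.norm(target, axis=1,
                                                 keepdims=True) / 0.9)
        x, y = make_timeseries(target, T=10000, noise_sd=0.0, seed=1)
        xs = (x - x.mean(1, keepdims=True))
        ys = (y - y.mean(1, keepdims=True))
        emp = (xs / np.linalg.norm(xs, axis=1, keepdims=True)) @ (
            ys / np.linalg.norm(ys, axis=1, keepdims=True)).T
        assert np.max(np.abs(emp - target)) < 0.05

    def test_zero_target_gives_near_zero_correlations(self):
        x, y = make_timeseries(np.zeros((5, 4)), T=5000, seed=2)
        emp = np.corrcoef(np.vstack([x, y]))[:5, 5:]
        assert np.max(np.abs(emp)) < 0.1

    def test_deterministic_and_t_validation(self):
        t = np.full((3, 3), 0.2)
        a = make_timeseries(t, T=50, seed=5)
        b = make_timeseries(t, T=50, seed=5)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])
        with pytest.raises(ValueError):
            make_timeseries(t, T=1)


class TestStructuralCounts:
    def test_zero_weight_zero_count(self):
        w = np.zeros((4, 6))
        w[0, 0] = 1.0
        c = make_structural_counts(w, scale=100, dispersion=0.5, seed=0)
        assert np.all(c[1:] == 0) and np.all(c[:, 1:] == 0)

    def test_low_dispersion_counts_track_weights(self):
        rng = np.random.default_rng(3)
        w = rng.uniform(0.1, 1.0, size=(200, 50))
        c = make_structural_counts(w, scale=1000, dispersion=0.0, seed=4)
        ratio = c.mean() / (1000 * w.mean())
        assert abs(ratio - 1) < 0.05
        assert np.all(np.abs(c / 1000 - w).mean(axis=0) < 0.05)

    def test_nonnegative_integers(self):
        c = make_structural_counts(np.random.default_rng(0).uniform(
            0, 1, (10, 10)), scale=50, dispersion=1.0, seed=1)
        assert np.issubdtype(c.dtype, np.integer) and c.min() >= 0

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            make_structural_counts(np.array([[-0.1]]))


class TestReceptorMaps:
    def test_opposite_loadings_anticorrelate(self, small_domain):
        domain, _ = small_domain
        axes = (domain.coords[:, 1:2] - domain.coords[:, 1:2].mean())
        axes = axes / np.linalg.norm(axes)
        r = make_receptor_maps(domain, 2, axes, [[1.0], [-1.0]],
                               noise_sd=0.0)
        assert np.corrcoef(r[:, 0], r[:, 1])[0, 1] == pytest.approx(-1.0)

    def test_zero_loading_without_noise_rejected(self, small_domain):
        domain, _ = small_domain
        axes = np.ones((domain.n_voxels, 1))
        with pytest.raises(ValueError):
            make_receptor_maps(domain, 2, axes, [[1.0], [0.0]], noise_sd=0.0)

    def test_deterministic(self, small_domain):
        domain, _ = small_domain
        axes = (domain.coords[:, :1] - domain.coords[:, :1].mean())
        a = make_receptor_maps(domain, 3, axes, [[1], [2], [-1]],
                               noise_sd=0.2, seed=9)
        b = make_receptor_maps(domain, 3, axes, [[1], [2], [-1]],
                               noise_sd=0.2, seed=9)
        assert np.array_equal(a, b)


class TestSaField:
    def test_white_limit_flat_variogram(self, sa_field_500):
        coords, D, _ = sa_field_500
        y = make_sa_field(coords, correlation_length=1e-3, seed=0)
        h, g = pg.empirical_variogram(y, D)
        assert np.std(g) / np.mean(g) < 0.2  # flat within sampling noise

    def test_smooth_field_variogram_rises(self, sa_field_500):
        coords, D, y = sa_field_500
        h, g = pg.empirical_variogram(y, D)
        first = g[: len(g) // 3]
        assert np.all(np.diff(first) > -0.01)  # monotone over first bins
        assert g[0] < 0.25 * g[-1]

    def test_long_length_near_constant(self, sa_field_500):
        coords, D, _ = sa_field_500
        y = make_sa_field(coords, correlation_length=1e4, seed=1)
        _, g = pg.empirical_variogram(y, D)
        assert g[0] < 1e-4

    def test_minimum_points(self):
        with pytest.raises(ValueError):
            make_sa_field(np.zeros((1, 3)), 5.0)
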