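"""Embedding correctness: affinity geometry, diffusion-operator oracle,
scree elbow, sign and Procrustes alignment."""

import numpy as np
import pytest
import scipy.linalg

import pulvigrad as pg
from pulvigrad.embedding import (
    DiffusionMapEmbedding,
    GradientSet,
    align_signs,
    cosine_affinity,
    diffusion_embedding,
    elbow_select,
    procrustes_align,
)
from pulvigrad.features import FeatureMatrix


def oracle_diffusion_map(a: np.ndarray, alpha: float, n_components: int):
    """Independent dense oracle: nonsymmetric eigendecomposition of the
    explicitly formed row-stochastic operator, trivial mode dropped,
    multiscale lambda/(1-lambda) scaling."""
    q = a.sum(axis=1)
    k = a / np.outer(q**alpha, q**alpha)
    m = k / k.sum(axis=1)[:, None]
    lam, vec = scipy.linalg.eig(m)
    lam, vec = np.real(lam), np.real(vec)
    order = np.argsort(lam)[::-1]
    lam, vec = lam[order], vec[:, order]
    # normalise so the trivial eigenvector is all-ones
    psi = vec / vec[:, [0]]
    lam_nt = lam[1 : n_components + 1]
    comp = psi[:, 1 : n_components + 1] * (lam_nt / (1 - lam_nt))
    return comp, lam_nt


def random_affinity(rng, n):
    """Random symmetric nonnegative affinity with unit diagonal."""
    b = rng.uniform(0.05, 1.0, size=(n, n))
    a = 0.5 * (b + b.T)
    np.fill_diagonal(a, 1.0)
    return a


class TestCosineAffinity:
    def test_closed_form_entries(self):
        f = FeatureMatrix(np.array([[1.0, 0.0], [1.0, 1.0], [0.0, 2.0]]),
                          "functional")
        a = cosine_affinity(f).values
        assert a[0, 1] == pytest.approx(1 / np.sqrt(2))
        assert a[0, 2] == pytest.approx(0.0)
        assert np.allclose(np.diag(a), 1.0)

    def test_identical_rows_affinity_one(self):
        a = cosine_affinity(np.tile([1.0, 2.0, 3.0], (3, 1))).values
        assert np.allclose(a, 1.0)

    def test_negative_similarities_rectified(self):
        a = cosine_affinity(np.array([[1.0, 0.0], [-1.0, 0.1]])).values
        assert a.min() >= 0.0

    def test_zero_row_named(self):
        with pytest.raises(ValueError, match="voxel 1"):
            cosine_affinity(np.array([[1.0, 0.0], [0.0, 0.0]]))

    def test_row_scale_invariance(self):
        rng = np.random.default_rng(0)
        f = rng.uniform(0.1, 1, size=(10, 6))
        scaled = f * rng.uniform(0.5, 5, size=(10, 1))
        assert np.allclose(cosine_affinity(f).values,
                           cosine_affinity(scaled).values)


class TestDiffusionEmbedding:
    def test_matches_independent_oracle_on_random_affinities(self):
        rng = np.random.default_rng(42)
        for trial in range(20):
            n = int(rng.integers(10, 51))
            a = random_affinity(rng, n)
            est = DiffusionMapEmbedding(n_components=5, alpha=0.5).fit(a)
            comp_o, lam_o = oracle_diffusion_map(a, 0.5, 5)
            assert np.allclose(est.eigenvalues_, lam_o, atol=1e-8)
            for j in range(5):
                r = np.corrcoef(est.embedding_[:, j], comp_o[:, j])[0, 1]
                assert abs(r) > 1 - 1e-10

    def test_two_block_affinity_first_gradient_separates(self):
        n = 20
        a = np.full((n, n), 1e-3)
        a[:10, :10] = 1.0
        a[10:, 10:] = 1.0
        g = diffusion_embedding(a, n_components=2)
        signs = np.sign(g.components[:, 0])
        assert len(set(signs[:10])) == 1 and len(set(signs[10:])) == 1
        assert signs[0] != signs[10]

    def test_identical_rows_degenerate_flagged(self):
        a = np.ones((8, 8))
        with pytest.warns(UserWarning, match="degenerate"):
            g = diffusion_embedding(a, n_components=2)
        assert np.all(np.abs(g.eigenvalues) < 1e-10)

    def test_markov_row_sums_and_spectrum_bounds(self):
        rng = np.random.default_rng(7)
        a = random_affinity(rng, 30)
        q = a.sum(1)
        k = a / np.outer(np.sqrt(q), np.sqrt(q))
        m = k / k.sum(1)[:, None]
        assert np.allclose(m.sum(1), 1.0, atol=1e-10)
        g = diffusion_embedding(a, n_components=10)
        assert np.all(g.eigenvalues <= 1 + 1e-10)
        assert np.all(np.diff(g.eigenvalues) <= 1e-12)

    def test_explained_variance_descending_fractions(self):
        rng = np.random.default_rng(8)
        g = diffusion_embedding(random_affinity(rng, 40), n_components=6)
        ev = g.explained_variance
        assert np.all(ev >= 0) and ev.sum() <= 1 + 1e-12
        assert np.all(np.diff(ev) <= 1e-12)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(9)
        a = random_affinity(rng, 25)
        perm = rng.permutation(25)
        g1 = diffusion_embedding(a, n_components=3)
        g2 = diffusion_embedding(a[np.ix_(perm, perm)], n_components=3)
        for j in range(3):
            r = np.corrcoef(g1.components[perm, j], g2.components[:, j])[0, 1]
            assert abs(r) > 1 - 1e-8

    def test_disconnected_graph_rejected(self):
        a = np.eye(6)
        a[:3, :3] = 1.0
        a[3:, 3:] = 1.0
        with pytest.raises(ValueError, match="disconnected"):
            diffusion_embedding(a, n_components=2)

    def test_too_many_components_rejected(self):
        with pytest.raises(ValueError):
            diffusion_embedding(np.ones((4, 4)), n_components=4)

    def test_sklearn_get_set_params_roundtrip(self):
        est = DiffusionMapEmbedding(n_components=3, alpha=0.7)
        params = est.get_params()
        est2 = DiffusionMapEmbedding().set_params(**params)
        assert est2.get_params() == params


class TestElbowSelect:
    def test_worked_examples(self):
        assert elbow_select([0.50, 0.15, 0.14, 0.01]) == 3
        assert elbow_select([0.9, 0.05, 0.05]) == 1

    def test_flat_scree_degenerate(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert elbow_select([0.25, 0.25, 0.25, 0.25]) == 1

    def test_short_input_returns_all(self):
        assert elbow_select([0.7, 0.3]) == 2
        assert elbow_select([1.0]) == 1


def _gset(components):
    components = np.asarray(components, dtype=float)
    k = components.shape[1]
    return GradientSet(components, np.zeros(k), np.zeros(k))


class TestAlignment:
    def test_sign_flip_restores_reference(self):
        rng = np.random.default_rng(1)
        ref = _gset(rng.normal(size=(30, 3)))
        flipped = _gset(ref.components * np.array([-1, 1, -1]))
        out = align_signs(ref, flipped)
        assert np.allclose(out.components, ref.components)
        same = align_signs(ref, ref)
        assert np.allclose(same.components, ref.components)

    def test_zero_variance_component_rejected(self):
        ref = _gset(np.random.default_rng(2).normal(size=(10, 2)))
        tgt = _gset(np.column_stack([np.ones(10),
                                     ref.components[:, 1]]))
        with pytest.raises(ValueError):
            align_signs(ref, tgt)

    def test_procrustes_inverts_random_rotation(self):
        rng = np.random.default_rng(3)
        ref = _gset(rng.normal(size=(50, 4)))
        q, _ = np.linalg.qr(rng.normal(size=(4, 4)))
        out = procrustes_align(ref, _gset(ref.components @ q))
        for j in range(4):
            r = np.corrcoef(out.components[:, j], ref.components[:, j])[0, 1]
            assert r == pytest.approx(1.0, abs=1e-8)

    def test_alignment_never_hurts_total_correlation(self):
        rng = np.random.default_rng(4)
        ref = _gset(rng.normal(size=(40, 3)))
        for _ in range(100):
            q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
            tgt = _gset(ref.components @ q + 0.1 * rng.normal(size=(40, 3)))
            before = sum(np.corrcoef(tgt.components[:, j],
                                     ref.components[:, j])[0, 1]
                         for j in range(3))
            aligned = procrustes_align(ref, tgt)
            after = sum(np.corrcoef(aligned.components[:, j],
                                    ref.components[:, j])[0, 1]
                        for j in range(3))
            assert after >= before - 1e-9
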