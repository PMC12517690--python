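"""Cosine affinities and diffusion-map gradient embedding.

The gradient machinery: a feature matrix is converted to a symmetric
voxel-by-voxel cosine similarity (1 minus cosine distance) affinity, and the
spectrum of the anisotropically normalised diffusion operator built from that
affinity yields the gradients.  With density-normalisation exponent
``alpha = 0.5`` the operator approximates the Fokker-Planck diffusion and is
robust to nonuniform sampling noise.

Algorithm (for affinity A, degrees q_i = sum_j A_ij):

1. anisotropic kernel     K = A / (q_i^alpha q_j^alpha)
2. Markov operator        M = D^-1 K        (D = rowsums of K)
3. spectrum of M via the symmetric conjugate D^1/2 M D^-1/2
4. drop the trivial constant eigenvector (lambda_0 = 1); component k is the
   k-th nontrivial right eigenvector scaled by lambda_k / (1 - lambda_k)
   (diffusion time 0) or lambda_k^t otherwise
5. explained variance of component i is lambda_i over the sum of the retained
   positive nontrivial eigenvalues

`DiffusionMapEmbedding` exposes this as a scikit-learn style transformer;
`diffusion_embedding` is the functional wrapper returning a `GradientSet`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import scipy.linalg
from scipy.sparse.csgraph import connected_components
from sklearn.base import BaseEstimator
from sklearn.metrics.pairwise import cosine_similarity

from .features import FeatureMatrix

__all__ = [
    "AffinityMatrix",
    "GradientSet",
    "cosine_affinity",
    "DiffusionMapEmbedding",
    "diffusion_embedding",
    "elbow_select",
    "align_signs",
    "procrustes_align",
]


@dataclass
class AffinityMatrix:
    """Symmetric nonnegative voxel-by-voxel similarity with unit diagonal."""

    values: np.ndarray
    kernel: str = "cosine"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("affinity must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("affinity must be symmetric")
        if np.any(v < -1e-12):
            raise ValueError("affinity must be nonnegative")

    @property
    def n_voxels(self) -> int:
        return self.values.shape[0]


@dataclass
class GradientSet:
    """Voxel-by-component gradient embedding with its spectrum.

    ``components`` are the diffusion-scaled gradient values (unitless);
    ``eigenvalues`` the corresponding raw operator eigenvalues (descending);
    ``explained_variance`` their fractions of the retained positive
    nontrivial spectrum.
    """

    components: np.ndarray
    eigenvalues: np.ndarray
    explained_variance: np.ndarray
    alpha: float = 0.5
    diffusion_time: float = 0.0
    modality: str = ""
    hemisphere: str = ""

    def __post_init__(self) -> None:
        self.components = np.asarray(self.components, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        self.explained_variance = np.asarray(
            self.explained_variance, dtype=float
        )
        if not np.all(np.isfinite(self.components)):
            raise ValueError("gradient components must be finite")

    @property
    def n_components(self) -> int:
        return self.components.shape[1]

    @property
    def n_voxels(self) -> int:
        return self.components.shape[0]


def cosine_affinity(features: FeatureMatrix | np.ndarray) -> AffinityMatrix:
    """Voxel-by-voxel cosine similarity (1 minus cosine distance).

    Negative similarities (possible for signed, e.g. z-scored, features) are
    rectified to zero so the result is a valid diffusion affinity; the
    diagonal is set to exactly 1.
    """
    v = features.values if isinstance(features, FeatureMatrix) else np.asarray(
        features, dtype=float
    )
    norms = np.linalg.norm(v, axis=1)
    bad = np.flatnonzero(norms == 0)
    if bad.size:
        raise ValueError(f"all-zero feature row for voxel {bad[0]}")
    a = cosine_similarity(v)
    n_neg = int(np.sum(a < 0))
    if n_neg:
        a = np.where(a < 0, 0.0, a)
    a = 0.5 * (a + a.T)
    np.fill_diagonal(a, 1.0)
    return AffinityMatrix(values=a, kernel="cosine")


class DiffusionMapEmbedding(BaseEstimator):
    """Diffusion-map embedding of an affinity (or feature) matrix.

    Scikit-learn style transformer.  With ``affinity="precomputed"`` (default)
    ``fit`` expects a symmetric nonnegative affinity; with
    ``affinity="cosine"`` it builds the rectified cosine affinity from the
    rows of ``X`` first.

    Parameters
    ----------
    n_components : int
        Number of nontrivial gradients to retain.
    alpha : float
        Density-normalisation exponent; 0.5 approximates Fokker-Planck
        diffusion and maximises robustness to sampling-density noise.
    diffusion_time : float
        0 selects the multiscale lambda/(1-lambda) component scaling,
        a positive t selects lambda**t.
    affinity : {"precomputed", "cosine"}

    Attributes
    ----------
    embedding_ : (n, n_components) gradient values
    eigenvalues_ : (n_components,) raw operator eigenvalues, descending
    explained_variance_ratio_ : (n_components,) fractions of the retained
        positive nontrivial spectrum
    affinity_matrix_ : the affinity actually embedded
    """

    def __init__(
        self,
        n_components: int = 10,
        alpha: float = 0.5,
        diffusion_time: float = 0.0,
        affinity: str = "precomputed",
    ):
        self.n_components = n_components
        self.alpha = alpha
        self.diffusion_time = diffusion_time
        self.affinity = affinity

    def _build_affinity(self, X) -> np.ndarray:
        if self.affinity == "cosine":
            return cosine_affinity(X).values
        if isinstance(X, AffinityMatrix):
            return X.values
        a = np.asarray(X, dtype=float)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("precomputed affinity must be square")
        if not np.allclose(a, a.T, atol=1e-8):
            raise ValueError("affinity must be symmetric")
        if np.any(a < 0):
            raise ValueError("affinity must be nonnegative")
        return 0.5 * (a + a.T)

    def fit(self, X, y=None):
        a = self._build_affinity(X)
        n = a.shape[0]
        if not 1 <= self.n_components < n:
            raise ValueError("need 1 <= n_components < n_voxels")
        off = a.copy()
        np.fill_diagonal(off, 0.0)
        n_comp, labels = connected_components(off > 0, directed=False)
        if n_comp > 1:
            sizes = np.bincount(labels)
            raise ValueError(
                f"affinity graph is disconnected ({n_comp} components of "
                f"sizes {sizes.tolist()})"
            )

        q = a.sum(axis=1)
        k = a / np.outer(q**self.alpha, q**self.alpha)
        d = k.sum(axis=1)
        d_sqrt = np.sqrt(d)
        msym = k / np.outer(d_sqrt, d_sqrt)
        msym = 0.5 * (msym + msym.T)
        lam, vec = scipy.linalg.eigh(msym)
        order = np.argsort(lam, kind="stable")[::-1]
        lam, vec = lam[order], vec[:, order]

        psi = vec / d_sqrt[:, None]
        psi = psi / psi[:, [0]]  # trivial eigenvector becomes all-ones
        nontrivial = lam[1:]
        m = self.n_components
        if np.all(nontrivial[:m] < 1e-12):
            warnings.warn(
                "degenerate embedding: all nontrivial eigenvalues are ~0 "
                "(all affinity rows identical?)",
                stacklevel=2,
            )
        if self.diffusion_time == 0:
            scale = nontrivial[:m] / (1.0 - np.clip(nontrivial[:m], None,
                                                    1 - 1e-12))
        else:
            scale = nontrivial[:m] ** self.diffusion_time
        comp = psi[:, 1 : m + 1] * scale

        # deterministic sign convention: first nonzero loading positive
        for j in range(comp.shape[1]):
            col = comp[:, j]
            nz = np.flatnonzero(np.abs(col) > 1e-12 * max(1.0,
                                                          np.abs(col).max()))
            if nz.size and col[nz[0]] < 0:
                comp[:, j] = -col

        pos = nontrivial[nontrivial > 0]
        denom = pos.sum() if pos.size else 1.0
        ev = np.clip(nontrivial[:m], 0.0, None) / denom

        self.embedding_ = comp
        self.eigenvalues_ = nontrivial[:m]
        self.explained_variance_ratio_ = ev
        self.affinity_matrix_ = a
        self.n_features_in_ = n
        return self

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).embedding_


def diffusion_embedding(
    affinity: AffinityMatrix | np.ndarray,
    alpha: float = 0.5,
    n_components: int = 10,
    diffusion_time: float = 0.0,
    modality: str = "",
    hemisphere: str = "",
) -> GradientSet:
    """Functional wrapper around :class:`DiffusionMapEmbedding`."""
    est = DiffusionMapEmbedding(
        n_components=n_components,
        alpha=alpha,
        diffusion_time=diffusion_time,
        affinity="precomputed",
    ).fit(affinity)
    return GradientSet(
        components=est.embedding_,
        eigenvalues=est.eigenvalues_,
        explained_variance=est.explained_variance_ratio_,
        alpha=alpha,
        diffusion_time=diffusion_time,
        modality=modality,
        hemisphere=hemisphere,
    )


def elbow_select(explained_variance: np.ndarray) -> int:
    """Number of gradients at the scree elbow.

    The elbow is the point of the cumulative explained-variance curve with
    maximum perpendicular distance to the chord joining its first and last
    points (an automated stand-in for visual scree inspection).  Fewer than 3
    values: all are kept.  A flat (linear) cumulative curve is degenerate and
    yields 1 with a warning.
    """
    ev = np.asarray(explained_variance, dtype=float)
    if ev.ndim != 1 or ev.size == 0:
        raise ValueError("explained_variance must be a nonempty vector")
    k = ev.size
    if k < 3:
        return k
    cum = np.cumsum(ev)
    x = np.arange(1, k + 1, dtype=float)
    dx, dy = x[-1] - x[0], cum[-1] - cum[0]
    nrm = np.hypot(dx, dy)
    dist = np.abs(dx * (cum - cum[0]) - dy * (x - x[0])) / nrm
    if dist.max() < 1e-12:
        warnings.warn(
            "degenerate scree (linear cumulative curve); selecting 1",
            stacklevel=2,
        )
        return 1
    return int(np.argmax(dist)) + 1


def align_signs(reference: GradientSet, target: GradientSet) -> GradientSet:
    """Flip each target component whose correlation with the reference is < 0.

    Resolves the intrinsic sign indeterminacy of gradients, e.g. aligning
    right-hemisphere gradients with their left-hemisphere counterparts through
    a shared voxel correspondence.
    """
    ref, tgt = reference.components, target.components
    if ref.shape != tgt.shape:
        raise ValueError("reference and target must share shape")
    out = tgt.copy()
    for j in range(tgt.shape[1]):
        if ref[:, j].std() == 0 or tgt[:, j].std() == 0:
            raise ValueError(f"zero-variance component {j}")
        r = np.corrcoef(ref[:, j], tgt[:, j])[0, 1]
        if r < 0:
            out[:, j] = -out[:, j]
    return replace(target, components=out)


def procrustes_align(reference: GradientSet, target: GradientSet) -> GradientSet:
    """Orthogonally rotate/reflect target gradients onto the reference.

    Least-squares orthogonal Procrustes (no scaling), resolving
    rotation/reflection indeterminacy before gradient comparison.
    """
    ref, tgt = reference.components, target.components
    if ref.shape != tgt.shape:
        raise ValueError("reference and target must share shape")
    if np.linalg.matrix_rank(tgt) < tgt.shape[1]:
        warnings.warn("rank-deficient target components", stacklevel=2)
    rot, _ = scipy.linalg.orthogonal_procrustes(tgt, ref)
    return replace(target, components=tgt @ rot)
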