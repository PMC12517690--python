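"""Gradient-space k-means with silhouette model selection and Dice overlap.

Continuous gradients are discretised by min-max normalising the selected
components to [0, 1], concatenating them across modalities, and sweeping
k-means over a range of k; the mean silhouette coefficient selects the number
of clusters.  Overlap between data-driven clusters and atlas nuclei is
quantified with the Dice similarity coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .embedding import GradientSet

__all__ = [
    "ClusterSolution",
    "minmax_concat",
    "GradientKMeans",
    "kmeans_sweep",
    "select_k",
    "dice_overlap",
]


@dataclass
class ClusterSolution:
    """One k-means solution in gradient space (labels are 1..k)."""

    labels: np.ndarray
    k: int
    silhouette: float
    inertia: float
    seed: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        u = np.unique(self.labels)
        if u.min() < 1 or u.max() > self.k or u.size != self.k:
            raise ValueError("labels must cover 1..k with no empty cluster")
        if not -1 <= self.silhouette <= 1:
            raise ValueError("silhouette must lie in [-1, 1]")


def minmax_concat(
    gradients: list[GradientSet],
    selection: list[int] | None = None,
) -> np.ndarray:
    """Min-max scale selected components to [0, 1] and concatenate.

    ``selection[i]`` components are taken from ``gradients[i]`` (all when
    ``selection`` is None).  Constant components are rejected.
    """
    if selection is None:
        selection = [g.n_components for g in gradients]
    if len(selection) != len(gradients):
        raise ValueError("selection must give one count per gradient set")
    n_vox = {g.n_voxels for g in gradients}
    if len(n_vox) != 1:
        raise ValueError("gradient sets must share the voxel set")
    cols = []
    for g, take in zip(gradients, selection):
        if not 1 <= take <= g.n_components:
            raise ValueError("invalid component count in selection")
        for j in range(take):
            c = g.components[:, j]
            rng = c.max() - c.min()
            if rng == 0:
                raise ValueError(
                    f"constant component {j} ({g.modality or 'unnamed'})"
                )
            cols.append((c - c.min()) / rng)
    return np.column_stack(cols)


class GradientKMeans(BaseEstimator, ClusterMixin):
    """K-means sweep over k with silhouette-based model selection.

    Parameters
    ----------
    k_min, k_max : int
        Inclusive range of cluster counts to evaluate (default 2..30).
    n_init : int
        Restarts per k; the best by within-cluster sum of squares is kept.
    random_state : int

    Attributes
    ----------
    solutions_ : list of ClusterSolution, one per k
    best_ : the selected solution (max mean silhouette; ties -> smallest k)
    labels_ : labels of the selected solution (1..k)
    k_ : selected number of clusters
    silhouette_ : its mean silhouette coefficient
    """

    def __init__(
        self,
        k_min: int = 2,
        k_max: int = 30,
        n_init: int = 10,
        random_state: int = 0,
    ):
        self.k_min = k_min
        self.k_max = k_max
        self.n_init = n_init
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (voxels x gradient features)")
        n = X.shape[0]
        if not 2 <= self.k_min <= self.k_max:
            raise ValueError("need 2 <= k_min <= k_max")
        if self.k_max >= n:
            raise ValueError("k_max must be smaller than the number of voxels")
        sols = []
        for k in range(self.k_min, self.k_max + 1):
            km = KMeans(
                n_clusters=k,
                n_init=self.n_init,
                random_state=self.random_state % (2**31),
            ).fit(X)
            sil = float(silhouette_score(X, km.labels_))
            sols.append(
                ClusterSolution(
                    labels=km.labels_ + 1,
                    k=k,
                    silhouette=sil,
                    inertia=float(km.inertia_),
                    seed=self.random_state,
                )
            )
        self.solutions_ = sols
        self.best_ = select_k(sols)
        self.labels_ = self.best_.labels
        self.k_ = self.best_.k
        self.silhouette_ = self.best_.silhouette
        return self


def kmeans_sweep(
    X: np.ndarray,
    k_range: tuple[int, int] = (2, 30),
    n_init: int = 10,
    seed: int = 0,
) -> list[ClusterSolution]:
    """All k-means solutions over a k range (functional wrapper)."""
    est = GradientKMeans(
        k_min=k_range[0], k_max=k_range[1], n_init=n_init, random_state=seed
    ).fit(X)
    return est.solutions_


def select_k(solutions: list[ClusterSolution]) -> ClusterSolution:
    """Solution with the maximum mean silhouette; ties go to the smallest k."""
    if not solutions:
        raise ValueError("empty solution list")
    best = solutions[0]
    for s in solutions[1:]:
        if s.silhouette > best.silhouette or (
            s.silhouette == best.silhouette and s.k < best.k
        ):
            best = s
    return best


def dice_overlap(
    labels_a: np.ndarray,
    labels_b: np.ndarray,
) -> tuple[pd.DataFrame, pd.Series]:
    """Dice coefficients between every pair of clusters across two partitions.

    ``Dice(A, B) = 2|A & B| / (|A| + |B|)``.  Returns the full a-by-b Dice
    matrix and, per b-label, the maximum Dice across a-labels (the
    best-matching-cluster convention for cluster-vs-nucleus overlap).
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("partitions must share the voxel set")
    if a.size == 0:
        raise ValueError("empty partitions")
    ua, ub = np.unique(a), np.unique(b)
    mat = np.zeros((ua.size, ub.size))
    for i, la in enumerate(ua):
        in_a = a == la
        for j, lb in enumerate(ub):
            in_b = b == lb
            mat[i, j] = 2.0 * np.sum(in_a & in_b) / (in_a.sum() + in_b.sum())
    df = pd.DataFrame(mat, index=[str(x) for x in ua],
                      columns=[str(x) for x in ub])
    return df, df.max(axis=0)
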