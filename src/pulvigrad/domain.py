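"""Core spatial containers: voxel domains, cortical parcel sets, ground truth.

A :class:`VoxelDomain` holds the voxel grid of a bilateral subcortical mask
(here, a pulvinar-like blob) together with per-voxel hemisphere and nucleus
labels.  A :class:`ParcelSet` holds the centroids and network labels of a
cortical parcellation.  :class:`GroundTruth` records the planted structure of
a synthetic dataset so recovery can be asserted downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VoxelDomain", "ParcelSet", "GroundTruth"]


@dataclass
class VoxelDomain:
    """Voxels of a bilateral mask with hemisphere and nucleus labels.

    Parameters
    ----------
    coords : (n_voxels, 3) float array
        Voxel-centre world coordinates in millimetres.
    hemisphere : (n_voxels,) str array
        ``"left"`` or ``"right"`` per voxel.
    nucleus_label : (n_voxels,) str array
        Nucleus assignment per voxel (e.g. ``MED``/``LAT``/``ANT``/``INF``).
    voxel_size : float
        Isotropic voxel edge length in millimetres.
    """

    coords: np.ndarray
    hemisphere: np.ndarray
    nucleus_label: np.ndarray
    voxel_size: float

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.hemisphere = np.asarray(self.hemisphere)
        self.nucleus_label = np.asarray(self.nucleus_label)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be an (n, 3) array")
        n = self.coords.shape[0]
        if len(self.hemisphere) != n or len(self.nucleus_label) != n:
            raise ValueError("hemisphere/nucleus_label length mismatch")
        uniq = np.unique(self.coords, axis=0)
        if uniq.shape[0] != n:
            raise ValueError("voxel coordinates must be unique")
        bad = set(np.unique(self.hemisphere)) - {"left", "right"}
        if bad:
            raise ValueError(f"unknown hemisphere labels: {sorted(bad)}")

    @property
    def n_voxels(self) -> int:
        return self.coords.shape[0]

    @property
    def voxel_id(self) -> np.ndarray:
        return np.arange(self.n_voxels)

    def mask(self, hemisphere: str) -> np.ndarray:
        """Boolean mask selecting one hemisphere."""
        return self.hemisphere == hemisphere

    def nuclei(self) -> list[str]:
        """Nucleus label levels in order of first appearance."""
        _, idx = np.unique(self.nucleus_label, return_index=True)
        return [self.nucleus_label[i] for i in np.sort(idx)]


@dataclass
class ParcelSet:
    """Cortical parcellation centroids with network and hemisphere labels.

    Parcels are stored left hemisphere first, then right; when the two
    hemisphere counts match, parcel ``i`` on the left mirrors parcel
    ``n_left + i`` on the right (x negated).
    """

    centroids: np.ndarray
    network_label: np.ndarray
    hemisphere: np.ndarray

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        self.network_label = np.asarray(self.network_label)
        self.hemisphere = np.asarray(self.hemisphere)
        if self.centroids.ndim != 2 or self.centroids.shape[1] != 3:
            raise ValueError("centroids must be an (n, 3) array")
        n = self.centroids.shape[0]
        if len(self.network_label) != n or len(self.hemisphere) != n:
            raise ValueError("label array length mismatch")

    @property
    def n_parcels(self) -> int:
        return self.centroids.shape[0]

    @property
    def parcel_id(self) -> np.ndarray:
        return np.arange(1, self.n_parcels + 1)

    def mirror_index(self) -> np.ndarray:
        """Index of the mirror parcel (x negated) for every parcel.

        The mirror of parcel ``i`` is the parcel whose centroid is nearest to
        ``(-x, y, z)`` of ``i``'s centroid.  Raises when the nearest mirror
        lies in the same hemisphere (no cross-hemisphere counterpart).
        """
        flipped = self.centroids * np.array([-1.0, 1.0, 1.0])
        d = np.linalg.norm(
            flipped[:, None, :] - self.centroids[None, :, :], axis=2
        )
        idx = np.argmin(d, axis=1)
        same = self.hemisphere[idx] == self.hemisphere
        if np.any(same):
            raise ValueError(
                f"{int(same.sum())} parcels have no mirror counterpart in the "
                "opposite hemisphere"
            )
        return idx


@dataclass
class GroundTruth:
    """Planted structure of a synthetic dataset.

    ``planted_axes`` are centred, mutually orthogonal voxel-level gradient
    targets; ``planted_cortical_gradients`` the parcel-level counterparts;
    ``planted_labels`` a voxel cluster assignment; ``sa_length`` the spatial
    correlation length (mm) used for autocorrelated scalar maps.
    """

    planted_axes: np.ndarray | None = None
    planted_cortical_gradients: np.ndarray | None = None
    planted_labels: np.ndarray | None = None
    sa_length: float | None = None
    seed: int = 0
    extras: dict = field(default_factory=dict)
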