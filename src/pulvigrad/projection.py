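"""Gradient-weighted cortical maps and gradient characterisation.

A pulvinar gradient is projected onto the cortex by averaging, over voxels,
the product of the gradient value and the voxel's connectivity to each
cortical parcel.  The resulting parcel maps are summarised by network (or the
voxel gradients by nucleus), correlated with cortico-cortical gradient maps,
with receptor density maps, and with gradients from other modalities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .domain import ParcelSet
from .embedding import GradientSet
from .features import FeatureMatrix

__all__ = [
    "GradientWeightedMap",
    "gradient_weighted_map",
    "hemiflip_average",
    "labeled_summary",
    "map_correlation",
    "receptor_correlates",
    "cross_modal_correlation",
]


@dataclass
class GradientWeightedMap:
    """Parcel-level projection of one gradient through a connectome."""

    values: np.ndarray
    source_gradient: str = ""
    modality: str = ""
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("map values must be a vector")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("map values must be finite")

    def minmax(self) -> "GradientWeightedMap":
        """Min-max normalised copy (display only; statistics use raw values)."""
        v = self.values
        rng = v.max() - v.min()
        if rng == 0:
            raise ValueError("constant map cannot be min-max normalised")
        return GradientWeightedMap(
            (v - v.min()) / rng, self.source_gradient, self.modality, True
        )


def gradient_weighted_map(
    features: FeatureMatrix | np.ndarray,
    g: np.ndarray,
    source_gradient: str = "",
) -> GradientWeightedMap:
    """Average over voxels of gradient value times voxel-parcel connectivity.

    Parcel ``p``'s value is ``mean_v g(v) * F(v, p)``; linear in ``g``.
    """
    modality = ""
    if isinstance(features, FeatureMatrix):
        modality = features.modality
        values = features.values
    else:
        values = np.asarray(features, dtype=float)
    g = np.asarray(g, dtype=float).ravel()
    if values.shape[0] != g.size:
        raise ValueError("gradient and feature matrix must share voxels")
    return GradientWeightedMap(
        values.T @ g / g.size, source_gradient, modality
    )


def hemiflip_average(
    left_map: GradientWeightedMap,
    right_map: GradientWeightedMap,
    parcels: ParcelSet,
    mode: str = "plain",
) -> GradientWeightedMap:
    """Average left and right parcel maps, optionally mirroring the right.

    ``plain`` averages elementwise (symmetric functional maps); ``xflip``
    re-indexes the right map through the mirror correspondence before
    averaging, so ipsilateral structural connectivity stacks on one side.
    """
    lv, rv = left_map.values, right_map.values
    if lv.shape != rv.shape or lv.size != parcels.n_parcels:
        raise ValueError("maps must both cover the full parcel set")
    if mode == "plain":
        out = 0.5 * (lv + rv)
    elif mode == "xflip":
        out = 0.5 * (lv + rv[parcels.mirror_index()])
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return GradientWeightedMap(
        out, left_map.source_gradient, left_map.modality
    )


def labeled_summary(
    values: np.ndarray,
    labels: np.ndarray,
    normalize: bool = False,
) -> dict[str, np.ndarray]:
    """Partition values by label (for nucleus/network violin distributions).

    With ``normalize``, values are first min-max scaled to [0, 1] over the
    whole vector.  Empty groups are retained with a warning.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape != labels.shape:
        raise ValueError("values and labels must share length")
    if normalize:
        rng = values.max() - values.min()
        if rng == 0:
            raise ValueError("constant values cannot be min-max normalised")
        values = (values - values.min()) / rng
    out: dict[str, np.ndarray] = {}
    for lab in np.unique(labels):
        member = values[labels == lab]
        if member.size == 0:
            warnings.warn(f"empty group {lab!r}", stacklevel=2)
        out[str(lab)] = member
    return out


def map_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation between two parcel (or voxel) maps."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size or a.size < 3:
        raise ValueError("maps must share length >= 3")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("constant map has no defined correlation")
    return float(pearsonr(a, b).statistic)


def receptor_correlates(
    g: np.ndarray,
    receptors: FeatureMatrix,
    top_n: int = 5,
) -> pd.DataFrame:
    """Tracers ranked by |Pearson r| with a voxel-wise gradient.

    Returns the ``top_n`` strongest correlates as a DataFrame with columns
    ``tracer``, ``r``, ``abs_r``.  Zero-variance tracers are skipped with a
    warning.
    """
    g = np.asarray(g, dtype=float).ravel()
    if receptors.n_voxels != g.size:
        raise ValueError("gradient and receptor matrix must share voxels")
    rows = []
    for j, tracer in enumerate(receptors.feature_ids):
        col = receptors.values[:, j]
        if col.std() == 0:
            warnings.warn(f"zero-variance tracer {tracer!r} skipped",
                          stacklevel=2)
            continue
        r = map_correlation(g, col)
        rows.append({"tracer": tracer, "r": r, "abs_r": abs(r)})
    df = pd.DataFrame(rows).sort_values(
        ["abs_r", "tracer"], ascending=[False, True], kind="stable"
    )
    return df.head(top_n).reset_index(drop=True)


def cross_modal_correlation(
    gradients: list[GradientSet],
    labels: list[str] | None = None,
) -> pd.DataFrame:
    """Pairwise |r| between gradient components of different modalities.

    Absolute correlations are reported because gradient signs are
    indeterminate.  Rows: one per (modality A component, modality B component)
    pair across distinct gradient sets.
    """
    if labels is None:
        labels = [g.modality or f"set{i}" for i, g in enumerate(gradients)]
    n_vox = {g.n_voxels for g in gradients}
    if len(n_vox) != 1:
        raise ValueError("gradient sets must share the voxel set")
    rows = []
    for ia in range(len(gradients)):
        for ib in range(ia + 1, len(gradients)):
            ga, gb = gradients[ia], gradients[ib]
            for ca in range(ga.n_components):
                for cb in range(gb.n_components):
                    r = map_correlation(
                        ga.components[:, ca], gb.components[:, cb]
                    )
                    rows.append(
                        {
                            "modality_a": labels[ia],
                            "component_a": ca + 1,
                            "modality_b": labels[ib],
                            "component_b": cb + 1,
                            "abs_r": abs(r),
                            "r": r,
                        }
                    )
    return pd.DataFrame(rows)
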