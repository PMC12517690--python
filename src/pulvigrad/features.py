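"""Modality-specific voxel-by-feature matrices and voxel-wise SNR maps.

The three feature matrices feeding the embedding are built here: the
functional connectome (voxel-to-parcel Pearson correlation, row-sparsified to
its top fraction, Fisher r-to-z transformed, group averaged), the structural
connectome (group-mean tract-density counts, neither sparsified nor
transformed), and the receptor coexpression matrix (column-z-scored tracer
densities).  Temporal and b0 signal-to-noise maps are per-voxel mean/SD along
the series axis.

The standard-deviation convention is the sample SD (n-1 denominator)
throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "FeatureMatrix",
    "SnrMap",
    "functional_connectome",
    "sparsify",
    "fisher_z",
    "group_average",
    "structural_density",
    "zscore_columns",
    "snr_map",
]

_STAGES = {"raw", "thresholded", "fisher_z", "group_mean", "zscored"}
_MODALITIES = {"functional", "structural", "coexpression"}


@dataclass
class FeatureMatrix:
    """A voxel-by-feature matrix with modality and processing-stage tags."""

    values: np.ndarray
    modality: str
    feature_ids: list | None = None
    hemisphere: str | None = None
    stage: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (voxel x feature)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")
        if self.modality not in _MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.stage not in _STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.feature_ids is None:
            self.feature_ids = [str(j + 1) for j in range(self.values.shape[1])]
        if len(self.feature_ids) != self.values.shape[1]:
            raise ValueError("feature_ids length mismatch")

    @property
    def n_voxels(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class SnrMap:
    """Per-voxel signal-to-noise values; undefined voxels are flagged."""

    values: np.ndarray
    kind: str
    defined: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.defined = np.asarray(self.defined, dtype=bool)
        if self.kind not in {"tsnr", "b0_snr"}:
            raise ValueError(f"unknown SNR kind {self.kind!r}")
        if self.values.shape != self.defined.shape:
            raise ValueError("values/defined shape mismatch")


def _row_standardize(x: np.ndarray, what: str) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    xc = x - mu
    nrm = np.linalg.norm(xc, axis=1, keepdims=True)
    bad = np.flatnonzero(nrm.ravel() == 0)
    if bad.size:
        raise ValueError(f"constant time series for {what} index {bad[0]}")
    return xc / nrm


def functional_connectome(
    voxel_ts: np.ndarray,
    parcel_ts: np.ndarray,
    feature_ids: list | None = None,
    hemisphere: str | None = None,
) -> FeatureMatrix:
    """Pearson correlation of each voxel series with each parcel-mean series."""
    voxel_ts = np.asarray(voxel_ts, dtype=float)
    parcel_ts = np.asarray(parcel_ts, dtype=float)
    if voxel_ts.shape[1] != parcel_ts.shape[1]:
        raise ValueError("voxel and parcel series must share the time axis")
    if voxel_ts.shape[1] < 3:
        raise ValueError("need at least 3 time points")
    r = _row_standardize(voxel_ts, "voxel") @ _row_standardize(
        parcel_ts, "parcel"
    ).T
    return FeatureMatrix(
        np.clip(r, -1.0, 1.0), "functional", feature_ids, hemisphere, "raw"
    )


def sparsify(m: FeatureMatrix, sparsity: float = 0.10) -> FeatureMatrix:
    """Zero negatives, then keep each row's top ``sparsity`` fraction.

    The per-row threshold is the linear-interpolation percentile
    ``100 * (1 - sparsity)`` computed after zeroing negatives; entries
    strictly below the threshold are zeroed, ties at the threshold kept.
    """
    if m.modality != "functional":
        raise ValueError("sparsification applies to functional matrices only")
    if not 0 < sparsity <= 1:
        raise ValueError("sparsity must lie in (0, 1]")
    v = np.where(m.values < 0, 0.0, m.values)
    thr = np.percentile(v, 100.0 * (1.0 - sparsity), axis=1, method="linear")
    v = np.where(v < thr[:, None], 0.0, v)
    return replace(m, values=v, stage="thresholded")


def fisher_z(m: FeatureMatrix) -> FeatureMatrix:
    """Elementwise Fisher r-to-z (atanh); |r| >= 1 clamped with a warning."""
    v = m.values
    if np.any(np.abs(v) >= 1):
        warnings.warn(
            "correlations with |r| >= 1 clamped to 1 - 1e-7 before atanh",
            stacklevel=2,
        )
        v = np.clip(v, -1 + 1e-7, 1 - 1e-7)
    return replace(m, values=np.arctanh(v), stage="fisher_z")


def group_average(matrices: list[FeatureMatrix]) -> FeatureMatrix:
    """Elementwise mean across subjects of identically shaped matrices."""
    if not matrices:
        raise ValueError("empty subject list")
    first = matrices[0]
    for m in matrices[1:]:
        if m.values.shape != first.values.shape:
            raise ValueError("subject matrices must share shape")
        if m.modality != first.modality or m.feature_ids != first.feature_ids:
            raise ValueError("subject matrices must share modality/features")
    mean = np.mean([m.values for m in matrices], axis=0)
    return replace(first, values=mean, stage="group_mean")


def structural_density(
    count_stack: np.ndarray | list,
    feature_ids: list | None = None,
    hemisphere: str | None = None,
) -> FeatureMatrix:
    """Group-mean tract-density matrix from a stack of per-subject counts.

    Counts are averaged as-is: no thresholding, no sign handling (those steps
    apply to the functional modality only).
    """
    stack = np.asarray(count_stack, dtype=float)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim != 3:
        raise ValueError("expected a (subjects, voxels, parcels) stack")
    if np.any(stack < 0):
        raise ValueError("counts must be nonnegative")
    return FeatureMatrix(
        stack.mean(axis=0), "structural", feature_ids, hemisphere, "group_mean"
    )


def zscore_columns(
    values: np.ndarray | FeatureMatrix,
    feature_ids: list | None = None,
    hemisphere: str | None = None,
) -> FeatureMatrix:
    """Z-score each tracer column (sample SD) over the supplied mask voxels."""
    if isinstance(values, FeatureMatrix):
        feature_ids = feature_ids or values.feature_ids
        hemisphere = hemisphere or values.hemisphere
        values = values.values
    v = np.asarray(values, dtype=float)
    sd = v.std(axis=0, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        ids = feature_ids or [str(j + 1) for j in range(v.shape[1])]
        raise ValueError(f"zero-variance tracer column {ids[bad[0]]!r}")
    z = (v - v.mean(axis=0)) / sd
    return FeatureMatrix(z, "coexpression", feature_ids, hemisphere, "zscored")


def snr_map(series: np.ndarray, kind: str = "tsnr") -> SnrMap:
    """Per-voxel mean / sample-SD along the series axis.

    ``tsnr`` for BOLD time series, ``b0_snr`` for stacks of b0-weighted
    volumes.  Voxels with zero series SD are flagged undefined (NaN value),
    never silently zeroed.
    """
    s = np.asarray(series, dtype=float)
    if s.ndim != 2 or s.shape[1] < 2:
        raise ValueError("series must be (voxels, n) with n >= 2")
    sd = s.std(axis=1, ddof=1)
    defined = sd > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.where(defined, s.mean(axis=1) / np.where(defined, sd, 1.0),
                          np.nan)
    return SnrMap(values=values, kind=kind, defined=defined)
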