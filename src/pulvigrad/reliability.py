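"""Split-half stability, test-retest repeatability, and SNR confounds.

Gradient reliability is measured by re-deriving gradients from resampled or
repeated data and correlating them, component by component, after Procrustes
realignment (which resolves rotation/reflection/sign indeterminacy).
Split-half stability randomly halves the subject cohort, embeds each half's
group connectome, and reports the per-gradient median and IQR of correlations
across iterations; test-retest embeds two acquisitions of the same cohort;
the SNR association correlates gradients with a voxel-wise SNR map under the
SA-corrected permutation test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .embedding import (
    GradientSet,
    cosine_affinity,
    diffusion_embedding,
    procrustes_align,
)
from .features import FeatureMatrix, SnrMap, fisher_z, group_average, sparsify
from .nulls import SurrogateEnsemble, bh_fdr, generate_surrogates, \
    sa_permutation_pvalue

__all__ = [
    "EmbedConfig",
    "StabilityReport",
    "embed_connectome",
    "split_half_stability",
    "test_retest",
    "snr_gradient_association",
]


@dataclass
class EmbedConfig:
    """Parameters of the connectome -> affinity -> gradients chain."""

    n_components: int = 5
    alpha: float = 0.5
    diffusion_time: float = 0.0
    sparsity: float = 0.10


@dataclass
class StabilityReport:
    """Per-gradient split-half stability across resampling iterations."""

    median_r: np.ndarray
    iqr: np.ndarray
    mean_r: np.ndarray
    all_r: np.ndarray  # (n_iterations, n_components)
    n_iterations: int
    seed: int
    extras: dict = field(default_factory=dict)


def embed_connectome(
    matrix: FeatureMatrix | np.ndarray,
    config: EmbedConfig | None = None,
    modality: str = "functional",
    hemisphere: str = "",
) -> GradientSet:
    """Run the modality-appropriate feature processing and embedding.

    Functional matrices are row-sparsified and Fisher-z transformed before
    the cosine affinity; structural and coexpression matrices are embedded
    as supplied.
    """
    config = config or EmbedConfig()
    if not isinstance(matrix, FeatureMatrix):
        matrix = FeatureMatrix(np.asarray(matrix, dtype=float), modality)
    if matrix.modality == "functional" and matrix.stage in {"raw",
                                                            "group_mean"}:
        matrix = fisher_z(sparsify(matrix, config.sparsity))
    aff = cosine_affinity(matrix)
    return diffusion_embedding(
        aff,
        alpha=config.alpha,
        n_components=config.n_components,
        diffusion_time=config.diffusion_time,
        modality=matrix.modality,
        hemisphere=hemisphere or (matrix.hemisphere or ""),
    )


def _per_component_r(a: GradientSet, b: GradientSet) -> np.ndarray:
    out = np.empty(a.n_components)
    for j in range(a.n_components):
        x, y = a.components[:, j], b.components[:, j]
        if x.std() == 0 or y.std() == 0:
            out[j] = np.nan
        else:
            out[j] = np.corrcoef(x, y)[0, 1]
    return out


def split_half_stability(
    subject_matrices: list[np.ndarray] | list[FeatureMatrix],
    n_iterations: int = 100,
    embed_config: EmbedConfig | None = None,
    seed: int = 0,
    modality: str = "functional",
) -> StabilityReport:
    """Split-half gradient stability over random disjoint halves.

    Each iteration randomly assigns subjects to two disjoint, exhaustive
    halves (floor split with a warning when the count is odd), group-averages
    each half, embeds both, Procrustes-aligns the second onto the first, and
    records the per-gradient Pearson r.  Median and IQR (and the mean) across
    iterations are reported.
    """
    mats = [
        m if isinstance(m, FeatureMatrix)
        else FeatureMatrix(np.asarray(m, dtype=float), modality)
        for m in subject_matrices
    ]
    n_sub = len(mats)
    if n_sub < 4:
        raise ValueError("need at least 4 subjects")
    if n_sub % 2:
        warnings.warn(
            "odd subject count: one subject left out of each split",
            stacklevel=2,
        )
    config = embed_config or EmbedConfig()
    rng = np.random.default_rng(seed)
    half = n_sub // 2
    rs = np.empty((n_iterations, config.n_components))
    for it in range(n_iterations):
        order = rng.permutation(n_sub)
        g1 = group_average([mats[i] for i in order[:half]])
        g2 = group_average([mats[i] for i in order[half : 2 * half]])
        e1 = embed_connectome(g1, config, modality)
        e2 = embed_connectome(g2, config, modality)
        rs[it] = np.abs(_per_component_r(e1, procrustes_align(e1, e2)))
    q25, q75 = np.percentile(rs, [25, 75], axis=0)
    return StabilityReport(
        median_r=np.median(rs, axis=0),
        iqr=q75 - q25,
        mean_r=rs.mean(axis=0),
        all_r=rs,
        n_iterations=n_iterations,
        seed=seed,
    )


def test_retest(
    test_connectome: FeatureMatrix | np.ndarray,
    retest_connectome: FeatureMatrix | np.ndarray,
    embed_config: EmbedConfig | None = None,
    modality: str = "functional",
) -> np.ndarray:
    """Per-gradient Pearson r between test and retest embeddings.

    Both connectomes are embedded with the same configuration and the retest
    gradients Procrustes-aligned onto the test gradients before correlation.
    """
    a = np.asarray(
        test_connectome.values
        if isinstance(test_connectome, FeatureMatrix)
        else test_connectome
    )
    b = np.asarray(
        retest_connectome.values
        if isinstance(retest_connectome, FeatureMatrix)
        else retest_connectome
    )
    if a.shape != b.shape:
        raise ValueError("test and retest connectomes must share shape")
    config = embed_config or EmbedConfig()
    e1 = embed_connectome(test_connectome, config, modality)
    e2 = embed_connectome(retest_connectome, config, modality)
    return _per_component_r(e1, procrustes_align(e1, e2))


def snr_gradient_association(
    snr: SnrMap,
    gradients: GradientSet,
    D: np.ndarray,
    n_surrogates: int = 1000,
    seed: int = 0,
    ensemble: SurrogateEnsemble | None = None,
) -> pd.DataFrame:
    """Spatial correlation of each gradient with a voxel-wise SNR map.

    Undefined-SNR voxels are excluded pairwise with a warning.  P-values come
    from SA-preserving surrogates of the SNR map; Benjamini-Hochberg
    adjustment is applied across gradients.
    """
    values = snr.values
    keep = snr.defined
    if not np.all(keep):
        warnings.warn(
            f"{int((~keep).sum())} undefined-SNR voxels excluded", stacklevel=2
        )
    x = values[keep]
    if x.std() == 0:
        raise ValueError("SNR map is constant over defined voxels")
    Dk = np.asarray(D)[np.ix_(keep, keep)]
    if ensemble is None:
        ensemble = generate_surrogates(
            x, Dk, n_surrogates=n_surrogates, seed=seed
        )
    rows = []
    for j in range(gradients.n_components):
        res = sa_permutation_pvalue(x, gradients.components[keep, j], ensemble)
        rows.append({"gradient": j + 1, "r": res.observed_r, "p": res.p})
    df = pd.DataFrame(rows)
    df["q"] = bh_fdr(df["p"].to_numpy())
    return df
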