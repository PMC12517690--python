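"""Synthetic data generators with planted, recoverable structure.

Every input the gradient-mapping pipeline consumes can be generated here with
known ground truth: a bilateral ellipsoidal voxel blob with contiguous nucleus
labels, a spherical-shell cortical parcellation with contiguous network
sectors, parcel-level connectomes with planted orthogonal gradients,
voxel-to-parcel connectivity profiles organised along planted spatial axes,
BOLD-like time series whose sample correlations converge to a target
connectome, overdispersed streamline-count matrices, receptor density maps
with smooth coexpression structure, and spatially autocorrelated scalar
fields with a known correlation length.

All generators are pure functions of their arguments, including ``seed``.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from .domain import GroundTruth, ParcelSet, VoxelDomain

__all__ = [
    "make_voxel_domain",
    "make_parcel_set",
    "plant_cortical_connectivity",
    "plant_pulvinar_connectivity",
    "make_timeseries",
    "make_structural_counts",
    "make_receptor_maps",
    "make_sa_field",
]

# Right-pulvinar-like centre in MNI-flavoured world coordinates (mm) and the
# relative semi-axes of the ellipsoidal blob.
_CENTRE = np.array([14.0, -28.0, 6.0])
_SEMI_AXES = np.array([1.0, 1.6, 0.9])
_NUCLEUS_NAMES = ["MED", "LAT", "ANT", "INF"]


def _nucleus_names(n: int) -> list[str]:
    if n <= len(_NUCLEUS_NAMES):
        return _NUCLEUS_NAMES[:n]
    return _NUCLEUS_NAMES + [f"N{i}" for i in range(5, n + 1)]


def make_voxel_domain(
    n_voxels_target: int,
    nuclei: int = 4,
    voxel_size: float = 2.0,
    seed: int = 0,
) -> tuple[VoxelDomain, np.ndarray]:
    """Build a bilateral ellipsoidal voxel blob with contiguous nucleus labels.

    The right-hemisphere blob is the ``ceil(n/2)`` grid voxels closest to an
    ellipsoidal centre; the left hemisphere mirrors it across the mid-sagittal
    plane (x negated).  Nuclei are Voronoi cells of k-means centroids on the
    right-hemisphere coordinates (mirrored to the left), which makes each
    nucleus convex, hence spatially contiguous.

    Returns
    -------
    domain : VoxelDomain
    nucleus_index : (n,) int array
        Integer nucleus assignment (0-based), matching ``domain.nucleus_label``.
    """
    if n_voxels_target < 1:
        raise ValueError("n_voxels_target must be positive")
    if nuclei < 1:
        raise ValueError("nuclei must be positive")
    if nuclei > n_voxels_target:
        raise ValueError("need at least one voxel per nucleus")
    n_right = (n_voxels_target + 1) // 2
    n_left = n_voxels_target // 2

    # Candidate grid of voxel centres around the right-hemisphere ellipsoid.
    m = int(np.ceil((6.0 * n_right) ** (1.0 / 3.0))) + 2
    ax = np.arange(-m, m + 1, dtype=float) * voxel_size
    gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()]) + _CENTRE
    r = np.linalg.norm((pts - _CENTRE) / _SEMI_AXES, axis=1)
    order = np.argsort(r, kind="stable")
    right = pts[order[:n_right]]
    left = right[:n_left] * np.array([-1.0, 1.0, 1.0])

    coords = np.vstack([left, right])
    hemisphere = np.array(["left"] * n_left + ["right"] * n_right)

    if nuclei == 1:
        nuc_idx = np.zeros(coords.shape[0], dtype=int)
    elif nuclei <= n_right:
        km = KMeans(
            n_clusters=nuclei, n_init=4, random_state=seed % (2**31)
        ).fit(right)
        right_idx = km.labels_
        left_idx = right_idx[:n_left]
        nuc_idx = np.concatenate([left_idx, right_idx])
    else:  # too few voxels per hemisphere: partition the full set instead
        km = KMeans(
            n_clusters=nuclei, n_init=4, random_state=seed % (2**31)
        ).fit(coords)
        nuc_idx = km.labels_
    names = np.array(_nucleus_names(int(nuc_idx.max()) + 1))
    domain = VoxelDomain(
        coords=coords,
        hemisphere=hemisphere,
        nucleus_label=names[nuc_idx],
        voxel_size=float(voxel_size),
    )
    return domain, nuc_idx


def make_parcel_set(
    n_parcels: int = 100, n_networks: int = 7, seed: int = 0
) -> ParcelSet:
    """Sample cortical parcel centroids on a sphere-like shell.

    Right-hemisphere centroids are sampled uniformly on the positive-x half of
    a jittered shell (radius ~70 mm) and mirrored to the left, so parcel ``i``
    (left) corresponds to parcel ``n_left + i`` (right).  The seven canonical
    networks are assigned as contiguous angular sectors of the polar angle in
    the (y, z) plane, split so that every network is nonempty.
    """
    if n_parcels < 1:
        raise ValueError("n_parcels must be positive")
    if n_networks < 1 or n_networks > n_parcels:
        raise ValueError("need 1 <= n_networks <= n_parcels")
    rng = np.random.default_rng(seed)
    n_right = (n_parcels + 1) // 2
    n_left = n_parcels // 2

    u = rng.standard_normal((n_right, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    u[:, 0] = np.abs(u[:, 0]) + 0.05  # keep clear of the midline
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    radius = 70.0 + rng.normal(0.0, 3.0, size=n_right)
    right = u * radius[:, None]
    left = right[:n_left] * np.array([-1.0, 1.0, 1.0])

    centroids = np.vstack([left, right])
    hemisphere = np.array(["left"] * n_left + ["right"] * n_right)

    # Contiguous angular sectors in the sagittal (y, z) plane on the right,
    # mirrored to the left so mirror pairs share a network.  When there are
    # more networks than right-hemisphere parcels, sectors span the full set.
    if n_networks <= n_right:
        theta = np.arctan2(right[:, 2], right[:, 1])
        sect_order = np.argsort(theta, kind="stable")
        right_net = np.empty(n_right, dtype=int)
        for net, chunk in enumerate(np.array_split(sect_order, n_networks)):
            right_net[chunk] = net
        net_idx = np.concatenate([right_net[:n_left], right_net])
    else:
        both = np.vstack([left, right])
        theta = np.arctan2(both[:, 2], both[:, 1])
        sect_order = np.argsort(theta, kind="stable")
        net_idx = np.empty(n_parcels, dtype=int)
        for net, chunk in enumerate(np.array_split(sect_order, n_networks)):
            net_idx[chunk] = net
    names = np.array([f"net{j + 1}" for j in range(n_networks)])
    return ParcelSet(
        centroids=centroids,
        network_label=names[net_idx],
        hemisphere=hemisphere,
    )


def _orthonormal_smooth_basis(coords: np.ndarray, k: int) -> np.ndarray:
    """Centred, orthonormal low-order polynomial functions of coordinates.

    Columns are Gram-Schmidt-orthonormalised monomials of the standardised
    coordinates, giving analytically smooth spatial modes.
    """
    c = coords - coords.mean(axis=0)
    sd = c.std(axis=0)
    sd[sd == 0] = 1.0
    x, y, z = (c / sd).T
    raw = [x, y, z, x * y, x * z, y * z, x * x - 1.0, y * y - 1.0, z * z - 1.0,
           x * y * z, x * x * y, y * y * z]
    if k > len(raw):
        raise ValueError(f"at most {len(raw)} smooth basis functions available")
    basis = []
    for col in raw:
        v = col - col.mean()
        for b in basis:
            v = v - (v @ b) * b
        nrm = np.linalg.norm(v)
        if nrm < 1e-10:
            continue
        basis.append(v / nrm)
        if len(basis) == k:
            break
    if len(basis) < k:
        raise ValueError("coordinates too degenerate for requested k")
    return np.column_stack(basis)


def plant_cortical_connectivity(
    parcels: ParcelSet,
    k: int = 2,
    weights: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Build a parcel-by-parcel connectome with planted low-rank gradients.

    ``C = sum_j w_j g_j g_j^T + E`` with ``g_j`` centred orthonormal smooth
    functions of the centroids, ``E`` symmetric Gaussian noise; the diagonal
    is set to 1 and the matrix symmetrised.

    Returns
    -------
    C : (P, P) symmetric matrix
    gradients : (P, k) planted cortical gradients (orthonormal columns)
    """
    if weights is None:
        weights = 3.0 / (1.0 + np.arange(k))
    weights = np.asarray(weights, dtype=float)
    if len(weights) != k:
        raise ValueError("weights must have length k")
    if np.any(weights <= 0) or np.any(np.diff(weights) >= 0):
        raise ValueError("weights must be strictly decreasing and positive")
    if k >= parcels.n_parcels:
        raise ValueError("k must be smaller than the number of parcels")
    g = _orthonormal_smooth_basis(parcels.centroids, k)
    c = (g * weights) @ g.T
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        e = rng.normal(0.0, noise_sd, size=c.shape)
        c = c + 0.5 * (e + e.T)
    c = 0.5 * (c + c.T)
    np.fill_diagonal(c, 1.0)
    return c, g


# Per-axis amplitude decay of the planted pulvinar profiles.  Axis j carries
# amplitude AMP0 * AMP_DECAY**j, mirroring the empirically typical fall-off of
# explained variance across successive connectivity gradients.
_AMP0 = 0.5
_AMP_DECAY = 0.6
_BASELINE = 0.25


def plant_pulvinar_connectivity(
    domain: VoxelDomain,
    parcels: ParcelSet,
    cortical_gradients: np.ndarray,
    axis_directions: np.ndarray,
    snr: float = 10.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Plant voxel-to-parcel connectivity organised along spatial axes.

    Voxel ``v``'s profile is a shared nonnegative baseline plus
    ``sum_j a_j s_j(v) g_j(p)`` where ``s_j`` increases monotonically with the
    coordinate of ``v`` along ``axis_directions[j]`` (centred, then
    orthogonalised across axes) and ``g_j`` is the j-th cortical gradient as a
    parcel loading.  Gaussian noise with standard deviation
    ``sd(signal) / snr`` is added and values are clipped to [-1, 1] so the
    matrix behaves like a correlation-based connectome.

    Returns
    -------
    W : (n_voxels, n_parcels) matrix
    planted_axes : (n_voxels, k) centred orthonormal voxel axes
    """
    cortical_gradients = np.asarray(cortical_gradients, dtype=float)
    axis_directions = np.atleast_2d(np.asarray(axis_directions, dtype=float))
    k = cortical_gradients.shape[1]
    if axis_directions.shape != (k, 3):
        raise ValueError("axis_directions must be (k, 3)")
    if np.linalg.matrix_rank(axis_directions) < k:
        raise ValueError("axis_directions must be linearly independent")
    if not snr > 0:
        raise ValueError("snr must be positive")

    # Work in mirrored per-hemisphere coordinates (left x negated, each
    # hemisphere centred on itself) so a planted axis varies smoothly within
    # each hemisphere instead of separating the hemispheres.
    c = domain.coords.copy()
    c[domain.hemisphere == "left", 0] *= -1.0
    for h in ("left", "right"):
        m = domain.hemisphere == h
        if np.any(m):
            c[m] -= c[m].mean(axis=0)
    axes = []
    for j in range(k):
        d = axis_directions[j] / np.linalg.norm(axis_directions[j])
        v = c @ d
        v = v - v.mean()
        for b in axes:
            v = v - (v @ b) * b
        nrm = np.linalg.norm(v)
        if nrm < 1e-12:
            raise ValueError(f"axis {j} is spatially degenerate on this domain")
        axes.append(v / nrm)
    planted_axes = np.column_stack(axes)

    n = domain.n_voxels
    g = cortical_gradients / np.linalg.norm(cortical_gradients, axis=0)
    s = planted_axes * np.sqrt(n)  # unit-sd voxel scores
    amps = _AMP0 * _AMP_DECAY ** np.arange(k)
    signal = (s * amps) @ g.T
    w = _BASELINE + signal
    if np.isfinite(snr):
        rng = np.random.default_rng(seed)
        noise_sd = float(np.std(signal)) / snr
        w = w + rng.normal(0.0, noise_sd, size=w.shape)
    return np.clip(w, -1.0, 1.0), planted_axes


def make_timeseries(
    connectome: np.ndarray,
    T: int = 400,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Latent-factor time series whose sample correlations match a target.

    Parcel series are i.i.d. standard normal factors ``Y``; voxel ``v``'s
    series is ``t_v . Y + sqrt(1 - |t_v|^2) eta_v`` with ``t_v`` the target
    correlation row, so in population ``corr(X_v, Y_p) = t_vp`` exactly.
    Rows whose norm exceeds ``sqrt(0.99)`` are rescaled (with a warning) to
    keep the residual variance positive.  ``noise_sd`` adds white measurement
    noise to both outputs, attenuating the empirical correlations.

    Returns
    -------
    voxel_ts : (n_voxels, T)
    parcel_ts : (n_parcels, T)
    """
    t = np.asarray(connectome, dtype=float)
    if T < 2:
        raise ValueError("T must be at least 2")
    rng = np.random.default_rng(seed)
    norms = np.linalg.norm(t, axis=1)
    cap = np.sqrt(0.99)
    over = norms > cap
    if np.any(over):
        warnings.warn(
            f"{int(over.sum())} rows of the target exceed unit norm and were "
            "rescaled; their correlations will be attenuated",
            stacklevel=2,
        )
        t = t.copy()
        t[over] *= (cap / norms[over])[:, None]
    n, p = t.shape
    y = rng.standard_normal((p, T))
    resid = np.sqrt(np.clip(1.0 - np.sum(t**2, axis=1), 0.0, None))
    x = t @ y + resid[:, None] * rng.standard_normal((n, T))
    if noise_sd > 0:
        x = x + noise_sd * rng.standard_normal(x.shape)
        y = y + noise_sd * rng.standard_normal(y.shape)
    return x, y


def make_structural_counts(
    weights: np.ndarray,
    scale: float = 1000.0,
    dispersion: float = 0.5,
    seed: int = 0,
) -> np.ndarray:
    """Overdispersed streamline-like counts with mean ``scale * weight``.

    Counts follow a negative-binomial law with variance
    ``mu + dispersion * mu**2`` (Poisson when ``dispersion <= 0``), matching
    the overdispersion of tractography streamline counts.  A zero weight
    always yields a zero count.
    """
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    rng = np.random.default_rng(seed)
    mu = scale * w
    if dispersion <= 0:
        return rng.poisson(mu)
    r = 1.0 / dispersion
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


def make_receptor_maps(
    domain: VoxelDomain,
    n_tracers: int,
    planted_axes: np.ndarray,
    loading_matrix: np.ndarray,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> np.ndarray:
    """Voxel-by-tracer density maps as loadings on the planted axes.

    Tracer ``t``'s map is ``sum_j loading[t, j] * axis_j + noise`` with the
    axes scaled to unit standard deviation, so loadings are in map-SD units.
    """
    axes = np.asarray(planted_axes, dtype=float)
    load = np.atleast_2d(np.asarray(loading_matrix, dtype=float))
    if load.shape != (n_tracers, axes.shape[1]):
        raise ValueError("loading_matrix must be (n_tracers, k)")
    if axes.shape[0] != domain.n_voxels:
        raise ValueError("planted_axes must have one row per voxel")
    zero = np.all(load == 0, axis=1)
    if np.any(zero) and noise_sd == 0:
        raise ValueError(
            f"tracers {np.flatnonzero(zero).tolist()} have all-zero loadings "
            "and no noise: their maps would have zero variance"
        )
    sd = axes.std(axis=0)
    sd[sd == 0] = 1.0
    r = (axes / sd) @ load.T
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        r = r + rng.normal(0.0, noise_sd, size=r.shape)
    return r


def make_sa_field(
    coords: np.ndarray,
    correlation_length: float,
    seed: int = 0,
    sill: float = 1.0,
) -> np.ndarray:
    """Zero-mean Gaussian field with squared-exponential spatial covariance.

    ``cov(i, j) = sill * exp(-d_ij^2 / (2 l^2))``; the empirical variogram of
    the field rises with distance and plateaus near ``sill``.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] < 2:
        raise ValueError("need at least 2 points")
    if not correlation_length > 0:
        raise ValueError("correlation_length must be positive")
    rng = np.random.default_rng(seed)
    d = cdist(coords, coords)
    cov = sill * np.exp(-0.5 * (d / correlation_length) ** 2)
    cov[np.diag_indices_from(cov)] += 1e-9 * sill
    lam, vec = np.linalg.eigh(cov)
    lam = np.clip(lam, 0.0, None)
    z = rng.standard_normal(coords.shape[0])
    y = vec @ (np.sqrt(lam) * z)
    return y - y.mean()


def make_ground_truth_bundle(
    n_voxels: int = 600,
    n_parcels: int = 100,
    k: int = 2,
    nuclei: int = 4,
    snr: float = 10.0,
    sa_length: float = 8.0,
    seed: int = 0,
) -> dict:
    """Convenience bundle: domain, parcels, planted connectomes, ground truth.

    Used by the pipeline driver and the command-line ``simulate`` verb.
    """
    rng = np.random.default_rng(seed)
    sub = [int(s) for s in rng.integers(0, 2**31 - 1, size=6)]
    domain, nuc_idx = make_voxel_domain(n_voxels, nuclei, seed=sub[0])
    parcels = make_parcel_set(n_parcels, seed=sub[1])
    cort_c, cort_g = plant_cortical_connectivity(
        parcels, k=k, noise_sd=0.02, seed=sub[2]
    )
    dirs = np.eye(3)[:k]  # x (medio-lateral) then y (antero-posterior) axes
    w, axes = plant_pulvinar_connectivity(
        domain, parcels, cort_g, dirs, snr=snr, seed=sub[3]
    )
    truth = GroundTruth(
        planted_axes=axes,
        planted_cortical_gradients=cort_g,
        planted_labels=nuc_idx,
        sa_length=sa_length,
        seed=seed,
    )
    return {
        "domain": domain,
        "parcels": parcels,
        "cortical_connectome": cort_c,
        "cortical_gradients": cort_g,
        "connectome": w,
        "ground_truth": truth,
        "subseeds": sub,
    }
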