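"""PCA/ICA source extraction: variance normalization, SVD, singular-spectrum
shoulder detection, dimensionality choice, spatial ICA, sign convention,
z-score ROI masks and weighted ROI time series.

The extraction pipeline mirrors melodic-style probabilistic ICA for
functional imaging: a first SVD pass strips the dominant components before
estimating per-voxel noise variance; the data are variance normalized;
SVD is reapplied; the number of retained modes is twice the index of the
singular-spectrum shoulder (the point with a 45-degree tangent on the
normalized log spectrum); and FastICA unmixes the retained spatial modes
into independent maps, whose time series follow by least-squares projection.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning
from sklearn.utils.extmath import randomized_svd

from .datatypes import ComponentSet, RoiMask, SingularSpectrum, VolumeSeries


# ---------------------------------------------------------------------------
# variance normalization

def variance_normalize(vs: VolumeSeries, n_presvd: int = 2,
                       eps: float = 1e-12) -> tuple[VolumeSeries, np.ndarray]:
    """Divide each voxel by its residual temporal standard deviation.

    A first SVD removes the ``n_presvd`` largest components so that the
    per-voxel temporal variance estimates noise rather than signal; the
    original (unsubtracted) data are then divided voxelwise by the square
    root of that residual variance, epsilon-floored.  Returns the normalized
    movie and the variance map.
    """
    mat = vs.as_matrix().astype(float)
    if n_presvd >= min(mat.shape):
        raise ValueError("n_presvd must be below the matrix rank")
    resid = mat
    if n_presvd > 0:
        u, s, vt = randomized_svd(mat, n_components=n_presvd, random_state=0)
        resid = mat - (u * s) @ vt
    var = resid.var(axis=1)
    if np.all(var <= eps):
        raise ValueError("movie is constant: zero variance everywhere")
    n_flagged = int((var <= eps).sum())
    if n_flagged:
        warnings.warn(f"{n_flagged} zero-variance voxels floored")
    scale = 1.0 / np.sqrt(np.maximum(var, eps))
    out = (mat * scale[:, None]).reshape(vs.data.shape)
    return (vs.evolve(out.astype(np.float32, copy=False),
                      f"variance_normalize(n_presvd={n_presvd})"),
            var.reshape(vs.vol_shape))


# ---------------------------------------------------------------------------
# SVD / PCA

def pca(vs: VolumeSeries) -> SingularSpectrum:
    """Thin SVD of the voxels x time matrix."""
    mat = vs.as_matrix().astype(float)
    if mat.shape[1] < 2:
        raise ValueError("need at least 2 frames")
    if not np.all(np.isfinite(mat)):
        raise ValueError("non-finite values in movie")
    u, s, vt = np.linalg.svd(mat, full_matrices=False)
    return SingularSpectrum(values=s, spatial_modes=u, temporal_modes=vt.T,
                            vol_shape=vs.vol_shape, frame_rate_hz=vs.frame_rate_hz)


def detect_shoulder(spectrum: SingularSpectrum | np.ndarray,
                    drop_zero_tol: float = 1e-12) -> int:
    """Index of the singular-spectrum shoulder: the 45-degree tangent point.

    Both axes are normalized to [0, 1] — the mode index and the log singular
    value — and the shoulder is the first index at which the centered
    finite-difference slope of the normalized curve crosses -1 (in either
    direction: a steep signal decay flattening into the noise floor, or a
    shallow plateau breaking downward).  This axis normalization is the
    stated convention that makes "45 degrees" well-defined.  Raises if the
    slope never crosses -1 (e.g. a flat spectrum); callers may fall back to
    a fixed count.
    """
    s = spectrum.values if isinstance(spectrum, SingularSpectrum) else np.asarray(spectrum, float)
    s = s[s > drop_zero_tol * max(s[0], 1.0)]
    if len(s) < 4:
        raise ValueError("need at least 4 positive singular values")
    y = np.log(s)
    if np.ptp(y) == 0:
        raise ValueError("no shoulder: flat spectrum")
    y = (y - y.min()) / np.ptp(y)
    x = np.arange(len(s)) / (len(s) - 1)
    slopes = (y[2:] - y[:-2]) / (x[2:] - x[:-2])  # centered, at indices 1..n-2
    excess = slopes + 1.0
    if excess[0] == 0.0:
        return 1
    for i in range(1, len(slopes)):
        if excess[i] == 0.0 or excess[i] * excess[i - 1] < 0:
            return i + 1  # slope index i corresponds to spectrum index i+1
    raise ValueError("no shoulder: normalized slope never crosses -1")


def choose_n_components(shoulder: int, rank: int | None = None) -> int:
    """Twice the shoulder index, clamped to the available rank.

    Components past the shoulder still contain some activity, so keeping
    twice the shoulder count trades a little noise for completeness.
    """
    if shoulder < 1:
        raise ValueError("shoulder must be >= 1")
    n = 2 * shoulder
    return min(n, rank) if rank is not None else n


# ---------------------------------------------------------------------------
# spatial ICA

def run_ica(spectrum: SingularSpectrum, n: int, seed: int = 0,
            max_iter: int = 500, tol: float = 1e-4,
            frame_rate_hz: float | None = None) -> ComponentSet:
    """Unmix the top-n SVD spatial modes into independent spatial maps.

    Spatial ICA with a logcosh contrast: the orthonormal spatial modes are
    already white, so FastICA rotates them into maximally non-Gaussian
    (spatially independent) maps.  Each component's time series is the
    least-squares projection of the data onto its map, variance normalized,
    with the amplitude folded into the map.  Deterministic given ``seed``;
    components are ordered by decreasing temporal variance explained.
    """
    if n < 1 or n > spectrum.rank:
        raise ValueError(f"n must be in [1, rank={spectrum.rank}]")
    u_n = spectrum.spatial_modes[:, :n]
    nvox = u_n.shape[0]
    converged = True
    if n == 1:
        maps = u_n.copy()
        mixing = np.ones((1, 1))
    else:
        ica = FastICA(n_components=n, whiten=False, fun="logcosh",
                      max_iter=max_iter, tol=tol, random_state=seed)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            sources_mat = ica.fit_transform(u_n * np.sqrt(nvox))
            if any(issubclass(w.category, ConvergenceWarning) for w in caught):
                converged = False
                warnings.warn(f"FastICA did not converge in {max_iter} iterations",
                              stacklevel=2)
        maps = sources_mat / np.sqrt(nvox)
        mixing = None  # traces from projection below

    # Time series: least-squares fit of data onto the maps.  The data's
    # n-mode truncation is U_n S_n V_n^T and maps = U_n W^T, so the
    # coefficients are (W^T)^-1 S_n V_n^T, computed in the n-dim mode space.
    sn_vt = spectrum.values[:n, None] * spectrum.temporal_modes[:, :n].T
    if mixing is None:
        traces = np.linalg.pinv(u_n.T @ maps) @ sn_vt
    else:
        traces = sn_vt
    traces = np.asarray(traces, dtype=float)

    # variance-normalize traces; fold amplitude into the maps
    sd = traces.std(axis=1)
    sd[sd == 0] = 1.0
    traces = traces / sd[:, None]
    maps = maps * sd[None, :]

    order = np.argsort(-(sd ** 2))
    maps = maps[:, order]
    traces = traces[order]

    rate = frame_rate_hz if frame_rate_hz is not None else spectrum.frame_rate_hz
    nx, ny, nz = spectrum.vol_shape
    return ComponentSet(maps=maps.T.reshape(n, nx, ny, nz), traces=traces,
                        frame_rate_hz=rate, converged=converged)


def fix_signs(cs: ComponentSet) -> ComponentSet:
    """Flip (map, trace) pairs so each map's positive side outweighs the negative.

    A pair is negated iff the mean of the map's positive part is smaller
    than the absolute mean of its negative part; idempotent.
    """
    maps = cs.maps.copy()
    traces = cs.traces.copy()
    for i in range(cs.n_components):
        m = maps[i]
        pos = m[m > 0]
        neg = m[m < 0]
        pos_mean = pos.mean() if pos.size else 0.0
        neg_mean = abs(neg.mean()) if neg.size else 0.0
        if pos_mean < neg_mean:
            maps[i] = -m
            traces[i] = -traces[i]
    return ComponentSet(maps=maps, traces=traces, frame_rate_hz=cs.frame_rate_hz,
                        sign_fixed=True, region_label=list(cs.region_label),
                        artifact=list(cs.artifact),
                        n_regions_present=cs.n_regions_present,
                        n_objects=cs.n_objects, converged=cs.converged)


# ---------------------------------------------------------------------------
# ROI masks and time series

def zscore_threshold_mask(map3d: np.ndarray, k: float = 3.0, component_id: int = 0,
                          center: str = "zero") -> RoiMask:
    """Zero all voxels below ``k`` standard deviations of the map.

    The SD is computed over all voxels of the map, about zero by default
    (ICA maps are mean-free by construction; set ``center='mean'`` to
    subtract the map mean first).  The surviving positive voxels become
    nonnegative ROI weights.
    """
    m = np.asarray(map3d, dtype=float)
    if m.size <= 1:
        raise ValueError("map must have more than one voxel")
    if center == "zero":
        sd = float(np.sqrt(np.mean(m ** 2)))
    elif center == "mean":
        sd = float(m.std())
    else:
        raise ValueError("center must be 'zero' or 'mean'")
    if sd == 0:
        raise ValueError("map has zero standard deviation")
    weights = np.where(m >= k * sd, m, 0.0)
    return RoiMask(weights=weights, component_id=component_id, threshold_k=k)


def roi_timeseries(vs_dff: VolumeSeries, mask: RoiMask) -> np.ndarray:
    """Weighted average of the dF/F time series over an ROI mask."""
    if mask.weights.shape != vs_dff.vol_shape:
        raise ValueError(f"mask shape {mask.weights.shape} != volume "
                         f"shape {vs_dff.vol_shape}")
    w = mask.weights.ravel()
    return (w @ vs_dff.as_matrix()) / w.sum()


# ---------------------------------------------------------------------------
# convenience driver

def extract_sources(vs: VolumeSeries, seed: int = 0, n_presvd: int = 2,
                    n_components: int | None = None, fallback_n: int = 20,
                    max_iter: int = 500, tol: float = 1e-4
                    ) -> tuple[ComponentSet, SingularSpectrum]:
    """Full extraction chain on a preprocessed movie.

    variance_normalize -> pca -> detect_shoulder (falling back to
    ``fallback_n`` when no shoulder exists) -> choose_n_components ->
    run_ica -> fix_signs.
    """
    vn, _ = variance_normalize(vs, n_presvd=n_presvd)
    spectrum = pca(vn)
    if n_components is None:
        try:
            shoulder = detect_shoulder(spectrum)
            n_components = choose_n_components(shoulder, spectrum.rank)
        except ValueError as exc:
            warnings.warn(f"shoulder detection failed ({exc}); "
                          f"using fallback of {fallback_n} components")
            n_components = min(fallback_n, spectrum.rank)
    cs = run_ica(spectrum, n_components, seed=seed, max_iter=max_iter, tol=tol)
    return fix_signs(cs), spectrum
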