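"""Preprocessing chain from reconstructed movie to analysis-ready dF/F.

Order of the canonical chain: rigid motion correction, sign flip (ArcLight
only), slow-trend removal by box-average subtraction, causal Kalman-style
denoising (gain 0.5), SVD subtraction of movement components, optional
concatenation of recordings, dF/F, and behavior/fluorescence alignment with
linear clock-drift correction (~30 ms per minute).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage, signal

from .datatypes import BehaviorTrace, RigidMotion, VolumeSeries


# ---------------------------------------------------------------------------
# motion correction

def _xcorr_shift(frame: np.ndarray, ref_f: np.ndarray, max_shift: float) -> np.ndarray:
    """Translation maximizing circular cross-correlation over integer shifts
    within +-max_shift, with per-axis 3-point parabolic sub-voxel refinement."""
    f = np.fft.rfftn(frame)
    cc = np.fft.irfftn(f * np.conj(ref_f), s=frame.shape,
                       axes=range(frame.ndim))
    shape = np.array(frame.shape)
    ms = int(max_shift)
    # candidate integer shifts live in the corners of the circular cc array
    allowed = np.zeros(frame.shape, dtype=bool)
    sel = tuple(np.r_[0: min(ms + 1, n), max(n - ms, 0): n] for n in shape)
    allowed[np.ix_(*sel)] = True
    masked = np.where(allowed, cc, -np.inf)
    idx = np.array(np.unravel_index(np.argmax(masked), cc.shape))
    wrapped = np.where(idx > shape // 2, idx - shape, idx).astype(float)
    est = np.empty(3)
    for ax in range(3):
        i0 = int(idx[ax])
        other = [int(idx[a]) for a in range(3)]
        pts = []
        for j in (-1, 0, 1):
            coord = tuple((i0 + j) % shape[a] if a == ax else other[a]
                          for a in range(3))
            pts.append(cc[coord])
        denom = pts[0] - 2 * pts[1] + pts[2]
        frac = 0.0
        if abs(denom) > 1e-15:
            frac = float(np.clip(0.5 * (pts[0] - pts[2]) / denom, -0.5, 0.5))
        est[ax] = wrapped[ax] + frac
    return est


def motion_correct(vs: VolumeSeries, reference: str = "mean",
                   max_shift_voxels: float = 8.0) -> tuple[VolumeSeries, RigidMotion]:
    """Rigidly align every frame to a reference volume.

    The shift of each frame is estimated by maximizing the phase
    cross-correlation with the reference over integer translations, refined
    to sub-voxel precision by a quadratic fit around the peak, then removed
    by linear interpolation.  Translation-only; this fills the role of an
    external rigid registration tool without reproducing its internals.
    """
    if vs.n_frames < 2:
        raise ValueError("need at least 2 frames to motion correct")
    if reference == "first":
        ref = vs.data[..., 0].astype(float)
    elif reference == "mean":
        ref = vs.data.mean(axis=3).astype(float)
    else:
        raise ValueError("reference must be 'first' or 'mean'")
    ref = ref - ref.mean()
    if np.ptp(ref) == 0:
        warnings.warn("constant reference volume: skipping motion correction")
        return vs.evolve(vs.data.copy(), "motion_correct(skipped: zero variance)"), \
            RigidMotion(np.zeros((vs.n_frames, 3)))
    ref_f = np.fft.rfftn(ref)

    out = np.empty_like(vs.data)
    shifts = np.zeros((vs.n_frames, 3))
    for t in range(vs.n_frames):
        frame = vs.data[..., t].astype(float)
        if np.ptp(frame) == 0:
            warnings.warn(f"frame {t} has zero variance; leaving it in place")
            out[..., t] = vs.data[..., t]
            continue
        est = _xcorr_shift(frame - frame.mean(), ref_f, max_shift_voxels)
        shifts[t] = est
        if np.any(est != 0):
            out[..., t] = ndimage.shift(frame, -est, order=1, mode="nearest")
        else:
            out[..., t] = vs.data[..., t]
    motion = RigidMotion(shifts)
    return vs.evolve(out, f"motion_correct(reference={reference})"), motion


# ---------------------------------------------------------------------------
# simple per-voxel transforms

def invert_sign(vs: VolumeSeries, force: bool = False) -> VolumeSeries:
    """Multiply the movie by -1 (ArcLight dims with depolarization).

    Refuses on non-ArcLight probes unless ``force`` is set.  An even number
    of applications restores the input bit-exactly.
    """
    if vs.probe != "arclight" and not force:
        raise ValueError(f"sign inversion is for arclight data, not {vs.probe!r} "
                         "(pass force=True to override)")
    return vs.evolve(-vs.data, "invert_sign")


def _box_mean(data: np.ndarray, length: int) -> np.ndarray:
    """Centered moving average along the last axis with shrinking edge
    windows (window [t-(L-1)//2, t+L//2], clipped to the record)."""
    nt = data.shape[-1]
    left = (length - 1) // 2
    right = length // 2
    c = np.concatenate([np.zeros(data.shape[:-1] + (1,)), np.cumsum(data, axis=-1)], axis=-1)
    lo = np.clip(np.arange(nt) - left, 0, nt)
    hi = np.clip(np.arange(nt) + right + 1, 0, nt)
    return (c[..., hi] - c[..., lo]) / (hi - lo)


def detrend(vs: VolumeSeries, window_s: float = 20.0) -> VolumeSeries:
    """Subtract a per-voxel box average over ``window_s`` (15-30 s typical).

    Removes background fluorescence and the slow photobleaching trend.
    Edges use shrinking (truncated) windows rather than padded data.
    """
    length = int(round(window_s * vs.frame_rate_hz))
    if length < 3:
        raise ValueError("window must span at least 3 frames")
    if length > vs.n_frames:
        raise ValueError(f"window of {length} frames exceeds recording "
                         f"({vs.n_frames} frames)")
    out = vs.data - _box_mean(vs.data.astype(float), length)
    return vs.evolve(out.astype(vs.data.dtype, copy=False),
                     f"detrend(window_s={window_s})")


def highpass(vs: VolumeSeries, window_s: float = 0.1) -> VolumeSeries:
    """Subtract the movie smoothed over ``window_s`` (default 100 ms).

    At a 200 Hz frame rate the default window is exactly 20 frames,
    revealing only activity above ~10 Hz.
    """
    length = int(round(window_s * vs.frame_rate_hz))
    if length < 2:
        raise ValueError(f"frame rate {vs.frame_rate_hz} Hz too low for a "
                         f"{window_s}s high-pass window")
    out = vs.data - _box_mean(vs.data.astype(float), length)
    return vs.evolve(out.astype(vs.data.dtype, copy=False),
                     f"highpass(window_s={window_s})")


def kalman_denoise(vs: VolumeSeries, gain: float = 0.5) -> VolumeSeries:
    """Causal first-order recursive filter per voxel.

    ``est[t] = (1 - g) * est[t-1] + g * obs[t]`` with ``est[0] = obs[0]``.
    The gain of 0.5 follows the steady-state filter used on real data.
    """
    if not 0 < gain <= 1:
        raise ValueError("gain must be in (0, 1]")
    if gain == 1.0:
        return vs.evolve(vs.data.copy(), "kalman_denoise(gain=1)")
    x = vs.data.astype(float)
    # IIR filter y[t] = g x[t] + (1-g) y[t-1]; zi seeds y[-1] = x[0]
    zi = (1 - gain) * x[..., 0:1]
    y, _ = signal.lfilter([gain], [1.0, -(1.0 - gain)], x, axis=-1, zi=zi)
    return vs.evolve(y.astype(vs.data.dtype, copy=False),
                     f"kalman_denoise(gain={gain})")


# ---------------------------------------------------------------------------
# SVD movement-component subtraction

def svd_motion_removal(vs: VolumeSeries, component_indices=None,
                       n_candidates: int = 10, edge_fraction: float = 0.5,
                       seed: int = 0) -> tuple[VolumeSeries, list[int]]:
    """Subtract SVD components dominated by movement shadows.

    ``component_indices`` may be an explicit set of rank positions, or
    ``None`` for auto mode, which flags components whose spatial map energy
    concentrates (> ``edge_fraction``) on high-spatial-gradient voxels —
    the shadow signature movement leaves around intensity boundaries.
    """
    if vs.data.size == 0:
        raise ValueError("empty movie")
    mat = vs.as_matrix().astype(float)
    if component_indices is not None:
        component_indices = sorted(set(int(i) for i in component_indices))
        if not component_indices:
            return vs.evolve(vs.data.copy(), "svd_motion_removal(none)"), []
        k_needed = max(component_indices) + 1
    else:
        k_needed = min(n_candidates, min(mat.shape) - 1)
    mean = mat.mean(axis=1, keepdims=True)
    centered = mat - mean
    if min(centered.shape) <= 1024:
        u, s, vt = np.linalg.svd(centered, full_matrices=False)
        u, s, vt = u[:, :k_needed], s[:k_needed], vt[:k_needed]
    else:
        from sklearn.utils.extmath import randomized_svd
        u, s, vt = randomized_svd(centered, n_components=k_needed,
                                  n_iter=7, random_state=seed)

    if component_indices is None:
        grad = np.zeros(vs.vol_shape)
        mimg = mean.reshape(vs.vol_shape)
        for ax in range(3):
            grad += np.abs(np.gradient(mimg, axis=ax))
        thr = np.quantile(grad, 0.9)
        edge = (grad >= thr).ravel()
        component_indices = []
        for i in range(u.shape[1]):
            energy = u[:, i] ** 2
            if energy[edge].sum() / energy.sum() > edge_fraction:
                component_indices.append(i)
    removed = np.zeros_like(centered)
    for i in component_indices:
        if not 0 <= i < len(s):
            raise ValueError(f"component index {i} out of range (rank {len(s)})")
        removed += np.outer(u[:, i] * s[i], vt[i])
    out = (mat - removed).reshape(vs.data.shape)
    return (vs.evolve(out.astype(vs.data.dtype, copy=False),
                      f"svd_motion_removal(indices={list(component_indices)})"),
            list(component_indices))


# ---------------------------------------------------------------------------
# dF/F

def dff(vs: VolumeSeries, baseline: str = "mean", percentile: float = 10.0,
        window_s: float = 20.0, eps: float = 1e-6) -> VolumeSeries:
    """Fractional fluorescence change (F - F0) / F0 per voxel.

    ``baseline`` is the per-voxel temporal mean, a low percentile, or
    ``"moving"``: a per-frame box average over ``window_s``, which folds the
    slow-trend (photobleaching) removal into F0 so the result is
    trend-free.  Voxels whose baseline is not strictly positive after
    epsilon flooring are masked to zero and their count reported via a
    warning.
    """
    if baseline == "mean":
        f0 = vs.data.mean(axis=3)[..., None]
    elif baseline == "percentile":
        f0 = np.percentile(vs.data, percentile, axis=3)[..., None]
    elif baseline == "moving":
        length = int(round(window_s * vs.frame_rate_hz))
        if not 3 <= length <= vs.n_frames:
            raise ValueError("moving-baseline window must span 3 frames to the "
                             "recording length")
        f0 = _box_mean(vs.data.astype(float), length)
    else:
        raise ValueError("baseline must be 'mean', 'percentile' or 'moving'")
    bad = np.any(f0 <= eps, axis=3)
    if bad.any():
        warnings.warn(f"{int(bad.sum())} voxels with non-positive baseline masked")
    f0safe = np.where(bad[..., None], 1.0, f0)
    out = (vs.data - f0safe) / f0safe
    out[bad, :] = 0.0
    return vs.evolve(out.astype(np.float32, copy=False), f"dff(baseline={baseline})")


# ---------------------------------------------------------------------------
# alignment, concatenation, z-slab reduction

def align_behavior(behavior: BehaviorTrace, fluor_frames: int, fluor_rate_hz: float,
                   drift_ms_per_min: float = 30.0) -> BehaviorTrace:
    """Resample a behavior trace onto the fluorescence frame grid.

    The behavior clock is first rescaled linearly to remove the camera clock
    discrepancy (about 30 ms per minute: a behavior timestamp t becomes
    t * (1 - drift/60000)), then states are resampled by nearest neighbor
    and flows by linear interpolation.
    """
    if fluor_frames <= 0 or behavior.n_frames == 0:
        raise ValueError("both recordings must be non-empty")
    drift_frac = drift_ms_per_min / 60000.0
    if abs(drift_frac) > 0.1:
        raise ValueError(f"implausible drift {drift_ms_per_min} ms/min (>10%)")
    t_beh = np.arange(behavior.n_frames) / behavior.frame_rate_hz * (1.0 - drift_frac)
    t_fluor = np.arange(fluor_frames) / fluor_rate_hz
    nearest = np.clip(np.searchsorted(t_beh, t_fluor, side="left"), 0, len(t_beh) - 1)
    prev = np.clip(nearest - 1, 0, len(t_beh) - 1)
    # epsilon breaks exact midpoints toward the earlier sample, robustly to
    # floating-point jitter in the time grids
    use_prev = (np.abs(t_beh[prev] - t_fluor)
                <= np.abs(t_beh[nearest] - t_fluor) + 1e-9 / fluor_rate_hz)
    idx = np.where(use_prev, prev, nearest)
    state = behavior.state[idx]
    flow_l = np.interp(t_fluor, t_beh, behavior.flow_left)
    flow_r = np.interp(t_fluor, t_beh, behavior.flow_right)
    return BehaviorTrace(frame_rate_hz=fluor_rate_hz, state=state,
                         flow_left=flow_l, flow_right=flow_r)


def concat(vs_list: list[VolumeSeries]) -> VolumeSeries:
    """Concatenate recordings in time after preprocessing.

    All inputs must agree on spatial dims, voxel size, frame rate and probe;
    segment boundary indices are recorded in provenance.
    """
    if not vs_list:
        raise ValueError("nothing to concatenate")
    first = vs_list[0]
    for field_name, get in [("spatial dims", lambda v: v.vol_shape),
                            ("voxel size", lambda v: v.voxel_size_um),
                            ("frame rate", lambda v: v.frame_rate_hz),
                            ("probe", lambda v: v.probe)]:
        vals = {get(v) for v in vs_list}
        if len(vals) > 1:
            raise ValueError(f"cannot concatenate: mismatched {field_name}: {vals}")
    data = np.concatenate([v.data for v in vs_list], axis=3)
    boundaries = [int(b) for b in np.cumsum([v.n_frames for v in vs_list])[:-1]]
    prov = sum((v.provenance for v in vs_list), [])
    return VolumeSeries(data=data, voxel_size_um=first.voxel_size_um,
                        frame_rate_hz=first.frame_rate_hz, probe=first.probe,
                        provenance=prov + [f"concat(boundaries={boundaries})"])


def zslab_partition(n_layers: int, layer_dz_um: float, profile,
                    focal_index: int | None = None) -> list[tuple[int, int]]:
    """Greedy z-slab partition from the focal plane outward.

    ``profile`` maps signed depth (um from the focal plane) to the desired
    slab thickness (um, e.g. the PSF axial FWHM at that depth).  Slab sizes
    in layers are ``max(1, round(profile(start_depth) / dz))``.  Returns
    (start, stop) layer index pairs covering [0, n_layers).
    """
    if focal_index is None:
        focal_index = n_layers // 2
    if not 0 <= focal_index < n_layers:
        raise ValueError("focal index outside the stack")
    slabs: list[tuple[int, int]] = []
    z = focal_index
    while z < n_layers:  # outward toward +z
        th = float(profile((z - focal_index) * layer_dz_um))
        if th <= 0:
            raise ValueError("profile must be positive")
        size = max(1, int(round(th / layer_dz_um)))
        slabs.append((z, min(n_layers, z + size)))
        z += size
    z = focal_index
    while z > 0:  # outward toward -z
        th = float(profile((z - focal_index) * layer_dz_um))
        size = max(1, int(round(th / layer_dz_um)))
        slabs.insert(0, (max(0, z - size), z))
        z -= size
    if not slabs:
        raise ValueError("profile yields zero slabs")
    return slabs


def zslab_reduce(vs: VolumeSeries, psf_height_profile,
                 focal_index: int | None = None) -> VolumeSeries:
    """Average z-layers within slabs whose thickness tracks the axial PSF.

    Reduces oversampled reconstructions to physically meaningful layers:
    slices far from the focal plane, where the PSF is tall, are merged into
    thicker slabs.  Slab boundaries are recorded in provenance.
    """
    nz = vs.data.shape[2]
    dz = vs.voxel_size_um[2]
    slabs = zslab_partition(nz, dz, psf_height_profile, focal_index)
    layers = [vs.data[:, :, a:b, :].mean(axis=2) for a, b in slabs]
    out = np.stack(layers, axis=2)
    return vs.evolve(out, f"zslab_reduce(slabs={slabs})")
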