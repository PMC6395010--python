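"""Condition maps, stimulus-response maps, indicator kernels and
behavior/fluorescence statistics.

The two map operations implement the voxelwise contrasts used for
whole-brain activity maps: mean dF/F in one set of frames minus the mean in
another (behavioral conditions), and mean over a post-onset window minus the
pre-onset window (stimulus responses).  Regressors for ball optic flow and
stimulus onsets are built by convolving the raw trace with the indicator's
impulse response.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.optimize import brentq

from .datatypes import ComponentSet, ConditionMap, Kernel, RegionAtlas, VolumeSeries

#: Stated rise time from fluorescence onset to spike peak, per probe (s).
RISE_TO_PEAK_S = {"gcamp6f": 0.15, "gcamp6s": 0.55, "arclight": 0.10}

#: Default decay time constants (s); indicator off-kinetics, configurable.
DECAY_S = {"gcamp6f": 0.6, "gcamp6s": 1.8, "arclight": 0.3}


# ---------------------------------------------------------------------------
# indicator kernels and regressors

def make_kernel(probe: str, frame_rate_hz: float, decay_s: float | None = None,
                rise_to_peak_s: float | None = None) -> Kernel:
    """Build a peak-normalized double-exponential impulse response.

    The kernel is ``(1 - exp(-t/tau_r)) * exp(-t/tau_d)`` with the rise
    constant solved numerically so the peak lands at the probe's stated
    rise-to-peak time (0.15 s for GCaMP6f, 0.10 s for ArcLight).  Taps are
    truncated once they fall below 1e-3 of the peak.
    """
    if probe not in RISE_TO_PEAK_S:
        raise ValueError(f"no kernel model for probe {probe!r}")
    tp = rise_to_peak_s if rise_to_peak_s is not None else RISE_TO_PEAK_S[probe]
    td = decay_s if decay_s is not None else DECAY_S[probe]
    if td <= 0:
        raise ValueError("decay_s must be > 0")
    dt = 1.0 / frame_rate_hz
    if tp / dt < 2:
        raise ValueError(
            f"frame rate {frame_rate_hz} Hz cannot sample a {tp}s rise "
            "(need >= 2 taps before the peak)")

    # Peak time of the double exponential: h'(tp) = 0  <=>
    # exp(-tp/tr)/tr = (1 - exp(-tp/tr))/td;  solve for tr.
    def peak_residual(tr: float) -> float:
        e = np.exp(-tp / tr)
        return e / tr - (1.0 - e) / td

    tr = brentq(peak_residual, 1e-6 * tp, 50.0 * td)
    t = np.arange(0, tp + 12.0 * td, dt)
    h = (1.0 - np.exp(-t / tr)) * np.exp(-t / td)
    h /= h.max()
    keep = np.nonzero(h >= 1e-3)[0]
    h = h[: keep[-1] + 1]
    return Kernel(taps=h, rise_to_peak_s=float(np.argmax(h) * dt), frame_rate_hz=frame_rate_hz)


def build_regressor(trace: np.ndarray, kernel: Kernel,
                    frame_rate_hz: float | None = None) -> np.ndarray:
    """Causal discrete convolution of a per-frame trace with a kernel.

    Output has the same length as the trace.  ``frame_rate_hz``, when given,
    must match the kernel's rate (the trace has no intrinsic rate).
    """
    if frame_rate_hz is not None and not np.isclose(frame_rate_hz, kernel.frame_rate_hz):
        raise ValueError(
            f"trace rate {frame_rate_hz} Hz != kernel rate {kernel.frame_rate_hz} Hz")
    trace = np.asarray(trace, dtype=float)
    return np.convolve(trace, kernel.taps)[: len(trace)]


# ---------------------------------------------------------------------------
# correlation statistics

def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation; rejects constant or mismatched input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length 1D series with >= 3 samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    return float(np.corrcoef(x, y)[0, 1])


def r_squared(x: np.ndarray, y: np.ndarray) -> float:
    return pearson_r(x, y) ** 2


def xcorr_peak_lag(x: np.ndarray, y: np.ndarray, frame_rate_hz: float,
                   max_lag_s: float) -> float:
    """Lag (seconds) of the peak of the normalized cross-correlation.

    Positive lag means ``y`` follows ``x`` (y is a delayed copy of x).  The
    integer-lag peak is refined by a parabolic fit through its neighbors, so
    sub-frame lags are resolvable.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("cross-correlation undefined for constant input")
    max_lag = int(round(max_lag_s * frame_rate_hz))
    if max_lag < 1 or max_lag >= len(x):
        raise ValueError("max_lag_s must cover >= 1 and < n frames")
    lags = np.arange(-max_lag, max_lag + 1)
    cc = np.empty(len(lags))
    for i, lag in enumerate(lags):
        if lag >= 0:
            a, b = x[: len(x) - lag], y[lag:]
        else:
            a, b = x[-lag:], y[: len(y) + lag]
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            cc[i] = -np.inf
        else:
            cc[i] = np.corrcoef(a, b)[0, 1]
    if np.ptp(cc[np.isfinite(cc)]) < 1e-12:
        raise ValueError("flat cross-correlation; no peak")
    k = int(np.argmax(cc))
    lag = float(lags[k])
    if 0 < k < len(lags) - 1 and np.all(np.isfinite(cc[k - 1 : k + 2])):
        denom = cc[k - 1] - 2 * cc[k] + cc[k + 1]
        if abs(denom) > 1e-15:
            lag += 0.5 * (cc[k - 1] - cc[k + 1]) / denom
    return lag / frame_rate_hz


# ---------------------------------------------------------------------------
# voxelwise maps

def condition_difference_map(vs_dff: VolumeSeries, frames_a: np.ndarray,
                             frames_b: np.ndarray, name_a: str = "a",
                             name_b: str = "b",
                             color_convention: dict[str, str] | None = None) -> ConditionMap:
    """Mean dF/F per voxel over ``frames_a`` minus the mean over ``frames_b``."""
    frames_a = np.asarray(frames_a, dtype=int)
    frames_b = np.asarray(frames_b, dtype=int)
    if frames_a.size == 0 or frames_b.size == 0:
        raise ValueError("both frame sets must be nonempty")
    if np.intersect1d(frames_a, frames_b).size:
        raise ValueError("frame sets must be disjoint")
    diff = vs_dff.data[..., frames_a].mean(axis=3) - vs_dff.data[..., frames_b].mean(axis=3)
    conv = color_convention or {"positive": "green", "negative": "magenta"}
    return ConditionMap(diff, name_a, name_b, conv)


def stimulus_response_map(vs_dff: VolumeSeries, onsets_s: np.ndarray,
                          window_s: float = 1.0) -> ConditionMap:
    """Mean over the 1 s after each onset minus the mean over the 1 s before.

    Onsets too close to a recording edge to fit the window on both sides are
    dropped (and reported in the map's condition names).
    """
    rate = vs_dff.frame_rate_hz
    w = int(round(window_s * rate))
    if w < 1:
        raise ValueError("window shorter than one frame")
    post = np.zeros(vs_dff.vol_shape)
    pre = np.zeros(vs_dff.vol_shape)
    used = 0
    dropped = []
    for onset in np.atleast_1d(onsets_s):
        i = int(round(onset * rate))
        if i - w < 0 or i + w > vs_dff.n_frames:
            dropped.append(float(onset))
            continue
        post += vs_dff.data[..., i : i + w].mean(axis=3)
        pre += vs_dff.data[..., i - w : i].mean(axis=3)
        used += 1
    if used == 0:
        raise ValueError("no usable onsets (all too close to recording edges)")
    if dropped:
        warnings.warn(f"dropped {len(dropped)} onsets too close to edges: {dropped}")
    return ConditionMap((post - pre) / used, "post", "pre")


def permutation_sign_test(vs_dff: VolumeSeries, frames_a: np.ndarray,
                          frames_b: np.ndarray, n_perm: int | None = None,
                          seed: int = 0, min_shift_s: float = 0.0) -> np.ndarray:
    """Per-voxel one-sided p-value for mean(a) > mean(b), by circular shifts.

    Circularly shifting the condition labels in time preserves the movie's
    autocorrelation while breaking the frame/condition pairing.  The mean
    difference under every shift is computed at once by FFT circular
    cross-correlation with the condition-contrast indicator; the p-value is
    the fraction of shifts whose difference meets or exceeds the observed
    one.  ``n_perm`` limits the test to a seeded random subset of shifts
    (default: all nonzero shifts, fully deterministic).

    ``min_shift_s`` excludes shifts smaller than the condition signal's
    correlation time (bout length plus indicator decay): such surrogates
    remain aligned with the behavior and are not valid draws from the null,
    which makes the default (0, keep all) conservative.
    """
    frames_a = np.asarray(frames_a, dtype=int)
    frames_b = np.asarray(frames_b, dtype=int)
    if frames_a.size == 0 or frames_b.size == 0:
        raise ValueError("both frame sets must be nonempty")
    nt = vs_dff.n_frames
    w = np.zeros(nt)
    w[frames_a] += 1.0 / frames_a.size
    w[frames_b] -= 1.0 / frames_b.size
    mat = vs_dff.as_matrix().astype(float)
    # diff(s) per voxel = sum_t mat[t] * w[(t - s) mod nt]
    diffs = np.fft.irfft(np.fft.rfft(mat, axis=1) * np.conj(np.fft.rfft(w)),
                         n=nt, axis=1)
    observed = diffs[:, 0]
    guard = int(round(min_shift_s * vs_dff.frame_rate_hz))
    if 2 * guard >= nt - 1:
        raise ValueError("min_shift_s leaves no valid null shifts")
    shifts = np.arange(1 + guard, nt - guard)
    if n_perm is not None and n_perm < nt - 1:
        rng = np.random.default_rng(seed)
        shifts = rng.choice(shifts, size=n_perm, replace=False)
    null = diffs[:, shifts]
    count = (null >= observed[:, None] - 1e-12).sum(axis=1)
    return ((count + 1) / (len(shifts) + 1)).reshape(vs_dff.vol_shape)


# ---------------------------------------------------------------------------
# component-level summaries

def count_responsive(cs: ComponentSet, regressor: np.ndarray, atlas: RegionAtlas | None = None,
                     r_min: float = 0.1) -> dict[str, float]:
    """Per-region counts of responsive components, normalized to the busiest region.

    A component is responsive when its trace's correlation with the
    regressor exceeds ``r_min`` and it is not flagged as an artifact.
    Components must already carry region labels.
    """
    counts: dict[str, int] = {}
    if atlas is not None:
        for rid in atlas.region_ids:
            counts[atlas.names[rid]] = 0
    for i in range(cs.n_components):
        label = cs.region_label[i]
        counts.setdefault(label, 0)
        if cs.artifact[i] not in ("activity",):
            continue
        if label == "unassigned":
            continue
        trace = cs.traces[i]
        if np.ptp(trace) == 0:
            continue
        if pearson_r(trace, regressor) > r_min:
            counts[label] += 1
    counts.pop("unassigned", None)
    peak = max(counts.values()) if counts else 0
    if peak == 0:
        warnings.warn("no responsive components in any region")
        return {k: 0.0 for k in counts}
    return {k: v / peak for k, v in counts.items()}


def export_twocolor(cmap: ConditionMap, background: np.ndarray) -> np.ndarray:
    """Render a signed map over a grayscale background as per-slice RGB.

    Returns a (nz, ny, nx, 3) uint8 stack.  Positive values take the color
    recorded for "positive" in the map's convention (default green), negative
    values the complementary color (default magenta); intensity is scaled to
    the map's absolute maximum.
    """
    if cmap.values.shape != background.shape:
        raise ValueError("map and background grids differ")
    vmax = np.abs(cmap.values).max()
    if vmax == 0:
        warnings.warn("all-zero map: exporting background only")
    bg = background.astype(float)
    bg = (bg - bg.min()) / (np.ptp(bg) or 1.0)
    channels = {"green": (1,), "magenta": (0, 2), "red": (0,), "cyan": (1, 2)}
    pos_ch = channels[cmap.color_convention["positive"]]
    neg_ch = channels[cmap.color_convention["negative"]]
    nx, ny, nz = cmap.values.shape
    out = np.zeros((nz, ny, nx, 3))
    for c in range(3):
        out[..., c] = np.transpose(bg, (2, 1, 0)) * 0.5
    mag = np.transpose(np.abs(cmap.values), (2, 1, 0)) / (vmax or 1.0)
    pos = np.transpose(cmap.values, (2, 1, 0)) > 0
    neg = np.transpose(cmap.values, (2, 1, 0)) < 0
    for c in pos_ch:
        out[..., c] = np.where(pos, mag, out[..., c])
    for c in neg_ch:
        out[..., c] = np.where(neg, mag, out[..., c])
    return (np.clip(out, 0, 1) * 255).astype(np.uint8)


def save_twocolor_png(rgb_stack: np.ndarray, out_dir, prefix: str = "slice") -> list:
    """Write a (nz, ny, nx, 3) RGB stack as one PNG per z-slice."""
    import imageio.v3 as iio
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for z in range(rgb_stack.shape[0]):
        p = out / f"{prefix}_{z:03d}.png"
        iio.imwrite(p, rgb_stack[z])
        paths.append(p)
    return paths
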