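"""Seeded ground-truth phantoms: atlas, sources, behavior, stimuli, and the
renderer that turns them into noisy, bleaching, moving 4D movies.

Every downstream stage of the pipeline is tested against movies produced
here, because the generating sources, motion path, bleach curve, behavior
and stimulus trains are all known exactly.  The generator emulates the
salient properties of real recordings — indicator kinetics (0.15 s rise to
peak for GCaMP6f, 0.10 s for ArcLight), photobleaching (13% intensity loss
over 30 s for GCaMP6, 20% for ArcLight), rigid brain motion, and
walk/groom/rest bouts with one-sided ball turns — without claiming optical
realism (that is the lightfield module's job).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .datatypes import (
    BehaviorTrace,
    GroundTruth,
    RegionAtlas,
    StimulusTrain,
    VolumeSeries,
)
from .mapstats import make_kernel

#: Default fractional intensity loss over 30 s, per probe.
BLEACH_FRACTION_30S = {"gcamp6f": 0.13, "gcamp6s": 0.13, "gfp": 0.13, "arclight": 0.20}

#: Mean bout lengths (s) of the two-state semi-Markov behavior model.
MEAN_BOUT_S = {"walk": 5.0, "rest": 8.0, "groom": 3.0}

#: Neuropil names cycled over generated regions.
REGION_NAMES = ("MB", "AL", "PB", "FB", "EB", "LH", "AMMC", "SLP", "PLP",
                "SAD", "WED", "GNG", "ATL", "NO", "OL", "CRE")

#: Default coupling schedule: the first sources are tied to behavior states,
#: turn directions and stimuli; the remainder fire spontaneously.
DEFAULT_COUPLING = ("walk", "flow_left", "flow_right", "stim:light", "stim:odor")


# ---------------------------------------------------------------------------
# atlas

def make_atlas(shape: tuple[int, int, int], n_regions: int, seed: int,
               voxel_size_um: tuple[float, float, float] = (3.0, 3.0, 6.0)) -> RegionAtlas:
    """Generate a labeled region atlas on an ellipsoidal brain mask.

    Regions are Voronoi cells of random interior seed points, which keeps
    each region connected; connectivity is verified and the seeding retried
    if a cell fragments.  At least four landmarks (region centroids plus
    brain poles) are stored with names, in physical micrometres.
    """
    shape = tuple(int(s) for s in shape)
    if n_regions < 2:
        raise ValueError("need at least 2 regions")
    if any(s < 8 for s in shape):
        raise ValueError(f"each dimension must be >= 8 voxels, got {shape}")

    grid = np.indices(shape).reshape(3, -1).T.astype(float)
    center = (np.array(shape) - 1) / 2.0
    radii = np.array(shape) / 2.0 - 0.5
    inside = (((grid - center) / radii) ** 2).sum(axis=1) <= 1.0
    mask = inside.reshape(shape)
    if mask.sum() < 8 * n_regions:
        raise ValueError(
            f"shape {shape} too small to host {n_regions} connected regions")

    rng = np.random.default_rng(seed)
    coords = np.argwhere(mask)
    struct = ndimage.generate_binary_structure(3, 3)
    for _attempt in range(20):
        seeds = coords[rng.choice(len(coords), size=n_regions, replace=False)]
        # Voronoi assignment: nearest seed, anisotropy-aware
        scale = np.asarray(voxel_size_um)
        d2 = ((coords[:, None, :] * scale - seeds[None, :, :] * scale) ** 2).sum(axis=2)
        assign = d2.argmin(axis=1)
        labels = np.zeros(shape, dtype=np.int32)
        labels[tuple(coords.T)] = assign + 1
        ok = True
        for r in range(1, n_regions + 1):
            lab, n_cc = ndimage.label(labels == r, structure=struct)
            if n_cc != 1:
                ok = False
                break
        if ok:
            break
    else:
        raise ValueError(f"could not seat {n_regions} connected regions in {shape}")

    names = {r: REGION_NAMES[(r - 1) % len(REGION_NAMES)] + (
        "" if r <= len(REGION_NAMES) else str((r - 1) // len(REGION_NAMES) + 1))
        for r in range(1, n_regions + 1)}
    vx = np.asarray(voxel_size_um)
    landmarks: dict[str, tuple[float, float, float]] = {}
    for r in range(1, n_regions + 1):
        c = ndimage.center_of_mass(labels == r)
        landmarks[f"{names[r]}_centroid"] = tuple(np.asarray(c) * vx)
    # Brain poles guarantee >= 4 well-spread, non-coplanar landmarks even
    # for a 2-region atlas.
    poles = {
        "anterior_pole": center + np.array([radii[0] - 1, 0, 0]),
        "posterior_pole": center - np.array([radii[0] - 1, 0, 0]),
        "left_pole": center + np.array([0, radii[1] - 1, 0]),
        "dorsal_pole": center + np.array([0, 0, radii[2] - 1]),
    }
    for name, p in poles.items():
        landmarks[name] = tuple(p * vx)
    return RegionAtlas(labels=labels, names=names, landmarks=landmarks,
                       voxel_size_um=tuple(voxel_size_um))


# ---------------------------------------------------------------------------
# behavior and stimuli

def make_behavior(duration_s: float, frame_rate_hz: float, seed: int,
                  mean_bout_s: dict[str, float] | None = None,
                  turn_bout_s: float = 1.5, flow_peak: float = 1.0) -> BehaviorTrace:
    """Semi-Markov rest/walk/groom bouts with one-sided ball turns.

    Bout durations are exponential with the configured means (walk 5 s,
    rest 8 s, groom 3 s by default, floored at 0.3 s).  Within walk bouts,
    turn sub-bouts of ~``turn_bout_s`` alternate direction at random; the
    flow magnitude is a smooth half-sine so a turn starts and ends at zero.
    """
    means = dict(MEAN_BOUT_S)
    if mean_bout_s:
        means.update(mean_bout_s)
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * frame_rate_hz))
    state = np.empty(n, dtype="<U5")
    flow_l = np.zeros(n)
    flow_r = np.zeros(n)

    t = 0
    current = "rest"
    while t < n:
        dur = max(0.3, rng.exponential(means[current]))
        end = min(n, t + int(round(dur * frame_rate_hz)))
        state[t:end] = current
        if current == "walk":
            # carve the bout into turn/straight sub-bouts
            s = t
            while s < end:
                sub = max(3, int(round(rng.exponential(turn_bout_s) * frame_rate_hz)))
                e = min(end, s + sub)
                kind = rng.choice(["left", "right", "straight"])
                if kind != "straight" and e - s >= 3:
                    bump = flow_peak * np.sin(np.linspace(0, np.pi, e - s))
                    (flow_l if kind == "left" else flow_r)[s:e] = bump
                s = e
        t = end
        if current == "rest":
            current = str(rng.choice(["walk", "groom"], p=[0.7, 0.3]))
        else:
            current = "rest"
    return BehaviorTrace(frame_rate_hz=frame_rate_hz, state=state,
                         flow_left=flow_l, flow_right=flow_r)


def make_stimuli(duration_s: float, seed: int, period_s: float = 6.0,
                 pulse_s: float = 1.0) -> StimulusTrain:
    """Alternating light/odor pulses with jittered onsets, non-overlapping."""
    rng = np.random.default_rng(seed)
    events = []
    t = period_s / 2
    i = 0
    while t + pulse_s < duration_s:
        modality = ("light", "odor")[i % 2]
        onset = t + rng.uniform(-0.1, 0.1) * period_s
        onset = max(0.0, onset)
        if onset + pulse_s < duration_s:
            events.append((onset, onset + pulse_s, modality))
        t += period_s
        i += 1
    return StimulusTrain(events=events)


# ---------------------------------------------------------------------------
# ground truth

def _source_blob(region_mask: np.ndarray, rng: np.random.Generator,
                 sigma_vox: float) -> np.ndarray:
    """Smooth compact Gaussian blob, support strictly inside the region."""
    coords = np.argwhere(region_mask)
    # bias the center toward the region interior
    dist = ndimage.distance_transform_edt(region_mask)
    weights = dist[tuple(coords.T)] ** 2
    weights = weights / weights.sum()
    c = coords[rng.choice(len(coords), p=weights)]
    grid = np.indices(region_mask.shape).astype(float)
    r2 = sum((grid[i] - c[i]) ** 2 for i in range(3))
    blob = np.exp(-r2 / (2 * sigma_vox**2))
    blob[blob < 0.05] = 0.0
    blob *= region_mask
    peak = blob.max()
    if peak <= 0:
        raise RuntimeError("degenerate source blob")
    return blob / peak


def make_ground_truth(atlas: RegionAtlas, n_sources: int, probe: str,
                      duration_s: float, frame_rate_hz: float, seed: int,
                      coupling: list[str] | None = None,
                      amplitude: float = 25.0,
                      event_rate_hz: float = 0.25,
                      bleach_fraction_30s: float | None = None,
                      source_sigma_vox: float = 2.5,
                      structured_baseline: bool = True) -> GroundTruth:
    """Plant sources in atlas regions and synthesize their fluorescence.

    Each source map is a smooth compact blob inside exactly one region.
    Traces are event (or behavior/stimulus drive) trains convolved with the
    probe's impulse response, scaled so the peak excursion equals
    ``amplitude`` (a.u. over baseline; the default of 25 on a baseline of
    100 gives realistic tens-of-percent dF/F transients); ArcLight traces
    are negated because depolarization dims that indicator.  The bleach
    curve is an exponential decay parameterized by fractional loss over
    30 s (13% GCaMP6 / 20% ArcLight by default).
    """
    region_ids = atlas.region_ids
    if n_sources > len(region_ids) * 4:
        raise ValueError("too many sources for this atlas (max 4 per region)")
    n_frames = int(round(duration_s * frame_rate_hz))
    if n_frames < 64:
        raise ValueError("need duration_s * frame_rate_hz >= 64 frames")
    kernel = make_kernel(probe if probe != "gfp" else "gcamp6f", frame_rate_hz)
    if n_frames < len(kernel.taps):
        raise ValueError("recording shorter than the probe kernel")

    rng = np.random.default_rng(seed)
    behavior = make_behavior(duration_s, frame_rate_hz, seed=int(rng.integers(2**31)))
    stimuli = make_stimuli(duration_s, seed=int(rng.integers(2**31)))

    if coupling is None:
        coupling = [DEFAULT_COUPLING[i] if i < len(DEFAULT_COUPLING) else "spontaneous"
                    for i in range(n_sources)]
    if len(coupling) != n_sources:
        raise ValueError("coupling list must have one entry per source")

    maps, regions, traces = [], [], []
    for i in range(n_sources):
        rid = region_ids[i % len(region_ids)]
        maps.append(_source_blob(atlas.mask(rid), rng, source_sigma_vox))
        regions.append(rid)
        mode = coupling[i]
        if mode == "spontaneous":
            drive = np.zeros(n_frames)
            n_ev = rng.poisson(event_rate_hz * duration_s)
            idx = rng.integers(0, n_frames, size=n_ev)
            drive[idx] += rng.lognormal(mean=0.0, sigma=0.35, size=n_ev)
        elif mode in ("walk", "rest", "groom"):
            drive = behavior.indicator(mode)
        elif mode == "flow_left":
            drive = behavior.flow_left
        elif mode == "flow_right":
            drive = behavior.flow_right
        elif mode.startswith("stim:"):
            drive = stimuli.indicator(mode.split(":", 1)[1], n_frames, frame_rate_hz)
        else:
            raise ValueError(f"unknown coupling {mode!r}")
        trace = np.convolve(drive, kernel.taps)[:n_frames]
        # `amplitude` is the trace's peak excursion (a.u. over baseline):
        # sustained drives integrate over the kernel, so normalize the peak
        # rather than the drive
        peak = np.abs(trace).max()
        if peak > 0:
            trace = trace * (amplitude / peak)
        if probe == "arclight":
            trace = -trace
        traces.append(trace)

    frac = bleach_fraction_30s
    if frac is None:
        frac = BLEACH_FRACTION_30S[probe]
    t = np.arange(n_frames) / frame_rate_hz
    if frac > 0:
        tau = -30.0 / np.log(1.0 - frac)
        bleach = np.exp(-t / tau)
    else:
        bleach = np.ones(n_frames)

    # Smooth unit-scale random walk; the renderer scales it by its motion
    # amplitude.  z excursion halved: volumes are thin in z.
    steps = rng.standard_normal((n_frames, 3))
    path = ndimage.gaussian_filter1d(np.cumsum(steps, axis=0), sigma=10.0, axis=0)
    path -= path[0]
    peak = np.abs(path).max(axis=0)
    peak[peak == 0] = 1.0
    path = path / peak
    path[:, 2] *= 0.5

    # Anatomical baseline: per-region fluorescence levels on the brain mask,
    # smoothed, over a small out-of-brain floor.  The bright-brain/dark-
    # background structure is what rigid registration locks onto in real
    # recordings (and what movement shadows form around).
    baseline_map = None
    if structured_baseline:
        levels = np.concatenate([[0.0], rng.uniform(0.7, 1.0, size=max(region_ids))])
        field = levels[atlas.labels]
        baseline_map = 0.05 + ndimage.gaussian_filter(field, sigma=1.5)
        baseline_map /= baseline_map.max()

    return GroundTruth(source_maps=maps, source_traces=np.array(traces),
                       source_regions=regions, source_coupling=list(coupling),
                       motion_path=path, bleach_curve=bleach, behavior=behavior,
                       stimuli=stimuli, frame_rate_hz=frame_rate_hz,
                       probe=probe, seed=seed, baseline_map=baseline_map)


# ---------------------------------------------------------------------------
# rendering

def render_movie(truth: GroundTruth, baseline: float = 100.0,
                 motion_amp_voxels: float = 0.0,
                 noise: dict[str, float] | None = None,
                 seed: int = 0,
                 voxel_size_um: tuple[float, float, float] = (3.0, 3.0, 6.0)) -> VolumeSeries:
    """Render a ground truth bundle into a noisy 4D movie.

    Frame t is ``shift(bleach[t] * (baseline + sum_s map_s * trace_s[t]),
    motion_amp * path[t])`` plus Gaussian read noise and optional
    scaled-Poisson shot noise.  When the ground truth carries an anatomical
    ``baseline_map``, the scalar baseline is modulated by it (brain-shaped
    fluorescence over a dark background); otherwise the baseline is flat.
    Deterministic given ``seed``.
    """
    if baseline <= 0:
        raise ValueError("baseline must be > 0")
    noise = dict(noise or {"gaussian_sd": 2.0, "poisson_scale": 0.0})
    g_sd = float(noise.get("gaussian_sd", 0.0))
    p_scale = float(noise.get("poisson_scale", 0.0))
    if g_sd < 0 or p_scale < 0:
        raise ValueError("noise parameters must be nonnegative")

    shape = truth.source_maps[0].shape if truth.source_maps else None
    if shape is None:
        raise ValueError("ground truth has no source maps (shape unknown)")
    nt = truth.n_frames
    m = np.stack([s.ravel() for s in truth.source_maps])  # (n_src, voxels)
    if truth.baseline_map is not None:
        base_field = baseline * truth.baseline_map.ravel()[:, None]
    else:
        base_field = baseline
    clean = base_field + (truth.source_traces.T @ m).T  # (voxels, nt)
    clean = clean * truth.bleach_curve[None, :]
    movie = clean.reshape(shape + (nt,)).astype(np.float32)

    if motion_amp_voxels != 0:
        shifts = motion_amp_voxels * truth.motion_path
        for ti in range(nt):
            if np.any(shifts[ti] != 0):
                movie[..., ti] = ndimage.shift(movie[..., ti], shifts[ti],
                                               order=1, mode="nearest")
    rng = np.random.default_rng(seed)
    if p_scale > 0:
        movie = rng.poisson(np.clip(movie, 0, None) * p_scale).astype(np.float32) / p_scale
    if g_sd > 0:
        movie = movie + rng.normal(0.0, g_sd, size=movie.shape).astype(np.float32)
    return VolumeSeries(data=movie, voxel_size_um=voxel_size_um,
                        frame_rate_hz=truth.frame_rate_hz, probe=truth.probe,
                        provenance=[f"synthgen.render(seed={seed}, baseline={baseline}, "
                                    f"motion={motion_amp_voxels}, noise={noise})"])


def applied_shifts(truth: GroundTruth, motion_amp_voxels: float) -> np.ndarray:
    """The rigid shifts (voxels) actually imposed by :func:`render_movie`."""
    return motion_amp_voxels * truth.motion_path
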