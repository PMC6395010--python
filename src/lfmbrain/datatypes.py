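"""Core in-memory containers shared across the pipeline.

The universal currency is :class:`VolumeSeries`, a 4D fluorescence movie
(x, y, z, t) with physical voxel size and frame rate.  Everything else —
atlases, behavior traces, stimulus trains, PSF libraries, component sets —
is a thin dataclass with validated invariants, so that each pipeline stage
can state its contract in terms of these types.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

BEHAVIOR_STATES = ("rest", "walk", "groom")

#: Column order of an FWHM resolution profile (one row per measured bead,
#: grouped by signed depth from the focal plane); held in a DataFrame.
FWHM_COLUMNS = ("depth_um", "lateral_fwhm_um", "axial_fwhm_um", "flagged")
PROBES = ("gcamp6f", "gcamp6s", "arclight", "gfp")
STIM_MODALITIES = ("light", "odor")


@dataclass
class VolumeSeries:
    """A 4D scalar fluorescence movie.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz, nt)
        Voxel intensities (arbitrary units, or dimensionless after dF/F).
        0-based indexing, x fastest.
    voxel_size_um : (dx, dy, dz)
        Physical voxel size in micrometres.
    frame_rate_hz : float
        Acquisition rate of the volumes.
    probe : str
        Fluorescent indicator: ``gcamp6f``, ``gcamp6s``, ``arclight`` or
        ``gfp`` (activity-independent control).
    provenance : list of str
        Append-only record of the operations applied so far.
    """

    data: np.ndarray
    voxel_size_um: tuple[float, float, float]
    frame_rate_hz: float
    probe: str = "gcamp6f"
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4D (x,y,z,t) data, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("VolumeSeries data must be finite")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be > 0")
        if self.probe not in PROBES:
            raise ValueError(f"unknown probe {self.probe!r}; expected one of {PROBES}")
        self.voxel_size_um = tuple(float(v) for v in self.voxel_size_um)

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    @property
    def vol_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def evolve(self, data: np.ndarray, note: str, **changes) -> "VolumeSeries":
        """Return a copy with new data and ``note`` appended to provenance."""
        out = replace(self, data=data, provenance=self.provenance + [note], **changes)
        return out

    def as_matrix(self) -> np.ndarray:
        """Voxels x time view (no copy when contiguous)."""
        return self.data.reshape(-1, self.n_frames)


@dataclass
class RigidMotion:
    """Per-frame rigid motion estimate (voxels; optional rotation in degrees)."""

    translation: np.ndarray  # (nt, 3)
    rotation_deg: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.translation = np.asarray(self.translation, dtype=float)
        if self.translation.ndim != 2 or self.translation.shape[1] != 3:
            raise ValueError("translation must be (n_frames, 3)")
        if not np.all(np.isfinite(self.translation)):
            raise ValueError("translations must be finite")
        if self.rotation_deg is not None:
            self.rotation_deg = np.asarray(self.rotation_deg, dtype=float)
            if self.rotation_deg.shape != self.translation.shape:
                raise ValueError("rotation must match translation shape")


@dataclass
class BehaviorTrace:
    """Per-frame behavioral readout on the ball.

    ``state`` is a categorical array over rest/walk/groom; ``flow_left`` and
    ``flow_right`` are nonnegative ball angular speeds (a.u.).  A turn is
    one-sided, so at every frame at most one of the two flows is nonzero.
    """

    frame_rate_hz: float
    state: np.ndarray
    flow_left: np.ndarray
    flow_right: np.ndarray

    def __post_init__(self) -> None:
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be > 0")
        self.state = np.asarray(self.state)
        self.flow_left = np.asarray(self.flow_left, dtype=float)
        self.flow_right = np.asarray(self.flow_right, dtype=float)
        n = len(self.state)
        if len(self.flow_left) != n or len(self.flow_right) != n:
            raise ValueError("state and flow arrays must share length")
        bad = set(np.unique(self.state)) - set(BEHAVIOR_STATES)
        if bad:
            raise ValueError(f"unknown behavior states {sorted(bad)}")
        if np.any(self.flow_left < 0) or np.any(self.flow_right < 0):
            raise ValueError("optic flow must be nonnegative")
        overlap = (self.flow_left > 0) & (self.flow_right > 0)
        if np.any(overlap):
            # Resampling across a turn switch can smear a frame onto both
            # sides; snap the weaker side to zero rather than reject.
            warnings.warn("two-sided flow frames snapped to the dominant side")
            keep_left = self.flow_left >= self.flow_right
            self.flow_right[overlap & keep_left] = 0.0
            self.flow_left[overlap & ~keep_left] = 0.0

    @property
    def n_frames(self) -> int:
        return len(self.state)

    def indicator(self, state: str) -> np.ndarray:
        if state not in BEHAVIOR_STATES:
            raise ValueError(f"unknown state {state!r}")
        return (self.state == state).astype(float)


@dataclass
class StimulusTrain:
    """Stimulus events as (onset_s, offset_s, modality) triples."""

    events: list[tuple[float, float, str]]

    def __post_init__(self) -> None:
        evs = []
        for onset, offset, modality in self.events:
            if modality not in STIM_MODALITIES:
                raise ValueError(f"unknown modality {modality!r}")
            if not onset < offset:
                raise ValueError(f"onset {onset} must precede offset {offset}")
            evs.append((float(onset), float(offset), str(modality)))
        self.events = evs
        for modality in STIM_MODALITIES:
            spans = sorted((a, b) for a, b, m in self.events if m == modality)
            for (a1, b1), (a2, _) in zip(spans, spans[1:]):
                if a2 < b1:
                    raise ValueError(f"overlapping {modality} events at {a2:.3f}s")

    def onsets(self, modality: str) -> np.ndarray:
        return np.array([a for a, _, m in self.events if m == modality])

    def indicator(self, modality: str, n_frames: int, frame_rate_hz: float) -> np.ndarray:
        """Boxcar (0/1) drive at the given frame grid."""
        t = np.arange(n_frames) / frame_rate_hz
        out = np.zeros(n_frames)
        for onset, offset, m in self.events:
            if m == modality:
                out[(t >= onset) & (t < offset)] = 1.0
        return out

    def onset_deltas(self, modality: str, n_frames: int, frame_rate_hz: float) -> np.ndarray:
        """Unit impulse at the frame nearest each onset."""
        out = np.zeros(n_frames)
        for onset in self.onsets(modality):
            i = int(round(onset * frame_rate_hz))
            if 0 <= i < n_frames:
                out[i] = 1.0
        return out


@dataclass
class RegionAtlas:
    """Labeled 3D region volume with named landmarks.

    ``labels`` holds integer region ids (0 = background); ``names`` maps each
    nonzero label to a region name; ``landmarks`` maps landmark names to
    physical coordinates in micrometres.
    """

    labels: np.ndarray
    names: dict[int, str]
    landmarks: dict[str, tuple[float, float, float]]
    voxel_size_um: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("atlas labels must be 3D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("atlas labels must be integer")
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.names)
        if missing:
            raise ValueError(f"labels without names: {sorted(missing)}")
        if len(set(self.landmarks)) != len(self.landmarks):
            raise ValueError("landmark names must be unique")
        self.voxel_size_um = tuple(float(v) for v in self.voxel_size_um)

    @property
    def region_ids(self) -> list[int]:
        return sorted(set(np.unique(self.labels)) - {0})

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label


@dataclass
class GroundTruth:
    """Known-answer phantom behind a synthetic movie.

    ``source_maps`` are nonnegative 3D weight fields (one per source),
    ``source_traces`` the matching fluorescence time series.  ``motion_path``
    is a unit-normalized per-frame rigid shift (scaled by the renderer's
    motion amplitude), ``bleach_curve`` a non-increasing multiplicative
    factor in (0, 1].
    """

    source_maps: list[np.ndarray]
    source_traces: np.ndarray  # (n_sources, nt)
    source_regions: list[int]
    source_coupling: list[str]  # "spontaneous", "walk", "flow_left", "stim:light", ...
    motion_path: np.ndarray  # (nt, 3), unit scale
    bleach_curve: np.ndarray  # (nt,)
    behavior: BehaviorTrace
    stimuli: StimulusTrain
    frame_rate_hz: float
    probe: str
    seed: int
    #: relative anatomical baseline field (peak 1), or None for a flat baseline
    baseline_map: np.ndarray | None = None

    def __post_init__(self) -> None:
        for m in self.source_maps:
            if np.any(m < 0) or not np.all(np.isfinite(m)):
                raise ValueError("source maps must be nonnegative and finite")
        self.source_traces = np.atleast_2d(np.asarray(self.source_traces, dtype=float))
        self.motion_path = np.asarray(self.motion_path, dtype=float)
        self.bleach_curve = np.asarray(self.bleach_curve, dtype=float)
        if np.any(np.diff(self.bleach_curve) > 1e-12):
            raise ValueError("bleach_curve must be non-increasing")
        if np.any(self.bleach_curve <= 0) or np.any(self.bleach_curve > 1 + 1e-12):
            raise ValueError("bleach_curve must lie in (0, 1]")
        if not np.allclose(self.motion_path[0], 0):
            raise ValueError("motion_path must start at the origin")

    @property
    def n_sources(self) -> int:
        return len(self.source_maps)

    @property
    def n_frames(self) -> int:
        return self.source_traces.shape[1]


@dataclass
class PSFLibrary:
    """Depth-indexed blur kernels: the light field forward model.

    Each entry is a separable 3D Gaussian kernel (lateral x axial) at a
    signed focal offset; kernels are normalized to unit sum and widen with
    distance from the focal plane under the default geometric-optics model.
    """

    depths_um: np.ndarray
    kernels: list[np.ndarray]  # per-depth 3D (kx, ky, kz), sum 1
    voxel_size_um: tuple[float, float, float]
    lateral_sigma_um: np.ndarray | None = None
    axial_sigma_um: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.depths_um = np.asarray(self.depths_um, dtype=float)
        if np.any(np.diff(self.depths_um) <= 0):
            raise ValueError("depths must be strictly increasing")
        if len(self.kernels) != len(self.depths_um):
            raise ValueError("one kernel per depth required")
        for k in self.kernels:
            if np.any(k < 0):
                raise ValueError("kernels must be nonnegative")
            if abs(k.sum() - 1.0) > 1e-9:
                raise ValueError("each kernel must sum to 1 within 1e-9")
        self.voxel_size_um = tuple(float(v) for v in self.voxel_size_um)

    @property
    def n_depths(self) -> int:
        return len(self.depths_um)

    def lateral_kernel(self, i: int) -> np.ndarray:
        """2D lateral kernel at depth i (axial marginal summed out)."""
        k = self.kernels[i].sum(axis=2)
        return k / k.sum()


@dataclass
class LightFieldSeries:
    """Raw 2D sensor frames behind a microlens array."""

    frames: np.ndarray  # (nt, h, w)
    lenslet_pitch_px: int
    frame_rate_hz: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim == 2:
            self.frames = self.frames[None]
        if self.frames.ndim != 3:
            raise ValueError("frames must be (t, h, w)")
        h, w = self.frames.shape[1:]
        p = self.lenslet_pitch_px
        if p < 1 or h % p or w % p:
            raise ValueError(f"frame dims {(h, w)} must be divisible by lenslet pitch {p}")
        if np.any(self.frames < 0):
            raise ValueError("sensor values must be nonnegative")


@dataclass
class SingularSpectrum:
    """Thin SVD of a voxels x time matrix, with the movie geometry kept."""

    values: np.ndarray  # (k,) non-increasing, > 0 entries first
    spatial_modes: np.ndarray  # (voxels, k), orthonormal columns
    temporal_modes: np.ndarray  # (time, k), orthonormal columns
    vol_shape: tuple[int, int, int]
    frame_rate_hz: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.values) > 1e-10 * self.values[0]):
            raise ValueError("singular values must be non-increasing")

    @property
    def rank(self) -> int:
        return len(self.values)

    def mode_map(self, i: int) -> np.ndarray:
        return self.spatial_modes[:, i].reshape(self.vol_shape)


@dataclass
class ComponentSet:
    """Paired spatial maps and time series from PCA/ICA unmixing.

    Traces are variance normalized; maps carry the amplitude.  Components
    accumulate annotations downstream: sign convention, main atlas region,
    artifact class, and the region-count / object-count diagnostics used by
    the automatic artifact rules.
    """

    maps: np.ndarray  # (n, nx, ny, nz)
    traces: np.ndarray  # (n, nt)
    frame_rate_hz: float
    sign_fixed: bool = False
    region_label: list[str] = field(default_factory=list)
    artifact: list[str] = field(default_factory=list)
    n_regions_present: np.ndarray | None = None
    n_objects: np.ndarray | None = None
    converged: bool = True

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        self.traces = np.atleast_2d(np.asarray(self.traces, dtype=float))
        if self.maps.shape[0] != self.traces.shape[0]:
            raise ValueError("|maps| must equal |traces|")
        if not self.region_label:
            self.region_label = ["unassigned"] * self.n_components
        if not self.artifact:
            self.artifact = ["activity"] * self.n_components

    @property
    def n_components(self) -> int:
        return self.maps.shape[0]

    @property
    def vol_shape(self) -> tuple[int, int, int]:
        return self.maps.shape[1:]


@dataclass
class RoiMask:
    """Nonnegative voxel weights from a z-score-thresholded component map."""

    weights: np.ndarray
    component_id: int
    threshold_k: float

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < 0):
            raise ValueError("ROI weights must be nonnegative")
        if self.weights.sum() <= 0:
            raise ValueError("ROI mask is empty")


@dataclass
class AffineTransform:
    """3x4 affine (linear + translation) in physical micrometre coordinates."""

    matrix: np.ndarray  # (3, 4)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (3, 4):
            raise ValueError("affine matrix must be 3x4")
        if abs(np.linalg.det(self.matrix[:, :3])) <= 1e-9:
            raise ValueError("linear part must be invertible")

    @property
    def linear(self) -> np.ndarray:
        return self.matrix[:, :3]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:, 3]

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.linear.T + self.translation

    def inverse(self) -> "AffineTransform":
        inv = np.linalg.inv(self.linear)
        return AffineTransform(np.hstack([inv, -inv @ self.translation[:, None]]))

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.hstack([np.eye(3), np.zeros((3, 1))]))


@dataclass
class ConditionMap:
    """Voxelwise mean dF/F difference between two conditions.

    Antisymmetric under swapping the conditions.  ``color_convention``
    records which sign maps to which display color in two-color exports
    (e.g. green for condition_a > condition_b, magenta for the reverse).
    """

    values: np.ndarray
    condition_a: str
    condition_b: str
    color_convention: dict[str, str] = field(
        default_factory=lambda: {"positive": "green", "negative": "magenta"}
    )

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("condition map must be finite")

    def swapped(self) -> "ConditionMap":
        conv = {"positive": self.color_convention["negative"],
                "negative": self.color_convention["positive"]}
        return ConditionMap(-self.values, self.condition_b, self.condition_a, conv)


@dataclass
class Kernel:
    """Peak-normalized indicator impulse response at a given frame rate."""

    taps: np.ndarray
    rise_to_peak_s: float
    frame_rate_hz: float

    def __post_init__(self) -> None:
        self.taps = np.asarray(self.taps, dtype=float)
        if np.any(self.taps < 0):
            raise ValueError("kernel taps must be nonnegative")
        if abs(self.taps.max() - 1.0) > 1e-9:
            raise ValueError("kernel must be peak-normalized")
        dt = 1.0 / self.frame_rate_hz
        if abs(int(np.argmax(self.taps)) * dt - self.rise_to_peak_s) > dt + 1e-9:
            raise ValueError("kernel argmax inconsistent with stated rise-to-peak")
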