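"""Readers and writers for the pipeline's on-disk formats.

Movies and atlases travel as NIfTI-1 (voxel size in the header, frame rate
in pixdim[4]); behavior and stimuli as CSV; landmarks, component metadata
and ground-truth manifests as JSON; raw sensor frames as multi-page TIFF.
Sidecar JSON files carry fields NIfTI cannot (probe, provenance).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .datatypes import (
    BehaviorTrace,
    ComponentSet,
    GroundTruth,
    LightFieldSeries,
    RegionAtlas,
    StimulusTrain,
    VolumeSeries,
)


# ---------------------------------------------------------------------------
# NIfTI volumes

def _affine(voxel_size_um) -> np.ndarray:
    return np.diag(list(voxel_size_um) + [1.0])


def write_volume(vs: VolumeSeries, path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(vs.data, dtype=np.float32), _affine(vs.voxel_size_um))
    img.header["pixdim"][4] = 1.0 / vs.frame_rate_hz
    img.header.set_xyzt_units(xyz="micron", t="sec")
    nib.save(img, path)
    sidecar = {"probe": vs.probe, "frame_rate_hz": vs.frame_rate_hz,
               "provenance": vs.provenance}
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_volume(path) -> VolumeSeries:
    path = Path(path)
    img = nib.load(path)
    data = np.asarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected 4D (x,y,z,t) volume, got {data.ndim}D")
    zooms = img.header.get_zooms()
    voxel = tuple(float(z) for z in zooms[:3])
    tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    probe, provenance, rate = "gcamp6f", [], 1.0 / tr
    sc = _sidecar_path(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
        probe = meta.get("probe", probe)
        provenance = meta.get("provenance", [])
        rate = meta.get("frame_rate_hz", rate)
    return VolumeSeries(data=data, voxel_size_um=voxel, frame_rate_hz=rate,
                        probe=probe, provenance=provenance)


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


# ---------------------------------------------------------------------------
# atlas

def write_atlas(atlas: RegionAtlas, path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(atlas.labels.astype(np.int32), _affine(atlas.voxel_size_um))
    nib.save(img, path)
    meta = {"names": {str(k): v for k, v in atlas.names.items()},
            "landmarks": {k: list(v) for k, v in atlas.landmarks.items()},
            "voxel_size_um": list(atlas.voxel_size_um)}
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_atlas(path) -> RegionAtlas:
    path = Path(path)
    img = nib.load(path)
    labels = np.asarray(img.dataobj).astype(np.int32)
    meta = json.loads(_sidecar_path(path).read_text())
    return RegionAtlas(labels=labels,
                       names={int(k): v for k, v in meta["names"].items()},
                       landmarks={k: tuple(v) for k, v in meta["landmarks"].items()},
                       voxel_size_um=tuple(meta["voxel_size_um"]))


# ---------------------------------------------------------------------------
# behavior / stimuli CSV

def write_behavior(behavior: BehaviorTrace, path) -> Path:
    path = Path(path)
    t = np.arange(behavior.n_frames) / behavior.frame_rate_hz
    pd.DataFrame({"time_s": t, "state": behavior.state,
                  "flow_left": behavior.flow_left,
                  "flow_right": behavior.flow_right}).to_csv(path, index=False)
    return path


def read_behavior(path) -> BehaviorTrace:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    rate = 1.0 / float(np.median(np.diff(t))) if len(t) > 1 else 1.0
    return BehaviorTrace(frame_rate_hz=rate, state=df["state"].to_numpy(dtype="<U5"),
                         flow_left=df["flow_left"].to_numpy(),
                         flow_right=df["flow_right"].to_numpy())


def write_stimuli(stimuli: StimulusTrain, path) -> Path:
    path = Path(path)
    pd.DataFrame(stimuli.events, columns=["onset_s", "offset_s", "modality"]
                 ).to_csv(path, index=False)
    return path


def read_stimuli(path) -> StimulusTrain:
    df = pd.read_csv(path)
    return StimulusTrain(events=[(r.onset_s, r.offset_s, r.modality)
                                 for r in df.itertuples()])


# ---------------------------------------------------------------------------
# TIFF sensor frames

def import_tiff_stack(path, frame_rate_hz: float,
                      lenslet_pitch_px: int = 4) -> LightFieldSeries:
    """Read raw camera frames from a multi-page TIFF, dtype preserved to float."""
    import tifffile

    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        if not tf.pages:
            raise ValueError(f"{path}: empty TIFF")
        shapes = {p.shape for p in tf.pages}
        if len(shapes) > 1:
            raise ValueError(f"{path}: ragged pages {sorted(shapes)}")
        frames = tf.asarray().astype(float)
    if frames.ndim == 2:
        frames = frames[None]
    return LightFieldSeries(frames=frames, lenslet_pitch_px=lenslet_pitch_px,
                            frame_rate_hz=frame_rate_hz)


def export_tiff_stack(frames: np.ndarray, path) -> Path:
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, np.asarray(frames, dtype=np.float32))
    return path


# ---------------------------------------------------------------------------
# component sets

def write_components(cs: ComponentSet, out_dir,
                     voxel_size_um=(3.0, 3.0, 6.0)) -> Path:
    """maps -> 4D NIfTI (component as 4th dim), traces -> CSV, metadata -> JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    maps4d = np.moveaxis(cs.maps, 0, -1).astype(np.float32)
    nib.save(nib.Nifti1Image(maps4d, _affine(voxel_size_um)), out / "component_maps.nii")
    pd.DataFrame(cs.traces.T,
                 columns=[f"component_{i}" for i in range(cs.n_components)]
                 ).to_csv(out / "component_traces.csv", index=False)
    meta = {
        "frame_rate_hz": cs.frame_rate_hz,
        "sign_fixed": cs.sign_fixed,
        "converged": cs.converged,
        "region_label": list(cs.region_label),
        "artifact": list(cs.artifact),
        "n_regions_present": None if cs.n_regions_present is None
        else [int(v) for v in cs.n_regions_present],
        "n_objects": None if cs.n_objects is None else [int(v) for v in cs.n_objects],
    }
    (out / "components.json").write_text(json.dumps(meta, indent=1))
    return out


def read_components(out_dir) -> ComponentSet:
    out = Path(out_dir)
    maps4d = np.asarray(nib.load(out / "component_maps.nii").dataobj)
    traces = pd.read_csv(out / "component_traces.csv").to_numpy().T
    meta = json.loads((out / "components.json").read_text())
    return ComponentSet(
        maps=np.moveaxis(maps4d, -1, 0), traces=traces,
        frame_rate_hz=meta["frame_rate_hz"], sign_fixed=meta["sign_fixed"],
        region_label=meta["region_label"], artifact=meta["artifact"],
        n_regions_present=None if meta["n_regions_present"] is None
        else np.array(meta["n_regions_present"]),
        n_objects=None if meta["n_objects"] is None else np.array(meta["n_objects"]),
        converged=meta["converged"])


def write_classification_report(cs: ComponentSet, path, rule: str = "or") -> Path:
    path = Path(path)
    rows = []
    for i in range(cs.n_components):
        rows.append({
            "component": i,
            "region": cs.region_label[i],
            "n_regions": int(cs.n_regions_present[i]) if cs.n_regions_present is not None else -1,
            "n_objects": int(cs.n_objects[i]) if cs.n_objects is not None else -1,
            "flag": cs.artifact[i],
            "rule": rule,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# ground-truth bundle

def save_ground_truth(truth: GroundTruth, out_dir,
                      voxel_size_um=(3.0, 3.0, 6.0)) -> Path:
    """Write a ground-truth bundle as a directory with a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    maps4d = np.stack(truth.source_maps, axis=-1).astype(np.float32)
    nib.save(nib.Nifti1Image(maps4d, _affine(voxel_size_um)), out / "source_maps.nii")
    np.savetxt(out / "source_traces.csv", truth.source_traces.T, delimiter=",")
    if truth.baseline_map is not None:
        nib.save(nib.Nifti1Image(truth.baseline_map.astype(np.float32),
                                 _affine(voxel_size_um)), out / "baseline_map.nii")
    np.savetxt(out / "motion_path.csv", truth.motion_path, delimiter=",")
    np.savetxt(out / "bleach_curve.csv", truth.bleach_curve, delimiter=",")
    write_behavior(truth.behavior, out / "behavior.csv")
    write_stimuli(truth.stimuli, out / "stimuli.csv")
    manifest = {
        "n_sources": truth.n_sources,
        "n_frames": truth.n_frames,
        "frame_rate_hz": truth.frame_rate_hz,
        "probe": truth.probe,
        "seed": truth.seed,
        "source_regions": [int(r) for r in truth.source_regions],
        "source_coupling": list(truth.source_coupling),
        "files": ["source_maps.nii", "source_traces.csv", "motion_path.csv",
                  "bleach_curve.csv", "behavior.csv", "stimuli.csv"],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def load_ground_truth(out_dir) -> GroundTruth:
    out = Path(out_dir)
    manifest = json.loads((out / "manifest.json").read_text())
    maps4d = np.asarray(nib.load(out / "source_maps.nii").dataobj)
    traces = np.loadtxt(out / "source_traces.csv", delimiter=",", ndmin=2).T
    baseline_map = None
    if (out / "baseline_map.nii").exists():
        baseline_map = np.asarray(nib.load(out / "baseline_map.nii").dataobj)
    return GroundTruth(
        baseline_map=baseline_map,
        source_maps=[maps4d[..., i] for i in range(maps4d.shape[-1])],
        source_traces=traces,
        source_regions=manifest["source_regions"],
        source_coupling=manifest["source_coupling"],
        motion_path=np.loadtxt(out / "motion_path.csv", delimiter=","),
        bleach_curve=np.loadtxt(out / "bleach_curve.csv", delimiter=","),
        behavior=read_behavior(out / "behavior.csv"),
        stimuli=read_stimuli(out / "stimuli.csv"),
        frame_rate_hz=manifest["frame_rate_hz"],
        probe=manifest["probe"],
        seed=manifest["seed"])
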