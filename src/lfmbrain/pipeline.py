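"""End-to-end pipeline driver: simulate -> preprocess -> sources -> atlas ->
mapstats, with a structured run log.

Each stage writes its artifacts under the output directory before the next
begins, so a failed run preserves everything up to the failing stage.
Re-running with the same config and seed reproduces the outputs
bit-identically.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np

from . import atlas as atlasmod
from . import io, mapstats, preprocess, sources, synthgen
from .config import PipelineConfig
from .datatypes import VolumeSeries


class StageError(RuntimeError):
    def __init__(self, stage: str, out_dir: Path, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause} "
                         f"(artifacts preserved under {out_dir})")
        self.stage = stage


def run_pipeline(config: PipelineConfig, out_dir) -> Path:
    """Run the full analysis workflow on a simulated recording.

    Writes the simulated bundle, the preprocessed movie, the component set
    (maps NIfTI + traces CSV), the classification TSV, condition /
    stimulus-response maps, and a provenance log with the config hash.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"config_hash": config.config_hash(), "seed": config.seed,
                 "stages": {}, "versions": _versions()}
    config.to_yaml(out / "config.yaml")

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                result = fn()
            except Exception as exc:
                log["stages"][name] = {"status": "failed", "error": str(exc)}
                (out / "run_log.json").write_text(json.dumps(log, indent=1))
                raise StageError(name, out, exc) from exc
            log["stages"][name] = {"status": "ok",
                                   "seconds": round(time.perf_counter() - t0, 3)}
            return result
        return deco

    sim = config.simulate

    def _simulate():
        region_atlas = synthgen.make_atlas(sim.shape, sim.n_regions, seed=config.seed,
                                           voxel_size_um=sim.voxel_size_um)
        truth = synthgen.make_ground_truth(
            region_atlas, sim.n_sources, sim.probe, sim.duration_s,
            sim.frame_rate_hz, seed=config.seed + 1, amplitude=sim.amplitude,
            bleach_fraction_30s=sim.bleach_fraction_30s)
        movie = synthgen.render_movie(
            truth, baseline=sim.baseline, motion_amp_voxels=sim.motion_amp_voxels,
            noise={"gaussian_sd": sim.gaussian_sd, "poisson_scale": sim.poisson_scale},
            seed=config.seed + 2, voxel_size_um=sim.voxel_size_um)
        io.write_atlas(region_atlas, out / "atlas.nii")
        io.save_ground_truth(truth, out / "ground_truth", sim.voxel_size_um)
        io.write_volume(movie, out / "movie.nii")
        return region_atlas, truth, movie

    region_atlas, truth, movie = stage("simulate")(_simulate)

    pp = config.preprocess

    def _preprocess():
        vs = movie
        n_skip = int(round(pp.discard_initial_s * vs.frame_rate_hz))
        if 0 < n_skip < vs.n_frames:
            vs = vs.evolve(vs.data[..., n_skip:], f"discard_initial({n_skip} frames)")
        if pp.motion_correct:
            vs, _motion = preprocess.motion_correct(vs, reference=pp.motion_reference)
        vs_dff = preprocess.dff(vs, baseline=pp.dff_baseline)
        vs = preprocess.detrend(vs, window_s=min(pp.detrend_window_s,
                                                 vs.n_frames / vs.frame_rate_hz))
        if vs.probe == "arclight":
            vs = preprocess.invert_sign(vs)
            vs_dff = preprocess.invert_sign(vs_dff, force=True)
        vs = preprocess.kalman_denoise(vs, gain=pp.kalman_gain)
        if pp.svd_removal == "auto":
            vs, _removed = preprocess.svd_motion_removal(vs)
        if pp.highpass_window_s:
            vs = preprocess.highpass(vs, window_s=pp.highpass_window_s)
        io.write_volume(vs, out / "preprocessed.nii")
        behavior = preprocess.align_behavior(truth.behavior, vs.n_frames,
                                             vs.frame_rate_hz)
        return vs, vs_dff, behavior, n_skip

    vs, vs_dff, behavior, n_skip = stage("preprocess")(_preprocess)

    sc = config.sources

    def _sources():
        cs, spectrum = sources.extract_sources(
            vs, seed=sc.seed, n_presvd=sc.n_presvd, n_components=sc.n_components,
            fallback_n=sc.fallback_n, max_iter=sc.max_iter, tol=sc.tol)
        np.savetxt(out / "singular_values.csv", spectrum.values, delimiter=",")
        return cs

    cs = stage("sources")(_sources)

    ac = config.atlas

    def _atlas():
        annotated = atlasmod.sort_by_region(cs, region_atlas)
        annotated = atlasmod.classify_artifacts(
            annotated, region_atlas, rule=ac.artifact_rule,
            max_regions=ac.max_regions, max_objects=ac.max_objects,
            connectivity=ac.connectivity, min_fraction=ac.presence_fraction)
        io.write_components(annotated, out / "components", sim.voxel_size_um)
        io.write_classification_report(annotated, out / "classification.tsv",
                                       rule=ac.artifact_rule)
        return annotated

    annotated = stage("atlas")(_atlas)

    ms = config.mapstats

    def _mapstats():
        walk = np.nonzero(behavior.state == "walk")[0]
        rest = np.nonzero(behavior.state == "rest")[0]
        if walk.size and rest.size:
            cmap = mapstats.condition_difference_map(vs_dff, walk, rest, "walk", "rest")
            _write_map(cmap.values, out / "walk_vs_rest.nii", sim.voxel_size_um)
        t_offset = n_skip / vs.frame_rate_hz
        onsets = truth.stimuli.onsets("light") - t_offset
        onsets = onsets[onsets > 0]
        if onsets.size:
            smap = mapstats.stimulus_response_map(vs_dff, onsets,
                                                  window_s=ms.stimulus_window_s)
            _write_map(smap.values, out / "light_response.nii", sim.voxel_size_um)
        kernel = mapstats.make_kernel(
            vs.probe if vs.probe != "gfp" else "gcamp6f", vs.frame_rate_hz,
            decay_s=ms.kernel_decay_s)
        stats = {}
        for name, drive in [("flow_left", behavior.flow_left),
                            ("flow_right", behavior.flow_right),
                            ("walk", behavior.indicator("walk"))]:
            if np.ptp(drive) == 0:
                continue
            reg = mapstats.build_regressor(drive, kernel)
            counts = mapstats.count_responsive(annotated, reg, region_atlas,
                                               r_min=ms.r_min)
            stats[name] = counts
        (out / "responsive_counts.json").write_text(json.dumps(stats, indent=1))
        return stats

    stage("mapstats")(_mapstats)
    (out / "run_log.json").write_text(json.dumps(log, indent=1))
    return out


def _write_map(values: np.ndarray, path: Path, voxel_size_um) -> None:
    vs = VolumeSeries(values[..., None], voxel_size_um, 1.0, probe="gcamp6f")
    io.write_volume(vs, path)


def _versions() -> dict[str, str]:
    import nibabel
    import numpy
    import scipy
    import sklearn

    from . import __version__

    return {"lfmbrain": __version__, "numpy": numpy.__version__,
            "scipy": scipy.__version__, "sklearn": sklearn.__version__,
            "nibabel": nibabel.__version__}
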