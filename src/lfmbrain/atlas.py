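"""Landmark registration to a region atlas, component-to-region sorting,
and automatic artifact classification.

Components are sorted into neuropil regions by the highest within-region
mean of the positive map, and auto-flagged as artifacts when they are
present in more than five regions or fragment into more than 200 connected
objects — movement shadows smear across regions, noise speckles fragment.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .datatypes import AffineTransform, ComponentSet, RegionAtlas
from .sources import zscore_threshold_mask

CONNECTIVITY_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def landmark_affine(moving: dict[str, tuple[float, float, float]],
                    fixed: dict[str, tuple[float, float, float]]
                    ) -> tuple[AffineTransform, float]:
    """Least-squares affine mapping moving landmarks onto fixed ones.

    Uses the landmarks shared by name between the two sets (at least four,
    non-coplanar).  Returns the transform and the residual RMS (um).
    """
    shared = sorted(set(moving) & set(fixed))
    if len(shared) < 4:
        raise ValueError(f"need >= 4 shared landmark names, got {len(shared)}")
    m = np.array([moving[k] for k in shared], dtype=float)
    f = np.array([fixed[k] for k in shared], dtype=float)
    centered = m - m.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[-1] < 1e-6 * max(sv[0], 1.0):
        raise ValueError("landmarks are coplanar; affine is underdetermined")
    design = np.hstack([m, np.ones((len(shared), 1))])
    sol, *_ = np.linalg.lstsq(design, f, rcond=None)
    t = AffineTransform(sol.T)
    rms = float(np.sqrt(np.mean(np.sum((t.apply(m) - f) ** 2, axis=1))))
    return t, rms


def apply_transform(field: np.ndarray, t: AffineTransform,
                    voxel_size_um: tuple[float, float, float],
                    target_shape: tuple[int, int, int] | None = None,
                    target_voxel_size_um: tuple[float, float, float] | None = None
                    ) -> np.ndarray:
    """Resample a 3D field through an affine transform (pull-back).

    The transform maps moving physical coordinates to fixed ones; the
    output is sampled on the target grid by evaluating the input at the
    inverse-transformed position.  Integer (label) fields use
    nearest-neighbor interpolation, continuous fields trilinear.
    """
    field = np.asarray(field)
    if target_shape is None:
        target_shape = field.shape
    tvx = np.asarray(target_voxel_size_um if target_voxel_size_um is not None
                     else voxel_size_um, dtype=float)
    svx = np.asarray(voxel_size_um, dtype=float)
    inv = t.inverse()
    # voxel(target) -> phys(fixed) -> phys(moving) -> voxel(moving)
    lin = (inv.linear * tvx[None, :]) / svx[:, None]
    off = inv.translation / svx
    order = 0 if np.issubdtype(field.dtype, np.integer) else 1
    out = ndimage.affine_transform(field.astype(float), lin, offset=off,
                                   output_shape=target_shape, order=order,
                                   mode="constant", cval=0.0)
    if order == 0:
        out = out.astype(field.dtype)
    return out


def sort_by_region(cs: ComponentSet, atlas: RegionAtlas) -> ComponentSet:
    """Assign each component its main region: the one with the highest mean
    of the positive map within the region mask.

    Ties break toward the region with the larger overlap count, then the
    lowest label.  Background is excluded; a map with no positive weight in
    any region is "unassigned".
    """
    if atlas.labels.shape != cs.vol_shape:
        raise ValueError("atlas must be resampled to the component grid first")
    labels = []
    for i in range(cs.n_components):
        pos = np.clip(cs.maps[i], 0, None)
        best = None  # (mean, overlap, -label)
        best_label = "unassigned"
        for rid in atlas.region_ids:
            mask = atlas.mask(rid)
            vals = pos[mask]
            mean = float(vals.mean()) if vals.size else 0.0
            overlap = int((vals > 0).sum())
            if mean <= 0:
                continue
            key = (mean, overlap, -rid)
            if best is None or key > best:
                best = key
                best_label = atlas.names[rid]
        labels.append(best_label)
    out = ComponentSet(maps=cs.maps, traces=cs.traces, frame_rate_hz=cs.frame_rate_hz,
                       sign_fixed=cs.sign_fixed, region_label=labels,
                       artifact=list(cs.artifact), n_regions_present=cs.n_regions_present,
                       n_objects=cs.n_objects, converged=cs.converged)
    return out


def count_objects(mask: np.ndarray, connectivity: int = 26) -> int:
    """Number of connected components of a binary 3D field."""
    if connectivity not in CONNECTIVITY_STRUCTS:
        raise ValueError("connectivity must be 6, 18 or 26")
    mask = np.asarray(mask).astype(bool)
    _, n = ndimage.label(mask, structure=CONNECTIVITY_STRUCTS[connectivity])
    return int(n)


def region_presence(map3d: np.ndarray, atlas: RegionAtlas, threshold_k: float = 3.0,
                    min_fraction: float = 0.005) -> set[int]:
    """Regions in which a component map is considered present.

    Convention: a region is present when the fraction of its voxels
    exceeding the map's ``k``-sigma threshold (SD about zero) is greater
    than ``min_fraction`` (default 0.5%).
    """
    m = np.asarray(map3d, dtype=float)
    sd = float(np.sqrt(np.mean(m ** 2)))
    if sd == 0:
        return set()
    supra = m >= threshold_k * sd
    present = set()
    for rid in atlas.region_ids:
        mask = atlas.mask(rid)
        n = int(mask.sum())
        if n and supra[mask].sum() / n > min_fraction:
            present.add(rid)
    return present


def classify_artifacts(cs: ComponentSet, atlas: RegionAtlas, rule: str = "or",
                       max_regions: int = 5, max_objects: int = 200,
                       threshold_k: float = 3.0, connectivity: int = 26,
                       min_fraction: float = 0.005,
                       manual: dict[int, str] | None = None) -> ComponentSet:
    """Auto-flag movement/noise artifact components.

    A component is flagged when it is present in more than ``max_regions``
    regions OR fragments into more than ``max_objects`` connected objects
    in its 3-sigma mask (default rule "or"; rule "and" requires both).
    Manual overrides are recorded as class "manual:<label>" and never
    silently dropped.
    """
    if rule not in ("or", "and"):
        raise ValueError("rule must be 'or' or 'and'")
    n_regions = np.zeros(cs.n_components, dtype=int)
    n_objects = np.zeros(cs.n_components, dtype=int)
    flags = []
    for i in range(cs.n_components):
        m = cs.maps[i]
        n_regions[i] = len(region_presence(m, atlas, threshold_k, min_fraction))
        try:
            mask = zscore_threshold_mask(m, k=threshold_k, component_id=i)
            n_objects[i] = count_objects(mask.weights > 0, connectivity)
        except ValueError:  # empty / constant map
            n_objects[i] = 0
        many_regions = n_regions[i] > max_regions
        many_objects = n_objects[i] > max_objects
        hit = (many_regions or many_objects) if rule == "or" \
            else (many_regions and many_objects)
        if hit:
            flags.append("movement" if many_regions else "noise")
        else:
            flags.append("activity")
    if manual:
        for idx, label in manual.items():
            flags[idx] = f"manual:{label}"
    return ComponentSet(maps=cs.maps, traces=cs.traces, frame_rate_hz=cs.frame_rate_hz,
                        sign_fixed=cs.sign_fixed, region_label=list(cs.region_label),
                        artifact=flags, n_regions_present=n_regions,
                        n_objects=n_objects, converged=cs.converged)
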