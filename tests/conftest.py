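"""Shared fixtures: small seeded phantoms reused across test modules."""

import numpy as np
import pytest

from lfmbrain import lightfield, synthgen


@pytest.fixture(scope="session")
def small_atlas():
    return synthgen.make_atlas((32, 16, 8), n_regions=4, seed=11)


@pytest.fixture(scope="session")
def small_truth(small_atlas):
    return synthgen.make_ground_truth(small_atlas, n_sources=4, probe="gcamp6f",
                                      duration_s=20.0, frame_rate_hz=25.0, seed=12)


@pytest.fixture(scope="session")
def small_movie(small_truth):
    return synthgen.render_movie(small_truth, baseline=100.0, seed=13)


@pytest.fixture(scope="session")
def desk_psf():
    """Desk-scale PSF library: 9 layers, lenslet pitch 4, 24x24 sensor."""
    return lightfield.build_psf_library(n_layers=9, layer_spacing_um=6.0,
                                        focal_width_um=4.0, widening_rate=0.05,
                                        voxel_size_um=(3.0, 3.0, 6.0))


def match_sources(true_maps, true_traces, cs):
    """Hungarian matching of extracted components to ground-truth sources.

    Returns (map |cosine|, trace |Pearson r|) per true source, using the
    assignment maximizing total map cosine similarity.
    """
    from scipy.optimize import linear_sum_assignment

    M = np.stack([np.ravel(m) for m in true_maps]).astype(float)
    C = np.stack([np.ravel(m) for m in cs.maps])
    Mn = M / np.linalg.norm(M, axis=1, keepdims=True)
    Cn = C / np.linalg.norm(C, axis=1, keepdims=True)
    cos = Mn @ Cn.T
    rows, cols = linear_sum_assignment(-np.abs(cos))
    cosines = np.abs(cos[rows, cols])
    rs = np.empty(len(rows))
    for k, (i, j) in enumerate(zip(rows, cols)):
        t = np.asarray(true_traces)[i]
        if np.ptp(t) == 0 or np.ptp(cs.traces[j]) == 0:
            rs[k] = 0.0
        else:
            rs[k] = abs(np.corrcoef(t, cs.traces[j])[0, 1])
    return cosines, rs
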