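"""Source extraction: variance normalization, SVD, shoulder detection,
ICA unmixing, sign convention, ROI masks."""

import numpy as np
import pytest
from scipy.stats import norm

from lfmbrain import sources
from lfmbrain.datatypes import RoiMask, SingularSpectrum, VolumeSeries


def _vs(data, rate=25.0):
    return VolumeSeries(np.asarray(data, dtype=float), (3.0, 3.0, 6.0), rate)


def shoulder_oracle(values):
    """Independent exhaustive scan: normalize both axes to [0,1], compute
    every centered slope in a plain loop, return the first index where the
    slope sits on the other side of -1 from its predecessor (or hits -1)."""
    y = [float(np.log(v)) for v in values]
    lo, hi = min(y), max(y)
    if hi == lo:
        raise ValueError("flat")
    y = [(v - lo) / (hi - lo) for v in y]
    n = len(y)
    dx = 1.0 / (n - 1)
    slopes = []
    for i in range(1, n - 1):
        slopes.append((y[i + 1] - y[i - 1]) / (2 * dx))
    if slopes[0] == -1.0:
        return 1
    for j in range(1, len(slopes)):
        a, b = slopes[j - 1] + 1.0, slopes[j] + 1.0
        if b == 0.0 or a * b < 0:
            return j + 1
    raise ValueError("no crossing")


class TestVarianceNormalize:
    def test_iid_noise_unit_variance(self):
        rng = np.random.default_rng(0)
        vs = _vs(rng.standard_normal((8, 8, 4, 400)))
        out, var = sources.variance_normalize(vs, n_presvd=0)
        v = out.as_matrix().var(axis=1)
        assert np.all(np.abs(v - 1.0) < 0.1 * 1.0 + 0.35)  # sample scatter
        assert abs(np.median(v) - 1.0) < 0.1

    def test_constant_voxel_floored_and_flagged(self):
        rng = np.random.default_rng(1)
        data = rng.standard_normal((4, 4, 2, 100))
        data[0, 0, 0, :] = 5.0
        with pytest.warns(UserWarning, match="floored"):
            out, var = sources.variance_normalize(_vs(data), n_presvd=0)
        assert np.all(np.isfinite(out.data))

    def test_presvd_removes_signal_from_variance_map(self):
        """Rank-1 phantom: after subtracting 1 SVD term the variance map
        estimates the noise floor, not the signal."""
        rng = np.random.default_rng(2)
        u = np.abs(rng.random(128)) + 0.5
        v = np.sin(np.arange(300) / 5.0) * 10.0
        noise_sd = 0.5
        data = (np.outer(u, v) + rng.normal(0, noise_sd, (128, 300)))
        vs = _vs(data.reshape(8, 4, 4, 300))
        _, var0 = sources.variance_normalize(vs, n_presvd=0)
        _, var1 = sources.variance_normalize(vs, n_presvd=1)
        assert np.median(var0) > 10 * noise_sd**2
        assert np.median(var1) == pytest.approx(noise_sd**2, rel=0.25)

    def test_all_constant_rejected(self):
        with pytest.raises(ValueError):
            sources.variance_normalize(_vs(np.ones((4, 4, 2, 50))), n_presvd=0)


class TestPca:
    def test_rank2_movie_third_value_vanishes(self):
        rng = np.random.default_rng(3)
        a = np.outer(rng.random(64), rng.standard_normal(100))
        b = np.outer(rng.random(64), rng.standard_normal(100))
        spec = sources.pca(_vs((a + b).reshape(4, 4, 4, 100)))
        assert spec.values[2] / spec.values[0] < 1e-8

    def test_values_non_increasing_random(self):
        rng = np.random.default_rng(4)
        spec = sources.pca(_vs(rng.random((4, 4, 4, 50))))
        assert np.all(np.diff(spec.values) <= 1e-12)

    def test_matches_constructed_svd_oracle(self):
        """3x3 matrix built from known orthonormal factors: the SVD is known
        by construction, independent of the decomposition under test."""
        theta = 0.3
        u = np.array([[np.cos(theta), -np.sin(theta), 0],
                      [np.sin(theta), np.cos(theta), 0],
                      [0, 0, 1.0]])
        phi = 1.1
        v = np.array([[1.0, 0, 0],
                      [0, np.cos(phi), -np.sin(phi)],
                      [0, np.sin(phi), np.cos(phi)]])
        s_true = np.array([5.0, 2.0, 0.5])
        mat = u @ np.diag(s_true) @ v.T
        spec = sources.pca(_vs(mat.reshape(3, 1, 1, 3), rate=1.0))
        assert np.allclose(spec.values, s_true, atol=1e-10)
        for i in range(3):
            assert abs(abs(spec.spatial_modes[:, i] @ u[:, i]) - 1) < 1e-10
            assert abs(abs(spec.temporal_modes[:, i] @ v[:, i]) - 1) < 1e-10

    def test_reconstruction_from_all_modes(self):
        rng = np.random.default_rng(5)
        vs = _vs(rng.random((4, 4, 2, 30)))
        spec = sources.pca(vs)
        recon = (spec.spatial_modes * spec.values) @ spec.temporal_modes.T
        assert np.allclose(recon, vs.as_matrix(), rtol=0, atol=1e-6 * spec.values[0])

    def test_nonfinite_rejected(self):
        data = np.ones((2, 2, 2, 5))
        data[0, 0, 0, 0] = np.nan
        vs = VolumeSeries.__new__(VolumeSeries)  # bypass constructor check
        vs.data = data
        vs.voxel_size_um = (1, 1, 1)
        vs.frame_rate_hz = 1.0
        vs.probe = "gcamp6f"
        vs.provenance = []
        with pytest.raises(ValueError):
            sources.pca(vs)


class TestDetectShoulder:
    def test_flat_spectrum_no_shoulder(self):
        with pytest.raises(ValueError, match="shoulder"):
            sources.detect_shoulder(np.full(10, 3.0))

    def test_piecewise_loglinear_join_at_20(self):
        """Normalized slopes -0.2 then -3 joined at index 20: with n=29,
        0.2*20 + 3*8 = 28 = n-1 so the normalized range is exactly [0,1]."""
        n = 29
        dx = 1.0 / (n - 1)
        y = [1.0]
        for i in range(1, n):
            y.append(y[-1] - (0.2 if i <= 20 else 3.0) * dx)
        assert abs(y[-1]) < 1e-12
        values = np.exp(np.array(y) * 7.0)  # arbitrary positive scale
        assert sources.detect_shoulder(values) == 20

    def test_matches_exhaustive_oracle_on_random_spectra(self):
        """100 seeded random decaying spectra: detector equals the
        brute-force scan, or both report no crossing."""
        rng = np.random.default_rng(42)
        checked = 0
        for _ in range(100):
            n = int(rng.integers(20, 200))
            # steep signal decay into a slowly decaying noise floor
            k = int(rng.integers(3, 12))
            sig = np.exp(-np.arange(k) * rng.uniform(0.5, 2.0))
            noise = sig[-1] * np.exp(-rng.uniform(1e-3, 0.02) * np.arange(n - k)
                                     - rng.uniform(0.3, 1.0))
            values = np.concatenate([sig, noise])
            values *= np.exp(rng.normal(0, 0.01, len(values)))  # jitter
            values = np.sort(values)[::-1]
            try:
                expected = shoulder_oracle(values)
            except ValueError:
                with pytest.raises(ValueError):
                    sources.detect_shoulder(values)
                continue
            assert sources.detect_shoulder(values) == expected
            checked += 1
        assert checked >= 80


class TestChooseN:
    @pytest.mark.parametrize("shoulder,rank,expected",
                             [(30, None, 60), (30, 45, 45), (1, None, 2)])
    def test_twice_shoulder_clamped(self, shoulder, rank, expected):
        assert sources.choose_n_components(shoulder, rank) == expected

    def test_zero_shoulder_rejected(self):
        with pytest.raises(ValueError):
            sources.choose_n_components(0)


class TestRunIca:
    def _mixture(self, seed=7, n_src=4, nvox=512, nt=300):
        """Disjoint sparse maps x independent traces + weak noise."""
        rng = np.random.default_rng(seed)
        maps = np.zeros((n_src, nvox))
        block = nvox // n_src
        for i in range(n_src):
            sl = slice(i * block + 5, i * block + 40)
            maps[i, sl] = rng.random(35) + 0.5
        traces = rng.laplace(size=(n_src, nt))
        data = maps.T @ traces + rng.normal(0, 0.01, (nvox, nt))
        return maps, traces, _vs(data.reshape(8, 8, 8, nt))

    def test_recovers_disjoint_sources(self):
        from scipy.optimize import linear_sum_assignment

        maps, traces, vs = self._mixture()
        spec = sources.pca(vs)
        cs = sources.run_ica(spec, n=4, seed=0)
        got = cs.maps.reshape(4, -1)
        cos = np.abs((maps / np.linalg.norm(maps, axis=1, keepdims=True))
                     @ (got / np.linalg.norm(got, axis=1, keepdims=True)).T)
        r, c = linear_sum_assignment(-cos)
        assert np.all(cos[r, c] > 0.95)

    def test_same_seed_identical(self):
        _, _, vs = self._mixture(seed=8)
        spec = sources.pca(vs)
        a = sources.run_ica(spec, n=4, seed=3)
        b = sources.run_ica(spec, n=4, seed=3)
        assert np.array_equal(a.maps, b.maps)
        assert np.array_equal(a.traces, b.traces)

    def test_single_component_spans_dominant_mode(self):
        rng = np.random.default_rng(9)
        data = np.outer(rng.random(64), rng.standard_normal(80))
        vs = _vs(data.reshape(4, 4, 4, 80))
        spec = sources.pca(vs)
        cs = sources.run_ica(spec, n=1, seed=0)
        m = cs.maps.reshape(-1)
        u1 = spec.spatial_modes[:, 0]
        assert abs(np.corrcoef(m, u1)[0, 1]) > 0.99

    def test_unmixing_reconstructs_truncation(self):
        _, _, vs = self._mixture(seed=10)
        spec = sources.pca(vs)
        n = 4
        cs = sources.run_ica(spec, n=n, seed=0)
        recon = cs.maps.reshape(n, -1).T @ cs.traces
        trunc = (spec.spatial_modes[:, :n] * spec.values[:n]) @ spec.temporal_modes[:, :n].T
        assert np.allclose(recon, trunc, atol=1e-6 * spec.values[0])

    def test_n_out_of_range(self):
        _, _, vs = self._mixture(seed=11)
        spec = sources.pca(vs)
        with pytest.raises(ValueError):
            sources.run_ica(spec, n=0)
        with pytest.raises(ValueError):
            sources.run_ica(spec, n=spec.rank + 1)


class TestFixSigns:
    def _cs(self, map3d, trace):
        from lfmbrain.datatypes import ComponentSet
        return ComponentSet(maps=map3d[None], traces=trace[None], frame_rate_hz=1.0)

    def test_positive_dominant_unchanged(self):
        m = np.zeros((4, 4, 2))
        m[0, 0, 0], m[1, 0, 0] = 0.8, -0.2
        cs = self._cs(m, np.arange(5.0))
        out = sources.fix_signs(cs)
        assert np.array_equal(out.maps[0], m)
        assert out.sign_fixed

    def test_negation_flips_back(self):
        m = np.zeros((4, 4, 2))
        m[0, 0, 0], m[1, 0, 0] = 0.8, -0.2
        tr = np.arange(5.0)
        out = sources.fix_signs(self._cs(-m, tr))
        assert np.array_equal(out.maps[0], m)
        assert np.array_equal(out.traces[0], -tr)

    def test_idempotent(self):
        rng = np.random.default_rng(12)
        m = rng.standard_normal((4, 4, 2))
        cs = self._cs(m, rng.standard_normal(6))
        once = sources.fix_signs(cs)
        twice = sources.fix_signs(once)
        assert np.array_equal(once.maps, twice.maps)
        assert np.array_equal(once.traces, twice.traces)


class TestZscoreMaskAndRoi:
    def test_single_hot_voxel_survives_alone(self):
        m = np.zeros((5, 5, 4))
        m[2, 2, 2] = 10.0
        sd = np.sqrt(np.mean(m**2))  # oracle: SD about zero of this map
        assert 10.0 > 3 * sd
        mask = sources.zscore_threshold_mask(m, k=3.0)
        assert mask.weights[2, 2, 2] == 10.0
        assert mask.weights.sum() == 10.0

    def test_gaussian_tail_fraction(self):
        """iid standard normal, k=3: surviving fraction ~ P(X>3) = 0.00135."""
        rng = np.random.default_rng(13)
        m = rng.standard_normal((40, 40, 40))
        mask = sources.zscore_threshold_mask(m, k=3.0)
        frac = (mask.weights > 0).mean()
        p = norm.sf(3.0)
        tol = 4 * np.sqrt(p * (1 - p) / m.size)  # binomial 4-sigma
        assert abs(frac - p) < tol

    def test_k0_keeps_positive_part(self):
        rng = np.random.default_rng(14)
        m = rng.standard_normal((6, 6, 3))
        mask = sources.zscore_threshold_mask(m, k=0.0)
        assert np.array_equal(mask.weights, np.clip(m, 0, None))

    def test_zero_sd_rejected(self):
        with pytest.raises(ValueError):
            sources.zscore_threshold_mask(np.zeros((4, 4, 2)))

    def test_roi_uniform_weights_is_plain_mean(self):
        rng = np.random.default_rng(15)
        vs = _vs(rng.random((3, 3, 2, 20)))
        mask = RoiMask(np.ones((3, 3, 2)), 0, 0.0)
        ts = sources.roi_timeseries(vs, mask)
        assert np.allclose(ts, vs.as_matrix().mean(axis=0))

    def test_roi_single_voxel_exact(self):
        rng = np.random.default_rng(16)
        vs = _vs(rng.random((3, 3, 2, 20)))
        w = np.zeros((3, 3, 2))
        w[1, 2, 0] = 1.0
        ts = sources.roi_timeseries(vs, RoiMask(w, 0, 0.0))
        assert np.array_equal(ts, vs.data[1, 2, 0, :])

    def test_roi_weighted_mean_hand_computed(self):
        data = np.zeros((2, 1, 1, 3))
        data[0, 0, 0] = [1.0, 2.0, 3.0]
        data[1, 0, 0] = [5.0, 6.0, 7.0]
        w = np.array([[[1.0]], [[3.0]]])
        ts = sources.roi_timeseries(_vs(data), RoiMask(w, 0, 0.0))
        assert np.allclose(ts, [(1 + 15) / 4, (2 + 18) / 4, (3 + 21) / 4])

    def test_roi_dim_mismatch(self):
        vs = _vs(np.ones((3, 3, 2, 5)))
        with pytest.raises(ValueError):
            sources.roi_timeseries(vs, RoiMask(np.ones((2, 2, 2)), 0, 0.0))
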