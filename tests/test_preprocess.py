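"""Preprocessing contracts: motion correction, detrending, denoising,
dF/F, alignment, concatenation, z-slab reduction."""

import numpy as np
import pytest

from lfmbrain import preprocess, synthgen
from lfmbrain.datatypes import BehaviorTrace, VolumeSeries


def _vs(data, rate=25.0, probe="gcamp6f"):
    return VolumeSeries(np.asarray(data, dtype=float), (3.0, 3.0, 6.0), rate, probe)


class TestMotionCorrect:
    def test_aligned_movie_zero_shifts(self, small_movie):
        _, motion = preprocess.motion_correct(small_movie, reference="mean")
        assert np.all(np.abs(motion.translation) <= 0.25)

    def test_recovers_imposed_shifts(self, small_truth):
        """Ground-truth shifts up to +-2 voxels recovered within 0.5 voxel RMS."""
        amp = 2.0
        vs = synthgen.render_movie(small_truth, baseline=100.0,
                                   motion_amp_voxels=amp,
                                   noise={"gaussian_sd": 1.0}, seed=21)
        _, motion = preprocess.motion_correct(vs, reference="first")
        truth_shifts = synthgen.applied_shifts(small_truth, amp)
        err = motion.translation - truth_shifts
        rms = np.sqrt(np.mean(np.sum(err**2, axis=1)))
        assert rms < 0.5

    def test_reduces_residual_displacement(self, small_truth):
        """Estimated motion removes >= 75% of the imposed RMS displacement."""
        amp = 2.0
        vs = synthgen.render_movie(small_truth, baseline=100.0,
                                   motion_amp_voxels=amp,
                                   noise={"gaussian_sd": 1.0}, seed=21)
        _, motion = preprocess.motion_correct(vs, reference="first")
        truth_shifts = synthgen.applied_shifts(small_truth, amp)
        before = np.sqrt(np.mean(np.sum(truth_shifts**2, axis=1)))
        after = np.sqrt(np.mean(np.sum((truth_shifts - motion.translation) ** 2, axis=1)))
        assert after <= 0.25 * before

    def test_pure_noise_warns_but_finite(self):
        rng = np.random.default_rng(0)
        vs = _vs(rng.random((8, 8, 4, 5)))
        out, motion = preprocess.motion_correct(vs)
        assert np.all(np.isfinite(out.data))

    def test_constant_movie_warns_zero_shift(self):
        vs = _vs(np.ones((8, 8, 4, 5)))
        with pytest.warns(UserWarning):
            _, motion = preprocess.motion_correct(vs)
        assert np.all(motion.translation == 0)


class TestInvertSign:
    def test_negates(self):
        vs = _vs(np.full((4, 4, 2, 3), 5.0), probe="arclight")
        assert np.all(preprocess.invert_sign(vs).data == -5.0)

    def test_involution_bit_exact(self):
        rng = np.random.default_rng(1)
        vs = _vs(rng.random((4, 4, 2, 3)), probe="arclight")
        twice = preprocess.invert_sign(preprocess.invert_sign(vs))
        assert np.array_equal(twice.data, vs.data)

    def test_guard_on_calcium_probe(self):
        vs = _vs(np.ones((4, 4, 2, 3)), probe="gcamp6f")
        with pytest.raises(ValueError):
            preprocess.invert_sign(vs)
        preprocess.invert_sign(vs, force=True)  # override allowed


class TestDetrend:
    def test_constant_movie_to_zero(self):
        out = preprocess.detrend(_vs(np.full((4, 4, 2, 100), 7.0)), window_s=1.0)
        assert np.allclose(out.data, 0.0)

    def test_linear_ramp_interior_exact_zero(self):
        nt = 100
        ramp = np.tile(np.arange(nt, dtype=float), (4, 4, 2, 1))
        win = 25  # odd window: symmetric box average of a line equals the line
        out = preprocess.detrend(_vs(ramp, rate=1.0), window_s=float(win))
        h = win // 2
        assert np.allclose(out.data[..., h:nt - h], 0.0, atol=1e-9)

    def test_removes_13pct_bleach_trend(self):
        """Least-squares slope oracle: residual trend reduced > 90%."""
        rate, dur = 25.0, 60.0
        t = np.arange(int(rate * dur)) / rate
        tau = -30.0 / np.log(1 - 0.13)
        trace = 100.0 * np.exp(-t / tau)
        movie = np.tile(trace, (4, 4, 2, 1))
        out = preprocess.detrend(_vs(movie, rate=rate), window_s=20.0)

        def ls_slope(y):
            return np.polyfit(t, y, 1)[0]

        before = abs(ls_slope(movie[0, 0, 0]))
        after = abs(ls_slope(out.data[0, 0, 0]))
        assert after < 0.1 * before

    def test_window_longer_than_recording_rejected(self):
        with pytest.raises(ValueError):
            preprocess.detrend(_vs(np.ones((2, 2, 2, 10))), window_s=100.0)


class TestKalman:
    def test_gain_one_identity(self, small_movie):
        out = preprocess.kalman_denoise(small_movie, gain=1.0)
        assert np.array_equal(out.data, small_movie.data)

    def test_constant_trace_unchanged(self):
        vs = _vs(np.full((2, 2, 2, 20), 3.5))
        out = preprocess.kalman_denoise(vs, gain=0.3)
        assert np.allclose(out.data, 3.5)

    def test_unit_step_matches_hand_recursion(self):
        """est_t = (1-g) est_{t-1} + g obs_t from obs (0,0,0,1,1,1,...)."""
        obs = np.zeros(8)
        obs[3:] = 1.0
        vs = _vs(obs.reshape(1, 1, 1, 8))
        out = preprocess.kalman_denoise(vs, gain=0.5)
        expected = [0.0, 0.0, 0.0, 0.5, 0.75, 0.875, 0.9375, 0.96875]
        assert np.allclose(out.data[0, 0, 0], expected, atol=1e-12)

    @pytest.mark.parametrize("gain", [0.0, -0.2, 1.5])
    def test_bad_gain_rejected(self, gain):
        with pytest.raises(ValueError):
            preprocess.kalman_denoise(_vs(np.ones((2, 2, 2, 5))), gain=gain)


class TestSvdMotionRemoval:
    def test_empty_set_is_identity(self, small_movie):
        out, removed = preprocess.svd_motion_removal(small_movie, component_indices=[])
        assert np.array_equal(out.data, small_movie.data)
        assert removed == []

    def test_rank1_contaminant_removed_orthogonal(self):
        rng = np.random.default_rng(3)
        u = rng.random(64)
        v = rng.standard_normal(200)
        clean = rng.normal(0, 0.01, size=(64, 200))
        data = (clean + np.outer(u, v)).reshape(4, 4, 4, 200)
        vs = _vs(data)
        out, _ = preprocess.svd_motion_removal(vs, component_indices=[0])
        # oracle: numpy SVD of the same centered matrix gives the removed
        # temporal vector (unique up to sign for a dominant sigma_1)
        mat = data.reshape(64, 200)
        centered = mat - mat.mean(axis=1, keepdims=True)
        v1 = np.linalg.svd(centered, full_matrices=False)[2][0]
        resid = out.data.reshape(64, 200) - mat.mean(axis=1, keepdims=True)
        inner = np.abs(resid @ v1) / (np.linalg.norm(resid, axis=1) * np.linalg.norm(v1) + 1e-30)
        assert np.all(inner < 1e-8)

    def test_variance_never_increases(self, small_movie):
        out, _ = preprocess.svd_motion_removal(small_movie, component_indices=[0, 1])
        def tvar(vs):
            m = vs.as_matrix().astype(float)
            return ((m - m.mean(1, keepdims=True)) ** 2).sum()
        assert tvar(out) <= tvar(small_movie) * (1 + 1e-12)


class TestDff:
    def test_constant_movie_zero(self):
        out = preprocess.dff(_vs(np.full((2, 2, 2, 10), 4.0)))
        assert np.allclose(out.data, 0.0)

    def test_doubling_gives_one(self):
        data = np.full((1, 1, 1, 4), 10.0)
        data[0, 0, 0, 2] = 20.0
        out = preprocess.dff(_vs(data), baseline="percentile", percentile=10)
        assert out.data[0, 0, 0, 2] == pytest.approx(1.0, abs=1e-6)

    def test_known_amplitude_recovered(self, small_atlas):
        truth = synthgen.make_ground_truth(small_atlas, 1, "gcamp6f", 10.0, 25.0,
                                           seed=6, coupling=["spontaneous"],
                                           event_rate_hz=0.0, bleach_fraction_30s=0.0,
                                           structured_baseline=False)
        truth.source_traces[0, :] = 0.0
        truth.source_traces[0, 100] = 30.0  # single impulse over baseline 100
        vs = synthgen.render_movie(truth, baseline=100.0, noise={"gaussian_sd": 0.0},
                                   seed=0)
        out = preprocess.dff(vs, baseline="percentile", percentile=10)
        peak_vox = np.unravel_index(np.argmax(truth.source_maps[0]),
                                    truth.source_maps[0].shape)
        expected = 30.0 * truth.source_maps[0][peak_vox] / 100.0
        assert out.data[peak_vox][100] == pytest.approx(expected, rel=0.01)

    def test_nonpositive_baseline_masked(self):
        data = np.zeros((2, 1, 1, 5))
        data[1] = 10.0
        with pytest.warns(UserWarning):
            out = preprocess.dff(_vs(data))
        assert np.all(out.data[0] == 0)


class TestHighpass:
    def test_dc_removed(self):
        out = preprocess.highpass(_vs(np.full((2, 2, 2, 400), 3.0), rate=200.0))
        assert np.allclose(out.data, 0.0)

    def test_box_filter_frequency_response(self):
        """FFT oracle: 1 Hz attenuated > 95%, 40 Hz < 30% at 200 Hz rate."""
        rate, nt = 200.0, 2000
        t = np.arange(nt) / rate

        def attenuation(freq):
            sig = np.sin(2 * np.pi * freq * t)
            vs = _vs(sig.reshape(1, 1, 1, nt), rate=rate)
            out = preprocess.highpass(vs, window_s=0.1).data[0, 0, 0]
            spec_in = np.abs(np.fft.rfft(sig))
            spec_out = np.abs(np.fft.rfft(out))
            k = int(round(freq * nt / rate))
            return 1.0 - spec_out[k] / spec_in[k]

        assert attenuation(1.0) > 0.95
        assert attenuation(40.0) < 0.30

    def test_100ms_window_is_20_frames_at_200hz(self):
        assert int(round(0.1 * 200.0)) == 20
        vs = _vs(np.random.default_rng(0).random((2, 2, 2, 100)), rate=200.0)
        out = preprocess.highpass(vs, window_s=0.1)
        assert "highpass(window_s=0.1)" in out.provenance[-1]

    def test_rate_too_low_rejected(self):
        with pytest.raises(ValueError):
            preprocess.highpass(_vs(np.ones((2, 2, 2, 50)), rate=5.0), window_s=0.1)


class TestAlignBehavior:
    def _behavior(self, n, rate):
        state = np.array(["rest", "walk"] * (n // 2) + ["rest"] * (n % 2))
        flow = np.zeros(n)
        return BehaviorTrace(rate, state[:n], flow, flow.copy())

    def test_equal_rates_zero_drift_identity(self):
        b = self._behavior(50, 25.0)
        out = preprocess.align_behavior(b, 50, 25.0, drift_ms_per_min=0.0)
        assert np.array_equal(out.state, b.state)
        assert np.allclose(out.flow_left, b.flow_left)

    def test_drift_maps_last_sample_earlier(self):
        """Closed-form time-warp oracle: 30 ms/min over 60 s -> the behavior
        clock's t=60 s lands at 59.97 s."""
        rate = 100.0
        n = 6001  # 60 s inclusive
        b = BehaviorTrace(rate, np.array(["rest"] * n), np.arange(n, dtype=float),
                          np.zeros(n))
        out = preprocess.align_behavior(b, n, rate, drift_ms_per_min=30.0)
        # fluor time 59.97 s should retrieve the behavior sample from t=60 s
        warped_last = 60.0 * (1 - 30.0 / 60000.0)
        j = int(round(warped_last * rate))
        expected = np.interp(j / rate, np.arange(n) / rate * (1 - 30.0 / 60000.0),
                             b.flow_left)
        assert out.flow_left[j] == pytest.approx(expected, abs=1e-9)
        assert out.flow_left[j] == pytest.approx(6000.0, abs=1.0)

    def test_upsampling_duplicates_states(self):
        b = self._behavior(10, 100.0)
        out = preprocess.align_behavior(b, 20, 200.0, drift_ms_per_min=0.0)
        # each behavior sample lands on two consecutive fluorescence frames
        assert np.array_equal(out.state[::2], b.state)
        assert np.array_equal(out.state[1::2], b.state)

    def test_implausible_drift_rejected(self):
        b = self._behavior(10, 10.0)
        with pytest.raises(ValueError):
            preprocess.align_behavior(b, 10, 10.0, drift_ms_per_min=-7000.0)


class TestConcatAndZslab:
    def test_concat_single_identity(self, small_movie):
        out = preprocess.concat([small_movie])
        assert np.array_equal(out.data, small_movie.data)

    def test_concat_boundary_recorded(self):
        a = _vs(np.ones((2, 2, 2, 10)))
        b = _vs(np.zeros((2, 2, 2, 10)))
        out = preprocess.concat([a, b])
        assert out.n_frames == 20
        assert "boundaries=[10]" in out.provenance[-1]

    def test_concat_mismatch_names_field(self):
        a = _vs(np.ones((2, 2, 2, 10)))
        b = VolumeSeries(np.ones((2, 2, 2, 10)), (1.0, 1.0, 1.0), 25.0, "gcamp6f")
        with pytest.raises(ValueError, match="voxel size"):
            preprocess.concat([a, b])

    def test_zslab_uniform_profile_identity(self):
        rng = np.random.default_rng(0)
        vs = _vs(rng.random((4, 4, 6, 5)))
        out = preprocess.zslab_reduce(vs, lambda d: 6.0, focal_index=0)
        assert np.allclose(out.data, vs.data)

    def test_zslab_preserves_global_mean(self):
        rng = np.random.default_rng(1)
        vs = _vs(rng.random((4, 4, 8, 5)))
        out = preprocess.zslab_reduce(vs, lambda d: 12.0, focal_index=0)
        assert out.data.shape[2] == 4
        assert out.data.mean() == pytest.approx(vs.data.mean(), abs=1e-12)

    def test_zslab_greedy_partition_matches_hand_oracle(self):
        """Profile (6,6,12,12,24,...) um on 6-um layers -> sizes (1,1,2,2,4...)."""
        def profile(d):
            if d < 12:
                return 6.0
            if d < 36:
                return 12.0
            return 24.0

        slabs = preprocess.zslab_partition(12, 6.0, profile, focal_index=0)
        sizes = [b - a for a, b in slabs]
        assert sizes == [1, 1, 2, 2, 4, 2]  # greedy from the focal plane out

    def test_full_chain_deterministic(self, small_movie):
        def chain(vs):
            vs, _ = preprocess.motion_correct(vs)
            vs = preprocess.detrend(vs, 10.0)
            return preprocess.kalman_denoise(vs, 0.5)

        a = chain(small_movie)
        b = chain(small_movie)
        assert np.array_equal(a.data, b.data)

    def test_detrend_idempotent_on_smooth_input(self):
        rate, nt = 25.0, 500
        t = np.arange(nt) / rate
        sig = np.exp(-t / 40.0) * 100.0
        vs = _vs(np.tile(sig, (2, 2, 2, 1)), rate=rate)
        once = preprocess.detrend(vs, window_s=8.0)
        twice = preprocess.detrend(once, window_s=8.0)
        slope1 = abs(np.polyfit(t, once.data[0, 0, 0], 1)[0])
        slope2 = abs(np.polyfit(t, twice.data[0, 0, 0], 1)[0])
        assert slope2 <= slope1 + 1e-9
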