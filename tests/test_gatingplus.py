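import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from petgate import gatingplus
from petgate.errors import ParameterError
from petgate.experiments import random_companion


def as4d(values):
    return np.asarray(values, dtype=float).reshape(1, 1, 1, -1)


class TestSpectrumAndNoise:
    def test_dc_coefficient_is_the_gate_mean(self, rng):
        v = rng.uniform(0, 10, (3, 3, 2, 16))
        c = gatingplus.voxel_spectrum(v)
        assert np.allclose(c[..., 0].real, v.mean(axis=-1))
        assert np.allclose(gatingplus.inverse_spectrum(c, 16), v, atol=1e-12)

    def test_constant_series_has_zero_effective_noise(self):
        c = gatingplus.voxel_spectrum(np.array([5.0, 5, 5, 5]))
        assert gatingplus.effective_noise(c) == 0.0

    def test_alternating_series_noise_is_the_nyquist_amplitude(self):
        c = gatingplus.voxel_spectrum(np.array([6.0, 4, 6, 4]))
        assert gatingplus.effective_noise(c) == pytest.approx(1.0)

    def test_noise_is_invariant_to_a_dc_shift(self, rng):
        v = rng.uniform(0, 5, 16)
        n0 = gatingplus.effective_noise(gatingplus.voxel_spectrum(v))
        n1 = gatingplus.effective_noise(gatingplus.voxel_spectrum(v + 100.0))
        assert n0 == pytest.approx(n1, abs=1e-12)


class TestCutoffIndex:
    def test_contiguous_run_of_passing_amplitudes(self):
        c = np.array([7.0, 5.0, 4.0, 1.0])  # |c_k| for k = 0..3
        assert gatingplus.cutoff_index(c, noise=2.0) == 2

    def test_run_is_anchored_at_the_fundamental(self):
        c = np.array([7.0, 1.0, 9.0, 9.0])
        assert gatingplus.cutoff_index(c, noise=2.0) == 0

    def test_zero_noise_passes_every_strictly_positive_run(self):
        c = np.array([7.0, 3.0, 2.0, 0.0])
        assert gatingplus.cutoff_index(c, noise=0.0) == 2


class TestApplyFilter:
    def test_hand_worked_example(self):
        gated = as4d([10.0, 6.0, 4.0, 6.0])
        # companion [6,4,6,4]: c_1 = 0, |c_2| = 1 -> effective noise 1
        res = gatingplus.apply_filter(gated, as4d([6.0, 4.0, 6.0, 4.0]))
        assert np.allclose(res.filtered.ravel(), [9.5, 6.5, 3.5, 6.5])
        assert res.motion_map.cutoff.ravel()[0] == 1
        assert res.filtered.sum() == pytest.approx(26.0)

    def test_overwhelming_noise_reduces_each_voxel_to_its_mean(self, rng):
        gated = rng.uniform(0, 10, (4, 4, 1, 16))
        random = gated + 1000.0 * rng.standard_normal(gated.shape)
        res = gatingplus.apply_filter(gated, random)
        means = gated.mean(axis=-1, keepdims=True)
        assert np.allclose(res.filtered, np.broadcast_to(means, gated.shape))
        assert res.motion_map.cutoff.max() == 0

    def test_zero_noise_with_nonzero_coefficients_is_identity(self):
        gated = as4d([10.0, 6.0, 4.0, 6.0])
        random = as4d([5.0, 5.0, 5.0, 5.0])
        res = gatingplus.apply_filter(gated, random)
        assert np.allclose(res.filtered, gated, atol=1e-12)

    def test_conservation_variance_and_idempotence(self, rng):
        gated = rng.poisson(20.0, (6, 5, 2, 16)).astype(float)
        random = random_companion(gated, rng)
        res = gatingplus.apply_filter(gated, random)
        # per-voxel gate sums conserved exactly
        assert np.allclose(res.filtered.sum(-1), gated.sum(-1), rtol=1e-9)
        # truncation can only remove spectral power (Parseval)
        assert np.all(
            res.filtered.var(-1) <= gated.var(-1) + 1e-9
        )
        # projection: filtering its own output changes nothing
        again = gatingplus.apply_filter(res.filtered, random)
        assert np.allclose(again.filtered, res.filtered, atol=1e-9)

    def test_negative_outputs_are_reported_not_clipped(self):
        # a strong fundamental over a small mean swings below zero
        gated = as4d([4.0, 3.0, 1.0, 0.0, 0.0, 0.0, 1.0, 3.0])
        random = as4d([2.0, 1.0, 2.0, 1.0, 2.0, 2.0, 1.0, 1.0])
        res = gatingplus.apply_filter(gated, random)
        assert res.filtered.min() < 0
        assert res.diagnostics["negative_value_fraction"] > 0
        assert res.diagnostics["total_negative_mass"] < 0
        assert res.filtered.sum() == pytest.approx(gated.sum())

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ParameterError):
            gatingplus.apply_filter(np.zeros((2, 2, 1, 8)), np.zeros((2, 2, 1, 4)))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.sampled_from([4, 8, 15, 16]))
    def test_conservation_holds_for_arbitrary_count_series(self, seed, n_gates):
        rng = np.random.default_rng(seed)
        gated = rng.poisson(rng.uniform(0.1, 30), (3, 3, 1, n_gates)).astype(float)
        random = random_companion(gated, rng)
        res = gatingplus.apply_filter(gated, random)
        assert np.allclose(res.filtered.sum(-1), gated.sum(-1), rtol=1e-9, atol=1e-9)
        assert np.all(res.filtered.var(-1) <= gated.var(-1) + 1e-9)


class TestNoMotionNull:
    def test_spurious_pass_fraction_is_bounded(self):
        """Static Poisson voxels against their own re-partition: fewer than
        25% of nonzero voxels pass any frequency (factor 1.2 against a
        max-of-all-frequencies noise estimate is conservative)."""
        rng = np.random.default_rng(6)
        fractions = []
        for _ in range(50):
            gated = rng.poisson(8.0, (10, 10, 1, 16)).astype(float)
            random = random_companion(gated, rng)
            res = gatingplus.apply_filter(gated, random)
            nonzero = gated.sum(-1) > 0
            fractions.append((res.motion_map.cutoff[nonzero] > 0).mean())
        assert np.mean(fractions) < 0.25


class TestCmiFrames:
    def test_single_harmonic_closed_form(self):
        coeffs = np.zeros((1, 1, 1, 3), dtype=complex)
        coeffs[..., 0] = 6.5
        coeffs[..., 1] = 1.5
        res = gatingplus.GatingPlusResult(
            filtered=gatingplus.inverse_spectrum(coeffs, 4),
            coeffs=coeffs,
            motion_map=gatingplus.MotionMap(np.array([[[1]]]), 4),
        )
        frames = gatingplus.cmi_frames(res, 8)
        assert frames[0, 0, 0, 1] == pytest.approx(6.5 + 3 * np.cos(np.pi / 4))

    def test_full_spectrum_frames_reproduce_the_gates(self, rng):
        gated = rng.uniform(0, 9, (2, 2, 1, 16))
        random = np.broadcast_to(gated.mean(-1, keepdims=True), gated.shape)
        res = gatingplus.apply_filter(gated, random.copy())
        frames = gatingplus.cmi_frames(res, 16)
        assert np.allclose(frames, res.filtered, atol=1e-9)

    def test_frame_mean_equals_dc(self, rng):
        gated = rng.poisson(15.0, (3, 3, 1, 16)).astype(float)
        res = gatingplus.apply_filter(gated, random_companion(gated, rng))
        frames = gatingplus.cmi_frames(res, 90)
        assert np.allclose(frames.mean(-1), gated.mean(-1), atol=1e-9)

    def test_gate_phase_evaluation_matches_filtered_gates(self, rng):
        gated = rng.poisson(25.0, (4, 3, 2, 16)).astype(float)
        res = gatingplus.apply_filter(gated, random_companion(gated, rng))
        phases = np.arange(16) / 16.0
        vals = gatingplus.evaluate_phases(res.coeffs, 16, phases)
        assert np.allclose(vals, res.filtered, atol=1e-9)

    def test_motion_map_cutoff_in_hz(self):
        mm = gatingplus.MotionMap(np.array([[[2]]]), 16)
        assert mm.cutoff_hz(1.0)[0, 0, 0] == pytest.approx(2.0)
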