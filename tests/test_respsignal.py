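import numpy as np
import pytest

from petgate import respsignal, simdata
from petgate.errors import ParameterError


def sinusoid_trace(n_bins=600, bin_ms=100.0, freq_hz=1.0, amp=20.0, base=100.0):
    t = (np.arange(n_bins) + 0.5) * bin_ms / 1000.0
    return base + amp * np.sin(2 * np.pi * freq_hz * t)


class TestBinShortTime:
    def test_floor_arithmetic(self, small_geom):
        stream = simdata.ListmodeStream(
            geometry=small_geom, duration_ms=300,
            t_ms=[0, 50, 99, 100, 250], rho=[0] * 5, theta=[0] * 5, z=[0] * 5,
            origin=[-1] * 5,
        )
        series = respsignal.bin_short_time(stream, 100)
        assert series.counts[0, 0, 0].tolist() == [3, 1, 1]

    def test_conservation_and_equivalence_of_fast_path(self, moving_stream):
        stream, _ = moving_stream
        series = respsignal.bin_short_time(stream, 100)
        assert series.counts.sum() == stream.n_events
        ids_a, traces_a = series.region_traces((4, 4, 1))
        ids_b, traces_b, _ = respsignal.region_traces_from_stream(stream, 100, (4, 4, 1))
        assert np.array_equal(traces_a, traces_b)
        assert np.array_equal(ids_a, ids_b)

    def test_empty_stream_gives_zero_series(self, small_geom):
        stream = simdata.ListmodeStream(
            geometry=small_geom, duration_ms=1000,
            t_ms=[], rho=[], theta=[], z=[], origin=[],
        )
        assert respsignal.bin_short_time(stream, 100).counts.sum() == 0

    def test_bin_longer_than_scan_rejected(self, small_geom):
        stream = simdata.ListmodeStream(
            geometry=small_geom, duration_ms=1000,
            t_ms=[], rho=[], theta=[], z=[], origin=[],
        )
        with pytest.raises(ParameterError):
            respsignal.bin_short_time(stream, 2000)


class TestScoreRegions:
    def test_pure_respiratory_sinusoid_ranks_first(self, rng):
        ids = np.zeros((3, 3), dtype=int)
        ids[1] = (1, 0, 0)
        ids[2] = (2, 0, 0)
        traces = np.stack([
            sinusoid_trace(),
            rng.poisson(100.0, 600).astype(float),
            np.full(600, 7.0),
        ])
        scored = respsignal.score_regions((ids, traces.astype(int)), bin_ms=100.0)
        assert scored[0].region_id == (0, 0, 0)
        assert scored[0].window_power_fraction > 0.95

    def test_constant_region_scores_zero(self):
        ids = np.array([[0, 0, 0]])
        traces = np.full((1, 600), 9)
        scored = respsignal.score_regions((ids, traces), bin_ms=100.0)
        assert scored[0].window_power_fraction == 0.0

    def test_zero_count_regions_excluded(self):
        ids = np.array([[0, 0, 0], [1, 0, 0]])
        traces = np.stack([np.zeros(600, int), np.ones(600, int)])
        scored = respsignal.score_regions((ids, traces), bin_ms=100.0)
        assert [r.region_id for r in scored] == [(1, 0, 0)]

    def test_white_noise_fraction_matches_bandwidth_ratio(self, rng):
        """Flat-spectrum oracle: fraction ~ window width / non-DC bandwidth."""
        n = 200
        ids = np.stack([np.arange(n), np.zeros(n, int), np.zeros(n, int)], axis=1)
        traces = rng.poisson(50.0, (n, 600))
        scored = respsignal.score_regions(
            (ids, traces), bin_ms=100.0, detrend_window_s=600.0
        )
        fractions = [r.window_power_fraction for r in scored]
        expected = (3.33 - 0.66) / 5.0
        assert np.mean(fractions) == pytest.approx(expected, abs=0.03)

    def test_window_above_nyquist_rejected(self):
        ids = np.array([[0, 0, 0]])
        traces = np.ones((1, 600), int)
        with pytest.raises(ParameterError):
            respsignal.score_regions((ids, traces), bin_ms=100.0, window_hz=(0.66, 6.0))


class TestPhaseConsistency:
    def test_identical_traces_agree_positively(self):
        x = sinusoid_trace()
        assert respsignal.phase_consistency(x, x) == 1

    def test_negated_trace_agrees_negatively(self):
        x = sinusoid_trace()
        assert respsignal.phase_consistency(-x + 200, x) == -1

    def test_zero_variance_segment_rejects(self):
        x = sinusoid_trace()
        flat = np.zeros_like(x)
        assert respsignal.phase_consistency(flat, x) is None

    def test_independent_noise_rejected_at_the_sign_agreement_rate(self, rng):
        """P(all 6 segment signs agree) = 2 * (1/2)^6 -> ~3.1% acceptance."""
        x = rng.normal(size=(2000, 600))
        ref = rng.normal(size=600)
        accepted = sum(
            respsignal.phase_consistency(row, ref) is not None for row in x
        )
        rate = accepted / 2000
        assert rate == pytest.approx(1 / 32, abs=0.012)


class TestBuildGlobalTrace:
    def test_two_identical_sinusoids_combine_coherently(self):
        ids = np.array([[0, 0, 0], [1, 0, 0]])
        x = sinusoid_trace()
        traces = np.stack([x, x]).astype(int)
        trace = respsignal.build_global_trace(
            (ids, traces), bin_ms=100.0, top_fraction=1.0
        )
        assert trace.n_regions_used == 2
        ref = x - x.mean()
        r = np.corrcoef(trace.values, ref)[0, 1]
        assert abs(r) > 0.99

    def test_simulated_scan_trace_tracks_the_true_phase(self, moving_stream):
        stream, waveform = moving_stream
        ids, traces, _ = respsignal.region_traces_from_stream(stream, 100.0)
        trace = respsignal.build_global_trace((ids, traces), bin_ms=100.0)
        truth = np.cos(2 * np.pi * waveform.phase(trace.times_s))
        r = np.corrcoef(trace.values, truth)[0, 1]
        assert abs(r) > 0.8

    def test_sign_flip_of_all_regions_leaves_magnitude_unchanged(self, moving_stream):
        stream, waveform = moving_stream
        ids, traces, _ = respsignal.region_traces_from_stream(stream, 100.0)
        # negate every region's fluctuation about its mean (totals preserved)
        flipped = 2 * traces.mean(axis=1, keepdims=True) - traces
        a = respsignal.build_global_trace((ids, traces), bin_ms=100.0)
        b = respsignal.build_global_trace((ids, flipped), bin_ms=100.0)
        truth = np.cos(2 * np.pi * waveform.phase(a.times_s))
        ra = np.corrcoef(a.values, truth)[0, 1]
        rb = np.corrcoef(b.values, truth)[0, 1]
        assert abs(ra) == pytest.approx(abs(rb), abs=1e-9)

    def test_determinism(self, moving_stream):
        stream, _ = moving_stream
        ids, traces, _ = respsignal.region_traces_from_stream(stream, 100.0)
        a = respsignal.build_global_trace((ids, traces), bin_ms=100.0)
        b = respsignal.build_global_trace((ids, traces), bin_ms=100.0)
        assert np.array_equal(a.values, b.values)

    def test_dominant_frequency_matches_breathing(self, moving_stream):
        """Spectral fidelity: trace peak within one bin of the true rate."""
        stream, waveform = moving_stream
        ids, traces, _ = respsignal.region_traces_from_stream(stream, 100.0)
        trace = respsignal.build_global_trace((ids, traces), bin_ms=100.0)
        x = trace.values - trace.values.mean()
        freqs = np.fft.rfftfreq(len(x), d=0.1)
        peak = freqs[1:][np.argmax(np.abs(np.fft.rfft(x))[1:])]
        f_true = 1.0 / waveform.periods.mean()
        assert abs(peak - f_true) <= freqs[1] + 1e-12
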