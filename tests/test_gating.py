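import numpy as np
import pytest
from scipy import stats

from petgate import gating, metrics, respsignal, simdata
from petgate.errors import ParameterError
from petgate.geometry import ScannerGeometry


def cosine_trace(period_s=1.2, duration_s=600.0, bin_ms=100.0, harmonic=None):
    t = (np.arange(int(duration_s * 1000 / bin_ms)) + 0.5) * bin_ms / 1000.0
    v = np.cos(2 * np.pi * t / period_s)
    if harmonic:
        k, amp = harmonic
        v = v + amp * np.cos(2 * np.pi * k * t / period_s)
    return respsignal.GlobalTrace(values=v, bin_ms=bin_ms)


class TestMostRepresentedPeriod:
    def test_uniform_intervals(self):
        assert gating.most_represented_period([1.2] * 5) == pytest.approx(1.2)

    def test_mode_wins(self):
        intervals = [1.1] * 5 + [1.3] * 2
        assert gating.most_represented_period(intervals) == pytest.approx(1.1)

    def test_tie_breaks_toward_shorter(self):
        intervals = [1.1] * 3 + [1.3] * 3
        assert gating.most_represented_period(intervals) == pytest.approx(1.1)

    def test_too_few_intervals_rejected(self):
        with pytest.raises(ParameterError):
            gating.most_represented_period([1.0, 1.0])


class TestDetectTriggers:
    def test_pure_cosine_recovers_every_cycle(self):
        trace = cosine_trace(1.2, 600.0)
        trig = gating.detect_triggers(trace)
        # 500 crests; the one at t = 0 sits on the edge and has no left
        # neighbor, so 499 or 500 depending on sampling alignment
        assert len(trig.times_ms) in (499, 500)
        assert trig.median_period_s == pytest.approx(1.2, abs=0.11)
        # peaks at multiples of 1.2 s, up to one 100 ms bin
        offsets = np.abs(trig.times_ms / 1000.0 - np.round(trig.times_ms / 1200.0) * 1.2)
        assert offsets.max() <= 0.101

    def test_secondary_peak_within_half_period_is_suppressed(self):
        """A 2.5 Hz harmonic creates extra maxima < half a period apart;
        only the higher peak of each conflicting pair survives."""
        trace = cosine_trace(1.2, 600.0, harmonic=(3, 0.5))
        trig = gating.detect_triggers(trace)
        assert len(trig.times_ms) == pytest.approx(500, abs=1)
        assert trig.most_represented_period_s == pytest.approx(1.2, abs=0.05)

    def test_simulated_scan_triggers_align_with_true_cycles(self, moving_stream):
        stream, waveform = moving_stream
        ids, traces, _ = respsignal.region_traces_from_stream(stream, 100.0)
        trace = respsignal.build_global_trace((ids, traces), bin_ms=100.0)
        trig = gating.detect_triggers(trace)
        agree = gating.trigger_phase_agreement(trig.times_ms, waveform.boundaries)
        assert agree >= 0.9

    def test_flat_trace_rejected(self):
        trace = respsignal.GlobalTrace(values=np.zeros(600), bin_ms=100.0)
        with pytest.raises(ParameterError):
            gating.detect_triggers(trace)


class TestInsertAndRandomTriggers:
    def test_insertion_preserves_events_and_merges_sorted(self, small_geom):
        stream = simdata.ListmodeStream(
            geometry=small_geom, duration_ms=1000,
            t_ms=[100, 400, 900], rho=[0] * 3, theta=[0] * 3, z=[0] * 3,
            origin=[-1] * 3,
        )
        trig = gating.TriggerSet(times_ms=np.array([250, 800]), kind="respiratory")
        out = gating.insert_triggers(stream, trig)
        assert out.n_events == 3
        assert out.triggers_of_kind("respiratory").tolist() == [250, 800]

    def test_empty_trigger_set_is_identity(self, small_geom):
        stream = simdata.ListmodeStream(
            geometry=small_geom, duration_ms=1000,
            t_ms=[100], rho=[0], theta=[0], z=[0], origin=[-1],
        )
        out = gating.insert_triggers(
            stream, gating.TriggerSet(times_ms=np.array([], dtype=int), kind="respiratory")
        )
        assert np.array_equal(out.t_ms, stream.t_ms)
        assert len(out.trig_t_ms) == 0

    def test_random_triggers_permute_the_interval_multiset(self, small_geom, rng):
        times = np.cumsum([0, 1000, 1200, 900, 1100, 1000]) + 500
        ref = gating.TriggerSet(times_ms=times, kind="respiratory")
        stream = simdata.ListmodeStream(
            geometry=small_geom, duration_ms=10_000,
            t_ms=[], rho=[], theta=[], z=[], origin=[],
        )
        rnd = gating.random_triggers(stream, ref, seed=3)
        assert sorted(np.diff(rnd.times_ms)) == sorted(np.diff(ref.times_ms))
        assert rnd.times_ms.max() <= stream.duration_ms

    @staticmethod
    def _gate_mi(gate_a, gate_b):
        ok = (gate_a >= 0) & (gate_b >= 0)
        joint = np.histogram2d(gate_a[ok], gate_b[ok], bins=16)[0]
        p = joint / joint.sum()
        px = p.sum(axis=1, keepdims=True)
        py = p.sum(axis=0, keepdims=True)
        nz = p > 0
        return float(np.sum(p[nz] * np.log2(p[nz] / (px @ py)[nz])))

    def test_random_gate_assignment_is_independent_of_respiratory_phase(self, rng):
        """Permutation-null oracle: gate labels from permuted-interval
        triggers share no more information with the respiratory labels
        than labels from fully independent triggers do (both sequences
        share the mean period, which sets a small common floor), and both
        are far below phase-locked gating."""
        periods = rng.integers(800, 1300, size=600)
        resp = np.concatenate([[0], np.cumsum(periods)])
        t = rng.integers(1000, int(resp[-1]) - 1000, size=100_000)
        _, gate_r = gating.assign_gates(t, resp, 16)
        perm = 357 + np.concatenate([[0], np.cumsum(rng.permutation(periods))])
        _, gate_p = gating.assign_gates(t, perm, 16)
        indep = np.concatenate([[0], np.cumsum(rng.integers(800, 1300, 600))])
        _, gate_i = gating.assign_gates(t, indep, 16)
        _, gate_locked = gating.assign_gates(t, resp + 400, 16)
        mi_perm = self._gate_mi(gate_r, gate_p)
        mi_indep = self._gate_mi(gate_r, gate_i)
        mi_locked = self._gate_mi(gate_r, gate_locked)
        assert mi_perm < 3 * max(mi_indep, 1e-3)
        assert mi_perm < 0.05 * mi_locked


class TestBinGates:
    def test_uniform_stream_fills_gates_evenly(self, small_geom, rng):
        t = np.sort(rng.integers(0, 60_000, size=50_000))
        vox = np.ravel_multi_index((5, 5, 5), small_geom.image_shape)
        stream = simdata.ListmodeStream(
            geometry=small_geom, duration_ms=60_000,
            t_ms=t, rho=np.zeros_like(t), theta=np.zeros_like(t),
            z=np.zeros_like(t), origin=np.full_like(t, vox),
        )
        trig = np.arange(0, 60_001, 1000)
        gated = gating.bin_gates(stream, trig, n_gates=16)
        chi = stats.chisquare(gated.counts_per_gate)
        assert chi.pvalue > 0.001

    def test_gate_partition_identity(self, moving_stream):
        stream, waveform = moving_stream
        trig = np.round(waveform.boundaries * 1000).astype(int)
        gated = gating.bin_gates(stream, trig, n_gates=16)
        in_cycles = (stream.t_ms >= trig[0]) & (stream.t_ms < trig[-1])
        full = simdata.reconstruct_ideal(stream, in_cycles)
        assert np.array_equal(gated.ungated, full)
        assert gated.events_used + gated.events_discarded == stream.n_events

    def test_lesion_moves_by_the_prescribed_displacement_across_gates(self):
        phantom = simdata.make_lesion_phantom()
        waveform = simdata.make_waveform(1.0, 0.0, 120.0)
        stream = simdata.sample_events(phantom, waveform, 4.0e5, 120.0, seed=4)
        trig = np.round(waveform.boundaries * 1000).astype(int)
        gated = gating.bin_gates(stream, trig, n_gates=16)

        from scipy import ndimage

        def lesion_x(img):
            sub = ndimage.gaussian_filter(img[:, 30:44, 0], 2.0)
            return float(np.unravel_index(sub.argmax(), sub.shape)[0])

        dx = lesion_x(gated.data[..., 0]) - lesion_x(gated.data[..., 8])
        assert abs(dx) == pytest.approx(0.6 * 8.0, abs=1.0)

    def test_short_cycles_are_discarded_with_bookkeeping(self, small_geom):
        t = np.arange(0, 5000, 10).astype(int)
        vox = 0
        stream = simdata.ListmodeStream(
            geometry=small_geom, duration_ms=5000,
            t_ms=t, rho=np.zeros_like(t), theta=np.zeros_like(t),
            z=np.zeros_like(t), origin=np.full_like(t, vox),
        )
        trig = np.array([0, 1000, 1010, 2010, 5000])  # one 10 ms cycle
        gated = gating.bin_gates(stream, trig, n_gates=16)
        assert gated.cycles_discarded == 1
        assert gated.cycles_used == 3

    def test_random_gating_displacement_matches_trigger_periodicity_null(
        self, static_stream
    ):
        """On a static phantom, permuted-interval random gating and
        offset periodic gating draw max-COM displacements from the same
        distribution (two-sample KS)."""
        stream, _ = static_stream
        rng = np.random.default_rng(5)
        ref = gating.TriggerSet(
            times_ms=np.arange(500, 59_500, 1000), kind="respiratory"
        )
        d_rand, d_per = [], []
        for _ in range(25):
            r = gating.random_triggers(stream, ref, seed=rng)
            d_rand.append(metrics.max_com_displacement(
                gating.bin_gates(stream, r, n_gates=8)))
            off = int(rng.integers(0, 1000))
            per = np.arange(off, 59_000, 1000)
            d_per.append(metrics.max_com_displacement(
                gating.bin_gates(stream, per, n_gates=8)))
        ks = stats.ks_2samp(d_rand, d_per)
        assert ks.pvalue > 0.01
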