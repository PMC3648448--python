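"""Simulate a breathing rat scan and gate it from its own raw data.

Builds a 2-minute, 1e6-count listmode acquisition of a rat-like phantom
breathing at ~1 Hz, extracts the global respiratory trace from short-time
sinograms, derives cycle triggers, and bins 16 respiratory gates.  The
printed numbers show that the scan's own count fluctuations suffice to
recover the breathing period and a gate-to-gate center-of-mass excursion
well above the random-gating noise floor.
"""

import numpy as np

from petgate import gating, metrics, respsignal, simdata
from petgate.geometry import ScannerGeometry

geom = ScannerGeometry.small()
waveform = simdata.make_waveform(mean_period=1.0, jitter_sd=0.05, duration=120.0, seed=1)
phantom = simdata.make_rat_phantom(geom)
stream = simdata.sample_events(phantom, waveform, 1.0e6, 120.0, seed=1, geometry=geom)
print(f"simulated {stream.n_events} events over 120 s "
      f"({waveform.n_cycles} breathing cycles)")

ids, traces, _ = respsignal.region_traces_from_stream(stream, bin_ms=100.0)
trace = respsignal.build_global_trace((ids, traces), bin_ms=100.0)
print(f"global trace combined from {trace.n_regions_used} sinogram regions")

triggers = gating.detect_triggers(trace)
agree = gating.trigger_phase_agreement(triggers.times_ms, waveform.boundaries)
print(f"{len(triggers.times_ms)} triggers; most represented period "
      f"{triggers.most_represented_period_s:.2f} s (true 1.00 s); "
      f"{100 * agree:.0f}% of triggers within 150 ms of a fixed cycle phase")

gated = gating.bin_gates(stream, triggers, n_gates=16)
com = metrics.max_com_displacement(gated)

# random gating of the same events: the noise floor of the COM measure
rng = np.random.default_rng(2)
com_rand = []
for _ in range(10):
    rnd = gating.random_triggers(stream, triggers, seed=rng)
    com_rand.append(metrics.max_com_displacement(gating.bin_gates(stream, rnd, 16)))
print(f"max COM displacement: respiratory gated {com:.2f} mm vs "
      f"random gated {np.mean(com_rand):.2f} +- {np.std(com_rand):.2f} mm")
print("a respiratory value far above the random level indicates real motion")
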