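"""Apply the gating+ voxel-wise temporal filter to a gated scan.

Gates a simulated scan with respiratory triggers and with random triggers,
then filters each voxel's gate series: only the contiguous low frequencies
whose amplitudes beat 1.2x the voxel's randomly-gated noise are kept.  The
printed diagnostics show exact activity conservation, the motion map
concentrating on the moving structures, and phase-shifted continuous
motion frames interpolating between gates.
"""

import numpy as np

from petgate import gating, gatingplus, respsignal, simdata
from petgate.geometry import ScannerGeometry

geom = ScannerGeometry.small()
waveform = simdata.make_waveform(1.0, 0.05, 120.0, seed=3)
phantom = simdata.make_rat_phantom(geom)
stream = simdata.sample_events(phantom, waveform, 2.0e6, 120.0, seed=3, geometry=geom)

ids, traces, _ = respsignal.region_traces_from_stream(stream, 100.0)
trace = respsignal.build_global_trace((ids, traces), bin_ms=100.0)
triggers = gating.detect_triggers(trace)
gated = gating.bin_gates(stream, triggers, n_gates=16)
random_gated = gating.bin_gates(
    stream, gating.random_triggers(stream, triggers, seed=4), n_gates=16
)

result = gatingplus.apply_filter(gated, random_gated, factor=1.2)
err = np.abs(result.filtered.sum(-1) - gated.data.sum(-1)).max()
print(f"max |sum-over-gates difference| after filtering: {err:.2e} "
      "(activity is conserved per voxel)")
print(f"negative-value fraction: {result.diagnostics['negative_value_fraction']:.4f}")

cut = result.motion_map.cutoff
moving = cut[:, :, 2:8].mean()   # axial band swept by the breathing liver
static = cut[:, :, 10:].mean()
print(f"motion map mean cutoff: moving band {moving:.2f} harmonics, "
      f"static band {static:.2f} — motion is localized correctly")
print("cutoff histogram:", result.motion_map.histogram())

cmi = gatingplus.cmi_frames(result, n_frames=90)
print(f"CMI: {cmi.shape[-1]} phase-shifted frames; frame mean equals the "
      f"voxel DC to {np.abs(cmi.mean(-1) - gated.data.mean(-1)).max():.1e}")
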