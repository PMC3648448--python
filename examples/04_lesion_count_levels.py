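"""Moving-lesion count-level study: where does gating+ sit between
ungated and gated?

A hot lesion (3x background) moves sinusoidally by 60% of its diameter
next to a stationary two-compartment boundary.  At each relative count
level, 16-gate Poisson realizations are gated, randomly re-partitioned,
and gating+ filtered; lesion maximum, 70%-isocontour volume,
VOI/background ratio and FWHM are normalized to the high-count gated
value (= 100).  At low counts gating+ falls back to the low-noise ungated
behavior; at high counts it reproduces the motion-resolved gated values.
"""

import pandas as pd

from petgate import experiments

pd.set_option("display.width", 120)
table = experiments.lesion_experiment(
    count_levels=(1, 4, 13, 55, 2000), n_realizations=30, seed=0
)
print(table.round(1))
print()
m = table.xs("maximum")
print(f"lowest level:  gating+ maximum {m.loc['gatingplus', 1]:.0f} tracks "
      f"ungated {m.loc['ungated', 1]:.0f}, not the noise-inflated gated "
      f"{m.loc['gated', 1]:.0f}")
print(f"highest level: gating+ maximum {m.loc['gatingplus', 2000]:.0f} matches "
      f"gated {m.loc['gated', 2000]:.0f}")
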