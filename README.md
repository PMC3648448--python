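# petgate

Data-driven respiratory gating and voxel-wise temporal-frequency
filtering ("gating+") for PET.

Respiratory motion blurs PET images around the lungs and diaphragm.
Gating — partitioning listmode events by breathing phase — restores
resolution, but each gate holds only a fraction of the counts and is
correspondingly noisier.  `petgate` implements the full software-only
workflow for small-animal (rat-scale) PET:

1. **Signal extraction.** Events are binned into 100 ms short-time SSRB
   sinograms.  Small sinogram regions are ranked by the fraction of their
   non-DC spectral power inside the respiratory window (0.66–3.33 Hz for
   rats, whose breathing is ~1 Hz); the z-scored traces of the best
   regions are combined — sign-corrected, and only when a six-segment
   phase-consistency test agrees in every segment — into a global 1D
   respiratory trace.
2. **Triggers and gating.** Cycle-start triggers are local maxima of the
   trace separated by at least half the most-represented period.  Each
   trigger-to-trigger cycle is split into 16 equal phase bins and
   reconstructed into a 4D gated image `(x, y, z, gate)`.  *Random*
   triggers — a permutation of the respiratory intervals — gate the same
   events without any phase relation to motion, measuring the pure noise
   cost of subdividing counts.
3. **Gating+.** For every voxel, the gate series of both 4D sets is
   Fourier transformed along the gate axis with the convention
   `c_k = (1/N) Σ_n v_n e^(−2πikn/N)`, so `c_0` is the gate mean.  The
   voxel's *effective noise* is the maximum non-DC amplitude of its
   randomly gated spectrum, and the filter keeps the contiguous band
   `k = 1..k*` where every gated amplitude satisfies
   `|c_k| > 1.2 × noise`, truncating the rest to zero.  DC is never
   touched, so per-voxel total activity is conserved exactly and
   across-gate variance can only decrease (Parseval).  The per-voxel
   cutoff `k*` is a **motion map**; evaluating the retained spectrum at
   arbitrary phase gives **continuous motion images** (CMI, 90 frames).
4. **Validation metrics.** Center of mass per gate
   (`x_cm = Σ m_i x_i / M` from plane sums) and its maximum inter-gate
   displacement; the random-gating significance envelope (moving average
   + 2 SD of random-gated displacements vs counts); spherical VOI means
   and %SD; line profiles, boundary displacement and FWHM.
5. **Calibration experiments.** The Monte-Carlo derivation of the 1.2
   threshold, the CMI-vs-step interpolation study, the moving-lesion
   count-level study, per-voxel accuracy probabilities, and ramp/Wiener
   comparison filters.

A bundled simulator (`petgate.simdata`) generates quasi-periodic
breathing waveforms, dynamic phantoms, Poisson listmode streams (with
each event's true origin voxel, enabling idealized reconstruction) and
the documented RGLM v1 listmode file format, so the entire chain is
testable without scanner data.

## Worked example

```bash
python examples/01_simulate_and_gate.py
```

```
simulated 1000033 events over 120 s (119 breathing cycles)
global trace combined from 40 sinogram regions
122 triggers; most represented period 1.00 s (true 1.00 s); 98% of triggers within 150 ms of a fixed cycle phase
max COM displacement: respiratory gated 0.82 mm vs random gated 0.23 +- 0.05 mm
a respiratory value far above the random level indicates real motion
```

The scan's own count fluctuations recover the 1.00 s breathing period
exactly, 98% of derived triggers sit within 150 ms of a fixed phase of
the true cycle, and the gated center-of-mass excursion (0.82 mm) is far
above the random-gating noise floor (0.23 mm) — the scan genuinely
contains motion.  `examples/02_gating_plus_filter.py` then shows the
filter conserving activity to 1e−13 while the motion map concentrates on
the moving structures; `examples/03_threshold_calibration.py` and
`examples/04_lesion_count_levels.py` reproduce the calibration and
count-level studies.  A thin CLI mirrors the same stages
(`petgate simulate | extract-trace | trigger | gate | plus | cmi |
metrics | calibrate | pipeline`).

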