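"""Trigger derivation and phase-binned 4D gated reconstruction.

Respiratory triggers are the times where a new breathing cycle begins:
local maxima of the global trace, subject to a minimum separation of half
the most-represented respiratory period.  Random triggers — a permutation
of the respiratory inter-trigger intervals laid down at a random offset —
gate the same data with motion-unrelated boundaries, measuring the pure
noise cost of subdividing counts.  Each complete trigger-to-trigger cycle
is divided into ``n_gates`` equal-duration phase bins and the events in
each bin are reconstructed into one gate of the 4D image.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .errors import ParameterError
from .respsignal import GlobalTrace
from .simdata import (
    KIND_TRIGGER_RAND,
    KIND_TRIGGER_RESP,
    ListmodeStream,
    reconstruct_ideal,
)

PERIOD_HIST_BIN_S = 0.1  # 100 ms histogram bins for period estimation


@dataclass
class TriggerSet:
    times_ms: np.ndarray  # strictly increasing
    kind: str  # "respiratory" | "random"
    most_represented_period_s: float | None = None
    median_period_s: float | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times_ms, dtype=np.int64)
        if len(t) and np.any(np.diff(t) <= 0):
            raise ParameterError("trigger times must be strictly increasing")
        self.times_ms = t

    @property
    def intervals_s(self) -> np.ndarray:
        return np.diff(self.times_ms) / 1000.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_ms": self.times_ms, "kind": self.kind})


def most_represented_period(intervals_s: np.ndarray, bin_s: float = PERIOD_HIST_BIN_S) -> float:
    """Mode of the peak-to-peak interval histogram (100 ms bins).

    Bins are centered on multiples of the bin width (an interval of exactly
    1.2 s reports 1.2 s); ties break toward the shorter period.
    """
    intervals_s = np.asarray(intervals_s, dtype=float)
    if len(intervals_s) < 3:
        raise ParameterError("need at least 3 candidate peak intervals")
    idx = np.rint(intervals_s / bin_s).astype(int)
    counts = np.bincount(idx)
    mode = int(np.argmax(counts))  # argmax takes the first (shorter) on ties
    return mode * bin_s


def bandlimit(values: np.ndarray, bin_ms: float, max_hz: float) -> np.ndarray:
    """Zero spectral content above ``max_hz`` (used before peak picking)."""
    spec = np.fft.rfft(np.asarray(values, dtype=float))
    freqs = np.fft.rfftfreq(len(values), d=bin_ms / 1000.0)
    spec[freqs > max_hz] = 0.0
    return np.fft.irfft(spec, n=len(values))


def dominant_period(values: np.ndarray, bin_ms: float,
                    window_hz: tuple[float, float] = (0.2, 3.33)) -> float:
    """Period of the strongest non-DC spectral component in the window (s)."""
    x = np.asarray(values, dtype=float)
    amp = np.abs(np.fft.rfft(x - x.mean()))
    freqs = np.fft.rfftfreq(len(x), d=bin_ms / 1000.0)
    sel = (freqs >= window_hz[0]) & (freqs <= window_hz[1])
    if not sel.any() or amp[sel].max() == 0:
        raise ParameterError("no spectral peak inside the respiratory window")
    return float(1.0 / freqs[sel][np.argmax(amp[sel])])


def detect_triggers(trace: GlobalTrace, max_hz: float = 3.33) -> TriggerSet:
    """Local-maxima triggers with half-period minimum separation.

    The trace is band-limited to the respiratory pass window (its signal
    content by construction) so bin-level noise cannot split a breath
    crest into several candidate maxima.  Candidates are local maxima
    (plateaus contribute their leftmost sample) pre-separated by half the
    dominant spectral period; the most-represented period is then taken
    from the candidate intervals, and conflicting peaks closer than half
    that period are resolved by keeping the higher one.  Trigger times are
    bin centers.
    """
    v = np.asarray(trace.values, dtype=float)
    if len(v) < 3:
        raise ParameterError("trace too short for peak detection")
    smooth = bandlimit(v, trace.bin_ms, max_hz)
    coarse = 0.5 * dominant_period(v, trace.bin_ms) * 1000.0 / trace.bin_ms
    peaks, props = signal.find_peaks(
        smooth, plateau_size=(1, None), distance=max(coarse, 1)
    )
    peaks = props["left_edges"]  # leftmost sample of any plateau
    if len(peaks) == 0:
        raise ParameterError("no local maxima found in the global trace")
    if len(peaks) < 4:
        raise ParameterError("too few candidate peaks to estimate a period")
    cand_intervals = np.diff(peaks) * trace.bin_ms / 1000.0
    mrp = most_represented_period(cand_intervals)
    min_sep_bins = 0.5 * mrp * 1000.0 / trace.bin_ms
    v = smooth

    # keep the higher of any pair closer than the minimum separation
    order = np.argsort(v[peaks], kind="stable")[::-1]
    accepted: list[int] = []
    for p in peaks[order]:
        if all(abs(p - q) >= min_sep_bins for q in accepted):
            accepted.append(int(p))
    accepted.sort()
    times_ms = np.round((np.asarray(accepted) + 0.5) * trace.bin_ms).astype(np.int64)
    intervals = np.diff(times_ms) / 1000.0
    return TriggerSet(
        times_ms=times_ms,
        kind="respiratory",
        most_represented_period_s=most_represented_period(intervals),
        median_period_s=float(np.median(intervals)),
    )


def trigger_phase_agreement(
    trigger_times_ms: np.ndarray,
    boundaries_s: np.ndarray,
    tol_ms: float = 150.0,
) -> float:
    """Fraction of triggers within ``tol_ms`` of a constant phase offset.

    Detected triggers sit at a fixed — but arbitrary, since the global
    trace's sign is arbitrary — phase of the true cycle.  Each trigger's
    phase within its ground-truth cycle is mapped to the circle, the mean
    phase direction is removed, and the residual (converted to time via
    the median true period) is compared against the tolerance.
    """
    trig_s = np.asarray(trigger_times_ms, dtype=float) / 1000.0
    b = np.asarray(boundaries_s, dtype=float)
    i = np.clip(np.searchsorted(b, trig_s, side="right") - 1, 0, len(b) - 2)
    phase = (trig_s - b[i]) / (b[i + 1] - b[i])
    ang = 2 * np.pi * phase
    mean_dir = np.angle(np.exp(1j * ang).mean())
    dev = np.angle(np.exp(1j * (ang - mean_dir)))  # wrapped to (-pi, pi]
    period_ms = float(np.median(np.diff(b))) * 1000.0
    dev_ms = np.abs(dev) / (2 * np.pi) * period_ms
    return float(np.mean(dev_ms <= tol_ms))


def insert_triggers(stream: ListmodeStream, triggers: TriggerSet) -> ListmodeStream:
    """Insert trigger records into the stream (events untouched)."""
    t = np.asarray(triggers.times_ms, dtype=np.int64)
    if len(t) and (t.min() < 0 or t.max() > stream.duration_ms):
        raise ParameterError("trigger times outside the stream duration")
    if len(t) > 1 and np.any(np.diff(t) < 0):
        warnings.warn("unsorted trigger input; sorting")
        t = np.sort(t)
    code = KIND_TRIGGER_RESP if triggers.kind == "respiratory" else KIND_TRIGGER_RAND
    all_t = np.concatenate([stream.trig_t_ms.astype(np.int64), t])
    all_k = np.concatenate(
        [stream.trig_kind, np.full(len(t), code, dtype=np.uint8)]
    )
    return stream.with_triggers(all_t.astype(np.uint32), all_k)


def random_triggers(
    stream: ListmodeStream,
    reference: TriggerSet,
    seed: int | np.random.Generator | None = None,
) -> TriggerSet:
    """Motion-unrelated triggers preserving the interval multiset.

    The respiratory inter-trigger intervals are randomly permuted and laid
    down from a uniformly random start offset in [0, first interval), which
    keeps per-gate count statistics while destroying any phase relation to
    the motion.
    """
    if len(reference.times_ms) < 2:
        raise ParameterError("reference trigger set needs >= 2 triggers")
    rng = np.random.default_rng(seed)
    intervals = np.diff(reference.times_ms).astype(np.int64)
    perm = rng.permutation(intervals)
    offset = int(rng.uniform(0, perm[0]))
    times = offset + np.concatenate([[0], np.cumsum(perm)])
    times = times[times <= stream.duration_ms]
    intervals_s = np.diff(times) / 1000.0
    return TriggerSet(
        times_ms=times,
        kind="random",
        most_represented_period_s=(
            most_represented_period(intervals_s) if len(intervals_s) >= 3 else None
        ),
        median_period_s=float(np.median(intervals_s)) if len(intervals_s) else None,
    )


@dataclass
class Gated4D:
    """Phase-binned 4D image: (x, y, z, gate)."""

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    counts_per_gate: np.ndarray = field(default=None)
    cycles_used: int = 0
    cycles_discarded: int = 0
    events_used: int = 0
    events_discarded: int = 0
    cycle_periods_s: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_gates(self) -> int:
        return self.data.shape[-1]

    @property
    def ungated(self) -> np.ndarray:
        """Sum over gates: the ungated image restricted to complete cycles."""
        return self.data.sum(axis=-1)

    def report(self) -> dict:
        hist, edges = np.histogram(self.cycle_periods_s, bins=20) if len(
            self.cycle_periods_s
        ) else (np.empty(0, int), np.empty(0))
        return {
            "n_gates": int(self.n_gates),
            "cycles_used": int(self.cycles_used),
            "cycles_discarded": int(self.cycles_discarded),
            "events_used": int(self.events_used),
            "events_discarded": int(self.events_discarded),
            "discarded_event_fraction": (
                float(self.events_discarded / max(self.events_used + self.events_discarded, 1))
            ),
            "counts_per_gate": [int(c) for c in self.counts_per_gate],
            "period_histogram": {
                "counts": hist.tolist(),
                "edges_s": np.asarray(edges).tolist(),
            },
        }


def assign_gates(
    t_ms: np.ndarray, trigger_times_ms: np.ndarray, n_gates: int
) -> tuple[np.ndarray, np.ndarray]:
    """Map event times to (cycle index, gate index); -1 marks discarded.

    Events before the first or after the last trigger have no complete
    cycle and are discarded, as are cycles shorter than ``n_gates`` clock
    ticks (whose phase bins would be sub-resolution).
    """
    trig = np.asarray(trigger_times_ms, dtype=np.int64)
    t = np.asarray(t_ms, dtype=np.int64)
    cyc = np.searchsorted(trig, t, side="right") - 1
    valid = (cyc >= 0) & (cyc < len(trig) - 1)
    gate = np.full(len(t), -1, dtype=np.int64)
    periods = np.diff(trig)
    short = periods < n_gates
    ok = valid.copy()
    ok[valid] &= ~short[cyc[valid]]
    phase = (t[ok] - trig[cyc[ok]]) / periods[cyc[ok]]
    gate[ok] = np.minimum((phase * n_gates).astype(np.int64), n_gates - 1)
    cyc[~ok] = -1
    return cyc, gate


def bin_gates(
    stream: ListmodeStream,
    triggers: TriggerSet | np.ndarray,
    n_gates: int = 16,
    smoothing_fwhm: float = 0.0,
) -> Gated4D:
    """Bin events into ``n_gates`` equal-phase gates and reconstruct each."""
    if n_gates < 1:
        raise ParameterError("n_gates must be >= 1")
    trig = triggers.times_ms if isinstance(triggers, TriggerSet) else np.asarray(triggers)
    if len(trig) < 2:
        raise ParameterError("need at least 2 triggers to define a cycle")
    cyc, gate = assign_gates(stream.t_ms, trig, n_gates)
    used = gate >= 0
    geom = stream.geometry
    data = np.zeros(geom.image_shape + (n_gates,), dtype=float)
    counts = np.zeros(n_gates, dtype=np.int64)
    for g in range(n_gates):
        sel = used & (gate == g)
        counts[g] = int(sel.sum())
        if counts[g]:
            data[..., g] = reconstruct_ideal(stream, sel, smoothing_fwhm)
        elif counts[g] == 0:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                data[..., g] = 0.0
    periods = np.diff(trig)
    n_short = int(np.sum(periods < n_gates))
    return Gated4D(
        data=data,
        voxel_size=geom.voxel_size,
        counts_per_gate=counts,
        cycles_used=int(len(periods) - n_short),
        cycles_discarded=n_short,
        events_used=int(used.sum()),
        events_discarded=int(stream.n_events - used.sum()),
        cycle_periods_s=periods[periods >= n_gates] / 1000.0,
    )
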