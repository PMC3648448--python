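"""Data-driven extraction of the 1D global respiratory trace.

As the animal breathes, activity concentration in fixed regions of
projection space fluctuates at the respiratory frequency.  Each region's
signal is weak and noisy; the global trace is built by (1) binning the
listmode stream into short-time (100 ms) SSRB sinograms, (2) scoring small
sinogram regions by the fraction of their non-DC spectral power inside a
respiratory pass window (0.66 - 3.33 Hz for rats), and (3) accumulating
z-scored region traces — sign-corrected, and only when a six-segment
phase-consistency test agrees in every segment — into a single 1D signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ParameterError, StageError
from .simdata import ListmodeStream

DEFAULT_BLOCK = (4, 4, 1)  # (rho, theta, z) cells per region
DEFAULT_WINDOW_HZ = (0.66, 3.33)


@dataclass
class ShortTimeSinogramSeries:
    """Dense (rho, theta, z_ssrb, time_bin) count series."""

    counts: np.ndarray  # int32
    bin_ms: float
    start_ms: float = 0.0

    @property
    def n_bins(self) -> int:
        return self.counts.shape[-1]

    def region_traces(self, block: tuple[int, int, int] = DEFAULT_BLOCK):
        """Aggregate cells into non-overlapping blocks -> (ids, traces)."""
        r, th, z, t = self.counts.shape
        br, bt, bz = block
        ids = np.stack(
            np.meshgrid(
                np.arange(r) // br, np.arange(th) // bt, np.arange(z) // bz,
                indexing="ij",
            ),
            axis=-1,
        ).reshape(-1, 3)
        nb = ids.max(axis=0) + 1
        flat_ids = np.ravel_multi_index(ids.T, nb)
        n_regions = int(flat_ids.max()) + 1
        traces = np.zeros((n_regions, t), dtype=np.int64)
        np.add.at(traces, flat_ids, self.counts.reshape(-1, t))
        uniq = np.stack(np.unravel_index(np.arange(n_regions), nb), axis=-1)
        return uniq, traces


def bin_short_time(stream: ListmodeStream, bin_ms: float = 100.0) -> ShortTimeSinogramSeries:
    """Histogram events into short-time sinograms of ``bin_ms`` duration."""
    if bin_ms <= 0:
        raise ParameterError("bin_ms must be positive")
    if bin_ms > stream.duration_ms:
        raise ParameterError("bin_ms exceeds the stream duration")
    n_bins = int(np.ceil(stream.duration_ms / bin_ms))
    shape = stream.geometry.sinogram_shape + (n_bins,)
    counts = np.zeros(shape, dtype=np.int32)
    if stream.n_events:
        tbin = np.minimum((stream.t_ms / bin_ms).astype(np.intp), n_bins - 1)
        flat = np.ravel_multi_index(
            (stream.rho.astype(np.intp), stream.theta.astype(np.intp),
             stream.z.astype(np.intp), tbin),
            shape,
        )
        counts.reshape(-1)[:] = np.bincount(flat, minlength=counts.size)
    return ShortTimeSinogramSeries(counts=counts, bin_ms=float(bin_ms))


def region_traces_from_stream(
    stream: ListmodeStream,
    bin_ms: float = 100.0,
    block: tuple[int, int, int] = DEFAULT_BLOCK,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Bin events directly to (region, time) without a dense 4D series.

    Equivalent to ``bin_short_time(...).region_traces(block)`` but memory
    proportional to regions x time bins; preferred for large streams.
    Returns (region_ids, traces, n_bins).
    """
    if bin_ms <= 0:
        raise ParameterError("bin_ms must be positive")
    if bin_ms > stream.duration_ms:
        raise ParameterError("bin_ms exceeds the stream duration")
    g = stream.geometry
    br, bt, bz = block
    nb = (
        -(-g.n_radial_bins // br),
        -(-g.n_angles // bt),
        -(-g.n_ssrb_slices // bz),
    )
    n_bins = int(np.ceil(stream.duration_ms / bin_ms))
    n_regions = nb[0] * nb[1] * nb[2]
    traces = np.zeros((n_regions, n_bins), dtype=np.int64)
    if stream.n_events:
        rid = np.ravel_multi_index(
            (stream.rho.astype(np.intp) // br,
             stream.theta.astype(np.intp) // bt,
             stream.z.astype(np.intp) // bz),
            nb,
        )
        tbin = np.minimum((stream.t_ms / bin_ms).astype(np.intp), n_bins - 1)
        flat = rid * n_bins + tbin
        traces.reshape(-1)[:] = np.bincount(flat, minlength=traces.size)
    ids = np.stack(np.unravel_index(np.arange(n_regions), nb), axis=-1)
    return ids, traces, n_bins


@dataclass
class RegionTrace:
    region_id: tuple[int, int, int]
    values: np.ndarray  # detrended counts per time bin
    window_power_fraction: float
    total_counts: int
    flip: int | None = None  # +1 / -1 after consistency testing, None = untested


@dataclass
class GlobalTrace:
    """The combined 1D respiratory signal, sampled at the short-time bin rate."""

    values: np.ndarray
    bin_ms: float
    n_regions_used: int = 0

    @property
    def times_s(self) -> np.ndarray:
        """Bin-center times in seconds."""
        return (np.arange(len(self.values)) + 0.5) * self.bin_ms / 1000.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_s": self.times_s, "value": self.values})


def detrend_traces(traces: np.ndarray, bin_ms: float, window_s: float = 10.0) -> np.ndarray:
    """Subtract a moving mean to suppress tracer-kinetics drift.

    Uptake trends (e.g. FDG accumulation) would otherwise leak power into
    the low-frequency end of the spectrum and distort region scoring.
    """
    traces = np.asarray(traces, dtype=float)
    size = max(int(round(window_s * 1000.0 / bin_ms)), 1)
    size = min(size, traces.shape[-1])
    trend = ndimage.uniform_filter1d(traces, size=size, axis=-1, mode="nearest")
    return traces - trend


def window_power_fraction(
    trace: np.ndarray, bin_ms: float, window_hz: tuple[float, float]
) -> float:
    """Fraction of non-DC spectral power inside the pass window."""
    x = np.asarray(trace, dtype=float)
    x = x - x.mean()
    power = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(len(x), d=bin_ms / 1000.0)
    nondc = power[1:]
    total = nondc.sum()
    if total <= 0:
        return 0.0
    in_win = (freqs[1:] >= window_hz[0]) & (freqs[1:] <= window_hz[1])
    return float(nondc[in_win].sum() / total)


def score_regions(
    series_or_traces,
    bin_ms: float | None = None,
    window_hz: tuple[float, float] = DEFAULT_WINDOW_HZ,
    block: tuple[int, int, int] = DEFAULT_BLOCK,
    detrend_window_s: float = 10.0,
) -> list[RegionTrace]:
    """Rank sinogram regions by respiratory-window power fraction.

    Accepts either a ShortTimeSinogramSeries (regions are ``block``-sized
    cell groups) or a pre-binned ``(ids, traces)`` pair.  Regions with zero
    counts are excluded; the list is sorted by descending fraction.
    """
    if isinstance(series_or_traces, ShortTimeSinogramSeries):
        series = series_or_traces
        bin_ms = series.bin_ms
        ids, traces = series.region_traces(block)
    else:
        ids, traces = series_or_traces
        if bin_ms is None:
            raise ParameterError("bin_ms required with pre-binned traces")
    nyquist = 1000.0 / (2 * bin_ms)
    if not (0 < window_hz[0] < window_hz[1] <= nyquist):
        raise ParameterError(
            f"pass window {window_hz} must lie within (0, Nyquist={nyquist:g}] Hz"
        )
    totals = traces.sum(axis=1)
    keep = np.flatnonzero(totals > 0)
    det = detrend_traces(traces[keep], bin_ms, detrend_window_s)
    out = []
    for row, k in enumerate(keep):
        frac = window_power_fraction(det[row], bin_ms, window_hz)
        out.append(
            RegionTrace(
                region_id=tuple(int(v) for v in ids[k]),
                values=det[row],
                window_power_fraction=frac,
                total_counts=int(totals[k]),
            )
        )
    out.sort(key=lambda r: r.window_power_fraction, reverse=True)
    return out


def phase_consistency(
    region: np.ndarray, reference: np.ndarray, n_segments: int = 6
) -> int | None:
    """Segment-wise sign test between a region trace and the reference.

    The scan is split into ``n_segments`` equal time segments; in each, the
    sign of the zero-mean correlation between region and reference is
    taken.  The region is accepted (with that sign) only if all segments
    agree on a nonzero sign; anything else - disagreement, a zero
    correlation, or a zero-variance segment - rejects the region.
    """
    region = np.asarray(region, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if region.shape != reference.shape:
        raise ParameterError("region and reference traces must have equal length")
    if n_segments < 1:
        raise ParameterError("n_segments must be >= 1")
    n = len(region) // n_segments
    if n < 2:
        raise ParameterError("trace too short for the requested segmentation")
    signs = []
    for s in range(n_segments):
        a = region[s * n : (s + 1) * n]
        b = reference[s * n : (s + 1) * n]
        a = a - a.mean()
        b = b - b.mean()
        if not (a.any() and b.any()):
            return None
        c = float(np.dot(a, b))
        if c == 0.0:
            return None
        signs.append(1 if c > 0 else -1)
    return signs[0] if len(set(signs)) == 1 else None


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


def build_global_trace(
    series_or_traces,
    bin_ms: float | None = None,
    window_hz: tuple[float, float] = DEFAULT_WINDOW_HZ,
    block: tuple[int, int, int] = DEFAULT_BLOCK,
    n_segments: int = 6,
    top_fraction: float = 0.10,
    detrend_window_s: float = 10.0,
) -> GlobalTrace:
    """Combine phase-consistent region traces into the global signal.

    The reference starts as the z-scored top-ranked region; each further
    candidate (the best ``top_fraction`` of regions by window power
    fraction) is added, sign-flipped as needed, only if the six-segment
    phase test agrees in every segment.
    """
    regions = score_regions(series_or_traces, bin_ms=bin_ms, window_hz=window_hz,
                            block=block, detrend_window_s=detrend_window_s)
    if not regions:
        raise StageError("extract-trace", "no regions with counts to score")
    if isinstance(series_or_traces, ShortTimeSinogramSeries):
        bin_ms = series_or_traces.bin_ms
    n_candidates = max(int(np.ceil(top_fraction * len(regions))), 1)
    candidates = regions[:n_candidates]
    reference = _zscore(candidates[0].values)
    candidates[0].flip = 1
    n_used = 1
    for region in candidates[1:]:
        flip = phase_consistency(region.values, reference, n_segments)
        region.flip = flip
        if flip is not None:
            reference = reference + flip * _zscore(region.values)
            n_used += 1
    return GlobalTrace(values=reference, bin_ms=float(bin_ms), n_regions_used=n_used)


def region_ranking_table(regions: list[RegionTrace]) -> pd.DataFrame:
    """Diagnostic table of region scores and flips."""
    return pd.DataFrame(
        {
            "rho_block": [r.region_id[0] for r in regions],
            "theta_block": [r.region_id[1] for r in regions],
            "z_block": [r.region_id[2] for r in regions],
            "window_power_fraction": [r.window_power_fraction for r in regions],
            "total_counts": [r.total_counts for r in regions],
            "flip": [r.flip if r.flip is not None else 0 for r in regions],
        }
    )
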