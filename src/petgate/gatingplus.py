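"""Gating+: voxel-wise temporal-frequency filtering of gated PET images.

For every voxel, the gate-value series of the respiratory-gated image and
of a randomly-gated companion are Fourier transformed along the gate axis.
The random companion carries no motion, so its non-DC spectral amplitudes
measure the *effective noise* of subdividing this voxel's counts; the
maximum non-DC amplitude is a conservative per-voxel noise scalar.  The
filter passes the DC term plus the contiguous run of low frequencies,
anchored at the fundamental, whose gated amplitudes exceed ``factor``
(default 1.2) times that noise; everything above the run is truncated to
zero.  Because DC is never modified, per-voxel total activity over the
gates is conserved exactly, and because truncation only removes spectral
power, the across-gate variance can only decrease (Parseval).

Transform convention: one-sided real-input DFT with 1/N forward
normalization, ``c_k = (1/N) sum_n v_n exp(-2 pi i k n / N)``; c_0 equals
the gate mean, so conservation is a statement about c_0 alone.

The retained coefficients are a continuous model of the voxel's activity
over the cycle: evaluating the spectrum at arbitrary phase yields
phase-shifted "continuous motion image" (CMI) frames, and the per-voxel
cutoff index forms a motion map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError
from .gating import Gated4D


def voxel_spectrum(values: np.ndarray) -> np.ndarray:
    """One-sided DFT coefficients with 1/N normalization (c_0 = mean)."""
    v = np.asarray(values, dtype=float)
    return np.fft.rfft(v, axis=-1) / v.shape[-1]


def inverse_spectrum(coeffs: np.ndarray, n_gates: int) -> np.ndarray:
    """Inverse of :func:`voxel_spectrum`."""
    return np.fft.irfft(np.asarray(coeffs) * n_gates, n=n_gates, axis=-1)


def effective_noise(random_coeffs: np.ndarray) -> np.ndarray:
    """Max non-DC amplitude of the randomly gated spectrum (per voxel)."""
    c = np.asarray(random_coeffs)
    if c.shape[-1] < 2:
        raise ParameterError("need at least 2 gates (one non-DC frequency)")
    return np.abs(c[..., 1:]).max(axis=-1)


def cutoff_index(
    gated_coeffs: np.ndarray, noise: float | np.ndarray, factor: float = 1.2
) -> np.ndarray:
    """Highest contiguous frequency k* whose amplitudes all beat the noise.

    k* is the largest K such that |c_k| > factor * noise for every
    k = 1..K; the run is anchored at the fundamental, so K = 0 as soon as
    |c_1| fails.  This mirrors the principle that higher frequencies need
    supporting statistics: none is passed without all lower ones.
    """
    if factor <= 0:
        raise ParameterError("factor must be positive")
    c = np.asarray(gated_coeffs)
    mags = np.abs(c[..., 1:])
    ok = mags > np.asarray(noise)[..., None] * factor
    run = np.logical_and.accumulate(ok, axis=-1)
    return run.sum(axis=-1).astype(np.int64)


@dataclass
class MotionMap:
    """Per-voxel highest passed harmonic; 0 = reduced to the temporal mean."""

    cutoff: np.ndarray  # integer, 0..floor(N/2)
    n_gates: int

    def cutoff_hz(self, cycle_period_s: float) -> np.ndarray:
        """Cutoff as a temporal frequency, given the breathing period."""
        if cycle_period_s <= 0:
            raise ParameterError("cycle period must be positive")
        return self.cutoff / cycle_period_s

    def histogram(self) -> dict:
        kmax = self.n_gates // 2
        counts = np.bincount(self.cutoff.ravel(), minlength=kmax + 1)
        return {int(k): int(c) for k, c in enumerate(counts)}


@dataclass
class GatingPlusResult:
    filtered: np.ndarray  # (x, y, z, gate); values may be negative
    coeffs: np.ndarray  # (x, y, z, N//2+1) retained complex coefficients
    motion_map: MotionMap
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_gates(self) -> int:
        return self.filtered.shape[-1]


def apply_filter(
    gated: Gated4D | np.ndarray,
    random_gated: Gated4D | np.ndarray,
    factor: float = 1.2,
) -> GatingPlusResult:
    """Run the gating+ filter voxel by voxel (vectorized).

    Negative output values are possible when passed fluctuations exceed the
    voxel mean; they are reported in the diagnostics, never clipped.
    """
    g = gated.data if isinstance(gated, Gated4D) else np.asarray(gated, dtype=float)
    r = (
        random_gated.data
        if isinstance(random_gated, Gated4D)
        else np.asarray(random_gated, dtype=float)
    )
    if g.shape != r.shape:
        raise ParameterError(
            f"gated {g.shape} and randomly gated {r.shape} shapes must match"
        )
    n_gates = g.shape[-1]
    if n_gates < 2:
        raise ParameterError("need at least 2 gates")
    c = voxel_spectrum(g)
    noise = effective_noise(voxel_spectrum(r))
    cut = cutoff_index(c, noise, factor)
    k = np.arange(1, c.shape[-1])
    keep = k <= cut[..., None]
    c[..., 1:] *= keep
    filtered = inverse_spectrum(c, n_gates)
    neg = filtered < 0
    total = filtered.sum()
    diagnostics = {
        "factor": float(factor),
        "negative_value_fraction": float(neg.mean()),
        "total_negative_mass": float(filtered[neg].sum()),
        "relative_negative_mass": float(-filtered[neg].sum() / total) if total > 0 else 0.0,
        "mean_cutoff": float(cut.mean()),
    }
    return GatingPlusResult(
        filtered=filtered,
        coeffs=c,
        motion_map=MotionMap(cutoff=cut, n_gates=n_gates),
        diagnostics=diagnostics,
    )


def evaluate_phases(
    coeffs: np.ndarray, n_gates: int, phases: np.ndarray
) -> np.ndarray:
    """Evaluate a one-sided spectrum at arbitrary phases in [0, 1).

    v(phi) = c_0 + sum_{k>=1} w_k Re{c_k exp(+2 pi i k phi)} with w_k = 2
    except for the Nyquist term (k = N/2, N even), which appears once in
    the full spectrum and is not doubled.  At phi = n/N this reproduces the
    inverse DFT of the coefficients exactly.
    """
    c = np.asarray(coeffs)
    phases = np.atleast_1d(np.asarray(phases, dtype=float))
    n_k = c.shape[-1]
    k = np.arange(n_k)
    w = np.full(n_k, 2.0)
    w[0] = 1.0
    if n_gates % 2 == 0:
        w[-1] = 1.0
    ang = 2 * np.pi * np.outer(phases, k)  # (n_phases, n_k)
    cosm = np.cos(ang) * w
    sinm = np.sin(ang) * w
    # Re{c e^{i ang}} = Re(c) cos - Im(c) sin
    return np.tensordot(c.real, cosm, axes=([-1], [1])) - np.tensordot(
        c.imag, sinm, axes=([-1], [1])
    )


def cmi_frames(result: GatingPlusResult, n_frames: int = 90) -> np.ndarray:
    """Phase-shifted continuous-motion frames from the retained spectrum.

    Frame j sits at phase j / n_frames; with n_frames = N and the full
    spectrum retained the frames equal the gate values, and the mean over
    frames always equals c_0.
    """
    if n_frames < 1:
        raise ParameterError("n_frames must be >= 1")
    phases = np.arange(n_frames) / n_frames
    return evaluate_phases(result.coeffs, result.n_gates, phases)
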