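"""Quantitative motion and noise metrics for gated images.

Center of mass (COM) per gate and its maximum inter-gate displacement are
the global motion measure; the random-gating envelope (moving average of
random-gated displacements plus two standard deviations, as a function of
scan counts) separates significant motion from gating noise; spherical
VOIs quantify uptake and across-gate noise; line profiles track boundary
displacement and FWHM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ParameterError
from .gating import Gated4D


@dataclass(frozen=True)
class ComPoint:
    """Activity-weighted mean position in mm (voxel centers at index*pitch)."""

    x: float
    y: float
    z: float
    total: float  # total activity M

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


def center_of_mass(
    image: np.ndarray, voxel_size: tuple[float, float, float]
) -> ComPoint:
    """COM from plane sums: x_cm = sum_i m_i x_i / M per axis.

    ``m_i`` is the summed intensity of image plane i and ``x_i`` its
    coordinate in mm.  Negative-valued images (e.g. after filtering) use
    algebraic sums; the total must remain positive.
    """
    img = np.asarray(image, dtype=float)
    total = img.sum()
    if total <= 0:
        raise ParameterError("total activity must be positive for a COM")
    out = []
    for axis in range(3):
        planes = img.sum(axis=tuple(a for a in range(3) if a != axis))
        coords = np.arange(img.shape[axis]) * voxel_size[axis]
        out.append(float(np.dot(planes, coords) / total))
    return ComPoint(out[0], out[1], out[2], float(total))


def max_com_displacement(
    gated: Gated4D | np.ndarray, voxel_size: tuple[float, float, float] | None = None
) -> float:
    """Greatest Euclidean distance between the COMs of any two gates (mm)."""
    if isinstance(gated, Gated4D):
        data, voxel_size = gated.data, gated.voxel_size
    else:
        data = np.asarray(gated)
        if voxel_size is None:
            raise ParameterError("voxel_size required with a bare array")
    if data.shape[-1] < 2:
        raise ParameterError("need at least 2 gates")
    coms = np.stack(
        [center_of_mass(data[..., g], voxel_size).xyz for g in range(data.shape[-1])]
    )
    d = np.linalg.norm(coms[:, None, :] - coms[None, :, :], axis=-1)
    return float(d.max())


@dataclass
class EnvelopeCurve:
    """Count-ordered moving mean + 2 SD of random-gated displacements."""

    counts: np.ndarray
    displacement_mm: np.ndarray
    moving_mean: np.ndarray
    moving_sd: np.ndarray
    threshold_mm: np.ndarray
    window: int

    def threshold_at(self, count: float) -> float:
        """Threshold for a scan of the given counts (nearest-point lookup)."""
        i = int(np.argmin(np.abs(self.counts - count)))
        return float(self.threshold_mm[i])

    def is_significant(self, count: float, displacement_mm: float) -> bool:
        return displacement_mm > self.threshold_at(count)


def random_envelope(
    counts: np.ndarray, displacement_mm: np.ndarray, window: int = 9
) -> EnvelopeCurve:
    """Significance envelope from random-gated COM displacements.

    Points are ordered by scan counts; a centered moving average and moving
    SD over ``window`` points define threshold = mean + 2 SD (about 97.7%
    of random displacements fall below it for Gaussian noise).  Edge points
    use shrunken windows.
    """
    if window < 3:
        raise ParameterError("window must be >= 3")
    counts = np.asarray(counts, dtype=float)
    disp = np.asarray(displacement_mm, dtype=float)
    if len(counts) != len(disp):
        raise ParameterError("counts and displacements must align")
    if len(counts) < window:
        raise ParameterError("need at least `window` points")
    order = np.argsort(counts, kind="stable")
    counts, disp = counts[order], disp[order]
    half = window // 2
    n = len(disp)
    mean = np.empty(n)
    sd = np.empty(n)
    for i in range(n):
        seg = disp[max(0, i - half) : min(n, i + half + 1)]
        mean[i] = seg.mean()
        sd[i] = seg.std(ddof=1) if len(seg) > 1 else 0.0
    return EnvelopeCurve(
        counts=counts,
        displacement_mm=disp,
        moving_mean=mean,
        moving_sd=sd,
        threshold_mm=mean + 2 * sd,
        window=window,
    )


def sphere_mask(
    shape: tuple[int, int, int],
    voxel_size: tuple[float, float, float],
    center_mm: tuple[float, float, float],
    volume_cc: float,
) -> np.ndarray:
    """Voxels whose centers lie within a sphere of the given volume."""
    radius = (3.0 * volume_cc * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)  # mm
    coords = np.meshgrid(
        *(np.arange(n) * p for n, p in zip(shape, voxel_size)), indexing="ij"
    )
    d2 = sum((ax - c) ** 2 for ax, c in zip(coords, center_mm))
    lo = np.asarray(center_mm) - radius
    hi = np.asarray(center_mm) + radius
    ext = (np.asarray(shape) - 1) * np.asarray(voxel_size)
    if np.any(lo < -1e-9) or np.any(hi > ext + 1e-9):
        raise ParameterError("sphere extends outside the image grid")
    return d2 <= radius**2


def voi_stats(
    gated: Gated4D | np.ndarray,
    center_mm: tuple[float, float, float],
    volume_cc: float,
    voxel_size: tuple[float, float, float] | None = None,
) -> tuple[np.ndarray, float]:
    """Per-gate VOI means and the percent SD of the gate-mean series.

    %SD = 100 * SD / mean of the per-gate VOI means; for a single-frame
    (ungated) input it is 0 by definition.
    """
    if isinstance(gated, Gated4D):
        data, voxel_size = gated.data, gated.voxel_size
    else:
        data = np.asarray(gated, dtype=float)
        if data.ndim == 3:
            data = data[..., None]
        if voxel_size is None:
            raise ParameterError("voxel_size required with a bare array")
    mask = sphere_mask(data.shape[:3], voxel_size, center_mm, volume_cc)
    if not mask.any():
        raise ParameterError("VOI sphere contains no voxel centers")
    means = data[mask].mean(axis=0)
    grand = means.mean()
    if data.shape[-1] < 2 or grand == 0:
        return means, 0.0
    return means, float(100.0 * means.std(ddof=1) / grand)


def line_profile(
    image: np.ndarray,
    p0_mm: tuple[float, float, float],
    p1_mm: tuple[float, float, float],
    n_samples: int = 100,
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Trilinear samples along the segment p0 -> p1; returns (dist_mm, values)."""
    p0 = np.asarray(p0_mm, dtype=float)
    p1 = np.asarray(p1_mm, dtype=float)
    ext = (np.asarray(image.shape) - 1) * np.asarray(voxel_size)
    for p in (p0, p1):
        if np.any(p < -1e-9) or np.any(p > ext + 1e-9):
            raise ParameterError("profile endpoint outside the image grid")
    frac = np.linspace(0.0, 1.0, n_samples)
    pts = p0[None, :] + frac[:, None] * (p1 - p0)[None, :]
    idx = (pts / np.asarray(voxel_size)).T  # index coordinates
    vals = ndimage.map_coordinates(np.asarray(image, float), idx, order=1)
    dist = frac * np.linalg.norm(p1 - p0)
    return dist, vals


def boundary_position(
    dist: np.ndarray, values: np.ndarray, level: float = 0.5
) -> float:
    """First crossing of level * plateau along the profile (mm), or NaN.

    The plateau is the profile maximum; the crossing is located by linear
    interpolation between the bracketing samples, scanning from the start.
    """
    values = np.asarray(values, dtype=float)
    thr = level * values.max()
    above = values >= thr
    if not above.any() or above[0]:
        return float("nan") if not above.any() else float(dist[0])
    i = int(np.argmax(above))  # first sample at/above threshold
    x0, x1 = dist[i - 1], dist[i]
    y0, y1 = values[i - 1], values[i]
    if y1 == y0:
        return float(x1)
    return float(x0 + (thr - y0) * (x1 - x0) / (y1 - y0))


def boundary_displacement(
    profiles: list[tuple[np.ndarray, np.ndarray]], level: float = 0.5
) -> tuple[float, np.ndarray]:
    """Max - min boundary position across gates; NaN gates are flagged.

    Returns (displacement_mm, per-gate positions).
    """
    pos = np.array([boundary_position(d, v, level) for d, v in profiles])
    good = np.isfinite(pos)
    if good.sum() < 2:
        raise ParameterError("fewer than two gates with a boundary crossing")
    return float(pos[good].max() - pos[good].min()), pos


def fwhm(dist: np.ndarray, values: np.ndarray) -> float:
    """Full width at half maximum of a unimodal profile (mm).

    Baseline is the profile minimum; half-max crossings on both flanks of
    the peak are located by linear interpolation.
    """
    v = np.asarray(values, dtype=float)
    d = np.asarray(dist, dtype=float)
    peak = int(np.argmax(v))
    half = (v.max() + v.min()) / 2.0
    left = v[: peak + 1]
    right = v[peak:]
    below_l = np.flatnonzero(left < half)
    below_r = np.flatnonzero(right < half)
    if len(below_l) == 0 or len(below_r) == 0:
        raise ParameterError("half-maximum crossings not found on both flanks")
    i = below_l[-1]  # last sample below half on the rising flank
    x_l = d[i] + (half - v[i]) * (d[i + 1] - d[i]) / (v[i + 1] - v[i])
    j = peak + below_r[0]
    x_r = d[j - 1] + (half - v[j - 1]) * (d[j] - d[j - 1]) / (v[j] - v[j - 1])
    return float(x_r - x_l)


def metrics_table(rows: list[dict]) -> pd.DataFrame:
    """Tidy one-row-per-measurement table for CSV export."""
    return pd.DataFrame(rows)
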