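"""Synthetic listmode data: phantoms, breathing waveforms, Poisson events.

This module provides the ground truth against which every downstream stage
is validated.  It emulates a rat-scale acquisition: ~1 Hz quasi-periodic
respiration with period jitter, an activity scene whose moving structures
follow a periodic trajectory, and Poisson counting statistics spanning
1e6 - 1e8 coincidences over a 10-minute scan.

Reconstruction is *idealized*: every simulated event remembers its voxel of
origin, so an image is a histogram of origins (optionally Gaussian
smoothed).  The gating and filtering methods under study operate on count
fluctuations in 4D images and sinograms, not on tomographic fidelity, so
this removes an orthogonal error source while keeping all count statistics
exact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage, stats

from .errors import ParameterError
from .geometry import ScannerGeometry

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

# record kinds used in listmode streams and the RGLM file format
KIND_EVENT = 0
KIND_TRIGGER_RESP = 1
KIND_TRIGGER_RAND = 2
KIND_TRIGGER_HW = 3

TRIGGER_KIND_NAMES = {
    KIND_TRIGGER_RESP: "respiratory",
    KIND_TRIGGER_RAND: "random",
    KIND_TRIGGER_HW: "hardware",
}
TRIGGER_KIND_CODES = {v: k for k, v in TRIGGER_KIND_NAMES.items()}


# ---------------------------------------------------------------------------
# Respiratory waveform
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RespiratoryWaveform:
    """Quasi-periodic breathing cycle structure.

    ``boundaries`` are the cycle-start times in seconds (strictly
    increasing, starting at 0 and covering the scan duration).  Phase is 0
    at each boundary and advances linearly to 1 within the cycle.
    """

    boundaries: np.ndarray  # seconds
    duration: float  # seconds

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, dtype=float)
        if b.ndim != 1 or len(b) < 2:
            raise ParameterError("waveform needs at least one full cycle")
        if np.any(np.diff(b) <= 0):
            raise ParameterError("cycle boundaries must be strictly increasing")
        object.__setattr__(self, "boundaries", b)

    @property
    def periods(self) -> np.ndarray:
        return np.diff(self.boundaries)

    @property
    def n_cycles(self) -> int:
        """Number of complete cycles inside [0, duration]."""
        return int(np.sum(self.boundaries[1:] <= self.duration + 1e-9))

    def phase(self, t) -> np.ndarray:
        """Respiratory phase in [0, 1) at time(s) ``t`` (seconds)."""
        t = np.asarray(t, dtype=float)
        b = self.boundaries
        i = np.clip(np.searchsorted(b, t, side="right") - 1, 0, len(b) - 2)
        return np.clip((t - b[i]) / (b[i + 1] - b[i]), 0.0, np.nextafter(1.0, 0.0))

    def amplitude(self, t) -> np.ndarray:
        """Unitless displacement scale: sin^2 of the phase (0 at boundaries)."""
        return np.sin(np.pi * self.phase(t)) ** 2


def make_waveform(
    mean_period: float,
    jitter_sd: float,
    duration: float,
    seed: int | np.random.Generator | None = None,
) -> RespiratoryWaveform:
    """Draw a quasi-periodic waveform with i.i.d. truncated-normal periods.

    Periods come from a normal with the given mean and SD, truncated at
    +-50% of the mean so no non-physical (negative or giant) cycles occur.
    """
    if mean_period <= 0:
        raise ParameterError("mean_period must be positive")
    if jitter_sd < 0:
        raise ParameterError("jitter_sd must be non-negative")
    if duration <= mean_period:
        raise ParameterError("duration must exceed one mean period")
    rng = np.random.default_rng(seed)
    n_guess = int(np.ceil(duration / mean_period * 1.5)) + 4
    if jitter_sd == 0:
        periods = np.full(n_guess, float(mean_period))
    else:
        half = 0.5 * mean_period
        tn = stats.truncnorm(-half / jitter_sd, half / jitter_sd,
                             loc=mean_period, scale=jitter_sd)
        periods = tn.rvs(size=n_guess, random_state=rng)
        while periods.sum() < duration:  # pragma: no cover - generous guess
            periods = np.concatenate([periods, tn.rvs(size=n_guess, random_state=rng)])
    boundaries = np.concatenate([[0.0], np.cumsum(periods)])
    last = int(np.searchsorted(boundaries, duration, side="left"))
    boundaries = boundaries[: last + 1]
    return RespiratoryWaveform(boundaries=boundaries, duration=float(duration))


# ---------------------------------------------------------------------------
# Dynamic phantoms
# ---------------------------------------------------------------------------

class Ellipsoid:
    """Axis-aligned ellipsoid; ``radii_mm`` may be scalar (sphere)."""

    def __init__(self, center_mm: Sequence[float], radii_mm) -> None:
        self.center = np.asarray(center_mm, dtype=float)
        r = np.asarray(radii_mm, dtype=float)
        if r.ndim == 0:
            r = np.full(3, float(r))
        if np.any(r <= 0):
            raise ParameterError("ellipsoid radii must be positive")
        self.radii = r

    def mask(self, coords: tuple[np.ndarray, ...], offset_mm: np.ndarray) -> np.ndarray:
        c = self.center + offset_mm
        d2 = sum(((ax - ci) / ri) ** 2 for ax, ci, ri in zip(coords, c, self.radii))
        return d2 <= 1.0

    def extent(self, offset_mm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        c = self.center + offset_mm
        return c - self.radii, c + self.radii


class Box:
    """Axis-aligned box defined by its center and half sizes in mm."""

    def __init__(self, center_mm: Sequence[float], half_sizes_mm: Sequence[float]) -> None:
        self.center = np.asarray(center_mm, dtype=float)
        self.half = np.asarray(half_sizes_mm, dtype=float)
        if np.any(self.half <= 0):
            raise ParameterError("box half sizes must be positive")

    def mask(self, coords: tuple[np.ndarray, ...], offset_mm: np.ndarray) -> np.ndarray:
        c = self.center + offset_mm
        out = np.ones(np.broadcast_shapes(*(a.shape for a in coords)), dtype=bool)
        for ax, ci, hi in zip(coords, c, self.half):
            out &= np.abs(ax - ci) <= hi
        return out

    def extent(self, offset_mm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        c = self.center + offset_mm
        return c - self.half, c + self.half


@dataclass
class Structure:
    shape: object  # Ellipsoid | Box
    activity: float  # concentration, arbitrary units
    trajectory: Callable[[float], np.ndarray] | None = None  # phase -> mm offset

    def __post_init__(self) -> None:
        if self.activity < 0:
            raise ParameterError("activity concentrations must be >= 0")

    def offset(self, phase: float) -> np.ndarray:
        if self.trajectory is None:
            return np.zeros(3)
        off = np.asarray(self.trajectory(phase % 1.0), dtype=float)
        return off


class DynamicPhantom:
    """Analytic activity-vs-phase scene on a voxel grid.

    Structures are painted in order (later structures overwrite earlier
    ones where they overlap), so structure activities are absolute
    concentrations rather than additive increments.  Trajectories are
    periodic in phase with period 1.
    """

    def __init__(
        self,
        shape: tuple[int, int, int],
        voxel_size: tuple[float, float, float],
        structures: Sequence[Structure],
    ) -> None:
        if not structures:
            raise ParameterError("phantom needs at least one structure")
        self.shape = tuple(int(s) for s in shape)
        self.voxel_size = tuple(float(v) for v in voxel_size)
        self.structures = list(structures)
        self._coords = np.meshgrid(
            *(np.arange(n) * p for n, p in zip(self.shape, self.voxel_size)),
            indexing="ij",
        )

    @property
    def is_static(self) -> bool:
        return all(s.trajectory is None for s in self.structures)

    @property
    def grid_extent_mm(self) -> np.ndarray:
        return (np.asarray(self.shape) - 1) * np.asarray(self.voxel_size)

    def activity_grid(self, phase: float) -> np.ndarray:
        """Activity concentration per voxel at the given phase."""
        out = np.zeros(self.shape, dtype=float)
        for s in self.structures:
            m = s.shape.mask(self._coords, s.offset(phase))
            out[m] = s.activity
        return out

    def activity_stack(self, phases: np.ndarray) -> np.ndarray:
        """Activity grids stacked over a set of phases (last axis)."""
        return np.stack([self.activity_grid(p) for p in phases], axis=-1)


def make_lesion_phantom(
    lesion_diameter: float = 8.0,
    displacement_fraction: float = 0.6,
    lesion_to_background: float = 3.0,
    diaphragm_ratios: tuple[float, float] = (1.5, 3.0),
    grid: tuple[int, int] = (64, 64),
    voxel_mm: float = 1.0,
) -> DynamicPhantom:
    """2D+time moving-lesion scene used for the count-level simulations.

    A circular hot lesion (activity ratio ``lesion_to_background`` vs a
    uniform background of 1) moves sinusoidally left-to-right with
    peak-to-peak displacement ``displacement_fraction x diameter``, next to
    a stationary two-compartment boundary with activity ratios
    ``diaphragm_ratios`` vs background.  The grid is (nx, ny, 1) so the
    scene flows through the same 3D machinery as volumetric phantoms.
    """
    if lesion_diameter <= 0 or lesion_to_background <= 0:
        raise ParameterError("lesion diameter and ratio must be positive")
    if any(r <= 0 for r in diaphragm_ratios):
        raise ParameterError("diaphragm ratios must be positive")
    if displacement_fraction < 0:
        raise ParameterError("displacement_fraction must be >= 0")
    nx, ny = grid
    shape = (nx, ny, 1)
    vox = (voxel_mm, voxel_mm, voxel_mm)
    radius = lesion_diameter / 2.0
    disp = displacement_fraction * lesion_diameter

    cx = (nx - 1) * voxel_mm / 2.0
    cy = (ny - 1) * voxel_mm * 0.60
    center = np.array([cx, cy, 0.0])
    if (center[0] - radius - disp / 2.0 < 0) or (
        center[0] + radius + disp / 2.0 > (nx - 1) * voxel_mm
    ):
        raise ParameterError("lesion trajectory leaves the grid")

    def traj(phase: float) -> np.ndarray:
        return np.array([0.5 * disp * np.cos(2 * np.pi * phase), 0.0, 0.0])

    full = Box(
        center_mm=((nx - 1) * voxel_mm / 2, (ny - 1) * voxel_mm / 2, 0.0),
        half_sizes_mm=(nx * voxel_mm, ny * voxel_mm, 1.0),
    )
    y_ext = (ny - 1) * voxel_mm
    upper = Box(  # compartment adjacent to the background (ratio 1.5)
        center_mm=(cx, y_ext * 0.185, 0.0),
        half_sizes_mm=(nx * voxel_mm, y_ext * 0.065, 1.0),
    )
    lower = Box(  # deeper compartment (ratio 3.0)
        center_mm=(cx, y_ext * 0.06, 0.0),
        half_sizes_mm=(nx * voxel_mm, y_ext * 0.06, 1.0),
    )
    lesion = Ellipsoid(center_mm=center, radii_mm=(radius, radius, 1.0))
    return DynamicPhantom(
        shape=shape,
        voxel_size=vox,
        structures=[
            Structure(full, 1.0),
            Structure(upper, diaphragm_ratios[0]),
            Structure(lower, diaphragm_ratios[1]),
            Structure(lesion, lesion_to_background, trajectory=traj),
        ],
    )


def make_rat_phantom(
    geometry: ScannerGeometry | None = None,
    motion_amplitude_mm: float = 3.0,
    liver_to_background: float = 4.0,
    lesion_to_background: float = 8.0,
) -> DynamicPhantom:
    """Rat-like 3D scene: body, axially breathing liver dome, hot lesion.

    The liver compartment and an embedded hot lesion translate axially with
    a sinusoidal peak-to-peak excursion of ``motion_amplitude_mm``,
    emulating diaphragm-driven motion; the body background is static.
    """
    geom = geometry or ScannerGeometry.small()
    nx, ny, nz = geom.image_shape
    vx, vy, vz = geom.voxel_size
    cx, cy = (nx - 1) * vx / 2, (ny - 1) * vy / 2
    cz = (nz - 1) * vz / 2

    def traj(phase: float) -> np.ndarray:
        return np.array([0.0, 0.0, 0.5 * motion_amplitude_mm * np.cos(2 * np.pi * phase)])

    body = Ellipsoid((cx, cy, cz), (0.42 * nx * vx, 0.42 * ny * vy, 0.55 * nz * vz))
    liver = Ellipsoid((cx, cy, cz - 0.18 * nz * vz),
                      (0.30 * nx * vx, 0.30 * ny * vy, 0.14 * nz * vz))
    lesion = Ellipsoid((cx + 0.15 * nx * vx, cy, cz - 0.05 * nz * vz),
                       (0.08 * nx * vx, 0.08 * ny * vy, 0.08 * nz * vz))
    return DynamicPhantom(
        shape=geom.image_shape,
        voxel_size=geom.voxel_size,
        structures=[
            Structure(body, 1.0),
            Structure(liver, liver_to_background, trajectory=traj),
            Structure(lesion, lesion_to_background, trajectory=traj),
        ],
    )


# ---------------------------------------------------------------------------
# Listmode stream
# ---------------------------------------------------------------------------

@dataclass
class ListmodeStream:
    """Time-ordered coincidence events plus trigger records.

    Events carry sinogram coordinates (rho, theta, SSRB z) and, for
    simulated data, the flat index of the voxel the emission originated
    from (-1 when unknown).  Trigger records are kept in a parallel pair of
    arrays; the on-disk RGLM format interleaves them with events by time.
    """

    geometry: ScannerGeometry
    duration_ms: int
    t_ms: np.ndarray  # uint32 (n_events,)
    rho: np.ndarray  # uint16
    theta: np.ndarray  # uint16
    z: np.ndarray  # uint16
    origin: np.ndarray  # int32, flat voxel index or -1
    trig_t_ms: np.ndarray = field(default_factory=lambda: np.empty(0, np.uint32))
    trig_kind: np.ndarray = field(default_factory=lambda: np.empty(0, np.uint8))
    clock_ms: int = 1
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t_ms = np.asarray(self.t_ms, dtype=np.uint32)
        self.rho = np.asarray(self.rho, dtype=np.uint16)
        self.theta = np.asarray(self.theta, dtype=np.uint16)
        self.z = np.asarray(self.z, dtype=np.uint16)
        self.origin = np.asarray(self.origin, dtype=np.int32)
        self.trig_t_ms = np.asarray(self.trig_t_ms, dtype=np.uint32)
        self.trig_kind = np.asarray(self.trig_kind, dtype=np.uint8)
        n = len(self.t_ms)
        if not (len(self.rho) == len(self.theta) == len(self.z) == len(self.origin) == n):
            raise ParameterError("event columns must have equal length")
        if n and np.any(np.diff(self.t_ms.astype(np.int64)) < 0):
            raise ParameterError("event times must be non-decreasing")
        if n and int(self.t_ms[-1]) > self.duration_ms:
            raise ParameterError("event times exceed the stream duration")
        g = self.geometry
        if n:
            if int(self.rho.max()) >= g.n_radial_bins or int(self.theta.max()) >= g.n_angles:
                raise ParameterError("sinogram indices out of geometry bounds")
            if int(self.z.max()) >= g.n_ssrb_slices:
                raise ParameterError("SSRB slice index out of bounds")
        if len(self.trig_t_ms) and np.any(np.diff(self.trig_t_ms.astype(np.int64)) < 0):
            raise ParameterError("trigger times must be non-decreasing")

    @property
    def n_events(self) -> int:
        return len(self.t_ms)

    def triggers_of_kind(self, kind: str) -> np.ndarray:
        code = TRIGGER_KIND_CODES[kind]
        return self.trig_t_ms[self.trig_kind == code]

    def with_triggers(self, trig_t_ms: np.ndarray, trig_kind: np.ndarray) -> "ListmodeStream":
        """Return a copy with the given trigger records (time sorted)."""
        order = np.argsort(trig_t_ms, kind="stable")
        return ListmodeStream(
            geometry=self.geometry,
            duration_ms=self.duration_ms,
            t_ms=self.t_ms,
            rho=self.rho,
            theta=self.theta,
            z=self.z,
            origin=self.origin,
            trig_t_ms=np.asarray(trig_t_ms)[order],
            trig_kind=np.asarray(trig_kind)[order],
            clock_ms=self.clock_ms,
            provenance=dict(self.provenance),
        )


def project_voxels_to_sinogram(
    origin: np.ndarray,
    geometry: ScannerGeometry,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simplified voxel -> (rho, theta, z) projection.

    Each event gets a uniformly random projection angle; the radial bin is
    the signed distance of the voxel's transaxial position from the center
    along that angle, and the SSRB slice equals the voxel's axial index
    (the image grid is defined on the SSRB slice grid).  This preserves the
    spatial localization of count fluctuations, which is all the trace
    extraction needs.
    """
    nx, ny, nz = geometry.image_shape
    vx, vy, _ = geometry.voxel_size
    iz = origin % nz
    ixy = origin // nz
    iy = ixy % ny
    ix = ixy // ny
    x = (ix - (nx - 1) / 2.0) * vx
    y = (iy - (ny - 1) / 2.0) * vy
    theta_idx = rng.integers(0, geometry.n_angles, size=len(origin))
    theta = theta_idx * (np.pi / geometry.n_angles)
    rho_mm = x * np.cos(theta) + y * np.sin(theta)
    rho_idx = np.clip(
        np.rint(rho_mm / geometry.radial_spacing + (geometry.n_radial_bins - 1) / 2.0),
        0,
        geometry.n_radial_bins - 1,
    ).astype(np.uint16)
    return rho_idx, theta_idx.astype(np.uint16), iz.astype(np.uint16)


def sample_events(
    phantom: DynamicPhantom,
    waveform: RespiratoryWaveform | None,
    total_expected_counts: float,
    duration: float,
    seed: int | np.random.Generator | None = None,
    geometry: ScannerGeometry | None = None,
    time_step_ms: float = 10.0,
    n_phase_samples: int = 32,
    include_truth_triggers: bool = False,
) -> ListmodeStream:
    """Inhomogeneous-Poisson listmode sampling from a dynamic phantom.

    Emission rate per voxel is proportional to the phantom activity at the
    instantaneous respiratory phase; the realized event total is
    Poisson(``total_expected_counts``).  Phase is discretized to
    ``n_phase_samples`` activity grids and time to ``time_step_ms`` steps,
    both far finer than the 100-ms analysis binning downstream.
    """
    if total_expected_counts <= 0:
        raise ParameterError("total_expected_counts must be positive")
    if duration <= 0:
        raise ParameterError("duration must be positive")
    geom = geometry or ScannerGeometry(
        n_rings=(phantom.shape[2] + 1) // 2,
        n_radial_bins=max(phantom.shape[0], 4),
        n_angles=16,
        radial_spacing=phantom.voxel_size[0],
        axial_crystal_pitch=2 * phantom.voxel_size[2],
        image_shape=phantom.shape,
        voxel_size=phantom.voxel_size,
    )
    if tuple(geom.image_shape) != tuple(phantom.shape):
        raise ParameterError("geometry image grid must match the phantom grid")
    rng = np.random.default_rng(seed)
    duration_ms = int(round(duration * 1000))

    static = phantom.is_static or waveform is None
    if static:
        grids = phantom.activity_grid(0.0)[..., None]
        n_phase = 1
    else:
        n_phase = int(n_phase_samples)
        phases = (np.arange(n_phase) + 0.5) / n_phase
        grids = phantom.activity_stack(phases)
    flat = grids.reshape(-1, grids.shape[-1])  # (n_voxels, n_phase)
    totals = flat.sum(axis=0)
    if np.all(totals <= 0):
        raise ParameterError("phantom has no activity")

    n_steps = int(np.ceil(duration_ms / time_step_ms))
    step_centers_s = (np.arange(n_steps) + 0.5) * time_step_ms / 1000.0
    if static:
        step_phase_idx = np.zeros(n_steps, dtype=np.intp)
    else:
        step_phase_idx = np.minimum(
            (waveform.phase(step_centers_s) * n_phase).astype(np.intp), n_phase - 1
        )

    n_total = int(rng.poisson(total_expected_counts))
    w = totals[step_phase_idx]
    counts_per_step = rng.multinomial(n_total, w / w.sum())

    # voxel draws grouped by phase sample (grids are identical inside a group)
    origin = np.empty(n_total, dtype=np.int64)
    t_ms = np.empty(n_total, dtype=np.float64)
    pos = 0
    order = np.argsort(step_phase_idx, kind="stable")
    group_sizes = np.bincount(step_phase_idx, weights=counts_per_step, minlength=n_phase)
    # per-step times laid down in phase-group order, then globally sorted
    for p in range(n_phase):
        n_p = int(group_sizes[p])
        if n_p == 0:
            continue
        probs = flat[:, p] / totals[p]
        vox_counts = rng.multinomial(n_p, probs)
        vox_idx = np.repeat(np.arange(flat.shape[0]), vox_counts)
        rng.shuffle(vox_idx)
        origin[pos : pos + n_p] = vox_idx
        steps_p = np.flatnonzero(step_phase_idx == p)
        reps = counts_per_step[steps_p]
        starts = np.repeat(steps_p * time_step_ms, reps)
        t_ms[pos : pos + n_p] = starts + rng.uniform(0, time_step_ms, size=n_p)
        pos += n_p

    srt = np.argsort(t_ms, kind="stable")
    origin = origin[srt]
    t_ms_i = np.minimum(np.floor(t_ms[srt]), duration_ms - 1).astype(np.uint32)

    rho, theta_idx, z = project_voxels_to_sinogram(origin, geom, rng)

    trig_t = np.empty(0, np.uint32)
    trig_k = np.empty(0, np.uint8)
    if include_truth_triggers and waveform is not None:
        bt = np.round(waveform.boundaries * 1000).astype(np.int64)
        bt = bt[(bt >= 0) & (bt <= duration_ms)]
        trig_t = bt.astype(np.uint32)
        trig_k = np.full(len(bt), KIND_TRIGGER_HW, dtype=np.uint8)

    return ListmodeStream(
        geometry=geom,
        duration_ms=duration_ms,
        t_ms=t_ms_i,
        rho=rho,
        theta=theta_idx,
        z=z,
        origin=origin.astype(np.int32),
        trig_t_ms=trig_t,
        trig_kind=trig_k,
        provenance={"generator": "petgate.simdata.sample_events",
                    "total_expected_counts": float(total_expected_counts)},
    )


# ---------------------------------------------------------------------------
# Idealized reconstruction
# ---------------------------------------------------------------------------

def reconstruct_ideal(
    stream: ListmodeStream,
    selection: np.ndarray | Callable[[np.ndarray], np.ndarray] | None = None,
    smoothing_fwhm: float = 0.0,
    geometry: ScannerGeometry | None = None,
) -> np.ndarray:
    """Histogram selected events' origin voxels; optional Gaussian smoothing.

    ``selection`` is either a boolean mask over events, a callable mapping
    the event time array (ms) to such a mask, or None for all events.  With
    no smoothing, the voxel sum equals the number of selected events
    exactly; smoothing conserves counts up to truncation at the grid edge.
    """
    geom = geometry or stream.geometry
    if stream.n_events and int(stream.origin.min()) < 0:
        raise ParameterError("reconstruct_ideal requires events with origin voxels")
    if selection is None:
        mask = slice(None)
        n_sel = stream.n_events
    else:
        if callable(selection):
            selection = selection(stream.t_ms)
        mask = np.asarray(selection, dtype=bool)
        n_sel = int(mask.sum())
    if n_sel == 0:
        warnings.warn("selection matched zero events; returning an all-zero image")
        return np.zeros(geom.image_shape, dtype=float)
    counts = np.bincount(stream.origin[mask], minlength=geom.n_voxels).astype(float)
    img = counts.reshape(geom.image_shape)
    if smoothing_fwhm > 0:
        sigma = [smoothing_fwhm * FWHM_TO_SIGMA / v for v in geom.voxel_size]
        img = ndimage.gaussian_filter(img, sigma=sigma)
    return img
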