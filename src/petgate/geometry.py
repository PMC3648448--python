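"""Scanner geometry: sinogram dimensions, SSRB slices and the image grid.

The default geometry mirrors a rat-scale preclinical PET system: 80 detector
rings rebinned to 2*80 - 1 = 159 single-slice-rebinned (SSRB) sinogram
slices, 128 radial bins of 0.815 mm, 160 azimuthal angles, and a
128 x 128 x 159 image grid with 0.7764 x 0.7764 x 0.796 mm voxels.  A
reduced geometry (`ScannerGeometry.small()`) with identical invariants is
provided for simulation studies and tests, where the full grid would only
add cost, not information.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ParameterError


@dataclass(frozen=True)
class ScannerGeometry:
    n_rings: int = 80
    n_radial_bins: int = 128
    n_angles: int = 160
    radial_spacing: float = 0.815  # mm
    axial_crystal_pitch: float = 1.592  # mm
    image_shape: tuple[int, int, int] = (128, 128, 159)
    voxel_size: tuple[float, float, float] = (0.7764, 0.7764, 0.796)

    def __post_init__(self) -> None:
        if min(self.n_rings, self.n_radial_bins, self.n_angles) < 1:
            raise ParameterError("sinogram dimensions must be positive")
        if self.radial_spacing <= 0 or self.axial_crystal_pitch <= 0:
            raise ParameterError("detector spacings must be positive")
        if any(v <= 0 for v in self.voxel_size):
            raise ParameterError("voxel sizes must be positive")
        if self.image_shape[2] != self.n_ssrb_slices:
            raise ParameterError(
                f"image axial extent {self.image_shape[2]} must equal the "
                f"SSRB slice count 2*n_rings-1 = {self.n_ssrb_slices}"
            )

    @property
    def n_ssrb_slices(self) -> int:
        """Number of single-slice-rebinned sinogram slices (2*rings - 1)."""
        return 2 * self.n_rings - 1

    @property
    def n_voxels(self) -> int:
        nx, ny, nz = self.image_shape
        return nx * ny * nz

    @property
    def sinogram_shape(self) -> tuple[int, int, int]:
        return (self.n_radial_bins, self.n_angles, self.n_ssrb_slices)

    @classmethod
    def small(cls) -> "ScannerGeometry":
        """Reduced geometry for simulation studies (8 rings -> 15 slices)."""
        return cls(
            n_rings=8,
            n_radial_bins=32,
            n_angles=16,
            radial_spacing=1.0,
            axial_crystal_pitch=2.0,
            image_shape=(32, 32, 15),
            voxel_size=(1.0, 1.0, 1.0),
        )

    def to_dict(self) -> dict:
        return {
            "n_rings": self.n_rings,
            "n_radial_bins": self.n_radial_bins,
            "n_angles": self.n_angles,
            "radial_spacing": self.radial_spacing,
            "axial_crystal_pitch": self.axial_crystal_pitch,
            "image_shape": list(self.image_shape),
            "voxel_size": list(self.voxel_size),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScannerGeometry":
        return cls(
            n_rings=int(d["n_rings"]),
            n_radial_bins=int(d["n_radial_bins"]),
            n_angles=int(d["n_angles"]),
            radial_spacing=float(d["radial_spacing"]),
            axial_crystal_pitch=float(d["axial_crystal_pitch"]),
            image_shape=tuple(int(v) for v in d["image_shape"]),
            voxel_size=tuple(float(v) for v in d["voxel_size"]),
        )


def ssrb_slice(z1: int, z2: int, n_rings: int = 80) -> int:
    """SSRB slice index for a coincidence between detector rings z1 and z2.

    The oblique line of response is assigned to the 2D sinogram plane midway
    between the rings; on the half-pitch slice grid that midpoint is simply
    ``z1 + z2`` in 0 .. 2*n_rings - 2.
    """
    if not (0 <= z1 < n_rings and 0 <= z2 < n_rings):
        raise ParameterError(
            f"ring indices ({z1}, {z2}) out of range for {n_rings} rings"
        )
    return z1 + z2
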