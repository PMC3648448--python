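"""Pipeline configuration with validated, manifest-echoed defaults."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .errors import ParameterError


@dataclass
class PipelineConfig:
    """End-to-end workflow parameters.

    Defaults encode the rat-scale analysis conditions: 100 ms short-time
    sinogram bins, a 0.66-3.33 Hz respiratory pass window, six
    phase-consistency segments, 16 gates, 90 CMI frames, the 1.2 spectral
    threshold factor and 2 mm FWHM reconstruction smoothing.
    """

    bin_ms: float = 100.0
    pass_window_hz: tuple[float, float] = (0.66, 3.33)
    n_segments: int = 6
    n_gates: int = 16
    n_cmi_frames: int = 90
    threshold_factor: float = 1.2
    smoothing_fwhm_mm: float = 2.0
    region_block: tuple[int, int, int] = (4, 4, 1)
    top_fraction: float = 0.10
    detrend_window_s: float = 10.0
    n_random_repeats: int = 20
    seed: int = 0
    # simulator block (used when no input stream is given)
    simulate: dict | None = field(
        default_factory=lambda: {
            "mean_period_s": 1.0,
            "jitter_sd_s": 0.05,
            "duration_s": 600.0,
            "total_expected_counts": 1.0e7,
        }
    )
    input_rglm: str | None = None

    def validate(self) -> None:
        nyquist = 1000.0 / (2 * self.bin_ms)
        if self.bin_ms <= 0:
            raise ParameterError("bin_ms must be positive")
        if not (0 < self.pass_window_hz[0] < self.pass_window_hz[1] <= nyquist):
            raise ParameterError(
                f"pass window {self.pass_window_hz} outside (0, Nyquist={nyquist:g}]"
            )
        if self.n_gates < 2:
            raise ParameterError("n_gates must be >= 2")
        if self.n_segments < 1:
            raise ParameterError("n_segments must be >= 1")
        if self.n_cmi_frames < 1:
            raise ParameterError("n_cmi_frames must be >= 1")
        if self.threshold_factor <= 0:
            raise ParameterError("threshold_factor must be positive")
        if self.smoothing_fwhm_mm < 0:
            raise ParameterError("smoothing_fwhm_mm must be >= 0")
        if not (0 < self.top_fraction <= 1):
            raise ParameterError("top_fraction must be in (0, 1]")
        if self.simulate is None and self.input_rglm is None:
            raise ParameterError("either an input stream or a simulator block is required")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["pass_window_hz"] = list(self.pass_window_hz)
        d["region_block"] = list(self.region_block)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "pass_window_hz" in d:
            d["pass_window_hz"] = tuple(d["pass_window_hz"])
        if "region_block" in d:
            d["region_block"] = tuple(d["region_block"])
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))
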