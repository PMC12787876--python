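"""Single home for the pipeline's physical defaults.

All numeric constants of the estimation pipeline (window length, camera
sample rate, number of discarded low-frequency bins, bias-correction
coefficients, window-extraction policy) live here so that every module and
script draws them from one overridable schema.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any

import yaml


@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    """Defaults of the cadence-estimation pipeline.

    Attributes
    ----------
    window_size:
        Analysis window length in frames. Must be a power of two (radix-2
        FFT). 128 frames at 30 Hz span ~4.27 s.
    sample_rate:
        Camera capture rate in Hz.
    discard_bins:
        Number of leading FFT bins excluded from the dominant-bin search,
        suppressing the low-frequency peak caused by slow head displacement.
    correction_slope, correction_intercept:
        Coefficients of the linear bias correction
        ``corrected = slope * raw + intercept`` (steps/min scale).
    skip_seconds:
        Leading portion of a recording discarded before extracting the
        centered analysis window (start-up artifacts).
    """

    window_size: int = 128
    sample_rate: float = 30.0
    discard_bins: int = 5
    correction_slope: float = 0.83
    correction_intercept: float = 13.70
    skip_seconds: float = 10.0

    def __post_init__(self) -> None:
        if self.window_size < 2 or self.window_size & (self.window_size - 1):
            raise ValueError(f"window_size must be a power of two, got {self.window_size}")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.discard_bins < 0:
            raise ValueError("discard_bins must be nonnegative")

    @property
    def window_duration(self) -> float:
        """Window span in seconds (window_size / sample_rate)."""
        return self.window_size / self.sample_rate

    def replace(self, **kwargs: Any) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        """Short stable hash embedded in output files for provenance."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "PipelineConfig":
        """Load a config file; keyword overrides win over file values."""
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update(overrides)
        return cls(**data)


DEFAULT_CONFIG = PipelineConfig()
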