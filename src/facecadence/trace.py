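"""The landmark trace container shared by every stage of the pipeline."""

from __future__ import annotations

import dataclasses

import numpy as np


@dataclasses.dataclass
class LandmarkTrace:
    """A 30 Hz time series of vertical nose position with optional head yaw.

    Parameters
    ----------
    sample_rate:
        Frames per second of the capture (Hz).
    nose_y:
        Vertical position of the nose landmark, arbitrary tracker units,
        one value per frame.
    yaw:
        Head yaw in degrees per frame, or ``None`` when the recording has
        no orientation channel. NaN marks frames where tracking was lost.
    tracked:
        Per-frame tracking flag; ``None`` means all frames tracked.
    trace_id:
        Free-form identifier recorded in window provenance.
    """

    sample_rate: float
    nose_y: np.ndarray
    yaw: np.ndarray | None = None
    tracked: np.ndarray | None = None
    trace_id: str = "trace"

    def __post_init__(self) -> None:
        self.nose_y = np.asarray(self.nose_y, dtype=float)
        if self.nose_y.ndim != 1:
            raise ValueError("nose_y must be one-dimensional")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        n = self.nose_y.size
        if self.yaw is not None:
            self.yaw = np.asarray(self.yaw, dtype=float)
            if self.yaw.shape != (n,):
                raise ValueError("yaw must have one value per frame")
        if self.tracked is None:
            self.tracked = np.ones(n, dtype=bool)
        else:
            self.tracked = np.asarray(self.tracked, dtype=bool)
            if self.tracked.shape != (n,):
                raise ValueError("tracked must have one value per frame")
        if not np.all(np.isfinite(self.nose_y[self.tracked])):
            raise ValueError("nose_y must be finite on tracked frames")

    def __len__(self) -> int:
        return self.nose_y.size

    @property
    def frame_index(self) -> np.ndarray:
        return np.arange(len(self), dtype=int)

    @property
    def time(self) -> np.ndarray:
        """Frame timestamps in seconds (frame_index / sample_rate)."""
        return self.frame_index / self.sample_rate

    @property
    def duration(self) -> float:
        return len(self) / self.sample_rate

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LandmarkTrace):
            return NotImplemented
        same_yaw = (
            (self.yaw is None and other.yaw is None)
            or (
                self.yaw is not None
                and other.yaw is not None
                and np.array_equal(self.yaw, other.yaw, equal_nan=True)
            )
        )
        return (
            self.sample_rate == other.sample_rate
            and np.array_equal(self.nose_y, other.nose_y, equal_nan=True)
            and same_yaw
            and np.array_equal(self.tracked, other.tracked)
        )
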