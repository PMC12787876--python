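"""Synthetic head-motion trace generator.

Emulates the signal the FFT cadence estimator assumes: a single dominant
sinusoid at the step frequency (the head bobs once per step), superimposed
on slow postural drift (a linear trend plus a slow sine, standing in for
gradual position changes on the treadmill belt) and white Gaussian tracker
noise. The generator can additionally pre-distort the oscillation frequency
with the inverse of the linear bias-correction model so that the *raw* FFT
estimate reproduces the systematic overestimation seen on real recordings
while the *corrected* estimate recovers the true cadence.

None of the amplitudes are measurements; they are stated defaults chosen so
that the low-frequency drift peak genuinely dominates the first FFT bins
(exercising the discard-five-bins rule) while the gait peak dominates the
searched range.
"""

from __future__ import annotations

import dataclasses
from typing import Iterator, Mapping, Sequence

import numpy as np

from .config import DEFAULT_CONFIG
from .spectral import CorrectionModel
from .trace import LandmarkTrace

__all__ = ["TraceSpec", "CohortMember", "generate_trace", "generate_cohort"]


@dataclasses.dataclass(frozen=True)
class TraceSpec:
    """Stated world of one synthetic trace.

    Attributes
    ----------
    true_cadence:
        Ground-truth cadence in steps/min; the head oscillates at
        ``true_cadence / 60`` Hz unless ``bias_mode`` pre-distorts it.
    duration:
        Recording length in seconds (default 60, one treadmill trial).
    sample_rate:
        Capture rate in Hz (default 30, smartphone front camera).
    oscillation_amplitude:
        Amplitude of the step sinusoid, tracker units.
    drift_slope:
        Linear drift in tracker units per second.
    drift_sine_amplitude, drift_sine_period:
        Slow postural sway: amplitude (tracker units) and period (seconds).
        Periods of 10 s and above keep the sway inside the discarded
        low-frequency bins.
    noise_sd:
        Standard deviation of additive white Gaussian tracker noise.
    bias_mode:
        ``"none"``: oscillate exactly at the true step frequency.
        ``"inverse_correction"``: oscillate at ``((c - b) / a) / 60`` Hz so
        the raw FFT estimate overestimates and the linear correction
        ``a * raw + b`` recovers the true cadence.
    seed:
        Seed for phase and noise; identical spec -> identical trace.
    """

    true_cadence: float
    duration: float = 60.0
    sample_rate: float = 30.0
    oscillation_amplitude: float = 1.0
    drift_slope: float = 0.05
    drift_sine_amplitude: float = 5.0
    drift_sine_period: float = 20.0
    noise_sd: float = 0.2
    bias_mode: str = "none"
    yaw_amplitude: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_cadence <= 0:
            raise ValueError("true_cadence must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.bias_mode not in ("none", "inverse_correction"):
            raise ValueError(f"unknown bias_mode: {self.bias_mode!r}")
        if self.drift_sine_amplitude and self.drift_sine_period <= 0:
            raise ValueError("drift_sine_period must be positive")


def _oscillation_frequency(spec: TraceSpec, model: CorrectionModel | None) -> float:
    """Step-oscillation frequency in Hz implied by the spec's bias mode."""
    if spec.bias_mode == "none":
        return spec.true_cadence / 60.0
    if model is None:
        model = CorrectionModel(
            slope=DEFAULT_CONFIG.correction_slope,
            intercept=DEFAULT_CONFIG.correction_intercept,
        )
    if model.slope == 0:
        raise ValueError("correction model with zero slope cannot be inverted")
    return ((spec.true_cadence - model.intercept) / model.slope) / 60.0


def generate_trace(
    spec: TraceSpec,
    model: CorrectionModel | None = None,
    min_frames: int = 128,
) -> LandmarkTrace:
    """Generate one synthetic landmark trace from its spec.

    The vertical nose signal is
    ``A cos(2 pi f t + phi) + drift(t) + noise(t)`` with the phase drawn
    from the seeded generator. Raises ``ValueError`` if the requested
    duration cannot hold one analysis window of ``min_frames`` frames.
    """
    n = int(round(spec.duration * spec.sample_rate))
    if n < min_frames:
        raise ValueError(
            f"duration {spec.duration} s at {spec.sample_rate} Hz yields {n} frames; "
            f"at least {min_frames} are required for one analysis window"
        )
    rng = np.random.default_rng(spec.seed)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    t = np.arange(n) / spec.sample_rate
    f_osc = _oscillation_frequency(spec, model)

    nose_y = spec.oscillation_amplitude * np.cos(2.0 * np.pi * f_osc * t + phase)
    nose_y = nose_y + spec.drift_slope * t
    if spec.drift_sine_amplitude:
        nose_y = nose_y + spec.drift_sine_amplitude * np.sin(
            2.0 * np.pi * t / spec.drift_sine_period
        )
    if spec.noise_sd:
        nose_y = nose_y + rng.normal(0.0, spec.noise_sd, size=n)

    yaw = None
    if spec.yaw_amplitude:
        yaw = spec.yaw_amplitude * np.sin(2.0 * np.pi * t / max(spec.duration, 1.0))
    return LandmarkTrace(
        sample_rate=spec.sample_rate,
        nose_y=nose_y,
        yaw=yaw,
        trace_id=f"synth-c{spec.true_cadence:g}-s{spec.seed}",
    )


@dataclasses.dataclass(frozen=True)
class CohortMember:
    subject: int
    speed_kmh: float
    true_cadence: float
    trace: LandmarkTrace


def generate_cohort(
    n_subjects: int,
    speeds: Sequence[float],
    cadence_map: Mapping[float, tuple[float, float]],
    spec_defaults: TraceSpec | None = None,
    seed: int = 0,
    model: CorrectionModel | None = None,
) -> list[CohortMember]:
    """Generate one trace per subject x treadmill speed.

    ``cadence_map`` gives a ``(low, high)`` uniform cadence range per speed
    (steps/min); a degenerate range ``(c, c)`` pins the cadence exactly.
    Each subject draws one cadence per speed from the seeded stream, so the
    cohort is reproducible under ``seed``.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be at least 1")
    if not speeds:
        raise ValueError("speeds list must not be empty")
    for s in speeds:
        if s not in cadence_map:
            raise ValueError(f"no cadence distribution for speed {s}")
    if spec_defaults is None:
        spec_defaults = TraceSpec(true_cadence=150.0)

    rng = np.random.default_rng(seed)
    members: list[CohortMember] = []
    for subject in range(1, n_subjects + 1):
        for speed in speeds:
            low, high = cadence_map[speed]
            cadence = float(low) if low == high else float(rng.uniform(low, high))
            trace_seed = int(rng.integers(0, 2**31 - 1))
            spec = dataclasses.replace(
                spec_defaults, true_cadence=cadence, seed=trace_seed
            )
            trace = generate_trace(spec, model=model)
            trace.trace_id = f"subj{subject:02d}-{speed:g}kmh"
            members.append(CohortMember(subject, float(speed), cadence, trace))
    return members


def iter_windows(trace: LandmarkTrace, size: int, hop: int) -> Iterator[np.ndarray]:
    """Yield successive length-``size`` sample blocks with the given hop."""
    for start in range(0, len(trace) - size + 1, hop):
        yield trace.nose_y[start : start + size]
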