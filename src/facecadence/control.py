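"""Head-yaw directional control: scaled, clamped, slerp-smoothed rotation.

Each frame, the user's head yaw is multiplied by a sensitivity factor,
clamped to +/-90 degrees, converted to a rotation about the vertical axis,
and the avatar's orientation is moved toward that target by spherical
linear interpolation (slerp) with a fixed smoothing factor. For rotations
sharing the vertical axis, slerp reduces to linear interpolation of the
yaw angles, so a constant target is approached geometrically:
``|yaw_n - target| = |yaw_0 - target| * (1 - smoothing)**n``.

Orientation state is kept as a unit quaternion to stay faithful to the
engine-style update; yaw extraction is exact for the same-axis case.
Non-finite yaw input models tracking loss: the state is returned unchanged
with ``tracking_lost`` set, mirroring the on-screen realignment cue.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .trace import LandmarkTrace

__all__ = ["RotationState", "update_rotation", "simulate_turn", "replay_trace"]


def _quat_from_yaw(yaw_deg: float) -> np.ndarray:
    """Unit quaternion (w, x, y, z) for a rotation about the vertical axis."""
    half = math.radians(yaw_deg) / 2.0
    return np.array([math.cos(half), 0.0, math.sin(half), 0.0])


def _yaw_from_quat(q: np.ndarray) -> float:
    """Yaw in degrees of a vertical-axis rotation quaternion."""
    return math.degrees(2.0 * math.atan2(q[2], q[0]))


def _slerp(q0: np.ndarray, q1: np.ndarray, t: float) -> np.ndarray:
    """Spherical linear interpolation between unit quaternions.

    Takes the shorter arc (flips sign on negative dot product) and falls
    back to normalized linear interpolation for nearly parallel inputs.
    """
    dot = float(np.dot(q0, q1))
    if dot < 0.0:
        q1 = -q1
        dot = -dot
    if dot > 1.0 - 1e-12:
        out = q0 + t * (q1 - q0)
        return out / np.linalg.norm(out)
    theta = math.acos(min(dot, 1.0))
    s0 = math.sin((1.0 - t) * theta) / math.sin(theta)
    s1 = math.sin(t * theta) / math.sin(theta)
    out = s0 * q0 + s1 * q1
    return out / np.linalg.norm(out)


@dataclasses.dataclass(frozen=True)
class RotationState:
    """Avatar orientation plus the control parameters.

    ``rotation_intensity`` scales head yaw to avatar yaw (sensitivity;
    tuned empirically in practice, default 1.0). ``smoothing_factor`` in
    [0, 1] is the per-frame slerp fraction at 30 Hz. ``clamp_limit`` bounds
    the target yaw in degrees. Positive yaw means the head is turned
    toward the user's left as seen by the camera (configurable via
    ``yaw_sign``).
    """

    orientation: np.ndarray = dataclasses.field(
        default_factory=lambda: np.array([1.0, 0.0, 0.0, 0.0])
    )
    rotation_intensity: float = 1.0
    smoothing_factor: float = 0.5
    clamp_limit: float = 90.0
    yaw_sign: float = 1.0
    tracking_lost: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.smoothing_factor <= 1.0:
            raise ValueError("smoothing_factor must lie in [0, 1]")
        if self.clamp_limit <= 0:
            raise ValueError("clamp_limit must be positive")
        q = np.asarray(self.orientation, dtype=float)
        norm = np.linalg.norm(q)
        if not np.isfinite(norm) or norm == 0:
            raise ValueError("orientation must be a nonzero finite quaternion")
        object.__setattr__(self, "orientation", q / norm)

    @property
    def yaw(self) -> float:
        """Current avatar yaw in degrees."""
        return _yaw_from_quat(self.orientation)


def update_rotation(state: RotationState, head_yaw: float) -> RotationState:
    """One engine-frame update of the avatar orientation.

    target = clamp(head_yaw * intensity, +/-clamp_limit) about the vertical
    axis; the new orientation is the slerp of the current orientation toward
    the target by ``smoothing_factor``. Non-finite yaw (tracking loss)
    leaves the orientation unchanged and flags the state.
    """
    if not np.isfinite(head_yaw):
        return dataclasses.replace(state, tracking_lost=True)
    scaled = state.yaw_sign * head_yaw * state.rotation_intensity
    target_yaw = max(-state.clamp_limit, min(state.clamp_limit, scaled))
    target = _quat_from_yaw(target_yaw)
    new_q = _slerp(state.orientation, target, state.smoothing_factor)
    return dataclasses.replace(state, orientation=new_q, tracking_lost=False)


def simulate_turn(
    initial: RotationState, constant_head_yaw: float, n_frames: int
) -> np.ndarray:
    """Per-frame yaw trajectory under a constant head-yaw input."""
    if n_frames < 1:
        raise ValueError("n_frames must be at least 1")
    state = initial
    yaws = np.empty(n_frames)
    for i in range(n_frames):
        state = update_rotation(state, constant_head_yaw)
        yaws[i] = state.yaw
    return yaws


def replay_trace(
    trace: LandmarkTrace, initial: RotationState | None = None
) -> np.ndarray:
    """Replay a recorded yaw channel through the control loop.

    Returns the avatar yaw per frame; frames with missing yaw (NaN) hold
    the previous orientation, as during tracking loss.
    """
    if trace.yaw is None:
        raise ValueError("trace has no yaw channel to replay")
    state = initial if initial is not None else RotationState()
    out = np.empty(len(trace))
    for i, head_yaw in enumerate(trace.yaw):
        state = update_rotation(state, float(head_yaw))
        out[i] = state.yaw
    return out
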