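"""Drive the avatar's direction from head yaw: scale, clamp, slerp.

Shows the control loop's response to a constant head turn (geometric
approach to the clamped target) and a replay of a recorded yaw channel
with a tracking-loss gap.
"""

import numpy as np

from facecadence import LandmarkTrace, RotationState, replay_trace, simulate_turn

state = RotationState(rotation_intensity=1.5, smoothing_factor=0.3)

# Head held 40 degrees left: target = clamp(40 * 1.5) = 60 degrees.
traj = simulate_turn(state, 40.0, 12)
print("constant 40-degree head turn, intensity 1.5, smoothing 0.3:")
for i, yaw in enumerate(traj, 1):
    print(f"  frame {i:2d}: avatar yaw {yaw:6.2f} deg")
print("(approaches the 60-degree target geometrically: 60*(1-0.7^n))\n")

# Extreme input is clamped at +/-90 regardless of magnitude.
print(f"spoofed 10000-degree input settles at {simulate_turn(state, 1e4, 60)[-1]:.1f} deg\n")

# Replay a yaw channel with a tracking dropout (NaN holds orientation).
yaw = np.concatenate([np.full(10, 30.0), [np.nan] * 3, np.full(10, -30.0)])
trace = LandmarkTrace(
    sample_rate=30.0,
    nose_y=np.zeros(yaw.size),
    yaw=yaw,
    tracked=~np.isnan(yaw),
)
out = replay_trace(trace, RotationState(smoothing_factor=0.5))
print("replayed yaw trajectory (30 deg held, 3 lost frames, then -30 deg):")
print("  " + " ".join(f"{v:6.1f}" for v in out))
# During the dropout the avatar holds its last orientation instead of
# snapping, mirroring the on-screen realignment cue.
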