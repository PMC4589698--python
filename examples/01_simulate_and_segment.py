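"""Simulate one water-maze trial and segment its swimming path.

Generates a 90 s trial composed of three behaviours, then cuts the path
into overlapping 250 cm windows (90% overlap -> 25 cm step).
"""

import swimpath as sp

trial = sp.generate_trial(
    [
        sp.BehaviourSpec("thigmotaxis", 35.0),
        sp.BehaviourSpec("scanning", 30.0),
        sp.BehaviourSpec("target_scanning", 25.0),
    ],
    seed=42,
)
traj = trial.trajectory
params = sp.SegmentationParams(segment_length=250.0, overlap=0.9)
segments = sp.segment_trajectory(traj, params)

print(f"trial duration : {traj.t[-1]:.1f} s at 25 Hz ({len(traj.points)} samples)")
print(f"path length    : {traj.path_length():.0f} cm")
print(f"minimum path interval (step): {params.step:.0f} cm")
print(f"segments       : {len(segments)} windows of ~{params.segment_length:.0f} cm")
print(f"first window   : offset {segments[0].start_offset:.0f} cm, "
      f"actual length {segments[0].actual_length:.1f} cm")
# The number of windows ~ (path_length - 250) / 25 + 1: each advances one
# 25 cm step, so every stretch of path is seen by ~10 overlapping windows.
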