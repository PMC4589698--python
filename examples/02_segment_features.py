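"""Compute the eight classification features for segments of two contrasting
behaviours and print them side by side.

Thigmotaxis (wall hugging) should show a high median distance to centre and
a tiny spread; target scanning (closed loops around the platform) should
show high target proximity and a long self-intersecting loop.
"""

import swimpath as sp

arena = sp.default_arena()
params = sp.SegmentationParams(250.0, 0.9)

rows = {}
for cls in ("thigmotaxis", "target_scanning"):
    trial = sp.generate_trial([sp.BehaviourSpec(cls, 12.0)], seed=7, animal_id=cls)
    seg = sp.segment_trajectory(trial.trajectory, params)[0]
    rows[cls] = sp.compute_features(seg, arena)

print(f"{'feature':28s} {'thigmotaxis':>12s} {'target_scanning':>16s}")
for name in sp.FEATURE_NAMES:
    print(f"{name:28s} {rows['thigmotaxis'][name]:12.3f} {rows['target_scanning'][name]:16.3f}")
# All features are dimensionless: radial statistics are normalised by the
# arena radius, ellipse-derived shape measures by the segment length, so
# segments of slightly different lengths can be mixed in one classification.
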