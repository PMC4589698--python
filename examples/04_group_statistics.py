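"""Group-level behaviour statistics on ground-truth classified paths.

Uses the generator's own truth (no clustering) to show the statistical
outputs: per-trial strategy lengths, the within-trial transition matrix,
switch counts and the Friedman comparison of stressed vs control animals.
"""

import numpy as np
import pandas as pd

import swimpath as sp
from swimpath.path_mapping import ClassifiedPath
from swimpath.stats import compare_groups, count_transitions, strategy_lengths, transition_matrix
from swimpath.synthetic import interval_truth

manifest, trials = sp.generate_cohort(n_per_group=8, n_trials=6, seed=3)
step = 25.0

paths, rows = [], []
for tid, st in trials.items():
    classes = interval_truth(st, step)
    cp = ClassifiedPath(tid, step, classes, step * len(classes), step * len(classes))
    paths.append(cp)
    meta = manifest.set_index("id").loc[tid]
    rows.append(
        {
            "animal_id": meta["animal_id"],
            "group": meta["group"],
            "trial": meta["trial"],
            "value": count_transitions(cp),
            "thigmotaxis_m": strategy_lengths(cp)["thigmotaxis"] / 100.0,
            "path_m": st.trajectory.path_length() / 100.0,
        }
    )
df = pd.DataFrame(rows)

tm = transition_matrix(paths)
print("transition probabilities (rows normalised, first 4 classes):")
print(tm.probabilities.iloc[:4, :4].round(3).to_string())
print()
print("mean strategy switches per trial by group:")
print(df.groupby("group")["value"].mean().round(2).to_string())
print()
for label, col in [
    ("switch counts", "value"),
    ("thigmotaxis metres", "thigmotaxis_m"),
    ("path length (m)", "path_m"),
]:
    stat, p = compare_groups(
        df.assign(value=df[col])[["animal_id", "group", "trial", "value"]]
    )
    print(f"Friedman ({label:18s}, trials as blocks): chi2={stat:.3f}, p={p:.4f}")
# Stressed animals swim ~15% faster by construction, so the path-length
# comparison comes out clearly significant; the thigmotaxis-dwell shift is
# real but noisier at 8 animals per group over 6 matched trials.
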