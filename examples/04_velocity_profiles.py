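"""Validate the spatial classification with pre/post-MAD velocity profiles.

Each trial's speed curve is cut at its own point of maximum orthogonal
deviation (MAD) and the two segments are renormalized to a common 0-100%
axis before averaging, aligning change-of-mind turns that happen at
different times. Single-step movements should be near peak speed at the
MAD; multi-step movements should show a deceleration into the turn and a
re-acceleration out of it.
"""

import numpy as np
import pandas as pd

import trajsplit as ts
from trajsplit.pipeline import velocity_profiles

params = ts.GeneratorParams(n_participants=8, n_trials=100, seed=3)
ds = ts.generate_dataset(params)
proc = ts.process_trials(ds.trials, ds.geometry)

cut = ts.default_cutoff(ds.geometry)
labels = pd.Series(
    np.where(ts.classify_dataset(proc.table, cut).to_numpy(), "excluded", "retained"),
    index=proc.table.index,
)
profiles, skipped = velocity_profiles(proc, labels, mask=proc.retained)

for group, (prof, n) in profiles.items():
    peak = max(prof.pre.max(), prof.post.max())
    print(f"{group:9s} (n={n:5d}): peak {peak:.2f} px/ms | "
          f"speed entering MAD {prof.pre[-1]:.2f} "
          f"({100 * prof.pre[-1] / peak:.0f}% of peak) | "
          f"speed leaving MAD {prof.post[0]:.2f}")
print(f"({skipped} trials skipped: MAD on an endpoint)")
print("\nRetained (single-step) movements pass their MAD at near-peak speed;"
      "\nexcluded (multi-step) movements nearly stop there - the spatial cutoff"
      "\nseparates two genuinely different movement types.")
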