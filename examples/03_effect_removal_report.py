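"""The headline analysis: does the compatibility effect survive the cutoff?

Runs the paired within-subject report twice - on all retained trials and
on single-step movements only. In this generator the single-step path
distribution is identical across conditions, so the spatial effect (AUC,
MAD) is carried entirely by multi-step trials and should collapse after
the cutoff, while the initiation-time effect is injected independently
and should persist. A relaxed-cutoff sweep traces the transition.
"""

import trajsplit as ts

params = ts.GeneratorParams(n_participants=20, n_trials=200, seed=9)
ds = ts.generate_dataset(params)
proc = ts.process_trials(ds.trials, ds.geometry)

rep = ts.build_report(proc.table, ds.geometry)
frame = rep.to_frame()
print(frame[["measure", "stage", "mean_compatible", "mean_incompatible",
             "t", "df", "p", "dz"]].round(3).to_string(index=False))

print("\nReading: without the cutoff, AUC/MAD/IT/MT all show significant "
      "compatibility effects;\nwith the cutoff the spatial and MT effects "
      "shrink to noise while IT stays highly significant.")

sweep = ts.cutoff_sweep(proc.table[proc.retained], ds.geometry)
sub = sweep.frame.iloc[::6][["fraction", "n_multistep", "dz", "p"]]
print("\nAUC effect size while the cutoff is relaxed toward the wrong target:")
print(sub.round(3).to_string(index=False))
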