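"""Recall metrics across systems consolidation (two-region network).

Full protocol: training, consolidation with forked test phases at three
time points, partial-cue testing.  Prints the hippocampal and cortical
recall curves; HPC typically starts near ceiling and fades
(de-maturation), CTX starts lower and holds or rises (maturation).
Takes several minutes.
"""
from engramsim import build_network, make_preset, make_stimuli, run_protocol

spec, sched, kind = make_preset("two_region", seed=1)
sched.test_points = (0.0, 300.0, 600.0)
sim = build_network(spec)
stimuli = make_stimuli(kind, spec.N_stim, 4, sim.rng_protocol,
                       grid_side=spec.grid_side)
res = run_protocol(sim, stimuli, sched)
print("consolidation-time  region  accuracy  t.p.r.  f.p.r.")
for row in res.metrics:
    print(f"{row['cons_time']:>12.0f} s      {row['region']:<5}"
          f"  {row['accuracy']:.2f}      {row['tpr']:.2f}   {row['fpr']:.2f}")
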