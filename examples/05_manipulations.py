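"""Blocking and ablation manipulations.

Demonstrates the manipulation API on the three-region network: blocking
hippocampal engram output during consolidation and ablating HPC during
testing.  Prints which projections are masked in each case.
"""
import numpy as np

from engramsim import (Manipulation, apply_manipulation, build_network,
                       make_preset)

spec, _, _ = make_preset("three_region", seed=0)
sim = build_network(spec)

cells = np.arange(40)  # a stand-in engram ensemble
apply_manipulation(sim, Manipulation("block-engram-output", region="HPC",
                                     neurons=cells))
print("block-engram-output on HPC:")
for name, proj in sim.projections.items():
    if proj.blocked.any():
        print(f"  {name}: {proj.blocked.sum()} sources masked")
print("  (recurrent HPC synapses stay live - only inter-region output is cut)")

sim2 = build_network(spec)
apply_manipulation(sim2, Manipulation("ablate-region", region="HPC"))
print("ablate-region HPC:")
for name, proj in sim2.projections.items():
    if proj.blocked.all():
        print(f"  {name}: fully removed")
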