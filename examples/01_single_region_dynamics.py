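"""Membrane and conductance dynamics of a driven integrate-and-fire cell.

Builds a one-neuron population, injects a constant excitatory conductance,
and prints the membrane trajectory against the algebraic fixed point
U* = (U_rest + g U_exc) / (1 + g).
"""
import numpy as np

from engramsim import NeuronParams, RegionState, integrate_membrane

p = NeuronParams()
state = RegionState(1, p)
g = 0.6
dt = 1e-4
for step in range(4000):
    state.g_ampa[:] = g
    state.g_nmda[:] = g
    integrate_membrane(state, p, dt)
    state.theta[:] = 1e9  # hold spiking off to expose the fixed point
    if step % 800 == 0:
        print(f"t = {step * dt * 1e3:6.1f} ms   U = {state.U[0]:7.2f} mV")
fixed = (p.U_rest + g * p.U_exc) / (1 + g)
print(f"algebraic fixed point: {fixed:.2f} mV (trajectory converges to it)")
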