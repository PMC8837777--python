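"""Single-population neuron dynamics: membrane, threshold and conductances.

These functions define the per-timestep update semantics used throughout the
package.  The production simulator (:mod:`engramsim.engine`) implements the
same updates in a fused, compiled loop; tests assert step-for-step agreement
between the two on small networks.

Update order within one timestep (one-step synaptic delay convention):

1. :func:`decay_and_deliver_conductances` — decay all conductances, then add
   the weighted spike input from the *previous* step and the adaptation
   increment for the population's own previous spikes.
2. :func:`integrate_membrane` — one forward-Euler step of the membrane and
   threshold equations.
3. :func:`detect_spikes_and_reset` — threshold crossing, reset, refractory
   threshold jump.

Membrane and conductances use plain forward Euler, matching the simulation
scheme the model is defined with; an exact-exponential decay variant for the
conductances can be enabled via ``exact_decay=True``.
"""

from __future__ import annotations

import numpy as np

from .params import NeuronParams

__all__ = [
    "RegionState",
    "integrate_membrane",
    "detect_spikes_and_reset",
    "decay_and_deliver_conductances",
]


class RegionState:
    """Dynamical state vectors of one neuron population.

    Vectors: membrane voltage ``U`` [mV], firing threshold ``theta`` [mV],
    and the nonnegative dimensionless conductances ``g_ampa``, ``g_nmda``,
    ``g_gaba``, ``g_a``.  Length is fixed at construction.
    """

    __slots__ = ("n", "U", "theta", "g_ampa", "g_nmda", "g_gaba", "g_a")

    def __init__(self, n: int, params: NeuronParams):
        if n <= 0:
            raise ValueError("population size must be positive")
        self.n = n
        self.U = np.full(n, params.U_rest, dtype=np.float64)
        self.theta = np.full(n, params.theta_rest, dtype=np.float64)
        self.g_ampa = np.zeros(n)
        self.g_nmda = np.zeros(n)
        self.g_gaba = np.zeros(n)
        self.g_a = np.zeros(n)

    def g_exc(self, params: NeuronParams) -> np.ndarray:
        """Total excitatory conductance: alpha*g_ampa + (1-alpha)*g_nmda."""
        return params.alpha * self.g_ampa + (1.0 - params.alpha) * self.g_nmda

    def _check_finite(self):
        for name in ("U", "theta", "g_ampa", "g_nmda", "g_gaba", "g_a"):
            v = getattr(self, name)
            if not np.all(np.isfinite(v)):
                bad = int(np.flatnonzero(~np.isfinite(v))[0])
                raise FloatingPointError(
                    f"non-finite {name} at neuron index {bad}: {v[bad]!r}"
                )


def integrate_membrane(state: RegionState, params: NeuronParams, dt: float) -> RegionState:
    """One forward-Euler step of the membrane and threshold equations.

    tau_m dU/dt = (U_rest - U) + g_exc (U_exc - U) + (g_gaba + g_a)(U_inh - U)
    tau_thr dtheta/dt = theta_rest - theta

    No spike detection happens here.  The state is modified in place and
    returned.
    """
    if not dt > 0:
        raise ValueError("dt must be > 0")
    state._check_finite()
    g_exc = state.g_exc(params)
    dU = (
        (params.U_rest - state.U)
        + g_exc * (params.U_exc - state.U)
        + (state.g_gaba + state.g_a) * (params.U_inh - state.U)
    )
    state.U += (dt / params.tau_m) * dU
    state.theta += (dt / params.tau_thr) * (params.theta_rest - state.theta)
    return state


def detect_spikes_and_reset(state: RegionState, params: NeuronParams) -> np.ndarray:
    """Return indices of neurons with U > theta; reset them.

    Spikers have their voltage set back to U_rest and their threshold raised
    to theta_spike (it then relaxes back via ``integrate_membrane``).
    """
    spikers = np.flatnonzero(state.U > state.theta)
    if spikers.size:
        state.U[spikers] = params.U_rest
        state.theta[spikers] = params.theta_spike
    return spikers


def decay_and_deliver_conductances(
    state: RegionState,
    params: NeuronParams,
    exc_input: np.ndarray | float,
    inh_input: np.ndarray | float,
    own_spikes: np.ndarray | None,
    dt: float,
    exact_decay: bool = False,
) -> RegionState:
    """Decay conductances and add this step's weighted spike input.

    ``exc_input``/``inh_input`` are per-neuron sums of presynaptic weights
    (already multiplied by the short-term-plasticity factor u*x for
    excitatory synapses).  Weights are nonnegative magnitudes — the sign of
    the current is carried by the reversal potentials — so negative inputs
    are rejected.  ``own_spikes`` are this population's spikes from the
    previous step and drive the adaptation conductance.

    g_ampa decays with tau_ampa and jumps by exc_input; g_nmda low-passes
    g_ampa with tau_nmda; g_gaba decays with tau_gaba and jumps by
    inh_input; g_a decays with tau_a and jumps by Delta_a per own spike.
    """
    if not dt > 0:
        raise ValueError("dt must be > 0")
    exc_input = np.asarray(exc_input, dtype=np.float64)
    inh_input = np.asarray(inh_input, dtype=np.float64)
    if np.any(exc_input < 0) or np.any(inh_input < 0):
        raise ValueError("conductance inputs must be nonnegative magnitudes")
    if exact_decay:
        state.g_ampa *= np.exp(-dt / params.tau_ampa)
        state.g_gaba *= np.exp(-dt / params.tau_gaba)
        state.g_a *= np.exp(-dt / params.tau_a)
    else:
        state.g_ampa *= 1.0 - dt / params.tau_ampa
        state.g_gaba *= 1.0 - dt / params.tau_gaba
        state.g_a *= 1.0 - dt / params.tau_a
    state.g_ampa += exc_input
    state.g_gaba += inh_input
    if own_spikes is not None and len(own_spikes):
        state.g_a[np.asarray(own_spikes)] += params.Delta_a
    # NMDA low-pass reads the already-updated AMPA conductance.
    state.g_nmda += (dt / params.tau_nmda) * (state.g_ampa - state.g_nmda)
    return state
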