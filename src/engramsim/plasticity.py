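"""Synaptic state and learning rules.

Four interacting mechanisms shape excitatory weights:

* **Triplet STDP** — potentiation on a postsynaptic spike proportional to the
  presynaptic trace z+ and the slow postsynaptic trace z_slow; depression on
  a presynaptic spike proportional to the fast postsynaptic trace z- with a
  homeostatically regulated rate B = A*min(C, 1), where C integrates the
  squared homeostatic trace z_ht.
* **Heterosynaptic plasticity** — on a postsynaptic spike every afferent
  weight is pulled toward its reference weight w~ with strength
  beta * (z-)^3, stabilizing runaway potentiation.
* **Transmitter-induced plasticity** — a small increment delta per
  presynaptic spike; this term drives spontaneous engram reactivations.
* **Synaptic consolidation** — each reference weight w~ follows the negative
  gradient of a double-well potential, slowly copying w into a bistable
  long-term variable.

Plus short-term plasticity (per presynaptic neuron) and an inhibitory rule
that steers the local excitatory population rate toward a target.

Spike-triggered rule evaluations read trace values *before* the increment
caused by that same spike ("t - epsilon" semantics); call
:func:`trace_step` after the rule evaluations of a step.  Traces decay with
exact exponential factors (they are linear ODEs); membrane and conductances
elsewhere use forward Euler.
"""

from __future__ import annotations

import numpy as np

from .params import ExcPlasticityParams, InhPlasticityParams, STPParams

__all__ = [
    "STPState",
    "TripletTraces",
    "InhPlasticityState",
    "stp_step",
    "exc_on_pre_spike",
    "exc_on_post_spike",
    "update_homeostasis",
    "consolidate_reference",
    "inh_plasticity_step",
    "trace_step",
]


class STPState:
    """Release variable u and resource x, one pair per presynaptic neuron
    (shared across all efferent synapses of that neuron)."""

    __slots__ = ("u", "x")

    def __init__(self, n: int, params: STPParams):
        self.u = np.full(n, params.U_stp, dtype=np.float64)
        self.x = np.ones(n, dtype=np.float64)


class TripletTraces:
    """Spike traces and homeostatic variables for one population.

    z_plus is a presynaptic trace (indexed by source neuron); z_minus,
    z_slow, z_ht, C live on postsynaptic neurons.  B is derived:
    B = A * min(C, 1).
    """

    __slots__ = ("z_plus", "z_minus", "z_slow", "z_ht", "C")

    def __init__(self, n: int):
        self.z_plus = np.zeros(n)
        self.z_minus = np.zeros(n)
        self.z_slow = np.zeros(n)
        self.z_ht = np.zeros(n)
        self.C = np.zeros(n)

    def B(self, params: ExcPlasticityParams) -> np.ndarray:
        return params.A * np.minimum(self.C, 1.0)


class InhPlasticityState:
    """Region-wide secreted factor H plus pre/post traces z (common tau).

    ``z_pre`` lives on the inhibitory (source) side, ``z_post`` on the
    excitatory (target) side.
    """

    __slots__ = ("H", "z_pre", "z_post")

    def __init__(self, n_pre: int, n_post: int):
        self.H = 0.0
        self.z_pre = np.zeros(n_pre)
        self.z_post = np.zeros(n_post)


def stp_step(state: STPState, params: STPParams, spikes, dt: float) -> STPState:
    """Relax (u, x) toward their fixed point, then apply spike jumps.

    Continuous part (exact exponential relaxation of the linear ODEs):
    x -> 1 with tau_d, u -> U_stp with tau_f.  For each spiking presynaptic
    neuron the delivered efficacy is the *pre-spike* product u*x; then u is
    facilitated first, u += U_stp*(1-u), and x depressed with the updated u,
    x -= u*x.
    """
    if not dt > 0:
        raise ValueError("dt must be > 0")
    ed = np.exp(-dt / params.tau_d)
    ef = np.exp(-dt / params.tau_f)
    state.x = 1.0 + (state.x - 1.0) * ed
    state.u = params.U_stp + (state.u - params.U_stp) * ef
    spikes = np.asarray(spikes, dtype=np.intp)
    if spikes.size:
        u = state.u[spikes]
        u_new = u + params.U_stp * (1.0 - u)
        state.u[spikes] = u_new
        state.x[spikes] -= u_new * state.x[spikes]
    return state


def exc_on_pre_spike(
    proj,
    traces: TripletTraces,
    params: ExcPlasticityParams,
    pre_id: int,
):
    """Presynaptic-spike terms: homeostatic LTD plus transmitter-induced.

    For every synapse (pre_id -> i):
    w += eta_exc * (-B_i * z_minus_i) + delta, then clip to bounds.
    ``proj`` is a :class:`engramsim.network.SparseProjection`.
    """
    lo, hi = proj.row_slice(pre_id)
    tgt = proj.targets[lo:hi]
    B = traces.z_minus[tgt] * params.A * np.minimum(traces.C[tgt], 1.0)
    proj.w[lo:hi] = np.clip(
        proj.w[lo:hi] - params.eta_exc * B + params.delta,
        params.w_min_exc,
        params.w_max_exc,
    )
    return proj.w


def exc_on_post_spike(
    proj,
    traces_pre: TripletTraces,
    traces_post: TripletTraces,
    params: ExcPlasticityParams,
    post_id: int,
):
    """Postsynaptic-spike terms: triplet LTP plus heterosynaptic decay.

    For every synapse (j -> post_id):
    w += eta_exc * A * z_plus_j * z_slow_post - beta * (w - w~) * z_minus_post^3
    with z_slow and z_minus read before this spike's own increment.
    """
    syn = proj.afferent_synapses(post_id)
    src = proj.afferent_sources(post_id)
    zslow = traces_post.z_slow[post_id]
    zm3 = traces_post.z_minus[post_id] ** 3
    dw = (
        params.eta_exc * params.A * traces_pre.z_plus[src] * zslow
        - params.beta * (proj.w[syn] - proj.w_tilde[syn]) * zm3
    )
    proj.w[syn] = np.clip(proj.w[syn] + dw, params.w_min_exc, params.w_max_exc)
    return proj.w


def update_homeostasis(
    traces: TripletTraces,
    params: ExcPlasticityParams,
    post_spikes,
    dt: float,
) -> TripletTraces:
    """Integrate the homeostatic variable C from the squared trace z_ht.

    dC/dt = -C/tau_hom + (z_ht)^2, discretized as exact-exponential leak
    plus an Euler source term.  The LTD rate is B = A*C clipped at A.
    ``post_spikes`` is accepted for interface symmetry; z_ht itself is
    maintained by :func:`trace_step`.
    """
    if not dt > 0:
        raise ValueError("dt must be > 0")
    traces.C = traces.C * np.exp(-dt / params.tau_hom) + dt * traces.z_ht**2
    return traces


def double_well_drift(w, w_tilde, params: ExcPlasticityParams):
    """Right-hand side of the reference-weight dynamics (times tau_cons):

    w - w~ - P * w~ * (w_P/2 - w~) * (w_P - w~)
    """
    wt = np.asarray(w_tilde, dtype=np.float64)
    return (
        np.asarray(w, dtype=np.float64)
        - wt
        - params.P * wt * (params.w_P / 2.0 - wt) * (params.w_P - wt)
    )


def consolidate_reference(proj, params: ExcPlasticityParams, dt_long: float):
    """One Euler step (step dt_long) of the double-well reference dynamics.

    Invoked on a long timestep (default 1.2 s), not every simulation step;
    w~ is frozen in between.  Aborts if the update is numerically unstable.
    """
    if not dt_long > 0:
        raise ValueError("dt_long must be > 0")
    proj.w_tilde += (dt_long / params.tau_cons) * double_well_drift(
        proj.w, proj.w_tilde, params
    )
    if not np.all(np.isfinite(proj.w_tilde)) or np.any(np.abs(proj.w_tilde) > 1e6):
        raise FloatingPointError(
            "reference-weight update diverged; decrease dt_long/tau_cons "
            f"(currently {dt_long / params.tau_cons:.3g})"
        )
    return proj.w_tilde


def inh_plasticity_step(
    proj,
    state: InhPlasticityState,
    params: InhPlasticityParams,
    pre_spikes,
    post_spikes,
    region_exc_spike_count: int,
    dt: float,
):
    """Inhibitory plasticity driven by the region-wide activity gap G = H - gamma.

    H low-passes *all* excitatory spikes of the region (tau_H) regardless of
    connectivity.  Per presynaptic (inhibitory) spike on synapse (j -> i):
    w += eta_inh * G * (z_i + 1); per postsynaptic (excitatory) spike:
    w += eta_inh * G * z_j.  Traces z are maintained by :func:`trace_step`
    on both populations with the common tau_istdp.

    Order within a step: H decays, G is evaluated, spike terms apply, then H
    absorbs this step's excitatory spikes (so rule evaluations use the
    pre-increment H, consistent with the trace convention).
    """
    if not dt > 0:
        raise ValueError("dt must be > 0")
    state.H *= np.exp(-dt / params.tau_H)
    G = state.H - params.gamma
    z_post = state.z_post  # per-target trace array (excitatory side)
    z_pre = state.z_pre    # per-source trace array (inhibitory side)
    for j in np.asarray(pre_spikes, dtype=np.intp):
        lo, hi = proj.row_slice(j)
        tgt = proj.targets[lo:hi]
        proj.w[lo:hi] = np.clip(
            proj.w[lo:hi] + params.eta_inh * G * (z_post[tgt] + 1.0),
            params.w_min_inh,
            params.w_max_inh,
        )
    for i in np.asarray(post_spikes, dtype=np.intp):
        syn = proj.afferent_synapses(i)
        src = proj.afferent_sources(i)
        proj.w[syn] = np.clip(
            proj.w[syn] + params.eta_inh * G * z_pre[src],
            params.w_min_inh,
            params.w_max_inh,
        )
    state.H += float(region_exc_spike_count)
    return proj.w, state.H


def trace_step(traces, taus: dict, spikes: dict, dt: float):
    """Decay every trace by its exact exponential factor, then add this
    step's spike increments (+1 per spike).

    ``traces`` maps name -> array, ``taus`` name -> time constant,
    ``spikes`` name -> index array of neurons whose trace increments.
    Rule evaluations triggered by the same spikes must run *before* this
    call ("t - epsilon" semantics).
    """
    if not dt > 0:
        raise ValueError("dt must be > 0")
    for name, z in traces.items():
        z *= np.exp(-dt / taus[name])
        idx = spikes.get(name)
        if idx is not None and len(idx):
            np.add.at(z, np.asarray(idx, dtype=np.intp), 1.0)
    return traces
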