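"""Parameter containers for neurons, synapses and plasticity rules.

All conductances are dimensionless multiples of the leak conductance, so
synaptic weights are dimensionless as well.  Voltages are in mV, times in
seconds unless a field name says otherwise.  Defaults are the package's
desk-scale operating point; every value can be overridden from a config
file (see :mod:`engramsim.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace


def _check_positive(obj, names):
    for n in names:
        v = getattr(obj, n)
        if not v > 0:
            raise ValueError(f"{type(obj).__name__}.{n} must be > 0, got {v!r}")


@dataclass
class NeuronParams:
    """Leaky integrate-and-fire neuron with adaptive threshold and
    conductance-based AMPA/NMDA/GABA input plus spike-triggered adaptation.

    ``alpha`` weights the fast AMPA-like conductance against the slow
    NMDA-like conductance in the total excitatory conductance
    ``g_exc = alpha * g_ampa + (1 - alpha) * g_nmda``.
    """

    tau_m: float = 20e-3          # membrane time constant [s]
    U_rest: float = -60.0         # resting potential [mV]
    U_exc: float = 0.0            # excitatory reversal potential [mV]
    U_inh: float = -80.0          # inhibitory reversal potential [mV]
    theta_rest: float = -50.0     # resting firing threshold [mV]
    theta_spike: float = -20.0    # post-spike threshold [mV]
    tau_thr: float = 5e-3         # threshold decay time constant [s]
    alpha: float = 0.5            # AMPA fraction of excitatory conductance
    tau_ampa: float = 5e-3        # AMPA decay [s]
    tau_nmda: float = 100e-3      # NMDA low-pass [s]
    tau_gaba: float = 10e-3       # GABA decay [s]
    tau_a: float = 200e-3         # adaptation decay [s]
    Delta_a: float = 0.05         # adaptation conductance increment per spike

    def __post_init__(self):
        _check_positive(
            self, ["tau_m", "tau_thr", "tau_ampa", "tau_nmda", "tau_gaba", "tau_a"]
        )
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")
        if not self.U_exc > self.U_rest:
            raise ValueError("U_exc must exceed U_rest")
        if not (self.U_inh <= self.U_rest < self.theta_rest):
            raise ValueError("require U_inh <= U_rest < theta_rest")
        if self.Delta_a < 0:
            raise ValueError("Delta_a must be >= 0")

    def with_(self, **kw) -> "NeuronParams":
        return replace(self, **kw)


@dataclass
class STPParams:
    """Short-term plasticity (per presynaptic neuron): depression resource x
    relaxing to 1 with tau_d, facilitation variable u relaxing to the initial
    release probability U_stp with tau_f.  Delivered efficacy is u*x."""

    U_stp: float = 0.1
    tau_d: float = 20e-3   # depression recovery [s]
    tau_f: float = 600e-3   # facilitation decay [s]

    def __post_init__(self):
        _check_positive(self, ["tau_d", "tau_f"])
        if not 0.0 < self.U_stp <= 1.0:
            raise ValueError("U_stp must lie in (0, 1]")


@dataclass
class ExcPlasticityParams:
    """Long-term excitatory plasticity: triplet STDP with a homeostatically
    regulated depression rate, heterosynaptic decay toward a consolidated
    reference weight, and transmitter-induced potentiation; plus the slow
    bistable (double-well) dynamics of the reference weight itself.

    ``eta_exc`` scales only the Hebbian (triplet) term; the heterosynaptic
    strength ``beta`` and transmitter-induced strength ``delta`` act
    independently of it.
    """

    eta_exc: float = 1.0
    A: float = 1e-3               # LTP rate (and ceiling of the LTD rate B)
    beta: float = 20.0e-3         # heterosynaptic strength
    delta: float = 5e-5           # weight increment per presynaptic spike
    tau_plus: float = 30e-3     # presynaptic trace z+ [s]
    tau_minus: float = 20e-3    # fast postsynaptic trace z- [s]
    tau_slow: float = 150e-3      # slow postsynaptic trace z_slow [s]
    tau_ht: float = 30e-3        # homeostatic trace z_ht [s]
    tau_hom: float = 20.0        # homeostatic integrator C [s]
    tau_cons: float = 180.0       # reference-weight consolidation [s]
    P: float = 10.0               # double-well magnitude
    w_P: float = 1.0              # double-well upper-well scale
    w_min_exc: float = 0.0
    w_max_exc: float = 5.0

    def __post_init__(self):
        _check_positive(
            self,
            ["tau_plus", "tau_minus", "tau_slow", "tau_ht", "tau_hom", "tau_cons"],
        )
        for n in ("eta_exc", "A", "beta", "delta"):
            if getattr(self, n) < 0:
                raise ValueError(f"{n} must be >= 0")
        if not self.w_min_exc < self.w_max_exc:
            raise ValueError("w_min_exc must be < w_max_exc")


@dataclass
class InhPlasticityParams:
    """Inhibitory plasticity onto excitatory cells, gated by the gap between
    a region-wide low-pass of all excitatory spiking, H, and a target level
    gamma (``G = H - gamma``).  With H in units of spikes filtered at tau_H,
    the steady state of H is N_exc * rate * tau_H, so gamma encodes a target
    population rate."""

    eta_inh: float = 2e-7
    gamma: float = 10240.0        # target activity level [spikes * tau_H]
    tau_H: float = 10.0           # secreted-factor low-pass [s]
    tau_istdp: float = 20e-3      # pre/post trace time constant [s]
    w_min_inh: float = 0.0
    w_max_inh: float = 10.0

    def __post_init__(self):
        _check_positive(self, ["tau_H", "tau_istdp"])
        if self.eta_inh < 0:
            raise ValueError("eta_inh must be >= 0")
        if not self.w_min_inh < self.w_max_inh:
            raise ValueError("w_min_inh must be < w_max_inh")

    @staticmethod
    def gamma_for_rate(n_exc: int, rate_hz: float, tau_H: float = 10.0) -> float:
        """Target level gamma corresponding to a mean population rate."""
        return n_exc * rate_hz * tau_H


def asdict_flat(obj) -> dict:
    """Dataclass -> plain dict (for manifests and config round-trips)."""
    return {f.name: getattr(obj, f.name) for f in fields(obj)}
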