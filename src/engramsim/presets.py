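"""Network and protocol presets for the model's standard configurations.

Each preset returns a ``(NetworkSpec, ProtocolSchedule, stimulus_kind)``
triple.  Two scales are provided:

* ``desk`` — 512 excitatory / 128 inhibitory neurons per region, a 1024-cell
  (32 x 32) stimulus grid and minutes of simulated consolidation.  All slow
  plasticity timescales (synaptic consolidation, homeostatic integration)
  are compressed by the same factor as the protocol durations, so the desk
  runs traverse the full consolidation trajectory.  These are the package's
  standard operating conditions for tests and analyses.
* ``paper`` — 4096/1024 neurons per region, a 64 x 64 grid and hour-scale
  phases (cluster-scale; provided for completeness, not exercised by the
  test suite).

Available presets: ``two_region`` (unconnected HPC + CTX), the HPC->CTX
connected variants (plastic, static, bidirectional), ``three_region``
(HPC -> THL -> CTX), ``three_region_rdt`` (a readout region downstream of
CTX) and ``two_cortex_reentrant`` (two reciprocally connected cortical
regions).
"""

from __future__ import annotations

from dataclasses import replace

from .network import NetworkSpec, ProjectionSpec, RegionSpec
from .params import (
    ExcPlasticityParams,
    InhPlasticityParams,
    NeuronParams,
    STPParams,
)
from .protocol import ProtocolSchedule

__all__ = ["make_preset", "PRESETS", "desk_region"]


def desk_region(
    name: str,
    n_exc: int = 512,
    n_inh: int = 128,
    eta_exc: float = 1.0,
    eta_inh: float = 4e-4,
    tau_cons: float = 180.0,
    target_rate: float = 3.0,
) -> RegionSpec:
    """Region with desk-scale defaults; gamma follows the target rate."""
    inh = InhPlasticityParams(
        eta_inh=eta_inh,
        gamma=InhPlasticityParams.gamma_for_rate(n_exc, target_rate),
    )
    exc = ExcPlasticityParams(eta_exc=eta_exc, tau_cons=tau_cons)
    return RegionSpec(
        name,
        N_exc=n_exc,
        N_inh=n_inh,
        exc_plasticity=exc,
        inh_plasticity=inh,
    )


def _scale_sizes(scale):
    if scale == "desk":
        return dict(n_exc=512, n_inh=128, N_stim=1024, dt=5e-4)
    if scale == "mini":
        # half-size regions on the same stimulus grid, for the slowest
        # multi-trial experiments; doubled recurrent density keeps the
        # recurrent and inhibitory in-degrees of the desk scale
        return dict(n_exc=256, n_inh=64, N_stim=1024, dt=5e-4)
    if scale == "paper":
        return dict(n_exc=4096, n_inh=1024, N_stim=4096, dt=1e-4)
    raise ValueError(f"unknown scale {scale!r}")


def _desk_schedule(**kw) -> ProtocolSchedule:
    base = dict(
        T_burn=30.0,
        T_training=300.0,
        T_consolidation=600.0,
        T_testing=60.0,
        T_on_training=2.0,
        T_off_training=2.0,
        T_on_testing=1.0,
        T_off_testing=2.0,
        nu_bg=5.0,
        nu_stim=50.0,
        nu_cons=5.0,
        nu_ext_cons=5.0,
        dt_eng=60.0,
    )
    base.update(kw)
    return ProtocolSchedule(**base)


def _paper_schedule(**kw) -> ProtocolSchedule:
    base = dict(
        T_burn=300.0,
        T_training=3600.0,
        T_consolidation=43200.0,
        T_testing=600.0,
        dt_eng=300.0,
        nu_bg=5.0,
        nu_stim=50.0,
        nu_cons=5.0,
        nu_ext_cons=5.0,
    )
    base.update(kw)
    return ProtocolSchedule(**base)


# desk-scale plasticity operating point (see docs/methods.md)
_ETA_HPC = 2.5
_ETA_CTX = 0.12
_ETA_INH_HPC = 1.0e-6
_ETA_INH_CTX = 0.7e-6
_TAU_CONS_FAST = 120.0     # THL, CTX and their projections [s]
_TAU_CONS_HPC = 1800.0     # HPC recurrent / STIM->HPC [s]


def two_region(seed=0, scale="desk", hpc_to_ctx=None):
    """Unconnected HPC and CTX driven by a shared stimulus population.

    ``hpc_to_ctx``: None (no connection), "plastic", "static" (stp-only) or
    "bidirectional" (plastic both ways).
    """
    s = _scale_sizes(scale)
    hpc = desk_region("HPC", s["n_exc"], s["n_inh"], _ETA_HPC, _ETA_INH_HPC,
                      _TAU_CONS_HPC)
    ctx = desk_region("CTX", s["n_exc"], s["n_inh"], _ETA_CTX, _ETA_INH_CTX,
                      _TAU_CONS_FAST)
    projections = [
        ProjectionSpec("STIM", "HPC", eps_ff=0.05, w_init=1.0,
                       plasticity="stp+longterm", tau_cons=_TAU_CONS_HPC),
        ProjectionSpec("STIM", "CTX", eps_ff=0.05, w_init=1.0,
                       plasticity="stp+longterm", tau_cons=_TAU_CONS_FAST),
    ]
    if hpc_to_ctx is not None:
        plast = "stp-only" if hpc_to_ctx == "static" else "stp+longterm"
        projections.append(
            ProjectionSpec("HPC", "CTX", eps_ff=0.1, w_init=0.05,
                           plasticity=plast, tau_cons=_TAU_CONS_FAST,
                           eta_exc=_ETA_CTX)
        )
        if hpc_to_ctx == "bidirectional":
            projections.append(
                ProjectionSpec("CTX", "HPC", eps_ff=0.1, w_init=0.05,
                               plasticity="stp+longterm",
                               tau_cons=_TAU_CONS_FAST, eta_exc=_ETA_CTX)
            )
    if scale == "mini":
        for r in (hpc, ctx):
            r.eps_rec = 0.2
    spec = NetworkSpec(
        regions=[hpc, ctx],
        projections=projections,
        N_stim=s["N_stim"],
        master_seed=seed,
        dt=s["dt"],
    )
    sched = _paper_schedule() if scale == "paper" else _desk_schedule()
    return spec, sched, "random-nonoverlapping"


def three_region(seed=0, scale="desk", beta_thl_ctx_factor=1.0):
    """HPC -> THL -> CTX chain with receptive-field stimulus input.

    STIM->THL is static (developmentally fixed receptive fields);
    STIM->HPC is plastic with the longest consolidation timescale.  During
    consolidation STIM is silent and two external Poisson populations drive
    HPC and CTX independently.  ``beta_thl_ctx_factor`` scales the
    heterosynaptic strength of THL->CTX (the retrograde-amnesia knob).
    """
    s = _scale_sizes(scale)
    hpc = desk_region("HPC", s["n_exc"], s["n_inh"], _ETA_HPC, _ETA_INH_HPC,
                      _TAU_CONS_FAST)
    thl = desk_region("THL", s["n_exc"], s["n_inh"], _ETA_HPC, _ETA_INH_HPC,
                      _TAU_CONS_FAST)
    ctx = desk_region("CTX", s["n_exc"], s["n_inh"], _ETA_CTX, _ETA_INH_CTX,
                      _TAU_CONS_FAST)
    grid_side = int(round(s["N_stim"] ** 0.5))
    radius = grid_side / 10.0
    ctx_beta = ctx.exc_plasticity.beta
    projections = [
        ProjectionSpec("STIM", "HPC", kind="circular-receptive-field",
                       radius=radius, w_init=0.12, plasticity="stp+longterm",
                       tau_cons=_TAU_CONS_HPC),
        ProjectionSpec("STIM", "THL", kind="circular-receptive-field",
                       radius=radius, w_init=0.3, plasticity="static"),
        ProjectionSpec("HPC", "THL", eps_ff=0.1, w_init=0.15,
                       plasticity="stp+longterm", eta_exc=_ETA_HPC,
                       tau_cons=_TAU_CONS_FAST),
        ProjectionSpec("THL", "CTX", eps_ff=0.2, w_init=0.5,
                       plasticity="stp+longterm", eta_exc=_ETA_CTX,
                       tau_cons=_TAU_CONS_FAST,
                       beta=ctx_beta * beta_thl_ctx_factor),
    ]
    if scale == "mini":
        for r in (hpc, thl, ctx):
            r.eps_rec = 0.2
    n_ext = s["N_stim"]
    spec = NetworkSpec(
        regions=[hpc, thl, ctx],
        projections=projections,
        N_stim=s["N_stim"],
        external={"HPC": (n_ext, 0.05, 0.1), "CTX": (n_ext, 0.05, 0.1)},
        master_seed=seed,
        dt=s["dt"],
    )
    sched_kw = dict(stim_silent_consolidation=True)
    sched = (
        _paper_schedule(**sched_kw) if scale == "paper" else _desk_schedule(**sched_kw)
    )
    return spec, sched, "horizontal-bars"


def three_region_rdt(seed=0, scale="desk"):
    """Three-region chain plus a readout region downstream of CTX."""
    spec, sched, kind = three_region(seed, scale)
    s = _scale_sizes(scale)
    rdt = desk_region("RDT", s["n_exc"], s["n_inh"], _ETA_CTX, _ETA_INH_CTX,
                      _TAU_CONS_FAST)
    spec.regions.append(rdt)
    spec.projections.append(
        ProjectionSpec("CTX", "RDT", eps_ff=0.1, w_init=0.05,
                       plasticity="stp+longterm", eta_exc=_ETA_CTX,
                       tau_cons=_TAU_CONS_FAST)
    )
    return spec, sched, kind


def two_cortex_reentrant(seed=0, scale="desk"):
    """Two reciprocally connected cortical regions (no hippocampus)."""
    s = _scale_sizes(scale)
    c1 = desk_region("CTXa", s["n_exc"], s["n_inh"], _ETA_CTX, _ETA_INH_CTX,
                     _TAU_CONS_FAST)
    c2 = desk_region("CTXb", s["n_exc"], s["n_inh"], _ETA_CTX, _ETA_INH_CTX,
                     _TAU_CONS_FAST)
    projections = [
        ProjectionSpec("STIM", "CTXa", eps_ff=0.1, w_init=0.3,
                       plasticity="stp+longterm", tau_cons=_TAU_CONS_FAST),
        ProjectionSpec("STIM", "CTXb", eps_ff=0.1, w_init=0.3,
                       plasticity="stp+longterm", tau_cons=_TAU_CONS_FAST),
        ProjectionSpec("CTXa", "CTXb", eps_ff=0.1, w_init=0.05,
                       plasticity="stp+longterm", eta_exc=_ETA_CTX,
                       tau_cons=_TAU_CONS_FAST),
        ProjectionSpec("CTXb", "CTXa", eps_ff=0.1, w_init=0.05,
                       plasticity="stp+longterm", eta_exc=_ETA_CTX,
                       tau_cons=_TAU_CONS_FAST),
    ]
    spec = NetworkSpec(
        regions=[c1, c2], projections=projections, N_stim=s["N_stim"],
        master_seed=seed, dt=s["dt"],
    )
    sched = _desk_schedule() if scale == "desk" else _paper_schedule()
    return spec, sched, "random-nonoverlapping"


PRESETS = {
    "two_region": two_region,
    "two_region_hpc_to_ctx": lambda seed=0, scale="desk": two_region(
        seed, scale, hpc_to_ctx="plastic"
    ),
    "two_region_hpc_to_ctx_static": lambda seed=0, scale="desk": two_region(
        seed, scale, hpc_to_ctx="static"
    ),
    "two_region_bidirectional": lambda seed=0, scale="desk": two_region(
        seed, scale, hpc_to_ctx="bidirectional"
    ),
    "three_region": three_region,
    "three_region_rdt": three_region_rdt,
    "two_cortex_reentrant": two_cortex_reentrant,
}


def make_preset(name: str, seed: int = 0, scale: str = "desk", **kw):
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    return PRESETS[name](seed=seed, scale=scale, **kw)
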