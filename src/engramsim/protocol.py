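"""Stimuli, phase scheduling, Poisson drive and protocol execution.

A simulation follows the four-phase structure burn-in -> training ->
consolidation -> testing.  During training, full stimulus patterns are
presented in random order with exponentially distributed on/off intervals;
during testing, partial cues (50% of a stimulus) are presented the same
way.  Testing at intermediate consolidation times runs on a *forked* copy
of the network state, so probing recall never perturbs the ongoing
consolidation trajectory.  Plasticity stays on in every phase, including
testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np

from .engine import Simulator

__all__ = [
    "StimulusSet",
    "ProtocolSchedule",
    "Manipulation",
    "make_stimuli",
    "schedule_events",
    "poisson_drive",
    "apply_manipulation",
    "run_protocol",
    "RunResult",
]


@dataclass
class StimulusSet:
    """Active source-index sets and cue subsets, one per stimulus."""

    kind: str
    n_source: int
    active: list          # list of int arrays (full patterns)
    cues: list            # list of int arrays (partial cues)

    @property
    def n_stimuli(self) -> int:
        return len(self.active)


def make_stimuli(
    kind: str,
    N_stim: int,
    n_stimuli: int,
    rng: np.random.Generator,
    fraction: float = 0.25,
    cue_fraction: float = 0.5,
    grid_side: Optional[int] = None,
) -> StimulusSet:
    """Build training stimuli and their partial cues.

    ``random-nonoverlapping``: each stimulus is a 25% subset of STIM, all
    pairwise disjoint; cue = random 50% of the stimulus.
    ``random-overlapping``: each stimulus drawn independently (expected
    pairwise overlap = 25% of a stimulus); cue = random 50%.
    ``horizontal-bars``: the grid's rows are split into ``n_stimuli`` equal
    horizontal bars; cue = the central 50% of each bar's columns at full bar
    height.
    """
    if kind in ("random-nonoverlapping", "random-overlapping"):
        size = int(round(fraction * N_stim))
        if kind == "random-nonoverlapping":
            if n_stimuli * size > N_stim:
                raise ValueError(
                    f"cannot draw {n_stimuli} disjoint subsets of {size} from {N_stim}"
                )
            perm = rng.permutation(N_stim)
            active = [np.sort(perm[i * size : (i + 1) * size]) for i in range(n_stimuli)]
        else:
            active = [
                np.sort(rng.choice(N_stim, size=size, replace=False))
                for _ in range(n_stimuli)
            ]
        cues = [
            np.sort(rng.choice(a, size=int(round(cue_fraction * len(a))), replace=False))
            for a in active
        ]
    elif kind == "horizontal-bars":
        side = grid_side or int(round(N_stim**0.5))
        if side * side != N_stim:
            raise ValueError("horizontal bars require a square STIM grid")
        if side % n_stimuli:
            raise ValueError("grid side must divide evenly into bars")
        rows_per_bar = side // n_stimuli
        c0, c1 = side // 4, 3 * side // 4  # central 50% of columns
        active, cues = [], []
        for b in range(n_stimuli):
            rows = np.arange(b * rows_per_bar, (b + 1) * rows_per_bar)
            bar = (rows[:, None] * side + np.arange(side)[None, :]).ravel()
            cue = (rows[:, None] * side + np.arange(c0, c1)[None, :]).ravel()
            active.append(np.sort(bar))
            cues.append(np.sort(cue))
    else:
        raise ValueError(f"unknown stimulus kind {kind!r}")
    return StimulusSet(kind, N_stim, active, cues)


def schedule_events(
    duration: float,
    T_on: float,
    T_off: float,
    n_stimuli: int,
    rng: np.random.Generator,
) -> list[tuple[int, float, float]]:
    """Alternating off/on intervals with exponential durations.

    Returns ordered (stimulus id, on-time, off-time) tuples truncated at the
    phase end; identities are uniform over the stimulus set.
    """
    events = []
    t = 0.0
    while True:
        t += rng.exponential(T_off)
        if t >= duration:
            break
        on = rng.exponential(T_on)
        sid = int(rng.integers(n_stimuli))
        t_end = min(t + on, duration)
        if t_end > t:
            events.append((sid, t, t_end))
        t = t_end
        if t >= duration:
            break
    return events


def poisson_drive(
    active_set,
    rate_active: float,
    rate_background: float,
    n_neurons: int,
    duration: float,
    dt: float,
    rng: np.random.Generator,
):
    """Bernoulli(rate*dt) spikes for a Poisson population.

    Returns (step, neuron) arrays.  The active subset fires at
    ``rate_active``; everyone else at ``rate_background``.
    """
    if rate_active < 0 or rate_background < 0:
        raise ValueError("rates must be >= 0")
    if max(rate_active, rate_background) * dt >= 1.0:
        raise ValueError("rate * dt >= 1: rate too high for this timestep")
    n_steps = int(round(duration / dt))
    rates = np.full(n_neurons, rate_background, dtype=np.float64)
    rates[np.asarray(active_set, dtype=np.intp)] = rate_active
    m = rng.random((n_steps, n_neurons)) < rates * dt
    step, idx = np.nonzero(m)
    return step.astype(np.int64), idx.astype(np.int32)


# ---------------------------------------------------------------------------


@dataclass
class ProtocolSchedule:
    """Durations, interval statistics and drive rates of the four phases.

    ``nu_ext_bg`` is fixed at 0: external consolidation populations are
    silent outside the consolidation phase.  ``stim_silent_consolidation``
    switches the consolidation drive from STIM background (two-region
    layout) to the external populations (three-region layout).
    """

    T_burn: float = 30.0
    T_training: float = 120.0
    T_consolidation: float = 600.0
    T_testing: float = 60.0
    T_on_training: float = 1.0
    T_off_training: float = 2.0
    T_on_testing: float = 1.0
    T_off_testing: float = 2.0
    nu_bg: float = 5.0            # STIM background rate [Hz]
    nu_stim: float = 100.0        # stimulus/cue rate [Hz]
    nu_cons: float = 5.0          # STIM rate during consolidation [Hz]
    nu_ext_cons: float = 10.0     # external drive during consolidation [Hz]
    nu_ext_bg: float = 0.0        # external drive outside consolidation
    stim_silent_consolidation: bool = False
    test_points: tuple = (0.0,)   # consolidation times at which to test
    dt_eng: float = 60.0          # labeling window at end of training [s]
    zeta_thr: float = 10.0        # engram threshold [Hz]
    activity_bin: float = 10e-3   # population-activity resolution [s]

    def __post_init__(self):
        for n in ("T_burn", "T_training", "T_consolidation", "T_testing"):
            if getattr(self, n) < 0:
                raise ValueError(f"{n} must be >= 0")
        if self.nu_ext_bg != 0.0:
            raise ValueError("external populations are silent outside consolidation")
        if any(tp < 0 or tp > self.T_consolidation for tp in self.test_points):
            raise ValueError("test points must lie within the consolidation phase")


@dataclass
class Manipulation:
    """A blocking / ablation / plasticity manipulation.

    kinds: ``block-engram-output`` (mask inter-region efferents of listed
    excitatory engram cells; recurrent synapses untouched),
    ``block-inhibitory-neurons`` (mask all efferents of listed inhibitory
    cells), ``block-inhibitory-engrams`` (same masking, applied to
    inhibitory engram cells), ``ablate-region`` (remove the region and all
    its afferent/efferent projections), ``ablate-plasticity-term`` (zero
    exactly one of A/beta/delta, or freeze the inhibitory rule), and
    ``scale-beta`` (multiply beta of one projection).
    ``phase``: "testing", "consolidation" or "all".
    """

    kind: str
    region: Optional[str] = None
    projection: Optional[str] = None
    neurons: Optional[np.ndarray] = None   # local indices within the population
    term: Optional[str] = None             # 'A' | 'beta' | 'delta' | 'inh'
    factor: float = 1.0
    phase: str = "testing"

    KINDS = (
        "block-engram-output",
        "block-inhibitory-neurons",
        "block-inhibitory-engrams",
        "ablate-region",
        "ablate-plasticity-term",
        "scale-beta",
    )

    def __post_init__(self):
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown manipulation kind {self.kind!r}")


def apply_manipulation(sim: Simulator, m: Manipulation) -> Simulator:
    """Apply a manipulation to a simulator in place (masks and removals)."""
    proj_names = list(sim.projections)
    if m.kind == "block-engram-output":
        pop = sim.pops[f"{m.region}.exc"]
        for i, p in enumerate(sim._projs):
            inter_region = "->" in p["name"]
            if inter_region and p["src_kind"] == 0 and p["src_off"] == pop.offset:
                sim.set_blocked(p["name"], m.neurons, True)
    elif m.kind in ("block-inhibitory-neurons", "block-inhibitory-engrams"):
        pop = sim.pops[f"{m.region}.inh"]
        neurons = (
            m.neurons
            if m.neurons is not None
            else np.arange(pop.n)
        )
        for p in sim._projs:
            if p["src_kind"] == 0 and p["src_off"] == pop.offset:
                sim.set_blocked(p["name"], neurons, True)
    elif m.kind == "ablate-region":
        for pop_name in (f"{m.region}.exc", f"{m.region}.inh"):
            pop = sim.pops[pop_name]
            sim.set_enabled(pop_name, np.arange(pop.n), False)
            for p in sim._projs:
                efferent = p["src_kind"] == 0 and p["src_off"] == pop.offset
                afferent = p["tgt0"] == pop.offset and p["n_tgt"] == pop.n
                if efferent or afferent:
                    sim.set_blocked(p["name"], np.arange(p["n_src"]), True)
    elif m.kind == "ablate-plasticity-term":
        targets = [m.projection] if m.projection else [
            p["name"] for p in sim._projs
        ]
        for name in targets:
            i = [p["name"] for p in sim._projs].index(name)
            if m.term == "A" and sim.P_kind[i] == 2:
                sim.P_A[i] = 0.0
            elif m.term == "beta" and sim.P_kind[i] == 2:
                sim.P_beta[i] = 0.0
            elif m.term == "delta" and sim.P_kind[i] == 2:
                sim.P_delta[i] = 0.0
            elif m.term == "inh" and sim.P_kind[i] == 3:
                sim.P_eta[i] = 0.0
    elif m.kind == "scale-beta":
        sim.scale_param(m.projection, "beta", m.factor)
    return sim


# ---------------------------------------------------------------------------


class SpikeBuffer:
    """Accumulates (step, neuron) chunks; converts to a raster on demand."""

    def __init__(self):
        self.steps = []
        self.ids = []

    def __call__(self, step, idx):
        self.steps.append(step.copy())
        self.ids.append(idx.copy())

    def arrays(self):
        if not self.steps:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int32)
        return np.concatenate(self.steps), np.concatenate(self.ids)


class BinnedActivity:
    """Online per-subset binned spike counts (10 ms default resolution).

    ``subsets`` maps name -> global neuron index array; a neuron may appear
    in several subsets.
    """

    def __init__(self, subsets: dict, n_neurons_total: int, step0: int,
                 n_steps: int, dt: float, bin_width: float):
        self.names = list(subsets)
        self.step0 = step0
        self.dt = dt
        self.bin_width = bin_width
        self.steps_per_bin = max(1, int(round(bin_width / dt)))
        self.n_bins = int(np.ceil(n_steps / self.steps_per_bin))
        self.counts = np.zeros((len(self.names), self.n_bins))
        self.sizes = np.array([len(subsets[k]) for k in self.names])
        self.masks = np.zeros((len(self.names), n_neurons_total), dtype=bool)
        for i, k in enumerate(self.names):
            self.masks[i, subsets[k]] = True

    def __call__(self, step, idx):
        b = (step - self.step0) // self.steps_per_bin
        ok = (b >= 0) & (b < self.n_bins)
        b, idx = b[ok], idx[ok]
        for i in range(len(self.names)):
            sel = self.masks[i, idx]
            if sel.any():
                np.add.at(self.counts[i], b[sel], 1.0)

    def rates(self) -> dict:
        """name -> population rate series [Hz]."""
        out = {}
        for i, k in enumerate(self.names):
            denom = max(self.sizes[i], 1) * self.bin_width
            out[k] = self.counts[i] / denom
        return out


class _Tee:
    def __init__(self, *sinks):
        self.sinks = [s for s in sinks if s is not None]

    def __call__(self, step, idx):
        for s in self.sinks:
            s(step, idx)


@dataclass
class RunResult:
    """Artifacts of one protocol run."""

    labels: dict = field(default_factory=dict)        # region -> list of index arrays
    inh_labels: dict = field(default_factory=dict)
    metrics: list = field(default_factory=list)       # rows of per-test-point metrics
    consolidation_rates: dict = field(default_factory=dict)  # name -> Hz series
    consolidation_bin: float = 10e-3
    weight_snapshots: dict = field(default_factory=dict)     # (proj, time) -> DataFrame
    training_raster: Optional[tuple] = None
    test_rasters: dict = field(default_factory=dict)  # cons_time -> (steps, ids, events)
    manifest: dict = field(default_factory=dict)


def _stim_rates(sim, stimuli, sid, schedule, cue=False):
    rates = np.full(sim.pois["STIM"].n, schedule.nu_bg)
    idx = stimuli.cues[sid] if cue else stimuli.active[sid]
    rates[idx] = schedule.nu_stim
    return rates


def _run_phase_events(sim, stimuli, schedule, duration, T_on, T_off, cue, sink):
    """Drive one event-structured phase; returns the realized event list."""
    events = schedule_events(
        duration, T_on, T_off, stimuli.n_stimuli, sim.rng_protocol
    )
    t0 = sim.t
    cursor = 0.0
    bg = np.full(sim.pois["STIM"].n, schedule.nu_bg)
    for sid, on, off in events:
        if on > cursor:
            sim.set_rate("STIM", bg)
            sim.run(on - cursor, sink)
        sim.set_rate("STIM", _stim_rates(sim, stimuli, sid, schedule, cue))
        sim.run(off - on, sink)
        cursor = off
    if duration > cursor:
        sim.set_rate("STIM", bg)
        sim.run(duration - cursor, sink)
    return [(sid, t0 + a, t0 + b) for sid, a, b in events]


def run_protocol(
    sim: Simulator,
    stimuli: StimulusSet,
    schedule: ProtocolSchedule,
    manipulations: list = (),
    snapshot_projections: list = (),
    keep_test_rasters: bool = False,
) -> RunResult:
    """Execute burn-in -> training -> consolidation with forked test phases.

    Engram cells are labeled from the final ``dt_eng`` of training; at every
    configured consolidation test point the state is forked, testing-phase
    manipulations are applied to the fork, partial cues are presented and
    recall metrics computed; consolidation then continues from the unforked
    state.  Returns a :class:`RunResult`.
    """
    from . import analysis

    res = RunResult()
    dt = sim.dt
    exc_pops = {r: sim.pops[f"{r}.exc"] for r in sim.regions}
    inh_pops = {r: sim.pops[f"{r}.inh"] for r in sim.regions}

    consolidation_manips = [m for m in manipulations if m.phase in ("consolidation", "all")]
    testing_manips = [m for m in manipulations if m.phase in ("testing", "all")]

    # --- burn-in ---------------------------------------------------------
    sim.set_rate("STIM", schedule.nu_bg)
    for name in sim.pois:
        if name.startswith("EXT."):
            sim.set_rate(name, schedule.nu_ext_bg)
    sim.run(schedule.T_burn)

    # --- training --------------------------------------------------------
    train_buf = SpikeBuffer()
    train_step0 = sim.t_step
    train_events = _run_phase_events(
        sim, stimuli, schedule, schedule.T_training,
        schedule.T_on_training, schedule.T_off_training, False, train_buf,
    )
    steps, ids = train_buf.arrays()
    t_end = sim.t
    res.training_raster = (steps, ids, train_events)

    # --- engram labeling -------------------------------------------------
    window_start = t_end - min(schedule.dt_eng, schedule.T_training)
    label_events = [e for e in train_events if e[2] > window_start]
    # a stimulus can by chance miss the labeling window: fall back to its
    # most recent presentations
    for s in range(stimuli.n_stimuli):
        if not any(sid == s for sid, _, _ in label_events):
            earlier = [e for e in train_events if e[0] == s]
            label_events.extend(earlier[-3:])
    for r in sim.regions:
        for pops, store in ((exc_pops, res.labels), (inh_pops, res.inh_labels)):
            pop = pops[r]
            raster = analysis.SpikeRaster(
                steps * dt, ids - pop.offset, pop.n,
                t0=train_step0 * dt, duration=t_end - train_step0 * dt,
            )
            store[r] = analysis.label_engrams(
                raster,
                label_events,
                zeta_thr=schedule.zeta_thr,
                n_stimuli=stimuli.n_stimuli,
            )

    # ensembles for consolidation-phase activity tracking (excitatory)
    subsets = {}
    for r in sim.regions:
        for s in range(stimuli.n_stimuli):
            cells = res.labels[r][s]
            subsets[f"{r}:{s}"] = cells + exc_pops[r].offset

    def snapshot(tag):
        from .network import snapshot_weights

        for name in snapshot_projections:
            res.weight_snapshots[(name, tag)] = snapshot_weights(sim.projections[name])

    snapshot(0.0)

    # engram-targeted manipulations default to the union of the region's
    # labeled ensembles (labels only exist after training)
    for m in manipulations:
        if m.neurons is None and m.kind in (
            "block-engram-output", "block-inhibitory-engrams"
        ):
            source = (
                res.inh_labels if m.kind == "block-inhibitory-engrams" else res.labels
            )
            cells = [c for c in source[m.region] if len(c)]
            m.neurons = (
                np.unique(np.concatenate(cells)) if cells else np.array([], dtype=int)
            )

    # --- consolidation with forked testing ------------------------------
    for m in consolidation_manips:
        apply_manipulation(sim, m)
    if schedule.stim_silent_consolidation:
        sim.set_rate("STIM", 0.0)
    else:
        sim.set_rate("STIM", schedule.nu_cons)
    for name in sim.pois:
        if name.startswith("EXT."):
            sim.set_rate(name, schedule.nu_ext_cons)

    n_cons_steps = int(round(schedule.T_consolidation / dt))
    act = BinnedActivity(
        subsets, sim.NL, sim.t_step, n_cons_steps, dt, schedule.activity_bin
    )

    def run_test_point(tp):
        state = sim.state_dict()
        t_step_before = sim.t_step
        for m in testing_manips:
            apply_manipulation(sim, m)
        sim.set_rate("STIM", schedule.nu_bg)
        for name in sim.pois:
            if name.startswith("EXT."):
                sim.set_rate(name, schedule.nu_ext_bg)
        buf = SpikeBuffer()
        test_step0 = sim.t_step
        events = _run_phase_events(
            sim, stimuli, schedule, schedule.T_testing,
            schedule.T_on_testing, schedule.T_off_testing, True, buf,
        )
        tsteps, tids = buf.arrays()
        for r in sim.regions:
            if not any(len(v) for v in res.labels[r]):
                continue
            pop = exc_pops[r]
            raster = analysis.SpikeRaster(
                tsteps * dt, tids - pop.offset, pop.n,
                t0=test_step0 * dt, duration=schedule.T_testing,
            )
            m_ = analysis.recall_metrics(
                raster, res.labels[r], events, zeta_thr=schedule.zeta_thr
            )
            act_frac = analysis.engram_activation_fraction(
                raster, res.labels[r], events, zeta_thr=schedule.zeta_thr
            )
            res.metrics.append(
                dict(region=r, cons_time=tp, accuracy=m_.accuracy, tpr=m_.tpr,
                     fpr=m_.fpr, n_cues=m_.n_cues, engram_activation=act_frac)
            )
        if keep_test_rasters:
            res.test_rasters[tp] = (tsteps, tids, events)
        sim.load_state(state)
        assert sim.t_step == t_step_before

    done = 0.0
    for tp in sorted(set(schedule.test_points)):
        if tp > done:
            sim.run(tp - done, act)
            done = tp
        run_test_point(tp)
    if schedule.T_consolidation > done:
        sim.run(schedule.T_consolidation - done, act)
    snapshot(schedule.T_consolidation)

    res.consolidation_rates = act.rates()
    res.consolidation_bin = schedule.activity_bin
    res.manifest = dict(
        master_seed=sim.spec.master_seed,
        dt=dt,
        regions=sim.regions,
        n_stimuli=stimuli.n_stimuli,
        stimulus_kind=stimuli.kind,
        schedule={k: getattr(schedule, k) for k in vars(schedule)},
        test_points=list(schedule.test_points),
    )
    return res
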