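"""Populations, regions and sparse inter-/intra-region projections.

A network is a set of regions (each an excitatory + an inhibitory
recurrently connected population), one Poisson stimulus population (STIM)
laid out on a square grid, optional Poisson external populations, and a set
of sparse projections.  Plasticity assignment follows the model's fixed
scheme: recurrent E->E carries short- plus long-term plasticity, E->I
short-term only, I->E the inhibitory rule, I->I is static; inter-region
projections run from excitatory cells of one region to excitatory cells of
another (Dale's law at the projection level).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import sparse

from .params import (
    ExcPlasticityParams,
    InhPlasticityParams,
    NeuronParams,
    STPParams,
)

__all__ = [
    "SparseProjection",
    "RegionSpec",
    "ProjectionSpec",
    "NetworkSpec",
    "random_connectivity",
    "build_circular_receptive_fields",
    "snapshot_weights",
    "restore_weights",
    "validate_spec",
]

PLASTICITY_KINDS = ("static", "stp-only", "stp+longterm", "inhibitory")


class SparseProjection:
    """Sparse source->target connectivity in CSR-by-source layout.

    ``indptr[j]:indptr[j+1]`` addresses the synapses of source neuron ``j``;
    ``targets`` holds target indices, ``w`` weights, and — on consolidating
    projections — ``w_tilde`` the per-synapse reference weights.  A per-source
    boolean ``blocked`` mask silences transmission (and plasticity) of the
    masked sources on this projection only.
    """

    def __init__(
        self,
        n_source: int,
        n_target: int,
        indptr: np.ndarray,
        targets: np.ndarray,
        w: np.ndarray,
        plasticity: str = "static",
        w_tilde: Optional[np.ndarray] = None,
        name: str = "",
    ):
        if plasticity not in PLASTICITY_KINDS:
            raise ValueError(f"unknown plasticity kind {plasticity!r}")
        if len(indptr) != n_source + 1:
            raise ValueError("indptr length must be n_source + 1")
        if len(targets) != len(w):
            raise ValueError("targets and w must align")
        self.n_source = int(n_source)
        self.n_target = int(n_target)
        self.indptr = np.asarray(indptr, dtype=np.int64)
        self.targets = np.asarray(targets, dtype=np.int32)
        self.w = np.asarray(w, dtype=np.float64)
        self.plasticity = plasticity
        self.name = name
        self.blocked = np.zeros(n_source, dtype=bool)
        if plasticity == "stp+longterm":
            self.w_tilde = (
                np.zeros_like(self.w) if w_tilde is None
                else np.asarray(w_tilde, dtype=np.float64)
            )
            if self.w_tilde.shape != self.w.shape:
                raise ValueError("w_tilde must align with w")
        else:
            self.w_tilde = None
        self._col = None  # lazy reverse (by-target) index

    @property
    def n_synapses(self) -> int:
        return len(self.w)

    def row_slice(self, source: int):
        return int(self.indptr[source]), int(self.indptr[source + 1])

    def _build_reverse(self):
        order = np.argsort(self.targets, kind="stable")
        counts = np.bincount(self.targets, minlength=self.n_target)
        colptr = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
        sources = np.repeat(
            np.arange(self.n_source, dtype=np.int32), np.diff(self.indptr)
        )[order]
        self._col = (colptr, order.astype(np.int64), sources)

    def afferent_synapses(self, target: int) -> np.ndarray:
        """Indices into ``w`` of all synapses onto ``target``."""
        if self._col is None:
            self._build_reverse()
        colptr, order, _ = self._col
        return order[colptr[target] : colptr[target + 1]]

    def afferent_sources(self, target: int) -> np.ndarray:
        if self._col is None:
            self._build_reverse()
        colptr, _, sources = self._col
        return sources[colptr[target] : colptr[target + 1]]

    def to_csr(self) -> sparse.csr_matrix:
        return sparse.csr_matrix(
            (self.w, self.targets, self.indptr),
            shape=(self.n_source, self.n_target),
        )


# ---------------------------------------------------------------------------
# Connectivity builders


def random_connectivity(
    n_source: int,
    n_target: int,
    p: float,
    rng: np.random.Generator,
    exclude_self: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """i.i.d. Bernoulli(p) connectivity as (indptr, targets).

    ``exclude_self`` removes the diagonal (for recurrent projections on the
    same population).
    """
    if not 0 < p <= 1:
        raise ValueError(f"connection probability must lie in (0, 1], got {p}")
    counts = np.empty(n_source, dtype=np.int64)
    rows = []
    for j in range(n_source):
        mask = rng.random(n_target) < p
        if exclude_self and j < n_target:
            mask[j] = False
        tgt = np.flatnonzero(mask).astype(np.int32)
        rows.append(tgt)
        counts[j] = len(tgt)
    indptr = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
    targets = np.concatenate(rows) if rows else np.empty(0, dtype=np.int32)
    return indptr, targets


def build_circular_receptive_fields(
    grid_side: int,
    n_target: int,
    radius: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Receptive-field connectivity from a square source grid.

    Each target neuron connects to every source cell whose Euclidean grid
    distance from a uniformly drawn random center is <= radius.  Returns
    (indptr, targets) in *source-major* CSR layout plus the drawn centers
    (n_target x 2 array of (row, col)).
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    diag = np.hypot(grid_side - 1, grid_side - 1)
    if radius > diag:
        warnings.warn("receptive-field radius exceeds grid diagonal: full connectivity")
    n_source = grid_side * grid_side
    gr, gc = np.divmod(np.arange(n_source), grid_side)
    centers = np.column_stack(
        [rng.integers(0, grid_side, n_target), rng.integers(0, grid_side, n_target)]
    )
    pairs_src = []
    pairs_tgt = []
    for t in range(n_target):
        d2 = (gr - centers[t, 0]) ** 2 + (gc - centers[t, 1]) ** 2
        src = np.flatnonzero(d2 <= radius * radius)
        pairs_src.append(src)
        pairs_tgt.append(np.full(len(src), t, dtype=np.int64))
    src = np.concatenate(pairs_src)
    tgt = np.concatenate(pairs_tgt)
    order = np.argsort(src, kind="stable")
    src, tgt = src[order], tgt[order]
    counts = np.bincount(src, minlength=n_source)
    indptr = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
    return indptr, tgt.astype(np.int32), centers


# ---------------------------------------------------------------------------
# Specs


@dataclass
class RegionSpec:
    """One brain-region recurrent network (excitatory + inhibitory pool)."""

    name: str
    N_exc: int = 512
    N_inh: int = 128
    eps_rec: float = 0.1
    w_EE: float = 0.2
    w_EI: float = 4.0
    w_IE: float = 3.0
    w_II: float = 0.5
    neuron: NeuronParams = field(default_factory=NeuronParams)
    stp: STPParams = field(default_factory=STPParams)
    exc_plasticity: ExcPlasticityParams = field(default_factory=ExcPlasticityParams)
    inh_plasticity: InhPlasticityParams = field(default_factory=InhPlasticityParams)

    def __post_init__(self):
        if self.N_exc <= 0 or self.N_inh <= 0:
            raise ValueError("population sizes must be positive")
        if not 0 < self.eps_rec <= 1:
            raise ValueError("eps_rec must lie in (0, 1]")


@dataclass
class ProjectionSpec:
    """Inter-population projection (excitatory source cells only)."""

    source: str
    target: str
    kind: str = "random-uniform"  # or "circular-receptive-field"
    eps_ff: float = 0.1
    radius: float = 4.0
    w_init: float = 0.1
    plasticity: str = "stp+longterm"
    # optional per-projection overrides of the target region's exc rule
    eta_exc: Optional[float] = None
    beta: Optional[float] = None
    delta: Optional[float] = None
    tau_cons: Optional[float] = None

    def __post_init__(self):
        if self.kind not in ("random-uniform", "circular-receptive-field"):
            raise ValueError(f"unknown projection kind {self.kind!r}")
        if self.plasticity not in ("static", "stp-only", "stp+longterm"):
            raise ValueError(
                "inter-region projections are excitatory: plasticity must be "
                "static, stp-only or stp+longterm"
            )


@dataclass
class NetworkSpec:
    """Full network: STIM grid, external drives, regions, projections."""

    regions: list = field(default_factory=list)
    projections: list = field(default_factory=list)
    N_stim: int = 1024
    stim_stp: STPParams = field(default_factory=STPParams)
    # external Poisson populations (used in the three-region consolidation
    # phase); maps target region name -> (size, eps, weight)
    external: dict = field(default_factory=dict)
    master_seed: int = 0
    dt: float = 1e-4
    allow_ordering_override: bool = False

    @property
    def grid_side(self) -> int:
        side = int(round(self.N_stim**0.5))
        if side * side != self.N_stim:
            raise ValueError("N_stim must be a perfect square (STIM is a grid)")
        return side

    def region(self, name: str) -> RegionSpec:
        for r in self.regions:
            if r.name == name:
                return r
        raise KeyError(f"unknown region {name!r}")


def validate_spec(spec: NetworkSpec) -> None:
    """Structural checks plus the model's plasticity-timescale orderings.

    The consolidation hierarchy requires the hippocampus to learn faster and
    consolidate more slowly than the cortex: eta_hpc > eta_ctx (excitatory
    and inhibitory) and tau_cons of STIM->HPC above every other excitatory
    projection.  Configs violating the orderings are rejected unless
    ``allow_ordering_override`` is set.
    """
    names = [r.name for r in spec.regions]
    if len(set(names)) != len(names):
        raise ValueError("region names must be unique")
    for p in spec.projections:
        for end in (p.source, p.target):
            if end not in names and end != "STIM":
                raise ValueError(f"projection endpoint {end!r} does not resolve")
        if p.target == "STIM":
            raise ValueError("STIM cannot be a projection target")
    if spec.allow_ordering_override:
        return
    if {"HPC", "CTX"} <= set(names):
        hpc, ctx = spec.region("HPC"), spec.region("CTX")
        if not (
            hpc.exc_plasticity.eta_exc > ctx.exc_plasticity.eta_exc
            and hpc.inh_plasticity.eta_inh > ctx.inh_plasticity.eta_inh
        ):
            raise ValueError(
                "plasticity ordering violated: require eta_hpc > eta_ctx "
                "(exc and inh); set allow_ordering_override to bypass"
            )
        stim_hpc = [
            p for p in spec.projections if p.source == "STIM" and p.target == "HPC"
        ]
        if stim_hpc and stim_hpc[0].plasticity == "stp+longterm":
            tau_sh = stim_hpc[0].tau_cons or hpc.exc_plasticity.tau_cons
            others = {
                r.name: r.exc_plasticity.tau_cons for r in spec.regions
            }
            for p in spec.projections:
                if p is not stim_hpc[0] and p.plasticity == "stp+longterm":
                    tau_p = (
                        p.tau_cons
                        if p.tau_cons is not None
                        else spec.region(p.target).exc_plasticity.tau_cons
                    )
                    others[f"{p.source}->{p.target}"] = tau_p
            if not (
                all(tau_sh >= t for t in others.values())
                and tau_sh > others["CTX"]
            ):
                raise ValueError(
                    "plasticity ordering violated: require tau_cons(STIM->HPC) "
                    "at or above every other excitatory projection and above "
                    "the cortical value"
                )


# ---------------------------------------------------------------------------
# Snapshots


def snapshot_weights(proj: SparseProjection) -> pd.DataFrame:
    """Lossless triplet table of (source, target, w[, w_tilde])."""
    src = np.repeat(np.arange(proj.n_source), np.diff(proj.indptr))
    data = {"source": src, "target": proj.targets.astype(np.int64), "w": proj.w.copy()}
    if proj.w_tilde is not None:
        data["w_tilde"] = proj.w_tilde.copy()
    return pd.DataFrame(data)


def restore_weights(proj: SparseProjection, table: pd.DataFrame) -> SparseProjection:
    """Write a snapshot table back into an existing projection in place."""
    if len(table) != proj.n_synapses:
        raise ValueError(
            f"snapshot has {len(table)} rows; projection holds {proj.n_synapses}"
        )
    src = np.repeat(np.arange(proj.n_source), np.diff(proj.indptr))
    if not (
        np.array_equal(table["source"].to_numpy(), src)
        and np.array_equal(table["target"].to_numpy(), proj.targets)
    ):
        raise ValueError("snapshot connectivity does not match projection")
    proj.w[:] = table["w"].to_numpy()
    if proj.w_tilde is not None:
        if "w_tilde" not in table:
            raise ValueError("consolidating projection requires w_tilde column")
        proj.w_tilde[:] = table["w_tilde"].to_numpy()
    return proj
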