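"""Configuration, serialization, manifests and test fixtures.

Formats: YAML configs, TSV event tables, MatrixMarket weight snapshots
(coordinate format, 1-based indices, with a companion ``*.wtilde.mtx`` for
consolidating projections), JSON manifests.  Every run is reproducible from
its manifest: a single master seed is split into named independent streams
(connectivity, protocol, Poisson drive, analysis), so changing one
component's draws does not perturb the others.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import io as sio
from scipy import sparse

from .network import NetworkSpec, ProjectionSpec, RegionSpec, SparseProjection, validate_spec
from .params import (
    ExcPlasticityParams,
    InhPlasticityParams,
    NeuronParams,
    STPParams,
    asdict_flat,
)
from .protocol import Manipulation, ProtocolSchedule

__all__ = [
    "load_config",
    "dump_config",
    "write_events",
    "read_events",
    "write_weights_mtx",
    "read_weights_mtx",
    "write_manifest",
    "make_fixture",
]


def _from_dict(cls, d: dict, path: str):
    """Construct a dataclass from a dict, rejecting unknown keys."""
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - names
    if unknown:
        raise ValueError(f"unknown key(s) at {path}: {sorted(unknown)}")
    return cls(**d)


_NESTED = {
    "neuron": NeuronParams,
    "stp": STPParams,
    "exc_plasticity": ExcPlasticityParams,
    "inh_plasticity": InhPlasticityParams,
}


def load_config(path) -> tuple[NetworkSpec, ProtocolSchedule, list]:
    """Parse a YAML config into (NetworkSpec, ProtocolSchedule, manipulations).

    Unknown keys are rejected with the path to the offending key.  A
    ``preset`` key seeds the spec from a named preset; any further keys
    override it.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known_top = {
        "preset", "scale", "master_seed", "dt", "N_stim", "regions",
        "projections", "external", "protocol", "manipulations",
        "allow_ordering_override", "stimulus_kind",
    }
    unknown = set(raw) - known_top
    if unknown:
        raise ValueError(f"unknown top-level key(s): {sorted(unknown)}")

    manips = [
        _from_dict(Manipulation, m, f"manipulations[{i}]")
        for i, m in enumerate(raw.get("manipulations", []))
    ]

    if "preset" in raw:
        from .presets import make_preset

        spec, sched, _kind = make_preset(
            raw["preset"],
            seed=raw.get("master_seed", 0),
            scale=raw.get("scale", "desk"),
        )
        if "protocol" in raw:
            sched = dataclasses.replace(sched, **raw["protocol"])
        if "dt" in raw:
            spec.dt = raw["dt"]
        return spec, sched, manips

    regions = []
    for i, r in enumerate(raw.get("regions", [])):
        r = dict(r)
        kw = {}
        for key, cls in _NESTED.items():
            if key in r:
                kw[key] = _from_dict(cls, r.pop(key), f"regions[{i}].{key}")
        regions.append(_from_dict(RegionSpec, {**r, **kw}, f"regions[{i}]"))
    projections = [
        _from_dict(ProjectionSpec, p, f"projections[{i}]")
        for i, p in enumerate(raw.get("projections", []))
    ]
    spec = NetworkSpec(
        regions=regions,
        projections=projections,
        N_stim=raw.get("N_stim", 1024),
        external={k: tuple(v) for k, v in raw.get("external", {}).items()},
        master_seed=raw.get("master_seed", 0),
        dt=raw.get("dt", 1e-4),
        allow_ordering_override=raw.get("allow_ordering_override", False),
    )
    validate_spec(spec)
    sched = _from_dict(
        ProtocolSchedule, raw.get("protocol", {}), "protocol"
    )
    if isinstance(sched.test_points, list):
        sched.test_points = tuple(sched.test_points)
    return spec, sched, manips


def dump_config(spec: NetworkSpec, sched: ProtocolSchedule, path) -> None:
    """Write a normalized full config (round-trips through load_config)."""
    doc = {
        "master_seed": spec.master_seed,
        "dt": spec.dt,
        "N_stim": spec.N_stim,
        "allow_ordering_override": spec.allow_ordering_override,
        "regions": [
            {
                "name": r.name,
                "N_exc": r.N_exc,
                "N_inh": r.N_inh,
                "eps_rec": r.eps_rec,
                "w_EE": r.w_EE,
                "w_EI": r.w_EI,
                "w_IE": r.w_IE,
                "w_II": r.w_II,
                "neuron": asdict_flat(r.neuron),
                "stp": asdict_flat(r.stp),
                "exc_plasticity": asdict_flat(r.exc_plasticity),
                "inh_plasticity": asdict_flat(r.inh_plasticity),
            }
            for r in spec.regions
        ],
        "projections": [asdict_flat(p) for p in spec.projections],
        "external": {k: list(v) for k, v in spec.external.items()},
        "protocol": {
            **asdict_flat(sched),
            "test_points": list(sched.test_points),
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Event tables


def write_events(times, ids, path, population: str = "", dt: float = 0.0,
                 duration: float = 0.0) -> None:
    """TSV event table: header comments, then (time [s], neuron) rows."""
    times = np.asarray(times)
    ids = np.asarray(ids)
    if times.size and np.any(np.diff(times) < 0):
        raise ValueError("events must be sorted by time")
    with open(path, "w") as fh:
        fh.write(f"# population\t{population}\n")
        fh.write(f"# dt\t{dt}\n# duration\t{duration}\n")
        fh.write("time\tneuron\n")
        for t, i in zip(times, ids):
            fh.write(f"{t:.6f}\t{i}\n")


def read_events(path):
    """Stream a TSV event table; returns (times, ids, header dict)."""
    header = {}
    times, ids = [], []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if line.startswith("#"):
                parts = line[1:].strip().split("\t")
                if len(parts) == 2:
                    header[parts[0]] = parts[1]
                continue
            if line.startswith("time"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"malformed row at line {ln} of {path}")
            t = float(parts[0])
            if times and t < times[-1]:
                raise ValueError(f"out-of-order event at line {ln} of {path}")
            times.append(t)
            ids.append(int(parts[1]))
    return np.array(times), np.array(ids, dtype=np.int64), header


# ---------------------------------------------------------------------------
# Weight snapshots (MatrixMarket coordinate, 1-based per the standard)


def write_weights_mtx(proj: SparseProjection, path) -> None:
    path = Path(path)
    sio.mmwrite(str(path), proj.to_csr())
    if proj.w_tilde is not None:
        m = sparse.csr_matrix(
            (proj.w_tilde, proj.targets, proj.indptr),
            shape=(proj.n_source, proj.n_target),
        )
        sio.mmwrite(str(path.with_suffix("")) + ".wtilde.mtx", m)


def read_weights_mtx(path):
    """Returns (w_csr, wtilde_csr_or_None)."""
    path = Path(path)
    w = sio.mmread(str(path)).tocsr()
    wt_path = Path(str(path.with_suffix("")) + ".wtilde.mtx")
    wt = sio.mmread(str(wt_path)).tocsr() if wt_path.exists() else None
    return w, wt


def write_manifest(run_dir, manifest: dict) -> Path:
    """JSON manifest with a checksum inventory of the run directory."""
    run_dir = Path(run_dir)
    inventory = {}
    for f in sorted(run_dir.rglob("*")):
        if f.is_file() and f.name != "manifest.json":
            inventory[str(f.relative_to(run_dir))] = hashlib.sha256(
                f.read_bytes()
            ).hexdigest()
    manifest = {**manifest, "artifacts": inventory}
    out = run_dir / "manifest.json"
    out.write_text(json.dumps(manifest, indent=2, default=str))
    return out


# ---------------------------------------------------------------------------
# Fixtures


def make_fixture(name: str, seed: int = 0):
    """Deterministic tiny configurations for tests.

    ``micro`` — two regions of 6 exc / 2 inh neurons, a 16-cell stimulus
    grid and sub-second phases; runs in well under a second and is the
    oracle-equivalence workhorse.  ``small`` — the desk-scale two-region
    preset (512 exc / 128 inh per region).
    Returns (NetworkSpec, ProtocolSchedule, stimulus_kind).
    """
    from .presets import desk_region, make_preset

    if name == "micro":
        hpc = desk_region("HPC", 6, 2, eta_exc=1.0, eta_inh=4e-4,
                          tau_cons=30.0, target_rate=5.0)
        ctx = desk_region("CTX", 6, 2, eta_exc=0.35, eta_inh=2e-4,
                          tau_cons=10.0, target_rate=5.0)
        hpc.eps_rec = 0.5
        ctx.eps_rec = 0.5
        spec = NetworkSpec(
            regions=[hpc, ctx],
            projections=[
                ProjectionSpec("STIM", "HPC", eps_ff=0.5, w_init=0.1,
                               plasticity="stp+longterm", tau_cons=30.0),
                ProjectionSpec("STIM", "CTX", eps_ff=0.5, w_init=0.1,
                               plasticity="stp+longterm", tau_cons=10.0),
            ],
            N_stim=16,
            master_seed=seed,
            dt=1e-4,
        )
        sched = ProtocolSchedule(
            T_burn=0.05, T_training=0.4, T_consolidation=0.4, T_testing=0.2,
            T_on_training=0.05, T_off_training=0.05,
            T_on_testing=0.05, T_off_testing=0.05,
            nu_bg=20.0, nu_stim=200.0, nu_cons=20.0,
            dt_eng=0.4, test_points=(0.0,),
        )
        return spec, sched, "random-nonoverlapping"
    if name == "small":
        return make_preset("two_region", seed=seed, scale="desk")
    raise ValueError(f"unknown fixture {name!r}")
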