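"""Scalar reference simulator for engine-equivalence tests.

A deliberately naive per-neuron, per-synapse Python implementation of the
documented update order (see docs/methods.md).  It reads the network
structure out of a built :class:`engramsim.Simulator` once (connectivity,
initial weights, per-neuron parameters) and then advances independently
with plain Python loops and dictionaries — no shared code with the
compiled step kernel.
"""

import math

import numpy as np


class ScalarOracle:
    def __init__(self, sim):
        spec = sim.spec
        self.dt = sim.dt
        self.NL = sim.NL
        self.NP = sim.NP
        # copy per-neuron parameter tables (plain floats)
        for name in (
            "c_mem", "Urest", "Uexc", "Uinh", "threst", "thspike", "c_thr",
            "alpha", "f_ampa", "f_gaba", "f_a", "c_nmda", "Da",
            "f_zp", "f_zm", "f_zs", "f_zht", "f_zi", "f_C",
            "Ustp", "e_d", "e_f",
        ):
            setattr(self, name, [float(v) for v in getattr(sim, name)])
        self.is_exc = [bool(v) for v in sim.is_exc]
        self.region_of = [int(v) for v in sim.region_of]
        self.enabled = [bool(v) for v in sim.enabled]
        self.R_fH = [float(v) for v in sim.R_fH]
        self.R_gamma = [float(v) for v in sim.R_gamma]
        self.n_regions = len(sim.R_H)
        self.Q_Ustp = [float(v) for v in sim.Q_Ustp]
        self.Q_e_d = [float(v) for v in sim.Q_e_d]
        self.Q_e_f = [float(v) for v in sim.Q_e_f]
        self.Q_f_zp = [float(v) for v in sim.Q_f_zp]
        # state
        self.U = [float(v) for v in sim.U]
        self.TH = [float(v) for v in sim.TH]
        self.GA = [0.0] * self.NL
        self.GN = [0.0] * self.NL
        self.GG = [0.0] * self.NL
        self.GAD = [0.0] * self.NL
        self.ZP = [0.0] * self.NL
        self.ZM = [0.0] * self.NL
        self.ZS = [0.0] * self.NL
        self.ZHT = [0.0] * self.NL
        self.CH = [0.0] * self.NL
        self.ZI = [0.0] * self.NL
        self.SU = [float(v) for v in sim.SU]
        self.SX = [float(v) for v in sim.SX]
        self.R_H = [0.0] * self.n_regions
        self.QU = [float(v) for v in sim.QU]
        self.QX = [float(v) for v in sim.QX]
        self.QZP = [0.0] * self.NP
        # projections: list of dicts with explicit synapse lists
        self.projs = []
        for i, p in enumerate(sim._projs):
            s0 = int(sim.P_syn0[i])
            n_syn = len(p["w"])
            rows = []  # per source: list of (synapse id, target)
            indptr = p["indptr"]
            for s in range(p["n_src"]):
                rows.append(
                    [(s0 + r, int(p["tgt"][r])) for r in range(indptr[s], indptr[s + 1])]
                )
            by_target = {}
            for s in range(p["n_src"]):
                for a, tgt in rows[s]:
                    by_target.setdefault(tgt, []).append((a, s + p["src_off"]))
            self.projs.append(
                dict(
                    kind=int(p["kind"]),
                    src_kind=int(p["src_kind"]),
                    src_off=int(p["src_off"]),
                    n_src=int(p["n_src"]),
                    tgt0=int(p["tgt0"]),
                    n_tgt=int(p["n_tgt"]),
                    tgt_region=int(p["tgt_region"]),
                    use_stp=bool(p["use_stp"]),
                    inh_syn=bool(p["inh_syn"]),
                    eta=float(p["eta"]),
                    A=float(p["A"]),
                    beta=float(p["beta"]),
                    delta=float(p["delta"]),
                    wmin=float(p["wmin"]),
                    wmax=float(p["wmax"]),
                    rows=rows,
                    by_target=by_target,
                    blocked=[False] * p["n_src"],
                )
            )
        self.w = {a: float(v) for a, v in enumerate(sim.S_w)}
        self.wt = {a: float(v) for a, v in enumerate(sim.S_wt)}
        self.prev_spikes = []
        self.spikes = []  # (step, neuron)
        self.step_count = 0

    def _clip(self, w, lo, hi):
        return lo if w < lo else (hi if w > hi else w)

    def step(self, poisson_spikes):
        """Advance one timestep; ``poisson_spikes`` is this step's list of
        global Poisson source indices."""
        dt = self.dt
        # phase 1: decay conductances
        for i in range(self.NL):
            self.GA[i] *= self.f_ampa[i]
            self.GG[i] *= self.f_gaba[i]
            self.GAD[i] *= self.f_a[i]
        for i in self.prev_spikes:
            self.GAD[i] += self.Da[i]
        # deliver through projections in build order
        for p in self.projs:
            spikes = self.prev_spikes if p["src_kind"] == 0 else poisson_spikes
            for g in spikes:
                s = g - p["src_off"]
                if s < 0 or s >= p["n_src"] or p["blocked"][s]:
                    continue
                if p["use_stp"]:
                    eff = (
                        self.SU[g] * self.SX[g]
                        if p["src_kind"] == 0
                        else self.QU[g] * self.QX[g]
                    )
                else:
                    eff = 1.0
                if p["kind"] == 3:  # inhibitory plastic
                    G = self.R_H[p["tgt_region"]] - self.R_gamma[p["tgt_region"]]
                    for a, tgt in p["rows"][s]:
                        self.GG[tgt] += self.w[a]
                        self.w[a] = self._clip(
                            self.w[a] + p["eta"] * G * (self.ZI[tgt] + 1.0),
                            p["wmin"], p["wmax"],
                        )
                elif p["inh_syn"]:
                    for a, tgt in p["rows"][s]:
                        self.GG[tgt] += self.w[a] * eff
                elif p["kind"] == 2:  # exc plastic
                    for a, tgt in p["rows"][s]:
                        self.GA[tgt] += self.w[a] * eff
                        Ci = min(self.CH[tgt], 1.0)
                        self.w[a] = self._clip(
                            self.w[a]
                            - p["eta"] * p["A"] * Ci * self.ZM[tgt]
                            + p["delta"],
                            p["wmin"], p["wmax"],
                        )
                else:
                    for a, tgt in p["rows"][s]:
                        self.GA[tgt] += self.w[a] * eff
        # STP jumps; Poisson z+ increments
        for i in self.prev_spikes:
            u = self.SU[i] + self.Ustp[i] * (1.0 - self.SU[i])
            self.SU[i] = u
            self.SX[i] -= u * self.SX[i]
        for i in poisson_spikes:
            u = self.QU[i] + self.Q_Ustp[i] * (1.0 - self.QU[i])
            self.QU[i] = u
            self.QX[i] -= u * self.QX[i]
            self.QZP[i] += 1.0
        # phase 2: integrate
        for i in range(self.NL):
            self.GN[i] += self.c_nmda[i] * (self.GA[i] - self.GN[i])
            g_exc = self.alpha[i] * self.GA[i] + (1.0 - self.alpha[i]) * self.GN[i]
            self.U[i] += self.c_mem[i] * (
                (self.Urest[i] - self.U[i])
                + g_exc * (self.Uexc[i] - self.U[i])
                + (self.GG[i] + self.GAD[i]) * (self.Uinh[i] - self.U[i])
            )
            self.TH[i] += self.c_thr[i] * (self.threst[i] - self.TH[i])
            self.ZP[i] *= self.f_zp[i]
            self.ZM[i] *= self.f_zm[i]
            self.ZS[i] *= self.f_zs[i]
            self.ZHT[i] *= self.f_zht[i]
            self.ZI[i] *= self.f_zi[i]
            self.CH[i] = self.CH[i] * self.f_C[i] + dt * self.ZHT[i] * self.ZHT[i]
            self.SX[i] = 1.0 + (self.SX[i] - 1.0) * self.e_d[i]
            self.SU[i] = self.Ustp[i] + (self.SU[i] - self.Ustp[i]) * self.e_f[i]
        for i in range(self.NP):
            self.QX[i] = 1.0 + (self.QX[i] - 1.0) * self.Q_e_d[i]
            self.QU[i] = self.Q_Ustp[i] + (self.QU[i] - self.Q_Ustp[i]) * self.Q_e_f[i]
            self.QZP[i] *= self.Q_f_zp[i]
        for r in range(self.n_regions):
            self.R_H[r] *= self.R_fH[r]
        # phase 3: detect
        new = [
            i for i in range(self.NL)
            if self.enabled[i] and self.U[i] > self.TH[i]
        ]
        for p in self.projs:
            if p["kind"] not in (2, 3):
                continue
            for i in new:
                tl = i - p["tgt0"]
                if tl < 0 or tl >= p["n_tgt"]:
                    continue
                aff = p["by_target"].get(i, [])
                if p["kind"] == 2:
                    zs_i = self.ZS[i]
                    zm3 = self.ZM[i] ** 3
                    for a, src in aff:
                        if p["blocked"][src - p["src_off"]]:
                            continue
                        zp = self.ZP[src] if p["src_kind"] == 0 else self.QZP[src]
                        self.w[a] = self._clip(
                            self.w[a]
                            + p["eta"] * p["A"] * zp * zs_i
                            - p["beta"] * (self.w[a] - self.wt[a]) * zm3,
                            p["wmin"], p["wmax"],
                        )
                else:
                    G = self.R_H[p["tgt_region"]] - self.R_gamma[p["tgt_region"]]
                    for a, src in aff:
                        if p["blocked"][src - p["src_off"]]:
                            continue
                        self.w[a] = self._clip(
                            self.w[a] + p["eta"] * G * self.ZI[src],
                            p["wmin"], p["wmax"],
                        )
        for i in new:
            self.U[i] = self.Urest[i]
            self.TH[i] = self.thspike[i]
            self.ZP[i] += 1.0
            self.ZI[i] += 1.0
            if self.is_exc[i]:
                self.ZM[i] += 1.0
                self.ZS[i] += 1.0
                self.ZHT[i] += 1.0
                self.R_H[self.region_of[i]] += 1.0
            self.spikes.append((self.step_count, i))
        self.prev_spikes = new
        self.step_count += 1

    def run(self, ptr, idx):
        """Advance len(ptr)-1 steps with a per-step CSR Poisson spike list."""
        for t in range(len(ptr) - 1):
            self.step([int(i) for i in idx[ptr[t] : ptr[t + 1]]])

    def weights_array(self):
        return np.array([self.w[a] for a in range(len(self.w))])
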