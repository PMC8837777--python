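"""Fused simulation engine.

The whole network — every LIF neuron, Poisson source, synapse, trace and
homeostatic variable — is flattened into plain arrays and advanced by a
single compiled (numba) step loop.  Semantics follow the per-operation
definitions in :mod:`engramsim.dynamics` and :mod:`engramsim.plasticity`;
tests assert step-for-step agreement with an independent scalar reference
on micro-networks.

Update order within a timestep (documented in docs/methods.md):

1. Decay conductances; deliver the previous step's LIF spikes and the
   current step's Poisson spikes (adaptation increment, synaptic delivery
   with the pre-jump short-term-plasticity factor, presynaptic-spike weight
   updates, then STP jumps and Poisson z+ increments).
2. Forward-Euler integration of membranes/thresholds; exact-exponential
   decay of all traces, STP relaxation, homeostatic C and region H.
3. Spike detection; postsynaptic-spike weight updates (reading pre-increment
   trace values); resets, threshold jumps, trace and H increments.

Reference weights (synaptic consolidation) advance on a long timestep
outside the kernel (:meth:`Simulator.run`).
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .network import (
    NetworkSpec,
    SparseProjection,
    build_circular_receptive_fields,
    random_connectivity,
    validate_spec,
)
__all__ = ["Simulator", "build_network"]

# projection kind codes
K_STATIC = 0
K_STP = 1
K_EXC_PLASTIC = 2
K_INH_PLASTIC = 3


@njit(cache=True, fastmath=False)
def _step_kernel(
    n_steps, dt, t0,
    # LIF state
    U, TH, GA, GN, GG, GAD,
    ZP, ZM, ZS, ZHT, CH, ZI, SU, SX,
    # LIF per-neuron params
    c_mem, Urest, Uexc, Uinh, threst, thspike, c_thr, alpha,
    f_ampa, f_gaba, f_a, c_nmda, Da,
    f_zp, f_zm, f_zs, f_zht, f_zi, f_C,
    Ustp, e_d, e_f, is_exc, region_of, enabled,
    # region state
    R_H, R_fH, R_gamma,
    # poisson state/params
    QU, QX, QZP, Q_Ustp, Q_e_d, Q_e_f, Q_f_zp,
    # projections (concatenated)
    P_kind, P_src_kind, P_src_off, P_n_src, P_tgt0, P_n_tgt, P_tgt_region,
    P_use_stp, P_inh_syn, P_eta, P_A, P_beta, P_delta, P_wmin, P_wmax,
    P_ind0, IND, P_syn0, S_tgt, S_w, S_wt,
    P_col0, CPTR, C_syn, C_src, P_blk0, BLK,
    # poisson input spikes for this call
    PS_ptr, PS_idx,
    # spike carry-over and output
    prev_spk, n_prev,
    out_step, out_id, out_cap,
):
    NL = U.shape[0]
    n_proj = P_kind.shape[0]
    new_spk = np.empty(NL, dtype=np.int32)
    n_out = 0
    for t in range(n_steps):
        if n_out + NL > out_cap:
            # not enough room for a worst-case step; caller retries the
            # remaining steps with a larger buffer
            return t, n_prev, n_out
        # ---- phase 1: decay conductances, deliver spikes -------------
        for i in range(NL):
            GA[i] *= f_ampa[i]
            GG[i] *= f_gaba[i]
            GAD[i] *= f_a[i]
        for k in range(n_prev):
            i = prev_spk[k]
            GAD[i] += Da[i]
        ps_lo = PS_ptr[t]
        ps_hi = PS_ptr[t + 1]
        for p in range(n_proj):
            kind = P_kind[p]
            src_kind = P_src_kind[p]
            off = P_src_off[p]
            nsrc = P_n_src[p]
            ind0 = P_ind0[p]
            syn0 = P_syn0[p]
            blk0 = P_blk0[p]
            use_stp = P_use_stp[p]
            inh_syn = P_inh_syn[p]
            eta = P_eta[p]
            Ap = P_A[p]
            dlt = P_delta[p]
            wmin = P_wmin[p]
            wmax = P_wmax[p]
            if src_kind == 0:
                lo, hi = 0, n_prev
            else:
                lo, hi = ps_lo, ps_hi
            for k in range(lo, hi):
                g = prev_spk[k] if src_kind == 0 else PS_idx[k]
                s = g - off
                if s < 0 or s >= nsrc:
                    continue
                if BLK[blk0 + s]:
                    continue
                if use_stp:
                    eff = (SU[g] * SX[g]) if src_kind == 0 else (QU[g] * QX[g])
                else:
                    eff = 1.0
                r0 = IND[ind0 + s]
                r1 = IND[ind0 + s + 1]
                if kind == K_INH_PLASTIC:
                    reg = P_tgt_region[p]
                    G = R_H[reg] - R_gamma[reg]
                    for r in range(r0, r1):
                        a = syn0 + r
                        tgt = S_tgt[a]
                        GG[tgt] += S_w[a]
                        w = S_w[a] + eta * G * (ZI[tgt] + 1.0)
                        if w < wmin:
                            w = wmin
                        elif w > wmax:
                            w = wmax
                        S_w[a] = w
                elif inh_syn:
                    for r in range(r0, r1):
                        a = syn0 + r
                        GG[S_tgt[a]] += S_w[a] * eff
                else:
                    if kind == K_EXC_PLASTIC:
                        for r in range(r0, r1):
                            a = syn0 + r
                            tgt = S_tgt[a]
                            GA[tgt] += S_w[a] * eff
                            Ci = CH[tgt]
                            if Ci > 1.0:
                                Ci = 1.0
                            w = S_w[a] - eta * Ap * Ci * ZM[tgt] + dlt
                            if w < wmin:
                                w = wmin
                            elif w > wmax:
                                w = wmax
                            S_w[a] = w
                    else:
                        for r in range(r0, r1):
                            a = syn0 + r
                            GA[S_tgt[a]] += S_w[a] * eff
        # STP jumps and z+ increments of the delivered spikes
        for k in range(n_prev):
            i = prev_spk[k]
            u = SU[i] + Ustp[i] * (1.0 - SU[i])
            SU[i] = u
            SX[i] -= u * SX[i]
        for k in range(ps_lo, ps_hi):
            i = PS_idx[k]
            u = QU[i] + Q_Ustp[i] * (1.0 - QU[i])
            QU[i] = u
            QX[i] -= u * QX[i]
            QZP[i] += 1.0
        # ---- phase 2: integrate ---------------------------------------
        for i in range(NL):
            GN[i] += c_nmda[i] * (GA[i] - GN[i])
            g_exc = alpha[i] * GA[i] + (1.0 - alpha[i]) * GN[i]
            U[i] += c_mem[i] * (
                (Urest[i] - U[i])
                + g_exc * (Uexc[i] - U[i])
                + (GG[i] + GAD[i]) * (Uinh[i] - U[i])
            )
            TH[i] += c_thr[i] * (threst[i] - TH[i])
            ZP[i] *= f_zp[i]
            ZM[i] *= f_zm[i]
            ZS[i] *= f_zs[i]
            ZHT[i] *= f_zht[i]
            ZI[i] *= f_zi[i]
            CH[i] = CH[i] * f_C[i] + dt * ZHT[i] * ZHT[i]
            SX[i] = 1.0 + (SX[i] - 1.0) * e_d[i]
            SU[i] = Ustp[i] + (SU[i] - Ustp[i]) * e_f[i]
        for i in range(QU.shape[0]):
            QX[i] = 1.0 + (QX[i] - 1.0) * Q_e_d[i]
            QU[i] = Q_Ustp[i] + (QU[i] - Q_Ustp[i]) * Q_e_f[i]
            QZP[i] *= Q_f_zp[i]
        for r in range(R_H.shape[0]):
            R_H[r] *= R_fH[r]
        # ---- phase 3: detect, post-spike plasticity, reset ------------
        n_new = 0
        for i in range(NL):
            if enabled[i] and U[i] > TH[i]:
                new_spk[n_new] = i
                n_new += 1
        for p in range(n_proj):
            kind = P_kind[p]
            if kind != K_EXC_PLASTIC and kind != K_INH_PLASTIC:
                continue
            tgt0 = P_tgt0[p]
            ntgt = P_n_tgt[p]
            col0 = P_col0[p]
            blk0 = P_blk0[p]
            syn0 = P_syn0[p]
            src_kind = P_src_kind[p]
            src_off = P_src_off[p]
            eta = P_eta[p]
            Ap = P_A[p]
            beta = P_beta[p]
            for k in range(n_new):
                i = new_spk[k]
                tl = i - tgt0
                if tl < 0 or tl >= ntgt:
                    continue
                c0 = CPTR[col0 + tl]
                c1 = CPTR[col0 + tl + 1]
                if kind == K_EXC_PLASTIC:
                    zs_i = ZS[i]
                    zm = ZM[i]
                    zm3 = zm * zm * zm
                    wmin = P_wmin[p]
                    wmax = P_wmax[p]
                    for c in range(c0, c1):
                        a = C_syn[syn0 + c]
                        src = C_src[syn0 + c]
                        if BLK[blk0 + (src - src_off)]:
                            continue
                        zp = ZP[src] if src_kind == 0 else QZP[src]
                        w = (
                            S_w[a]
                            + eta * Ap * zp * zs_i
                            - beta * (S_w[a] - S_wt[a]) * zm3
                        )
                        if w < wmin:
                            w = wmin
                        elif w > wmax:
                            w = wmax
                        S_w[a] = w
                else:
                    reg = P_tgt_region[p]
                    G = R_H[reg] - R_gamma[reg]
                    wmin = P_wmin[p]
                    wmax = P_wmax[p]
                    for c in range(c0, c1):
                        a = C_syn[syn0 + c]
                        src = C_src[syn0 + c]
                        if BLK[blk0 + (src - src_off)]:
                            continue
                        w = S_w[a] + eta * G * ZI[src]
                        if w < wmin:
                            w = wmin
                        elif w > wmax:
                            w = wmax
                        S_w[a] = w
        for k in range(n_new):
            i = new_spk[k]
            U[i] = Urest[i]
            TH[i] = thspike[i]
            ZP[i] += 1.0
            ZI[i] += 1.0
            if is_exc[i]:
                ZM[i] += 1.0
                ZS[i] += 1.0
                ZHT[i] += 1.0
                R_H[region_of[i]] += 1.0
            out_step[n_out] = t0 + t
            out_id[n_out] = i
            n_out += 1
            prev_spk[k] = i
        n_prev = n_new
    return n_steps, n_prev, n_out


class _Pop:
    """Bookkeeping for one LIF population (offset into the flat arrays)."""

    __slots__ = ("name", "region", "region_id", "is_exc", "offset", "n")

    def __init__(self, name, region, region_id, is_exc, offset, n):
        self.name = name
        self.region = region
        self.region_id = region_id
        self.is_exc = is_exc
        self.offset = offset
        self.n = n


class _PoisPop:
    __slots__ = ("name", "offset", "n")

    def __init__(self, name, offset, n):
        self.name = name
        self.offset = offset
        self.n = n


class Simulator:
    """Compiled network simulator built from a :class:`NetworkSpec`.

    All connectivity and initial weights are drawn from a dedicated
    ``connectivity`` random stream derived from the spec's master seed, so
    two simulators built from the same spec are bit-identical.
    """

    def __init__(self, spec: NetworkSpec):
        validate_spec(spec)
        self.spec = spec
        self.dt = float(spec.dt)
        self.t_step = 0  # global step counter
        self._cons_accum = 0.0
        self.dt_long = 1.2  # consolidation timestep [s]
        ss = np.random.SeedSequence(spec.master_seed)
        kids = ss.spawn(4)
        self.rng_conn = np.random.default_rng(kids[0])
        self.rng_protocol = np.random.default_rng(kids[1])
        self.rng_poisson = np.random.default_rng(kids[2])
        self._pois_key = int(kids[2].generate_state(1)[0])
        self.rng_analysis = np.random.default_rng(kids[3])
        self._build()

    # ------------------------------------------------------------------
    def _build(self):
        spec = self.spec
        dt = self.dt
        # LIF populations: per region E then I
        self.pops: dict[str, _Pop] = {}
        off = 0
        self.regions = [r.name for r in spec.regions]
        for rid, r in enumerate(spec.regions):
            self.pops[f"{r.name}.exc"] = _Pop(f"{r.name}.exc", r.name, rid, True, off, r.N_exc)
            off += r.N_exc
            self.pops[f"{r.name}.inh"] = _Pop(f"{r.name}.inh", r.name, rid, False, off, r.N_inh)
            off += r.N_inh
        self.NL = off
        # Poisson populations: STIM then externals
        self.pois: dict[str, _PoisPop] = {}
        poff = 0
        self.pois["STIM"] = _PoisPop("STIM", 0, spec.N_stim)
        poff += spec.N_stim
        for region, (n_ext, _eps, _w) in spec.external.items():
            name = f"EXT.{region}"
            self.pois[name] = _PoisPop(name, poff, n_ext)
            poff += n_ext
        self.NP = poff

        NL = self.NL
        z = lambda: np.zeros(NL)
        self.U = np.empty(NL)
        self.TH = np.empty(NL)
        self.GA, self.GN, self.GG, self.GAD = z(), z(), z(), z()
        self.ZP, self.ZM, self.ZS, self.ZHT, self.CH, self.ZI = (
            z(), z(), z(), z(), z(), z(),
        )
        self.SU, self.SX = np.empty(NL), np.ones(NL)

        f = lambda: np.empty(NL)
        self.c_mem, self.Urest, self.Uexc, self.Uinh = f(), f(), f(), f()
        self.threst, self.thspike, self.c_thr, self.alpha = f(), f(), f(), f()
        self.f_ampa, self.f_gaba, self.f_a, self.c_nmda, self.Da = (
            f(), f(), f(), f(), f(),
        )
        self.f_zp, self.f_zm, self.f_zs, self.f_zht, self.f_zi, self.f_C = (
            f(), f(), f(), f(), f(), f(),
        )
        self.Ustp, self.e_d, self.e_f = f(), f(), f()
        self.is_exc = np.zeros(NL, dtype=np.bool_)
        self.region_of = np.zeros(NL, dtype=np.int32)
        self.enabled = np.ones(NL, dtype=np.bool_)

        for rid, r in enumerate(spec.regions):
            for pop_is_exc in (True, False):
                pop = self.pops[f"{r.name}.{'exc' if pop_is_exc else 'inh'}"]
                sl = slice(pop.offset, pop.offset + pop.n)
                np_ = r.neuron
                ep = r.exc_plasticity
                ip = r.inh_plasticity
                st = r.stp
                self.U[sl] = np_.U_rest
                self.TH[sl] = np_.theta_rest
                self.SU[sl] = st.U_stp
                self.c_mem[sl] = dt / np_.tau_m
                self.Urest[sl] = np_.U_rest
                self.Uexc[sl] = np_.U_exc
                self.Uinh[sl] = np_.U_inh
                self.threst[sl] = np_.theta_rest
                self.thspike[sl] = np_.theta_spike
                self.c_thr[sl] = dt / np_.tau_thr
                self.alpha[sl] = np_.alpha
                self.f_ampa[sl] = 1.0 - dt / np_.tau_ampa
                self.f_gaba[sl] = 1.0 - dt / np_.tau_gaba
                self.f_a[sl] = 1.0 - dt / np_.tau_a
                self.c_nmda[sl] = dt / np_.tau_nmda
                self.Da[sl] = np_.Delta_a
                self.f_zp[sl] = np.exp(-dt / ep.tau_plus)
                self.f_zm[sl] = np.exp(-dt / ep.tau_minus)
                self.f_zs[sl] = np.exp(-dt / ep.tau_slow)
                self.f_zht[sl] = np.exp(-dt / ep.tau_ht)
                self.f_zi[sl] = np.exp(-dt / ip.tau_istdp)
                self.f_C[sl] = np.exp(-dt / ep.tau_hom)
                self.Ustp[sl] = st.U_stp
                self.e_d[sl] = np.exp(-dt / st.tau_d)
                self.e_f[sl] = np.exp(-dt / st.tau_f)
                self.is_exc[sl] = pop_is_exc
                self.region_of[sl] = rid

        self.R_H = np.zeros(len(spec.regions))
        self.R_fH = np.array(
            [np.exp(-dt / r.inh_plasticity.tau_H) for r in spec.regions]
        )
        self.R_gamma = np.array([r.inh_plasticity.gamma for r in spec.regions])

        NPp = self.NP
        self.QU = np.empty(NPp)
        self.QX = np.ones(NPp)
        self.QZP = np.zeros(NPp)
        self.Q_Ustp = np.empty(NPp)
        self.Q_e_d = np.empty(NPp)
        self.Q_e_f = np.empty(NPp)
        self.Q_f_zp = np.empty(NPp)
        st = spec.stim_stp
        # Poisson sources share the STIM short-term-plasticity parameters and
        # the z+ time constant of their (first) plastic target region.
        tau_plus_default = (
            spec.regions[0].exc_plasticity.tau_plus if spec.regions else 16.8e-3
        )
        self.QU[:] = st.U_stp
        self.Q_Ustp[:] = st.U_stp
        self.Q_e_d[:] = np.exp(-dt / st.tau_d)
        self.Q_e_f[:] = np.exp(-dt / st.tau_f)
        self.Q_f_zp[:] = np.exp(-dt / tau_plus_default)

        # rates vector for poisson pops (set by the protocol between segments)
        self.pois_rates = np.zeros(NPp)

        # ---- projections ------------------------------------------------
        self._projs: list[dict] = []
        self.projections: dict[str, SparseProjection] = {}

        def add_proj(name, src_kind, src_off, n_src, tgt_pop, indptr, targets_local,
                     w_init, kind, use_stp, inh_syn, eta, A, beta, delta,
                     wmin, wmax, w=None):
            tgt_glob = (targets_local + tgt_pop.offset).astype(np.int32)
            n_syn = len(tgt_glob)
            if w is None:
                # uniform random initial weights in [0.5, 1.5) * w_init
                w = w_init * (0.5 + self.rng_conn.random(n_syn))
            rec = dict(
                name=name, src_kind=src_kind, src_off=src_off, n_src=n_src,
                tgt0=tgt_pop.offset, n_tgt=tgt_pop.n, tgt_region=tgt_pop.region_id,
                kind=kind, use_stp=use_stp, inh_syn=inh_syn,
                eta=eta, A=A, beta=beta, delta=delta, wmin=wmin, wmax=wmax,
                indptr=np.asarray(indptr, dtype=np.int64),
                tgt=tgt_glob, w=np.asarray(w, dtype=np.float64),
                # reference weights start at the current weights: synapses
                # begin at their consolidated baseline and the double-well
                # dynamics take over from there
                wt=(np.asarray(w, dtype=np.float64).copy()
                    if kind == K_EXC_PLASTIC else np.zeros(n_syn)),
                tau_cons=None,
            )
            self._projs.append(rec)
            return rec

        for rid, r in enumerate(spec.regions):
            e_pop = self.pops[f"{r.name}.exc"]
            i_pop = self.pops[f"{r.name}.inh"]
            ep, ip = r.exc_plasticity, r.inh_plasticity
            rng = self.rng_conn
            # E->E: stp + longterm
            ind, tg = random_connectivity(r.N_exc, r.N_exc, r.eps_rec, rng, True)
            rec = add_proj(f"{r.name}.EE", 0, e_pop.offset, r.N_exc, e_pop, ind, tg,
                           r.w_EE, K_EXC_PLASTIC, True, False,
                           ep.eta_exc, ep.A, ep.beta, ep.delta,
                           ep.w_min_exc, ep.w_max_exc)
            rec["tau_cons"] = ep.tau_cons
            # E->I: stp only
            ind, tg = random_connectivity(r.N_exc, r.N_inh, r.eps_rec, rng)
            add_proj(f"{r.name}.EI", 0, e_pop.offset, r.N_exc, i_pop, ind, tg,
                     r.w_EI, K_STP, True, False, 0, 0, 0, 0, 0, np.inf)
            # I->E: inhibitory plasticity
            ind, tg = random_connectivity(r.N_inh, r.N_exc, r.eps_rec, rng)
            add_proj(f"{r.name}.IE", 0, i_pop.offset, r.N_inh, e_pop, ind, tg,
                     r.w_IE, K_INH_PLASTIC, False, True,
                     ip.eta_inh, 0, 0, 0, ip.w_min_inh, ip.w_max_inh)
            # I->I: static
            ind, tg = random_connectivity(r.N_inh, r.N_inh, r.eps_rec, rng, True)
            add_proj(f"{r.name}.II", 0, i_pop.offset, r.N_inh, i_pop, ind, tg,
                     r.w_II, K_STATIC, False, True, 0, 0, 0, 0, 0, np.inf)

        for ps in spec.projections:
            tgt_reg = spec.region(ps.target)
            tgt_pop = self.pops[f"{ps.target}.exc"]
            ep = tgt_reg.exc_plasticity
            eta = ps.eta_exc if ps.eta_exc is not None else ep.eta_exc
            beta = ps.beta if ps.beta is not None else ep.beta
            delta = ps.delta if ps.delta is not None else ep.delta
            if ps.source == "STIM":
                src_kind, src_off, n_src = 1, self.pois["STIM"].offset, spec.N_stim
                rng = self.rng_conn
                if ps.kind == "circular-receptive-field":
                    ind, tg, _ = build_circular_receptive_fields(
                        spec.grid_side, tgt_pop.n, ps.radius, rng
                    )
                else:
                    ind, tg = random_connectivity(n_src, tgt_pop.n, ps.eps_ff, rng)
            else:
                src_pop = self.pops[f"{ps.source}.exc"]
                src_kind, src_off, n_src = 0, src_pop.offset, src_pop.n
                if ps.kind == "circular-receptive-field":
                    raise ValueError("receptive fields require a STIM (grid) source")
                ind, tg = random_connectivity(n_src, tgt_pop.n, ps.eps_ff, self.rng_conn)
            kind = {
                "static": K_STATIC,
                "stp-only": K_STP,
                "stp+longterm": K_EXC_PLASTIC,
            }[ps.plasticity]
            use_stp = ps.plasticity != "static"
            rec = add_proj(f"{ps.source}->{ps.target}", src_kind, src_off, n_src,
                           tgt_pop, ind, tg, ps.w_init, kind, use_stp, False,
                           eta, ep.A, beta, delta, ep.w_min_exc, ep.w_max_exc)
            if kind == K_EXC_PLASTIC:
                rec["tau_cons"] = ps.tau_cons if ps.tau_cons is not None else ep.tau_cons

        # external Poisson drives (static, no stp)
        for region, (n_ext, eps_ext, w_ext) in spec.external.items():
            tgt_pop = self.pops[f"{region}.exc"]
            pp = self.pois[f"EXT.{region}"]
            ind, tg = random_connectivity(n_ext, tgt_pop.n, eps_ext, self.rng_conn)
            add_proj(f"EXT->{region}", 1, pp.offset, n_ext, tgt_pop, ind, tg,
                     w_ext, K_STATIC, False, False, 0, 0, 0, 0, 0, np.inf)

        self._flatten_projections()
        self._prev_spk = np.zeros(self.NL, dtype=np.int32)
        self._n_prev = 0

    def _flatten_projections(self):
        projs = self._projs
        n = len(projs)
        self.P_kind = np.array([p["kind"] for p in projs], dtype=np.int64)
        self.P_src_kind = np.array([p["src_kind"] for p in projs], dtype=np.int64)
        self.P_src_off = np.array([p["src_off"] for p in projs], dtype=np.int64)
        self.P_n_src = np.array([p["n_src"] for p in projs], dtype=np.int64)
        self.P_tgt0 = np.array([p["tgt0"] for p in projs], dtype=np.int64)
        self.P_n_tgt = np.array([p["n_tgt"] for p in projs], dtype=np.int64)
        self.P_tgt_region = np.array([p["tgt_region"] for p in projs], dtype=np.int64)
        self.P_use_stp = np.array([p["use_stp"] for p in projs], dtype=np.bool_)
        self.P_inh_syn = np.array([p["inh_syn"] for p in projs], dtype=np.bool_)
        for f in ("eta", "A", "beta", "delta", "wmin", "wmax"):
            setattr(
                self, "P_" + f, np.array([p[f] for p in projs], dtype=np.float64)
            )
        self.P_ind0 = np.zeros(n, dtype=np.int64)
        self.P_syn0 = np.zeros(n, dtype=np.int64)
        self.P_col0 = np.zeros(n, dtype=np.int64)
        self.P_blk0 = np.zeros(n, dtype=np.int64)
        ind_parts, syn_t, syn_w, syn_wt = [], [], [], []
        col_parts, c_syn, c_src, blk_parts = [], [], [], []
        ind_off = syn_off = col_off = blk_off = 0
        for i, p in enumerate(projs):
            self.P_ind0[i] = ind_off
            self.P_syn0[i] = syn_off
            self.P_col0[i] = col_off
            self.P_blk0[i] = blk_off
            ind_parts.append(p["indptr"])
            syn_t.append(p["tgt"])
            syn_w.append(p["w"])
            syn_wt.append(p["wt"])
            # reverse (by-target) structure
            tgt_local = p["tgt"].astype(np.int64) - p["tgt0"]
            order = np.argsort(tgt_local, kind="stable")
            counts = np.bincount(tgt_local, minlength=p["n_tgt"])
            colptr = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
            src_glob = (
                np.repeat(np.arange(p["n_src"]), np.diff(p["indptr"]))[order]
                + p["src_off"]
            )
            col_parts.append(colptr)
            c_syn.append(order + syn_off)
            c_src.append(src_glob)
            blk_parts.append(np.zeros(p["n_src"], dtype=np.bool_))
            ind_off += len(p["indptr"])
            syn_off += len(p["w"])
            col_off += len(colptr)
            blk_off += p["n_src"]
        self.IND = np.concatenate(ind_parts).astype(np.int64)
        self.S_tgt = np.concatenate(syn_t).astype(np.int32)
        self.S_w = np.concatenate(syn_w)
        self.S_wt = np.concatenate(syn_wt)
        self.CPTR = np.concatenate(col_parts).astype(np.int64)
        self.C_syn = np.concatenate(c_syn).astype(np.int64)
        self.C_src = np.concatenate(c_src).astype(np.int32)
        self.BLK = np.concatenate(blk_parts)
        # public SparseProjection views sharing the flat weight storage
        for i, p in enumerate(projs):
            s = slice(self.P_syn0[i], self.P_syn0[i] + len(p["w"]))
            kind = p["kind"]
            plast = {
                K_STATIC: "static",
                K_STP: "stp-only",
                K_EXC_PLASTIC: "stp+longterm",
                K_INH_PLASTIC: "inhibitory",
            }[kind]
            view = SparseProjection.__new__(SparseProjection)
            view.n_source = p["n_src"]
            view.n_target = p["n_tgt"]
            view.indptr = p["indptr"]
            view.targets = (self.S_tgt[s] - p["tgt0"]).astype(np.int32)
            view.w = self.S_w[s]
            view.plasticity = plast
            view.name = p["name"]
            view.blocked = self.BLK[self.P_blk0[i] : self.P_blk0[i] + p["n_src"]]
            view.w_tilde = self.S_wt[s] if kind == K_EXC_PLASTIC else None
            view._col = None
            self.projections[p["name"]] = view

    # ------------------------------------------------------------------
    @property
    def t(self) -> float:
        """Current simulated time [s]."""
        return self.t_step * self.dt

    def set_rate(self, pop: str, rates) -> None:
        """Set per-neuron Poisson rates [Hz] for a Poisson population."""
        pp = self.pois[pop]
        r = np.broadcast_to(np.asarray(rates, dtype=np.float64), (pp.n,))
        if np.any(r < 0):
            raise ValueError("rates must be >= 0")
        if np.any(r * self.dt >= 1.0):
            raise ValueError("rate * dt >= 1: rate too high for the timestep")
        self.pois_rates[pp.offset : pp.offset + pp.n] = r

    def set_blocked(self, proj_name: str, sources, flag: bool = True) -> None:
        """Mask transmission (and plasticity) of given source neurons on one
        projection."""
        i = [p["name"] for p in self._projs].index(proj_name)
        p = self._projs[i]
        src = np.asarray(sources, dtype=np.intp)
        self.BLK[self.P_blk0[i] + src] = flag

    def set_enabled(self, pop_name: str, neurons, flag: bool) -> None:
        pop = self.pops[pop_name]
        self.enabled[pop.offset + np.asarray(neurons, dtype=np.intp)] = flag

    def scale_param(self, proj_name: str, param: str, factor: float) -> None:
        """Multiply a per-projection plasticity constant (eta/A/beta/delta)."""
        i = [p["name"] for p in self._projs].index(proj_name)
        getattr(self, "P_" + param)[i] *= factor

    _POIS_BLOCK = 2048  # steps per independently-seeded generation block

    def _gen_block(self, block: int, rates) -> tuple[np.ndarray, np.ndarray]:
        """Poisson spikes for one absolute-step block.

        Draws are a pure function of (master seed, block index, rates), so
        the realized input spike trains do not depend on how the simulation
        is chopped into chunks — forked test phases resume on exactly the
        trajectory they left.
        """
        B = self._POIS_BLOCK
        rng = np.random.default_rng((self._pois_key, block))
        ptr = np.zeros(B + 1, dtype=np.int64)
        positive = np.unique(rates[rates > 0])
        if positive.size == 0:
            return ptr, np.empty(0, dtype=np.int32)
        groups = []
        counts_all = np.zeros(B, dtype=np.int64)
        for r in positive:
            idx = np.flatnonzero(rates == r)
            counts = rng.poisson(r * self.dt * idx.size, B)
            draws = idx[rng.integers(0, idx.size, int(counts.sum()))].astype(np.int32)
            groups.append((counts, draws))
            counts_all += counts
        ptr[1:] = np.cumsum(counts_all)
        out = np.empty(int(counts_all.sum()), dtype=np.int32)
        offs = np.zeros(B, dtype=np.int64)
        for counts, draws in groups:
            seg = np.repeat(ptr[:-1] + offs, counts)
            cum = np.concatenate([[0], np.cumsum(counts)[:-1]])
            within = np.arange(len(draws)) - np.repeat(cum, counts)
            out[seg + within] = draws
            offs += counts
        return ptr, out

    def _gen_poisson(self, n_steps: int, start_step: int | None = None):
        """Per-step CSR spike list for [start_step, start_step + n_steps).

        Spike counts per step are Poisson with mean sum(rate_i * dt) per
        distinct-rate group; emitting neurons are drawn uniformly within
        the group (a neuron may emit more than one spike per step, as a
        Poisson process allows).
        """
        if start_step is None:
            start_step = self.t_step
        B = self._POIS_BLOCK
        rates = self.pois_rates
        ptrs, idxs = [np.zeros(1, dtype=np.int64)], []
        total = 0
        s = start_step
        end = start_step + n_steps
        while s < end:
            block = s // B
            lo = s - block * B
            hi = min(end - block * B, B)
            bptr, bidx = self._gen_block(block, rates)
            ptrs.append(bptr[lo + 1 : hi + 1] - bptr[lo] + total)
            idxs.append(bidx[bptr[lo] : bptr[hi]])
            total += int(bptr[hi] - bptr[lo])
            s = (block + 1) * B
        ptr = np.concatenate(ptrs)
        idx = (
            np.concatenate(idxs) if idxs else np.empty(0, dtype=np.int32)
        )
        return ptr, idx

    def run_steps(self, n_steps: int, spike_sink=None) -> None:
        """Advance ``n_steps`` with the current Poisson rates.

        ``spike_sink(step_array, id_array)`` receives the LIF spikes (global
        step index, global neuron index) of each internal chunk.
        """
        done = 0
        while done < n_steps:
            chunk = min(4096, n_steps - done)
            ptr, idx = self._gen_poisson(chunk)
            self.run_steps_given_poisson(chunk, ptr, idx, spike_sink)
            done += chunk

    def run_steps_given_poisson(self, chunk: int, ptr, idx, spike_sink=None) -> None:
        """Advance ``chunk`` steps with an explicit Poisson spike list
        (per-step CSR: ``ptr`` of length chunk+1 into ``idx``)."""
        if True:
            cap = max(65536, int(chunk * self.NL * 0.02))
            t_in_chunk = 0
            while t_in_chunk < chunk:
                out_step = np.empty(cap, dtype=np.int64)
                out_id = np.empty(cap, dtype=np.int32)
                consumed, self._n_prev, n_out = _step_kernel(
                    chunk - t_in_chunk, self.dt, self.t_step,
                    self.U, self.TH, self.GA, self.GN, self.GG, self.GAD,
                    self.ZP, self.ZM, self.ZS, self.ZHT, self.CH, self.ZI,
                    self.SU, self.SX,
                    self.c_mem, self.Urest, self.Uexc, self.Uinh,
                    self.threst, self.thspike, self.c_thr, self.alpha,
                    self.f_ampa, self.f_gaba, self.f_a, self.c_nmda, self.Da,
                    self.f_zp, self.f_zm, self.f_zs, self.f_zht, self.f_zi,
                    self.f_C, self.Ustp, self.e_d, self.e_f,
                    self.is_exc, self.region_of, self.enabled,
                    self.R_H, self.R_fH, self.R_gamma,
                    self.QU, self.QX, self.QZP,
                    self.Q_Ustp, self.Q_e_d, self.Q_e_f, self.Q_f_zp,
                    self.P_kind, self.P_src_kind, self.P_src_off, self.P_n_src,
                    self.P_tgt0, self.P_n_tgt, self.P_tgt_region,
                    self.P_use_stp, self.P_inh_syn,
                    self.P_eta, self.P_A, self.P_beta, self.P_delta,
                    self.P_wmin, self.P_wmax,
                    self.P_ind0, self.IND, self.P_syn0,
                    self.S_tgt, self.S_w, self.S_wt,
                    self.P_col0, self.CPTR, self.C_syn, self.C_src,
                    self.P_blk0, self.BLK,
                    ptr[t_in_chunk:] - ptr[t_in_chunk],
                    idx[ptr[t_in_chunk]:],
                    self._prev_spk, self._n_prev,
                    out_step, out_id, cap,
                )
                if not np.all(np.isfinite(self.U)):
                    bad = int(np.flatnonzero(~np.isfinite(self.U))[0])
                    raise FloatingPointError(
                        f"membrane diverged at neuron {bad}, t={self.t:.3f} s"
                    )
                self.t_step += consumed
                if spike_sink is not None and n_out:
                    spike_sink(out_step[:n_out], out_id[:n_out])
                t_in_chunk += consumed
                if consumed == 0:
                    cap *= 4

    def consolidation_tick(self) -> None:
        """Advance every consolidating projection's reference weights by one
        long step (Euler, step ``dt_long``)."""
        for i, p in enumerate(self._projs):
            if p["kind"] != K_EXC_PLASTIC:
                continue
            tau = p["tau_cons"]
            view = self.projections[p["name"]]
            w = view.w
            wt = view.w_tilde
            # inline double-well Euler step (P, w_P from the target region)
            reg = self.spec.regions[p["tgt_region"]].exc_plasticity
            drift = w - wt - reg.P * wt * (reg.w_P / 2.0 - wt) * (reg.w_P - wt)
            wt += (self.dt_long / tau) * drift
            if not np.all(np.isfinite(wt)):
                raise FloatingPointError(
                    f"reference weights diverged on {p['name']}; "
                    f"dt_long/tau_cons = {self.dt_long / tau:.3g}"
                )

    def run(self, duration: float, spike_sink=None) -> None:
        """Run for ``duration`` seconds, interleaving consolidation ticks
        every ``dt_long`` of simulated time."""
        n_total = int(round(duration / self.dt))
        steps_per_tick = int(round(self.dt_long / self.dt))
        done = 0
        while done < n_total:
            until_tick = steps_per_tick - (self.t_step % steps_per_tick)
            n = min(until_tick, n_total - done)
            self.run_steps(n, spike_sink)
            done += n
            if self.t_step % steps_per_tick == 0:
                self.consolidation_tick()

    # ------------------------------------------------------------------
    def state_dict(self) -> dict:
        """Deep copy of all mutable simulation state (for forked testing)."""
        arrays = [
            "U", "TH", "GA", "GN", "GG", "GAD", "ZP", "ZM", "ZS", "ZHT",
            "CH", "ZI", "SU", "SX", "R_H", "QU", "QX", "QZP",
            "S_w", "S_wt", "BLK", "enabled", "pois_rates", "_prev_spk",
            "P_eta", "P_A", "P_beta", "P_delta",
        ]
        d = {a: getattr(self, a).copy() for a in arrays}
        d["_n_prev"] = self._n_prev
        d["t_step"] = self.t_step
        d["rng_poisson"] = self.rng_poisson.bit_generator.state
        return d

    def load_state(self, d: dict) -> None:
        for a, v in d.items():
            if a == "_n_prev":
                self._n_prev = v
            elif a == "t_step":
                self.t_step = v
            elif a == "rng_poisson":
                self.rng_poisson.bit_generator.state = v
            else:
                getattr(self, a)[...] = v


def build_network(spec: NetworkSpec) -> Simulator:
    """Construct a ready-to-run simulator from a network spec."""
    return Simulator(spec)
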