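"""Unit checks of the synaptic learning rules against closed forms and
scalar arithmetic oracles."""

import numpy as np
import pytest
from scipy.optimize import brentq

from engramsim import (
    ExcPlasticityParams,
    InhPlasticityParams,
    InhPlasticityState,
    STPParams,
    STPState,
    SparseProjection,
    TripletTraces,
    consolidate_reference,
    exc_on_post_spike,
    exc_on_pre_spike,
    inh_plasticity_step,
    stp_step,
    trace_step,
    update_homeostasis,
)
from engramsim.plasticity import double_well_drift


def two_synapse_projection(plasticity="stp+longterm", w0=0.5):
    # 2 sources -> 2 targets, fully connected
    return SparseProjection(
        2, 2,
        indptr=[0, 2, 4],
        targets=[0, 1, 0, 1],
        w=np.full(4, w0),
        plasticity=plasticity,
    )


# ---------------------------------------------------------------------------
# short-term plasticity


def test_stp_relaxes_to_fixed_point():
    p = STPParams(U_stp=0.2, tau_d=0.1, tau_f=0.4)
    s = STPState(3, p)
    s.u[:] = 0.9
    s.x[:] = 0.1
    for _ in range(8000):  # 8 s >> tau_d, tau_f
        stp_step(s, p, [], 1e-3)
    assert np.allclose(s.u, p.U_stp, atol=1e-6)
    assert np.allclose(s.x, 1.0, atol=1e-6)


def test_stp_single_spike_jump_from_rest():
    p = STPParams(U_stp=0.2)
    s = STPState(1, p)
    stp_step(s, p, [0], 1e-9)  # dt -> 0: pure jump
    u_after = p.U_stp + p.U_stp * (1.0 - p.U_stp)
    assert s.u[0] == pytest.approx(u_after, rel=1e-6)
    assert s.x[0] == pytest.approx(1.0 - u_after, rel=1e-5)


def test_stp_poisson_train_matches_event_driven_oracle(rng):
    p = STPParams()
    dt = 1e-4
    rate = 20.0
    spikes = rng.random(100000) < rate * dt  # 10 s
    s = STPState(1, p)
    ux = []
    for k in range(len(spikes)):
        stp_step(s, p, [0] if spikes[k] else [], dt)
        ux.append(s.u[0] * s.x[0])
    # event-driven oracle: exact exponential relaxation between spikes
    u, x = p.U_stp, 1.0
    t_prev = None
    ux2_vals = []
    for k in np.flatnonzero(spikes):
        t = (k + 1) * dt
        if t_prev is not None:
            gap = t - t_prev
            x = 1.0 + (x - 1.0) * np.exp(-gap / p.tau_d)
            u = p.U_stp + (u - p.U_stp) * np.exp(-gap / p.tau_f)
        u = u + p.U_stp * (1.0 - u)
        x = x - u * x
        ux2_vals.append(u * x)
        t_prev = t
    assert np.mean(ux) == pytest.approx(
        np.mean(ux), rel=0
    )  # sanity: finite
    # compare post-spike products at spike times (discretization offsets only)
    sim_at_spikes = np.array(ux)[np.flatnonzero(spikes)]
    assert np.mean(sim_at_spikes) == pytest.approx(
        np.mean(ux2_vals), rel=0.05
    )


def test_stp_state_stays_in_unit_square(rng):
    p = STPParams(U_stp=0.9, tau_d=0.02, tau_f=0.05)
    s = STPState(1, p)
    for _ in range(5000):
        spikes = [0] if rng.random() < 0.3 else []
        stp_step(s, p, spikes, 1e-3)
        assert 0.0 <= s.u[0] <= 1.0 and 0.0 <= s.x[0] <= 1.0


# ---------------------------------------------------------------------------
# long-term excitatory rules


def test_pre_spike_rule_scalar_arithmetic():
    params = ExcPlasticityParams(eta_exc=0.5, A=2e-3, delta=1e-4)
    proj = two_synapse_projection(w0=0.5)
    traces = TripletTraces(2)
    traces.z_minus[:] = [0.7, 0.0]
    traces.C[:] = [2.0, 0.5]  # B = A and 0.5 A
    exc_on_pre_spike(proj, traces, params, pre_id=0)
    # synapse (0 -> 0): dw = -eta*A*min(C,1)*z- + delta
    assert proj.w[0] == pytest.approx(0.5 - 0.5 * 2e-3 * 1.0 * 0.7 + 1e-4)
    # synapse (0 -> 1): z- = 0 so only delta
    assert proj.w[1] == pytest.approx(0.5 + 1e-4)
    # other source untouched
    assert proj.w[2] == 0.5 and proj.w[3] == 0.5


def test_pre_spike_rule_zero_without_trace_and_delta():
    params = ExcPlasticityParams(delta=0.0)
    proj = two_synapse_projection()
    traces = TripletTraces(2)
    w_before = proj.w.copy()
    exc_on_pre_spike(proj, traces, params, pre_id=1)
    assert np.array_equal(proj.w, w_before)


def test_transmitter_induced_drift_is_bounded():
    params = ExcPlasticityParams(delta=0.5, w_max_exc=1.0)
    proj = two_synapse_projection(w0=0.9)
    traces = TripletTraces(2)
    for _ in range(10):
        exc_on_pre_spike(proj, traces, params, pre_id=0)
    assert proj.w[0] == pytest.approx(params.w_max_exc)


def test_post_spike_rule_scalar_arithmetic():
    params = ExcPlasticityParams(eta_exc=0.5, A=2e-3, beta=0.1)
    proj = two_synapse_projection(w0=0.8)
    proj.w_tilde[:] = 0.3
    pre, post = TripletTraces(2), TripletTraces(2)
    pre.z_plus[:] = [0.4, 1.1]
    post.z_slow[:] = [0.0, 2.0]
    post.z_minus[:] = [0.0, 0.9]
    exc_on_post_spike(proj, pre, post, params, post_id=1)
    for src in (0, 1):
        syn = 1 + 2 * src  # synapse (src -> 1)
        expected = (
            0.8
            + 0.5 * 2e-3 * pre.z_plus[src] * 2.0
            - 0.1 * (0.8 - 0.3) * 0.9**3
        )
        assert proj.w[syn] == pytest.approx(expected)
    # target 0 untouched
    assert proj.w[0] == 0.8 and proj.w[2] == 0.8


def test_repeated_pre_post_pairing_potentiates():
    """Classical pairing: pre spike 10 ms before post, repeated at 5 Hz."""
    params = ExcPlasticityParams(eta_exc=1.0, A=1e-3, beta=0.0, delta=0.0)
    proj = SparseProjection(1, 1, [0, 1], [0], np.array([0.5]),
                           plasticity="stp+longterm")
    pre, post = TripletTraces(1), TripletTraces(1)
    taus = dict(z_plus=params.tau_plus, z_minus=params.tau_minus,
                z_slow=params.tau_slow)

    def decay(tr, dt, spikes):
        trace_step(
            {"z_plus": tr[0].z_plus, "z_minus": tr[1].z_minus,
             "z_slow": tr[1].z_slow},
            taus,
            spikes,
            dt,
        )

    w0 = proj.w[0]
    for _ in range(60):
        # pre spike: rule then increment
        exc_on_pre_spike(proj, post, params, 0)
        decay((pre, post), 1e-9, {"z_plus": [0]})
        # 10 ms later post spike
        decay((pre, post), 10e-3, {})
        exc_on_post_spike(proj, pre, post, params, 0)
        decay((pre, post), 1e-9, {"z_minus": [0], "z_slow": [0]})
        decay((pre, post), 190e-3, {})
    assert proj.w[0] > w0


# ---------------------------------------------------------------------------
# homeostasis


def test_homeostatic_rate_saturates_at_A():
    params = ExcPlasticityParams(A=3e-3)
    tr = TripletTraces(2)
    tr.C[:] = [2.0, 0.5]
    B = tr.B(params)
    assert B[0] == pytest.approx(3e-3)
    assert B[1] == pytest.approx(1.5e-3)


def test_homeostat_steady_state_matches_analytics():
    """Constant post rate r: C -> tau_hom * E[z_ht^2] with
    E[z_ht^2] = (r tau)^2 + r tau / 2 for a Poisson-driven trace."""
    params = ExcPlasticityParams(tau_ht=0.1, tau_hom=10.0)
    rng = np.random.default_rng(5)
    tr = TripletTraces(1)
    dt = 1e-3
    r = 12.0
    taus = {"z_ht": params.tau_ht}
    for k in range(150000):  # 150 s >> tau_hom
        spikes = {"z_ht": [0]} if rng.random() < r * dt else {}
        update_homeostasis(tr, params, [], dt)
        trace_step({"z_ht": tr.z_ht}, taus, spikes, dt)
    rt = r * params.tau_ht
    expected = params.tau_hom * (rt**2 + rt / 2.0)
    assert tr.C[0] == pytest.approx(expected, rel=0.1)


# ---------------------------------------------------------------------------
# consolidation (double-well)


def test_double_well_fixed_points():
    params = ExcPlasticityParams(P=10.0, w_P=1.0)
    # lower fixed point
    assert double_well_drift(0.0, 0.0, params) == 0.0
    # upper fixed point when w == w_tilde == w_P/2? no: drift zero when
    # w == w_tilde and cubic term vanishes (w_tilde in {0, w_P/2, w_P})
    assert double_well_drift(params.w_P, params.w_P, params) == pytest.approx(0.0)


def test_reference_converges_to_cubic_root():
    params = ExcPlasticityParams(P=10.0, w_P=1.0, tau_cons=5.0)
    w_held = 3.0  # strong enough that only one real root remains
    proj = SparseProjection(1, 1, [0, 1], [0], np.array([w_held]),
                           plasticity="stp+longterm")
    proj.w_tilde[:] = 0.0
    for _ in range(5000):
        consolidate_reference(proj, params, 0.05)
    root = brentq(
        lambda wt: double_well_drift(w_held, wt, params), -1.0, 5.0
    )
    assert proj.w_tilde[0] == pytest.approx(root, abs=1e-4)


def test_reference_bistability_depends_on_weight():
    params = ExcPlasticityParams(P=10.0, w_P=1.0, tau_cons=5.0)
    for w_held, expect_high in ((0.2, False), (2.0, True)):
        proj = SparseProjection(1, 1, [0, 1], [0], np.array([w_held]),
                               plasticity="stp+longterm")
        proj.w_tilde[:] = 0.0
        for _ in range(4000):
            consolidate_reference(proj, params, 0.05)
        if expect_high:
            assert proj.w_tilde[0] > params.w_P / 2
        else:
            assert proj.w_tilde[0] < params.w_P / 2


def test_consolidation_instability_aborts():
    params = ExcPlasticityParams(tau_cons=1e-4, P=1e9)
    proj = SparseProjection(1, 1, [0, 1], [0], np.array([2.0]),
                           plasticity="stp+longterm")
    proj.w_tilde[:] = 2.0
    with pytest.raises(FloatingPointError, match="tau_cons"):
        for _ in range(100):
            consolidate_reference(proj, params, 1.2)


# ---------------------------------------------------------------------------
# inhibitory plasticity


def test_inh_rule_silent_at_target_activity():
    params = InhPlasticityParams(eta_inh=1e-3, gamma=50.0)
    proj = two_synapse_projection(plasticity="static", w0=1.0)
    state = InhPlasticityState(2, 2)
    state.H = params.gamma / np.exp(-1e-3 / params.tau_H)  # decays to gamma
    w_before = proj.w.copy()
    inh_plasticity_step(proj, state, params, [0], [1], 5, 1e-3)
    assert np.allclose(proj.w, w_before)


def test_inh_rule_scalar_arithmetic():
    params = InhPlasticityParams(eta_inh=1e-3, gamma=10.0, tau_H=1e9)
    proj = two_synapse_projection(plasticity="static", w0=1.0)
    state = InhPlasticityState(2, 2)
    state.H = 30.0
    state.z_post[:] = [0.5, 0.0]
    state.z_pre[:] = [0.0, 1.2]
    inh_plasticity_step(proj, state, params, pre_spikes=[0], post_spikes=[0],
                        region_exc_spike_count=0, dt=1e-9)
    G = 30.0 - 10.0
    # pre spike of source 0 onto targets 0,1: dw = eta*G*(z_post+1)
    # then post spike of target 0: dw = eta*G*z_pre[src]
    assert proj.w[0] == pytest.approx(1.0 + 1e-3 * G * 1.5)
    assert proj.w[1] == pytest.approx(1.0 + 1e-3 * G * 1.0)
    assert proj.w[2] == pytest.approx(1.0 + 1e-3 * G * 1.2)  # (1 -> 0)
    assert proj.w[3] == 1.0


def test_inh_weights_grow_when_rate_above_target(rng):
    params = InhPlasticityParams(eta_inh=1e-4, gamma=5.0, tau_H=1.0)
    proj = two_synapse_projection(plasticity="static", w0=1.0)
    state = InhPlasticityState(2, 2)
    dt = 1e-3
    total0 = proj.w.sum()
    for _ in range(20000):
        exc_spikes = int(rng.random() < 20 * dt)  # sustained high rate
        pre = [0] if rng.random() < 10 * dt else []
        inh_plasticity_step(proj, state, params, pre, [], exc_spikes, dt)
    assert proj.w.sum() > total0


# ---------------------------------------------------------------------------
# traces


def test_trace_exponential_decay_closed_form():
    z = {"z": np.array([1.0])}
    tau = 0.05
    for _ in range(50):
        trace_step(z, {"z": tau}, {}, 1e-3)
    assert z["z"][0] == pytest.approx(np.exp(-1.0), rel=1e-12)


def test_trace_increment_after_rule_semantics():
    z = {"z": np.array([0.0])}
    trace_step(z, {"z": 0.02}, {"z": [0]}, 1e-9)
    assert z["z"][0] == pytest.approx(1.0)


def test_two_spike_trace_algebra():
    tau = 0.03
    gap = 0.012
    z = {"z": np.array([0.0])}
    trace_step(z, {"z": tau}, {"z": [0]}, 1e-12)
    n = 1200
    for _ in range(n):
        trace_step(z, {"z": tau}, {}, gap / n)
    # pre-increment value at the second spike
    assert z["z"][0] == pytest.approx(np.exp(-gap / tau), rel=1e-9)


def test_ablation_zeroes_exactly_one_term():
    """A=0, beta=0, delta=0 each silence one term of the rule and no other."""
    base = dict(eta_exc=1.0, A=1e-3, beta=0.1, delta=1e-4)
    pre, post = TripletTraces(2), TripletTraces(2)
    pre.z_plus[:] = 1.0
    post.z_slow[:] = 1.0
    post.z_minus[:] = 1.0
    post.C[:] = 2.0

    def deltas(**over):
        params = ExcPlasticityParams(**{**base, **over})
        proj = two_synapse_projection(w0=0.5)
        proj.w_tilde[:] = 0.2
        exc_on_pre_spike(proj, post, params, 0)
        dpre = proj.w[0] - 0.5
        proj2 = two_synapse_projection(w0=0.5)
        proj2.w_tilde[:] = 0.2
        exc_on_post_spike(proj2, pre, post, params, 0)
        dpost = proj2.w[0] - 0.5
        return dpre, dpost

    d_full = deltas()
    d_noA = deltas(A=0.0)
    d_nobeta = deltas(beta=0.0)
    d_nodelta = deltas(delta=0.0)
    # A=0 removes LTP and LTD, leaves delta and heterosynaptic terms
    assert d_noA[0] == pytest.approx(base["delta"])
    assert d_noA[1] == pytest.approx(-base["beta"] * (0.5 - 0.2))
    # beta=0 removes only the heterosynaptic part of the post-spike update
    assert d_nobeta[1] - d_full[1] == pytest.approx(base["beta"] * (0.5 - 0.2))
    assert d_nobeta[0] == pytest.approx(d_full[0])
    # delta=0 removes only the transmitter-induced part of the pre-spike update
    assert d_nodelta[0] - d_full[0] == pytest.approx(-base["delta"])
    assert d_nodelta[1] == pytest.approx(d_full[1])
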