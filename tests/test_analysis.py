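"""Engram labeling, recall metrics, coupling and statistics."""

import numpy as np
import pytest
from scipy import stats

from engramsim import (
    SpikeRaster,
    SparseProjection,
    bootstrap_ci,
    cumulative_ff_weight,
    engram_activation_fraction,
    ensemble_weight_matrix,
    label_engrams,
    lag_max,
    population_activity,
    recall_metrics,
    stat_tests,
)


# ---------------------------------------------------------------------------
# population activity


def test_empty_raster_gives_zero_series():
    r = SpikeRaster([], [], 10, duration=0.1)
    act = population_activity(r, np.arange(10), 10e-3)
    assert np.all(act == 0)


def test_hand_counted_bin():
    # 10 neurons each spiking once inside the same 10 ms bin -> 100 Hz
    times = np.full(10, 0.015)
    r = SpikeRaster(times, np.arange(10), 10, duration=0.05)
    act = population_activity(r, np.arange(10), 10e-3)
    assert act[1] == pytest.approx(100.0)
    assert act[[0, 2, 3, 4]].sum() == 0


def test_series_integral_conserves_spike_count(rng):
    times = np.sort(rng.random(500))
    ids = rng.integers(0, 20, 500)
    r = SpikeRaster(times, ids, 20, duration=1.0)
    act = population_activity(r, np.arange(20), 10e-3)
    assert act.sum() * 20 * 10e-3 == pytest.approx(500)


def test_empty_subset_rejected():
    r = SpikeRaster([0.0], [0], 4, duration=1.0)
    with pytest.raises(ValueError):
        population_activity(r, [])


# ---------------------------------------------------------------------------
# labeling


def _raster_with_rates(rate_in, rate_out, events, n=20, neuron=3, rng=None):
    """Neuron fires at rate_in during stimulus-0 windows, rate_out elsewhere."""
    rng = rng or np.random.default_rng(0)
    times = []
    t = 0.0
    for sid, a, b in events:
        r = rate_in if sid == 0 else rate_out
        k = rng.poisson(r * (b - a))
        times.extend(rng.uniform(a, b, k))
    times = np.sort(times)
    return SpikeRaster(times, np.full(len(times), neuron), n, duration=10.0)


def test_silent_raster_has_no_engrams():
    r = SpikeRaster([], [], 5, duration=1.0)
    labels = label_engrams(r, [(0, 0.0, 0.5), (1, 0.5, 1.0)], n_stimuli=2)
    assert all(len(c) == 0 for c in labels)


def test_labeling_by_stimulus_specific_rate():
    events = [(0, 0.0, 1.0), (1, 2.0, 3.0), (0, 4.0, 5.0), (1, 6.0, 7.0)]
    r = _raster_with_rates(14.0, 2.0, events)
    labels = label_engrams(r, events, zeta_thr=10.0, n_stimuli=2)
    assert 3 in labels[0]
    assert 3 not in labels[1]


def test_subthreshold_rate_excluded():
    events = [(0, 0.0, 2.0), (0, 3.0, 5.0)]
    # deterministic: exactly 8 Hz during windows
    times = np.sort(np.concatenate([np.linspace(0, 2, 16, endpoint=False),
                                    np.linspace(3, 5, 16, endpoint=False)]))
    r = SpikeRaster(times, np.full(len(times), 0), 4, duration=6.0)
    labels = label_engrams(r, events, zeta_thr=10.0, n_stimuli=1)
    assert 0 not in labels[0]


def test_labeling_monotone_in_threshold(rng):
    events = [(0, 0.0, 1.0), (0, 2.0, 3.0)]
    times = np.sort(rng.uniform(0, 3, 600))
    ids = rng.integers(0, 30, 600)
    r = SpikeRaster(times, ids, 30, duration=3.0)
    lo = label_engrams(r, events, zeta_thr=5.0, n_stimuli=1)[0]
    hi = label_engrams(r, events, zeta_thr=15.0, n_stimuli=1)[0]
    assert set(hi) <= set(lo)


def test_missing_presentations_raise():
    r = SpikeRaster([0.1], [0], 4, duration=1.0)
    with pytest.raises(ValueError, match="stimulus 1"):
        label_engrams(r, [(0, 0.0, 0.5)], n_stimuli=2)


# ---------------------------------------------------------------------------
# recall metrics


def _cue_raster(spec_rates, cues, n=40, rng=None):
    """spec_rates[(cue_index, ensemble)] -> rate of that ensemble's cells."""
    rng = rng or np.random.default_rng(7)
    times, ids = [], []
    for c, (sid, a, b) in enumerate(cues):
        for ens, cells in enumerate(ENSEMBLES):
            r = spec_rates.get((c, ens), 1.0)
            for cell in cells:
                k = rng.poisson(r * (b - a))
                times.extend(rng.uniform(a, b, k))
                ids.extend([cell] * k)
    order = np.argsort(times)
    return SpikeRaster(np.array(times)[order], np.array(ids)[order], n,
                       duration=cues[-1][2] + 1)


ENSEMBLES = [np.arange(0, 10), np.arange(10, 20), np.arange(20, 30),
             np.arange(30, 40)]


def test_recall_metrics_hand_enumeration():
    """8 cues over 4 ensembles; cue 3 also activates ensemble 2 (false
    positive), cue 7 activates nothing."""
    cues = [(c % 4, 2.0 * c, 2.0 * c + 1.0) for c in range(8)]
    rates = {}
    for c in range(8):
        if c == 7:
            continue  # cue 7 activates nothing
        rates[(c, c % 4)] = 30.0
    rates[(3, 2)] = 30.0  # extra wrong ensemble on cue 3
    r = _cue_raster(rates, cues)
    m = recall_metrics(r, ENSEMBLES, cues, zeta_thr=10.0)
    assert m.tpr == pytest.approx(7 / 8)
    assert m.accuracy == pytest.approx(6 / 8)
    assert m.fpr == pytest.approx((1 / 3) / 8)
    assert m.n_cues == 8


def test_recall_perfect_and_silent_cases():
    cues = [(c % 4, 2.0 * c, 2.0 * c + 1.0) for c in range(4)]
    perfect = _cue_raster({(c, c % 4): 30.0 for c in range(4)}, cues)
    m = recall_metrics(perfect, ENSEMBLES, cues)
    assert (m.accuracy, m.tpr, m.fpr) == (1.0, 1.0, 0.0)
    silent = _cue_raster({}, cues)
    m = recall_metrics(silent, ENSEMBLES, cues)
    assert (m.accuracy, m.tpr, m.fpr) == (0.0, 0.0, 0.0)


def test_accuracy_never_exceeds_tpr(rng):
    for trial in range(10):
        cues = [(int(rng.integers(4)), 2.0 * c, 2.0 * c + 1.0) for c in range(6)]
        rates = {
            (c, e): float(rng.choice([2.0, 30.0]))
            for c in range(6)
            for e in range(4)
        }
        r = _cue_raster(rates, cues, rng=rng)
        m = recall_metrics(r, ENSEMBLES, cues)
        assert m.accuracy <= m.tpr + 1e-12
        assert 0 <= m.fpr <= 1


def test_engram_activation_fraction_counts_active_members():
    cues = [(0, 0.0, 1.0)]
    # ensemble 0 activated; half its cells fire at 30 Hz, half at 2 Hz
    rng = np.random.default_rng(3)
    times, ids = [], []
    for cell in range(5):
        k = rng.poisson(30.0)
        times.extend(rng.uniform(0, 1, k)); ids.extend([cell] * k)
    for cell in range(5, 10):
        k = rng.poisson(2.0)
        times.extend(rng.uniform(0, 1, k)); ids.extend([cell] * k)
    order = np.argsort(times)
    r = SpikeRaster(np.array(times)[order], np.array(ids)[order], 40, duration=2.0)
    frac = engram_activation_fraction(r, ENSEMBLES, cues)
    assert frac == pytest.approx(0.5, abs=0.21)


# ---------------------------------------------------------------------------
# bootstrap


def test_bootstrap_degenerate_values():
    lo, hi = bootstrap_ci([0.7, 0.7, 0.7], rng=0)
    assert lo == pytest.approx(0.7) and hi == pytest.approx(0.7)
    assert hi - lo == pytest.approx(0.0, abs=1e-12)


def test_bootstrap_brackets_mean(rng):
    vals = np.repeat([0.0, 1.0], 50)
    lo, hi = bootstrap_ci(vals, rng=rng)
    assert lo < 0.5 < hi
    assert hi - lo < 0.4


def test_bootstrap_coverage_on_gaussian():
    rng = np.random.default_rng(11)
    cover = 0
    n_rep = 120
    for _ in range(n_rep):
        vals = rng.normal(0.0, 1.0, 25)
        lo, hi = bootstrap_ci(vals, level=0.90, n_boot=500, rng=rng)
        cover += lo <= 0.0 <= hi
    assert cover / n_rep == pytest.approx(0.90, abs=0.07)


# ---------------------------------------------------------------------------
# lag_max


def test_identical_series_zero_lag(rng):
    a = rng.random(2000)
    r = lag_max(a, a, 10e-3)
    assert r.lag == 0.0
    assert r.corr == pytest.approx(1.0)


def test_shifted_series_recovers_shift_with_sign(rng):
    a = rng.random(4000)
    shift = 250  # b lags a by 250 bins = 2.5 s at 10 ms
    b = np.roll(a, shift)
    r = lag_max(a[500:3500], b[500:3500], 10e-3)
    # positive lag = first series leads
    assert r.lag == pytest.approx(2.5)


def test_antisymmetry(rng):
    a, b = rng.random(3000), rng.random(3000)
    b[5:] += 0.5 * a[:-5]
    r_ab = lag_max(a, b, 10e-3)
    r_ba = lag_max(b, a, 10e-3)
    assert r_ab.lag == pytest.approx(-r_ba.lag)


def test_periodic_series_tie_breaks_to_smallest_lag():
    t = np.arange(3000)
    a = np.sin(2 * np.pi * t / 200)  # period 2 s at 10 ms bins
    b = np.roll(a, 40)  # shift 0.4 s
    r = lag_max(a, b, 10e-3, max_lag=10.0)
    assert r.lag == pytest.approx(0.4, abs=0.011)


def test_zero_variance_rejected():
    with pytest.raises(ValueError, match="variance"):
        lag_max(np.ones(100), np.random.default_rng(0).random(100), 1e-2)


# ---------------------------------------------------------------------------
# weight summaries


def _hand_projection():
    # 6 sources -> 6 targets; strong within-ensemble, weak between
    ens = [np.array([0, 1, 2]), np.array([3, 4, 5])]
    indptr = np.arange(0, 37, 6)
    targets = np.tile(np.arange(6), 6)
    src = np.repeat(np.arange(6), 6)
    w = np.where((src < 3) == (targets < 3), 0.8, 0.1).astype(float)
    return SparseProjection(6, 6, indptr, targets, w), ens


def test_ensemble_weight_matrix_matches_hand_computation():
    proj, ens = _hand_projection()
    M, diag, off = ensemble_weight_matrix(proj, ens, ens)
    assert np.allclose(np.diag(M), 0.8)
    assert M[0, 1] == pytest.approx(0.1) and M[1, 0] == pytest.approx(0.1)
    ks = stats.ks_2samp(diag, off)
    assert ks.pvalue < 0.05


def test_uniform_weights_give_constant_matrix():
    proj, ens = _hand_projection()
    proj.w[:] = 0.3
    M, diag, off = ensemble_weight_matrix(proj, ens, ens)
    assert np.allclose(M, 0.3)


def test_empty_ensemble_rejected():
    proj, ens = _hand_projection()
    with pytest.raises(ValueError, match="empty"):
        ensemble_weight_matrix(proj, [np.array([]), ens[1]], ens)


def test_cumulative_ff_weight_degenerate_and_random(rng):
    proj, ens = _hand_projection()
    proj.w[:] = 0.5  # in-degree 6 everywhere -> all sums = 3.0
    sums = cumulative_ff_weight(proj, ens)
    assert np.allclose(sums, 3.0)
    proj.w[:] = rng.random(proj.n_synapses)
    sums = cumulative_ff_weight(proj, [np.arange(6)])
    direct = np.zeros(6)
    src = np.repeat(np.arange(6), 6)
    for s, t, w in zip(src, proj.targets, proj.w):
        direct[t] += w
    assert np.allclose(sums, np.sort(direct))


# ---------------------------------------------------------------------------
# statistics


def test_ks_identical_samples():
    stat, p, kind = stat_tests([1, 2, 3, 4.0], [1, 2, 3, 4.0], "ks")
    assert stat == 0.0


def test_mannwhitney_matches_pair_enumeration(rng):
    a = rng.random(8)
    b = rng.random(6)
    stat, p, _ = stat_tests(a, b, "mannwhitney")
    u_brute = sum((x > y) + 0.5 * (x == y) for x in a for y in b)
    assert stat == pytest.approx(u_brute)


def test_welch_detects_shift_at_large_n(rng):
    a = rng.normal(0, 1, 500)
    b = rng.normal(0.5, 2, 500)
    stat, p, _ = stat_tests(a, b, "welch")
    assert p < 0.05


def test_auto_routing(rng):
    a = rng.normal(0, 1, 40)
    b = rng.normal(0, 1, 40)
    _, _, kind = stat_tests(a, b, "auto")
    assert kind == "ttest"
    c = rng.exponential(1, 40)
    _, _, kind = stat_tests(a, c, "auto")
    assert kind in ("mannwhitney", "welch")
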