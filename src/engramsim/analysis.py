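"""Engram labeling, recall metrics, reactivation coupling and statistics.

An *engram cell* for a stimulus is a neuron whose mean stimulus-evoked
firing rate over the presentation windows in the final part of training
exceeds the threshold zeta_thr (10 Hz).  An engram *ensemble* is activated
by a cue when its population rate during the cue window exceeds the same
threshold.  Recall true-positive rate, false-positive rate and accuracy
follow from ensemble activations per cue; cross-region reactivation
coupling is quantified by the lag maximizing the Pearson cross-correlogram
of binned ensemble activities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

__all__ = [
    "SpikeRaster",
    "RecallMetrics",
    "LagResult",
    "population_activity",
    "label_engrams",
    "recall_metrics",
    "engram_activation_fraction",
    "bootstrap_ci",
    "lag_max",
    "ensemble_weight_matrix",
    "cumulative_ff_weight",
    "stat_tests",
]


class SpikeRaster:
    """Time-ordered spike events (time [s], neuron index) of one population."""

    def __init__(self, times, ids, n_neurons: int, t0: float = 0.0,
                 duration: float | None = None):
        times = np.asarray(times, dtype=np.float64)
        ids = np.asarray(ids, dtype=np.int64)
        if times.shape != ids.shape:
            raise ValueError("times and ids must align")
        if times.size and np.any(np.diff(times) < 0):
            raise ValueError("times must be nondecreasing")
        keep = (ids >= 0) & (ids < n_neurons)
        self.times = times[keep]
        self.ids = ids[keep]
        self.n_neurons = int(n_neurons)
        self.t0 = float(t0)
        self.duration = float(
            duration if duration is not None
            else (self.times.max() - t0 if self.times.size else 0.0)
        )

    def __len__(self):
        return len(self.times)

    def window_counts(self, windows, subset=None) -> np.ndarray:
        """Per-neuron spike counts inside the union of [a, b) windows."""
        counts = np.zeros(self.n_neurons)
        for a, b in windows:
            lo = np.searchsorted(self.times, a, side="left")
            hi = np.searchsorted(self.times, b, side="left")
            np.add.at(counts, self.ids[lo:hi], 1.0)
        if subset is not None:
            return counts[np.asarray(subset, dtype=np.intp)]
        return counts


@dataclass
class RecallMetrics:
    accuracy: float
    tpr: float
    fpr: float
    n_cues: int


@dataclass
class LagResult:
    """Correlation-maximizing lag between two binned activities.

    ``lag`` is in seconds; positive means the *first* series leads (its
    activity precedes matching activity in the second).  Ties are broken
    toward the smallest absolute lag.
    """

    lag: float
    corr: float
    bin_width: float
    max_lag: float


def population_activity(
    raster: SpikeRaster, subset, bin_width: float = 10e-3
) -> np.ndarray:
    """Population rate [Hz] of a neuron subset in fixed bins, unsmoothed.

    rate(t) = spike count of the subset in the bin / (|subset| * bin).
    """
    if bin_width <= 0:
        raise ValueError("bin width must be > 0")
    subset = np.asarray(subset, dtype=np.intp)
    if subset.size == 0:
        raise ValueError("subset must be nonempty")
    n_bins = max(1, int(np.ceil(raster.duration / bin_width)))
    mask = np.zeros(raster.n_neurons, dtype=bool)
    mask[subset] = True
    sel = mask[raster.ids]
    b = ((raster.times[sel] - raster.t0) / bin_width).astype(np.int64)
    b = b[(b >= 0) & (b < n_bins)]
    counts = np.bincount(b, minlength=n_bins).astype(np.float64)
    return counts / (subset.size * bin_width)


def label_engrams(
    raster: SpikeRaster,
    presentation_events,
    zeta_thr: float = 10.0,
    n_stimuli: int | None = None,
) -> list[np.ndarray]:
    """Label engram cells per stimulus from training presentation windows.

    ``presentation_events`` is a list of (stimulus id, on, off) times within
    the raster.  A neuron joins the ensemble of stimulus s when its mean
    rate over s's presentation windows exceeds ``zeta_thr``; one neuron may
    belong to several ensembles.  Returns a list of index arrays.
    """
    if n_stimuli is None:
        n_stimuli = max(e[0] for e in presentation_events) + 1
    out = []
    for s in range(n_stimuli):
        windows = [(a, b) for sid, a, b in presentation_events if sid == s]
        total = sum(b - a for a, b in windows)
        if total <= 0:
            raise ValueError(f"no presentations of stimulus {s} in the window")
        counts = raster.window_counts(windows)
        out.append(np.flatnonzero(counts / total > zeta_thr))
    return out


def _activations(raster, labels, cue_events, zeta_thr):
    """Boolean activation matrix: rows = cues, cols = ensembles."""
    k = len(labels)
    acts = np.zeros((len(cue_events), k), dtype=bool)
    for c, (sid, a, b) in enumerate(cue_events):
        for s in range(k):
            cells = labels[s]
            if len(cells) == 0:
                continue
            n_spk = raster.window_counts([(a, b)], subset=cells).sum()
            rate = n_spk / (len(cells) * (b - a))
            acts[c, s] = rate > zeta_thr
    return acts


def recall_metrics(
    raster: SpikeRaster,
    labels,
    cue_events,
    zeta_thr: float = 10.0,
) -> RecallMetrics:
    """Recall metrics over a testing phase.

    t.p.r. — fraction of cue presentations that activate the cued ensemble;
    f.p.r. — fraction of the other k-1 ensembles activated, averaged over
    cues; accuracy — fraction of cues where *only* the cued ensemble is
    activated.
    """
    if not len(cue_events):
        raise ValueError("empty test schedule")
    k = len(labels)
    acts = _activations(raster, labels, cue_events, zeta_thr)
    cued = np.array([sid for sid, _, _ in cue_events])
    own = acts[np.arange(len(cue_events)), cued]
    others = acts.sum(axis=1) - own
    tpr = own.mean()
    fpr = (others / max(k - 1, 1)).mean()
    acc = (own & (others == 0)).mean()
    return RecallMetrics(float(acc), float(tpr), float(fpr), len(cue_events))


def engram_activation_fraction(
    raster: SpikeRaster, labels, cue_events, zeta_thr: float = 10.0
) -> float:
    """Of the labeled cells in an ensemble *activated* by its cue, the
    fraction individually firing above ``zeta_thr`` during the cue window,
    averaged over activating cue presentations.  NaN if no cue activates
    its ensemble."""
    acts = _activations(raster, labels, cue_events, zeta_thr)
    fracs = []
    for c, (sid, a, b) in enumerate(cue_events):
        if not acts[c, sid]:
            continue
        cells = labels[sid]
        rates = raster.window_counts([(a, b)], subset=cells) / (b - a)
        fracs.append(np.mean(rates > zeta_thr))
    return float(np.mean(fracs)) if fracs else float("nan")


def bootstrap_ci(
    values,
    level: float = 0.90,
    n_boot: int = 10_000,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap interval for the mean of per-trial metrics."""
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ValueError("need at least one value")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    means = values[idx].mean(axis=1)
    lo, hi = np.percentile(means, [(1 - level) / 2 * 100, (1 + level) / 2 * 100])
    return float(lo), float(hi)


def lag_max(
    activity_a,
    activity_b,
    bin_width: float,
    max_lag: float | None = None,
) -> LagResult:
    """Lag maximizing the Pearson cross-correlogram of two rate series.

    Series are mean-subtracted; the correlation at each lag is normalized by
    the overlap length and the full-series standard deviations (Pearson per
    lag).  Ties are broken toward the smallest |lag|.  Positive lag =
    ``activity_a`` leads ``activity_b``.
    """
    a = np.asarray(activity_a, dtype=np.float64)
    b = np.asarray(activity_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("series must have equal length")
    n = a.size
    if max_lag is None:
        max_lag = (n - 1) * bin_width / 2
    L = min(n - 1, int(round(max_lag / bin_width)))
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance series")
    # exact Pearson correlation per lag: at lag k >= 0 the overlapping
    # segments are a[:n-k] and b[k:]; means and variances are computed per
    # segment (prefix sums), the cross term comes from an FFT correlation.
    cc = signal.correlate(b, a, mode="full", method="fft")  # raw sum a_i b_{i+k}
    csa = np.concatenate([[0.0], np.cumsum(a)])
    csb = np.concatenate([[0.0], np.cumsum(b)])
    csa2 = np.concatenate([[0.0], np.cumsum(a * a)])
    csb2 = np.concatenate([[0.0], np.cumsum(b * b)])
    ks = np.arange(-L, L + 1)
    m = n - np.abs(ks)
    pos = ks >= 0
    kp = np.where(pos, ks, 0)
    kn = np.where(pos, 0, -ks)
    sa_ = np.where(pos, csa[m], csa[n] - csa[kn])
    sa2_ = np.where(pos, csa2[m], csa2[n] - csa2[kn])
    sb_ = np.where(pos, csb[n] - csb[kp], csb[m])
    sb2_ = np.where(pos, csb2[n] - csb2[kp], csb2[m])
    cross = cc[ks + n - 1]
    va = sa2_ - sa_ * sa_ / m
    vb = sb2_ - sb_ * sb_ / m
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (cross - sa_ * sb_ / m) / np.sqrt(va * vb)
    corr[(va <= 0) | (vb <= 0)] = -np.inf
    # ties (within numerical noise of the maximum) break toward |lag| -> 0
    top = corr.max()
    tied = np.flatnonzero(corr >= top - 1e-9)
    best = tied[np.argmin(np.abs(ks[tied]))]
    return LagResult(
        lag=float(ks[best] * bin_width),
        corr=float(corr[best]),
        bin_width=float(bin_width),
        max_lag=float(L * bin_width),
    )


def ensemble_weight_matrix(proj, labels_source, labels_target):
    """k x k mean weights clustered by engram preference.

    Entry (a, b) = mean weight over synapses from ensemble-b source cells to
    ensemble-a target cells (diagonal = within-ensemble).  Also returns the
    raw within/between weight samples for distribution tests:
    (matrix, diag_weights, offdiag_weights).
    """
    k = len(labels_target)
    if any(len(c) == 0 for c in labels_source) or any(
        len(c) == 0 for c in labels_target
    ):
        raise ValueError("empty ensemble")
    src_of = np.repeat(np.arange(proj.n_source), np.diff(proj.indptr))
    M = np.full((k, k), np.nan)
    diag, off = [], []
    src_masks = [np.isin(src_of, c) for c in labels_source]
    tgt_masks = [np.isin(proj.targets, c) for c in labels_target]
    for a in range(k):
        for b in range(k):
            sel = tgt_masks[a] & src_masks[b]
            if sel.any():
                M[a, b] = proj.w[sel].mean()
                (diag if a == b else off).append(proj.w[sel])
    diag = np.concatenate(diag) if diag else np.empty(0)
    off = np.concatenate(off) if off else np.empty(0)
    return M, diag, off


def cumulative_ff_weight(proj, labels_target):
    """Total afferent weight per target engram cell, as sorted samples.

    Returns the per-cell sums (the empirical CDF is their sorted sequence).
    """
    cells = np.concatenate([np.asarray(c) for c in labels_target]) if isinstance(
        labels_target, (list, tuple)
    ) else np.asarray(labels_target)
    if cells.size == 0:
        raise ValueError("labels must be nonempty")
    cells = np.unique(cells)
    sums = np.zeros(proj.n_target)
    np.add.at(sums, proj.targets, proj.w)
    return np.sort(sums[cells])


def stat_tests(sample_a, sample_b, kind: str = "auto"):
    """Two-sided two-sample test; returns (statistic, p_value, kind_used).

    kinds: ``mannwhitney``, ``ks``, ``ttest`` (equal variances), ``welch``;
    ``auto`` routes like the model's statistics: normal + equal variances ->
    t-test, normal + unequal -> Welch, otherwise Mann-Whitney (normality by
    Shapiro-Wilk at 0.05, variance equality by Levene at 0.05).
    """
    a = np.asarray(sample_a, dtype=np.float64)
    b = np.asarray(sample_b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be nonempty")
    if kind == "auto":
        normal = (
            a.size >= 3
            and b.size >= 3
            and stats.shapiro(a).pvalue > 0.05
            and stats.shapiro(b).pvalue > 0.05
        )
        if normal:
            equal_var = stats.levene(a, b).pvalue > 0.05
            kind = "ttest" if equal_var else "welch"
        else:
            kind = "mannwhitney"
    if kind == "mannwhitney":
        r = stats.mannwhitneyu(a, b, alternative="two-sided")
    elif kind == "ks":
        r = stats.ks_2samp(a, b, alternative="two-sided")
    elif kind == "ttest":
        r = stats.ttest_ind(a, b, equal_var=True)
    elif kind == "welch":
        r = stats.ttest_ind(a, b, equal_var=False)
    else:
        raise ValueError(f"unknown test kind {kind!r}")
    return float(r.statistic), float(r.pvalue), kind
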