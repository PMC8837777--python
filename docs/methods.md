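# Model and methods

`engramsim` simulates systems memory consolidation — the gradual transfer of
a memory's behavioral dependence from hippocampus (HPC) to cortex (CTX),
routed through thalamus (THL) — as the interaction of four synaptic
plasticity mechanisms operating on different timescales inside a network of
spiking brain-region models.

## Neurons and synapses

Each region is a recurrent network of leaky integrate-and-fire neurons
(ratio 4:1 excitatory:inhibitory) with conductance-based synapses and
spike-frequency adaptation.  The membrane voltage obeys

    tau_m dU/dt = (U_rest - U) + g_exc (U_exc - U) + (g_gaba + g_a)(U_inh - U)

with g_exc = alpha*g_ampa + (1-alpha)*g_nmda; the AMPA conductance jumps
with each presynaptic spike (scaled by the short-term-plasticity factor
u*x), the NMDA conductance low-passes it, the GABA conductance jumps with
inhibitory input, and the adaptation conductance g_a jumps by Delta_a at
each of the neuron's own spikes.  A spike is fired when U exceeds an
adaptive threshold theta; U resets to U_rest and theta jumps to theta_spike
before relaxing back with tau_thr (a relative refractory mechanism).
Conductances are dimensionless multiples of the leak conductance.

Defaults (all configurable): tau_m = 20 ms, U_rest = -60 mV, U_exc = 0 mV,
U_inh = -80 mV, theta_rest = -50 mV, theta_spike = -20 mV, tau_thr = 5 ms,
alpha = 0.5, tau_ampa = 5 ms, tau_nmda = 100 ms, tau_gaba = 10 ms,
tau_a = 200 ms, Delta_a = 0.05.

## Plasticity

Four mechanisms act on excitatory synapses onto excitatory neurons:

* **Triplet STDP** — LTP on a postsynaptic spike proportional to the
  presynaptic trace z+ (tau_plus = 30 ms) and the slow postsynaptic trace
  z_slow (150 ms); LTD on a presynaptic spike proportional to the fast
  postsynaptic trace z- (20 ms) with rate B = A*min(C, 1), where C
  integrates (z_ht)^2 (tau_ht = 30 ms, tau_hom = 20 s).  The Hebbian term
  is scaled by the region's learning rate eta_exc.
* **Heterosynaptic plasticity** — on each postsynaptic spike every afferent
  weight is pulled toward its reference weight w~ with strength
  beta*(z-)^3.  The cubic gating makes the pull negligible at background
  rates but strong during bursts, so it both stabilizes runaway
  potentiation and slowly erodes unconsolidated memories during
  reactivations.
* **Transmitter-induced plasticity** — a fixed increment delta per
  presynaptic spike.  This slow unsupervised drift is what re-ignites
  stored assemblies during the consolidation phase: weights creep up until
  an ensemble crosses ignition threshold, the burst triggers heterosynaptic
  and adaptation-mediated shutdown, and the cycle repeats.
* **Synaptic consolidation** — each reference weight follows the negative
  gradient of a double-well potential,

      tau_cons dw~/dt = (w - w~) - P w~ (w_P/2 - w~)(w_P - w~),

  integrated on a long timestep (1.2 s).  With P = 10 and w_P = 1 the wells
  sit at w~ = 0 and w~ ~= w_P; a synapse whose weight is held well above
  w_P/2 flips its reference into the upper well and becomes persistent.
  Reference weights are initialized at the initial weights — synapses start
  at a consolidated baseline and the double-well dynamics take over from
  there.

Short-term plasticity (per presynaptic neuron, shared across its efferent
synapses) uses a facilitation-dominant operating point: U_stp = 0.1,
tau_f = 600 ms, tau_d = 20 ms.  Low release probability with strong
facilitation passes *rate increases* supralinearly, which is what lets a
stimulus presentation stand out against background drive.

Inhibitory synapses onto excitatory cells follow a network-activity-gated
STDP rule: a region-wide low-pass H of all excitatory spikes (tau_H = 10 s)
is compared with a target gamma, and the gap G = H - gamma multiplies
pre/post trace terms (common tau = 20 ms).  The rule steers the mean
excitatory rate toward gamma's equivalent rate (3 Hz at desk scale) and,
because its trace terms weight high-rate cells more strongly, it
preferentially clamps cells that respond indiscriminately.

## Region asymmetries

The model's central hypothesis is implemented as two parameter orderings,
enforced by a config validator:

* eta_exc and eta_inh are higher in HPC (2.5, 1.0e-6) than in CTX
  (0.12, 0.7e-6): hippocampal engrams imprint strongly within a single
  training session (born *active*), cortical ones only weakly (born
  *silent*).
* tau_cons of STIM->HPC (1800 s at desk scale) exceeds every other
  excitatory projection's (120 s): hippocampal feedforward potentiation is
  never consolidated, so reactivation-driven heterosynaptic decay erodes it
  over the consolidation phase (de-maturation), while cortical pathways
  ratchet upward as their reference weights follow (maturation).

## Network configurations

*Two-region*: a 32x32-cell Poisson stimulus grid (STIM) projects to HPC and
CTX with sparse, strong random synapses (eps_ff = 0.05, w ~ U[0.5, 1.5]);
there is no HPC-CTX connection, so any coupling of reactivations across
regions can only come from shared input.  Stimuli are four disjoint random
25% subsets of STIM; cues are random halves of a stimulus.

*Three-region*: STIM projects to HPC (plastic) and THL (static) through
randomly-centered circular receptive fields (radius 3.2 grid cells, small
enough that most fields fall within a single bar); HPC
projects to THL and THL to CTX (both plastic).  Stimuli are four horizontal
bars; cues are the central 50% of each bar's columns at full bar height.
During consolidation STIM is silent and two independent external Poisson
populations drive HPC and CTX, so cross-region reactivation coupling must
flow through the HPC -> THL -> CTX pathway.

Sparse-strong feedforward connectivity is a deliberate desk-scale choice:
with 512 excitatory cells per region, stimulus selectivity rests on
connectivity fluctuations, and at eps_ff = 0.05 the per-stimulus in-degree
(about 13 +- 3.5) varies enough across cells for inhibition-mediated
competition plus Hebbian amplification to carve out distinct ensembles.

## Protocol

Burn-in (30 s) -> training (300 s; full patterns, exponential on/off
intervals with means 2 s / 2 s, stimulus rate 50 Hz against 5 Hz
background) -> consolidation (600-1800 s) -> testing (60 s; 50% cues,
1 s / 2 s intervals).  Engram cells are labeled per stimulus from the final
60 s of training at the 10 Hz threshold; an ensemble counts as activated by
a cue when its mean population rate over the cue window exceeds the same
threshold (mean-over-window was chosen over any-bin aggregation for
robustness to bin noise).  Testing at intermediate consolidation times runs
on a forked copy of the full simulator state (including the Poisson RNG
state), so probing recall never perturbs the consolidation trajectory;
plasticity remains active in every phase, including testing.

## Timescale compression

The full-scale experiments (4096 excitatory cells per region, 12-24 h of
consolidation at dt = 0.1 ms) are cluster-scale.  The package's standard
("desk") conditions compress all slow timescales together by roughly the
ratio of consolidation durations (~50x): tau_cons 120/1800 s, tau_hom 20 s,
minutes-long phases, 512/128 cells per region on a 1024-cell grid, and
dt = 0.5 ms.  A "mini" scale (256/64 cells, doubled recurrent density to
preserve in-degrees) exists for the slowest multi-trial manipulation
experiments.  What desk-scale results do show: the qualitative engram
dynamics (formation, selectivity, maturation/de-maturation directions,
cross-region coupling) and the model's manipulation phenotypes.  What they
do not show: quantitative agreement with full-scale rate statistics,
ensemble sizes as fractions of the population, or hour-scale retention
curves.

## Numerical choices

Forward Euler for membrane, threshold and conductances (dt = 0.5 ms desk /
0.1 ms full); exact exponential factors for all spike traces and
short-term-plasticity relaxation (linear ODEs; cheaper and stabler, and
indistinguishable at these steps); homeostatic C uses exact leak plus an
Euler source term.  Within a timestep: (1) conductance decay, then delivery
of the previous step's spikes (one-step synaptic delay) with presynaptic
plasticity terms, then STP jumps; (2) integration and trace decay; (3)
spike detection, postsynaptic plasticity terms reading pre-increment trace
values ("t - epsilon" semantics), then resets and trace increments.
Delivered efficacy uses the pre-jump u*x product; facilitation is applied
before depression within a spike.  Weights are clipped to their bounds
immediately after every discrete update.  Blocked sources neither transmit
nor update their synapses on the blocked projection; their dynamics
elsewhere are untouched.  Cross-correlograms use exact per-lag Pearson
correlation (segment means and variances via prefix sums, cross terms via
FFT), with ties broken toward zero lag.

All randomness derives from a single master seed split into four named
streams (connectivity, protocol, Poisson drive, analysis), so runs are
reproducible bit-for-bit and changing one component's draws leaves the
others untouched.

## Known limitations

The desk calibration trades ensemble size for selectivity: labeled
ensembles hold ~10-15% of a region's excitatory cells and partially
overlap, so recall false-positive rates are higher than at full scale.
Cortical time-zero recall is highly seed-dependent (trial means of the
true-positive rate range roughly 0.2-0.8), because at 512 cells part of
the cue response rides on raw connectivity fluctuations rather than
learned amplification.  Consolidation-phase reactivations are global
up-states rather than one-ensemble-at-a-time events: ensembles encoding
*different* stimuli co-reactivate, so cross-correlogram lags between
distinct-stimulus ensembles peak near zero instead of at the large lags
expected from temporally separated, stimulus-specific replay; for the
same reason, the shared stimulus background makes the unconnected
two-region control show a weak zero-lag correlation.  This also removes
the substrate for hippocampally *gated* cortical maturation in the
three-region chain: cortical recall there is carried by the thalamic
relay and does not grow during consolidation, so blocking hippocampal
engram output does not reduce it.  The model contains no
oscillations (no LFP proxy), no conduction delays beyond the one-step
convention, and no behavioral readout.
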