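# Methods

This note documents the models, numerical choices and design decisions
behind `biospike`. Everything quantitative stated here is computed by the
test suite or by `scripts/acceptance.py`; nothing is quoted from elsewhere.

## Sensor model

GCaMP fluorescence is modeled as arising from two semi-independent
calmodulin lobes, the fast-binding N-lobe and the slow-binding C-lobe.
Each lobe occupies one of three states — apo, calcium-bound, or
calcium-plus-peptide-bound — giving 9 joint states whose occupancy is a
probability vector. The joint representation (rather than two independent
3-state chains) is kept because the mechanistic state classes used in
analysis (fast-fluorescent, slow-fluorescent, slow-non-fluorescent)
condition on the C-lobe's status; rates remain lobe-local, so the joint
generator is the Kronecker sum of the two lobe generators and the two
formulations agree on all marginals.

Calcium binding is first-order with the pseudo-first-order on-rate

    k_on(ca) = k_off_ca · (ca / K_a)^H,

which makes K_a an apparent dissociation constant (at ca = K_a binding and
unbinding rates balance) and H a Hill exponent for cooperativity. H enters
only the rate law, not the state count; the calcium mass actually
sequestered per lobe-binding event is the separate integer
`n_ca_per_lobe` (default 2, two EF-hands per lobe), used only in the cell
model's mass balance. Peptide binding from a calcium-bound lobe follows
first-order kinetics (`k_on_pep`, `k_off_pep`).

A state is fluorescent when **at least one** lobe is in the
calcium-plus-peptide configuration, and all fluorescent states are equally
bright. Whether one peptide-engaged lobe suffices is genuinely ambiguous
mechanistically; the either-lobe reading is adopted because it is the only
one under which both the fast (N-lobe-only) and slow (C-lobe) pathways can
independently produce fluorescence, which the biphasic stopped-flow
kinetics require. Readout modes: stopped-flow traces are normalized to
[0, 1] between the zero-calcium and saturating steady states; cell-mode
fluorescence is scaled from 1 (zero calcium) to the dynamic range R_f
(saturation), and ΔF/F is taken against the steady-state fluorescence at
basal calcium.

### Integration

The master equation with clamped calcium factorizes per lobe, so
propagation uses the exact per-lobe 3×3 matrix exponential
(scaling-and-squaring Taylor, accurate to ~1e-12) applied as
P ← A_N P A_Cᵀ. Calcium is treated piecewise-constant per substep with
substeps capped at 0.1 ms; the scheme is unconditionally stable for
arbitrary rate stiffness, conserves total occupancy to machine precision,
and is exact in time for constant calcium (verified against
`scipy.linalg.expm` on the 9×9 generator to better than 1e-7).

## Cell model

A single well-mixed bouton compartment. Per action potential a total
calcium `a_ca` (µM) enters and is instantly equilibrated with a fast,
low-affinity endogenous buffer linearized to capacity κB (default 40): the
free pool receives a_ca/(1+κB). The same linearization divides all
continuous free-calcium fluxes by (1+κB). Continuous dynamics comprise
Michaelis–Menten plasma-membrane extrusion (`pump_vmax`, `pump_km`), an
internal store with Michaelis–Menten uptake and release, and a slow second
compartment (volume fraction `slow_frac`, exchange rate `slow_k`) that
produces the slow tail of the decay; the slow pool carries no sensor of
its own (fluorescence is read from the main pool only — the compartment's
physical identity is not resolved by the data being modeled). Store
content is tracked in main-volume-equivalent concentration so that all
exchange fluxes are exactly antisymmetric; with pumps and leak disabled,
total calcium across pools is conserved (integration test at 1e-7).

Rest is maintained by a constant leak influx computed at construction so
that `ca_basal` is an exact fixed point (resting store content is solved
from uptake/release balance); without it, traces would drift before any
spike. Spike influx is instantaneous rather than a brief current waveform
— at the ~1 kHz sampling the models target, sub-millisecond influx shape
is unresolvable. Observation noise is additive Gaussian on ΔF/F,
matching the SMC observation model.

Numerics: operator splitting per substep (≤0.1 ms) — exact sensor
propagator at frozen calcium, sensor-flux update of free calcium, then an
RK2 step of the scalar fluxes. The splitting preserves the resting fixed
point exactly.

### Default parameters

The bouton defaults (κB = 40, ca_basal = 0.05 µM, g_total = 10 µM
indicator, Michaelis–Menten store/pump constants, slow_frac = 0.1,
slow_k = 3 s⁻¹) describe a cerebellar granule-cell parallel-fiber bouton;
`a_ca` and `pump_vmax` were fitted jointly with the jGCaMP8f kinetics (see
Calibration) and then held fixed for all variants, since the ex vivo
statistics for all sensors come from the same cell type.

## Calibration of the shipped sensor parameter sets

`scripts/calibrate_defaults.py` fits each variant's 10 kinetic rate
constants plus R_f (log-scaled, bounded) by multistart bounded
least-squares (scrambled Sobol starts) against the measured single-bouton
response statistics: single-AP 10–90% rise time, single-AP peak ΔF/F,
single- and 10-AP half-decay times, the 10-AP:1-AP amplitude ratio and
the 10 ms paired-pulse ratio, plus a soft constraint on the
fast-pathway share of saturating fluorescence that encodes the
stopped-flow observation that jGCaMP8f fluorescence rises predominantly
through the fast (N-lobe) pathway while GCaMP6f/jGCaMP7f rise mainly
through the slow one. The winning parameter sets are frozen into
`src/biospike/params/*.json` with provenance metadata (loss, seed, number
of starts) and are what `default_sensor()` loads. That a single parameter
set per variant satisfies all these statistics simultaneously is the
central modeling claim, re-verified by `tests/test_acceptance.py` and
`scripts/acceptance.py`.

The paired-pulse ratio is defined as
(peak of pair response − peak of single response) / peak of single
response, computed from matched single and pair simulations; 1 indicates
linear summation. The 10:1 ratio is the ratio of burst to single-spike
peak amplitudes.

## Stopped flow

Mixing experiments are simulated with free calcium clamped at the
post-mix value: reactions are BAPTA-buffered with sensor at 175 nM, far
below the buffer, so depletion is negligible. Samples before the
instrument dead time (0.6–1.5 ms) are discarded. Multi-exponential fits
are linear in amplitudes/offset and nonlinear only in the time constants
(log-spaced multistart grid + trust-region polish, deterministic);
steady-state titrations are fitted with the four-parameter Hill equation.
The global sensor fit uses mean-squared error per trace with equal trace
weights (no weighting scheme is implied by the data), Sobol-quasi-random
starts over log-bounds, and defaults to far fewer starts than an
exhaustive desk-scale search — the start count is configurable.

"Accessible slowing" is shipped only as a clearly-flagged surrogate
(slow-pathway entry rate × slow-state dwell time, relative to the fast
pathway) because no exact formula is available for the original metric.

## Sequential Monte Carlo inference

The state-space model per time bin (bin width = the trace's sample
interval, at most one spike per bin): Bernoulli(rate·dt) spike indicator
with an absolute refractory period (default 3 ms, matching the synthetic
presets) under which the spike prior is zero; deterministic cell-model
advance within the bin using a tabulated per-bin lobe propagator
(256-point log-spaced calcium grid, linearly interpolated); a small
Gaussian process noise on free calcium (σ_ca = 2 nM) that makes the
transition kernel non-degenerate; an Ornstein–Uhlenbeck baseline
(stationary SD σ_drift, timescale 2 s — mean reversion is essential,
a pure random walk can absorb transient model mismatch); and Gaussian
observation noise σ on ΔF/F.

Bins containing a spike are advanced in five substeps with the calcium
increment injected at the bin midpoint — true spike times are uniform
within a bin, so midpoint injection makes the expected first post-spike
sample match the data convention; a single full-bin step with
start-of-bin injection overshoots the first sample by several noise SDs
and biases the amplitude parameters. Quiet bins use one exact-propagator
step (the within-bin calcium drift there is slow).

Each iteration runs a conditional SMC sweep followed by
Metropolis-within-Gibbs updates of the static parameters (a_ca, g_total,
pump_vmax, R_f, σ, spike rate, σ_drift; log-normal priors centered on the
calibrated defaults, log-normal random-walk proposals). The sweep uses
locally optimal spike proposals — the spike indicator is proposed from
its one-bin conditional posterior, with the particle weighted by the
predictive marginal — and ESS-adaptive systematic resampling (threshold
N/2). Trajectories are stored in innovation form (spike indicators,
calcium and baseline innovations); parameter updates rerun the
deterministic prediction pass under proposed parameters, i.e. a
non-centered parameterization.

Ancestor sampling for the reference particle uses the density of the
stochastic innovations (baseline increment, calcium innovation) and omits
the deterministic sensor-occupancy component of the transition density,
which is degenerate. This is an approximation: switching the reference's
ancestor splices innovation histories whose implied sensor states differ
transiently from those evaluated during weighting. The states relax on
the ~tens-of-milliseconds calcium timescale, so the inconsistency decays
quickly; without ancestor sampling the sampler is exactly invariant but
mixes poorly on long traces.

Initialization: the parameter chain starts at the prior mode — the
calibrated defaults — except the observation noise σ, whose prior center
and initial value come from a robust estimate on the trace itself
(median absolute first difference / (0.6745·√2); the signal is smooth at
the sample rate, so first differences are essentially pure noise).
Starting σ far below the true noise floods early sweeps with spurious
spikes and locks the chain into a many-small-spikes mode; the
data-driven start avoids that failure without touching the data twice.
The conditional posterior of the amplitude-like parameters given a fixed
spike trajectory is much sharper than their marginal posterior, so the
chain explores them slowly; this is a known mixing limitation of
particle Gibbs for strongly coupled static parameters and is documented
rather than hidden.

Defaults: 96 particles, 50 iterations, first 25% discarded as burn-in
(the acceptance tests use documented reduced budgets, e.g. 64 particles /
36 iterations on the 60 s recovery problem). Posterior spike
probabilities are per-bin means of sampled indicators after burn-in; MAP
spikes threshold at 0.5 with adjacent-bin merging at the
probability-weighted centroid. Same-seed runs are bit-identical.

The linear AR(2) baseline (`generative_model="linear_ar"`) replaces the
biophysical advance with a fixed-amplitude per-spike kernel under
second-order autoregressive decay, with coefficients fitted to the
single-spike response of the biophysical model; it exists to demonstrate
the failure mode of static-kernel models under use-dependent slowing
(excess false positives during the slowed decay of spike trains).

## Synthetic data

Presets mirror the targeted recording regimes: excitatory-like 10 Hz and
inhibitory-like 30 Hz Poisson spiking (the inhibitory preset halves the
per-spike calcium and the dynamic-range excess R_f − 1), ~1 kHz sampling,
additive white Gaussian noise (default σ = 0.12 ΔF/F, giving single-spike
SNR ≈ 5 for the jGCaMP8f defaults) and Ornstein–Uhlenbeck baseline drift
(default SD 0.05 ΔF/F, timescale 5 s; the drift form is a repository
choice). Spike trains are homogeneous Poisson thinned by an absolute
refractory period (3 ms default). Corpus generation draws per-trace cell
parameters log-normally (SD 0.2 in log space) around the defaults and
records every sub-seed and draw in a manifest; regeneration from the
manifest is bit-identical. What the generator does **not** emulate —
shot noise, scan jitter, neuropil contamination, multi-compartment
geometry — bounds what passing tests say about real recordings: they
validate the inference machinery against the generative model class, not
against instrument physics.

## Supervised inference

A windowed MLP regressor (scikit-learn MLPRegressor, two hidden layers)
maps a ±64 ms fluorescence window to the ground-truth spike density
smoothed with a 10 ms-SD Gaussian. The architecture is deliberately small
for CPU trainability; no published architecture is being reproduced.
Density traces are discretized by greedy matching pursuit: repeatedly
place a unit-mass Gaussian kernel at the matched-filter maximum while at
least half a kernel of residual mass remains (with a matched-filter floor
to stop on diffuse residue).

## Evaluation metrics

Spike matching solves a rectangular linear assignment with unassignment
cost max_dt/2 per spike, so pairs with |offset| > max_dt are never formed
(verified exactly against brute-force enumeration on ≤6-spike instances);
default window 10 ms. Precision, recall, their harmonic mean (F-score),
and accuracy = TP/(TP+FP+FN) — the Jaccard-style definition, chosen as
the standard definition that lies below both precision and recall; 0/0
cases are reported as undefined and excluded from aggregation. Timing
bias is the median signed offset (positive = imputed late) and
uncertainty the median absolute offset within a 100 ms window, via
nearest-neighbor or matched pairing. Filtered correlation convolves both
the continuous spike probability and the binned truth with Gaussians of
the requested SDs and reports Pearson r. Robust summaries use the median
and MAD/0.6745.

## Known limitations

- The ancestor-sampling approximation above; exactness would require
  process noise on every state component.
- Photophysics (bleaching, blinking), pH and magnesium competition are
  outside the sensor model's scope.
- The slow compartment is phenomenological; its exchange partner (main
  pool only) is a modeling choice.
- The supervised model ships untrained; training is minutes-scale on CPU
  from a generated corpus.
- Benchmarks against external paired optical/electrophysiology datasets
  require a local copy of such a dataset via the optional adapter in
  `biospike.io`; they are not part of the test suite.
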