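# biospike

Biophysical modeling of GCaMP calcium indicators and spike inference from
fluorescence imaging.

Fast GCaMP variants distort the mapping from action potentials to
fluorescence in ways that break linear deconvolution: older sensors
(GCaMP6f, jGCaMP7f) respond supralinearly to closely spaced spikes, and
jGCaMP8f shows a pronounced *use-dependent slowing* — its fluorescence
decay stretches roughly three-fold after bursts. `biospike` implements a
mechanistic account of these nonlinearities and builds spike-inference
methods on top of it, for experimenters and methods developers working
with single-bouton or single-cell calcium imaging at ~1 kHz.

## The model

A GCaMP molecule is two semi-independent calmodulin lobes — a fast
N-lobe and a slow C-lobe — each cycling through apo → Ca-bound →
Ca+peptide-bound states. Calcium binding per lobe is first-order with a
pseudo-first-order on-rate

```
k_on(ca) = k_off_ca · (ca / K_a)^H
```

(K_a the apparent dissociation constant, H a Hill coefficient), and a
calcium-bound lobe binds the sensor's target peptide with first-order
kinetics. Any state with at least one peptide-engaged lobe is
fluorescent. The 9-state joint occupancy evolves under a master equation
(Kronecker sum of the two lobe generators); fluorescence is scaled
between 1 (zero calcium) and the dynamic range R_f (saturation), and
ΔF/F is referenced to the resting steady state.

The sensor sits inside a single-compartment bouton model: per-spike
calcium influx `a_ca` instantly equilibrated with a linearized endogenous
buffer (capacity κB ≈ 40), Michaelis–Menten extrusion with a
rest-balancing leak, a Michaelis–Menten intracellular store, and a slow
exchange compartment. Use-dependent slowing *emerges* from occupancy of
slow (C-lobe) fluorescent states during bursts — it is not parameterized
directly.

On this generative core the package provides:

- **Biophys_SMC** — particle Gibbs with ancestor sampling over the
  state-space model; joint posterior over spike times and cell parameters
  (a_ca, GCaMP concentration, extrusion rate, R_f, noise, spike rate,
  baseline drift), with MAP spike extraction.
- **Linear_SMC** — the same machinery with a linear AR(2) kernel model,
  as the baseline that reproduces the failure mode of static-kernel
  inference under use-dependent slowing.
- **Biophys_ML** — a small supervised density regressor trained on
  synthetic traces from the biophysical model, with matching-pursuit
  spike discretization.
- Stopped-flow simulation and the calibration stack (multi-exponential,
  Hill, Sobol-multistart global fits), a synthetic-data generator with
  excitatory/inhibitory presets, and an assignment-based spike-matching
  evaluation suite (precision/recall/F-score, timing bias/uncertainty,
  filtered correlations, robust summaries).

Calibrated parameter sets for GCaMP6f, jGCaMP7f and jGCaMP8f ship in
`src/biospike/params/` with provenance metadata; they were produced by
`scripts/calibrate_defaults.py` against the measured single-bouton
response statistics (see `docs/methods.md`).

## Worked example

```python
import numpy as np
from biospike import (default_sensor, default_cell, slice_statistics,
                      SpikeTrain, simulate)

sensor = default_sensor("jgcamp8f")
cell = default_cell()

# ex-vivo-style protocols: 1 AP, a 10 ms pair, 10 APs at 100 Hz
stats = slice_statistics(cell, sensor)
print({k: round(v, 2) for k, v in stats.items()})
```

prints

```
{'rise_10_90_ms': 3.1, 'peak_dff': 0.59, 'half_decay_1_ms': 41.03,
 'half_decay_10_ms': 122.95, 'amp_ratio_10_1': 3.01,
 'paired_pulse_10ms': 0.99}
```

— a 3.1 ms 10–90% rise, 0.59 peak ΔF/F and a 41 ms single-spike
half-decay that triples after a 10-spike burst (123 ms): the
use-dependent slowing, emerging from the kinetic scheme. Spike inference
on a synthetic recording:

```python
from biospike import TracePreset, generate_trace, pgas_infer, InferenceConfig
from biospike.metrics import evaluate

preset = TracePreset(rate=10.0, duration=20.0, sigma=0.12, drift_amp=0.03)
trace, spikes, _ = generate_trace(preset, sensor, seed=11)
post = pgas_infer(trace, sensor,
                  InferenceConfig(n_particles=64, n_iterations=30, seed=5))
rep = evaluate(post.map_spikes, spikes)
print(round(rep.f_score, 3), len(post.map_spikes), len(spikes))
```

prints `0.962 201 217` — 0.96 F-score at 10 ms matching with zero false
positives on this 20 s, SNR ≈ 5 trace, and the posterior medians of
a_ca, R_f and σ land on the generative truth.

A command-line interface mirrors the library:

```bash
biospike simulate --sensor jgcamp8f --spikes spikes.txt --out trace.csv
biospike infer-smc --trace trace.csv --sensor jgcamp8f --seed 1 --out post.h5
biospike evaluate --imputed post.spikes.txt --truth spikes.txt --out report.json
```

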