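"""Ground-truth-paired synthetic fluorescence data.

Emulates the imaging regimes the models target: ~1 kHz single-bouton
traces with Poisson spiking (10 Hz excitatory-like, 30 Hz inhibitory-like
with halved per-spike calcium and halved dynamic range), additive white
Gaussian noise on ΔF/F and slow Ornstein–Uhlenbeck baseline drift.  Every
generated object is reproducible from its seed; seeds are split
deterministically into spike/noise/drift streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cell import (CellParams, FluorescenceTrace, SpikeTrain, simulate,
                   default_cell)
from .sensor import SensorModel


@dataclass(frozen=True)
class TracePreset:
    """Generation settings for one regime.

    The inhibitory preset follows the high-rate/low-amplitude construction:
    30 Hz Poisson spiking with the calcium increase per spike reduced by 2
    and the dynamic range reduced by a factor of 2.
    """

    name: str = "excitatory"
    rate: float = 10.0             # spike rate, Hz
    duration: float = 60.0         # s
    sample_rate: float = 1000.0    # Hz
    sigma: float = 0.12            # ΔF/F noise SD
    drift_amp: float = 0.05        # OU stationary SD, ΔF/F
    drift_tau: float = 5.0         # OU timescale, s
    refractory: float = 0.003      # absolute refractory period, s
    cell_overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.rate < 0:
            raise ValueError("spike rate must be nonnegative")


def excitatory_preset(**kw) -> TracePreset:
    return TracePreset(name="excitatory", rate=10.0, **kw)


def inhibitory_preset(**kw) -> TracePreset:
    return TracePreset(name="inhibitory", rate=30.0, **kw)


def _adapt(preset: TracePreset, cell: CellParams,
           sensor: SensorModel) -> tuple[CellParams, SensorModel]:
    cell = cell.replace(sigma=0.0, **preset.cell_overrides)
    if preset.name == "inhibitory":
        cell = cell.replace(a_ca=cell.a_ca / 2.0)
        sensor = SensorModel(lobe_N=sensor.lobe_N, lobe_C=sensor.lobe_C,
                             R_f=1.0 + (sensor.R_f - 1.0) / 2.0,
                             n_ca_per_lobe=sensor.n_ca_per_lobe,
                             name=sensor.name)
    return cell, sensor


def sample_spike_train(rate: float, duration: float, refractory: float = 0.0,
                       seed: int = 0) -> SpikeTrain:
    """Homogeneous Poisson process thinned by an absolute refractory period."""
    if rate < 0:
        raise ValueError("rate must be nonnegative")
    rng = np.random.default_rng(seed)
    if rate == 0 or duration <= 0:
        return SpikeTrain(np.empty(0))
    n_exp = rng.poisson(rate * duration)
    times = np.sort(rng.uniform(0.0, duration, size=n_exp))
    if refractory > 0 and times.size:
        kept = [times[0]]
        for t in times[1:]:
            if t - kept[-1] >= refractory:
                kept.append(t)
        times = np.array(kept)
    return SpikeTrain(times)


def ou_baseline(n: int, dt: float, amp: float, tau: float,
                rng: np.random.Generator) -> np.ndarray:
    """Stationary Ornstein–Uhlenbeck path with SD ``amp``, timescale ``tau``."""
    if amp == 0:
        return np.zeros(n)
    a = np.exp(-dt / tau)
    s = amp * np.sqrt(1.0 - a * a)
    x = np.empty(n)
    x[0] = amp * rng.standard_normal()
    z = rng.standard_normal(n - 1)
    for i in range(1, n):
        x[i] = a * x[i - 1] + s * z[i - 1]
    return x


def generate_trace(preset: TracePreset, sensor: SensorModel, seed: int = 0,
                   cell: CellParams | None = None):
    """One synthetic recording: (trace, spikes, latents dict).

    trace = noiseless cell simulation + OU baseline drift + white Gaussian
    noise; the seed is split into independent spike/drift/noise streams.
    """
    cell = cell or default_cell()
    cell, sensor = _adapt(preset, cell, sensor)
    ss = np.random.SeedSequence(seed)
    s_spk, s_drift, s_noise = ss.spawn(3)
    spikes = sample_spike_train(preset.rate, preset.duration,
                                preset.refractory,
                                seed=s_spk)
    clean, lat = simulate(cell, sensor, spikes, preset.duration,
                          preset.sample_rate, return_latents=True)
    n = clean.dff.size
    drift = ou_baseline(n, clean.dt, preset.drift_amp, preset.drift_tau,
                        np.random.default_rng(s_drift))
    noise = np.random.default_rng(s_noise).normal(0.0, preset.sigma, n) \
        if preset.sigma > 0 else np.zeros(n)
    trace = FluorescenceTrace(t=clean.t, dff=clean.dff + drift + noise,
                              rate=preset.sample_rate)
    latents = {"clean_dff": clean.dff, "drift": drift, **lat,
               "cell": cell, "sensor": sensor}
    return trace, spikes, latents


def generate_corpus(n_traces: int, presets, sensor: SensorModel,
                    seed: int = 0, cell: CellParams | None = None,
                    param_jitter: float = 0.2):
    """Corpus of paired (trace, spikes) with a reproducibility manifest.

    Per-trace cell parameters are drawn log-normally around the base cell
    (SD ``param_jitter`` in log space) for a_ca, g_total and pump_vmax —
    emulating cell-to-cell variability around model-fitted values.  The
    manifest records every sub-seed and parameter draw; regenerating from
    the manifest is bit-identical.
    """
    if n_traces < 1:
        raise ValueError("n_traces must be >= 1")
    presets = list(presets)
    cell = cell or default_cell()
    root = np.random.SeedSequence(seed)
    subs = root.spawn(n_traces)
    manifest = {"seed": seed, "n_traces": n_traces, "entries": []}
    data = []
    for i, sub in enumerate(subs):
        rng = np.random.default_rng(sub.spawn(1)[0])
        preset = presets[i % len(presets)]
        draws = {k: float(getattr(cell, k)
                          * np.exp(param_jitter * rng.standard_normal()))
                 for k in ("a_ca", "g_total", "pump_vmax")}
        trace_seed = int(rng.integers(0, 2 ** 31 - 1))
        entry = {"index": i, "preset": preset.name, "rate": preset.rate,
                 "trace_seed": trace_seed, "cell_draws": draws}
        manifest["entries"].append(entry)
        trace, spikes, _ = generate_trace(preset, sensor, seed=trace_seed,
                                          cell=cell.replace(**draws))
        data.append((trace, spikes))
    return data, manifest


def regenerate_from_manifest(manifest: dict, presets, sensor: SensorModel,
                             cell: CellParams | None = None):
    """Rebuild a corpus bit-identically from its manifest."""
    cell = cell or default_cell()
    presets = {p.name: p for p in presets}
    data = []
    for e in manifest["entries"]:
        p = presets[e["preset"]]
        trace, spikes, _ = generate_trace(
            p, sensor, seed=e["trace_seed"], cell=cell.replace(**e["cell_draws"]))
        data.append((trace, spikes))
    return data
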