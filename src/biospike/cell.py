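"""Granule-cell bouton calcium dynamics coupled to the sensor model.

A single well-mixed presynaptic compartment with:

* spike-evoked calcium influx ``a_ca`` (µM of total calcium per action
  potential), instantaneously equilibrated with a fast linearized endogenous
  buffer of capacity κB (free share 1/(1+κB));
* Michaelis–Menten plasma-membrane extrusion plus a constant leak influx
  chosen at construction so that the configured resting calcium is an exact
  fixed point;
* an internal calcium store with Michaelis–Menten uptake and release;
* a slow second compartment exchanging calcium with the main pool at rate
  ``slow_k`` (volume fraction ``slow_frac``), accounting for the slow tail
  of fluorescence decay;
* the GCaMP sensor at concentration ``g_total``, whose net calcium binding
  withdraws free calcium with stoichiometry ``n_ca_per_lobe`` per lobe.

Fluorescence is read from the main pool via the sensor's cell-mode scaling
and reported as ΔF/F against the resting steady state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict, replace

import numpy as np

from . import _kernels as _k
from .sensor import SensorModel, SensorState, steady_state, \
    fluorescence_normalization


@dataclass(frozen=True)
class CellParams:
    """Calcium-handling parameters of the bouton compartment model.

    Concentrations in µM, rates in µM/s or 1/s, times in seconds.
    """

    g_total: float = 10.0          # total GCaMP concentration
    a_ca: float = 20.0             # total calcium added per AP, pre-buffering
    kappa_b: float = 40.0          # endogenous buffer capacity κB
    pump_vmax: float = 600.0       # extrusion maximal rate
    pump_km: float = 0.5           # extrusion half-saturation
    store_in_vmax: float = 20.0
    store_in_km: float = 0.5
    store_out_vmax: float = 40.0
    store_out_km: float = 5.0
    slow_frac: float = 0.10        # slow-compartment volume fraction
    slow_k: float = 3.0            # main <-> slow exchange rate
    ca_basal: float = 0.05         # resting free calcium
    f0: float = 1.0                # absolute baseline fluorescence (a.u.)
    sigma: float = 0.0             # observation noise SD (ΔF/F units)

    def __post_init__(self):
        for name, v in asdict(self).items():
            if name != "sigma" and v < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not 0 <= self.slow_frac < 1:
            raise ValueError("slow_frac must be in [0, 1)")

    def replace(self, **kw) -> "CellParams":
        return replace(self, **kw)

    def store_rest(self) -> float:
        """Store content (main-volume µM) balancing uptake at rest."""
        uptake = self.store_in_vmax * self.ca_basal \
            / (self.store_in_km + self.ca_basal)
        if uptake <= 0:
            return 0.0
        if uptake >= self.store_out_vmax:
            raise ValueError("store release cannot balance uptake at rest")
        return self.store_out_km * uptake / (self.store_out_vmax - uptake)

    def leak(self) -> float:
        """Constant influx making ca_basal an exact fixed point."""
        return self.pump_vmax * self.ca_basal / (self.pump_km + self.ca_basal)

    def param_vector(self, sensor: SensorModel) -> np.ndarray:
        return np.array([self.g_total, self.a_ca, self.kappa_b,
                         self.pump_vmax, self.pump_km,
                         self.store_in_vmax, self.store_in_km,
                         self.store_out_vmax, self.store_out_km,
                         self.slow_frac, self.slow_k, self.ca_basal,
                         self.leak(), float(sensor.n_ca_per_lobe)])


def default_cell() -> CellParams:
    """The shipped bouton parameter set produced by the calibration
    pipeline (falls back to the dataclass defaults if absent)."""
    import json
    from pathlib import Path
    path = Path(__file__).parent / "params" / "bouton_cell.json"
    if path.exists():
        return CellParams(**json.loads(path.read_text())["params"])
    return CellParams()


@dataclass
class CellState:
    """Instantaneous state of the compartment model (µM everywhere)."""

    ca_free: float
    ca_slow: float
    b_ca: float
    ca_store: float
    sensor: SensorState

    @classmethod
    def resting(cls, params: CellParams, sensor: SensorModel) -> "CellState":
        return cls(ca_free=params.ca_basal,
                   ca_slow=params.ca_basal,
                   b_ca=params.kappa_b * params.ca_basal,
                   ca_store=params.store_rest(),
                   sensor=steady_state(sensor, params.ca_basal))

    def total_calcium(self, params: CellParams, sensor: SensorModel) -> float:
        """Total calcium referenced to main-pool volume (µM).

        free + buffer-bound + sensor-bound + store + slow-pool share; the
        slow pool is weighted by its volume ratio to the main pool.
        """
        r = params.slow_frac / (1.0 - params.slow_frac)
        bound = _k.bound_lobes(self.sensor.occupancy)
        return (self.ca_free + self.b_ca
                + params.g_total * sensor.n_ca_per_lobe * bound
                + self.ca_store + r * self.ca_slow)

    def to_vector(self) -> np.ndarray:
        x = np.empty(12)
        x[0] = self.ca_free
        x[1] = self.ca_slow
        x[2] = self.ca_store
        x[3:] = self.sensor.occupancy.reshape(9)
        return x

    @classmethod
    def from_vector(cls, x: np.ndarray, kappa_b: float) -> "CellState":
        return cls(ca_free=float(x[0]), ca_slow=float(x[1]),
                   b_ca=kappa_b * float(x[0]), ca_store=float(x[2]),
                   sensor=SensorState(np.clip(x[3:].reshape(3, 3), 0, None)
                                      / max(x[3:].sum(), 1e-300)))


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted spike times in seconds."""

    times: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float).ravel()
        if t.size and ((np.diff(t) <= 0).any() or t[0] < 0):
            raise ValueError("spike times must be strictly increasing "
                             "and nonnegative")
        object.__setattr__(self, "times", t)

    def __len__(self):
        return self.times.size


@dataclass
class FluorescenceTrace:
    """Uniformly sampled ΔF/F time series."""

    t: np.ndarray
    dff: np.ndarray
    rate: float

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.dff = np.asarray(self.dff, dtype=float)
        if self.t.shape != self.dff.shape:
            raise ValueError("t and dff must have equal length")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def dt(self) -> float:
        return 1.0 / self.rate

    @property
    def duration(self) -> float:
        return self.t.size / self.rate


def apply_spike(state: CellState, a_ca: float,
                kappa_b: float) -> CellState:
    """Instantaneous spike influx equilibrated with the endogenous buffer.

    Of the total ``a_ca``, the free pool receives a_ca/(1+κB) and the
    buffer κB/(1+κB); all other fields are unchanged.
    """
    if a_ca < 0:
        raise ValueError("a_ca must be nonnegative")
    beta = 1.0 + kappa_b
    return CellState(ca_free=state.ca_free + a_ca / beta,
                     ca_slow=state.ca_slow,
                     b_ca=state.b_ca + a_ca * kappa_b / beta,
                     ca_store=state.ca_store,
                     sensor=state.sensor)


def calcium_derivatives(state: CellState, params: CellParams,
                        sensor: SensorModel) -> dict:
    """Continuous-time derivatives of the calcium pools (µM/s).

    The free-calcium derivative is divided by (1+κB), the instantaneous
    buffer-equilibration factor; buffer-bound calcium follows as κB times
    the free derivative.  Store and slow-compartment fluxes are
    antisymmetric in main-volume units.
    """
    cp = params.param_vector(sensor)
    dca, dslow, dstore = _k._scalar_rates(state.ca_free, state.ca_slow,
                                          state.ca_store, cp)
    G = np.kron(sensor.lobe_N.generator(state.ca_free), np.eye(3)) \
        + np.kron(np.eye(3), sensor.lobe_C.generator(state.ca_free))
    docc = (G @ state.sensor.vector).reshape(3, 3)
    dbound = _k.bound_lobes(docc)
    j_sensor = params.g_total * sensor.n_ca_per_lobe * dbound
    beta = 1.0 + params.kappa_b
    dca = dca - j_sensor / beta
    return {"ca_free": dca,
            "b_ca": params.kappa_b * dca,
            "ca_slow": dslow,
            "ca_store": dstore,
            "sensor_bound": j_sensor}


def simulate(cell: CellParams, sensor: SensorModel, spikes: SpikeTrain,
             duration: float, rate: float = 1000.0,
             noise_seed: int | None = None, h_max: float = 1e-4,
             return_latents: bool = False):
    """Simulate the ΔF/F response of a bouton to a spike train.

    Returns a :class:`FluorescenceTrace`; with ``return_latents`` also a
    dict of latent trajectories (free/slow/store calcium and sensor
    occupancy per sample).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    times = spikes.times
    if times.size and (times.min() < 0 or times.max() > duration):
        raise ValueError("spike outside the simulation window")
    dt = 1.0 / rate
    n_sub = max(1, int(np.ceil(dt / h_max)))
    h = dt / n_sub
    n_samples = int(round(duration * rate))
    spike_sub = np.floor(times / h + 0.5).astype(np.int64)
    x0 = CellState.resting(cell, sensor).to_vector()
    phi0, phisat = fluorescence_normalization(sensor)
    phib = float(_k.fluorescent_frac(x0[3:].reshape(3, 3)))
    Fb = 1.0 + (sensor.R_f - 1.0) * (phib - phi0) / (phisat - phi0)
    dff, lat, clipped = _k.simulate_core(
        x0, spike_sub, n_samples, n_sub, h, sensor.param_vector(),
        cell.param_vector(sensor), phi0, phisat, sensor.R_f, Fb)
    if clipped:
        warnings.warn("negative calcium clipped to 0 during simulation",
                      RuntimeWarning, stacklevel=2)
    if not np.isfinite(dff).all():
        raise ArithmeticError("cell simulation produced non-finite output")
    if cell.sigma > 0:
        rng = np.random.default_rng(noise_seed)
        dff = dff + rng.normal(0.0, cell.sigma, size=dff.size)
    t = np.arange(n_samples) * dt
    trace = FluorescenceTrace(t=t, dff=dff, rate=rate)
    if return_latents:
        latents = {"ca_free": lat[:, 0], "ca_slow": lat[:, 1],
                   "ca_store": lat[:, 2],
                   "occupancy": lat[:, 3:].reshape(-1, 3, 3)}
        return trace, latents
    return trace


# ---------------------------------------------------------------------------
# Per-event summary statistics
# ---------------------------------------------------------------------------

def _interp_crossing(t, y, level, i_from, i_to, rising=True):
    """First crossing of ``level`` between samples, linearly interpolated."""
    rng = range(i_from, i_to) if rising else range(i_from, i_to)
    for i in rng:
        y0, y1 = y[i], y[i + 1]
        if (rising and y0 < level <= y1) or (not rising and y0 > level >= y1):
            if y1 == y0:
                return t[i]
            return t[i] + (level - y0) / (y1 - y0) * (t[i + 1] - t[i])
    return None


def summary_stats(trace: FluorescenceTrace, spikes: SpikeTrain,
                  baseline_window: float = 0.05) -> list[dict]:
    """Per-event response statistics.

    For each spike: peak ΔF/F relative to the pre-event baseline, SNR
    (peak over the robust SD of the pre-stimulus baseline, MAD/0.6745),
    10–90% rise time, half-decay time (peak to 50%), and for the second of
    a pair the paired-pulse amplitude ratio (second-response increment over
    first-response amplitude).  Statistics whose defining window is clipped
    by the trace edge are reported as ``None``.
    """
    t, y = trace.t, trace.dff
    events = []
    times = spikes.times
    for k, ts in enumerate(times):
        i0 = int(np.searchsorted(t, ts))
        ib = int(np.searchsorted(t, ts - baseline_window))
        base_seg = y[ib:i0] if i0 > ib else y[:1]
        baseline = float(np.median(base_seg))
        robust_sd = float(np.median(np.abs(base_seg - np.median(base_seg)))
                          / 0.6745) if base_seg.size > 2 else np.nan
        i_end = int(np.searchsorted(t, times[k + 1])) \
            if k + 1 < times.size else t.size
        seg = y[i0:i_end]
        if seg.size < 2:
            events.append({"t_spike": ts, "peak": None, "snr": None,
                           "rise_10_90": None, "half_decay": None,
                           "paired_pulse_ratio": None})
            continue
        ipk = i0 + int(np.argmax(seg))
        peak = float(y[ipk] - baseline)
        snr = peak / robust_sd if robust_sd and robust_sd > 0 else None
        t10 = _interp_crossing(t, y, baseline + 0.1 * peak, i0, ipk + 1)
        t90 = _interp_crossing(t, y, baseline + 0.9 * peak, i0, ipk + 1)
        rise = (t90 - t10) if (t10 is not None and t90 is not None) else None
        # decay is measured past the event window, until the next spike
        # would confound it only if it arrives before the 50% crossing
        i_decay_end = int(np.searchsorted(t, times[k + 1])) \
            if k + 1 < times.size else t.size - 1
        thd = _interp_crossing(t, y, baseline + 0.5 * peak, ipk,
                               min(i_decay_end, t.size - 1), rising=False)
        half_decay = (thd - t[ipk]) if thd is not None else None
        ppr = None
        if k > 0:
            prev = events[k - 1]
            if prev["peak"]:
                incr = float(y[ipk] - y[i0])
                ppr = incr / prev["peak"]
        events.append({"t_spike": ts, "peak": peak, "snr": snr,
                       "rise_10_90": rise, "half_decay": half_decay,
                       "paired_pulse_ratio": ppr})
    return events


def transient_stats(trace: FluorescenceTrace, t_onset: float = 0.0) -> dict:
    """Rise/peak/half-decay of a single compound transient.

    Treats everything after ``t_onset`` as one response (e.g. a burst),
    measuring the 10–90% rise to the global peak and the half-decay from
    the peak, against the pre-onset baseline.
    """
    t, y = trace.t, trace.dff
    i0 = int(np.searchsorted(t, t_onset))
    baseline = float(np.median(y[:i0])) if i0 > 0 else float(y[0])
    ipk = i0 + int(np.argmax(y[i0:]))
    peak = float(y[ipk] - baseline)
    t10 = _interp_crossing(t, y, baseline + 0.1 * peak, i0, ipk + 1)
    t90 = _interp_crossing(t, y, baseline + 0.9 * peak, i0, ipk + 1)
    thd = _interp_crossing(t, y, baseline + 0.5 * peak, ipk, t.size - 1,
                           rising=False)
    return {"peak": peak,
            "rise_10_90": (t90 - t10)
            if (t10 is not None and t90 is not None) else None,
            "half_decay": (thd - t[ipk]) if thd is not None else None,
            "t_peak": float(t[ipk])}


def slice_statistics(cell: CellParams, sensor: SensorModel,
                     rate: float = 1000.0) -> dict:
    """Noise-free single-bouton response statistics for one sensor variant.

    Mirrors the ex vivo stimulation protocols: a single action potential,
    a pair at 10 ms, and a 10-pulse 100 Hz train.  Returns
    rise_10_90_ms, peak_dff, half_decay_1_ms, half_decay_10_ms,
    amp_ratio_10_1 and paired_pulse_10ms.
    """
    quiet = cell.replace(sigma=0.0)
    t_on = 0.05
    tr1 = simulate(quiet, sensor, SpikeTrain(np.array([t_on])), 0.60, rate)
    s1 = transient_stats(tr1, t_on)
    train = SpikeTrain(t_on + np.arange(10) * 0.01)
    tr10 = simulate(quiet, sensor, train, 1.0, rate)
    s10 = transient_stats(tr10, t_on)
    pair = SpikeTrain(np.array([t_on, t_on + 0.01]))
    tr2 = simulate(quiet, sensor, pair, 0.30, rate)
    ppr = paired_pulse_ratio(tr1, tr2)
    ms = lambda v: None if v is None else float(1e3 * v)
    return {"rise_10_90_ms": ms(s1["rise_10_90"]),
            "peak_dff": float(s1["peak"]),
            "half_decay_1_ms": ms(s1["half_decay"]),
            "half_decay_10_ms": ms(s10["half_decay"]),
            "amp_ratio_10_1": float(s10["peak"] / s1["peak"])
            if s1["peak"] > 0 else None,
            "paired_pulse_10ms": float(ppr)}


def paired_pulse_ratio(trace_single: FluorescenceTrace,
                       trace_pair: FluorescenceTrace) -> float:
    """Second-response increment over single-response amplitude.

    Computed from matched single-spike and spike-pair simulations as
    (peak_pair - peak_single) / peak_single; 1 indicates linear summation.
    """
    p1 = float(trace_single.dff.max())
    p2 = float(trace_pair.dff.max())
    if p1 <= 0:
        raise ValueError("single-spike response has no positive peak")
    return (p2 - p1) / p1
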