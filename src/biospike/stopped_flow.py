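"""Stopped-flow protocol simulation and the calibration machinery.

Simulates rapid-mixing calcium steps against a clamped free-calcium bath
(the stopped-flow reactions are BAPTA-buffered with the sensor at 175 nM,
far below the buffer, so depletion is neglected), and provides the fitting
stack used for calibration: multi-exponential fits, Hill fits, and
multistart (Sobol quasi-random) global fitting of sensor kinetics, plus the
second-stage fit of cell parameters against ex-vivo-style recordings with
the sensor held fixed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from .sensor import (LobeKinetics, SensorModel, steady_state,
                     fluorescence_normalization)
from .cell import CellParams, FluorescenceTrace, SpikeTrain, simulate


@dataclass(frozen=True)
class StoppedFlowProtocol:
    """A single mixing experiment: equilibrate at ``ca_pre``, step to
    ``ca_post`` at t = 0; samples before ``dead_time`` are unobservable."""

    ca_pre: float
    ca_post: float
    dead_time: float = 1.0e-3
    duration: float = 1.0
    rate: float = 5000.0

    def __post_init__(self):
        if self.ca_pre < 0 or self.ca_post < 0 or self.dead_time < 0:
            raise ValueError("concentrations and dead time must be >= 0")


@dataclass
class ExpFit:
    """Sum-of-exponentials fit; taus ascending, seconds."""

    amplitudes: list
    taus: list
    offset: float
    residual_rms: float


@dataclass
class HillFit:
    kd: float
    hill: float
    f_min: float
    f_max: float

    def __call__(self, ca):
        ca = np.asarray(ca, dtype=float)
        x = ca ** self.hill
        return self.f_min + (self.f_max - self.f_min) * x \
            / (self.kd ** self.hill + x)


def simulate_stopped_flow(sensor: SensorModel,
                          protocol: StoppedFlowProtocol) -> FluorescenceTrace:
    """Normalized (0–1) fluorescence response to a clamped calcium step.

    Free calcium is buffer-controlled and not depleted by the sensor.  The
    first reported sample falls at or after the instrument dead time.
    """
    from . import _kernels as _k
    dt = 1.0 / protocol.rate
    n = int(round(protocol.duration * protocol.rate))
    t = np.arange(n) * dt
    keep = t >= protocol.dead_time
    start = steady_state(sensor, protocol.ca_pre)
    ca_traj = np.full(n, protocol.ca_post)
    # calcium is clamped, so the per-sample matrix-exponential step is
    # exact at any step size; no substepping needed
    out = _k.propagate_core(start.occupancy, ca_traj, dt, dt,
                            sensor.param_vector())
    phi = out[:, 2, :].sum(axis=1) + out[:, 0, 2] + out[:, 1, 2]
    phi0, phisat = fluorescence_normalization(sensor)
    f = (phi - phi0) / (phisat - phi0)
    return FluorescenceTrace(t=t[keep], dff=f[keep], rate=protocol.rate)


# ---------------------------------------------------------------------------
# Exponential and Hill fitting
# ---------------------------------------------------------------------------

def _exp_design(t, taus):
    return np.column_stack([np.exp(-t / tau) for tau in taus]
                           + [np.ones_like(t)])


def fit_multi_exponential(trace: FluorescenceTrace, n_components: int,
                          direction: str = "rise") -> ExpFit:
    """Deterministic least-squares sum-of-exponentials fit.

    Nonlinear in the time constants only: for each candidate tau set the
    amplitudes and offset are solved linearly, and the best point of a
    fixed log-spaced multistart grid is polished with a bounded
    trust-region refinement.  Returned taus are ascending.
    """
    if n_components not in (1, 2, 3):
        raise ValueError("n_components must be 1, 2 or 3")
    if direction not in ("rise", "decay"):
        raise ValueError("direction must be 'rise' or 'decay'")
    t = trace.t - trace.t[0]
    y = trace.dff

    def solve_lin(log_taus):
        taus = np.exp(log_taus)
        X = _exp_design(t, taus)
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = X @ coef - y
        return coef, float(np.sqrt(np.mean(r ** 2)))

    span = max(t[-1], 10 * (t[1] - t[0]))
    grid = np.log(np.geomspace(max(t[1] - t[0], 1e-5), span, 12))
    best = None
    from itertools import combinations
    for combo in combinations(range(grid.size), n_components):
        lt = grid[list(combo)]
        _, rms = solve_lin(lt)
        if best is None or rms < best[1]:
            best = (lt, rms)

    def resid(log_taus):
        X = _exp_design(t, np.exp(log_taus))
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        return X @ coef - y

    fit = least_squares(resid, best[0], method="lm", xtol=1e-14, ftol=1e-14)
    coef, rms = solve_lin(fit.x)
    if not np.isfinite(rms):
        raise ArithmeticError("exponential fit failed to converge")
    taus = np.exp(fit.x)
    order = np.argsort(taus)
    return ExpFit(amplitudes=list(coef[:-1][order]),
                  taus=list(taus[order]),
                  offset=float(coef[-1]), residual_rms=rms)


def fit_hill(ca, f) -> HillFit:
    """Least-squares Hill-equation fit of steady-state responses."""
    ca = np.asarray(ca, dtype=float)
    f = np.asarray(f, dtype=float)
    if np.unique(ca).size < 4:
        raise ValueError("need at least 4 distinct concentrations")
    if np.ptp(f) < 1e-12 * max(1.0, np.abs(f).max()):
        raise ValueError("flat data: Hill parameters not identifiable")

    fmin0, fmax0 = f.min(), f.max()
    pos = ca > 0
    kd0 = np.interp(0.5 * (fmin0 + fmax0), np.sort(f), np.sort(ca)) \
        if pos.any() else 1.0
    kd0 = max(kd0, ca[pos].min() if pos.any() else 1e-3)

    def resid(p):
        kd, h, lo, hi = np.exp(p[0]), np.exp(p[1]), p[2], p[3]
        x = ca ** h
        return lo + (hi - lo) * x / (kd ** h + x) - f

    fit = least_squares(resid, [np.log(kd0), 0.0, fmin0, fmax0],
                        xtol=1e-15, ftol=1e-15)
    kd, h = float(np.exp(fit.x[0])), float(np.exp(fit.x[1]))
    return HillFit(kd=kd, hill=h, f_min=float(fit.x[2]),
                   f_max=float(fit.x[3]))


# ---------------------------------------------------------------------------
# Global sensor fit and cell fit
# ---------------------------------------------------------------------------

#: log10 bounds of the 11 fitted sensor parameters
#: (lobe_N: koff, Ka, H, kon_pep, koff_pep; lobe_C: same; R_f)
SENSOR_BOUNDS_LOG10 = (
    np.log10([20, 0.05, 0.7, 20, 2, 1, 0.1, 0.7, 5, 0.2, 5]),
    np.log10([5000, 10, 3.0, 20000, 2000, 1000, 20, 3.0, 5000, 500, 100]),
)


def sensor_from_log10(z) -> SensorModel:
    v = 10.0 ** np.asarray(z, dtype=float)
    return SensorModel(
        lobe_N=LobeKinetics(v[0], v[1], v[2], v[3], v[4]),
        lobe_C=LobeKinetics(v[5], v[6], v[7], v[8], v[9]),
        R_f=v[10])


def sensor_to_log10(sensor: SensorModel) -> np.ndarray:
    return np.log10(np.concatenate([sensor.param_vector(),
                                    [sensor.R_f]]))


def global_fit_sensor(traces, n_starts: int = 128, seed: int = 0,
                      include: np.ndarray | None = None,
                      max_nfev: int = 200):
    """Multistart global fit of sensor kinetics to stopped-flow traces.

    ``traces`` is a sequence of (StoppedFlowProtocol, FluorescenceTrace)
    pairs; the loss is the mean squared error per trace, traces weighted
    equally.  Starts are drawn from a scrambled Sobol sequence over
    log-scaled bounds (optionally including extra points via ``include``),
    each refined by bounded least squares; the best-loss model wins.
    Deterministic given ``seed``.
    """
    traces = list(traces)
    if len(traces) < 3:
        raise ValueError("need at least 3 traces")
    if not any(p.ca_post < p.ca_pre for p, _ in traces):
        raise ValueError("need at least one step-down protocol")
    lo, hi = SENSOR_BOUNDS_LOG10

    def resid(z):
        try:
            sensor = sensor_from_log10(z)
            out = []
            for proto, tr in traces:
                sim = simulate_stopped_flow(sensor, proto.__class__(
                    ca_pre=proto.ca_pre, ca_post=proto.ca_post,
                    dead_time=proto.dead_time,
                    duration=tr.t[-1] + 1.0 / tr.rate, rate=tr.rate))
                m = min(sim.dff.size, tr.dff.size)
                out.append((sim.dff[:m] - tr.dff[:m]) / np.sqrt(m))
            return np.concatenate(out)
        except (ValueError, ArithmeticError):
            return np.full(10, 1e3)

    sob = qmc.Sobol(d=lo.size, scramble=True, seed=seed)
    starts = lo + sob.random(n_starts) * (hi - lo)
    if include is not None:
        starts = np.vstack([np.atleast_2d(include), starts])
    best, diagnostics = None, []
    for i, z0 in enumerate(starts):
        try:
            fit = least_squares(resid, z0, bounds=(lo, hi),
                                diff_step=1e-3, max_nfev=max_nfev)
            loss = float(np.mean(fit.fun ** 2) * fit.fun.size / len(traces))
            diagnostics.append((i, loss))
            if best is None or loss < best[1]:
                best = (fit.x, loss)
        except Exception as e:     # noqa: BLE001 - per-start diagnostics
            diagnostics.append((i, repr(e)))
    if best is None:
        raise RuntimeError(f"all starts failed: {diagnostics}")
    return sensor_from_log10(best[0]), best[1]


#: log10 bounds of the fitted cell parameters (a_ca, g_total, pump_vmax, R_f
#: is *not* refit here — the sensor stays fixed)
CELL_FIT_BOUNDS_LOG10 = (np.log10([2, 1, 50]), np.log10([100, 100, 5000]))


def fit_cell_params(recordings, sensor: SensorModel, seed: int = 0,
                    base: CellParams | None = None, n_starts: int = 8,
                    max_nfev: int = 100) -> list[CellParams]:
    """Fit per-recording cell parameters with the sensor model fixed.

    ``recordings`` is a sequence of (FluorescenceTrace, SpikeTrain) pairs.
    Optimizes (a_ca, g_total, pump_vmax) per recording over shared bounds
    by Sobol-multistart bounded least squares; deterministic given seed.
    """
    base = base or CellParams()
    lo, hi = CELL_FIT_BOUNDS_LOG10
    results = []
    for r, (trace, spikes) in enumerate(recordings):
        def resid(z):
            try:
                cell = base.replace(a_ca=10.0 ** z[0], g_total=10.0 ** z[1],
                                    pump_vmax=10.0 ** z[2], sigma=0.0)
                sim = simulate(cell, sensor, spikes, trace.duration,
                               trace.rate)
                m = min(sim.dff.size, trace.dff.size)
                return sim.dff[:m] - trace.dff[:m]
            except (ValueError, ArithmeticError):
                return np.full(10, 1e3)

        sob = qmc.Sobol(d=3, scramble=True, seed=seed + r)
        starts = np.vstack([0.5 * (lo + hi),
                            lo + sob.random(n_starts - 1) * (hi - lo)])
        best = None
        for z0 in starts:
            fit = least_squares(resid, z0, bounds=(lo, hi), diff_step=1e-3,
                                max_nfev=max_nfev)
            loss = float(np.mean(fit.fun ** 2))
            if best is None or loss < best[1]:
                best = (fit.x, loss)
        z = best[0]
        results.append(base.replace(a_ca=10.0 ** z[0],
                                    g_total=10.0 ** z[1],
                                    pump_vmax=10.0 ** z[2]))
    return results


def accessible_slowing_surrogate(sensor: SensorModel, ca: float = 10.0):
    """Documented surrogate for the slow-state accessibility tradeoff.

    Ratio of (slow-pathway entry rate x slow-state dwell time) to the
    fast-pathway counterpart, evaluated at calcium ``ca``.  This is a
    repository-defined surrogate, not a published formula: it compares how
    readily the C-lobe (slow) fluorescent pathway is entered and how long
    it persists, relative to the N-lobe (fast) pathway.
    """
    n, c = sensor.lobe_N, sensor.lobe_C
    slow = c.on_rate(ca) * c.k_on_pep / (c.k_on_pep + c.k_off_ca) \
        / c.k_off_pep
    fast = n.on_rate(ca) * n.k_on_pep / (n.k_on_pep + n.k_off_ca) \
        / n.k_off_pep
    return slow / fast
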