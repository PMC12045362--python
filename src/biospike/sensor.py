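"""Multistate GCaMP kinetic model.

A GCaMP molecule is modeled as two semi-independent calmodulin lobes — the
fast-binding N-lobe and the slow-binding C-lobe.  Each lobe occupies one of
three states: apo, calcium-bound, or calcium-and-peptide-bound.  Calcium
binding is a first-order step with a pseudo-first-order on-rate

    k_on(ca) = k_off_ca * (ca / K_a) ** H,

so that K_a acts as an apparent dissociation constant and H as a Hill
exponent for cooperative binding.  A calcium-bound lobe can bind the target
peptide (rates k_on_pep / k_off_pep), which renders the sensor fluorescent.
The joint occupancy over the 9 (N-lobe, C-lobe) state combinations is
tracked, with lobe-local rates: the joint generator is the Kronecker sum of
the two 3-state lobe generators.

States with at least one lobe in the Ca+peptide configuration are
fluorescent and contribute equally to total fluorescence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import _kernels as _k

N_STATES = 9
#: per-lobe state labels, indexing both axes of the occupancy matrix
LOBE_STATES = ("apo", "ca", "ca_pep")

#: calcium concentration treated as saturating when evaluating the dynamic
#: range normalization (µM)
CA_SATURATING = 1e6


@dataclass(frozen=True)
class LobeKinetics:
    """Rate constants of a single calmodulin lobe.

    Parameters
    ----------
    k_off_ca : float
        Calcium unbinding rate (1/s).
    K_a : float
        Apparent dissociation constant (µM).
    H : float
        Hill coefficient of cooperative calcium binding.
    k_on_pep, k_off_pep : float
        Peptide binding/unbinding rates from the calcium-bound lobe (1/s).
    """

    k_off_ca: float
    K_a: float
    H: float
    k_on_pep: float
    k_off_pep: float

    def __post_init__(self):
        for name in ("k_off_ca", "K_a", "k_on_pep", "k_off_pep"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0 < self.H <= 4:
            raise ValueError("Hill coefficient must be in (0, 4]")

    def on_rate(self, ca: float) -> float:
        """Pseudo-first-order calcium on-rate at free calcium ``ca`` (µM)."""
        if ca < 0:
            raise ValueError("calcium concentration must be nonnegative")
        return _k.lobe_on_rate(self.k_off_ca, self.K_a, self.H, float(ca))

    def generator(self, ca: float) -> np.ndarray:
        """3x3 column-generator of the apo <-> Ca <-> Ca+pep chain."""
        return _k.lobe_generator(self.on_rate(ca), self.k_off_ca,
                                 self.k_on_pep, self.k_off_pep)

    def stationary(self, ca: float) -> np.ndarray:
        """Closed-form stationary distribution of the 3-state chain."""
        if ca == np.inf:
            f = self.k_on_pep / (self.k_on_pep + self.k_off_pep)
            return np.array([0.0, 1.0 - f, f])
        kon = self.on_rate(ca)
        w = np.array([1.0,
                      kon / self.k_off_ca,
                      kon / self.k_off_ca * self.k_on_pep / self.k_off_pep])
        return w / w.sum()


@dataclass(frozen=True)
class SensorModel:
    """Full kinetic model of one GCaMP variant.

    ``lobe_N`` is by convention the faster calcium-binding lobe.  ``R_f`` is
    the dynamic range (fluorescence at saturating calcium relative to zero
    calcium).  ``n_ca_per_lobe`` is the number of calcium ions sequestered
    per lobe-binding event; it enters only the cell model's mass balance.
    """

    lobe_N: LobeKinetics
    lobe_C: LobeKinetics
    R_f: float = 10.0
    n_ca_per_lobe: int = 2
    name: str = "custom"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.R_f < 1:
            raise ValueError("dynamic range R_f must be >= 1")
        if self.n_ca_per_lobe < 1:
            raise ValueError("n_ca_per_lobe must be a positive integer")

    # -- packed parameter vector for the numba kernels ---------------------
    def param_vector(self) -> np.ndarray:
        n, c = self.lobe_N, self.lobe_C
        return np.array([n.k_off_ca, n.K_a, n.H, n.k_on_pep, n.k_off_pep,
                         c.k_off_ca, c.K_a, c.H, c.k_on_pep, c.k_off_pep])

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        d = {"name": self.name,
             "R_f": self.R_f,
             "n_ca_per_lobe": self.n_ca_per_lobe,
             "units": {"rates": "1/s", "K_a": "uM"},
             "lobe_N": asdict(self.lobe_N),
             "lobe_C": asdict(self.lobe_C)}
        if self.meta:
            d["meta"] = self.meta
        return d

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, d: dict) -> "SensorModel":
        return cls(lobe_N=LobeKinetics(**d["lobe_N"]),
                   lobe_C=LobeKinetics(**d["lobe_C"]),
                   R_f=d["R_f"], n_ca_per_lobe=d.get("n_ca_per_lobe", 2),
                   name=d.get("name", "custom"), meta=d.get("meta", {}))

    @classmethod
    def load(cls, path) -> "SensorModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def default_sensor(name: str) -> SensorModel:
    """Load one of the shipped calibrated parameter sets.

    ``name`` is one of ``gcamp6f``, ``jgcamp7f``, ``jgcamp8f``.
    """
    path = Path(__file__).parent / "params" / f"{name.lower()}.json"
    if not path.exists():
        raise KeyError(f"no shipped parameter set named {name!r}")
    return SensorModel.load(path)


@dataclass
class SensorState:
    """Occupancy over the 9 joint (N-lobe, C-lobe) states.

    ``occupancy`` is stored as a 3x3 matrix, row = N-lobe state, column =
    C-lobe state, per-lobe state order (apo, Ca, Ca+pep).  Entries are
    fractions of total sensor and sum to 1.
    """

    occupancy: np.ndarray

    def __post_init__(self):
        self.occupancy = np.asarray(self.occupancy, dtype=float)
        if self.occupancy.shape == (N_STATES,):
            self.occupancy = self.occupancy.reshape(3, 3)
        if self.occupancy.shape != (3, 3):
            raise ValueError("occupancy must be a 9-vector or 3x3 matrix")
        if (self.occupancy < -1e-12).any():
            raise ValueError("occupancy entries must be nonnegative")
        if abs(self.occupancy.sum() - 1.0) > 1e-9:
            raise ValueError("occupancy must sum to 1")

    @property
    def vector(self) -> np.ndarray:
        return self.occupancy.reshape(N_STATES)

    @property
    def fluorescent_fraction(self) -> float:
        """Occupancy of states with at least one lobe in Ca+peptide."""
        P = self.occupancy
        return float(P[2, :].sum() + P[:, 2].sum() - P[2, 2])

    @classmethod
    def all_apo(cls) -> "SensorState":
        P = np.zeros((3, 3))
        P[0, 0] = 1.0
        return cls(P)


@dataclass(frozen=True)
class StateClassOccupancy:
    """Mechanistic partition of the 9 states into four classes."""

    fast_fluorescent: float
    slow_fluorescent: float
    slow_nonfluorescent: float
    nonfluorescent_other: float


def lobe_on_rate(lobe: LobeKinetics, ca: float) -> float:
    """Pseudo-first-order on-rate k_off_ca * (ca/K_a)**H (1/s)."""
    return lobe.on_rate(ca)


def build_generator(sensor: SensorModel, ca: float) -> np.ndarray:
    """9x9 transition-rate matrix over the joint states at clamped ``ca``.

    Columns sum to zero; the only transitions change exactly one lobe's
    state by one step.  Row-major joint index: 3 * (N state) + (C state).
    """
    if ca < 0:
        raise ValueError("calcium concentration must be nonnegative")
    GN = sensor.lobe_N.generator(ca)
    GC = sensor.lobe_C.generator(ca)
    return np.kron(GN, np.eye(3)) + np.kron(np.eye(3), GC)


def steady_state(sensor: SensorModel, ca: float) -> SensorState:
    """Stationary occupancy at clamped calcium.

    The lobes are kinetically independent, so the joint stationary
    distribution is the outer product of the per-lobe birth-death chain
    stationary distributions; the result is verified against the joint
    generator.
    """
    if ca < 0:
        raise ValueError("calcium concentration must be nonnegative")
    piN = sensor.lobe_N.stationary(ca)
    piC = sensor.lobe_C.stationary(ca)
    P = np.outer(piN, piC)
    resid = np.abs(build_generator(sensor, min(ca, 1e12)) @ P.reshape(9))
    if resid.max() > 1e-6 * max(1.0, sensor.lobe_N.k_off_ca,
                                sensor.lobe_C.k_off_ca):
        raise ArithmeticError(
            f"stationary solve failed at ca={ca}: residual {resid.max():.3g}")
    return SensorState(P)


def saturating_state(sensor: SensorModel) -> SensorState:
    """Stationary occupancy in the saturating-calcium limit."""
    return SensorState(np.outer(sensor.lobe_N.stationary(np.inf),
                                sensor.lobe_C.stationary(np.inf)))


def fluorescence_normalization(sensor: SensorModel):
    """(phi0, phi_sat): fluorescent-class occupancy at zero and saturating
    calcium steady states."""
    phi0 = steady_state(sensor, 0.0).fluorescent_fraction
    phisat = saturating_state(sensor).fluorescent_fraction
    if phisat - phi0 <= 1e-12:
        raise ValueError("degenerate sensor: no fluorescence dynamic range")
    return phi0, phisat


def fluorescence(state: SensorState, sensor: SensorModel,
                 mode: str = "cell") -> float:
    """Fluorescence readout of an occupancy state.

    ``stopped_flow`` normalizes between 0 (zero-calcium steady state) and 1
    (saturating steady state); ``cell`` scales between 1 and the dynamic
    range R_f over the same occupancy span.
    """
    phi0, phisat = fluorescence_normalization(sensor)
    frac = (state.fluorescent_fraction - phi0) / (phisat - phi0)
    if mode == "stopped_flow":
        return frac
    if mode == "cell":
        return 1.0 + (sensor.R_f - 1.0) * frac
    raise ValueError(f"unknown fluorescence mode {mode!r}")


def dff(f_current: float, f_basal: float) -> float:
    """Fractional fluorescence change (F - F_basal) / F_basal."""
    if f_basal <= 0:
        raise ValueError("basal fluorescence must be positive")
    return (f_current - f_basal) / f_basal


def propagate(sensor: SensorModel, initial: SensorState,
              ca_trajectory: np.ndarray, dt: float,
              h_max: float = 1e-4) -> list[SensorState]:
    """Integrate the master equation along a clamped calcium trajectory.

    Calcium is held piecewise constant over each sample interval, within
    which the propagator is the exact (Kronecker-factored) matrix
    exponential applied in substeps of at most ``h_max`` seconds, so the
    scheme is unconditionally stable for arbitrarily stiff rate ratios.
    """
    ca_trajectory = np.asarray(ca_trajectory, dtype=float)
    if dt <= 0:
        raise ValueError("dt must be positive")
    if (ca_trajectory < 0).any():
        raise ValueError("calcium trajectory must be nonnegative")
    out = _k.propagate_core(initial.occupancy, ca_trajectory, float(dt),
                            float(h_max), sensor.param_vector())
    states = []
    for P in out:
        if not np.isfinite(P).all() or (P < -1e-6).any():
            raise ArithmeticError("master-equation integration failed")
        P = np.clip(P, 0.0, None)
        states.append(SensorState(P / P.sum()))
    return states


def classify_states(trajectory) -> list[StateClassOccupancy]:
    """Partition occupancy into mechanistic classes at every time point.

    slow-fluorescent: fluorescent states whose C-lobe carries the peptide;
    fast-fluorescent: the remaining fluorescent states (N-lobe pathway);
    slow-nonfluorescent: non-fluorescent states with the C-lobe
    calcium-engaged; everything else is nonfluorescent-other.
    """
    if isinstance(trajectory, SensorState):
        trajectory = [trajectory]
    out = []
    for st in trajectory:
        P = st.occupancy
        slow_f = float(P[:, 2].sum())
        fast_f = float(P[2, 0] + P[2, 1])
        slow_nf = float(P[0, 1] + P[1, 1])
        other = float(P[0, 0] + P[1, 0])
        out.append(StateClassOccupancy(fast_f, slow_f, slow_nf, other))
    return out
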