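"""Single clock-neuron model: state, parameters, light schedule, and drift.

The cell-autonomous oscillator is the five-variable PER negative-feedback
model (Goldbeter-type): *per* mRNA ``M`` is transcribed under cooperative
repression by nuclear PER ``PN``, translated to unphosphorylated cytosolic
protein ``P0``, reversibly phosphorylated twice (``P0 <-> P1 <-> P2``), and
the fully phosphorylated form ``P2`` is degraded enzymatically, shuttles in
and out of the nucleus by first-order transport, and is additionally degraded
linearly while the lights are on.  Units: concentrations in nM, time in hours.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

import numpy as np

__all__ = [
    "ClockParams",
    "ClockState",
    "LightSchedule",
    "PARAM_ORDER",
    "repression_fraction",
    "light_indicator",
    "light_trace",
    "clock_drift",
]

#: Canonical ordering of the kinetic constants when packed into a flat vector
#: (the integration kernels receive parameters in this order).
PARAM_ORDER = (
    "vs", "vm", "Km", "ks",
    "V1", "K1", "V2", "K2", "V3", "K3", "V4", "K4",
    "k1", "k2", "vd", "Kd", "KI", "n", "dL",
)


@dataclass(frozen=True)
class ClockParams:
    """Kinetic constants of one clock neuron.

    Defaults are the standard parameterization of the stochastic PER model;
    ``vd`` (maximal dark degradation of P2, nM/h) and ``dL`` (light-induced
    linear degradation of P2, 1/h) default to mid-range values of the
    intervals explored by the parameter-plane scans ([2.7, 3.0] nM/h and
    [0.2, 8.5] 1/h respectively).

    Attributes
    ----------
    vs : maximal transcription rate, nM/h.
    vm, Km : maximal mRNA degradation rate (nM/h) and its Michaelis constant (nM).
    ks : translation rate constant, 1/h.
    V1..V4, K1..K4 : maximal (de)phosphorylation rates (nM/h) and Michaelis
        constants (nM) of the two reversible phosphorylation steps.
    k1, k2 : nuclear entry / exit rate constants of P2, 1/h.
    vd, Kd : maximal non-photic degradation rate of P2 (nM/h) and its
        Michaelis constant (nM).
    KI, n : repression threshold (nM) and Hill exponent of PN on transcription.
    dL : light-induced linear degradation rate of P2, 1/h (0 = dark).
    """

    vs: float = 0.50
    vm: float = 0.35
    Km: float = 0.20
    ks: float = 2.00
    V1: float = 6.00
    K1: float = 1.50
    V2: float = 3.00
    K2: float = 2.00
    V3: float = 6.00
    K3: float = 1.50
    V4: float = 3.00
    K4: float = 2.00
    k1: float = 2.00
    k2: float = 1.00
    vd: float = 2.85
    Kd: float = 0.10
    KI: float = 1.50
    n: float = 4
    dL: float = 4.00

    def __post_init__(self) -> None:
        # k1, k2 and vd may reach exactly zero through mean-field modulation
        # (the decreasing laws clip there); everything else stays positive.
        nonneg = {"dL", "k1", "k2", "vd"}
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise ValueError(f"parameter {f.name} must be finite, got {v!r}")
            if f.name in nonneg:
                if v < 0:
                    raise ValueError(f"parameter {f.name} must be >= 0, got {v}")
            elif v <= 0:
                raise ValueError(f"parameter {f.name} must be > 0, got {v}")
        if self.n < 1:
            raise ValueError(f"Hill exponent n must be >= 1, got {self.n}")

    def to_vector(self) -> np.ndarray:
        """Pack the constants into a float64 vector in :data:`PARAM_ORDER`."""
        return np.array([getattr(self, k) for k in PARAM_ORDER], dtype=np.float64)

    def with_(self, **kwargs: float) -> "ClockParams":
        """Return a copy with the given constants replaced."""
        return replace(self, **kwargs)

    def as_dict(self) -> dict[str, float]:
        return {k: float(getattr(self, k)) for k in PARAM_ORDER}


@dataclass(frozen=True)
class ClockState:
    """The five concentrations (nM) of one clock neuron."""

    M: float = 0.0   #: per mRNA
    P0: float = 0.0  #: unphosphorylated cytosolic PER
    P1: float = 0.0  #: mono-phosphorylated cytosolic PER
    P2: float = 0.0  #: fully phosphorylated cytosolic PER
    PN: float = 0.0  #: nuclear PER

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"concentration {f.name} must be >= 0")

    def to_vector(self) -> np.ndarray:
        return np.array([self.M, self.P0, self.P1, self.P2, self.PN], dtype=np.float64)

    @classmethod
    def from_vector(cls, y: np.ndarray) -> "ClockState":
        return cls(*map(float, y))


@dataclass(frozen=True)
class LightSchedule:
    """Protocol of entrained (LD) days followed by free-running (DD) days.

    Lights turn ON at t = 0 of each LD day and stay on for ``photoperiod_on``
    hours; the remainder of the day and every DD day are dark.
    """

    ld_days: int = 9
    dd_days: int = 7
    photoperiod_on: float = 12.0
    day_length: float = 24.0

    def __post_init__(self) -> None:
        if self.ld_days < 0 or self.dd_days < 0:
            raise ValueError("day counts must be >= 0")
        if not 0 <= self.photoperiod_on <= self.day_length:
            raise ValueError("photoperiod_on must lie in [0, day_length]")

    @property
    def total_hours(self) -> float:
        return (self.ld_days + self.dd_days) * self.day_length

    @property
    def ld_hours(self) -> float:
        return self.ld_days * self.day_length


def repression_fraction(PN: float, KI: float, n: float) -> float:
    """Fraction of maximal transcription, ``KI^n / (KI^n + PN^n)``.

    Cooperative (Hill-type) repression of *per* transcription by nuclear PER:
    1 with no repressor, 1/2 at ``PN = KI``, monotone decreasing in ``PN``.
    """
    if PN < 0:
        raise ValueError(f"PN must be >= 0, got {PN}")
    if KI <= 0 or n < 1:
        raise ValueError("require KI > 0 and n >= 1")
    r = (PN / KI) ** n
    return 1.0 / (1.0 + r)


def light_indicator(t: float, schedule: LightSchedule) -> int:
    """1 if the lights are on at time ``t`` (hours from the first lights-on)."""
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t}")
    if t >= schedule.ld_hours:
        return 0
    return 1 if (t % schedule.day_length) < schedule.photoperiod_on else 0


def light_trace(times: np.ndarray, schedule: LightSchedule) -> np.ndarray:
    """Vectorized :func:`light_indicator` over a time grid."""
    t = np.asarray(times, dtype=np.float64)
    on = (t < schedule.ld_hours) & ((t % schedule.day_length) < schedule.photoperiod_on)
    return on.astype(np.int8)


def clock_drift(state, params: ClockParams, light: int) -> np.ndarray:
    """Deterministic drift (nM/h) of the five state variables.

    ``state`` may be a :class:`ClockState` or a length-5 vector
    ``(M, P0, P1, P2, PN)``.  ``light`` is the 0/1 light indicator; it enters
    only through the linear term ``-dL * light * P2``.
    """
    y = state.to_vector() if isinstance(state, ClockState) else np.asarray(state, dtype=np.float64)
    if y.shape != (5,):
        raise ValueError("state must have five components")
    if np.any(y < 0):
        raise ValueError("concentrations must be >= 0")
    M, P0, P1, P2, PN = y
    p = params

    v1 = p.V1 * P0 / (p.K1 + P0)
    v2 = p.V2 * P1 / (p.K2 + P1)
    v3 = p.V3 * P1 / (p.K3 + P1)
    v4 = p.V4 * P2 / (p.K4 + P2)

    dM = p.vs * repression_fraction(PN, p.KI, p.n) - p.vm * M / (p.Km + M)
    dP0 = p.ks * M - v1 + v2
    dP1 = v1 - v2 - v3 + v4
    dP2 = v3 - v4 - p.k1 * P2 + p.k2 * PN - p.vd * P2 / (p.Kd + P2) - p.dL * light * P2
    dPN = p.k1 * P2 - p.k2 * PN
    return np.array([dM, dP0, dP1, dP2, dPN])
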