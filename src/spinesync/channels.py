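"""Hodgkin–Huxley / Boltzmann channel machinery.

Each channel carries activation (m) and optionally inactivation (h) gates
with Boltzmann steady states and voltage-dependent time constants (fixed
values or piecewise-linear V->tau lookups).  A subset of channels uses a
modified inactivation h_eff = a*h + (1-a): the coefficient ``a`` scales the
depth of inactivation and reduces to plain HH at a = 1.

Calcium-activated channels (SK) use a Hill function of shell calcium in
place of the voltage-dependent activation.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np


def boltzmann_inf(V: float, Vh: float, k: float) -> float:
    """Boltzmann steady-state 1/(1+exp(-(V-Vh)/k)).

    Activation gates use k > 0; inactivation gates use k < 0 so the curve
    falls with depolarization.
    """
    if k == 0:
        raise ValueError("Boltzmann slope k must be nonzero")
    return 1.0 / (1.0 + math.exp(-(V - Vh) / k))


@dataclass
class TauSpec:
    """Gate time constant: a fixed value or a tabulated V->tau lookup."""

    value: float | None = None            # ms
    table_v: np.ndarray | None = None     # mV, ascending
    table_tau: np.ndarray | None = None   # ms

    def __post_init__(self) -> None:
        if self.value is None and self.table_v is None:
            raise ValueError("TauSpec needs a value or a table")
        if self.value is not None and self.value <= 0:
            raise ValueError("fixed tau must be > 0")
        if self.table_v is not None:
            self.table_v = np.asarray(self.table_v, dtype=float)
            self.table_tau = np.asarray(self.table_tau, dtype=float)
            if self.table_v.shape != self.table_tau.shape:
                raise ValueError("tau table shapes differ")
            if np.any(np.diff(self.table_v) <= 0):
                raise ValueError("tau table voltages must be ascending")
            if np.any(self.table_tau <= 0):
                raise ValueError("tabulated tau must be > 0 everywhere")

    @property
    def is_fixed(self) -> bool:
        return self.value is not None

    def __call__(self, V) -> np.ndarray | float:
        if self.value is not None:
            return self.value if np.isscalar(V) else np.full(np.shape(V), self.value)
        return np.interp(V, self.table_v, self.table_tau)


@dataclass
class GateSpec:
    vh: float = 0.0           # mV
    k: float = 1.0            # mV; sign encodes activation/inactivation
    tau: TauSpec = field(default_factory=lambda: TauSpec(value=1.0))
    #: calcium-gated alternative: m_inf = Ca^n/(Ca^n + ec50^n)
    ca_gated: bool = False
    ca_ec50: float = 5.7e-4   # mM
    ca_hill: float = 4.0

    def inf(self, V: float, ca: float = 0.0) -> float:
        if self.ca_gated:
            c = max(ca, 0.0) ** self.ca_hill
            return c / (c + self.ca_ec50 ** self.ca_hill)
        return boltzmann_inf(V, self.vh, self.k)


@dataclass
class ChannelSpec:
    """One channel type: conductance, reversal and gate definitions."""

    name: str
    gbar: float               # S/cm^2
    erev: float               # mV
    x: int = 1                # activation exponent
    y: int = 0                # inactivation exponent
    a: float = 1.0            # Eq-4 inactivation coefficient; 1 => plain HH
    m: GateSpec | None = None
    h: GateSpec | None = None
    is_calcium: bool = False  # current feeds the calcium shell

    def __post_init__(self) -> None:
        if self.gbar < 0:
            raise ValueError(f"{self.name}: gbar must be >= 0")
        if self.x < 0 or self.y < 0 or self.x != int(self.x) or self.y != int(self.y):
            raise ValueError(f"{self.name}: gate exponents must be non-negative integers")
        if self.x > 0 and self.m is None:
            raise ValueError(f"{self.name}: x > 0 requires an m gate")
        if self.y > 0 and self.h is None:
            raise ValueError(f"{self.name}: y > 0 requires an h gate")


@dataclass
class GateState:
    m: float = 1.0
    h: float = 1.0

    def __post_init__(self) -> None:
        self.m = min(max(self.m, 0.0), 1.0)
        self.h = min(max(self.h, 0.0), 1.0)


def effective_h(spec: ChannelSpec, h: float) -> float:
    """Modified inactivation h_eff = a*h + (1-a); a=1 gives plain HH."""
    return spec.a * h + (1.0 - spec.a)


def channel_current(spec: ChannelSpec, gates: GateState, V: float) -> float:
    """Ohmic current density gbar*m^x*h_eff^y*(V-E), in mA/cm^2.

    gbar in S/cm^2 and V in mV give mA/cm^2 directly.
    """
    g = spec.gbar * gates.m ** spec.x
    if spec.y > 0:
        g *= effective_h(spec, gates.h) ** spec.y
    return g * (V - spec.erev)


def step_gates(spec: ChannelSpec, gates: GateState, V: float, dt: float,
               ca: float = 0.0) -> GateState:
    """Exponential relaxation of each gate toward its steady state.

    m <- m_inf + (m - m_inf)*exp(-dt/tau(V)); exact for frozen V over dt.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    m, h = gates.m, gates.h
    if spec.x > 0:
        minf = spec.m.inf(V, ca)
        tau = float(spec.m.tau(V))
        if tau <= 0:
            raise ValueError(f"{spec.name}: tau(m) <= 0 at V={V}")
        m = minf + (m - minf) * math.exp(-dt / tau)
    if spec.y > 0:
        hinf = spec.h.inf(V, ca)
        tau = float(spec.h.tau(V))
        if tau <= 0:
            raise ValueError(f"{spec.name}: tau(h) <= 0 at V={V}")
        h = hinf + (h - hinf) * math.exp(-dt / tau)
    return GateState(m=m, h=h)
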