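"""The simulator-handle contract and closed-form toy simulators.

Any object with ``current_time``, ``step(to_time)``, ``get(name)`` and
``set(name, value)`` can be driven by the synchronization kernel.  The toy
simulators here have exact closed-form step semantics, so they serve as
independent oracles for kernel and coupling tests.
"""
from __future__ import annotations

import math
from typing import Protocol, runtime_checkable

from .events import TIME_TOL, Event


@runtime_checkable
class SimulatorHandle(Protocol):
    """Minimal contract a simulator must expose to be synchronized."""

    current_time: float

    def step(self, to_time: float) -> None: ...

    def get(self, name: str) -> float: ...

    def set(self, name: str, value: float) -> None: ...


class _ToyBase:
    """Common plumbing: monotone time, named scalar variables."""

    def __init__(self) -> None:
        self.current_time = 0.0
        self._vars: dict[str, float] = {}

    def _advance(self, to_time: float) -> float:
        if to_time < self.current_time - TIME_TOL:
            raise ValueError(
                f"step would move time backwards: {self.current_time} -> {to_time}"
            )
        dt = max(to_time - self.current_time, 0.0)
        self.current_time = to_time
        return dt

    def get(self, name: str) -> float:
        return self._vars[name]

    def set(self, name: str, value: float) -> None:
        self._vars[name] = float(value)


class ExponentialDecay(_ToyBase):
    """dx/dt = -lam*x + gain*u, with u an externally set input.

    ``lam`` is in 1/ms.  The step is the exact solution with u held constant,
    so trajectories are closed-form regardless of step partitioning.
    """

    def __init__(self, lam: float, x0: float = 1.0, gain: float = 0.0) -> None:
        super().__init__()
        if lam < 0:
            raise ValueError("lam must be >= 0")
        self.lam = lam
        self.gain = gain
        self._vars = {"x": float(x0), "u": 0.0}

    def step(self, to_time: float) -> None:
        dt = self._advance(to_time)
        if dt == 0.0:
            return
        x, u = self._vars["x"], self._vars["u"]
        if self.lam == 0.0:
            self._vars["x"] = x + self.gain * u * dt
        else:
            s = self.gain * u / self.lam
            self._vars["x"] = s + (x - s) * math.exp(-self.lam * dt)


class Constant(_ToyBase):
    """x held at a constant unless externally overwritten."""

    def __init__(self, c: float = 0.0) -> None:
        super().__init__()
        self._vars = {"x": float(c)}

    def step(self, to_time: float) -> None:
        self._advance(to_time)


class Ramp(_ToyBase):
    """x grows linearly in time at a fixed slope (per ms)."""

    def __init__(self, slope: float, x0: float = 0.0) -> None:
        super().__init__()
        self.slope = slope
        self._vars = {"x": float(x0)}

    def step(self, to_time: float) -> None:
        dt = self._advance(to_time)
        self._vars["x"] += self.slope * dt


class ScriptedTrace(_ToyBase):
    """A handle whose named variable follows a prescribed function of time.

    Useful as a stand-in fast simulator when testing the coupling transforms
    against a known calcium waveform.
    """

    def __init__(self, func, name: str = "Ca") -> None:
        super().__init__()
        self._func = func
        self._name = name
        self._vars = {name: float(func(0.0))}

    def step(self, to_time: float) -> None:
        self._advance(to_time)
        self._vars[self._name] = float(self._func(self.current_time))

    def set(self, name: str, value: float) -> None:  # scripted var is read-only
        if name == self._name:
            raise ValueError(f"{name} is scripted and cannot be set")
        super().set(name, value)


class EventEmitter(_ToyBase):
    """Toy fast simulator that emits pre-programmed events during steps.

    Models the on-demand scenario where events emerge from the simulation
    rather than being known a priori.
    """

    def __init__(self, emission_times, target_id: str = "spine0") -> None:
        super().__init__()
        self._pending = sorted(float(t) for t in emission_times)
        self._target = target_id
        self._emitted_last_step: list[Event] = []
        self._vars = {"x": 0.0}

    def step(self, to_time: float) -> None:
        t0 = self.current_time
        self._advance(to_time)
        self._emitted_last_step = [
            Event(time=t, target_id=self._target)
            for t in self._pending
            if t0 < t <= to_time + TIME_TOL
        ]
        self._pending = [t for t in self._pending if t > to_time + TIME_TOL]

    def emitted_events(self) -> list[Event]:
        return list(self._emitted_last_step)


def make_toy_simulator(kind: str, **params) -> SimulatorHandle:
    """Factory for closed-form toy simulators.

    Parameters
    ----------
    kind:
        One of ``exponential_decay`` (params ``lam`` [1/ms], ``x0``,
        ``gain``), ``constant`` (param ``c``) or ``ramp`` (params ``slope``
        [per ms], ``x0``).
    """
    kinds = {
        "exponential_decay": ExponentialDecay,
        "constant": Constant,
        "ramp": Ramp,
    }
    try:
        cls = kinds[kind]
    except KeyError:
        raise ValueError(f"unknown toy simulator kind {kind!r}; "
                         f"choose from {sorted(kinds)}") from None
    return cls(**params)
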