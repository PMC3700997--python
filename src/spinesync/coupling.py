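"""Variable-exchange transforms tying the electrical and biochemical models.

Two quantities cross the interface, forming the plasticity feedback loop:

* electrical shell calcium -> a zeroth-order influx constant for the
  biochemical network, computed as the discrete derivative of the electrical
  calcium concentration over the exchange interval;
* biochemical phosphorylated-AMPAR abundance -> a dimensionless synaptic
  weight, the ratio of the current phospho-AMPAR count to its equilibrium
  count, applied as a multiplicand of the AMPA peak conductance at the next
  delivered stimulus.

The generic :class:`CouplingSpec` maps arbitrary named variables between two
handles, so the same kernel code drives both toy fixtures and the hybrid
spine model.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable

from .constants import AVOGADRO
from .events import ExchangeRecord, SyncLog


# ---------------------------------------------------------------------------
# unit bridges
# ---------------------------------------------------------------------------

def conc_to_count(conc: float, volume_fl: float) -> float:
    """Molecule count of a concentration (M) in a volume (fL)."""
    if volume_fl <= 0:
        raise ValueError("volume must be > 0")
    return conc * AVOGADRO * volume_fl * 1e-15


def count_to_conc(count: float, volume_fl: float) -> float:
    """Inverse of :func:`conc_to_count`."""
    if volume_fl <= 0:
        raise ValueError("volume must be > 0")
    return count / (AVOGADRO * volume_fl * 1e-15)


def flux_constant(ca_t1: float, ca_t2: float, delta: float) -> float:
    """Zeroth-order calcium influx constant from the electrical trace.

    Parameters are the shell calcium concentration (mM) at the start and end
    of the exchange interval ``delta`` (ms).  Returns the flux in M/s; the
    mM/ms -> M/s conversion factor is exactly 1.  The sign is preserved: a
    declining electrical calcium drives a declining biochemical calcium.
    """
    if delta <= 0:
        raise ValueError("delta must be > 0")
    return (ca_t2 - ca_t1) / delta  # mM/ms == M/s


def compute_weight(ampar_p_t: float, ampar_p_eq: float) -> float:
    """Synaptic weight as the ratio of phospho-AMPAR to its equilibrium.

    Weight 1 at rest, >1 potentiated, <1 depressed.  Any common unit (count
    or concentration) may be used for both arguments.
    """
    if ampar_p_eq <= 0:
        raise ValueError("equilibrium AMPAR-P reference must be > 0")
    return ampar_p_t / ampar_p_eq


# ---------------------------------------------------------------------------
# variable maps
# ---------------------------------------------------------------------------

def _identity(value: float, delta: float) -> float:
    return value


@dataclass
class VariableMap:
    """One directed variable transfer: read, transform, write.

    ``transform`` receives ``(value, delta_ms)``; stateful transforms are
    plain callables holding their own state.
    """

    source_var: str
    target_var: str
    transform: Callable[[float, float], float] = _identity


class FluxTransform:
    """Stateful discrete-derivative transform for the calcium flux.

    Keeps the calcium value read at the previous exchange; on each call
    returns ``(current - previous)/delta`` in M/s.  ``reset`` re-samples the
    baseline at window opening so stale values from a previous window never
    leak into the derivative.
    """

    def __init__(self) -> None:
        self._prev: float | None = None

    def reset(self, value: float) -> None:
        self._prev = float(value)

    def __call__(self, value: float, delta: float) -> float:
        prev = self._prev if self._prev is not None else value
        self._prev = float(value)
        return flux_constant(prev, value, delta)


class WeightTransform:
    """Phospho-AMPAR concentration (M) -> synaptic weight."""

    def __init__(self, ampar_p_eq_conc: float, gain: float = 1.0) -> None:
        if ampar_p_eq_conc <= 0:
            raise ValueError("equilibrium AMPAR-P reference must be > 0")
        self.eq = ampar_p_eq_conc
        self.gain = gain

    def __call__(self, value: float, delta: float) -> float:
        w = compute_weight(value, self.eq)
        return 1.0 + self.gain * (w - 1.0)


@dataclass
class CouplingSpec:
    """Mapping of exchanged variables between the two simulators.

    ``slow_to_fast`` maps are applied in phase 1 of a synchronization cycle,
    ``fast_to_slow`` maps in phase 3.
    """

    slow_to_fast: list[VariableMap] = field(default_factory=list)
    fast_to_slow: list[VariableMap] = field(default_factory=list)
    volume_fl: float = 1.0
    delta_exchange: float = 1.0

    def _apply(self, maps: Iterable[VariableMap], source, target, delta: float,
               time: float, phase: int, log: SyncLog | None) -> None:
        for m in maps:
            try:
                raw = source.get(m.source_var)
            except KeyError:
                raise KeyError(f"unmapped variable {m.source_var!r} on source "
                               f"handle in phase {phase}") from None
            value = m.transform(raw, delta)
            target.set(m.target_var, value)
            if log is not None:
                log.exchanges.append(ExchangeRecord(
                    time=time, phase=phase, source_var=m.source_var,
                    target_var=m.target_var, raw=raw, transformed=value))

    def apply_slow_to_fast(self, slow, fast, delta: float, time: float,
                           log: SyncLog | None = None) -> None:
        self._apply(self.slow_to_fast, slow, fast, delta, time, 1, log)

    def apply_fast_to_slow(self, fast, slow, delta: float, time: float,
                           log: SyncLog | None = None) -> None:
        self._apply(self.fast_to_slow, fast, slow, delta, time, 3, log)

    def notify_window_open(self, fast, slow) -> None:
        """Re-baseline stateful transforms at the start of a sync window."""
        for m in self.fast_to_slow:
            reset = getattr(m.transform, "reset", None)
            if reset is not None:
                reset(fast.get(m.source_var))

    def notify_window_close(self, fast, slow) -> None:
        """Stop flux-like processes when the simulators decouple.

        Outside synchronization windows the two models evolve
        independently; a zeroth-order influx left running would keep
        injecting calcium with no electrical counterpart, so targets of
        stateful (derivative) transforms are zeroed at window close.
        """
        for m in self.fast_to_slow:
            if getattr(m.transform, "reset", None) is not None:
                slow.set(m.target_var, 0.0)


def exchange_pair(fast, slow, spec: CouplingSpec, delta: float,
                  log: SyncLog | None = None, time: float | None = None) -> None:
    """Apply both exchange directions once, without advancing time.

    Phase-1 reads from the slow simulator (weight update) strictly precede
    the phase-3 reads from the fast one (flux update), honoring the
    slow-read-first hierarchy.
    """
    t = fast.current_time if time is None else time
    spec.apply_slow_to_fast(slow, fast, delta, t, log)
    spec.apply_fast_to_slow(fast, slow, delta, t, log)


def hybrid_coupling(spine_ids, ampar_p_eq: dict[str, float], volume_fl: float,
                    delta_exchange: float = 1.0, weight_gain: float = 1.0,
                    ) -> CouplingSpec:
    """Build the calcium-flux / synaptic-weight coupling for a set of spines.

    Parameters
    ----------
    spine_ids:
        Spine identifiers; each must expose ``<id>.Ca`` (mM) and
        ``<id>.weight`` on the fast handle and ``<id>.AMPAR_P`` (M) and
        ``<id>.k_flux`` (M/s) on the slow handle.
    ampar_p_eq:
        Equilibrium phospho-AMPAR concentration (M) per spine, the
        normalization reference for the weight.
    volume_fl:
        Spine-head volume in fL, used for count reporting.
    """
    s2f = [VariableMap(f"{sid}.AMPAR_P", f"{sid}.weight",
                       WeightTransform(ampar_p_eq[sid], gain=weight_gain))
           for sid in spine_ids]
    f2s = [VariableMap(f"{sid}.Ca", f"{sid}.k_flux", FluxTransform())
           for sid in spine_ids]
    return CouplingSpec(slow_to_fast=s2f, fast_to_slow=f2s,
                        volume_fl=volume_fl, delta_exchange=delta_exchange)
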