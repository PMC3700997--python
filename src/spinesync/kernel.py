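"""The event-driven meta-simulator.

The kernel owns the timeline: simulators are always told explicit target
times (never increments), so floating-point drift cannot accumulate between
the two handles.  Between events the simulators run independently; at each
event both are brought to the exact event time and then forced through
four-phase synchronization cycles (slow-read, fast-step, fast-read,
slow-step) every ``delta_exchange`` ms for ``window_length`` ms.

Two baselines are provided for comparison: a fixed-step while-loop
synchronizer, which misses any event not on its grid, and an on-demand
variant for events that emerge from the fast simulator during the run.
"""
from __future__ import annotations

import time as _time
from collections import deque
from typing import Sequence

from .coupling import CouplingSpec
from .events import TIME_TOL, Event, SyncLog, SyncSchedule, validate_sorted


def _deliver(fast, events: Sequence[Event], at_time: float, log: SyncLog) -> None:
    for ev in events:
        hook = getattr(fast, "deliver_event", None)
        if hook is not None:
            hook(ev)
        log.delivered_events.append((ev, at_time))


def synchronize_cycle(fast, slow, delta: float, exchange: CouplingSpec,
                      log: SyncLog | None = None,
                      deliver: Sequence[Event] = ()) -> None:
    """One four-phase synchronization cycle advancing both handles by delta.

    Phase 1 reads the mapped variables from the slow simulator, transforms
    and writes them into the fast one; pending events are then delivered (so
    a stimulus always sees an up-to-date synaptic weight); phase 2 advances
    the fast simulator; phase 3 reads back from the fast simulator into the
    slow one; phase 4 advances the slow simulator to the same time.
    """
    t0 = fast.current_time
    if abs(slow.current_time - t0) > TIME_TOL:
        raise ValueError(
            f"time-consistency violation: fast at {t0} ms, slow at "
            f"{slow.current_time} ms")
    if delta < 0:
        raise ValueError("delta must be >= 0")
    if log is None:
        log = SyncLog()
    exchange.apply_slow_to_fast(slow, fast, delta, t0, log)     # phase 1
    if deliver:
        _deliver(fast, deliver, t0, log)
    fast.step(t0 + delta)                                       # phase 2
    exchange.apply_fast_to_slow(fast, slow, delta, t0 + delta, log)  # phase 3
    slow.step(t0 + delta)                                       # phase 4
    log.n_exchange_cycles += 1


def run_event_driven(fast, slow, events: Sequence[Event],
                     schedule: SyncSchedule, exchange: CouplingSpec,
                     ) -> SyncLog:
    """Run both simulators to ``schedule.t_stop``, synchronizing at events.

    Every event is delivered exactly once at its exact time.  Events falling
    inside a still-open synchronization window extend the window rather than
    nesting a new one.
    """
    t_start = _time.perf_counter()
    validate_sorted(events, schedule.t_stop)
    if abs(fast.current_time - slow.current_time) > TIME_TOL:
        raise ValueError("handles must start at the same current_time")
    log = SyncLog()
    t = fast.current_time
    queue = deque(events)
    delta = schedule.delta_exchange

    while queue:
        ev = queue.popleft()
        if ev.time > t + TIME_TOL:
            # fast regime: advance both simulators separately
            fast.step(ev.time)
            slow.step(ev.time)
            t = ev.time
        w_end = min(ev.time + schedule.window_length, schedule.t_stop)
        w_start = t
        pending: list[Event] = [ev]
        exchange.notify_window_open(fast, slow)
        while True:
            # absorb queued events due now; each extends the window
            while queue and queue[0].time <= t + TIME_TOL:
                e2 = queue.popleft()
                pending.append(e2)
                w_end = min(max(w_end, e2.time + schedule.window_length),
                            schedule.t_stop)
            if t >= w_end - TIME_TOL and not pending:
                break
            nxt = min(t + delta, w_end)
            if queue and queue[0].time < nxt - TIME_TOL:
                nxt = queue[0].time  # land exactly on the next event
            synchronize_cycle(fast, slow, nxt - t, exchange, log,
                              deliver=pending)
            pending = []
            t = nxt
        exchange.notify_window_close(fast, slow)
        log.windows.append((w_start, w_end))

    if t < schedule.t_stop - TIME_TOL:
        fast.step(schedule.t_stop)
        slow.step(schedule.t_stop)
    log.check_accounting(events)
    log.wall_clock_s = _time.perf_counter() - t_start
    return log


def run_fixed_step(fast, slow, events: Sequence[Event], dt_sync: float,
                   t_stop: float, exchange: CouplingSpec | None = None,
                   ) -> SyncLog:
    """Fixed-step while-loop baseline: synchronize at every multiple of dt.

    An event is delivered only if its time coincides with a synchronization
    point to within 1e-9 ms; all other events are recorded as missed.
    """
    t_start = _time.perf_counter()
    if dt_sync <= 0:
        raise ValueError("dt_sync must be > 0")
    validate_sorted(events, t_stop)
    if abs(fast.current_time - slow.current_time) > TIME_TOL:
        raise ValueError("handles must start at the same current_time")
    if exchange is None:
        exchange = CouplingSpec()
    log = SyncLog()
    start = fast.current_time
    n_full = int((t_stop - start + TIME_TOL) // dt_sync)
    queue = deque(events)
    exchange.notify_window_open(fast, slow)

    for i in range(n_full + 1):
        point = start + i * dt_sync
        due: list[Event] = []
        while queue and queue[0].time <= point + TIME_TOL:
            ev = queue.popleft()
            if abs(ev.time - point) <= TIME_TOL:
                due.append(ev)
            else:
                log.missed_events.append(ev)
        if i < n_full:
            synchronize_cycle(fast, slow, dt_sync, exchange, log, deliver=due)
        elif due:
            # terminal grid point: exchange and deliver without advancing
            synchronize_cycle(fast, slow, 0.0, exchange, log, deliver=due)

    log.missed_events.extend(queue)  # anything past the last grid point
    exchange.notify_window_close(fast, slow)
    t = fast.current_time
    if t < t_stop - TIME_TOL:
        fast.step(t_stop)
        slow.step(t_stop)
    log.check_accounting(events)
    log.wall_clock_s = _time.perf_counter() - t_start
    return log


def run_on_demand(fast, slow, schedule: SyncSchedule, exchange: CouplingSpec,
                  tstep: float = 1.0) -> SyncLog:
    """Synchronize on demand for events unknown before the run.

    The fast simulator is always advanced first by ``tstep`` and asked for
    events emitted during the step; the slow simulator follows.  When the
    fast side reports events, a synchronization window is opened exactly as
    in :func:`run_event_driven`.  A slow simulator reporting events is not
    supported.
    """
    t_start = _time.perf_counter()
    if tstep <= 0:
        raise ValueError("tstep must be > 0")
    if abs(fast.current_time - slow.current_time) > TIME_TOL:
        raise ValueError("handles must start at the same current_time")
    if getattr(fast, "emitted_events", None) is None:
        raise ValueError("fast handle must expose emitted_events() for "
                         "on-demand synchronization")
    slow_reports = getattr(slow, "emitted_events", None)
    log = SyncLog()
    scheduled: list[Event] = []
    t = fast.current_time
    delta = schedule.delta_exchange

    while t < schedule.t_stop - TIME_TOL:
        nxt = min(t + tstep, schedule.t_stop)
        fast.step(nxt)
        emitted = list(fast.emitted_events())
        slow.step(nxt)
        if slow_reports is not None and slow_reports():
            raise ValueError("slow simulator reporting events is unsupported")
        t = nxt
        if not emitted:
            continue
        scheduled.extend(emitted)
        w_end = min(max(e.time for e in emitted) + schedule.window_length,
                    schedule.t_stop)
        w_start = t
        pending = emitted
        exchange.notify_window_open(fast, slow)
        while t < w_end - TIME_TOL or pending:
            cyc_end = min(t + delta, w_end)
            synchronize_cycle(fast, slow, cyc_end - t, exchange, log,
                              deliver=pending)
            new = list(fast.emitted_events())
            if new:
                scheduled.extend(new)
                w_end = min(max(e.time for e in new) + schedule.window_length,
                            schedule.t_stop)
            pending = new
            t = cyc_end
        exchange.notify_window_close(fast, slow)
        log.windows.append((w_start, w_end))

    log.check_accounting(scheduled)
    log.wall_clock_s = _time.perf_counter() - t_start
    return log
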