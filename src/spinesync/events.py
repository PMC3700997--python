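"""Domain types for the event-driven synchronization kernel.

An :class:`Event` is a timed stimulus aimed at one spine's synapse.  The
kernel treats events as opaque beyond their time: delivery hands them to the
fast simulator, which knows what an AMPA/NMDA stimulus means.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

#: absolute tolerance (ms) for matching event times against time-grid points
TIME_TOL = 1e-9

SYNAPSE_KINDS = ("AMPA", "NMDA", "both")


@dataclass(frozen=True, order=True)
class Event:
    """A timed stimulus targeted at one spine's synapse."""

    time: float
    target_id: str = ""
    synapse_kind: str = "both"

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"event time must be >= 0, got {self.time}")
        if self.synapse_kind not in SYNAPSE_KINDS:
            raise ValueError(
                f"synapse_kind must be one of {SYNAPSE_KINDS}, got {self.synapse_kind!r}"
            )


@dataclass
class SyncSchedule:
    """Timing parameters of the forced-synchronization window.

    After each event the two simulators are kept in lock-step for
    ``window_length`` ms, exchanging variables every ``delta_exchange`` ms.
    """

    t_stop: float
    delta_exchange: float = 1.0
    window_length: float = 10.0

    def __post_init__(self) -> None:
        if self.t_stop <= 0:
            raise ValueError("t_stop must be > 0")
        if not (0 < self.delta_exchange <= self.window_length):
            raise ValueError("need 0 < delta_exchange <= window_length")


@dataclass
class ExchangeRecord:
    """One variable transfer between the simulators."""

    time: float
    phase: int  # 1 = slow->fast, 3 = fast->slow
    source_var: str
    target_var: str
    raw: float
    transformed: float


@dataclass
class SyncLog:
    """Bookkeeping for one synchronization run.

    ``delivered_events`` and ``missed_events`` together account for every
    scheduled event; delivery times never precede the event time.
    """

    delivered_events: list[tuple[Event, float]] = field(default_factory=list)
    missed_events: list[Event] = field(default_factory=list)
    n_exchange_cycles: int = 0
    exchanges: list[ExchangeRecord] = field(default_factory=list)
    windows: list[tuple[float, float]] = field(default_factory=list)
    wall_clock_s: float = 0.0

    # -- audits -----------------------------------------------------------
    def check_accounting(self, scheduled: Iterable[Event]) -> None:
        seen = sorted([e for e, _ in self.delivered_events] + list(self.missed_events))
        if seen != sorted(scheduled):
            raise AssertionError("delivered + missed != scheduled events")
        for ev, t in self.delivered_events:
            if t < ev.time - TIME_TOL:
                raise AssertionError(f"event {ev} delivered before its time ({t})")

    @property
    def n_missed(self) -> int:
        return len(self.missed_events)

    @property
    def n_delivered(self) -> int:
        return len(self.delivered_events)

    # -- export -----------------------------------------------------------
    def events_frame(self):
        import pandas as pd

        rows = [
            {"time": e.time, "target_id": e.target_id, "synapse_kind": e.synapse_kind,
             "delivery_time": t, "delivered": True}
            for e, t in self.delivered_events
        ] + [
            {"time": e.time, "target_id": e.target_id, "synapse_kind": e.synapse_kind,
             "delivery_time": np.nan, "delivered": False}
            for e in self.missed_events
        ]
        return pd.DataFrame(rows, columns=["time", "target_id", "synapse_kind",
                                           "delivery_time", "delivered"])

    def exchanges_frame(self):
        import pandas as pd

        return pd.DataFrame([dataclasses.asdict(x) for x in self.exchanges],
                            columns=["time", "phase", "source_var", "target_var",
                                     "raw", "transformed"])

    def to_hdf5(self, path, group: str = "/synclog") -> None:
        import h5py

        with h5py.File(path, "a") as fh:
            if group in fh:
                del fh[group]
            g = fh.create_group(group)
            ev = self.events_frame()
            ge = g.create_group("events")
            for col in ev.columns:
                data = ev[col].to_numpy()
                if data.dtype == object:
                    data = data.astype("S")
                ge.create_dataset(col, data=data)
            ex = self.exchanges_frame()
            gx = g.create_group("exchanges")
            for col in ex.columns:
                data = ex[col].to_numpy()
                if data.dtype == object:
                    data = data.astype("S")
                gx.create_dataset(col, data=data)
            gt = g.create_group("timings")
            gt.create_dataset("wall_clock_s", data=self.wall_clock_s)
            gt.create_dataset("n_exchange_cycles", data=self.n_exchange_cycles)
            win = np.asarray(self.windows, dtype=float).reshape(-1, 2)
            gt.create_dataset("windows", data=win)

    def to_csv(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.events_frame().to_csv(directory / "events.csv", index=False)
        self.exchanges_frame().to_csv(directory / "exchanges.csv", index=False)


def validate_sorted(events: Sequence[Event], t_stop: float) -> None:
    """Reject unsorted queues and events beyond the simulation end."""
    times = [e.time for e in events]
    if any(b < a for a, b in zip(times, times[1:])):
        raise ValueError("event queue must be sorted non-decreasing by time")
    late = [t for t in times if t > t_stop + TIME_TOL]
    if late:
        raise ValueError(
            f"{len(late)} event(s) scheduled after t_stop={t_stop} ms "
            f"(first at {late[0]} ms)"
        )
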