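"""Stimulation protocols, experiment orchestration and benchmarking.

A stimulation train delivers ``n_inputs`` glutamate events at a fixed
frequency to a set of spines; the double-train experiments deliver one
train at 2000 ms and a second at 15000 ms and compare the voltage
responses, which differ only through the biochemically computed synaptic
weight.
"""
from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .biochemical import BiochemicalSpine, build_network, equilibrate
from .config import (build_msn_model, deep_update, load_channel_config,
                     load_kinetics_config, load_morphology_config)
from .coupling import CouplingSpec, hybrid_coupling
from .events import Event, SyncLog, SyncSchedule
from .handles import Constant, make_toy_simulator
from .kernel import run_event_driven, run_fixed_step
from .biochemical import MultiSpineBiochem


# ---------------------------------------------------------------------------
# trains
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StimTrain:
    """A regular train of synaptic inputs.

    Event times are ``start + i*(1000/frequency)`` ms for i in
    0..n_inputs-1; the reported duration is ``n_inputs/frequency`` seconds.
    """

    frequency: float            # Hz
    n_inputs: int
    start: float = 0.0          # ms
    targets: tuple[str, ...] = ("spine0",)
    synapse_kind: str = "both"

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ValueError("frequency must be > 0")
        if self.n_inputs < 1:
            raise ValueError("need at least one input")

    @property
    def interval_ms(self) -> float:
        return 1000.0 / self.frequency

    @property
    def duration_s(self) -> float:
        return self.n_inputs / self.frequency

    def times(self) -> np.ndarray:
        return self.start + np.arange(self.n_inputs) * self.interval_ms

    def events(self) -> list[Event]:
        return [Event(time=float(t), target_id=sid,
                      synapse_kind=self.synapse_kind)
                for t in self.times() for sid in self.targets]


def build_train(frequency: float, n_inputs: int, start: float = 0.0,
                targets=("spine0",), synapse_kind: str = "both") -> StimTrain:
    return StimTrain(frequency=frequency, n_inputs=n_inputs, start=start,
                     targets=tuple(targets), synapse_kind=synapse_kind)


def merge_events(trains) -> list[Event]:
    evs = [e for t in trains for e in t.events()]
    return sorted(evs, key=lambda e: e.time)


# ---------------------------------------------------------------------------
# experiment configuration
# ---------------------------------------------------------------------------

@dataclass
class ExperimentConfig:
    """Resolved description of one co-simulation experiment."""

    t_stop: float = 20000.0            # ms
    n_spines: int = 1
    stimulated: tuple[str, ...] = ("spine0",)
    trains: list[dict] = field(default_factory=lambda: [
        dict(frequency=8.0, n_inputs=20, start=2000.0),
        dict(frequency=8.0, n_inputs=20, start=15000.0)])
    delta_exchange: float = 1.0        # ms
    window_length: float = 10.0        # ms
    biochemistry: bool = True
    weight_gain: float = 0.2
    dt_elec: float | None = None       # ms; None -> morphology default
    record_every_elec: float = 1.0     # ms
    record_every_biochem: float = 10.0 # ms
    morphology: dict = field(default_factory=dict)   # overrides
    channels: dict = field(default_factory=dict)
    kinetics: dict = field(default_factory=dict)
    seed: int = 0

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "stimulated" in d:
            d["stimulated"] = tuple(d["stimulated"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


# ---------------------------------------------------------------------------
# archive
# ---------------------------------------------------------------------------

@dataclass
class RecordingArchive:
    """Traces + synchronization log + resolved config of one experiment."""

    traces: dict[str, np.ndarray]
    synclog: SyncLog
    config: dict
    train_specs: list[dict]
    ampar_p_eq: dict[str, float] = field(default_factory=dict)

    def save_hdf5(self, path) -> None:
        import h5py

        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with h5py.File(path, "w") as fh:
            g = fh.create_group("traces")
            for name, arr in self.traces.items():
                g.create_dataset(name, data=arr)  # nested groups via '/'
            fh.attrs["config"] = yaml.safe_dump(self.config)
            fh.attrs["trains"] = yaml.safe_dump(self.train_specs)
            fh.attrs["ampar_p_eq"] = yaml.safe_dump(
                {k: float(v) for k, v in self.ampar_p_eq.items()})
        self.synclog.to_hdf5(path)

    @classmethod
    def load_hdf5(cls, path) -> "RecordingArchive":
        import h5py

        import h5py as _h5

        traces = {}
        with h5py.File(path, "r") as fh:
            def visit(name, obj):
                if isinstance(obj, _h5.Dataset):
                    traces[name] = obj[()]
            fh["traces"].visititems(visit)
            cfg = yaml.safe_load(fh.attrs["config"])
            trains = yaml.safe_load(fh.attrs["trains"])
            eq = yaml.safe_load(fh.attrs["ampar_p_eq"])
        return cls(traces=traces, synclog=SyncLog(), config=cfg,
                   train_specs=trains, ampar_p_eq=eq)

    def save_csv(self, directory) -> None:
        import pandas as pd

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for prefix in ("elec", "biochem"):
            cols = {k: v for k, v in self.traces.items()
                    if k.startswith(prefix)}
            if cols:
                pd.DataFrame(cols).to_csv(directory / f"{prefix}.csv",
                                          index=False)
        self.synclog.to_csv(directory)
        with open(directory / "config.yaml", "w") as fh:
            yaml.safe_dump(self.config, fh)


# ---------------------------------------------------------------------------
# experiment runner
# ---------------------------------------------------------------------------

_EQ_CACHE: dict[str, object] = {}


def _equilibrated_network(kin_cfg: dict):
    """Equilibrate the network once per parameter set (cached)."""
    key = yaml.safe_dump(kin_cfg, sort_keys=True)
    if key not in _EQ_CACHE:
        _EQ_CACHE[key] = equilibrate(build_network(kin_cfg))
    return copy.deepcopy(_EQ_CACHE[key])


def run_experiment(cfg: ExperimentConfig) -> RecordingArchive:
    """Build, equilibrate and run one hybrid experiment.

    Biochemical instances are created only for the stimulated spines; each
    is brought to its equilibrium before the run, and the equilibrium
    phospho-AMPAR level becomes the weight normalization reference.
    """
    morph = deep_update(load_morphology_config(), cfg.morphology)
    chans = deep_update(load_channel_config(), cfg.channels)
    kin = deep_update(load_kinetics_config(), cfg.kinetics)

    trains = [build_train(**dict(t, targets=t.get("targets",
                                                  cfg.stimulated)))
              for t in cfg.trains]
    events = merge_events(trains)

    model = build_msn_model(morph, chans, n_spines=cfg.n_spines,
                            dt=cfg.dt_elec,
                            record_every=cfg.record_every_elec)
    model.audit_spine_placement()
    unknown = [sid for sid in cfg.stimulated if sid not in model.spines]
    if unknown:
        raise ValueError(f"stimulated spines not in the model: {unknown}")

    schedule = SyncSchedule(t_stop=cfg.t_stop,
                            delta_exchange=cfg.delta_exchange,
                            window_length=cfg.window_length)

    ampar_p_eq: dict[str, float] = {}
    if cfg.biochemistry:
        base = _equilibrated_network(kin)
        spines = {}
        for sid in cfg.stimulated:
            net = copy.deepcopy(base)
            spines[sid] = BiochemicalSpine(
                net, record_every=cfg.record_every_biochem)
            ampar_p_eq[sid] = net.equilibrium["AMPARp"]
        slow = MultiSpineBiochem(spines)
        volume = next(iter(model.spines.values())).geometry.head_volume_fl()
        exchange = hybrid_coupling(list(cfg.stimulated), ampar_p_eq, volume,
                                   delta_exchange=cfg.delta_exchange,
                                   weight_gain=cfg.weight_gain)
    else:
        slow = Constant(0.0)
        exchange = CouplingSpec()

    log = run_event_driven(model, slow, events, schedule, exchange)

    traces: dict[str, np.ndarray] = {}
    for k, v in model.records.items():
        traces[f"elec/{k}"] = v
    if cfg.biochemistry:
        for sid, sp in slow.spines.items():
            for k, v in sp.records.items():
                traces[f"biochem/{sid}/{k}" if k != "t"
                       else "biochem/t"] = v
    return RecordingArchive(traces=traces, synclog=log,
                            config=cfg.to_dict(),
                            train_specs=[t.__dict__ | {
                                "targets": list(t.targets)} for t in trains],
                            ampar_p_eq=ampar_p_eq)


# ---------------------------------------------------------------------------
# plasticity summary
# ---------------------------------------------------------------------------

def summarize_plasticity(archive: RecordingArchive):
    """Per-spine response summary across the experiment's trains.

    Reports, per stimulated spine: peak head depolarization during each
    train, the difference between second- and first-train peaks (the
    biochemical-contribution statistic), peak phospho-AMPAR and its time,
    and peak enzyme fractional activations.
    """
    import pandas as pd

    trains = archive.train_specs
    t_el = archive.traces.get("elec/t")
    rows = []
    spine_ids = sorted({k.split("/")[1].split(".")[0]
                        for k in archive.traces
                        if k.startswith("elec/spine") and k.endswith(".V")})
    t_bio = archive.traces.get("biochem/t")
    for sid in spine_ids:
        row: dict = {"spine": sid}
        v = archive.traces.get(f"elec/{sid}.V")
        for i, tr in enumerate(trains, start=1):
            start = tr["start"]
            dur = tr["n_inputs"] * 1000.0 / tr["frequency"]
            sel = (t_el >= start) & (t_el <= start + dur + 100.0)
            row[f"peak_v_train{i}"] = float(np.max(v[sel])) if sel.any() else np.nan
        if len(trains) >= 2:
            row["second_minus_first_peak_mv"] = (row["peak_v_train2"]
                                                 - row["peak_v_train1"])
        p = archive.traces.get(f"biochem/{sid}/AMPAR_P")
        if p is not None:
            j = int(np.argmax(p))
            row["peak_ampar_p"] = float(p[j])
            row["t_peak_ampar_p_ms"] = float(t_bio[j])
            eq = archive.ampar_p_eq.get(sid)
            if eq:
                row["peak_ampar_p_ratio"] = float(p[j] / eq)
            for enz in ("active_CaMKII_frac", "active_PP1_frac",
                        "D32_P_frac"):
                tr_ = archive.traces.get(f"biochem/{sid}/{enz}")
                if tr_ is not None:
                    row[f"peak_{enz}"] = float(np.max(tr_))
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# synchronization benchmark
# ---------------------------------------------------------------------------

def table1_fixture(n_events: int = 240, spacing: float = 50.0,
                   start: float = 50.0) -> tuple[list[Event], float]:
    """Evenly spaced single-spine event queue and a matching t_stop."""
    events = [Event(time=start + i * spacing, target_id="spine0")
              for i in range(n_events)]
    return events, events[-1].time + 2 * spacing


def _toy_pair():
    fast = make_toy_simulator("exponential_decay", lam=1e-3, x0=1.0)
    slow = make_toy_simulator("exponential_decay", lam=1e-4, x0=2.0)
    return fast, slow


def benchmark_sync(strategies=("event", "fixed"), dt_values=(10.0, 100.0),
                   n_events: int = 240, spacing: float = 50.0,
                   sparseness=(1,)):
    """Compare synchronization strategies on identical event sets.

    Missed/delivered counts depend only on event times and the grid; the
    simulators are closed-form toys, so the table isolates the
    synchronization behavior.  Wall-clock columns are informational only.
    """
    import pandas as pd

    rows = []
    for n_spines in sparseness:
        # fixed total event count, targets assigned round-robin, so the
        # event-driven exchange-cycle count is sparseness-independent
        events = [Event(time=spacing * (1 + j),
                        target_id=f"spine{j % n_spines}")
                  for j in range(n_events)]
        t_stop = max(e.time for e in events) + 2 * spacing
        for strat in strategies:
            if strat == "event":
                fast, slow = _toy_pair()
                log = run_event_driven(
                    fast, slow, events,
                    SyncSchedule(t_stop=t_stop), CouplingSpec())
                rows.append(dict(strategy="event", dt_sync=np.nan,
                                 n_spines=n_spines, total=len(events),
                                 delivered=log.n_delivered,
                                 missed=log.n_missed,
                                 exchange_cycles=log.n_exchange_cycles,
                                 wall_clock_s=log.wall_clock_s))
            elif strat == "fixed":
                for dt in dt_values:
                    fast, slow = _toy_pair()
                    log = run_fixed_step(fast, slow, events, dt, t_stop,
                                         CouplingSpec())
                    rows.append(dict(strategy="fixed", dt_sync=dt,
                                     n_spines=n_spines, total=len(events),
                                     delivered=log.n_delivered,
                                     missed=log.n_missed,
                                     exchange_cycles=log.n_exchange_cycles,
                                     wall_clock_s=log.wall_clock_s))
            else:
                raise ValueError(f"unknown strategy {strat!r}")
    return pd.DataFrame(rows)
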