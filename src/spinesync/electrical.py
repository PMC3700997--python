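"""Reduced compartmental model of a medium spiny neuron with explicit spines.

Compartments are cylinders joined by axial resistances into a tree.  Each
spine is three sections — post-synaptic density (PSD), head and neck — with
co-localized AMPA/NMDA double-exponential synapses on the PSD and a thin
calcium shell under the head/PSD membrane fed by the voltage-gated calcium
channels.

Numerics: the voltage tree is advanced with a backward-Euler (implicit in
V) solve per internal step; channel conductances are frozen over the step
and gates relax exponentially toward their Boltzmann steady states; shells
are advanced with forward Euler.  Default internal step 0.025 ms.

Units: mV, ms, µm, mM, nS/µS internally.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .channels import ChannelSpec
from .constants import FARADAY_C_PER_MOL
from .events import TIME_TOL, Event
from .morphology import SpineGeometry


# ---------------------------------------------------------------------------
# calcium shell
# ---------------------------------------------------------------------------

@dataclass
class CalciumShell:
    """Thin-shell intracellular calcium under the membrane.

    d[Ca]/dt = -I_Ca/(2*F*depth) - Vmax*[Ca]/([Ca]+Km) - ([Ca]-[Ca]_inf)/tau_r

    with inward (negative) calcium current raising [Ca].  Concentrations in
    mM, time in ms.
    """

    ca: float = 1e-4            # mM
    depth_um: float = 0.1
    vmax: float = 1e-5          # mM/ms
    km: float = 5e-4            # mM
    tau_r: float = 43.0         # ms
    ca_inf: float = 1e-4        # mM
    #: implicit fast-buffer capacity: only 1/buffer_ratio of the entering
    #: calcium appears as free shell calcium (1 = no buffering)
    buffer_ratio: float = 1.0

    def __post_init__(self) -> None:
        if self.ca < 0:
            raise ValueError("[Ca] must be >= 0")
        if self.buffer_ratio < 1:
            raise ValueError("buffer_ratio must be >= 1")
        for name in ("depth_um", "km", "tau_r"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.vmax < 0 or self.ca_inf < 0:
            raise ValueError("vmax and ca_inf must be >= 0")


def shell_calcium_step(shell: CalciumShell, i_ca_nA: float, area_um2: float,
                       dt: float) -> CalciumShell:
    """Advance a shell by dt (ms) under a fixed calcium current (nA)."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if area_um2 <= 0:
        raise ValueError("area must be > 0")
    area_cm2 = area_um2 * 1e-8
    ica_mA_cm2 = i_ca_nA * 1e-6 / area_cm2
    depth_cm = shell.depth_um * 1e-4
    dca = (-ica_mA_cm2 / (2.0 * FARADAY_C_PER_MOL * depth_cm
                          * shell.buffer_ratio)
           - shell.vmax * shell.ca / (shell.ca + shell.km)
           - (shell.ca - shell.ca_inf) / shell.tau_r)
    ca = shell.ca + dca * dt
    if ca < 0:
        warnings.warn("shell calcium clamped at 0", RuntimeWarning,
                      stacklevel=2)
        ca = 0.0
    return replace(shell, ca=ca)


# ---------------------------------------------------------------------------
# synapses
# ---------------------------------------------------------------------------

@dataclass
class SynapseState:
    """Double-exponential synapse normalized to a per-event peak.

    Conductance for one event at t0 with weight w:
    w*gpeak*f*(exp(-(t-t0)/tau_d) - exp(-(t-t0)/tau_r)), with f chosen so
    the peak equals w*gpeak.
    """

    kind: str = "AMPA"
    tau_rise: float = 0.5       # ms
    tau_decay: float = 3.0      # ms
    gpeak: float = 1.0          # nS
    weight: float = 1.0
    #: fraction of the synaptic current carried by calcium (feeds the shell)
    ca_fraction: float = 0.0
    event_times: list[float] = field(default_factory=list)
    event_weights: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (self.tau_decay > self.tau_rise > 0):
            raise ValueError("need tau_decay > tau_rise > 0")
        if self.weight < 0:
            raise ValueError("weight must be >= 0")

    @property
    def t_peak(self) -> float:
        """Time-to-peak of the double exponential after an event."""
        tr, td = self.tau_rise, self.tau_decay
        return tr * td / (td - tr) * math.log(td / tr)

    @property
    def norm(self) -> float:
        tp = self.t_peak
        return 1.0 / (math.exp(-tp / self.tau_decay)
                      - math.exp(-tp / self.tau_rise))


def synapse_conductance(syn: SynapseState, t: float) -> float:
    """Summed conductance (nS) over all delivered events, closed form."""
    if t < 0:
        raise ValueError("t must be >= 0")
    g = 0.0
    weights = syn.event_weights or [syn.weight] * len(syn.event_times)
    for t0, w in zip(syn.event_times, weights):
        dt = t - t0
        if dt <= 0:
            continue
        g += w * syn.gpeak * syn.norm * (math.exp(-dt / syn.tau_decay)
                                         - math.exp(-dt / syn.tau_rise))
    return g


# ---------------------------------------------------------------------------
# compartments
# ---------------------------------------------------------------------------

@dataclass
class CompartmentSpec:
    name: str
    diameter: float              # µm
    length: float                # µm
    parent: str | None = None
    region: str = "dendrite"     # soma|proximal|medial|distal|psd|head|neck
    ra: float = 100.0            # Ω·cm
    cm: float = 1.0              # µF/cm²
    g_pas: float = 2.4e-5        # S/cm²
    e_pas: float = -70.0         # mV
    channels: list[ChannelSpec] = field(default_factory=list)
    #: membrane area override (µm²); spine sections use their full
    #: cylinder surface (lateral + both caps), not the lateral area alone
    area_override: float | None = None

    def __post_init__(self) -> None:
        if self.diameter <= 0 or self.length <= 0:
            raise ValueError(f"{self.name}: geometry must be positive")

    @property
    def area_um2(self) -> float:
        if self.area_override is not None:
            return self.area_override
        return math.pi * self.diameter * self.length  # lateral only


@dataclass
class SpineRegistry:
    """Per-spine bookkeeping: section names and synapses."""

    spine_id: str
    psd: str
    head: str
    neck: str
    geometry: SpineGeometry
    ampa: SynapseState = field(default_factory=lambda: SynapseState("AMPA"))
    nmda: SynapseState = field(default_factory=lambda: SynapseState(
        "NMDA", tau_rise=2.0, tau_decay=100.0, gpeak=0.5))


class ElectricalModel:
    """SimulatorHandle over the compartmental MSN model (the fast side)."""

    def __init__(self, compartments: list[CompartmentSpec],
                 spines: list[SpineRegistry] | None = None,
                 dt: float = 0.025, v_init: float = -80.0,
                 shell_template: CalciumShell | None = None,
                 record_every: float | None = None,
                 syn_erev: float = 0.0) -> None:
        if not compartments:
            raise ValueError("need at least one compartment")
        self.dt = float(dt)
        self.current_time = 0.0
        self.comps = compartments
        self.spines = {s.spine_id: s for s in (spines or [])}
        self.syn_erev = syn_erev
        self._name2idx = {c.name: i for i, c in enumerate(compartments)}
        if len(self._name2idx) != len(compartments):
            raise ValueError("duplicate compartment names")
        self._build_tree()
        self._build_channels()
        self._build_shells(shell_template or CalciumShell())
        self._build_synapses()
        self.v = np.full(self.n, float(v_init))
        self.i_inject_nA = np.zeros(self.n)  # constant current per compartment
        self._init_gates()
        self.record_every = record_every
        self._records: dict[str, list[float]] = {}
        self._next_record = 0.0
        self._warned_clamp = False
        if record_every is not None:
            self._record_now()

    # -- construction -----------------------------------------------------
    def _build_tree(self) -> None:
        n = self.n = len(self.comps)
        parent = np.full(n, -1, dtype=int)
        for i, c in enumerate(self.comps):
            if c.parent is not None:
                if c.parent not in self._name2idx:
                    raise ValueError(f"{c.name}: unknown parent {c.parent}")
                parent[i] = self._name2idx[c.parent]
                if parent[i] >= i:
                    raise ValueError("compartments must be listed parents-first")
        if np.sum(parent < 0) != 1:
            raise ValueError("connectivity must form a single tree")
        self.parent = parent
        area_cm2 = np.array([c.area_um2 * 1e-8 for c in self.comps])
        self.area_cm2 = area_cm2
        self.c_nF = np.array([c.cm for c in self.comps]) * area_cm2 * 1e3
        self.g_pas_uS = np.array([c.g_pas for c in self.comps]) * area_cm2 * 1e6
        self.e_pas = np.array([c.e_pas for c in self.comps])
        # axial conductance child<->parent through two half-cylinders, µS
        g_ax = np.zeros(n)
        for i, c in enumerate(self.comps):
            p = parent[i]
            if p < 0:
                continue
            cp = self.comps[p]
            r = 0.0
            for seg in (c, cp):
                l_cm = seg.length / 2 * 1e-4
                a_cm2 = math.pi * (seg.diameter / 2 * 1e-4) ** 2
                r += seg.ra * l_cm / a_cm2  # Ω
            g_ax[i] = 1e6 / r
        self.g_axial = g_ax
        # static part of the dense BE matrix (axial couplings)
        A = np.zeros((n, n))
        for i in range(n):
            p = parent[i]
            if p < 0:
                continue
            A[i, i] += g_ax[i]
            A[p, p] += g_ax[i]
            A[i, p] -= g_ax[i]
            A[p, i] -= g_ax[i]
        self._A_static = A

    def _build_channels(self) -> None:
        comp_idx, specs = [], []
        for i, c in enumerate(self.comps):
            for ch in c.channels:
                comp_idx.append(i)
                specs.append(ch)
        self.chan_specs = specs
        m_ = len(specs)
        self.chan_comp = np.array(comp_idx, dtype=int)
        self.chan_gmax = np.array(
            [s.gbar * self.area_cm2[i] * 1e6 for s, i in zip(specs, comp_idx)])
        self.chan_erev = np.array([s.erev for s in specs])
        self.chan_x = np.array([s.x for s in specs], dtype=float)
        self.chan_y = np.array([s.y for s in specs], dtype=float)
        self.chan_a = np.array([s.a for s in specs])
        self.chan_is_ca = np.array([s.is_calcium for s in specs], dtype=bool)
        self.m = np.ones(m_)
        self.h = np.ones(m_)
        # gate parameter arrays; tabulated-tau gates are handled per step
        def gate_arrays(which: str):
            vh = np.zeros(m_)
            k = np.ones(m_)
            ca_gated = np.zeros(m_, dtype=bool)
            ec50 = np.ones(m_)
            hill = np.ones(m_)
            fixed_decay = np.ones(m_)
            tab = []  # (index, TauSpec)
            active = np.zeros(m_, dtype=bool)
            for j, s in enumerate(specs):
                gate = getattr(s, which)
                exp_ = s.x if which == "m" else s.y
                if gate is None or exp_ == 0:
                    continue
                active[j] = True
                vh[j], k[j] = gate.vh, gate.k
                ca_gated[j] = gate.ca_gated
                ec50[j], hill[j] = gate.ca_ec50, gate.ca_hill
                if gate.tau.is_fixed:
                    fixed_decay[j] = math.exp(-self.dt / gate.tau.value)
                else:
                    tab.append((j, gate.tau))
            return dict(vh=vh, k=k, ca_gated=ca_gated, ec50=ec50, hill=hill,
                        fixed_decay=fixed_decay, tab=tab, active=active)
        self._gm = gate_arrays("m")
        self._gh = gate_arrays("h")
        self._ca_mask = self.chan_is_ca
        self._ca_comp = self.chan_comp[self.chan_is_ca]

    def _build_shells(self, template: CalciumShell) -> None:
        # one shell per spine (PSD and head share it; the PSD is an internal
        # section of the head) plus one per non-spine compartment carrying
        # calcium or calcium-gated channels
        alias: dict[int, int] = {}  # comp -> owner comp
        for reg in self.spines.values():
            alias[self._name2idx[reg.psd]] = self._name2idx[reg.head]
        needs = set(self.chan_comp[self.chan_is_ca])
        needs |= {self.chan_comp[j] for j in range(len(self.chan_specs))
                  if self._gm["ca_gated"][j]}
        needs |= {self._name2idx[reg.psd] for reg in self.spines.values()}
        owners = sorted({alias.get(int(c), int(c)) for c in needs})
        self.shell_comp = np.array(owners, dtype=int)
        self._comp2shell = {c: i for i, c in enumerate(owners)}
        for c, owner in alias.items():
            self._comp2shell[c] = self._comp2shell[owner]
        # membrane area drained by each shell (µm² -> cm²)
        area = np.zeros(len(owners))
        for c, i in self._comp2shell.items():
            area[i] += self.area_cm2[c]
        self.shell_area_cm2 = area
        # comp -> shell map for current accumulation (-1 = no shell)
        cmap = np.full(self.n, -1, dtype=int)
        for c, i in self._comp2shell.items():
            cmap[c] = i
        self._shell_map = cmap
        self.shell_template = template
        ns = len(self.shell_comp)
        self.shell_ca = np.full(ns, template.ca)
        depth_cm = template.depth_um * 1e-4
        self._shell_curr_factor = -1.0 / (2.0 * FARADAY_C_PER_MOL * depth_cm
                                          * template.buffer_ratio)
        # shell index per ca-gated channel gate (for SK/BK activation)
        for g in (self._gm, self._gh):
            cg = g["active"] & g["ca_gated"]
            g["cg_idx"] = np.flatnonzero(cg)
            g["cg_shell"] = np.array(
                [self._comp2shell[int(self.chan_comp[j])] for j in g["cg_idx"]],
                dtype=int)

    def _build_synapses(self) -> None:
        # event-driven two-state filters per synapse (A decays tau_r,
        # B decays tau_d; g = gpeak*norm*(B-A))
        self._syn: list[dict] = []
        for sid, reg in self.spines.items():
            for syn in (reg.ampa, reg.nmda):
                self._syn.append(dict(
                    sid=sid, kind=syn.kind, syn=syn,
                    comp=self._name2idx[reg.psd],
                    a=0.0, b=0.0, gs=0.0,
                    dec_r=math.exp(-self.dt / syn.tau_rise),
                    dec_d=math.exp(-self.dt / syn.tau_decay)))

    def _init_gates(self) -> None:
        V = self.v[self.chan_comp]
        for g, state in ((self._gm, self.m), (self._gh, self.h)):
            act = g["active"] & ~g["ca_gated"]
            state[act] = 1.0 / (1.0 + np.exp(-(V[act] - g["vh"][act]) / g["k"][act]))
            cg = g["active"] & g["ca_gated"]
            if np.any(cg):
                ca = self.shell_ca[[self._comp2shell[int(c)]
                                    for c in self.chan_comp[cg]]]
                cn = ca ** g["hill"][cg]
                state[cg] = cn / (cn + g["ec50"][cg] ** g["hill"][cg])

    # -- audits -----------------------------------------------------------
    def audit_spine_placement(self) -> None:
        """Verify the per-section channel placement of every spine."""
        want = {"psd": {"CaL1.2", "CaL1.3"},
                "head": {"CaQ", "CaR", "CaN", "SK", "KIR"},
                "neck": {"KIR"}}
        for sid, reg in self.spines.items():
            for section, required in want.items():
                comp = self.comps[self._name2idx[getattr(reg, section)]]
                have = {ch.name for ch in comp.channels}
                missing = required - have
                if missing:
                    raise AssertionError(
                        f"spine {sid} {section} missing channels {missing}")

    # -- stepping ---------------------------------------------------------
    def step(self, to_time: float) -> None:
        if to_time < self.current_time - TIME_TOL:
            raise ValueError("step would move time backwards")
        span = to_time - self.current_time
        if span <= TIME_TOL:
            self.current_time = to_time
            return
        n_sub = max(int(round(span / self.dt)), 1)
        dt = span / n_sub
        uniform = abs(dt - self.dt) < 1e-12
        for _ in range(n_sub):
            self._substep(dt, uniform)
        self.current_time = to_time
        if np.max(np.abs(self.v)) > 200.0:
            worst = int(np.argmax(np.abs(self.v)))
            raise RuntimeError(
                f"numerical blow-up: |V|={self.v[worst]:.1f} mV in "
                f"compartment {self.comps[worst].name} at t={to_time} ms "
                f"(reduce dt or conductances)")

    def _gate_update(self, g, state, V, dt, uniform) -> None:
        act = g["active"]
        if not np.any(act):
            return
        inf = 1.0 / (1.0 + np.exp(-(V - g["vh"]) / g["k"]))
        cg = g["cg_idx"]
        if cg.size:
            ca = self.shell_ca[g["cg_shell"]]
            cn = np.maximum(ca, 0.0) ** g["hill"][cg]
            inf[cg] = cn / (cn + g["ec50"][cg] ** g["hill"][cg])
        if uniform:
            decay = g["fixed_decay"] if not g["tab"] else g["fixed_decay"].copy()
        else:
            decay = np.exp(dt * np.log(np.maximum(g["fixed_decay"], 1e-300)) / self.dt)
        for j, tau in g["tab"]:
            decay[j] = math.exp(-dt / float(tau(V[j])))
        state[act] = inf[act] + (state[act] - inf[act]) * decay[act]

    def _substep(self, dt: float, uniform: bool) -> None:
        V = self.v[self.chan_comp]
        self._gate_update(self._gm, self.m, V, dt, uniform)
        self._gate_update(self._gh, self.h, V, dt, uniform)
        # channel conductances, µS
        g = self.chan_gmax * np.where(self._gm["active"],
                                      self.m ** self.chan_x, 1.0)
        heff = self.chan_a * self.h + (1.0 - self.chan_a)
        g = g * np.where(self._gh["active"], heff ** self.chan_y, 1.0)
        g_sum = np.bincount(self.chan_comp, weights=g, minlength=self.n)
        ge_sum = np.bincount(self.chan_comp, weights=g * self.chan_erev,
                             minlength=self.n)
        # synapses
        for s in self._syn:
            if uniform:
                s["a"] *= s["dec_r"]
                s["b"] *= s["dec_d"]
            else:
                s["a"] *= math.exp(-dt / s["syn"].tau_rise)
                s["b"] *= math.exp(-dt / s["syn"].tau_decay)
            gs = s["syn"].gpeak * s["syn"].norm * (s["b"] - s["a"]) * 1e-3  # µS
            s["gs"] = gs
            if gs != 0.0:
                g_sum[s["comp"]] += gs
                ge_sum[s["comp"]] += gs * self.syn_erev
        # backward-Euler voltage solve
        cdt = self.c_nF / dt
        A = self._A_static.copy()
        A[np.diag_indices(self.n)] += cdt + g_sum + self.g_pas_uS
        b = (cdt * self.v + ge_sum + self.g_pas_uS * self.e_pas
             + self.i_inject_nA)
        self.v = np.linalg.solve(A, b)
        # calcium shells (forward Euler at the new voltage)
        if len(self.shell_comp):
            mask = self._ca_mask
            i_ca = np.bincount(
                self._ca_comp,
                weights=g[mask] * (self.v[self._ca_comp]
                                   - self.chan_erev[mask]),
                minlength=self.n)  # nA
            # calcium fraction of the synaptic currents
            for s in self._syn:
                frac = s["syn"].ca_fraction
                if frac and s["gs"] != 0.0:
                    i_ca[s["comp"]] += frac * s["gs"] * (self.v[s["comp"]]
                                                         - self.syn_erev)
            n_shell = len(self.shell_comp)
            i_shell = np.zeros(n_shell)
            has = self._shell_map >= 0
            np.add.at(i_shell, self._shell_map[has], i_ca[has])
            tpl = self.shell_template
            ica_density = i_shell * 1e-6 / self.shell_area_cm2
            dca = (self._shell_curr_factor * ica_density
                   - tpl.vmax * self.shell_ca / (self.shell_ca + tpl.km)
                   - (self.shell_ca - tpl.ca_inf) / tpl.tau_r)
            self.shell_ca += dca * dt
            if np.any(self.shell_ca < 0):
                if not self._warned_clamp:
                    warnings.warn("shell calcium clamped at 0", RuntimeWarning)
                    self._warned_clamp = True
                np.clip(self.shell_ca, 0.0, None, out=self.shell_ca)
        self.current_time += dt
        if (self.record_every is not None
                and self.current_time >= self._next_record - 1e-9):
            self._record_now()

    def inject_current(self, comp_name: str, amp_nA: float) -> None:
        """Set a constant injected current (nA, depolarizing positive)."""
        self.i_inject_nA[self._name2idx[comp_name]] = float(amp_nA)

    # -- events -----------------------------------------------------------
    def deliver_event(self, ev: Event) -> None:
        if ev.target_id not in self.spines:
            raise KeyError(f"event targets unknown spine {ev.target_id!r}")
        for s in self._syn:
            if s["sid"] != ev.target_id:
                continue
            if ev.synapse_kind != "both" and s["kind"] != ev.synapse_kind:
                continue
            w = s["syn"].weight if s["kind"] == "AMPA" else 1.0
            s["a"] += w
            s["b"] += w
            s["syn"].event_times.append(self.current_time)
            s["syn"].event_weights.append(w)

    # -- variable access --------------------------------------------------
    def _spine_var(self, name: str):
        sid, _, var = name.partition(".")
        return sid, var

    def get(self, name: str) -> float:
        sid, var = self._spine_var(name)
        if sid == "soma" and var == "V":
            return float(self.v[self._name2idx["soma"]])
        if sid in self.spines:
            reg = self.spines[sid]
            if var == "V":
                return float(self.v[self._name2idx[reg.head]])
            if var == "Ca":
                shell = self._comp2shell.get(self._name2idx[reg.head])
                if shell is None:
                    shell = self._comp2shell[self._name2idx[reg.psd]]
                return float(self.shell_ca[shell])
            if var == "weight":
                return reg.ampa.weight
        if name in self._name2idx:  # raw compartment voltage
            return float(self.v[self._name2idx[name]])
        raise KeyError(name)

    def set(self, name: str, value: float) -> None:
        sid, var = self._spine_var(name)
        if sid in self.spines and var == "weight":
            if value < 0:
                raise ValueError("weight must be >= 0")
            self.spines[sid].ampa.weight = float(value)
            return
        if sid in self.spines and var == "Ca":
            reg = self.spines[sid]
            shell = self._comp2shell.get(self._name2idx[reg.head])
            self.shell_ca[shell] = max(float(value), 0.0)
            return
        raise KeyError(name)

    # -- recording --------------------------------------------------------
    def _record_now(self) -> None:
        rec = self._records
        rec.setdefault("t", []).append(self.current_time)
        rec.setdefault("soma.V", []).append(
            float(self.v[self._name2idx["soma"]])
            if "soma" in self._name2idx else float(self.v[0]))
        for sid in self.spines:
            rec.setdefault(f"{sid}.V", []).append(self.get(f"{sid}.V"))
            rec.setdefault(f"{sid}.Ca", []).append(self.get(f"{sid}.Ca"))
            rec.setdefault(f"{sid}.weight", []).append(self.get(f"{sid}.weight"))
        self._next_record = self.current_time + self.record_every

    @property
    def records(self) -> dict[str, np.ndarray]:
        return {k: np.asarray(v) for k, v in self._records.items()}
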