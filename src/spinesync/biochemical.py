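"""Deterministic kinetic model of the spine plasticity network.

The network couples an allosteric (two-conformation, MWC-style) calmodulin
calcium sensor to two opposing enzymatic branches acting on the AMPA
receptor:

* the potentiation branch — fully calcium-loaded calmodulin binds CaMKII;
  the complex autophosphorylates on Thr286 and phosphorylates AMPAR Ser831;
* the depression branch — partially loaded calmodulin binds calcineurin
  (PP2B), which dephosphorylates DARPP-32 Thr34; unphosphorylated DARPP-32
  releases its inhibition of PP1, which dephosphorylates both CaMKII-P and
  AMPAR-P.

PKA keeps DARPP-32 phosphorylated at rest, a Michaelis–Menten pump and a
constant leak set the resting calcium, and a zeroth-order influx process
(the coupling target) injects calcium mirroring the electrical model.

Units are M and s throughout; the coupling layer owns every ms<->s and
mM<->M conversion.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .constants import S_PER_MS


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Species:
    name: str
    concentration: float  # M
    #: moiety composition, e.g. {"CaM": 1, "Ca": 2}; used for conservation
    composition: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError(f"negative initial concentration for {self.name}")


@dataclass
class Reaction:
    """One elementary process.

    kinds:
      ``mass_action_bi``   A + B -> products, rate k*[A][B]
      ``mass_action_uni``  A -> products,     rate k*[A]
      ``michaelis_menten`` S -> P catalysed by a (possibly summed) enzyme
                           pool, rate kcat*E*S/(S+Km)
      ``constant_flux``    zeroth order production of one species
    """

    name: str
    kind: str
    reactants: list[str]
    products: list[str]
    rate: float = 0.0          # k, kcat or flux constant
    km: float | None = None    # michaelis_menten only
    enzymes: list[str] = field(default_factory=list)  # michaelis_menten only

    def __post_init__(self) -> None:
        if self.kind not in ("mass_action_bi", "mass_action_uni",
                             "michaelis_menten", "constant_flux"):
            raise ValueError(f"unknown reaction kind {self.kind!r}")
        if self.rate < 0 and self.kind != "constant_flux":
            raise ValueError(f"negative rate in {self.name}")
        if self.kind == "michaelis_menten" and (self.km is None or self.km <= 0):
            raise ValueError(f"michaelis_menten {self.name} needs Km > 0")


def mm_rate(kcat: float, km: float, enzyme: float, substrate: float) -> float:
    """Michaelis–Menten rate kcat*E*S/(S+Km) in M/s."""
    if km <= 0:
        raise ValueError("Km must be > 0")
    return kcat * enzyme * substrate / (substrate + km)


CONSERVED_MOIETIES = ("CaM", "CaMKII", "DARPP32", "PP1", "AMPAR")


class ReactionNetworkState:
    """Species vector + reaction set with a compiled ODE right-hand side."""

    def __init__(self, species: list[Species], reactions: list[Reaction],
                 rtol: float = 1e-8, atol: float = 1e-14) -> None:
        self.species = species
        self.reactions = reactions
        self.index = {s.name: i for i, s in enumerate(species)}
        if len(self.index) != len(species):
            raise ValueError("duplicate species names")
        self.x = np.array([s.concentration for s in species], dtype=float)
        self.time = 0.0  # s
        self.rtol = rtol
        self.atol = atol
        self.equilibrium: dict[str, float] = {}
        self._compile()
        self._audit_mass_balance()

    # -- compilation ------------------------------------------------------
    def _compile(self) -> None:
        n_s, n_r = len(self.species), len(self.reactions)
        self._stoich = np.zeros((n_s, n_r))
        self._kind: list[str] = []
        self._ridx: list[tuple] = []
        self._rate = np.zeros(n_r)
        self._km = np.zeros(n_r)
        for j, r in enumerate(self.reactions):
            for name in r.reactants:
                self._stoich[self.index[name], j] -= 1
            for name in r.products:
                self._stoich[self.index[name], j] += 1
            self._kind.append(r.kind)
            self._rate[j] = r.rate
            if r.kind == "mass_action_bi":
                a, b = (self.index[x] for x in r.reactants)
                self._ridx.append((a, b))
            elif r.kind == "mass_action_uni":
                self._ridx.append((self.index[r.reactants[0]],))
            elif r.kind == "michaelis_menten":
                self._km[j] = r.km
                self._ridx.append((self.index[r.reactants[0]],
                                   tuple(self.index[e] for e in r.enzymes)))
            else:  # constant_flux
                self._ridx.append((self.index[r.products[0]],))
        self._comp = np.zeros((len(CONSERVED_MOIETIES), n_s))
        for i, s in enumerate(self.species):
            for m, c in s.composition.items():
                if m in CONSERVED_MOIETIES:
                    self._comp[CONSERVED_MOIETIES.index(m), i] = c

    def _audit_mass_balance(self) -> None:
        imbalance = self._comp @ self._stoich
        if not np.allclose(imbalance, 0.0, atol=1e-12):
            bad = np.argwhere(np.abs(imbalance) > 1e-12)
            m, j = bad[0]
            raise ValueError(
                f"reaction {self.reactions[j].name!r} does not conserve "
                f"moiety {CONSERVED_MOIETIES[m]}")

    # -- dynamics ---------------------------------------------------------
    def rates(self, x: np.ndarray) -> np.ndarray:
        v = np.empty(len(self.reactions))
        for j, kind in enumerate(self._kind):
            if kind == "mass_action_bi":
                a, b = self._ridx[j]
                v[j] = self._rate[j] * x[a] * x[b]
            elif kind == "mass_action_uni":
                (a,) = self._ridx[j]
                v[j] = self._rate[j] * x[a]
            elif kind == "michaelis_menten":
                s, enz = self._ridx[j]
                # an empty enzyme list folds the enzyme into Vmax (the pump)
                e = sum(x[i] for i in enz) if enz else 1.0
                v[j] = self._rate[j] * e * x[s] / (x[s] + self._km[j])
            else:  # constant_flux
                (p,) = self._ridx[j]
                k = self._rate[j]
                if k >= 0:
                    v[j] = k
                else:
                    # soft floor at zero: the efflux shuts off smoothly as
                    # the species empties, keeping the RHS solver-friendly
                    xp = max(x[p], 0.0)
                    v[j] = k * xp / (xp + 1e-9)
        return v

    def rhs(self, t: float, x: np.ndarray) -> np.ndarray:
        return self._stoich @ self.rates(np.clip(x, 0.0, None))

    def advance(self, duration_s: float) -> None:
        if duration_s < 0:
            raise ValueError("cannot integrate backwards")
        if duration_s == 0:
            return
        sol = solve_ivp(self.rhs, (self.time, self.time + duration_s), self.x,
                        method="LSODA", rtol=self.rtol, atol=self.atol)
        if not sol.success:
            snapshot = {s.name: float(c) for s, c in zip(self.species, self.x)}
            raise RuntimeError(
                f"biochemical solver failed at t={self.time}s: {sol.message}; "
                f"species snapshot: {snapshot}")
        self.x = np.clip(sol.y[:, -1], 0.0, None)
        self.time += duration_s

    # -- accessors --------------------------------------------------------
    def conc(self, name: str) -> float:
        return float(self.x[self.index[name]])

    def set_conc(self, name: str, value: float) -> None:
        self.x[self.index[name]] = max(float(value), 0.0)

    def moiety_totals(self) -> dict[str, float]:
        totals = self._comp @ self.x
        return dict(zip(CONSERVED_MOIETIES, totals))

    def total_calcium(self) -> float:
        """Free plus protein-bound calcium, M."""
        return float(sum(s.composition.get("Ca", 0) * self.x[i]
                         for i, s in enumerate(self.species)))

    def set_calcium_influx(self, k_flux: float) -> None:
        """Set the zeroth-order calcium production constant (M/s).

        Negative values model net decline; the free-calcium floor at zero is
        enforced in the rate law.
        """
        j = next(i for i, r in enumerate(self.reactions)
                 if r.name == "ca_influx")
        self._rate[j] = float(k_flux)
        self.reactions[j].rate = float(k_flux)

    @property
    def calcium_influx(self) -> float:
        j = next(i for i, r in enumerate(self.reactions)
                 if r.name == "ca_influx")
        return float(self._rate[j])

    # -- export -----------------------------------------------------------
    def to_dict(self) -> dict:
        """Portable description: species, compositions, reactions, rates."""
        return {
            "species": [{"name": s.name, "concentration": float(x),
                         "composition": dict(s.composition)}
                        for s, x in zip(self.species, self.x)],
            "reactions": [{"name": r.name, "kind": r.kind,
                           "reactants": list(r.reactants),
                           "products": list(r.products),
                           "rate": float(self._rate[j]),
                           **({"km": r.km, "enzymes": list(r.enzymes)}
                              if r.kind == "michaelis_menten" else {})}
                          for j, r in enumerate(self.reactions)],
            "time_s": self.time,
        }

    def to_json(self, path) -> None:
        import json

        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    # -- graph audit ------------------------------------------------------
    def reaction_graph(self):
        """Bipartite species/reaction digraph for pathway audits."""
        import networkx as nx

        g = nx.DiGraph()
        for r in self.reactions:
            g.add_node(r.name, kind="reaction")
            for s in r.reactants:
                g.add_edge(s, r.name)
            for s in r.products:
                g.add_edge(r.name, s)
            for e in r.enzymes:
                g.add_edge(e, r.name, role="enzyme")
        return g


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------

def _require(params: dict, key: str):
    cur = params
    for part in key.split("."):
        if not isinstance(cur, dict) or part not in cur:
            raise KeyError(f"missing biochemical parameter {key!r}")
        cur = cur[part]
    return cur


def build_network(params: dict, rtol: float = 1e-8, atol: float = 1e-14,
                  ) -> ReactionNetworkState:
    """Assemble the plasticity network from a table-keyed parameter config.

    The calmodulin wiring is isolated here: ``options.cam_transitions``
    selects whether the R/T conformational change is allowed at every
    calcium occupancy (``"all"``, the MWC default) or only at the empty and
    fully loaded states (``"ends"``, the fully sequential alternative).
    ``options.can_binds`` sets which calcium occupancy of the R conformation
    calcineurin recognises (default 1, below CaMKII's requirement of 4 —
    this occupancy gap is what routes low calcium to the phosphatase branch
    and high calcium to the kinase branch).
    """
    t6 = _require(params, "table6")
    t7 = _require(params, "table7")
    t8 = _require(params, "table8")
    opts = params.get("options", {})
    transitions = opts.get("cam_transitions", "all")
    can_site = int(opts.get("can_binds", 1))
    if not 1 <= can_site <= 4:
        raise ValueError("options.can_binds must be in 1..4")

    kon = _require(t6, "kon")
    koff_T = _require(t6, "koff_T")
    koff_R = _require(t6, "koff_R")
    k_RT = _require(t6, "k_RT")
    k_TR = _require(t6, "k_TR")
    if not (len(koff_T) == len(koff_R) == 4 and len(k_RT) == len(k_TR) == 5):
        raise ValueError("table6 needs 4 per-step koff values per "
                         "conformation and 5 per-occupancy transition rates")

    sp: list[Species] = [
        Species("Ca", _require(t8, "Ca"), {"Ca": 1}),
        Species("CaN", _require(t8, "CaN"), {"CaN": 1}),
        Species("CaMKII", _require(t8, "CaMKII"), {"CaMKII": 1}),
        Species("PKA", _require(t8, "PKA"), {"PKA": 1}),
        Species("D32", _require(t8, "DARPP32"), {"DARPP32": 1}),
        Species("D32p", 0.0, {"DARPP32": 1}),
        Species("PP1", _require(t8, "PP1"), {"PP1": 1}),
        Species("AMPAR", _require(t8, "AMPAR"), {"AMPAR": 1}),
        Species("AMPARp", 0.0, {"AMPAR": 1}),
        Species("PKA_D32", 0.0, {"PKA": 1, "DARPP32": 1}),
        Species("D32p_PP1", 0.0, {"DARPP32": 1, "PP1": 1}),
    ]
    cam_total = _require(t8, "CaM")
    for conf in ("T", "R"):
        for i in range(5):
            sp.append(Species(f"CaM_{conf}{i}",
                              cam_total if (conf == "T" and i == 0) else 0.0,
                              {"CaM": 1, "Ca": i}))
    sp += [
        Species("CaM_CaN", 0.0, {"CaM": 1, "Ca": can_site, "CaN": 1}),
        Species("CaM_CaN_D32p", 0.0,
                {"CaM": 1, "Ca": can_site, "CaN": 1, "DARPP32": 1}),
        Species("CaM_CaMKII", 0.0, {"CaM": 1, "Ca": 4, "CaMKII": 1}),
        Species("CaM_CaMKIIp", 0.0, {"CaM": 1, "Ca": 4, "CaMKII": 1}),
        Species("PP1_CaM_CaMKIIp", 0.0,
                {"CaM": 1, "Ca": 4, "CaMKII": 1, "PP1": 1}),
    ]

    rx: list[Reaction] = []

    # (i) allosteric calmodulin: sequential binding in each conformation
    for conf, koff in (("T", koff_T), ("R", koff_R)):
        for i in range(4):
            # macroscopic on-rate carries the free-site statistical factor
            rx.append(Reaction(f"cam_{conf}{i}_bind", "mass_action_bi",
                               [f"CaM_{conf}{i}", "Ca"],
                               [f"CaM_{conf}{i + 1}"], rate=(4 - i) * kon))
            rx.append(Reaction(f"cam_{conf}{i + 1}_unbind", "mass_action_uni",
                               [f"CaM_{conf}{i + 1}"],
                               [f"CaM_{conf}{i}", "Ca"], rate=koff[i]))
    occs = range(5) if transitions == "all" else (0, 4)
    for i in occs:
        rx.append(Reaction(f"cam_R{i}_to_T{i}", "mass_action_uni",
                           [f"CaM_R{i}"], [f"CaM_T{i}"], rate=k_RT[i]))
        rx.append(Reaction(f"cam_T{i}_to_R{i}", "mass_action_uni",
                           [f"CaM_T{i}"], [f"CaM_R{i}"], rate=k_TR[i]))

    # (ii) calmodulin binding its targets
    rx.append(Reaction("can_bind", "mass_action_bi",
                       [f"CaM_R{can_site}", "CaN"], ["CaM_CaN"],
                       rate=_require(t7, "cam_can.kon")))
    rx.append(Reaction("can_unbind", "mass_action_uni",
                       ["CaM_CaN"], [f"CaM_R{can_site}", "CaN"],
                       rate=_require(t7, "cam_can.koff")))
    rx.append(Reaction("camkii_bind", "mass_action_bi",
                       ["CaM_R4", "CaMKII"], ["CaM_CaMKII"],
                       rate=_require(t7, "cam_camkii.kon")))
    rx.append(Reaction("camkii_unbind", "mass_action_uni",
                       ["CaM_CaMKII"], ["CaM_R4", "CaMKII"],
                       rate=_require(t7, "cam_camkii.koff")))

    # (iii) CaMKII Thr286 autophosphorylation, first order on the complex
    rx.append(Reaction("camkii_autop", "mass_action_uni",
                       ["CaM_CaMKII"], ["CaM_CaMKIIp"],
                       rate=_require(t7, "camkii_autop.kcat")))

    # (iv) PKA phosphorylates DARPP-32 Thr34
    rx.append(Reaction("pka_d32_bind", "mass_action_bi", ["PKA", "D32"],
                       ["PKA_D32"], rate=_require(t7, "pka_d32.kon")))
    rx.append(Reaction("pka_d32_unbind", "mass_action_uni", ["PKA_D32"],
                       ["PKA", "D32"], rate=_require(t7, "pka_d32.koff")))
    rx.append(Reaction("pka_d32_cat", "mass_action_uni", ["PKA_D32"],
                       ["PKA", "D32p"], rate=_require(t7, "pka_d32.kcat")))

    # (v) calcineurin dephosphorylates DARPP-32-P
    rx.append(Reaction("can_d32p_bind", "mass_action_bi",
                       ["CaM_CaN", "D32p"], ["CaM_CaN_D32p"],
                       rate=_require(t7, "can_d32p.kon")))
    rx.append(Reaction("can_d32p_unbind", "mass_action_uni",
                       ["CaM_CaN_D32p"], ["CaM_CaN", "D32p"],
                       rate=_require(t7, "can_d32p.koff")))
    rx.append(Reaction("can_d32p_cat", "mass_action_uni",
                       ["CaM_CaN_D32p"], ["CaM_CaN", "D32"],
                       rate=_require(t7, "can_d32p.kcat")))

    # (vi) DARPP-32-P inhibits PP1
    rx.append(Reaction("d32p_pp1_bind", "mass_action_bi", ["D32p", "PP1"],
                       ["D32p_PP1"], rate=_require(t7, "d32p_pp1.kon")))
    rx.append(Reaction("d32p_pp1_unbind", "mass_action_uni", ["D32p_PP1"],
                       ["D32p", "PP1"], rate=_require(t7, "d32p_pp1.koff")))

    # (vii) PP1 dephosphorylates CaMKII-P
    rx.append(Reaction("pp1_camkiip_bind", "mass_action_bi",
                       ["PP1", "CaM_CaMKIIp"], ["PP1_CaM_CaMKIIp"],
                       rate=_require(t7, "pp1_camkiip.kon")))
    rx.append(Reaction("pp1_camkiip_unbind", "mass_action_uni",
                       ["PP1_CaM_CaMKIIp"], ["PP1", "CaM_CaMKIIp"],
                       rate=_require(t7, "pp1_camkiip.koff")))
    rx.append(Reaction("pp1_camkiip_cat", "mass_action_uni",
                       ["PP1_CaM_CaMKIIp"], ["PP1", "CaM_CaMKII"],
                       rate=_require(t7, "pp1_camkiip.kcat")))

    # (viii) CaMKII.CaM phosphorylates AMPAR Ser831
    rx.append(Reaction("camkii_ampar", "michaelis_menten",
                       ["AMPAR"], ["AMPARp"],
                       rate=_require(t7, "camkii_ampar.kcat"),
                       km=_require(t7, "camkii_ampar.km"),
                       enzymes=["CaM_CaMKII", "CaM_CaMKIIp"]))

    # (ix) PP1 dephosphorylates AMPAR-P
    rx.append(Reaction("pp1_amparp", "michaelis_menten",
                       ["AMPARp"], ["AMPAR"],
                       rate=_require(t7, "pp1_amparp.kcat"),
                       km=_require(t7, "pp1_amparp.km"),
                       enzymes=["PP1"]))

    # (x) calcium pump, leak and the exchangeable influx
    rx.append(Reaction("ca_pump", "michaelis_menten", ["Ca"], [],
                       rate=_require(t7, "pump.vmax"),
                       km=_require(t7, "pump.km"), enzymes=[]))
    rx.append(Reaction("ca_leak", "constant_flux", [], ["Ca"],
                       rate=_require(t7, "leak.k")))
    rx.append(Reaction("ca_influx", "constant_flux", [], ["Ca"], rate=0.0))

    state = ReactionNetworkState(sp, rx, rtol=rtol, atol=atol)
    return state


# ---------------------------------------------------------------------------
# equilibration
# ---------------------------------------------------------------------------

def equilibrate(state: ReactionNetworkState, horizon: float = 5000.0,
                tol: float = 1e-6) -> ReactionNetworkState:
    """Integrate with zero influx until the network reaches its fixed point.

    Convergence is declared when the largest |dx/dt| relative to the species
    scale falls below ``tol`` (per second).  The equilibrium phospho-AMPAR
    concentration is stored as the weight normalization reference.
    """
    if state.calcium_influx != 0.0:
        raise ValueError("equilibrate requires zero calcium influx")
    floor = 1e-9 * max(state.x.max(), 1e-12)  # ignore truly empty species

    def rel_deriv() -> float:
        dx = state.rhs(state.time, state.x)
        return float(np.max(np.abs(dx) / np.maximum(np.abs(state.x), floor)))

    chunk = 50.0
    elapsed = 0.0
    converged = rel_deriv() < tol
    while not converged and elapsed < horizon:
        state.advance(min(chunk, horizon - elapsed))
        elapsed += chunk
        chunk = min(chunk * 2.0, 1000.0)
        converged = rel_deriv() < tol
    if not converged:
        warnings.warn(
            f"equilibrate did not converge within {horizon}s "
            f"(max per-species relative derivative {rel_deriv():.2e}/s)",
            RuntimeWarning)
    state.equilibrium = {s.name: float(c) for s, c in zip(state.species, state.x)}
    return state


# ---------------------------------------------------------------------------
# simulator handle
# ---------------------------------------------------------------------------

class BiochemicalSpine:
    """SimulatorHandle facade over one spine's reaction network (time in ms).

    With ``record_every`` set (ms), long steps are subdivided so traces are
    sampled at that cadence.
    """

    _RECORD_VARS = ("Ca", "Ca_total", "AMPAR_P", "active_CaMKII_frac",
                    "active_PP1_frac", "D32_P_frac")

    def __init__(self, state: ReactionNetworkState,
                 record_every: float | None = None) -> None:
        self.state = state
        self.current_time = 0.0  # ms
        self.record_every = record_every
        self._records: dict[str, list[float]] = {}
        if record_every is not None:
            self._record_now()

    def _record_now(self) -> None:
        self._records.setdefault("t", []).append(self.current_time)
        for var in self._RECORD_VARS:
            self._records.setdefault(var, []).append(self.get(var))

    @property
    def records(self):
        return {k: np.asarray(v) for k, v in self._records.items()}

    def step(self, to_time: float) -> None:
        if to_time < self.current_time - 1e-9:
            raise ValueError("step would move time backwards")
        if self.record_every is None:
            self.state.advance(max(to_time - self.current_time, 0.0) * S_PER_MS)
            self.current_time = to_time
            return
        while to_time - self.current_time > 1e-9:
            nxt = min(self.current_time + self.record_every, to_time)
            self.state.advance((nxt - self.current_time) * S_PER_MS)
            self.current_time = nxt
            self._record_now()

    def get(self, name: str) -> float:
        st = self.state
        if name == "AMPAR_P":
            return st.conc("AMPARp")
        if name == "Ca":
            return st.conc("Ca")
        if name == "Ca_total":
            return st.total_calcium()
        if name == "k_flux":
            return st.calcium_influx
        if name == "active_CaMKII_frac":
            tot = st.moiety_totals()["CaMKII"]
            act = (st.conc("CaM_CaMKII") + st.conc("CaM_CaMKIIp")
                   + st.conc("PP1_CaM_CaMKIIp"))
            return act / tot if tot > 0 else 0.0
        if name == "active_PP1_frac":
            tot = st.moiety_totals()["PP1"]
            return st.conc("PP1") / tot if tot > 0 else 0.0
        if name == "D32_P_frac":
            tot = st.moiety_totals()["DARPP32"]
            p = (st.conc("D32p") + st.conc("D32p_PP1")
                 + st.conc("CaM_CaN_D32p"))
            return p / tot if tot > 0 else 0.0
        raise KeyError(name)

    def set(self, name: str, value: float) -> None:
        if name == "k_flux":
            self.state.set_calcium_influx(value)
        elif name == "Ca":
            self.state.set_conc("Ca", value)
        else:
            raise KeyError(name)


class MultiSpineBiochem:
    """Composite slow handle: one reaction network per stimulated spine.

    Variables are namespaced ``<spine_id>.<name>``; ``step`` advances every
    instance to the same time.
    """

    def __init__(self, spines: dict[str, BiochemicalSpine]) -> None:
        if not spines:
            raise ValueError("need at least one biochemical spine")
        self.spines = spines
        times = {s.current_time for s in spines.values()}
        if len(times) != 1:
            raise ValueError("spine instances must start at the same time")
        self.current_time = times.pop()

    def step(self, to_time: float) -> None:
        for s in self.spines.values():
            s.step(to_time)
        self.current_time = to_time

    def _split(self, name: str) -> tuple[BiochemicalSpine, str]:
        sid, _, var = name.partition(".")
        if not var or sid not in self.spines:
            raise KeyError(name)
        return self.spines[sid], var

    def get(self, name: str) -> float:
        spine, var = self._split(name)
        return spine.get(var)

    def set(self, name: str, value: float) -> None:
        spine, var = self._split(name)
        spine.set(var, value)
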