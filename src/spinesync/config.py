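"""Configuration loading and model building.

Default channel, kinetic and morphology parameter sets ship with the
package as YAML keyed by the tables they implement; any entry can be
overridden by a user file of the same shape.
"""
from __future__ import annotations

import copy
from importlib import resources
from pathlib import Path

import yaml

from .channels import ChannelSpec, GateSpec, TauSpec
from .electrical import (CalciumShell, CompartmentSpec, ElectricalModel,
                         SpineRegistry, SynapseState)
from .morphology import CylinderSection, SpineGeometry, cylinder_area

_DATA = resources.files("spinesync") / "data"


def _load_yaml(name_or_path) -> dict:
    p = Path(name_or_path)
    if p.exists():
        with open(p) as fh:
            return yaml.safe_load(fh)
    with (_DATA / str(name_or_path)).open() as fh:
        return yaml.safe_load(fh)


def load_channel_config(path=None) -> dict:
    return _load_yaml(path or "channels.yaml")


def load_kinetics_config(path=None) -> dict:
    return _load_yaml(path or "kinetics.yaml")


def load_morphology_config(path=None) -> dict:
    return _load_yaml(path or "morphology.yaml")


def deep_update(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = deep_update(out[k], v)
        else:
            out[k] = v
    return out


# ---------------------------------------------------------------------------
# channel construction
# ---------------------------------------------------------------------------

def _tau_from_cfg(cfg) -> TauSpec:
    if isinstance(cfg, dict):
        return TauSpec(table_v=cfg["v"], table_tau=cfg["tau"])
    return TauSpec(value=float(cfg))


def _gate_from_cfg(cfg: dict) -> GateSpec:
    if cfg.get("ca_gated"):
        return GateSpec(ca_gated=True, ca_ec50=float(cfg["ca_ec50"]),
                        ca_hill=float(cfg["ca_hill"]),
                        tau=_tau_from_cfg(cfg["tau"]))
    return GateSpec(vh=float(cfg["vh"]), k=float(cfg["k"]),
                    tau=_tau_from_cfg(cfg["tau"]))


def channels_for_region(chan_cfg: dict, region: str,
                        gbar_scale: float = 1.0) -> list[ChannelSpec]:
    """Instantiate every channel the config places in a region."""
    erev_map = chan_cfg["erev"]
    out = []
    for entry in chan_cfg["channels"].values():
        gbar_map = entry.get("gbar", {})
        if region not in gbar_map:
            continue
        erev = entry["erev"]
        erev = erev_map[erev] if isinstance(erev, str) else float(erev)
        gates = entry.get("gates", {})
        out.append(ChannelSpec(
            name=entry.get("channel", "?"),
            gbar=float(gbar_map[region]) * gbar_scale,
            erev=erev,
            x=int(entry.get("x", 1)), y=int(entry.get("y", 0)),
            a=float(entry.get("a", 1.0)),
            m=_gate_from_cfg(gates["m"]) if "m" in gates else None,
            h=_gate_from_cfg(gates["h"]) if "h" in gates else None,
            is_calcium=bool(entry.get("is_calcium", False))))
    return out


# ---------------------------------------------------------------------------
# model building
# ---------------------------------------------------------------------------

def build_msn_model(morph_cfg: dict | None = None,
                    chan_cfg: dict | None = None,
                    n_spines: int = 1,
                    spine_branch: str | None = None,
                    dt: float | None = None,
                    record_every: float | None = 1.0,
                    passive_only: bool = False) -> ElectricalModel:
    """Build the reduced MSN with ``n_spines`` spines on one distal branch.

    ``passive_only`` zeroes every channel conductance, reducing the model
    to a passive cable (used by analytic oracle tests).
    """
    morph = morph_cfg or load_morphology_config()
    chans = chan_cfg or load_channel_config()
    pas = morph["passive"]
    scale = 0.0 if passive_only else 1.0

    def comp(name, sect, region, parent):
        return CompartmentSpec(
            name=name, diameter=float(sect["diameter"]),
            length=float(sect["length"]), parent=parent, region=region,
            ra=float(pas["ra"]), cm=float(pas["cm"]),
            g_pas=float(pas["g_pas"]), e_pas=float(pas["e_pas"]),
            channels=channels_for_region(chans, region, scale))

    comps = [comp("soma", morph["soma"], "soma", None)]
    n_dend = int(morph.get("n_dendrites", 1))
    for d in range(1, n_dend + 1):
        comps.append(comp(f"dend{d}_prox", morph["proximal"], "proximal", "soma"))
        comps.append(comp(f"dend{d}_med", morph["medial"], "medial",
                          f"dend{d}_prox"))
        comps.append(comp(f"dend{d}_dist1", morph["distal"], "distal",
                          f"dend{d}_med"))
        comps.append(comp(f"dend{d}_dist2", morph["distal"], "distal",
                          f"dend{d}_med"))

    branch = spine_branch or "dend1_dist1"
    spine_cfg = morph["spine"]
    geom = SpineGeometry(
        psd=CylinderSection(**spine_cfg["psd"]),
        head=CylinderSection(**spine_cfg["head"]),
        neck=CylinderSection(**spine_cfg["neck"]))
    syn_cfg = morph["synapse"]
    spines = []
    for i in range(n_spines):
        sid = f"spine{i}"
        for section, region, parent in (
                ("neck", "neck", branch),
                ("head", "head", f"{sid}_neck"),
                ("psd", "psd", f"{sid}_head")):
            sect = spine_cfg[section]
            comps.append(CompartmentSpec(
                name=f"{sid}_{section}", diameter=float(sect["diameter"]),
                length=float(sect["length"]), parent=parent, region=region,
                ra=float(pas["ra"]), cm=float(pas["cm"]),
                g_pas=float(pas["g_pas"]), e_pas=float(pas["e_pas"]),
                channels=channels_for_region(chans, region, scale),
                area_override=cylinder_area(float(sect["diameter"]),
                                            float(sect["length"]), caps=True)))
        spines.append(SpineRegistry(
            spine_id=sid, psd=f"{sid}_psd", head=f"{sid}_head",
            neck=f"{sid}_neck", geometry=geom,
            ampa=SynapseState("AMPA", **{k: float(v)
                                         for k, v in syn_cfg["ampa"].items()}),
            nmda=SynapseState("NMDA", **{k: float(v)
                                         for k, v in syn_cfg["nmda"].items()})))

    shell_cfg = morph["shell"]
    shell = CalciumShell(ca=float(shell_cfg["ca_inf"]),
                         depth_um=float(shell_cfg["depth_um"]),
                         vmax=float(shell_cfg["vmax"]),
                         km=float(shell_cfg["km"]),
                         tau_r=float(shell_cfg["tau_r"]),
                         ca_inf=float(shell_cfg["ca_inf"]),
                         buffer_ratio=float(shell_cfg.get("buffer_ratio", 1.0)))
    integ = morph.get("integration", {})
    return ElectricalModel(
        comps, spines,
        dt=float(dt if dt is not None else integ.get("dt", 0.025)),
        v_init=float(integ.get("v_init", -80.0)),
        shell_template=shell, record_every=record_every,
        syn_erev=float(syn_cfg.get("erev", 0.0)))
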