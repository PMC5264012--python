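"""YAML configuration schema (versioned ``schema: 1``) and loading.

A config file fully describes a run: initial geometry, the GRN (species,
Boolean gene logic in the textual DSL, reactions, secretion/transduction
rules, output nodes), mechanical and behavioural parameters, transport
parameters per diffusible ligand, initial conditions and scheduled events.
``apply_overrides`` implements dotted-path ``--set key=value`` overrides on
the raw dict before objects are built.
"""

from __future__ import annotations

import copy
from importlib import resources
from typing import Optional

import yaml

from .state_core import (BehaviourParams, DiffusibleParams, DivisionParams,
                         EpithelialPopulation, GeneDef, GRNSpec, BehaviourSpec,
                         MechanicsParams, MechanotransductionHook, OutputsSpec,
                         ReactionDef, SecretionDef, SimConfig, SpeciesDef,
                         TransductionDef, logic_from_str)


def load_config_dict(path) -> dict:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if not isinstance(d, dict):
        raise ValueError(f"config {path!r} did not parse to a mapping")
    if d.get("schema") != 1:
        raise ValueError(f"config {path!r}: unsupported schema {d.get('schema')!r}")
    return d


def load_bundled_config(name: str) -> dict:
    """Load a packaged scenario config (e.g. 'toggle_switch')."""
    ref = resources.files("morphosim.configs").joinpath(f"{name}.yaml")
    if not ref.is_file():
        raise KeyError(f"unknown scenario config {name!r}")
    d = yaml.safe_load(ref.read_text())
    if d.get("schema") != 1:
        raise ValueError(f"bundled config {name}: bad schema")
    return d


def _coerce(text: str):
    for cast in (int, float):
        try:
            return cast(text)
        except ValueError:
            pass
    low = text.lower()
    if low in ("true", "false"):
        return low == "true"
    if low in ("null", "none"):
        return None
    return text


def apply_overrides(config: dict, overrides) -> dict:
    """Apply dotted-path overrides, e.g. ``sim.seed=3`` or a {path: value} dict."""
    out = copy.deepcopy(config)
    if isinstance(overrides, dict):
        items = overrides.items()
    else:
        items = []
        for text in overrides or []:
            if "=" not in text:
                raise ValueError(f"override {text!r} is not of the form key=value")
            k, v = text.split("=", 1)
            items.append((k, _coerce(v)))
    for path, value in items:
        node = out
        parts = path.split(".")
        for p in parts[:-1]:
            if isinstance(node, list):
                node = node[int(p)]
            else:
                node = node.setdefault(p, {})
        if isinstance(node, list):
            node[int(parts[-1])] = value
        else:
            node[parts[-1]] = value
    return out


def grn_from_dict(d: dict) -> GRNSpec:
    species = [SpeciesDef(name=s["name"], kind=s.get("kind", "protein"),
                          degradation_rate=float(s.get("degradation_rate", 0.0)))
               for s in d.get("species", [])]
    genes = [GeneDef(name=g["name"], product_species=g.get("product", g["name"]),
                     logic=logic_from_str(g["logic"]),
                     production_rate=float(g.get("rate", 1.0)))
             for g in d.get("genes", [])]
    reactions = [ReactionDef(reactants=tuple(r["reactants"]),
                             product=r.get("product"),
                             rate=float(r["rate"]),
                             consume=tuple(r.get("consume", [True, True])))
                 for r in d.get("reactions", [])]
    secretions = [SecretionDef(protein=s["protein"], ligand=s["ligand"],
                               rate=float(s["rate"]), mode=s.get("mode", "diffusible"),
                               conversion=bool(s.get("conversion", True)))
                  for s in d.get("secretions", [])]
    transductions = [TransductionDef(ligand=t["ligand"], receptor=t["receptor"],
                                     messenger=t["messenger"], rate=float(t["rate"]),
                                     source=t.get("source", "local_field"),
                                     consume_ligand=bool(t.get("consume_ligand", False)))
                     for t in d.get("transductions", [])]
    od = d.get("outputs", {})
    pops = [EpithelialPopulation(name=p["name"], logic=logic_from_str(p["logic"]),
                                 guidance_ligand=p.get("guidance_ligand"),
                                 guidance_source=p.get("guidance_source",
                                                       "neighbour_surface"))
            for p in od.get("archetype_E", [])]
    bd = od.get("behaviour", {})
    outputs = OutputsSpec(
        archetype_M=logic_from_str(od.get("archetype_M", "never")),
        archetype_E=pops,
        behaviour=BehaviourSpec(
            protrusion_polarity=bd.get("protrusion_polarity", "bi"),
            phi=float(bd.get("phi", 0.0)),
            polarization_mode=bd.get("polarization_mode", "chemotactic"),
            guidance_ligand=bd.get("guidance_ligand")))
    return GRNSpec(species=species, genes=genes, reactions=reactions,
                   secretions=secretions, transductions=transductions,
                   outputs=outputs)


def sim_config_from_dict(d: dict) -> SimConfig:
    sim = d.get("sim", {})
    mech = d.get("mechanics", {})
    adh = mech.get("adhesion", {})
    beh = d.get("behaviour", {})
    div = d.get("division", {})
    mt = d.get("mechanotransduction", {})
    transport = {name: DiffusibleParams(
        D=float(p.get("D", 60.0)), gamma=float(p.get("gamma", 0.05)),
        clamp_body=p.get("clamp_body"), clamp_value=float(p.get("clamp_value", 0.0)))
        for name, p in (d.get("transport") or {}).items()}
    phi = beh.get("phi")
    return SimConfig(
        dt=float(sim.get("dt", 0.5)),
        duration=float(sim.get("duration", 60.0)),
        lam=float(sim.get("lambda", 1.0)),
        mechanics=MechanicsParams(
            k_rep=float(mech.get("k_rep", 2.0)),
            c_eq=float(mech.get("c_eq", 0.9)),
            c_max=float(mech.get("c_max", 1.3)),
            w={k: float(v) for k, v in (adh.get("pairs") or {}).items()},
            w_default=float(adh.get("default", 0.5)),
            k_plan=float(mech.get("k_plan", 1.0)),
            cone_half_angle=float(mech.get("cone_half_angle", 1.0))),
        behaviour=BehaviourParams(
            phi=None if phi is None else float(phi),
            protrusion_polarity=beh.get("protrusion_polarity"),
            lambda_ran=float(beh.get("lambda_ran", 0.0)),
            repolarization_period=float(beh.get("repolarization_period", 7.5))),
        division=DivisionParams(
            enabled=bool(div.get("enabled", False)),
            mean_cycle=float(div.get("mean_cycle", 268.0)),
            jitter=float(div.get("jitter", 0.2)),
            oriented=bool(div.get("oriented", False))),
        transport=transport,
        mechanotransduction=MechanotransductionHook(
            species=mt.get("species"), coefficient=float(mt.get("coefficient", 0.0))),
        seed=int(sim.get("seed", 0)),
        snapshot_every=float(sim.get("snapshot_every", 5.0)),
        genetics_substeps=int(sim.get("genetics_substeps", 5)),
        anchored_bodies=list(d.get("anchored_bodies", [])),
        init=list(d.get("init", [])),
        schedule=list(d.get("schedule", [])))


def build_from_dict(d: dict):
    """Return (geometry dict, SimConfig, GRNSpec) from a raw config dict."""
    return d.get("geometry", {}), sim_config_from_dict(d), grn_from_dict(d.get("grn", {}))
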