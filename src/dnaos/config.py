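"""YAML/JSON configuration loading and validation.

Recognised top-level keys::

    sequence:      {path, format}           # load a gene from file, or
    composition:   {seed, parts: [{length, at_count | at_fraction}, ...]}
    mechanics:     {bases: {A: {inertia, radius, torsion, k12}, ...},
                    beta: {A: ..., ...} | scalar}
    forcing:       {F0, omega}
    damping:       {beta}                   # scalar shortcut for all bases
    integration:   {dt, T}
    sampling:      {m}
    bond:          {EcrH | energies, kD}    # energies in 1e-22 N m
    substitution:  {site}
    plots:         bool

Unknown keys raise an error naming the key.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .dynamics import SimulationConfig
from .parameters import (
    BASES,
    DEFAULT_BASE_PARAMS,
    DEFAULT_BETA,
    ENERGY_UNIT,
    MechanicalParameterSet,
)
from .sequence import CompositionSpec, PartComposition

_TOP_KEYS = {
    "sequence",
    "composition",
    "mechanics",
    "forcing",
    "damping",
    "integration",
    "sampling",
    "bond",
    "substitution",
    "plots",
}


def load_config(path: "str | Path") -> dict:
    """Load and validate a YAML or JSON configuration file."""
    path = Path(path)
    text = path.read_text()
    cfg = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if cfg is None:
        cfg = {}
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict) -> None:
    unknown = set(cfg) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown configuration key(s): {sorted(unknown)}")


def build_composition(cfg: dict) -> CompositionSpec:
    comp = cfg.get("composition")
    if comp is None:
        return CompositionSpec.ifna17_like(seed=0)
    parts = []
    for p in comp["parts"]:
        parts.append(
            PartComposition(
                length=int(p["length"]),
                at_count=p.get("at_count"),
                at_fraction=p.get("at_fraction"),
            )
        )
    if len(parts) != 3:
        raise ValueError(f"composition needs exactly 3 parts, got {len(parts)}")
    return CompositionSpec(parts=tuple(parts), seed=int(comp.get("seed", 0)))


def build_mechanics(cfg: dict) -> MechanicalParameterSet:
    mech = cfg.get("mechanics", {})
    base_params = {b: dict(DEFAULT_BASE_PARAMS[b]) for b in BASES}
    for b, overrides in mech.get("bases", {}).items():
        base_params[b].update(overrides)
    beta_cfg = mech.get("beta", cfg.get("damping", {}).get("beta", DEFAULT_BETA))
    if isinstance(beta_cfg, dict):
        beta = {b: float(beta_cfg.get(b, DEFAULT_BETA)) for b in BASES}
    else:
        beta = {b: float(beta_cfg) for b in BASES}
    kD = float(cfg.get("bond", {}).get("kD", 1.05))
    return MechanicalParameterSet(base_params=base_params, beta=beta, kD=kD)


def build_simulation_config(cfg: dict) -> tuple[SimulationConfig, list[float]]:
    """SimulationConfig plus the critical-energy grid in joules."""
    forcing = cfg.get("forcing", {})
    integ = cfg.get("integration", {})
    bond = cfg.get("bond", {})
    energies = bond.get("energies")
    if energies is None:
        energies = [bond.get("EcrH", 0.581)]
    energies_si = [float(e) * ENERGY_UNIT for e in energies]
    sim = SimulationConfig(
        F0=float(forcing.get("F0", 0.526e-22)),
        omega=float(forcing.get("omega", 0.4e12)),
        T=float(integ.get("T", 3.0e-10)),
        dt=float(integ.get("dt", 1.0e-14)),
        m=int(cfg.get("sampling", {}).get("m", 1000)),
        EcrH=energies_si[0],
        kD=float(bond.get("kD", 1.05)),
        substitution_site=cfg.get("substitution", {}).get("site"),
    )
    return sim, energies_si
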