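"""Controlled vocabularies of signals and behaviors.

Signals are quantities a cell can sense — substrate concentrations and
gradients, mechanical pressure, contact counts, damage, live/dead
status, simulation time. Behaviors are the controllable phenotype
parameters — cycle entry, death rates, secretion/uptake, motility,
mechanics, cell-type transformations, phagocytosis, and effector
attack. Both vocabularies are parameterized by the simulation's
declared substrates and cell types, so compound names like
"contact with fibroblast" or "debris secretion" resolve by suffix.

Units convention: minutes, microns, mmHg for oxygen, arbitrary
concentration units for immuno-factors; all rates per minute.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "SignalSpec",
    "BehaviorSpec",
    "SignalDictionary",
    "BehaviorDictionary",
    "build_dictionaries",
    "get_signal_value",
    "set_behavior",
    "UnsupportedSignalError",
]


class UnsupportedSignalError(RuntimeError):
    """Raised for registered signals with no evaluation in this build."""


@dataclass(frozen=True)
class SignalSpec:
    """A resolvable signal: name, category, target (substrate/cell type), units."""

    name: str
    category: str
    units: str = "dimensionless"
    target: Optional[str] = None  # substrate or cell-type a parameterized signal refers to


@dataclass(frozen=True)
class BehaviorSpec:
    """A resolvable behavior: name, category, target, units, and value bounds."""

    name: str
    category: str
    units: str = "dimensionless"
    target: Optional[str] = None
    bounds: tuple = (0.0, float("inf"))


_SUBSTRATE_UNITS = {"oxygen": "mmHg"}


def _substrate_units(name: str) -> str:
    return _SUBSTRATE_UNITS.get(name, "a.u.")


class SignalDictionary:
    """Signals resolvable for a given set of substrates and cell types."""

    def __init__(self, substrates: Sequence[str], cell_types: Sequence[str]):
        self.substrates = list(substrates)
        self.cell_types = list(cell_types)
        self._fixed: dict[str, SignalSpec] = {}
        for sub in self.substrates:
            u = _substrate_units(sub)
            self._register(SignalSpec(sub, "substrate", u))
            self._register(SignalSpec(f"{sub} gradient", "substrate_gradient", f"{u}/um",
                                      target=sub))
            self._register(SignalSpec(f"internalized {sub}", "internalized_substrate", u,
                                      target=sub))
        for ct in self.cell_types:
            self._register(SignalSpec(f"contact with {ct}", "contact_type", "cells",
                                      target=ct))
        self._register(SignalSpec("contact with live cell", "contact_live", "cells"))
        self._register(SignalSpec("contact with dead cell", "contact_dead", "cells"))
        self._register(SignalSpec("contact with basement membrane", "contact_membrane",
                                  "boolean"))
        self._register(SignalSpec("pressure", "pressure"))
        self._register(SignalSpec("volume", "volume", "um^3"))
        self._register(SignalSpec("damage", "damage", "damage units"))
        self._register(SignalSpec("attack time", "attack_time", "min"))
        self._register(SignalSpec("dead", "dead", "boolean"))
        self._register(SignalSpec("time", "time", "min"))

    def _register(self, spec: SignalSpec) -> None:
        if spec.name in self._fixed:
            raise ValueError(f"duplicate signal name {spec.name!r}")
        self._fixed[spec.name] = spec

    def resolve(self, name: str) -> SignalSpec:
        if name in self._fixed:
            return self._fixed[name]
        if name.startswith("custom:"):
            return SignalSpec(name, "custom")
        raise KeyError(
            f"unknown signal {name!r}: not a declared substrate, contact, or "
            f"built-in signal"
        )

    def names(self) -> list[str]:
        return sorted(self._fixed)


class BehaviorDictionary:
    """Behaviors resolvable for a given set of substrates and cell types."""

    def __init__(self, substrates: Sequence[str], cell_types: Sequence[str]):
        self.substrates = list(substrates)
        self.cell_types = list(cell_types)
        self._fixed: dict[str, BehaviorSpec] = {}
        reg = self._register
        reg(BehaviorSpec("cycle entry", "cycle_entry", "1/min"))
        reg(BehaviorSpec("apoptosis", "apoptosis", "1/min"))
        reg(BehaviorSpec("necrosis", "necrosis", "1/min"))
        for sub in self.substrates:
            u = _substrate_units(sub)
            reg(BehaviorSpec(f"{sub} secretion", "secretion_rate", "1/min", target=sub))
            reg(BehaviorSpec(f"{sub} secretion target", "secretion_target", u, target=sub))
            reg(BehaviorSpec(f"{sub} uptake", "uptake_rate", "1/min", target=sub))
            reg(BehaviorSpec(f"{sub} export", "net_export", f"{u} um^3/min", target=sub,
                             bounds=(-float("inf"), float("inf"))))
            reg(BehaviorSpec(f"chemotactic response to {sub}", "chemotactic_sensitivity",
                             "dimensionless", target=sub,
                             bounds=(-float("inf"), float("inf"))))
        reg(BehaviorSpec("migration speed", "migration_speed", "um/min"))
        reg(BehaviorSpec("migration bias", "migration_bias", "dimensionless",
                         bounds=(0.0, 1.0)))
        reg(BehaviorSpec("migration persistence time", "persistence_time", "min"))
        reg(BehaviorSpec("cell-cell adhesion", "adhesion", "um/min"))
        reg(BehaviorSpec("cell-cell repulsion", "repulsion", "um/min"))
        reg(BehaviorSpec("cell attachment rate", "attachment_rate", "1/min"))
        reg(BehaviorSpec("cell detachment rate", "detachment_rate", "1/min"))
        reg(BehaviorSpec("maximum number of attachments", "max_attachments", "cells"))
        for ct in self.cell_types:
            reg(BehaviorSpec(f"adhesive affinity to {ct}", "adhesion_affinity",
                             "dimensionless", target=ct))
            reg(BehaviorSpec(f"transform to {ct}", "transformation_to_type", "1/min",
                             target=ct))
            reg(BehaviorSpec(f"fuse to {ct}", "fusion_to_type", "1/min", target=ct))
            reg(BehaviorSpec(f"phagocytose {ct}", "phagocytose_type", "1/min", target=ct))
            reg(BehaviorSpec(f"attack {ct}", "attack_type", "1/min", target=ct))
            reg(BehaviorSpec(f"immunogenicity to {ct}", "immunogenicity_to_type",
                             "dimensionless", target=ct))
        reg(BehaviorSpec("phagocytose dead cell", "phagocytose_dead", "1/min"))
        reg(BehaviorSpec("damage rate", "damage_rate", "damage units/min"))

    def _register(self, spec: BehaviorSpec) -> None:
        if spec.name in self._fixed:
            raise ValueError(f"duplicate behavior name {spec.name!r}")
        self._fixed[spec.name] = spec

    def resolve(self, name: str) -> BehaviorSpec:
        if name in self._fixed:
            return self._fixed[name]
        if name.startswith("custom:"):
            return BehaviorSpec(name, "custom",
                                bounds=(-float("inf"), float("inf")))
        if name.startswith("exit from cycle phase "):
            # Multi-phase cycle models are registered but not exercised here.
            return BehaviorSpec(name, "exit_rate_phase_k", "1/min")
        raise KeyError(
            f"unknown behavior {name!r}: not a dictionary behavior for the "
            f"declared substrates and cell types"
        )

    def names(self) -> list[str]:
        return sorted(self._fixed)


def build_dictionaries(substrates: Sequence[str], cell_types: Sequence[str]):
    """Convenience constructor returning (SignalDictionary, BehaviorDictionary)."""
    return SignalDictionary(substrates, cell_types), BehaviorDictionary(substrates, cell_types)


# ---------------------------------------------------------------------------
# signal evaluation and behavior application (per-agent path)

def contact_pressure(agent, neighbors) -> float:
    """Dimensionless crowding scalar: sum over overlapping neighbors of
    (1 - d_ij/(R_i+R_j))^2, divided by the reference simple-pressure
    scale so confluent packing reads as order-one pressure."""
    from .agents import SIMPLE_PRESSURE_SCALE

    p = 0.0
    for other in neighbors:
        if other is agent:
            continue
        d = float(np.linalg.norm(np.asarray(agent.position) - np.asarray(other.position)))
        s = agent.radius + other.radius
        if d < s:
            p += (1.0 - d / s) ** 2
    return p / SIMPLE_PRESSURE_SCALE


def _in_contact(agent, other) -> bool:
    d = float(np.linalg.norm(np.asarray(agent.position) - np.asarray(other.position)))
    return d < (agent.radius + other.radius)


def get_signal_value(agent, env, neighbors, spec: SignalSpec, now: float = 0.0) -> float:
    """Evaluate one signal for one agent. Side-effect-free.

    ``neighbors`` is the agent's candidate contact list (any iterable of
    agents; non-contacting entries are filtered here).
    """
    cat = spec.category
    if cat == "substrate":
        return float(env.sample(agent.position)[spec.name])
    if cat == "substrate_gradient":
        g = env.gradient(agent.position)[spec.target]
        return float(np.linalg.norm(g))
    if cat == "internalized_substrate":
        return float(getattr(agent, "internalized", {}).get(spec.target, 0.0))
    if cat == "contact_type":
        return float(sum(1 for o in neighbors if o is not agent
                         and o.type_name == spec.target and o.state == "live"
                         and _in_contact(agent, o)))
    if cat == "contact_live":
        return float(sum(1 for o in neighbors if o is not agent
                         and o.state == "live" and _in_contact(agent, o)))
    if cat == "contact_dead":
        return float(sum(1 for o in neighbors if o is not agent
                         and o.state != "live" and _in_contact(agent, o)))
    if cat == "contact_membrane":
        raise UnsupportedSignalError(
            "basement-membrane contact is registered but unsupported in this build"
        )
    if cat == "pressure":
        return contact_pressure(agent, neighbors)
    if cat == "volume":
        return float(agent.volume)
    if cat == "damage":
        return float(agent.damage)
    if cat == "attack_time":
        return float(agent.attack_time)
    if cat == "dead":
        return 0.0 if agent.state == "live" else 1.0
    if cat == "time":
        return float(now)
    if cat == "custom":
        return float(getattr(agent, "custom", {}).get(spec.name, 0.0))
    raise KeyError(f"no evaluation for signal category {cat!r}")


def set_behavior(agent, spec: BehaviorSpec, value: float) -> None:
    """Write one behavior parameter onto the agent's working phenotype.

    Rates are clamped at 0 from below; bounded behaviors (migration
    bias) are clamped into their declared bounds.
    """
    lo, hi = spec.bounds
    agent.set_phenotype(spec.name, float(min(max(value, lo), hi)))
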