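"""Off-lattice cell agents: phenotype, mechanics, motility, interactions.

Cells are simulated as lattice-free 2-D agents with volume, live/dead
state, accumulated damage, and a working phenotype (a copy of their
type's base parameters, overwritten by the behavior rules at every
phenotype step). Stochastic events — division, death, type
transformation, phagocytosis, attack initiation — fire with probability
1 - exp(-rate*dt) per step, exact for a Poisson process.

Storage is struct-of-arrays (:class:`Population`) for vectorized
mechanics and rule evaluation; :class:`CellAgent` is a lightweight
per-cell proxy exposing the agent-level API.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "CellDefinition",
    "CellAgent",
    "Population",
    "MechanicsParams",
    "DeathParams",
    "event_probability",
    "divide",
    "transform",
    "phagocytose",
    "progress_death",
    "update_motility",
    "update_mechanics",
    "run_attack",
    "advance_phenotype",
]

STATE_LIVE, STATE_APOPTOTIC, STATE_NECROTIC = 0, 1, 2
_STATE_NAMES = {STATE_LIVE: "live", STATE_APOPTOTIC: "apoptotic", STATE_NECROTIC: "necrotic"}
_STATE_CODES = {v: k for k, v in _STATE_NAMES.items()}

#: Base phenotype values every cell definition starts from (per minute,
#: micron units). Anything not listed defaults to 0.
DEFAULT_BEHAVIORS = {
    "cycle entry": 0.0,
    "apoptosis": 0.0,
    "necrosis": 0.0,
    "migration speed": 0.0,
    "migration bias": 0.0,
    "migration persistence time": 1.0,
    "cell-cell adhesion": 0.4,
    "cell-cell repulsion": 10.0,
    "damage rate": 1.0,
    "phagocytose dead cell": 0.0,
}

#: Default 2-D cell volume (um^3), radius ~8.4 um.
DEFAULT_VOLUME = 2494.0

#: Simple-pressure normalization (reference-framework convention): the
#: raw crowding sum over overlapping neighbors of (1 - d/(R_i+R_j))^2 is
#: divided by this scale so that confluent packing reads as order-one
#: pressure, the scale on which rule half-maxes (0.25-1) are written.
SIMPLE_PRESSURE_SCALE = 0.027288820670331


def event_probability(rate, dt: float):
    """Probability that a Poisson event of the given rate fires within dt."""
    return 1.0 - np.exp(-np.asarray(rate, dtype=float) * dt)


@dataclass
class MechanicsParams:
    """Pairwise force-law constants (reference-framework polynomial potentials)."""

    adhesion_distance_multiplier: float = 1.25
    drag: float = 1.0  # overdamped: velocity = force / drag


@dataclass
class DeathParams:
    """Dead-cell volume dynamics and removal."""

    apoptotic_volume_halflife: float = 8.6   # min
    apoptotic_removal_fraction: float = 0.05  # of volume at death
    necrotic_persistence: float = 1440.0      # min until removal
    volume_relaxation_rate: float = 0.0045    # 1/min toward target volume (live cells)


@dataclass
class CellDefinition:
    """Named cell type: target volume plus base phenotype parameter values.

    ``behaviors`` maps canonical behavior names (grammar vocabulary,
    e.g. "cycle entry", "oxygen uptake", "transform to tumor") to base
    values; anything unspecified falls back to :data:`DEFAULT_BEHAVIORS`
    or 0.
    """

    name: str
    volume: float = DEFAULT_VOLUME
    behaviors: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise ValueError(f"cell volume must be positive, got {self.volume}")
        for key, val in self.behaviors.items():
            if key not in ("migration bias",) and not key.startswith("chemotactic") \
                    and val < 0 and not key.endswith("export"):
                raise ValueError(f"{self.name}: rate {key!r} must be >= 0, got {val}")

    def base_value(self, key: str, default: float = None) -> float:
        if key in self.behaviors:
            return float(self.behaviors[key])
        if default is not None:
            return default
        return float(DEFAULT_BEHAVIORS.get(key, 0.0))


def radius_from_volume(volume):
    """Equivalent-sphere radius r = (3V / 4 pi)^(1/3)."""
    return (3.0 * np.asarray(volume, dtype=float) / (4.0 * np.pi)) ** (1.0 / 3.0)


class Population:
    """Struct-of-arrays store for all agents of one simulation.

    Slots are never reused; removed agents are deactivated in place so
    :class:`CellAgent` proxies stay valid.
    """

    def __init__(self, definitions: Sequence[CellDefinition],
                 behavior_keys: Optional[Sequence[str]] = None,
                 capacity: int = 256):
        self.definitions = list(definitions)
        self.type_index = {d.name: i for i, d in enumerate(self.definitions)}
        if len(self.type_index) != len(self.definitions):
            raise ValueError("duplicate cell definition names")
        if behavior_keys is None:
            keys = dict.fromkeys(DEFAULT_BEHAVIORS)
            for d in self.definitions:
                keys.update(dict.fromkeys(d.behaviors))
            behavior_keys = list(keys)
        self.behavior_keys = list(behavior_keys)
        self.key_index = {k: i for i, k in enumerate(self.behavior_keys)}
        self.base_table = np.zeros((len(self.definitions), len(self.behavior_keys)))
        for t, d in enumerate(self.definitions):
            for k, col in self.key_index.items():
                self.base_table[t, col] = d.base_value(k)
        self.n = 0
        self._next_id = 0
        self._alloc(capacity)
        # census bookkeeping
        self.births = 0
        self.removed = 0
        self.phagocytosed = 0

    def _alloc(self, cap: int) -> None:
        self.capacity = cap
        self.pos = np.zeros((cap, 2))
        self.volume = np.zeros(cap)
        self.target_volume = np.zeros(cap)
        self.original_volume = np.zeros(cap)
        self.damage = np.zeros(cap)
        self.attack_time = np.zeros(cap)
        self.death_clock = np.zeros(cap)
        self.pressure = np.zeros(cap)
        self.state = np.zeros(cap, dtype=np.int8)
        self.type_idx = np.zeros(cap, dtype=np.int32)
        self.id = np.zeros(cap, dtype=np.int64)
        self.attack_target = np.full(cap, -1, dtype=np.int64)  # slot index, -1 = none
        self.motility_dir = np.zeros((cap, 2))
        self.active = np.zeros(cap, dtype=bool)
        self.phenotype = np.zeros((cap, len(self.behavior_keys)))

    def _grow(self) -> None:
        old = self.__dict__.copy()
        cap = self.capacity * 2
        self._alloc(cap)
        for name in ("pos", "volume", "target_volume", "original_volume", "damage",
                     "attack_time", "death_clock", "pressure", "state", "type_idx",
                     "id", "attack_target", "motility_dir", "active", "phenotype"):
            getattr(self, name)[: self.n] = old[name][: self.n]

    def add(self, type_name: str, position, volume: Optional[float] = None) -> "CellAgent":
        if type_name not in self.type_index:
            raise KeyError(f"unknown cell type {type_name!r}")
        if self.n >= self.capacity:
            self._grow()
        i = self.n
        self.n += 1
        t = self.type_index[type_name]
        d = self.definitions[t]
        self.type_idx[i] = t
        self.pos[i] = np.asarray(position, dtype=float)[:2]
        self.volume[i] = d.volume if volume is None else float(volume)
        self.target_volume[i] = d.volume
        self.original_volume[i] = self.volume[i]
        self.id[i] = self._next_id
        self._next_id += 1
        self.attack_target[i] = -1
        self.state[i] = STATE_LIVE
        self.active[i] = True
        self.phenotype[i] = self.base_table[t]
        return CellAgent(self, i)

    def remove(self, agent_or_slot, *, phagocytosed: bool = False) -> None:
        i = agent_or_slot._slot if isinstance(agent_or_slot, CellAgent) else agent_or_slot
        if not self.active[i]:
            return
        self.active[i] = False
        if phagocytosed:
            self.phagocytosed += 1
        else:
            self.removed += 1

    def active_slots(self) -> np.ndarray:
        return np.flatnonzero(self.active[: self.n])

    def agents(self) -> list["CellAgent"]:
        return [CellAgent(self, int(i)) for i in self.active_slots()]

    def __len__(self) -> int:
        return int(self.active[: self.n].sum())

    def radius(self, slots=None) -> np.ndarray:
        v = self.volume[: self.n] if slots is None else self.volume[slots]
        return radius_from_volume(v)

    def definition_of(self, slot: int) -> CellDefinition:
        return self.definitions[self.type_idx[slot]]

    def counts(self) -> dict:
        """Live/dead census per cell type."""
        out = {}
        idx = self.active_slots()
        for t, d in enumerate(self.definitions):
            mine = idx[self.type_idx[idx] == t]
            live = int((self.state[mine] == STATE_LIVE).sum())
            out[d.name] = {"live": live, "dead": len(mine) - live}
        return out


class CellAgent:
    """Per-cell view into a :class:`Population` slot."""

    __slots__ = ("_pop", "_slot")

    def __init__(self, pop: Population, slot: int):
        self._pop = pop
        self._slot = slot

    def __eq__(self, other) -> bool:
        return (isinstance(other, CellAgent) and other._pop is self._pop
                and other._slot == self._slot)

    def __hash__(self) -> int:
        return hash((id(self._pop), self._slot))

    def __repr__(self) -> str:
        return (f"CellAgent(id={self.id}, type={self.type_name!r}, "
                f"state={self.state!r}, pos={self.position.round(2).tolist()})")

    # identity -------------------------------------------------------------
    @property
    def id(self) -> int:
        return int(self._pop.id[self._slot])

    @property
    def type_name(self) -> str:
        return self._pop.definitions[self._pop.type_idx[self._slot]].name

    @property
    def definition(self) -> CellDefinition:
        return self._pop.definition_of(self._slot)

    @property
    def alive_in_population(self) -> bool:
        return bool(self._pop.active[self._slot])

    # geometry -------------------------------------------------------------
    @property
    def position(self) -> np.ndarray:
        return self._pop.pos[self._slot]

    @position.setter
    def position(self, value) -> None:
        self._pop.pos[self._slot] = np.asarray(value, dtype=float)[:2]

    @property
    def volume(self) -> float:
        return float(self._pop.volume[self._slot])

    @volume.setter
    def volume(self, value: float) -> None:
        if value <= 0:
            raise ValueError("volume must be positive")
        self._pop.volume[self._slot] = value

    @property
    def radius(self) -> float:
        return float(radius_from_volume(self.volume))

    # state ----------------------------------------------------------------
    @property
    def state(self) -> str:
        return _STATE_NAMES[int(self._pop.state[self._slot])]

    @state.setter
    def state(self, value: str) -> None:
        self._pop.state[self._slot] = _STATE_CODES[value]
        if value != "live":
            self._pop.death_clock[self._slot] = 0.0
            self._pop.original_volume[self._slot] = self.volume
            self._pop.attack_target[self._slot] = -1

    @property
    def is_dead(self) -> bool:
        return self._pop.state[self._slot] != STATE_LIVE

    @property
    def damage(self) -> float:
        return float(self._pop.damage[self._slot])

    @damage.setter
    def damage(self, value: float) -> None:
        self._pop.damage[self._slot] = value

    @property
    def attack_time(self) -> float:
        return float(self._pop.attack_time[self._slot])

    @attack_time.setter
    def attack_time(self, value: float) -> None:
        self._pop.attack_time[self._slot] = value

    @property
    def attack_target(self) -> Optional["CellAgent"]:
        t = int(self._pop.attack_target[self._slot])
        return None if t < 0 else CellAgent(self._pop, t)

    @attack_target.setter
    def attack_target(self, target) -> None:
        self._pop.attack_target[self._slot] = -1 if target is None else target._slot

    @property
    def motility_direction(self) -> np.ndarray:
        return self._pop.motility_dir[self._slot]

    @motility_direction.setter
    def motility_direction(self, value) -> None:
        self._pop.motility_dir[self._slot] = np.asarray(value, dtype=float)[:2]

    # phenotype ------------------------------------------------------------
    def get_phenotype(self, key: str, default: Optional[float] = None) -> float:
        col = self._pop.key_index.get(key)
        if col is None:
            if key in self.definition.behaviors:
                return float(self.definition.behaviors[key])
            if default is not None:
                return default
            return self.definition.base_value(key)
        return float(self._pop.phenotype[self._slot, col])

    def set_phenotype(self, key: str, value: float) -> None:
        col = self._pop.key_index.get(key)
        if col is None:
            raise KeyError(f"behavior {key!r} has no phenotype column")
        self._pop.phenotype[self._slot, col] = value

    def reset_phenotype(self) -> None:
        self._pop.phenotype[self._slot] = self._pop.base_table[self._pop.type_idx[self._slot]]


# ---------------------------------------------------------------------------
# per-agent operations

def divide(agent: CellAgent, rng: np.random.Generator) -> tuple[CellAgent, CellAgent]:
    """Split an agent into two half-volume cells.

    The daughter is placed one parent radius away in a uniform random
    direction, inherits the type, and starts with zero damage. Volume is
    conserved across the division.
    """
    if agent.is_dead:
        raise ValueError("dead agents do not divide")
    pop = agent._pop
    r = agent.radius
    theta = rng.uniform(0.0, 2.0 * np.pi)
    offset = r * np.array([np.cos(theta), np.sin(theta)])
    half = agent.volume / 2.0
    agent.volume = half
    daughter = pop.add(agent.type_name, agent.position + offset, volume=half)
    pop.births += 1
    return agent, daughter


def transform(agent: CellAgent, new_type: str, definitions=None) -> CellAgent:
    """Change the agent's cell type in place (position/volume/damage kept)."""
    pop = agent._pop
    if new_type not in pop.type_index:
        raise KeyError(f"unknown cell type {new_type!r}")
    if new_type == agent.type_name:
        return agent
    t = pop.type_index[new_type]
    pop.type_idx[agent._slot] = t
    pop.target_volume[agent._slot] = pop.definitions[t].volume
    agent.reset_phenotype()
    return agent


def phagocytose(predator: CellAgent, prey: CellAgent) -> CellAgent:
    """Predator ingests prey: prey removed, predator gains its volume."""
    predator.volume = predator.volume + prey.volume
    predator._pop.remove(prey, phagocytosed=True)
    return predator


def progress_death(agent: CellAgent, dt: float,
                   params: DeathParams = DeathParams()) -> bool:
    """Advance dead-cell volume dynamics; returns True if removed.

    Apoptotic cells shrink exponentially and are removed below 5% of
    their volume at death; necrotic cells persist for a fixed duration.
    """
    pop = agent._pop
    i = agent._slot
    if pop.state[i] == STATE_LIVE:
        return False
    pop.death_clock[i] += dt
    if pop.state[i] == STATE_APOPTOTIC:
        pop.volume[i] *= math.exp(-math.log(2.0) / params.apoptotic_volume_halflife * dt)
        if pop.volume[i] < params.apoptotic_removal_fraction * pop.original_volume[i]:
            pop.remove(i)
            return True
    elif pop.death_clock[i] >= params.necrotic_persistence:
        pop.remove(i)
        return True
    return False


def update_motility(agent: CellAgent, env, dt: float, rng: np.random.Generator) -> np.ndarray:
    """Biased-random-walk motility for one agent; returns the displacement.

    With probability dt/persistence the direction is re-drawn as
    normalize(bias * chemotactic_direction + (1-bias) * random unit
    vector), where the chemotactic direction is the normalized
    sensitivity-weighted sum of substrate gradients.
    """
    if agent.is_dead:
        return np.zeros(2)
    speed = agent.get_phenotype("migration speed")
    tau = max(agent.get_phenotype("migration persistence time"), 1e-9)
    bias = agent.get_phenotype("migration bias")
    if rng.random() < min(dt / tau, 1.0):
        chemo = np.zeros(2)
        if env is not None:
            grads = env.gradient(agent.position)
            for name in env.substrates:
                s = agent.get_phenotype(f"chemotactic response to {name}", 0.0)
                if s != 0.0:
                    chemo += s * grads[name]
        norm = np.linalg.norm(chemo)
        if norm > 0:
            chemo /= norm
        phi = rng.uniform(0.0, 2.0 * np.pi)
        rand_dir = np.array([np.cos(phi), np.sin(phi)])
        direction = bias * chemo + (1.0 - bias) * rand_dir
        norm = np.linalg.norm(direction)
        agent.motility_direction = direction / norm if norm > 0 else np.zeros(2)
    disp = speed * agent.motility_direction * dt
    agent.position = agent.position + disp
    return disp


def pairwise_forces(pos: np.ndarray, radius: np.ndarray, adhesion: np.ndarray,
                    repulsion: np.ndarray, affinity: Optional[np.ndarray] = None,
                    params: MechanicsParams = MechanicsParams(),
                    pairs: Optional[np.ndarray] = None):
    """Net adhesion/repulsion velocity for each agent (vectorized).

    Repulsion acts when membranes overlap (d < R_i + R_j) with magnitude
    sqrt(c_i c_j) (1 - d/s)^2; adhesion attracts within the interaction
    range s * multiplier with the same polynomial form, weighted by the
    per-pair adhesion affinity. ``affinity`` may be a per-pair array or
    a callable mapping the pair list to one. Forces are equal and
    opposite by construction. Also returns the crowding pressure per
    agent (normalized by the simple-pressure scale) and the pair list.
    """
    n = len(pos)
    vel = np.zeros((n, 2))
    pressure = np.zeros(n)
    if n < 2:
        return vel, pressure, np.empty((0, 2), dtype=int)
    if pairs is None:
        rmax = float(radius.max())
        tree = cKDTree(pos)
        pairs = tree.query_pairs(r=2.0 * rmax * params.adhesion_distance_multiplier,
                                 output_type="ndarray")
    if len(pairs) == 0:
        return vel, pressure, pairs
    i, j = pairs[:, 0], pairs[:, 1]
    dvec = pos[i] - pos[j]
    d = np.linalg.norm(dvec, axis=1)
    s = radius[i] + radius[j]
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(d[:, None] > 0, dvec / np.maximum(d, 1e-12)[:, None], 0.0)
    # repulsion (overlap only)
    overlap = d < s
    frac = np.where(overlap, 1.0 - d / s, 0.0)
    f_rep = np.sqrt(repulsion[i] * repulsion[j]) * frac**2
    # adhesion (within extended interaction distance)
    ra = s * params.adhesion_distance_multiplier
    within = d < ra
    afrac = np.where(within, 1.0 - d / ra, 0.0)
    if callable(affinity):
        affinity = affinity(pairs)
    aff = 1.0 if affinity is None else affinity
    f_adh = np.sqrt(adhesion[i] * adhesion[j]) * aff * afrac**2
    fmag = (f_rep - f_adh) / params.drag
    fvec = fmag[:, None] * unit
    np.add.at(vel, i, fvec)
    np.add.at(vel, j, -fvec)
    np.add.at(pressure, i, frac**2 / SIMPLE_PRESSURE_SCALE)
    np.add.at(pressure, j, frac**2 / SIMPLE_PRESSURE_SCALE)
    return vel, pressure, pairs


def update_mechanics(agents: Iterable[CellAgent], dt: float,
                     params: MechanicsParams = MechanicsParams()) -> None:
    """Move a list of agents one overdamped step under pairwise forces."""
    agents = list(agents)
    if not agents:
        return
    pos = np.array([a.position for a in agents])
    radius = np.array([a.radius for a in agents])
    adhesion = np.array([a.get_phenotype("cell-cell adhesion") for a in agents])
    repulsion = np.array([a.get_phenotype("cell-cell repulsion") for a in agents])

    def affinity_for(pairs):
        if len(pairs) == 0:
            return None
        return np.sqrt([
            agents[i].get_phenotype(f"adhesive affinity to {agents[j].type_name}", 1.0)
            * agents[j].get_phenotype(f"adhesive affinity to {agents[i].type_name}", 1.0)
            for i, j in pairs
        ])

    vel, pressure, _ = pairwise_forces(pos, radius, adhesion, repulsion,
                                       affinity=affinity_for, params=params)
    for a, v, p in zip(agents, pos + vel * dt, pressure):
        a.position = v
        a._pop.pressure[a._slot] = p


def run_attack(attacker: CellAgent, target: CellAgent, dt: float,
               rng: np.random.Generator) -> bool:
    """One attack step between an effector and a candidate target.

    If no attack is in progress, initiation fires with probability
    1 - exp(-attack_rate * immunogenicity * dt) given membrane contact;
    while attacking, the target accumulates damage and attack time at
    the attacker's damage rate. The attack ends when contact is lost or
    the target dies. Returns True when attacking after this step.
    """
    if attacker.is_dead:
        return False
    d = float(np.linalg.norm(attacker.position - target.position))
    in_contact = d < (attacker.radius + target.radius)
    current = attacker.attack_target
    if current is not None and current == target:
        if not in_contact or target.is_dead or not target.alive_in_population:
            attacker.attack_target = None
            return False
        target.damage = target.damage + attacker.get_phenotype("damage rate") * dt
        target.attack_time = target.attack_time + dt
        return True
    if not in_contact or target.is_dead:
        return False
    rate = attacker.get_phenotype(f"attack {target.type_name}", 0.0)
    immuno = target.get_phenotype(f"immunogenicity to {attacker.type_name}", 1.0)
    if rng.random() < event_probability(rate * immuno, dt):
        attacker.attack_target = target
        return True
    return False


# ---------------------------------------------------------------------------
# phenotype step (reference per-agent path)

def advance_phenotype(agent: CellAgent, groups, env, neighbors, dt: float,
                      rng: np.random.Generator, now: float = 0.0,
                      signal_dictionary=None) -> list:
    """Apply behavior rules to one agent and sample its stochastic events.

    ``groups`` maps behavior name -> :class:`BehaviorRuleGroup` for the
    agent's cell type. Returns the fired events as (name, detail)
    tuples; the caller applies them. Dead agents evaluate only rules
    flagged ``applies_to_dead``; their remaining rate parameters are
    zeroed.
    """
    from . import response
    from .dictionaries import SignalDictionary, get_signal_value, set_behavior

    pop = agent._pop
    dead = agent.is_dead
    agent.reset_phenotype()
    if dead:
        _zero_dead_rates(pop, np.array([agent._slot]))

    if signal_dictionary is None:
        substrates = list(env.substrates) if env is not None else []
        signal_dictionary = SignalDictionary(substrates,
                                             [d.name for d in pop.definitions])
    sig_cache: dict[str, float] = {}

    def signal(name: str) -> float:
        if name not in sig_cache:
            spec = signal_dictionary.resolve(name)
            sig_cache[name] = get_signal_value(agent, env, neighbors, spec, now)
        return sig_cache[name]

    from .dictionaries import BehaviorDictionary
    substrates = list(env.substrates) if env is not None else []
    bdict = BehaviorDictionary(substrates, [d.name for d in pop.definitions])
    for behavior, group in groups.items():
        vec = response.SignalVector({
            e.signal: signal(e.signal)
            for e in list(group.up_signals) + list(group.down_signals)
        })
        rv = response.evaluate_behavior(group, vec, dead=dead)
        try:
            spec = bdict.resolve(behavior)
            set_behavior(agent, spec, rv.b)
        except KeyError:
            agent.set_phenotype(behavior, max(rv.b, 0.0))

    events: list = []
    if dead:
        return events
    # death first: a dying cell does nothing else this step
    if rng.random() < event_probability(agent.get_phenotype("apoptosis"), dt):
        events.append(("apoptosis", None))
        return events
    if rng.random() < event_probability(agent.get_phenotype("necrosis"), dt):
        events.append(("necrosis", None))
        return events
    # transformations: first fired in seeded shuffled order wins
    transforms = [k for k in pop.behavior_keys if k.startswith("transform to ")]
    order = list(rng.permutation(len(transforms)))
    for t in order:
        key = transforms[t]
        if rng.random() < event_probability(agent.get_phenotype(key), dt):
            events.append(("transform", key[len("transform to "):]))
            break
    if rng.random() < event_probability(agent.get_phenotype("cycle entry"), dt):
        events.append(("divide", None))
    # phagocytosis of eligible contacts
    dead_contacts = [o for o in neighbors if o is not agent and o.is_dead
                     and np.linalg.norm(agent.position - o.position)
                     < agent.radius + o.radius]
    if dead_contacts and rng.random() < event_probability(
            agent.get_phenotype("phagocytose dead cell"), dt):
        prey = dead_contacts[int(rng.integers(len(dead_contacts)))]
        events.append(("phagocytose", prey))
    # attack initiation against live contacts with a positive attack rate
    live_contacts = [o for o in neighbors if o is not agent and not o.is_dead
                     and np.linalg.norm(agent.position - o.position)
                     < agent.radius + o.radius]
    if agent.attack_target is None:
        order = list(rng.permutation(len(live_contacts))) if live_contacts else []
        for k in order:
            o = live_contacts[k]
            rate = agent.get_phenotype(f"attack {o.type_name}", 0.0)
            if rate <= 0:
                continue
            immuno = o.get_phenotype(f"immunogenicity to {agent.type_name}", 1.0)
            if rng.random() < event_probability(rate * immuno, dt):
                events.append(("attack", o))
                break
    return events


#: phenotype columns that stay at their base value in dead cells; dead
#: cells keep repulsion (they remain physical obstacles) but lose
#: adhesion (junctions are lost on death).
_DEAD_KEEP_PREFIXES = ("migration bias", "migration persistence time",
                       "cell-cell repulsion",
                       "adhesive affinity to", "immunogenicity to",
                       "maximum number of attachments")


def _dead_keep_mask(behavior_keys) -> np.ndarray:
    keep = np.zeros(len(behavior_keys), dtype=bool)
    for c, k in enumerate(behavior_keys):
        if k.startswith(_DEAD_KEEP_PREFIXES) or k.endswith("secretion target"):
            keep[c] = True
    return keep


def _zero_dead_rates(pop: Population, slots: np.ndarray) -> None:
    """Zero rate-like phenotype parameters for dead agents (secretion,
    uptake, motility, cycle, attack...); applies_to_dead rules may then
    overwrite."""
    keep = _dead_keep_mask(pop.behavior_keys)
    cols = np.flatnonzero(~keep)
    pop.phenotype[np.ix_(slots, cols)] = 0.0
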