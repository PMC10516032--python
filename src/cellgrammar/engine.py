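"""Simulation loop, configuration, seeding, and outputs.

A simulation couples three clocks (all in minutes):

- the diffusion step advances secretion/uptake and substrate transport,
- the mechanics step advances motility, pairwise forces, attack
  continuation, and dead-cell volume dynamics,
- the phenotype step re-evaluates every behavior rule against the
  current signals and samples the stochastic events (division, death,
  transformation, phagocytosis, attack initiation).

Configuration is a YAML file (see ``data/configs`` for annotated
examples); every run is fully determined by the config plus the seed.
"""

from __future__ import annotations

import hashlib
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy.spatial import cKDTree

from . import agents as ag
from . import grammar
from .dictionaries import BehaviorDictionary, SignalDictionary, build_dictionaries
from .microenv import Microenvironment, Substrate
from .response import _response_term

__all__ = [
    "SimulationConfig",
    "SimulationOutput",
    "load_config",
    "run_simulation",
    "seed_disk",
    "seed_ring",
]


@dataclass
class SimulationConfig:
    """Validated simulation setup (domain, clocks, substrates, cells, rules)."""

    domain: dict
    time: dict
    substrates: dict
    cell_types: dict
    placements: list
    rules_path: Optional[str] = None
    rules_text: Optional[str] = None
    seed: int = 0
    out_dir: Optional[str] = None
    save_snapshots: bool = False
    source_path: Optional[str] = None
    death: Optional[dict] = None      # DeathParams overrides
    mechanics: Optional[dict] = None  # MechanicsParams overrides

    def __post_init__(self) -> None:
        t = self.time
        t.setdefault("dt_diffusion", 0.01)
        t.setdefault("dt_mechanics", 0.1)
        t.setdefault("dt_phenotype", 6.0)
        t.setdefault("save_interval", 60.0)
        if t["duration"] < 0:
            raise ValueError("duration must be >= 0")
        if not (0 < t["dt_diffusion"] <= t["dt_mechanics"] <= t["dt_phenotype"]):
            raise ValueError(
                "time steps must satisfy 0 < dt_diffusion <= dt_mechanics <= dt_phenotype"
            )
        self.domain.setdefault("voxel_size", 20.0)

    def config_hash(self) -> str:
        blob = repr((self.domain, self.time, self.substrates, self.cell_types,
                     self.placements, self.rules_text, self.seed)).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class SimulationOutput:
    """Counts time series, snapshot manifest, and run metadata."""

    counts: pd.DataFrame
    snapshots: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def final_counts(self) -> dict:
        return self.counts.iloc[-1].to_dict()


def load_config(path, seed: Optional[int] = None,
                overrides: Optional[dict] = None) -> SimulationConfig:
    """Load a YAML simulation config; relative rule paths resolve
    against the config file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if overrides:
        raw.update(overrides)
    rules_path = raw.get("rules")
    rules_text = raw.get("rules_text")
    if rules_path is not None:
        if not os.path.isabs(rules_path):
            rules_path = os.path.join(os.path.dirname(os.path.abspath(path)), rules_path)
        with open(rules_path) as fh:
            rules_text = fh.read()
    cfg = SimulationConfig(
        domain=raw["domain"],
        time=raw["time"],
        substrates=raw.get("substrates", {}),
        cell_types=raw["cell_types"],
        placements=raw.get("placements", []),
        rules_path=rules_path,
        rules_text=rules_text,
        seed=raw.get("seed", 0) if seed is None else seed,
        out_dir=raw.get("out_dir"),
        save_snapshots=raw.get("save_snapshots", False),
        source_path=str(path),
        death=raw.get("death"),
        mechanics=raw.get("mechanics"),
    )
    return cfg


# ---------------------------------------------------------------------------
# seeding

def seed_disk(count: int, radius: float, center, type_name: str,
              rng: np.random.Generator) -> list:
    """Uniform-in-area placements in a disk: radius ~ R*sqrt(u)."""
    u = rng.random(count)
    theta = rng.uniform(0.0, 2.0 * np.pi, count)
    r = radius * np.sqrt(u)
    cx, cy = center
    return [(cx + ri * np.cos(ti), cy + ri * np.sin(ti), type_name)
            for ri, ti in zip(r, theta)]


def seed_ring(count_per_type: int, inner_radius: float, types, rng: np.random.Generator,
              width: float = 50.0, center=(0.0, 0.0)) -> list:
    """Uniform angular placements in an annulus just outside inner_radius."""
    out = []
    cx, cy = center
    for type_name in types:
        theta = rng.uniform(0.0, 2.0 * np.pi, count_per_type)
        r = inner_radius + rng.random(count_per_type) * width
        out.extend((cx + ri * np.cos(ti), cy + ri * np.sin(ti), type_name)
                   for ri, ti in zip(r, theta))
    return out


def _build_placements(config: SimulationConfig, rng: np.random.Generator) -> list:
    placements = []
    for p in config.placements:
        kind = p.get("kind", "file")
        if kind == "disk":
            placements += seed_disk(p["count"], p["radius"],
                                    tuple(p.get("center", (0.0, 0.0))),
                                    p["type"], rng)
        elif kind == "ring":
            placements += seed_ring(p["count_per_type"], p["inner_radius"],
                                    p["types"], rng, width=p.get("width", 50.0),
                                    center=tuple(p.get("center", (0.0, 0.0))))
        elif kind == "file":
            path = p["path"]
            if config.source_path and not os.path.isabs(path):
                path = os.path.join(os.path.dirname(os.path.abspath(config.source_path)),
                                    path)
            df = pd.read_csv(path)
            placements += [(row.x, row.y, row.type) for row in df.itertuples()]
        else:
            raise ValueError(f"unknown placement kind {kind!r}")
    return placements


# ---------------------------------------------------------------------------
# simulation

class Simulation:
    """Executable state for one configured run."""

    def __init__(self, config: SimulationConfig, seed: Optional[int] = None):
        self.config = config
        self.seed = config.seed if seed is None else seed
        self.rng = np.random.default_rng(self.seed)

        d = config.domain
        self.env = Microenvironment(
            (d["xmin"], d["xmax"], d["ymin"], d["ymax"]),
            voxel_size=d.get("voxel_size", 20.0),
        )
        for name, s in config.substrates.items():
            self.env.add_substrate(Substrate(
                name=name,
                diffusion=s.get("diffusion", 1e3),
                decay=s.get("decay", 0.01),
                initial=s.get("initial", 0.0),
                boundary=s.get("boundary", "no-flux"),
                boundary_value=s.get("boundary_value"),
                secretion_saturation=s.get("secretion_saturation", 1.0),
                dt=s.get("dt"),
            ))

        substrate_names = list(config.substrates)
        type_names = list(config.cell_types)
        self.signal_dict, self.behavior_dict = build_dictionaries(
            substrate_names, type_names)

        # rules
        if config.rules_text:
            self.ruleset = grammar.parse_statements_text(
                config.rules_text, source=config.rules_path or "<config>")
        else:
            self.ruleset = grammar.RuleSet()
        report = grammar.validate_rules(self.ruleset, self.signal_dict,
                                        self.behavior_dict, type_names)
        if not report.ok:
            raise ValueError(f"rule validation failed:\n{report}")

        # definitions and the full phenotype column set
        defs = []
        for name, spec in config.cell_types.items():
            defs.append(ag.CellDefinition(
                name=name,
                volume=spec.get("volume", ag.DEFAULT_VOLUME),
                behaviors=dict(spec.get("behaviors", {})),
            ))
        keys = dict.fromkeys(ag.DEFAULT_BEHAVIORS)
        for sub in substrate_names:
            for suffix in ("secretion", "secretion target", "uptake"):
                keys[f"{sub} {suffix}"] = None
            keys[f"chemotactic response to {sub}"] = None
        for ct in type_names:
            for prefix in ("transform to", "phagocytose", "attack",
                           "immunogenicity to", "adhesive affinity to"):
                keys[f"{prefix} {ct}"] = None
        for d_ in defs:
            keys.update(dict.fromkeys(d_.behaviors))
        for r in self.ruleset:
            keys[r.behavior] = None
        # secretion targets default to the substrate's saturation
        self.pop = ag.Population(defs, behavior_keys=list(keys))
        for sub in substrate_names:
            col = self.pop.key_index[f"{sub} secretion target"]
            sat = self.env.substrates[sub].secretion_saturation
            for t, d_ in enumerate(defs):
                if f"{sub} secretion target" not in d_.behaviors:
                    self.pop.base_table[t, col] = sat
        # immunogenicity defaults to 1 unless set
        for ct in type_names:
            col = self.pop.key_index[f"immunogenicity to {ct}"]
            for t, d_ in enumerate(defs):
                if f"immunogenicity to {ct}" not in d_.behaviors:
                    self.pop.base_table[t, col] = 1.0

        # aggregated rule groups per type
        self.groups: dict[str, dict[str, grammar.BehaviorRuleGroup]] = {}
        self.warnings: list[str] = []
        for t, d_ in enumerate(defs):
            base = {k: self.pop.base_table[t, c] for k, c in self.pop.key_index.items()}
            gs = grammar.aggregate_all(self.ruleset, d_.name, base)
            for g in gs.values():
                self.warnings.extend(g.warnings)
            self.groups[d_.name] = gs

        # initial placement
        bounds = (d["xmin"], d["xmax"], d["ymin"], d["ymax"])
        for x, y, tname in _build_placements(config, self.rng):
            if not (bounds[0] <= x <= bounds[1] and bounds[2] <= y <= bounds[3]):
                raise ValueError(f"placement ({x:.1f}, {y:.1f}) outside domain")
            self.pop.add(tname, (x, y))

        self.mech = ag.MechanicsParams(**(getattr(config, "mechanics", None) or {}))
        self.death = ag.DeathParams(**(getattr(config, "death", None) or {}))
        self.now = 0.0
        self._dead_keep = ag._dead_keep_mask(self.pop.behavior_keys)
        self._counts_rows: list[dict] = []
        self._snapshots: list = []

    # -- signal arrays ----------------------------------------------------

    def _contact_pairs(self, idx: np.ndarray):
        """Membrane-contact pairs among the given slots."""
        if len(idx) < 2:
            return np.empty((0, 2), dtype=int)
        pos = self.pop.pos[idx]
        radius = ag.radius_from_volume(self.pop.volume[idx])
        pairs = cKDTree(pos).query_pairs(r=2.0 * float(radius.max()),
                                         output_type="ndarray")
        if len(pairs) == 0:
            return pairs
        d = np.linalg.norm(pos[pairs[:, 0]] - pos[pairs[:, 1]], axis=1)
        touching = d < radius[pairs[:, 0]] + radius[pairs[:, 1]]
        return pairs[touching]

    def _signal_arrays(self, idx: np.ndarray, pairs: np.ndarray) -> dict:
        """Lazily evaluated per-slot signal arrays over the active slots."""
        pop, env = self.pop, self.env
        cache: dict[str, np.ndarray] = {}
        local = {int(s): k for k, s in enumerate(idx)}

        def contact_count(predicate) -> np.ndarray:
            out = np.zeros(len(idx))
            if len(pairs):
                a, b = idx[pairs[:, 0]], idx[pairs[:, 1]]
                sel = predicate(b)
                np.add.at(out, pairs[:, 0][sel], 1.0)
                sel = predicate(a)
                np.add.at(out, pairs[:, 1][sel], 1.0)
            return out

        def get(name: str) -> np.ndarray:
            if name in cache:
                return cache[name]
            spec = self.signal_dict.resolve(name)
            cat = spec.category
            if cat == "substrate":
                val = env.sample_field(name, pop.pos[idx])
            elif cat == "substrate_gradient":
                gx, gy = env.gradient_field(spec.target)
                i, j = env.voxel_indices(pop.pos[idx])
                val = np.hypot(gx[i, j], gy[i, j])
            elif cat == "pressure":
                val = pop.pressure[idx]
            elif cat == "damage":
                val = pop.damage[idx]
            elif cat == "attack_time":
                val = pop.attack_time[idx]
            elif cat == "volume":
                val = pop.volume[idx]
            elif cat == "dead":
                val = (pop.state[idx] != ag.STATE_LIVE).astype(float)
            elif cat == "time":
                val = np.full(len(idx), self.now)
            elif cat == "contact_type":
                t = pop.type_index[spec.target]
                val = contact_count(
                    lambda s: (pop.type_idx[s] == t) & (pop.state[s] == ag.STATE_LIVE))
            elif cat == "contact_live":
                val = contact_count(lambda s: pop.state[s] == ag.STATE_LIVE)
            elif cat == "contact_dead":
                val = contact_count(lambda s: pop.state[s] != ag.STATE_LIVE)
            else:
                raise KeyError(f"signal {name!r} unsupported in the engine loop")
            cache[name] = val
            return val

        return get

    # -- phenotype step ----------------------------------------------------

    def step_phenotype(self, dt: float) -> None:
        pop = self.pop
        idx = pop.active_slots()
        if len(idx) == 0:
            return
        # reset working phenotypes; dead agents keep only non-rate parameters
        pop.phenotype[idx] = pop.base_table[pop.type_idx[idx]]
        dead_local = pop.state[idx] != ag.STATE_LIVE
        if dead_local.any():
            cols = np.flatnonzero(~self._dead_keep)
            pop.phenotype[np.ix_(idx[dead_local], cols)] = 0.0

        pairs = self._contact_pairs(idx)
        signal = self._signal_arrays(idx, pairs)

        # rule evaluation, vectorized per (type, behavior)
        for tname, groups in self.groups.items():
            t = pop.type_index[tname]
            mine = np.flatnonzero(pop.type_idx[idx] == t)
            if len(mine) == 0:
                continue
            dead_mine = dead_local[mine]
            for behavior, group in groups.items():
                def pooled(entries):
                    total = np.zeros(len(mine))
                    for e in entries:
                        term = np.asarray(_response_term(
                            signal(e.signal)[mine], e.half_max, e.hill_power,
                            e.response_shape), dtype=float)
                        if not e.applies_to_dead:
                            term = np.where(dead_mine, 0.0, term)
                        total += term
                    return total / (1.0 + total)

                U = pooled(group.up_signals)
                D = pooled(group.down_signals)
                b = ((1.0 - D) * ((1.0 - U) * group.base_value
                                  + U * group.max_value)
                     + D * group.min_value)
                try:
                    lo, hi = self.behavior_dict.resolve(behavior).bounds
                except KeyError:
                    lo, hi = 0.0, np.inf
                pop.phenotype[idx[mine], pop.key_index[behavior]] = np.clip(b, lo, hi)

        self._sample_events(idx, pairs, dt)

    def _col(self, key: str) -> Optional[int]:
        return self.pop.key_index.get(key)

    def _sample_events(self, idx: np.ndarray, pairs: np.ndarray, dt: float) -> None:
        """Sample and apply the stochastic phenotype events for this step."""
        pop, rng = self.pop, self.rng
        live = pop.state[idx] == ag.STATE_LIVE
        live_idx = idx[live]
        n = len(live_idx)
        if n == 0:
            return
        P = pop.phenotype

        def prob(col) -> np.ndarray:
            if col is None:
                return np.zeros(n)
            return ag.event_probability(P[live_idx, col], dt)

        # fixed draw order for determinism
        fired_apop = rng.random(n) < prob(self._col("apoptosis"))
        fired_necr = rng.random(n) < prob(self._col("necrosis"))
        transform_keys = [k for k in pop.behavior_keys if k.startswith("transform to ")]
        fired_trans = {}
        for k in transform_keys:
            fired_trans[k] = rng.random(n) < prob(self._col(k))
        fired_div = rng.random(n) < prob(self._col("cycle entry"))
        fired_phago = rng.random(n) < prob(self._col("phagocytose dead cell"))

        # contact bookkeeping for phagocytosis / attack
        neighbor_map: dict[int, list[int]] = {}
        if len(pairs):
            for a, b in pairs:
                neighbor_map.setdefault(int(idx[a]), []).append(int(idx[b]))
                neighbor_map.setdefault(int(idx[b]), []).append(int(idx[a]))

        transform_order = rng.permutation(len(transform_keys))

        for k_local in range(n):
            slot = int(live_idx[k_local])
            if not pop.active[slot] or pop.state[slot] != ag.STATE_LIVE:
                continue
            agent = ag.CellAgent(pop, slot)
            if fired_apop[k_local]:
                agent.state = "apoptotic"
                continue
            if fired_necr[k_local]:
                agent.state = "necrotic"
                continue
            for t_i in transform_order:
                key = transform_keys[t_i]
                if fired_trans[key][k_local]:
                    ag.transform(agent, key[len("transform to "):])
                    break
            if fired_div[k_local]:
                ag.divide(agent, rng)
            if fired_phago[k_local]:
                prey = [s for s in neighbor_map.get(slot, [])
                        if pop.active[s] and pop.state[s] != ag.STATE_LIVE]
                if prey:
                    ag.phagocytose(agent, ag.CellAgent(
                        pop, prey[int(rng.integers(len(prey)))]))
            # attack initiation
            if pop.attack_target[slot] < 0:
                targets = [s for s in neighbor_map.get(slot, [])
                           if pop.active[s] and pop.state[s] == ag.STATE_LIVE]
                if targets:
                    for t_slot in rng.permutation(targets):
                        t_slot = int(t_slot)
                        col = self._col(f"attack {pop.definitions[pop.type_idx[t_slot]].name}")
                        if col is None:
                            continue
                        rate = P[slot, col]
                        if rate <= 0:
                            continue
                        icol = self._col(
                            f"immunogenicity to {pop.definitions[pop.type_idx[slot]].name}")
                        immuno = P[t_slot, icol] if icol is not None else 1.0
                        if rng.random() < ag.event_probability(rate * immuno, dt):
                            pop.attack_target[slot] = t_slot
                            break

    # -- mechanics step ----------------------------------------------------

    def step_mechanics(self, dt: float) -> None:
        pop, rng = self.pop, self.rng
        idx = pop.active_slots()
        if len(idx) == 0:
            return
        pos = pop.pos[idx]
        radius = ag.radius_from_volume(pop.volume[idx])
        adhesion = pop.phenotype[idx, pop.key_index["cell-cell adhesion"]]
        repulsion = pop.phenotype[idx, pop.key_index["cell-cell repulsion"]]
        # per-pair adhesion affinity sqrt(aff_i(type_j) * aff_j(type_i))
        affcols = np.array([pop.key_index[f"adhesive affinity to {d.name}"]
                            for d in pop.definitions])
        affmat = pop.phenotype[np.ix_(idx, affcols)]  # (n_active, n_types)
        types_local = pop.type_idx[idx]

        def affinity_for(pairs):
            if len(pairs) == 0:
                return None
            i, j = pairs[:, 0], pairs[:, 1]
            return np.sqrt(affmat[i, types_local[j]] * affmat[j, types_local[i]])

        vel, pressure, _ = ag.pairwise_forces(pos, radius, adhesion, repulsion,
                                              affinity=affinity_for,
                                              params=self.mech)
        pop.pressure[idx] = pressure

        # motility (live agents only)
        live = pop.state[idx] == ag.STATE_LIVE
        speed = pop.phenotype[idx, pop.key_index["migration speed"]]
        tau = np.maximum(pop.phenotype[idx, pop.key_index["migration persistence time"]],
                         1e-9)
        bias = pop.phenotype[idx, pop.key_index["migration bias"]]
        redraw = (rng.random(len(idx)) < np.minimum(dt / tau, 1.0)) & live
        if redraw.any():
            r_idx = np.flatnonzero(redraw)
            chemo = np.zeros((len(r_idx), 2))
            i, j = self.env.voxel_indices(pos[r_idx])
            for name in self.env.substrates:
                col = self._col(f"chemotactic response to {name}")
                if col is None:
                    continue
                sens = pop.phenotype[idx[r_idx], col]
                if not np.any(sens):
                    continue
                gx, gy = self.env.gradient_field(name)
                chemo[:, 0] += sens * gx[i, j]
                chemo[:, 1] += sens * gy[i, j]
            norm = np.linalg.norm(chemo, axis=1, keepdims=True)
            chemo = np.divide(chemo, norm, out=np.zeros_like(chemo),
                              where=norm > 0)
            phi = rng.uniform(0.0, 2.0 * np.pi, len(r_idx))
            rand_dir = np.column_stack([np.cos(phi), np.sin(phi)])
            b = bias[r_idx][:, None]
            direction = b * chemo + (1.0 - b) * rand_dir
            dn = np.linalg.norm(direction, axis=1, keepdims=True)
            direction = np.divide(direction, dn, out=np.zeros_like(direction),
                                  where=dn > 0)
            pop.motility_dir[idx[r_idx]] = direction
        vel = vel + (speed * live)[:, None] * pop.motility_dir[idx]

        new_pos = pos + vel * dt
        new_pos[:, 0] = np.clip(new_pos[:, 0], self.env.xmin, self.env.xmax)
        new_pos[:, 1] = np.clip(new_pos[:, 1], self.env.ymin, self.env.ymax)
        pop.pos[idx] = new_pos

        self._attack_continuation(dt)
        self._death_and_volume(idx, dt)

    def _attack_continuation(self, dt: float) -> None:
        pop = self.pop
        attackers = np.flatnonzero((pop.attack_target[: pop.n] >= 0)
                                   & pop.active[: pop.n])
        for a in attackers:
            t = int(pop.attack_target[a])
            if (not pop.active[t] or pop.state[t] != ag.STATE_LIVE
                    or pop.state[a] != ag.STATE_LIVE):
                pop.attack_target[a] = -1
                continue
            d = float(np.linalg.norm(pop.pos[a] - pop.pos[t]))
            ra = float(ag.radius_from_volume(pop.volume[a]))
            rt = float(ag.radius_from_volume(pop.volume[t]))
            if d >= ra + rt:
                pop.attack_target[a] = -1
                continue
            rate_col = pop.key_index.get("damage rate")
            rate = pop.phenotype[a, rate_col] if rate_col is not None else 1.0
            pop.damage[t] += rate * dt
            pop.attack_time[t] += dt

    def _death_and_volume(self, idx: np.ndarray, dt: float) -> None:
        pop = self.pop
        live = pop.state[idx] == ag.STATE_LIVE
        # live-cell volume relaxation toward the type's target volume
        rate = self.death.volume_relaxation_rate
        if rate > 0 and live.any():
            li = idx[live]
            pop.volume[li] += (pop.target_volume[li] - pop.volume[li]) * (
                1.0 - np.exp(-rate * dt))
        # apoptotic shrinkage and removal
        apop = idx[pop.state[idx] == ag.STATE_APOPTOTIC]
        if len(apop):
            pop.death_clock[apop] += dt
            pop.volume[apop] *= np.exp(
                -np.log(2.0) / self.death.apoptotic_volume_halflife * dt)
            gone = apop[pop.volume[apop] < self.death.apoptotic_removal_fraction
                        * pop.original_volume[apop]]
            for s in gone:
                pop.remove(int(s))
        # necrotic persistence
        necr = idx[pop.state[idx] == ag.STATE_NECROTIC]
        if len(necr):
            pop.death_clock[necr] += dt
            gone = necr[pop.death_clock[necr] >= self.death.necrotic_persistence]
            for s in gone:
                pop.remove(int(s))

    # -- diffusion step ----------------------------------------------------

    def step_diffusion(self, dt: float) -> None:
        """Advance sources/sinks + transport, sub-stepping stiff substrates.

        A substrate whose config declares a smaller ``dt`` (e.g. oxygen,
        whose cell uptake makes the reaction term stiff) is advanced in
        several sub-iterations of the coarse step; the others take one.
        """
        pop, env = self.pop, self.env
        idx = pop.active_slots()
        flat = fvol = None
        if len(idx):
            i, j = env.voxel_indices(pop.pos[idx])
            flat = i * env.nx + j
            fvol = pop.volume[idx] / env.voxel_volume
        for name, sub in env.substrates.items():
            n_sub = max(1, int(round(dt / sub.dt))) if sub.dt else 1
            h = dt / n_sub
            if flat is None:
                S = U = T = None
            else:
                scol = self._col(f"{name} secretion")
                ucol = self._col(f"{name} uptake")
                tcol = self._col(f"{name} secretion target")
                S = pop.phenotype[idx, scol] if scol is not None else None
                U = pop.phenotype[idx, ucol] if ucol is not None else None
                T = pop.phenotype[idx, tcol] if tcol is not None else None
            for _ in range(n_sub):
                if flat is not None:
                    env.apply_sources_sinks_one(name, flat, fvol, S, U, T, h)
                env.step_substrate(name, h)

    # -- main loop ---------------------------------------------------------

    def _record(self) -> None:
        row = {"time": self.now}
        for name, c in self.pop.counts().items():
            row[f"{name} (live)"] = c["live"]
            row[f"{name} (dead)"] = c["dead"]
        row["births"] = self.pop.births
        row["removed"] = self.pop.removed
        row["phagocytosed"] = self.pop.phagocytosed
        self._counts_rows.append(row)
        if self.config.save_snapshots and self.config.out_dir:
            self._snapshots.append(self._write_snapshot())

    def _write_snapshot(self) -> str:
        pop = self.pop
        idx = pop.active_slots()
        os.makedirs(self.config.out_dir, exist_ok=True)
        path = os.path.join(self.config.out_dir, f"cells_t{int(round(self.now)):07d}.csv")
        df = pd.DataFrame({
            "id": pop.id[idx],
            "x": pop.pos[idx, 0],
            "y": pop.pos[idx, 1],
            "type": [pop.definitions[t].name for t in pop.type_idx[idx]],
            "state": [ag._STATE_NAMES[s] for s in pop.state[idx]],
            "volume": pop.volume[idx],
            "damage": pop.damage[idx],
        })
        df.to_csv(path, index=False)
        return path

    def run(self) -> SimulationOutput:
        t = self.config.time
        dt_d, dt_m, dt_p = t["dt_diffusion"], t["dt_mechanics"], t["dt_phenotype"]
        duration, save_int = t["duration"], t["save_interval"]
        n_steps = int(round(duration / dt_d))
        mech_every = max(1, int(round(dt_m / dt_d)))
        phen_every = max(1, int(round(dt_p / dt_d)))
        save_every = max(1, int(round(save_int / dt_d)))

        # t=0 census reflects the initial placement
        self._record()
        for step in range(1, n_steps + 1):
            self.now = step * dt_d
            if step % phen_every == 0:
                self.step_phenotype(dt_p)
            if step % mech_every == 0:
                self.step_mechanics(dt_m)
            self.step_diffusion(dt_d)
            if step % save_every == 0 or step == n_steps:
                self._record()

        counts = pd.DataFrame(self._counts_rows).drop_duplicates(subset="time")
        meta = {
            "seed": self.seed,
            "config_hash": self.config.config_hash(),
            "duration": duration,
            "final_population": len(self.pop),
        }
        out = SimulationOutput(counts=counts.reset_index(drop=True),
                               snapshots=list(self._snapshots), metadata=meta)
        if self.config.out_dir:
            os.makedirs(self.config.out_dir, exist_ok=True)
            counts.to_csv(os.path.join(self.config.out_dir, "counts.csv"), index=False)
        return out


def run_simulation(config: SimulationConfig, seed: Optional[int] = None) -> SimulationOutput:
    """Validate, build, and run one simulation; returns its output."""
    return Simulation(config, seed=seed).run()
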