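"""Agent operations: division, death, mechanics, motility, attack,
phagocytosis, transformation, and stochastic event calibration."""

import numpy as np
import pytest

import cellgrammar.agents as ag
from cellgrammar.agents import (
    CellDefinition,
    DeathParams,
    Population,
    divide,
    event_probability,
    phagocytose,
    progress_death,
    run_attack,
    transform,
    update_mechanics,
    update_motility,
)
from cellgrammar.grammar import BehaviorRuleGroup, SignalTerm
from cellgrammar.microenv import Microenvironment, Substrate
from cellgrammar.response import evaluate_behavior


class TestEventProbability:
    def test_closed_form(self):
        assert event_probability(0.001, 6.0) == pytest.approx(
            1 - np.exp(-0.006), rel=1e-12)
        assert event_probability(0.001, 6.0) == pytest.approx(0.0059821, rel=1e-4)

    def test_zero_rate(self):
        assert event_probability(0.0, 6.0) == 0.0

    def test_never_exceeds_one(self):
        assert event_probability(100.0, 100.0) < 1.0 + 1e-15

    @pytest.mark.parametrize("rdt", [1e-4, 1e-2, 0.5])
    def test_frequency_calibration_within_3_sigma(self, rdt):
        """Observed event frequency over 1e5 trials matches 1-exp(-r*dt)."""
        n = 100_000
        rng = np.random.default_rng(int(rdt * 1e6) + 7)
        p = float(event_probability(rdt, 1.0))
        hits = int((rng.random(n) < p).sum())
        sigma = np.sqrt(n * p * (1 - p))
        assert abs(hits - n * p) <= 3 * sigma


class TestDivide:
    def test_volume_conserved_and_count_increments(self, small_population, rng):
        a = small_population.add("tumor", (0.0, 0.0))
        v0, n0 = a.volume, len(small_population)
        parent, daughter = divide(a, rng)
        assert parent.volume + daughter.volume == pytest.approx(v0)
        assert len(small_population) == n0 + 1

    def test_daughter_inherits_type_with_zero_damage(self, small_population, rng):
        a = small_population.add("tumor", (0.0, 0.0))
        a.damage = 50.0
        _, daughter = divide(a, rng)
        assert daughter.type_name == "tumor"
        assert daughter.damage == 0.0

    def test_daughter_placed_one_radius_away(self, small_population, rng):
        a = small_population.add("tumor", (0.0, 0.0))
        r_before = a.radius
        parent, daughter = divide(a, rng)
        d = np.linalg.norm(parent.position - daughter.position)
        assert d == pytest.approx(r_before)

    def test_dead_agents_do_not_divide(self, small_population, rng):
        a = small_population.add("tumor", (0.0, 0.0))
        a.state = "necrotic"
        with pytest.raises(ValueError):
            divide(a, rng)


class TestTransform:
    def test_round_trip_preserves_identity_and_position(self, small_population):
        a = small_population.add("tumor", (3.0, 4.0))
        ident, pos = a.id, a.position.copy()
        transform(a, "CD8 T cell")
        transform(a, "tumor")
        assert a.id == ident
        assert np.array_equal(a.position, pos)
        assert a.type_name == "tumor"

    def test_transform_to_own_type_is_noop(self, small_population):
        a = small_population.add("tumor", (0, 0))
        phen = small_population.phenotype[a._slot].copy()
        transform(a, "tumor")
        assert np.array_equal(small_population.phenotype[a._slot], phen)

    def test_unknown_type_rejected(self, small_population):
        a = small_population.add("tumor", (0, 0))
        with pytest.raises(KeyError):
            transform(a, "astrocyte")


class TestPhagocytose:
    def test_prey_removed_and_volume_transferred(self, small_population):
        pred = small_population.add("CD8 T cell", (0, 0))
        prey = small_population.add("tumor", (5, 0))
        prey.state = "necrotic"
        v = pred.volume + prey.volume
        n0 = len(small_population)
        phagocytose(pred, prey)
        assert len(small_population) == n0 - 1
        assert pred.volume == pytest.approx(v)
        assert small_population.phagocytosed == 1


class TestProgressDeath:
    def test_apoptotic_volume_strictly_decreases_until_removal(self,
                                                               small_population):
        a = small_population.add("tumor", (0, 0))
        a.state = "apoptotic"
        params = DeathParams(apoptotic_volume_halflife=8.6)
        prev = a.volume
        removed = False
        for _ in range(100):
            removed = progress_death(a, 6.0, params)
            if removed:
                break
            assert a.volume < prev
            prev = a.volume
        assert removed  # 5% of original is ~4.3 half-lives

    def test_necrotic_persists_then_removed(self, small_population):
        a = small_population.add("tumor", (0, 0))
        a.state = "necrotic"
        assert not progress_death(a, 60.0, DeathParams())  # still there at 1 h
        assert a.alive_in_population
        for _ in range(30):
            progress_death(a, 60.0, DeathParams())
        assert not a.alive_in_population

    def test_live_agents_untouched(self, small_population):
        a = small_population.add("tumor", (0, 0))
        v = a.volume
        assert not progress_death(a, 60.0, DeathParams())
        assert a.volume == v


class TestMechanics:
    def test_distant_agents_feel_no_force(self, small_population):
        a = small_population.add("tumor", (0, 0))
        b = small_population.add("tumor", (200, 0))
        update_mechanics([a, b], 0.1)
        assert np.array_equal(a.position, [0, 0])
        assert np.array_equal(b.position, [200, 0])

    def test_overlapping_pair_separates_monotonically(self):
        defs = [CellDefinition("c", behaviors={"cell-cell adhesion": 0.0})]
        pop = Population(defs)
        a = pop.add("c", (0.0, 0.0))
        b = pop.add("c", (4.0, 0.0))  # heavy overlap
        prev = 4.0
        for _ in range(200):
            update_mechanics([a, b], 0.1)
            d = np.linalg.norm(a.position - b.position)
            assert d >= prev - 1e-12
            prev = d
        assert prev > 4.0

    def test_pair_forces_are_equal_and_opposite(self, small_population):
        a = small_population.add("tumor", (0.0, 0.0))
        b = small_population.add("tumor", (10.0, 0.0))
        update_mechanics([a, b], 0.1)
        # net momentum zero: displacements cancel
        assert a.position[0] == pytest.approx(-(b.position[0] - 10.0), rel=1e-12)
        assert a.position[1] == b.position[1] == 0.0

    def test_crowding_pressure_recorded(self, small_population):
        a = small_population.add("tumor", (0.0, 0.0))
        b = small_population.add("tumor", (10.0, 0.0))
        update_mechanics([a, b], 0.01)
        assert small_population.pressure[a._slot] > 0


class TestMotility:
    def _env_with_ramp(self, g=0.1):
        env = Microenvironment((-100, 100, -100, 100), voxel_size=20.0)
        env.add_substrate(Substrate("oxygen", diffusion=0.0, decay=0.0))
        xx = (np.arange(env.nx) + 0.5) * 20.0 - 100
        env.fields["oxygen"][:] = 38.0 + g * xx[None, :]
        return env

    def test_zero_speed_no_displacement(self, small_population, rng):
        a = small_population.add("tumor", (0, 0))  # base migration speed 0
        disp = update_motility(a, self._env_with_ramp(), 0.1, rng)
        assert np.array_equal(disp, [0, 0])
        assert np.array_equal(a.position, [0, 0])

    def test_full_bias_follows_gradient_exactly(self, rng):
        defs = [CellDefinition("walker", behaviors={
            "migration speed": 1.0, "migration bias": 1.0,
            "migration persistence time": 1e-6,
            "chemotactic response to oxygen": 1.0})]
        pop = Population(defs)
        a = pop.add("walker", (0.0, 0.0))
        update_motility(a, self._env_with_ramp(), 0.1, rng)
        assert a.motility_direction[0] == pytest.approx(1.0)
        assert a.motility_direction[1] == pytest.approx(0.0, abs=1e-12)

    def test_unbiased_walk_is_isotropic(self, rng):
        defs = [CellDefinition("walker", behaviors={
            "migration speed": 1.0, "migration bias": 0.0,
            "migration persistence time": 1e-6})]
        pop = Population(defs, capacity=16384)
        n = 10_000
        agents = [pop.add("walker", (0.0, 0.0)) for _ in range(n)]
        for a in agents:
            update_motility(a, None, 1.0, rng)
        disp = pop.pos[: pop.n]
        # per-axis mean of n unit steps: sigma = 1/sqrt(2n)
        sigma = 1.0 / np.sqrt(2 * n)
        assert abs(disp[:, 0].mean()) < 3 * sigma
        assert abs(disp[:, 1].mean()) < 3 * sigma

    def test_dead_agents_do_not_move(self, small_population, rng):
        a = small_population.add("CD8 T cell", (0, 0))  # speed 1
        a.state = "apoptotic"
        disp = update_motility(a, None, 1.0, rng)
        assert np.array_equal(disp, [0, 0])


class TestAttack:
    def _pair(self, pop):
        atk = pop.add("CD8 T cell", (0.0, 0.0))
        tgt = pop.add("tumor", (10.0, 0.0))  # touching (radii ~8.4 each)
        return atk, tgt

    def test_zero_immunogenicity_never_initiates(self, small_population, rng):
        atk, tgt = self._pair(small_population)
        tgt.definition.behaviors["immunogenicity to CD8 T cell"] = 0.0
        # rebuild phenotype default path: per-agent lookup falls back to def
        for _ in range(200):
            assert not run_attack(atk, tgt, 6.0, rng)
        assert atk.attack_target is None

    def test_damage_accumulates_linearly_while_attacking(self, small_population,
                                                         rng):
        atk, tgt = self._pair(small_population)
        atk.attack_target = tgt
        for _ in range(10):
            run_attack(atk, tgt, 1.0, rng)  # damage rate 1.8/min
        assert tgt.damage == pytest.approx(18.0)
        assert tgt.attack_time == pytest.approx(10.0)

    def test_attack_ends_when_contact_lost(self, small_population, rng):
        atk, tgt = self._pair(small_population)
        atk.attack_target = tgt
        tgt.position = (100.0, 0.0)
        assert not run_attack(atk, tgt, 1.0, rng)
        assert atk.attack_target is None

    def test_damaged_tumor_apoptosis_at_half_max(self):
        """The printed damage rule gives the midpoint rate at damage 180."""
        group = BehaviorRuleGroup(
            "tumor", "apoptosis", base_value=7.2e-5, max_value=0.072,
            min_value=7.2e-5, up_signals=[SignalTerm("damage", 180.0, 2.0)])
        rv = evaluate_behavior(group, {"damage": 180.0})
        assert rv.b == pytest.approx((7.2e-5 + 0.072) / 2, rel=1e-12)


def test_example1_necrosis_rate_at_hypoxic_half_max():
    """'oxygen decreases necrosis from 0.0028' halves at the 3.75 half-max."""
    group = BehaviorRuleGroup(
        "tumor", "necrosis", base_value=0.0028, max_value=0.0028, min_value=0.0,
        down_signals=[SignalTerm("oxygen", 3.75, 8.0)])
    rv = evaluate_behavior(group, {"oxygen": 3.75})
    assert rv.b == pytest.approx(0.0028 * 0.5, rel=1e-12)


def test_radius_volume_relation(small_population):
    a = small_population.add("tumor", (0, 0))
    assert a.radius == pytest.approx((3 * a.volume / (4 * np.pi)) ** (1 / 3))
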