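"""Selectivity, Baranov harvest, effort allocation and the two regimes."""

import numpy as np
import pytest

from oceanfarm.fishing import (
    EffortField,
    FisheryConfig,
    allocate_effort,
    distribute_aggregate_effort,
    fishable_biomass,
    harvest,
    open_access_effort,
    redistribute_for_farm,
    selectivity_at_age,
    total_catch_at_effort,
)
from oceanfarm.life_history import PatchEnvironment, SpeciesParams, length_at_age
from oceanfarm.recruitment_mortality import PopulationState


def one_patch_state(numbers, weight, n_ages=1):
    return PopulationState(
        np.full((1, n_ages), float(numbers)), np.full((1, n_ages), float(weight))
    )


class TestSelectivity:
    def test_half_selected_at_legal_length(self, species):
        # invert the growth curve for the age whose length is legal_length
        age = (
            species.t0
            - np.log(1 - species.legal_length / species.linf) / species.k_growth
        )
        assert selectivity_at_age(age, species) == pytest.approx(0.5)

    def test_steepness_sharpens_toward_knife_edge(self, species):
        below, above = 2.0, species.max_age
        sharp_below = selectivity_at_age(below, species, steepness=50.0)
        sharp_above = selectivity_at_age(above, species, steepness=50.0)
        assert sharp_below < 1e-6 and sharp_above > 1 - 1e-6

    def test_logistic_hand_value(self):
        # steepness 0.2 and L - legal = 10: 1/(1+e^-2)
        sp = SpeciesParams(legal_length=50.0)
        age = sp.t0 - np.log(1 - 60.0 / sp.linf) / sp.k_growth
        assert selectivity_at_age(age, sp, steepness=0.2) == pytest.approx(
            1 / (1 + np.exp(-2.0)), rel=1e-9
        )

    def test_nondecreasing_in_age(self, species):
        nu = selectivity_at_age(np.linspace(0, 20, 100), species)
        assert np.all(np.diff(nu) >= 0)


class TestFishableBiomass:
    def test_farm_patches_count_zero(self, species):
        env = PatchEnvironment.uniform(2, 5.0)
        env.is_farm[0] = True
        state = PopulationState(
            np.full((2, species.max_age + 1), 1.0),
            np.full((2, species.max_age + 1), 1.0),
        )
        b = fishable_biomass(state, env, species)
        assert b[0] == 0.0 and b[1] > 0.0

    def test_sublegal_stock_is_unfishable(self, species):
        env = PatchEnvironment.uniform(2, 5.0)
        state = PopulationState(np.zeros((2, species.max_age + 1)), np.ones((2, species.max_age + 1)))
        state.numbers[:, 0] = 100.0  # age-0 fish, far below legal length
        b = fishable_biomass(state, env, species, steepness=50.0)
        assert np.allclose(b, 0.0, atol=1e-6)


class TestEffortAllocation:
    def test_uniform_biomass_uniform_effort(self):
        field = allocate_effort(0.25, np.full(8, 3.0))
        assert np.allclose(field.f_by_patch, 0.25)

    def test_gravity_example(self):
        field = allocate_effort(0.3, np.array([2.0, 1.0, 1.0]))
        assert np.allclose(field.f_by_patch, [0.45, 0.225, 0.225])

    def test_single_patch_takes_everything(self):
        field = allocate_effort(0.5, np.array([0.0, 4.0, 0.0]))
        assert field.f_by_patch[1] == pytest.approx(0.5)
        assert field.f_by_patch[[0, 2]].sum() == 0.0

    def test_no_biomass_warns_and_zeroes(self, caplog):
        field = allocate_effort(0.5, np.zeros(4))
        assert field.total_effort == 0.0


class TestRedistribution:
    def test_no_farm_is_identity(self):
        env = PatchEnvironment.uniform(4, 5.0)
        bau = EffortField(np.full(4, 0.2))
        out = redistribute_for_farm(bau, env, np.full(4, 1.0))
        assert np.allclose(out.f_by_patch, bau.f_by_patch)

    def test_half_farm_doubles_outside_effort(self):
        env = PatchEnvironment.uniform(4, 5.0)
        env.is_farm[:2] = True
        bau = EffortField(np.full(4, 0.2))
        out = redistribute_for_farm(bau, env, np.array([0.0, 0.0, 1.0, 1.0]))
        assert np.allclose(out.f_by_patch, [0.0, 0.0, 0.4, 0.4])

    def test_effort_conserved_and_proportional(self):
        env = PatchEnvironment.uniform(4, 5.0)
        env.is_farm[0] = True
        bau = EffortField(np.array([0.1, 0.3, 0.2, 0.1]))
        fishable = np.array([0.0, 3.0, 2.0, 1.0])
        out = redistribute_for_farm(bau, env, fishable)
        assert out.total_effort == pytest.approx(bau.total_effort, rel=1e-9)
        assert out.f_by_patch[0] == 0.0
        assert np.allclose(out.f_by_patch[1:] / fishable[1:], out.f_by_patch[1] / 3.0)

    def test_all_farm_rejected(self):
        env = PatchEnvironment.uniform(2, 5.0)
        env.is_farm[:] = True
        with pytest.raises(ValueError):
            redistribute_for_farm(EffortField(np.ones(2)), env, np.ones(2))


class TestHarvest:
    def test_no_effort_pure_natural_survival(self, species):
        env = PatchEnvironment.uniform(1, 5.0)
        state = one_patch_state(1000, 1.0, species.max_age + 1)
        catch, out = harvest(state, EffortField(np.zeros(1)), env, species)
        assert catch.sum() == 0.0
        assert np.allclose(out.numbers, 1000 * np.exp(-species.m_nat))

    def test_baranov_hand_value(self):
        # N=1000, w=1, M=0.2, F=0.3, nu=1: C = 0.6*1000*(1-e^-0.5) ~ 236.1
        sp = SpeciesParams(m_nat=0.2, legal_length=-1.0)
        env = PatchEnvironment.uniform(1, 5.0)
        state = one_patch_state(1000, 1.0, 1)
        catch, out = harvest(
            state, EffortField(np.array([0.3])), env, sp, selectivity_steepness=1e9
        )
        expected = (0.3 / 0.5) * 1000 * (1 - np.exp(-0.5))
        assert catch[0] == pytest.approx(expected, rel=1e-9)
        assert catch[0] == pytest.approx(236.1, abs=0.05)
        assert out.numbers[0, 0] == pytest.approx(1000 * np.exp(-0.5))

    def test_all_deaths_are_catch_when_m_zero(self):
        sp = SpeciesParams(m_nat=1e-12, legal_length=-1.0)
        env = PatchEnvironment.uniform(1, 5.0)
        state = one_patch_state(500, 2.0, 1)
        catch, _ = harvest(
            state, EffortField(np.array([0.4])), env, sp, selectivity_steepness=1e9
        )
        assert catch[0] == pytest.approx(2.0 * 500 * (1 - np.exp(-0.4)), rel=1e-6)

    def test_baranov_identity_partitions_deaths(self, species, rng):
        env = PatchEnvironment.uniform(3, 5.0)
        state = PopulationState(
            rng.uniform(10, 100, (3, species.max_age + 1)),
            rng.uniform(0.5, 5.0, (3, species.max_age + 1)),
        )
        f = EffortField(np.array([0.0, 0.3, 0.9]))
        nu = np.array(
            [selectivity_at_age(float(a), species) for a in range(species.max_age + 1)]
        )
        catch, out = harvest(state, f, env, species)
        deaths = state.numbers - out.numbers
        fa = f.f_by_patch[:, None] * nu[None, :]
        z = fa + species.m_nat
        catch_numbers = deaths * fa / z
        expected_catch = (catch_numbers * state.weight_at_age).sum(axis=1)
        assert np.allclose(catch, expected_catch, rtol=1e-9)

    def test_negative_effort_rejected(self, species):
        env = PatchEnvironment.uniform(1, 5.0)
        with pytest.raises(ValueError):
            harvest(one_patch_state(1, 1, species.max_age + 1), EffortField(np.array([-0.1])), env, species)


class TestOpenAccess:
    def test_zero_price_zero_effort(self, species):
        env = PatchEnvironment.uniform(2, 5.0)
        state = PopulationState(
            np.full((2, species.max_age + 1), 10.0),
            np.full((2, species.max_age + 1), 1.0),
        )
        cfg = FisheryConfig(regime="weak_open_access", price=0.0, cost_per_effort=1.0)
        assert open_access_effort(state, env, species, cfg) == 0.0

    def test_matches_dense_profit_scan(self, species):
        env = PatchEnvironment.uniform(1, 50.0)
        state = PopulationState(
            np.full((1, species.max_age + 1), 20.0),
            np.tile(np.linspace(0.1, 8.0, species.max_age + 1), (1, 1)),
        )
        cfg = FisheryConfig(
            regime="weak_open_access", price=1.0, cost_per_effort=5.0, max_effort=10.0
        )
        best = open_access_effort(state, env, species, cfg)
        grid = np.linspace(0.0, 10.0, 2001)
        profits = [
            cfg.price * total_catch_at_effort(e, state, env, species, cfg)
            - cfg.cost_per_effort * e
            for e in grid
        ]
        brute = grid[int(np.argmax(profits))]
        assert best == pytest.approx(brute, abs=0.02)

    def test_free_effort_runs_to_bound(self, species):
        env = PatchEnvironment.uniform(1, 50.0)
        state = PopulationState(
            np.full((1, species.max_age + 1), 100.0),
            np.full((1, species.max_age + 1), 5.0),
        )
        cfg = FisheryConfig(
            regime="weak_open_access", price=1.0, cost_per_effort=0.0, max_effort=7.0
        )
        assert open_access_effort(state, env, species, cfg) == pytest.approx(7.0, abs=0.01)
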