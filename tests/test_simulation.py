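"""Annual step order, equilibrium runs, and relative outcome metrics."""

import numpy as np
import pytest
from dataclasses import replace

from oceanfarm.farm_design import FarmDesign
from oceanfarm.fishing import distribute_aggregate_effort, fishable_biomass, harvest
from oceanfarm.life_history import length_at_age, unfished_equilibrium, update_weight_at_age, weight_length
from oceanfarm.movement import build_kernel, move
from oceanfarm.recruitment_mortality import PopulationState, advance_age, settle_and_survive, spawn
from oceanfarm.simulation import (
    RelativeOutcomes,
    ScenarioResult,
    equilibrate_unfished,
    relative_outcomes,
    run_to_equilibrium,
    step,
)


def make_result(biomass, catch):
    biomass = np.asarray(biomass, float)
    catch = np.asarray(catch, float)
    return ScenarioResult(
        biomass_trajectory=biomass,
        catch_trajectory=catch,
        effort_trajectory=np.zeros_like(catch),
        equilibrium_biomass=float(biomass[-1]),
        equilibrium_catch=float(catch[-1]),
        converged=True,
        years_run=len(catch),
    )


class TestStep:
    def test_unfished_equilibrium_is_fixed_point(self, small_config):
        sp = small_config.species
        env = unfished_equilibrium(sp, 20, 200.0)
        kernel = build_kernel(sp.sigma_m, 20)
        state = equilibrate_unfished(sp, env, kernel)
        nxt, catch, _ = step(state.copy(), env, kernel, None, sp)
        assert catch.sum() == 0.0
        assert nxt.total_biomass == pytest.approx(state.total_biomass, rel=1e-9)

    def test_empty_ocean_stays_empty(self, small_config):
        sp = small_config.species
        env = unfished_equilibrium(sp, 20, 200.0)
        kernel = build_kernel(sp.sigma_m, 20)
        state = PopulationState(
            np.zeros((20, sp.max_age + 1)), np.ones((20, sp.max_age + 1))
        )
        fishery = replace(small_config.fishery, total_effort=3.0)
        nxt, catch, _ = step(state, env, kernel, fishery, sp)
        assert catch.sum() == 0.0
        assert nxt.total_biomass == 0.0

    def test_step_equals_manual_stage_composition(self, small_config, rng):
        """One step must equal movement -> growth -> recruitment -> fishing -> aging."""
        sp = small_config.species
        env = unfished_equilibrium(sp, 20, 200.0)
        kernel = build_kernel(sp.sigma_m, 20)
        fishery = replace(small_config.fishery, total_effort=4.0)
        n_ages = sp.max_age + 1
        state = PopulationState(
            rng.uniform(0.1, 2.0, (20, n_ages)), rng.uniform(0.5, 5.0, (20, n_ages))
        )

        got, got_catch, _ = step(
            state.copy(), env, kernel, fishery, sp, density_dependent_movement=False
        )

        # manual composition from the public stage operations
        n = move(state.numbers, kernel)
        bm = move(state.numbers * state.weight_at_age, kernel)
        w = np.where(n > 0, bm / np.maximum(n, 1e-300), state.weight_at_age)
        ages = sp.ages.astype(float)
        w = update_weight_at_age(
            w,
            length_at_age(ages, sp)[None, :],
            length_at_age(ages + 1, sp)[None, :],
            (n * w).sum(axis=1)[:, None],
            env.k_patch[:, None],
            sp,
        )
        manual = PopulationState(n, w)
        recruits = settle_and_survive(spawn(manual, sp), env, sp)
        manual.numbers[:, 0] += recruits
        manual.weight_at_age[:, 0] = weight_length(length_at_age(0.0, sp), sp)
        fishable = fishable_biomass(manual, env, sp, fishery.selectivity_steepness)
        effort = distribute_aggregate_effort(fishery.total_effort, fishable)
        catch, manual = harvest(
            manual, effort, env, sp, selectivity_steepness=fishery.selectivity_steepness
        )
        manual = advance_age(manual)

        assert np.allclose(got_catch, catch, rtol=1e-12)
        assert np.allclose(got.numbers, manual.numbers, rtol=1e-12)
        assert np.allclose(got.weight_at_age, manual.weight_at_age, rtol=1e-12)


class TestRunToEquilibrium:
    def test_zero_farm_fraction_gives_unit_ratios(self, small_config):
        bau = run_to_equilibrium(small_config.without_farm())
        zero = run_to_equilibrium(small_config.with_farm(FarmDesign(0.0)))
        rel = relative_outcomes(zero, bau)
        assert rel.delta_b == pytest.approx(1.0)
        assert rel.delta_c == pytest.approx(1.0)
        assert rel.recovery_year == 0

    def test_reruns_are_bit_identical(self, small_config):
        cfg = small_config.with_farm(FarmDesign(0.25, layout="one_large", attraction=3.0))
        a = run_to_equilibrium(cfg)
        b = run_to_equilibrium(cfg)
        assert np.array_equal(a.biomass_trajectory, b.biomass_trajectory)
        assert np.array_equal(a.catch_trajectory, b.catch_trajectory)

    def test_anchor_translation_shifts_equilibrium_profile(self, small_config):
        """The wrapped lattice has no special patch: moving the farm anchor
        rotates the equilibrium spatial profile without changing totals."""
        fishery = replace(small_config.fishery, total_effort=4.0)
        cfg = replace(small_config, fishery=fishery)
        res = {}
        for anchor in (0, 4):
            farm = FarmDesign(0.25, layout="one_large", attraction=2.0, anchor=anchor)
            res[anchor] = run_to_equilibrium(cfg.with_farm(farm))
        prof0 = res[0].final_state.biomass_by_patch
        prof4 = res[4].final_state.biomass_by_patch
        assert np.allclose(np.roll(prof0, 4), prof4, rtol=1e-6)
        assert res[0].equilibrium_biomass == pytest.approx(
            res[4].equilibrium_biomass, rel=1e-6
        )


class TestRelativeOutcomes:
    def test_identical_runs_unit_ratios_immediate_recovery(self):
        r = make_result([10, 10, 10], [2, 2, 2])
        rel = relative_outcomes(r, r)
        assert rel == RelativeOutcomes(1.0, 1.0, 0)

    def test_catch_never_recovering(self):
        bau = make_result([10] * 5, [2.0] * 5)
        farm = make_result([12] * 5, [1.5] * 5)
        assert relative_outcomes(farm, bau).recovery_year is None

    def test_recovery_at_crossing_year(self):
        bau = make_result([10] * 10, [2.0] * 10)
        catches = [1.0] * 7 + [2.5, 2.6, 2.6]
        farm = make_result([12] * 10, catches)
        assert relative_outcomes(farm, bau).recovery_year == 7

    def test_zero_bau_biomass_rejected(self):
        bau = make_result([0.0], [0.0])
        farm = make_result([1.0], [1.0])
        with pytest.raises(ZeroDivisionError):
            relative_outcomes(farm, bau)
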