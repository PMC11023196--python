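"""The annual time-step driver and the relative outcome metrics.

Each simulated year runs, in fixed order: (1) adult movement through the
kernel; (2) density-dependent weight-at-age growth against the local
carrying capacity; (3) spawning, uniform larval settlement and
Beverton-Holt recruit survival; (4) effort determination for the active
management regime, with gravity allocation over fishable (non-farm)
patches; (5) combined natural + fishing mortality with Baranov catch
accounting; (6) aging with a plus group.  Equilibrium is declared when
the relative annual change of both total biomass and total catch stays
below a tolerance for a run of consecutive years.

Farm scenarios start from the business-as-usual (BAU) equilibrium, stamp
the farm onto the environment and kernel instantaneously, and continue
until the new equilibrium; outcomes are the ratios
``delta_B = B_farm / B_BAU`` and ``delta_C = C_farm / C_BAU`` of the two
equilibria, plus the time for annual catch to recover to the BAU level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .config import ScenarioConfig
from .farm_design import apply_farm_environment
from .fishing import (
    STRONG_MSY,
    WEAK_OPEN_ACCESS,
    EffortField,
    FisheryConfig,
    distribute_aggregate_effort,
    find_msy_effort,
    fishable_biomass,
    harvest,
    open_access_effort,
)
from .life_history import (
    PatchEnvironment,
    SpeciesParams,
    length_at_age,
    unfished_equilibrium,
    update_weight_at_age,
    weight_length,
)
from .movement import MovementKernel, apply_attraction, build_kernel, move, sigma_from_range
from .recruitment_mortality import (
    PopulationState,
    advance_age,
    settle_and_survive,
    spawn,
)

__all__ = [
    "ScenarioResult",
    "RelativeOutcomes",
    "step",
    "run_to_equilibrium",
    "relative_outcomes",
]

logger = logging.getLogger(__name__)


class NumericalIntegrityError(RuntimeError):
    """State went NaN, negative or unbounded during a run."""


@dataclass
class ScenarioResult:
    """Trajectories and equilibrium summaries of one run."""

    biomass_trajectory: np.ndarray
    catch_trajectory: np.ndarray
    effort_trajectory: np.ndarray
    equilibrium_biomass: float
    equilibrium_catch: float
    converged: bool
    years_run: int
    final_state: Optional[PopulationState] = None


@dataclass(frozen=True)
class RelativeOutcomes:
    """Farm-scenario outcomes relative to the no-farm baseline."""

    delta_b: float
    delta_c: float
    recovery_year: Optional[int]


def initial_state(params: SpeciesParams, env: PatchEnvironment) -> PopulationState:
    """A plausible seeding state: exponential age structure at half K."""
    ages = params.ages.astype(float)
    w_ref = weight_length(length_at_age(ages, params), params)
    n_shape = np.exp(-params.m_nat * ages)
    per_patch_bm = float(np.sum(n_shape * w_ref))
    scale = 0.5 * env.k_patch / max(per_patch_bm, 1e-300)
    numbers = scale[:, None] * n_shape[None, :]
    weights = np.tile(w_ref, (env.n_patches, 1))
    return PopulationState(numbers, weights)


def step(
    state: PopulationState,
    env: PatchEnvironment,
    kernel: Optional[MovementKernel],
    fishery: Optional[FisheryConfig],
    params: SpeciesParams,
    *,
    farm_m_multiplier: float = 1.0,
    density_dependent_movement: bool = False,
) -> tuple[PopulationState, np.ndarray, float]:
    """Advance one year; returns (state, catch per patch, aggregate effort)."""
    n = state.numbers
    w = state.weight_at_age

    # (1) adult movement: transport numbers and biomass, re-derive weights
    if kernel is not None and kernel.sigma_m > 0:
        if density_dependent_movement:
            probs = _density_scaled_probs(kernel, state, env)
            n1 = probs.T @ n
            bm1 = probs.T @ (n * w)
        else:
            n1 = move(n, kernel)
            bm1 = move(n * w, kernel)
        with np.errstate(invalid="ignore", divide="ignore"):
            w = np.where(n1 > 1e-300, bm1 / np.maximum(n1, 1e-300), w)
        n = n1

    # (2) density-dependent growth toward next year's length
    ages = params.ages.astype(float)
    bm_patch = np.sum(n * w, axis=1)
    w = update_weight_at_age(
        w,
        length_at_age(ages, params)[None, :],
        length_at_age(ages + 1.0, params)[None, :],
        bm_patch[:, None],
        env.k_patch[:, None],
        params,
    )
    state = PopulationState(n, w, state.year)

    # (3) reproduction: pooled larvae, uniform settlement, BH survival
    recruits = settle_and_survive(spawn(state, params), env, params)
    state.numbers[:, 0] += recruits
    w0 = weight_length(length_at_age(0.0, params), params)
    state.weight_at_age[:, 0] = w0

    # (4) effort determination and gravity allocation over fishable patches
    if fishery is None:
        effort = EffortField(np.zeros(env.n_patches))
        aggregate = 0.0
    else:
        fishable = fishable_biomass(
            state, env, params, fishery.selectivity_steepness
        )
        if fishery.regime == WEAK_OPEN_ACCESS:
            aggregate = open_access_effort(state, env, params, fishery)
        else:
            if fishery.total_effort is None:
                raise ValueError(
                    "strong regime needs total_effort (run the MSY search first)"
                )
            aggregate = fishery.total_effort
        effort = distribute_aggregate_effort(
            (fishery.catchability if fishery else 1.0) * aggregate, fishable
        )

    # (5) combined natural + fishing mortality with catch accounting
    catch, state = harvest(
        state,
        effort,
        env,
        params,
        farm_m_multiplier=farm_m_multiplier,
        selectivity_steepness=(
            fishery.selectivity_steepness if fishery else 0.25
        ),
    )

    # (6) aging with plus group
    state = advance_age(state)
    state.year += 1

    if not np.all(np.isfinite(state.numbers)) or np.any(state.numbers < 0):
        raise NumericalIntegrityError(f"invalid state at year {state.year}")
    return state, catch, aggregate


DENSITY_WEIGHT_FLOOR = 0.01


def _density_scaled_probs(
    kernel: MovementKernel, state: PopulationState, env: PatchEnvironment
) -> np.ndarray:
    """Habitat-choice movement: destinations weighted by free capacity.

    The kernel's (attraction-modified) weights toward each destination j
    are multiplied by ``max(1 - bm_j / K_j, floor)`` and rows are
    renormalized, so fish preferentially settle where density relative to
    carrying capacity is low — an ideal-free-distribution bias.  At a
    spatially uniform state the factor cancels and movement reduces to
    the plain kernel, so the no-farm baseline is unaffected; around
    farms, the tripled K creates headroom that draws and retains biomass
    until relative density equalizes, while the floor keeps a residual
    baseline exchange (spillover) even out of full patches.
    """
    headroom = np.maximum(
        1.0 - state.biomass_by_patch / env.k_patch, DENSITY_WEIGHT_FLOOR
    )
    w = kernel.probs * headroom[None, :]
    return w / w.sum(axis=1, keepdims=True)


def _run_dynamics(
    state: PopulationState,
    env: PatchEnvironment,
    kernel: Optional[MovementKernel],
    fishery: Optional[FisheryConfig],
    params: SpeciesParams,
    *,
    farm_m_multiplier: float = 1.0,
    density_dependent_movement: bool = False,
    max_years: int = 500,
    tol: float = 1e-6,
    window: int = 10,
    keep_state: bool = False,
) -> ScenarioResult:
    """Iterate annual steps until biomass and catch stop changing."""
    biomass, catches, efforts = [], [], []
    prev_b = state.total_biomass
    prev_c = None
    streak = 0
    converged = False
    years = 0
    for years in range(1, max_years + 1):
        state, catch, aggregate = step(
            state,
            env,
            kernel,
            fishery,
            params,
            farm_m_multiplier=farm_m_multiplier,
            density_dependent_movement=density_dependent_movement,
        )
        b = state.total_biomass
        if not np.isfinite(b) or b > 1e12 * max(env.k_patch.sum(), 1.0):
            raise NumericalIntegrityError(f"biomass diverged at year {years}")
        c = float(catch.sum())
        biomass.append(b)
        catches.append(c)
        efforts.append(aggregate)
        scale_b = max(abs(prev_b), 1e-12)
        scale_c = max(abs(prev_c), 1e-12 * max(b, 1.0)) if prev_c is not None else None
        rel = abs(b - prev_b) / scale_b
        if scale_c is not None:
            rel = max(rel, abs(c - prev_c) / scale_c)
        streak = streak + 1 if rel < tol else 0
        if streak >= window:
            converged = True
            break
        prev_b, prev_c = b, c
    return ScenarioResult(
        biomass_trajectory=np.asarray(biomass),
        catch_trajectory=np.asarray(catches),
        effort_trajectory=np.asarray(efforts),
        equilibrium_biomass=biomass[-1],
        equilibrium_catch=catches[-1],
        converged=converged,
        years_run=years,
        final_state=state if keep_state else None,
    )


def equilibrate_unfished(
    params: SpeciesParams,
    env: PatchEnvironment,
    kernel: Optional[MovementKernel] = None,
    *,
    max_years: int = 3000,
    tol: float = 1e-10,
) -> PopulationState:
    """Run the no-fishing dynamics to its fixed point."""
    if kernel is None:
        kernel = build_kernel(params.sigma_m, env.n_patches)
    result = _run_dynamics(
        initial_state(params, env),
        env,
        kernel,
        None,
        params,
        max_years=max_years,
        tol=tol,
        keep_state=True,
    )
    return result.final_state  # type: ignore[return-value]


def equilibrium_catch_at_constant_effort(
    aggregate_effort: float,
    params: SpeciesParams,
    env: PatchEnvironment,
    config: FisheryConfig,
    kernel: Optional[MovementKernel],
    start_state: Optional[PopulationState] = None,
    *,
    max_years: int = 500,
    tol: float = 1e-8,
) -> float:
    """Equilibrium annual catch under a fixed aggregate effort (MSY scoring)."""
    if start_state is None:
        start_state = equilibrate_unfished(params, env, kernel)
    fishery = replace(config, regime=STRONG_MSY, total_effort=float(aggregate_effort))
    result = _run_dynamics(
        start_state.copy(),
        env,
        kernel,
        fishery,
        params,
        max_years=max_years,
        tol=tol,
    )
    if not result.converged:
        raise RuntimeError(
            f"no equilibrium at aggregate effort {aggregate_effort:.4f}"
        )
    return result.equilibrium_catch


def prepare_system(
    config: ScenarioConfig,
) -> tuple[SpeciesParams, PatchEnvironment, MovementKernel, Optional[FisheryConfig]]:
    """Calibrate K, build the base kernel, resolve MSY effort if needed."""
    params = config.species
    sigma = sigma_from_range(params.range_fraction, config.n_patches)
    params = replace(params, sigma_m=sigma)
    env = unfished_equilibrium(params, config.n_patches, config.total_biomass_target)
    kernel = build_kernel(params.sigma_m, config.n_patches)
    fishery = config.fishery
    if (
        fishery is not None
        and fishery.regime == STRONG_MSY
        and fishery.total_effort is None
    ):
        e_msy = find_msy_effort(params, env, fishery, kernel)
        fishery = replace(fishery, total_effort=e_msy)
    return params, env, kernel, fishery


def run_to_equilibrium(
    config: ScenarioConfig,
    *,
    _system=None,
    _bau_state: Optional[PopulationState] = None,
) -> ScenarioResult:
    """Run a scenario to equilibrium; farm introduced into BAU equilibrium.

    The no-farm system is first burned in to its fished equilibrium.  If
    the config carries a farm, the farm is stamped on instantaneously and
    the recorded trajectories start at the introduction year; otherwise
    the BAU trajectories themselves are returned.
    """
    params, env, kernel, fishery = _system if _system is not None else prepare_system(
        config
    )
    if _bau_state is None:
        bau = _run_dynamics(
            equilibrate_unfished(params, env, kernel),
            env,
            kernel,
            fishery,
            params,
            density_dependent_movement=config.density_dependent_movement,
            max_years=config.max_years,
            tol=config.convergence_tol,
            window=config.convergence_window,
            keep_state=True,
        )
        bau_state = bau.final_state
    else:
        bau = None
        bau_state = _bau_state
    if config.farm is None or config.farm.total_fraction == 0.0:
        if bau is None:
            bau = _run_dynamics(
                bau_state.copy(),
                env,
                kernel,
                fishery,
                params,
                density_dependent_movement=config.density_dependent_movement,
                max_years=config.max_years,
                tol=config.convergence_tol,
                window=config.convergence_window,
                keep_state=True,
            )
        return bau
    farm_env = apply_farm_environment(env, config.farm, params.sigma_m)
    farm_kernel = apply_attraction(
        kernel,
        set(np.flatnonzero(farm_env.is_farm).tolist()),
        set(np.flatnonzero(farm_env.in_zoi).tolist()),
        config.farm.attraction,
    )
    state = bau_state.copy()
    state.year = 0
    return _run_dynamics(
        state,
        farm_env,
        farm_kernel,
        fishery,
        params,
        farm_m_multiplier=config.farm.m_multiplier,
        density_dependent_movement=config.density_dependent_movement,
        max_years=config.max_years,
        tol=config.convergence_tol,
        window=config.convergence_window,
        keep_state=True,
    )


def relative_outcomes(farm: ScenarioResult, bau: ScenarioResult) -> RelativeOutcomes:
    """delta_B, delta_C and years until catch recovers to the BAU level."""
    if bau.equilibrium_biomass <= 0:
        raise ZeroDivisionError("BAU equilibrium biomass is zero; ratios undefined")
    delta_b = farm.equilibrium_biomass / bau.equilibrium_biomass
    delta_c = (
        farm.equilibrium_catch / bau.equilibrium_catch
        if bau.equilibrium_catch > 0
        else float("nan")
    )
    recovery: Optional[int] = None
    threshold = bau.equilibrium_catch * (1.0 - 1e-9)
    hits = np.flatnonzero(farm.catch_trajectory >= threshold)
    if hits.size:
        recovery = int(hits[0])
    return RelativeOutcomes(delta_b=delta_b, delta_c=delta_c, recovery_year=recovery)
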