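"""Selectivity, the Baranov catch equation, and effort dynamics.

Two management regimes are modeled.  Strong management fishes at the
constant aggregate effort that maximizes equilibrium yield (MSY), found
by a grid search with golden-section refinement.  Weak management is a
high-value open-access fishery: each year aggregate effort is set at the
level that maximizes that year's profit (price x catch - cost x effort)
given the current biomass distribution — a myopic fleet with no
restraint.

In both regimes effort is gravity-allocated: fishers know where fishable
biomass is and spread effort across patches in proportion to it.  Farm
patches are closed to fishing; their effort share is redistributed over
the remaining patches so aggregate effort is conserved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import minimize_scalar

from .life_history import PatchEnvironment, SpeciesParams, length_at_age
from .recruitment_mortality import PopulationState, effective_m

__all__ = [
    "FisheryConfig",
    "EffortField",
    "selectivity_at_age",
    "fishable_biomass",
    "allocate_effort",
    "redistribute_for_farm",
    "harvest",
    "find_msy_effort",
    "open_access_effort",
]

logger = logging.getLogger(__name__)

STRONG_MSY = "strong_msy"
WEAK_OPEN_ACCESS = "weak_open_access"


@dataclass(frozen=True)
class FisheryConfig:
    """Fleet behavior and economics.

    ``total_effort`` is the aggregate effort (sum of per-patch fishing
    mortality at catchability 1) held constant under the strong regime;
    leave it None to have the MSY search fill it in.  ``price`` and
    ``cost_per_effort`` drive the open-access profit objective;
    ``max_effort`` bounds its per-year effort search.
    """

    regime: str = STRONG_MSY
    total_effort: Optional[float] = None
    price: float = 1.0
    cost_per_effort: float = 1.0
    catchability: float = 1.0
    selectivity_steepness: float = 0.25
    max_effort: float = 300.0

    def __post_init__(self) -> None:
        if self.regime not in (STRONG_MSY, WEAK_OPEN_ACCESS):
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.total_effort is not None and self.total_effort < 0:
            raise ValueError("total_effort must be non-negative")
        if self.regime == WEAK_OPEN_ACCESS:
            if self.price <= 0 and self.price != 0:
                raise ValueError("price must be non-negative")
            if self.cost_per_effort < 0 or self.catchability <= 0:
                raise ValueError(
                    "open access needs non-negative cost and positive catchability"
                )


@dataclass
class EffortField:
    """Per-patch fishing mortality for one time step."""

    f_by_patch: np.ndarray

    def __post_init__(self) -> None:
        self.f_by_patch = np.asarray(self.f_by_patch, dtype=float)
        if np.any(self.f_by_patch < 0):
            raise ValueError("fishing mortality must be non-negative")

    @property
    def total_effort(self) -> float:
        return float(self.f_by_patch.sum())


def selectivity_at_age(age, params: SpeciesParams, steepness: float = 0.25):
    """Logistic length-based selectivity, 0.5 at the legal length."""
    length = length_at_age(age, params)
    z = np.clip(-steepness * (length - params.legal_length), -700.0, 700.0)
    return 1.0 / (1.0 + np.exp(z))


def fishable_biomass(
    state: PopulationState,
    env: PatchEnvironment,
    params: SpeciesParams,
    steepness: float = 0.25,
) -> np.ndarray:
    """Selectivity-weighted (legal-size) biomass per patch; zero at farms."""
    nu = selectivity_at_age(np.arange(state.n_ages, dtype=float), params, steepness)
    b = np.sum(state.numbers * state.weight_at_age * nu[None, :], axis=1)
    b[env.is_farm] = 0.0
    return b


def allocate_effort(total_f_scale: float, fishable: np.ndarray) -> EffortField:
    """Gravity allocation: per-patch F proportional to fishable biomass.

    ``total_f_scale`` is the mean per-patch F over fishable patches, so
    aggregate effort is ``total_f_scale * n_fishable``; with uniform
    biomass every patch gets exactly ``total_f_scale``.
    """
    fishable = np.asarray(fishable, dtype=float)
    if np.any(fishable < 0):
        raise ValueError("fishable biomass must be non-negative")
    total = fishable.sum()
    if total <= 0:
        logger.warning("no fishable biomass anywhere; allocating zero effort")
        return EffortField(np.zeros_like(fishable))
    n_fishable = int(np.count_nonzero(fishable > 0))
    return EffortField(total_f_scale * n_fishable * fishable / total)


def distribute_aggregate_effort(
    aggregate_effort: float, fishable: np.ndarray
) -> EffortField:
    """Spread a fixed aggregate effort over patches in proportion to biomass."""
    fishable = np.asarray(fishable, dtype=float)
    total = fishable.sum()
    if total <= 0 or aggregate_effort <= 0:
        return EffortField(np.zeros_like(fishable))
    return EffortField(aggregate_effort * fishable / total)


def redistribute_for_farm(
    bau_effort: EffortField,
    env: PatchEnvironment,
    fishable: np.ndarray,
) -> EffortField:
    """Close farm patches and push their effort into the fishable space.

    The displaced fraction P_farm of effort is inflated back by
    ``1 / (1 - P_farm)`` and spread over non-farm patches in proportion to
    fishable biomass, so aggregate effort is exactly conserved.
    """
    p_farm = env.is_farm.mean()
    if p_farm >= 1.0:
        raise ValueError("all patches are farms; nothing fishable")
    if p_farm == 0.0:
        return EffortField(bau_effort.f_by_patch.copy())
    fishable = np.asarray(fishable, dtype=float).copy()
    fishable[env.is_farm] = 0.0
    return distribute_aggregate_effort(bau_effort.total_effort, fishable)


def harvest(
    state: PopulationState,
    effort: EffortField,
    env: PatchEnvironment,
    params: SpeciesParams,
    *,
    farm_m_multiplier: float = 1.0,
    selectivity_steepness: float = 0.25,
) -> tuple[np.ndarray, PopulationState]:
    """Baranov catch and combined natural + fishing survival.

    Per patch i and age a, with F_i the patch fishing mortality, nu_a the
    selectivity and M_i the (farm-modified) natural mortality::

        C_ia = F_i nu_a / (F_i nu_a + M_i) * N_ia * (1 - exp(-M_i - F_i nu_a)) * w_ia
        N'_ia = N_ia * exp(-M_i - F_i nu_a)

    Both mortality sources act through the single combined exponential,
    so the result does not depend on an arbitrary ordering of deaths
    within the year.  Returns (catch biomass per patch, surviving state).
    """
    f = effort.f_by_patch
    if f.shape[0] != state.n_patches:
        raise ValueError("effort field and state have different patch counts")
    nu = selectivity_at_age(
        np.arange(state.n_ages, dtype=float), params, selectivity_steepness
    )
    m = effective_m(env, params, farm_m_multiplier)
    fa = f[:, None] * nu[None, :]
    z = fa + m[:, None]
    deaths = state.numbers * (1.0 - np.exp(-z))
    with np.errstate(invalid="ignore", divide="ignore"):
        catch_numbers = np.where(z > 0, fa / z, 0.0) * deaths
    catch = np.sum(catch_numbers * state.weight_at_age, axis=1)
    out = state.copy()
    out.numbers = state.numbers * np.exp(-z)
    return catch, out


def total_catch_at_effort(
    aggregate_effort: float,
    state: PopulationState,
    env: PatchEnvironment,
    params: SpeciesParams,
    config: FisheryConfig,
) -> float:
    """This year's total catch if aggregate effort were set as given."""
    fishable = fishable_biomass(state, env, params, config.selectivity_steepness)
    effort = distribute_aggregate_effort(
        config.catchability * aggregate_effort, fishable
    )
    catch, _ = harvest(
        state,
        effort,
        env,
        params,
        selectivity_steepness=config.selectivity_steepness,
    )
    return float(catch.sum())


def find_msy_effort(
    params: SpeciesParams,
    env: PatchEnvironment,
    config: FisheryConfig,
    kernel,
    *,
    grid_max_mean_f: float = 1.0,
    grid_points: int = 21,
    refine_tol: float = 1e-3,
) -> float:
    """Aggregate effort maximizing equilibrium catch of the no-farm system.

    Coarse grid over constant aggregate effort followed by golden-section
    refinement around the best grid cell.  Each candidate is scored by
    running the full dynamics to equilibrium; a candidate that fails to
    converge scores zero.
    """
    from .simulation import equilibrate_unfished, equilibrium_catch_at_constant_effort

    n = env.n_patches
    unfished = equilibrate_unfished(params, env, kernel)

    def score(aggregate: float) -> float:
        try:
            return equilibrium_catch_at_constant_effort(
                aggregate, params, env, config, kernel, unfished
            )
        except RuntimeError:
            logger.warning("non-convergent equilibrium at effort %.3f", aggregate)
            return 0.0

    grid = np.linspace(0.0, grid_max_mean_f * n, grid_points)
    yields = np.array([score(e) for e in grid])
    best = int(np.argmax(yields))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, grid_points - 1)]
    res = minimize_scalar(
        lambda e: -score(e),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": refine_tol * n},
    )
    return float(res.x)


def open_access_effort(
    state: PopulationState,
    env: PatchEnvironment,
    params: SpeciesParams,
    config: FisheryConfig,
) -> float:
    """Myopic profit-maximizing aggregate effort for the current year.

    Maximizes ``price * C_total(E) - cost_per_effort * E`` over
    ``E in [0, max_effort]`` for the stock as it stands right now; no
    anticipation of future stock effects.  Returns 0 when no positive
    effort is profitable.
    """
    if config.price <= 0:
        return 0.0

    def neg_profit(e: float) -> float:
        catch = total_catch_at_effort(e, state, env, params, config)
        return -(config.price * catch - config.cost_per_effort * e)

    res = minimize_scalar(
        neg_profit,
        bounds=(0.0, config.max_effort),
        method="bounded",
        options={"xatol": 1e-4 * config.max_effort},
    )
    best = float(res.x)
    if -res.fun <= 0.0:
        return 0.0
    return best
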