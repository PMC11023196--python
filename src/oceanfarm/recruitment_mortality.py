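"""Reproduction, larval settlement, natural mortality and aging.

Larvae are produced in proportion to mature biomass, pooled, and settle
uniformly across all patches — dispersal is deliberately well-mixed so
that spatial structure in the results comes from adult movement, not
larval transport.  Settlers then pass through a per-patch Beverton-Holt
survival bottleneck whose capacity scales with the patch carrying
capacity, giving compensatory (density-dependent) recruitment.

Natural mortality is the standard exponential survival ``exp(-M)``, with
an optional multiplier on M inside farm patches representing fitness
effects of farm residence (food subsidy lowers M, disease or pollution
raises it).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .life_history import PatchEnvironment, SpeciesParams

__all__ = [
    "PopulationState",
    "spawn",
    "settle_and_survive",
    "natural_survival",
    "advance_age",
]


@dataclass
class PopulationState:
    """Numbers and mean weight per patch and age class.

    ``numbers[i, a]`` is the abundance of age-a fish in patch i;
    ``weight_at_age[i, a]`` their current mean individual weight.  Weights
    are per-patch because growth is density dependent, so the same cohort
    can weigh differently where it has lived in crowded patches.
    """

    numbers: np.ndarray
    weight_at_age: np.ndarray
    year: int = 0

    def __post_init__(self) -> None:
        self.numbers = np.asarray(self.numbers, dtype=float)
        self.weight_at_age = np.asarray(self.weight_at_age, dtype=float)
        if self.numbers.shape != self.weight_at_age.shape:
            raise ValueError("numbers and weight_at_age shapes differ")
        if np.any(self.numbers < 0):
            raise ValueError("negative abundance")

    @property
    def n_patches(self) -> int:
        return self.numbers.shape[0]

    @property
    def n_ages(self) -> int:
        return self.numbers.shape[1]

    @property
    def biomass_by_patch(self) -> np.ndarray:
        return np.sum(self.numbers * self.weight_at_age, axis=1)

    @property
    def total_biomass(self) -> float:
        return float(np.sum(self.numbers * self.weight_at_age))

    def copy(self) -> "PopulationState":
        return PopulationState(
            self.numbers.copy(), self.weight_at_age.copy(), self.year
        )

    def to_frame(self):
        """Tidy snapshot: one row per (patch, age) with numbers and weight."""
        import pandas as pd

        patches, ages = np.meshgrid(
            np.arange(self.n_patches), np.arange(self.n_ages), indexing="ij"
        )
        return pd.DataFrame(
            {
                "patch": patches.ravel(),
                "age": ages.ravel(),
                "numbers": self.numbers.ravel(),
                "weight": self.weight_at_age.ravel(),
            }
        )


def spawn(state: PopulationState, params: SpeciesParams) -> float:
    """Total larval production: fecundity x spawning (mature) biomass."""
    mature = state.numbers[:, params.age_mature :] * state.weight_at_age[
        :, params.age_mature :
    ]
    return params.fecundity * float(np.sum(mature))


def settle_and_survive(
    larvae: float, env: PatchEnvironment, params: SpeciesParams
) -> np.ndarray:
    """Uniform settlement with per-patch Beverton-Holt survival.

    Each patch receives ``larvae / n_patches`` settlers; survivors are
    ``S / (1 + S / (recruit_steepness * K))``, saturating at
    ``recruit_steepness * K`` recruits however many larvae arrive.  The
    capacity uses the baseline (recruitment) carrying capacity, which
    farms do not alter.
    """
    if larvae < 0:
        raise ValueError("larvae must be non-negative")
    settlers = larvae / env.n_patches
    capacity = params.recruit_steepness * env.k_recruit
    return settlers / (1.0 + settlers / capacity)


def natural_survival(
    state: PopulationState,
    env: PatchEnvironment,
    params: SpeciesParams,
    farm_m_multiplier: float = 1.0,
) -> PopulationState:
    """Apply one year of natural mortality, patch by patch.

    Survival is ``exp(-M)`` outside farms and ``exp(-M * multiplier)``
    inside; a multiplier of 0.9 models a positive farm impact on fitness,
    1.1 a negative one.  Used only when fishing is absent — with fishing,
    natural and fishing mortality act through a single combined
    exponential in :func:`oceanfarm.fishing.harvest`.
    """
    m = effective_m(env, params, farm_m_multiplier)
    out = state.copy()
    out.numbers = out.numbers * np.exp(-m)[:, None]
    return out


def effective_m(
    env: PatchEnvironment, params: SpeciesParams, farm_m_multiplier: float
) -> np.ndarray:
    """Per-patch natural mortality with the farm fitness modifier applied."""
    if farm_m_multiplier <= 0:
        raise ValueError("farm_m_multiplier must be positive")
    m = np.full(env.n_patches, params.m_nat)
    m[env.is_farm] *= farm_m_multiplier
    return m


def advance_age(state: PopulationState) -> PopulationState:
    """Shift all cohorts up one age class.

    The terminal class is a plus group: incoming max_age-1 survivors merge
    with the residents, with the merged weight taken as the
    biomass-weighted mean.  The age-0 slot is cleared for next year's
    recruits.  Aging alone conserves total numbers.
    """
    n = state.numbers
    w = state.weight_at_age
    new_n = np.zeros_like(n)
    new_w = w.copy()
    new_n[:, 1:-1] = n[:, :-2]
    new_w[:, 1:-1] = w[:, :-2]
    # plus group: merge the two oldest classes, biomass-weighted weight
    merged_n = n[:, -2] + n[:, -1]
    merged_bm = n[:, -2] * w[:, -2] + n[:, -1] * w[:, -1]
    new_n[:, -1] = merged_n
    with np.errstate(invalid="ignore", divide="ignore"):
        new_w[:, -1] = np.where(merged_n > 0, merged_bm / merged_n, w[:, -1])
    new_n[:, 0] = 0.0
    new_w[:, 0] = 0.0
    return PopulationState(new_n, new_w, state.year)
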