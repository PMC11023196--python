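"""Default parameterization: a generic theoretical fishery stock.

No real stock is modeled; the defaults are round, generic teleost values
(von Bertalanffy L_inf = 100, k = 0.2, cubic weight-length, M = 0.2/yr,
maturity at age 4, legal size at the length of age 3, 20-year plus
group) on a wrapped lattice of 100 patches holding 1000 biomass units
unfished.  The default species is of low-to-moderate mobility (adult
home range 8% of the domain), comparable to the 5-patch farm clusters it
interacts with.  The weak regime's price/cost ratio is set so that the
open-access no-farm equilibrium is heavily overfished — a high-value
fishery — while the strong regime fishes at MSY found by search.  These
values are the reference conditions for all shipped analyses; change
them through a YAML config, not in code.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Optional

from .config import ScenarioConfig
from .farm_design import FarmDesign
from .fishing import STRONG_MSY, FisheryConfig
from .life_history import SpeciesParams
from .movement import sigma_from_range
from .scenarios import ScenarioGrid

__all__ = [
    "default_species",
    "default_fishery",
    "default_config",
    "default_grid",
    "N_PATCHES",
    "TOTAL_BIOMASS",
]

N_PATCHES = 100
TOTAL_BIOMASS = 1000.0
DEFAULT_MOVEMENT = 0.08
LEGAL_AGE = 3.0


def default_species(movement_fraction: float = DEFAULT_MOVEMENT) -> SpeciesParams:
    """Generic teleost life history at a given mobility.

    Maturity at age 4 with the legal (50%-selected) length set at the
    length of age 3, so the gear starts taking fish one year before they
    spawn; fecundity 2 larvae per unit spawning biomass keeps recruitment
    responsive to spawning stock rather than saturated.
    """
    sp = SpeciesParams(
        linf=100.0,
        k_growth=0.2,
        t0=0.0,
        b1=3.0,
        b2=1e-5,
        m_nat=0.2,
        max_age=20,
        age_mature=4,
        range_fraction=movement_fraction,
        sigma_m=sigma_from_range(movement_fraction, N_PATCHES),
        recruit_steepness=0.2,
        fecundity=2.0,
    )
    from dataclasses import replace as _replace

    from .life_history import length_at_age

    return _replace(sp, legal_length=float(length_at_age(LEGAL_AGE, sp)))


def default_fishery(regime: str = STRONG_MSY) -> FisheryConfig:
    """Fleet defaults; open-access economics make the fishery high-value,
    depleting the unmanaged stock well below the MSY level."""
    return FisheryConfig(
        regime=regime,
        total_effort=None,
        price=1.0,
        cost_per_effort=1.1,
        catchability=1.0,
        selectivity_steepness=0.25,
        max_effort=300.0,
    )


def default_config(
    regime: str = STRONG_MSY,
    movement_fraction: float = DEFAULT_MOVEMENT,
    farm: Optional[FarmDesign] = None,
) -> ScenarioConfig:
    return ScenarioConfig(
        species=default_species(movement_fraction),
        fishery=default_fishery(regime),
        farm=farm,
        n_patches=N_PATCHES,
        total_biomass_target=TOTAL_BIOMASS,
    )


def default_grid() -> ScenarioGrid:
    """The headline sweep: farm area 0-40% x attraction 1-15, both
    layouts, both regimes, at the default mobility."""
    return ScenarioGrid(
        farm_fractions=tuple(round(0.05 * k, 2) for k in range(9)),
        attraction_levels=(1.0, 2.0, 5.0, 10.0, 15.0),
        movement_fractions=(DEFAULT_MOVEMENT,),
        regimes=("strong_msy", "weak_open_access"),
        layouts=("one_large", "several_small"),
        m_multipliers=(1.0,),
    )
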