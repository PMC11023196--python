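"""Batch scenario sweeps over farm designs, attraction and management.

A :class:`ScenarioGrid` is the cross product of farm-area fractions,
attraction levels, movement rates, management regimes, layouts and
farm-mortality multipliers.  :func:`run_grid` expands the grid into
individual scenario configs, reuses one calibrated system and one BAU
(no-farm) equilibrium per (regime, movement) pair, and returns a tidy
table with one row per cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import pandas as pd

from .config import ScenarioConfig
from .farm_design import ONE_LARGE, SEVERAL_SMALL, FarmDesign
from .simulation import relative_outcomes, run_to_equilibrium, prepare_system

__all__ = ["ScenarioGrid", "run_grid", "summarize_max_benefit"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScenarioGrid:
    """Cross-product experiment design."""

    farm_fractions: Sequence[float] = tuple(0.05 * k for k in range(9))
    attraction_levels: Sequence[float] = (1.0, 2.0, 5.0, 10.0, 15.0)
    movement_fractions: Sequence[float] = (0.3,)
    regimes: Sequence[str] = ("strong_msy", "weak_open_access")
    layouts: Sequence[str] = (ONE_LARGE, SEVERAL_SMALL)
    m_multipliers: Sequence[float] = (1.0,)

    def __post_init__(self) -> None:
        for name in (
            "farm_fractions",
            "attraction_levels",
            "movement_fractions",
            "regimes",
            "layouts",
            "m_multipliers",
        ):
            if len(getattr(self, name)) == 0:
                raise ValueError(f"{name} must be non-empty")

    @property
    def n_cells(self) -> int:
        return (
            len(self.farm_fractions)
            * len(self.attraction_levels)
            * len(self.movement_fractions)
            * len(self.regimes)
            * len(self.layouts)
            * len(self.m_multipliers)
        )


def run_grid(
    grid: ScenarioGrid,
    base_config: ScenarioConfig,
    *,
    progress: bool = False,
) -> pd.DataFrame:
    """Run every grid cell; one tidy row each.

    BAU equilibria (and the MSY effort search) are computed once per
    (regime, movement) pair and shared across all farm cells of that
    pair.  A failing cell is flagged rather than aborting the sweep.
    """
    rows = []
    cells = [
        (regime, mv, layout, frac, attr, mmult)
        for regime in grid.regimes
        for mv in grid.movement_fractions
        for layout in grid.layouts
        for frac in grid.farm_fractions
        for attr in grid.attraction_levels
        for mmult in grid.m_multipliers
    ]
    iterator = cells
    if progress:
        try:
            from tqdm import tqdm

            iterator = tqdm(cells, desc="scenarios")
        except ImportError:
            pass
    cache: dict = {}
    failures = 0
    for regime, mv, layout, frac, attr, mmult in iterator:
        key = (regime, mv)
        cfg = replace(
            base_config,
            species=replace(base_config.species, range_fraction=mv),
            fishery=replace(base_config.fishery, regime=regime, total_effort=None),
        ).without_farm()
        if key not in cache:
            system = prepare_system(cfg)
            bau = run_to_equilibrium(cfg, _system=system)
            cache[key] = (system, bau)
        system, bau = cache[key]
        row = {
            "regime": regime,
            "movement_fraction": mv,
            "layout": layout,
            "farm_fraction": frac,
            "attraction": attr,
            "m_multiplier": mmult,
        }
        try:
            if frac == 0.0:
                farm_result = bau
            else:
                farm = FarmDesign(
                    total_fraction=frac,
                    layout=layout,
                    attraction=attr,
                    m_multiplier=mmult,
                )
                farm_result = run_to_equilibrium(
                    cfg.with_farm(farm),
                    _system=system,
                    _bau_state=bau.final_state,
                )
            rel = relative_outcomes(farm_result, bau)
            row.update(
                delta_b=rel.delta_b,
                delta_c=rel.delta_c,
                recovery_year=rel.recovery_year,
                converged=bool(farm_result.converged),
                equilibrium_biomass=farm_result.equilibrium_biomass,
                equilibrium_catch=farm_result.equilibrium_catch,
                failed=False,
            )
        except Exception as exc:  # noqa: BLE001 - sweep must survive bad cells
            failures += 1
            logger.warning("cell %s failed: %s", row, exc)
            row.update(
                delta_b=float("nan"),
                delta_c=float("nan"),
                recovery_year=None,
                converged=False,
                equilibrium_biomass=float("nan"),
                equilibrium_catch=float("nan"),
                failed=True,
            )
        rows.append(row)
    if failures:
        logger.warning("%d of %d cells failed", failures, len(cells))
    return pd.DataFrame(rows)


def summarize_max_benefit(
    table: pd.DataFrame, regime: str, layout: str
) -> float:
    """Maximum percent catch gain over BAU in a (regime, layout) slice.

    Returns ``100 * (max delta_C - 1)`` over all farm-fraction x
    attraction cells of the slice.
    """
    mask = (table["regime"] == regime) & (table["layout"] == layout)
    slice_ = table.loc[mask & ~table["failed"]]
    if slice_.empty:
        raise ValueError(f"no cells for regime={regime!r}, layout={layout!r}")
    return 100.0 * (slice_["delta_c"].max() - 1.0)
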