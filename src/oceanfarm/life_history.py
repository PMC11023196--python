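"""Species life history: growth, weight-at-age, and patch carrying capacity.

Individual length follows von Bertalanffy growth.  Weight-at-age is *density
dependent*: each year a cohort gains the weight increment implied by the
length-weight relation, scaled by ``(1 - bm_patch / K_patch)`` where
``bm_patch`` is the biomass currently occupying the patch.  Crowded patches
therefore slow individual growth, which is the mechanism that closes density
dependence on adult biomass.

Carrying capacity itself is not a free parameter: ``K_patch`` is defined as
the per-patch share of the equilibrium stock biomass with no fishing, and is
obtained by calibrating the full unfished dynamics against a configured
system-wide biomass target (see :func:`unfished_equilibrium`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpeciesParams",
    "PatchEnvironment",
    "length_at_age",
    "weight_length",
    "update_weight_at_age",
    "unfished_equilibrium",
]


@dataclass(frozen=True)
class SpeciesParams:
    """Biological constants for the simulated stock.

    Parameters
    ----------
    linf, k_growth, t0
        von Bertalanffy asymptotic length, growth rate (1/yr) and
        theoretical age at zero length (yr).
    b1, b2
        Allometric weight-length exponent and coefficient,
        ``w = b2 * L**b1``.
    m_nat
        Instantaneous natural mortality M (1/yr).
    max_age
        Terminal age; a plus group accumulating all older survivors.
    age_mature
        First age contributing to spawning biomass.
    sigma_m
        Gaussian movement-kernel scale in patches (0 = sessile).
    range_fraction
        Adult home range as a fraction of the simulated space; used to
        derive ``sigma_m`` when a kernel is built from a range.
    recruit_steepness
        Shape of per-patch density-dependent larval survival
        (Beverton-Holt capacity = recruit_steepness * K_patch).
    fecundity
        Larvae produced per unit spawning biomass per year.
    legal_length
        Minimum fishable length; anchors the selectivity curve.
    """

    linf: float = 100.0
    k_growth: float = 0.2
    t0: float = 0.0
    b1: float = 3.0
    b2: float = 1e-5
    m_nat: float = 0.2
    max_age: int = 20
    age_mature: int = 3
    sigma_m: float = 7.5
    range_fraction: float = 0.3
    recruit_steepness: float = 0.2
    fecundity: float = 20.0
    legal_length: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.linf <= 0 or self.k_growth <= 0 or self.m_nat <= 0:
            raise ValueError("linf, k_growth and m_nat must be positive")
        if self.b1 <= 0:
            raise ValueError("b1 must be positive")
        if self.max_age < 2:
            raise ValueError("max_age must be at least 2")
        if not 0.0 <= self.range_fraction <= 1.0:
            raise ValueError("range_fraction must lie in [0, 1]")
        if self.sigma_m < 0:
            raise ValueError("sigma_m must be non-negative")
        if self.legal_length is None:
            object.__setattr__(
                self, "legal_length", length_at_age(float(self.age_mature), self)
            )

    @property
    def ages(self) -> np.ndarray:
        """Integer age classes 0..max_age (max_age is the plus group)."""
        return np.arange(self.max_age + 1)


@dataclass
class PatchEnvironment:
    """Per-patch habitat attributes, stored as arrays over the lattice.

    ``k_patch`` is the carrying capacity of each patch (biomass units),
    the ceiling that density-dependent individual growth works against;
    farms raise it.  ``k_recruit`` is the capacity scale of the
    recruit-survival bottleneck and stays at the calibrated baseline in
    all scenarios — farm structure lets resident individuals grow, it
    does not create nursery habitat.  ``is_farm`` marks patches occupied
    by a farm (never fishable); ``in_zoi`` marks the zone of influence
    from which movement toward farms is biased.
    """

    k_patch: np.ndarray
    is_farm: np.ndarray
    in_zoi: np.ndarray
    k_recruit: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.k_patch = np.asarray(self.k_patch, dtype=float)
        self.is_farm = np.asarray(self.is_farm, dtype=bool)
        self.in_zoi = np.asarray(self.in_zoi, dtype=bool)
        if self.k_recruit is None:
            self.k_recruit = self.k_patch.copy()
        else:
            self.k_recruit = np.asarray(self.k_recruit, dtype=float)
        if np.any(self.k_patch <= 0) or np.any(self.k_recruit <= 0):
            raise ValueError("carrying capacities must be positive everywhere")

    @property
    def n_patches(self) -> int:
        return self.k_patch.size

    @classmethod
    def uniform(cls, n_patches: int, k_patch: float) -> "PatchEnvironment":
        """A featureless lattice: uniform K, no farms, no ZOI."""
        return cls(
            k_patch=np.full(n_patches, float(k_patch)),
            is_farm=np.zeros(n_patches, dtype=bool),
            in_zoi=np.zeros(n_patches, dtype=bool),
        )

    def copy(self) -> "PatchEnvironment":
        return PatchEnvironment(
            self.k_patch.copy(),
            self.is_farm.copy(),
            self.in_zoi.copy(),
            self.k_recruit.copy(),
        )


def length_at_age(age, params: SpeciesParams):
    """von Bertalanffy length at age, floored at zero.

    ``L(a) = linf * (1 - exp(-k * (a - t0)))``.
    """
    age = np.asarray(age, dtype=float)
    if np.any(age < 0):
        raise ValueError("age must be non-negative")
    length = params.linf * (1.0 - np.exp(-params.k_growth * (age - params.t0)))
    return np.maximum(length, 0.0)[()] if length.ndim == 0 else np.maximum(length, 0.0)


def weight_length(length, params: SpeciesParams):
    """Allometric weight from length: ``w = b2 * L**b1``."""
    return params.b2 * np.asarray(length, dtype=float) ** params.b1


def update_weight_at_age(w_age, L_age, L_next, bm_patch, k_patch, params: SpeciesParams):
    """Density-dependent annual weight increment.

    The cohort gains ``(b2*L_next**b1 - b2*L_age**b1) * (1 - bm/K)``.
    When patch biomass exceeds K (transiently possible at farms), the
    increment is clamped at zero rather than shrinking fish.
    """
    k_patch = np.asarray(k_patch, dtype=float)
    if np.any(k_patch <= 0):
        raise ValueError("k_patch must be positive")
    bm = np.asarray(bm_patch, dtype=float)
    if np.any(bm < 0):
        raise ValueError("bm_patch must be non-negative")
    increment = (weight_length(L_next, params) - weight_length(L_age, params)) * (
        1.0 - bm / k_patch
    )
    return np.asarray(w_age, dtype=float) + np.maximum(increment, 0.0)


class ConvergenceError(RuntimeError):
    """Raised when an equilibrium calibration fails to settle."""


def unfished_equilibrium(
    params: SpeciesParams,
    n_patches: int,
    total_biomass_target: float,
    *,
    max_rounds: int = 8,
    rel_tol: float = 1e-6,
) -> PatchEnvironment:
    """Calibrate uniform per-patch K so unfished equilibrium hits a target.

    Runs the full no-fishing dynamics to equilibrium under a trial K and
    rescales K by ``target / realized``; the dynamics are homogeneous of
    degree one in (K, abundance), so this converges in essentially one
    round, but the rescale-and-verify loop is repeated until the realized
    equilibrium biomass is within ``rel_tol`` of the target.
    """
    # local import: simulation drives the dynamics, but depends on this module
    from .simulation import equilibrate_unfished

    if n_patches < 1:
        raise ValueError("n_patches must be at least 1")
    k_guess = total_biomass_target / n_patches
    env = PatchEnvironment.uniform(n_patches, k_guess)
    last_rel = np.inf
    for _ in range(max_rounds):
        state = equilibrate_unfished(params, env)
        realized = float(np.sum(state.numbers * state.weight_at_age))
        last_rel = abs(realized - total_biomass_target) / total_biomass_target
        if last_rel < rel_tol:
            return env
        env = PatchEnvironment.uniform(
            n_patches, env.k_patch[0] * total_biomass_target / realized
        )
    raise ConvergenceError(
        f"carrying-capacity calibration did not converge: last relative "
        f"deviation {last_rel:.3g}"
    )
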