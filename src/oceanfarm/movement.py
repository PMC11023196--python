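"""Adult movement on the wrapped 1-D lattice.

Movement is a row-stochastic Gaussian kernel: the probability of moving
from patch i to patch j falls off as ``exp(-d_ij^2 / (2 sigma_m^2))`` with
``d_ij`` the wrapped (toroidal) distance, and each row is normalized so a
fish always ends up somewhere.  Farms modify the kernel through an
attraction multiplier A >= 1 that widens the Gaussian toward farm
destinations for fish inside the farms' zone of influence, i.e. the weight
becomes ``exp(-d^2 / (A * 2 sigma_m^2))``, inflating the probability of
moving onto a farm patch at the expense of everywhere else in the row.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MovementKernel",
    "wrapped_distance",
    "sigma_from_range",
    "build_kernel",
    "apply_attraction",
    "move",
]


@dataclass(frozen=True)
class MovementKernel:
    """Row-stochastic patch-to-patch movement probabilities."""

    probs: np.ndarray
    sigma_m: float
    attraction: float = 1.0

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", probs)
        if probs.ndim != 2 or probs.shape[0] != probs.shape[1]:
            raise ValueError("kernel must be a square matrix")
        if np.any(probs < 0):
            raise ValueError("movement probabilities must be non-negative")
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("kernel rows must sum to 1")

    @property
    def n_patches(self) -> int:
        return self.probs.shape[0]

    def to_csv(self, path) -> None:
        """Write the probability matrix as plain CSV for inspection."""
        np.savetxt(path, self.probs, delimiter=",")


def wrapped_distance(i, j, n: int):
    """Shortest distance between patches on the wrapped lattice."""
    i = np.asarray(i)
    j = np.asarray(j)
    if np.any(i < 0) or np.any(i >= n) or np.any(j < 0) or np.any(j >= n):
        raise ValueError(f"patch indices must lie in [0, {n})")
    d = np.abs(i - j)
    return np.minimum(d, n - d)


def sigma_from_range(range_fraction: float, n: int) -> float:
    """Kernel scale from a species' home-range fraction of the space.

    The range is read as the +/-2 sigma span of the kernel, so
    ``sigma_m = range_fraction * n / 4``; a range fraction of zero gives a
    sessile species (sigma_m = 0).
    """
    if not 0.0 <= range_fraction <= 1.0:
        raise ValueError("range_fraction must lie in [0, 1]")
    return range_fraction * n / 4.0


def _gaussian_weights(n: int, sigma_m: float) -> np.ndarray:
    """Unnormalized Gaussian weights over wrapped distances; identity if sessile."""
    if sigma_m == 0:
        return np.eye(n)
    idx = np.arange(n)
    d = wrapped_distance(idx[:, None], idx[None, :], n)
    return np.exp(-(d.astype(float) ** 2) / (2.0 * sigma_m**2))


def build_kernel(sigma_m: float, n: int) -> MovementKernel:
    """Row-normalized wrapped Gaussian kernel; sigma_m = 0 yields identity."""
    if n < 1:
        raise ValueError("n must be at least 1")
    if sigma_m < 0:
        raise ValueError("sigma_m must be non-negative")
    w = _gaussian_weights(n, sigma_m)
    return MovementKernel(w / w.sum(axis=1, keepdims=True), sigma_m=sigma_m)


def apply_attraction(
    base: MovementKernel,
    farm_patches,
    zoi_patches,
    attraction: float,
) -> MovementKernel:
    """Bias movement from ZOI patches toward farm patches.

    Rows i in the ZOI get their unnormalized weight toward each farm
    column j replaced by ``exp(-d_ij^2 / (A * 2 sigma^2))`` — attraction
    widens the Gaussian toward farm destinations, extending the reach
    from which farms recruit movers; rows are then renormalized, so the
    probability of ending up on a farm patch rises at the expense of all
    other destinations.  A = 1 reproduces the base kernel exactly.  A
    sessile kernel (sigma_m = 0) is unchanged: fish that do not move
    cannot be attracted.
    """
    if attraction < 1.0:
        raise ValueError("attraction must be >= 1")
    n = base.n_patches
    farm = np.asarray(sorted(farm_patches), dtype=int)
    zoi = np.asarray(sorted(zoi_patches), dtype=int)
    if attraction == 1.0 or farm.size == 0 or zoi.size == 0 or base.sigma_m == 0:
        return MovementKernel(
            base.probs.copy(), sigma_m=base.sigma_m, attraction=attraction
        )
    w = _gaussian_weights(n, base.sigma_m)
    d = wrapped_distance(zoi[:, None], farm[None, :], n).astype(float)
    w[np.ix_(zoi, farm)] = np.exp(-(d**2) / (attraction * 2.0 * base.sigma_m**2))
    return MovementKernel(
        w / w.sum(axis=1, keepdims=True),
        sigma_m=base.sigma_m,
        attraction=attraction,
    )


def move(abundance: np.ndarray, kernel: MovementKernel) -> np.ndarray:
    """Redistribute a patch x age array through the kernel.

    ``out[j, a] = sum_i abundance[i, a] * p_ij``; per-age totals are
    conserved because rows are stochastic.
    """
    abundance = np.asarray(abundance, dtype=float)
    if abundance.shape[0] != kernel.n_patches:
        raise ValueError(
            f"abundance has {abundance.shape[0]} patches, kernel expects "
            f"{kernel.n_patches}"
        )
    if np.any(abundance < 0):
        raise ValueError("abundance must be non-negative")
    return kernel.probs.T @ abundance
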