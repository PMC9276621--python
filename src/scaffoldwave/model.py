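"""Constitutive laws and non-dimensionalisation for the multiphase scaffold model.

The tissue is described by a cell volume fraction ``n``, an extra-cellular
liquid fraction ``w`` and a rigid scaffold fraction ``s`` with
``n + w + s = 1``.  Darcy closure of the two-fluid momentum balance reduces
the mechanics to a single nonlinear diffusivity ``Phi(n)`` built from the
derivative of the extra cell-phase pressure ``Sigma(n)``.  After
non-dimensionalisation the dynamics depend only on the dimensionless group
``(kappa, s, mu, eta)`` where

* ``kappa = 1 - s - r_a/r_m`` is the net growth parameter (its sign selects
  the large-time regime),
* ``mu = mu_w / mu_n`` is the liquid/cell viscosity ratio,
* ``eta = nu / delta`` is the dispersal/repulsion interaction ratio.

All constitutive functions are pure and accept scalars or numpy arrays of
``n``; they sit in the inner loop of the PDE solver and the phase-plane
shooting integrator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np

__all__ = [
    "DimensionalParameters",
    "NondimParameters",
    "NondimScales",
    "sigma",
    "dsigma_dn",
    "Phi",
    "phi",
    "gamma",
    "nondimensionalise",
    "steady_state_eigenvalues",
    "DOMAIN_MARGIN",
]

ArrayLike = Union[float, np.ndarray]

#: evaluation is refused within this margin of the packing singularity n = 1 - s
DOMAIN_MARGIN = 1e-9


@dataclass(frozen=True)
class DimensionalParameters:
    """Lab-scale parameters of the three-phase model.

    Attributes
    ----------
    r_m, r_a : float
        Mitosis and apoptosis rates (1/time); ``r_m > 0``, ``r_a >= 0``.
    K : float
        Scaffold permeability (length^2).
    mu_n, mu_w : float
        Cell- and liquid-phase viscosities (pressure * time), independent
        of ``n``.
    delta : float
        Cell-cell / cell-scaffold repulsion coefficient (pressure); the
        model uses a single ``delta`` for both contact terms.
    nu : float
        Cell dispersal coefficient (pressure).  Restricted to ``nu > 0`` so
        the effective diffusivity is strictly positive (dispersal, not
        aggregation).
    chi : float
        Cell-scaffold attraction coefficient (pressure, >= 0).  It enters
        the pressure ``Sigma`` only through a constant offset, so it is
        dynamically inert; it is kept for completeness.
    s : float
        Scaffold volume fraction, ``0 < s < 1``; porosity is ``1 - s``.
    """

    r_m: float
    r_a: float
    K: float
    mu_n: float
    mu_w: float
    delta: float
    nu: float
    chi: float
    s: float

    def __post_init__(self) -> None:
        if self.r_m <= 0:
            raise ValueError(f"mitosis rate r_m must be > 0, got {self.r_m}")
        if self.r_a < 0:
            raise ValueError(f"apoptosis rate r_a must be >= 0, got {self.r_a}")
        for name in ("K", "mu_n", "mu_w", "delta"):
            v = getattr(self, name)
            if v <= 0:
                raise ValueError(f"{name} must be > 0, got {v}")
        if self.nu <= 0:
            raise ValueError(
                f"nu must be > 0 (dispersal regime; aggregation nu <= 0 is "
                f"outside the model's validity), got {self.nu}"
            )
        if self.chi < 0:
            raise ValueError(f"chi must be >= 0, got {self.chi}")
        if not 0 < self.s < 1:
            raise ValueError(f"scaffold fraction s must lie in (0, 1), got {self.s}")


@dataclass(frozen=True)
class NondimParameters:
    """The dimensionless group (kappa, s, mu, eta) governing all dynamics.

    ``kappa <= 1 - s`` always (equality only for zero apoptosis).  On
    construction the normalised diffusivity ``phi`` is checked to be
    strictly positive on a grid over ``[0, 1 - s)``; ``eta > 0`` guarantees
    this analytically but ``mu`` can break it through the mixture-viscosity
    denominator, so the numerical check guards the whole expression.
    """

    kappa: float
    s: float
    mu: float = 1.0
    eta: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.s < 1:
            raise ValueError(f"scaffold fraction s must lie in (0, 1), got {self.s}")
        if self.mu <= 0:
            raise ValueError(f"viscosity ratio mu must be > 0, got {self.mu}")
        if self.eta <= 0:
            raise ValueError(f"interaction ratio eta must be > 0, got {self.eta}")
        if self.kappa > 1 - self.s + 1e-12:
            raise ValueError(
                f"kappa = {self.kappa} exceeds 1 - s = {1 - self.s}; "
                "kappa = 1 - s - r_a/r_m cannot exceed the porosity"
            )
        grid = np.linspace(0.0, 1 - self.s - 1e-6, 512)
        vals = phi(grid, self)
        if not np.all(vals > 0):
            raise ValueError(
                "normalised diffusivity phi(n) is not strictly positive on "
                f"[0, 1-s) for (s={self.s}, mu={self.mu}, eta={self.eta})"
            )

    @property
    def n_max(self) -> float:
        """Packing limit 1 - s (cells plus scaffold fill all space)."""
        return 1.0 - self.s


@dataclass(frozen=True)
class NondimScales:
    """Characteristic scales removed by the non-dimensionalisation."""

    time_scale: float  # 1 / r_m
    length_scale: float  # sqrt(Phi(0) / r_m)
    Phi0: float  # dimensional diffusivity at n = 0

    def __post_init__(self) -> None:
        for name in ("time_scale", "length_scale", "Phi0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def _check_domain(n: ArrayLike, s: float) -> np.ndarray:
    n = np.asarray(n, dtype=float)
    if np.any(n < 0):
        raise ValueError("cell fraction n must be >= 0")
    if np.any(n >= 1 - s - DOMAIN_MARGIN):
        raise ValueError(
            f"cell fraction n must stay below the packing limit 1 - s = {1 - s}"
        )
    return n


def sigma(n: ArrayLike, p: DimensionalParameters) -> ArrayLike:
    """Extra cell-phase pressure Sigma(n) from cell-cell and cell-scaffold contact.

    Sigma(n) = delta n^2/(1-n-s) + nu n + delta s n/(1-n-s) - chi s.

    The first term is the contact repulsion that diverges at the packing
    limit ``n = 1 - s``; ``nu n`` is the dispersal pressure; the third term
    is cell-scaffold repulsion and ``-chi s`` a constant scaffold
    attraction offset.
    """
    n = _check_domain(n, p.s)
    free = 1.0 - n - p.s
    out = p.delta * n**2 / free + p.nu * n + p.delta * p.s * n / free - p.chi * p.s
    return out if out.shape else float(out)


def dsigma_dn(n: ArrayLike, p: DimensionalParameters) -> ArrayLike:
    """Analytic derivative d Sigma / d n; the attraction term chi drops out."""
    n = _check_domain(n, p.s)
    free = 1.0 - n - p.s
    out = (
        p.delta * (2 * n * free + n**2) / free**2
        + p.nu
        + p.delta * p.s * (1 - p.s) / free**2
    )
    return out if out.shape else float(out)


def Phi(n: ArrayLike, p: DimensionalParameters) -> ArrayLike:
    """Dimensional nonlinear diffusivity Phi(n) of the reduced cell equation.

    Phi(n) = K (1-n-s) / [mu_n (1-n-s) + mu_w n] * dSigma/dn,
    strictly positive on [0, 1-s) because ``nu > 0``.
    """
    n = _check_domain(n, p.s)
    free = 1.0 - n - p.s
    out = p.K * free / (p.mu_n * free + p.mu_w * n) * np.asarray(dsigma_dn(n, p))
    return out if out.shape else float(out)


def phi(n: ArrayLike, q: NondimParameters) -> ArrayLike:
    """Normalised diffusivity phi(n) = Phi(n)/Phi(0); phi(0) = 1 exactly.

    phi(n) = (1-s)(1-n-s) / [(eta(1-s)+s)(1-(1-mu)n-s)]
             * [(1-s)/(1-n-s)^2 + eta - 1].

    The mixture-viscosity factor 1-(1-mu)n-s comes from factoring mu_n out
    of mu_n(1-n-s) + mu_w n, so phi is identically Phi(n)/Phi(0); small mu
    (cells far more viscous than liquid) raises phi and speeds the front.
    """
    n = np.asarray(n, dtype=float)
    s, mu, eta = q.s, q.mu, q.eta
    if np.any(n < 0):
        raise ValueError("cell fraction n must be >= 0")
    if np.any(n >= 1 - s - DOMAIN_MARGIN):
        raise ValueError(
            f"cell fraction n must stay below the packing limit 1 - s = {1 - s}"
        )
    free = 1.0 - n - s
    mix = 1.0 - (1.0 - mu) * n - s  # mixture-viscosity factor, scaled by 1/mu_n
    if np.any(mix <= 0):
        raise ValueError(
            "mixture-viscosity factor 1 - (mu-1) n - s is non-positive; "
            "phi is undefined there"
        )
    out = (
        (1 - s) * free / ((eta * (1 - s) + s) * mix)
        * ((1 - s) / free**2 + eta - 1.0)
    )
    return out if out.shape else float(out)


def gamma(n: ArrayLike, kappa: float) -> ArrayLike:
    """Dimensionless net cell production n(kappa - n) (logistic with cap kappa)."""
    n = np.asarray(n, dtype=float)
    if np.any(n < 0):
        raise ValueError("cell fraction n must be >= 0")
    out = n * (kappa - n)
    return out if out.shape else float(out)


def nondimensionalise(p: DimensionalParameters) -> tuple[NondimParameters, NondimScales]:
    """Reduce lab-scale parameters to the dimensionless group plus scales.

    kappa = 1 - s - r_a/r_m, mu = mu_w/mu_n, eta = nu/delta; time is scaled
    by 1/r_m and length by sqrt(Phi(0)/r_m).  The permeability ``K`` drops
    out of the dimensionless model but enters the length scale, so the
    dimensional front position grows with scaffold permeability.
    """
    q = NondimParameters(
        kappa=1.0 - p.s - p.r_a / p.r_m,
        s=p.s,
        mu=p.mu_w / p.mu_n,
        eta=p.nu / p.delta,
    )
    phi0 = float(Phi(0.0, p))
    scales = NondimScales(
        time_scale=1.0 / p.r_m,
        length_scale=float(np.sqrt(phi0 / p.r_m)),
        Phi0=phi0,
    )
    return q, scales


def steady_state_eigenvalues(kappa: float) -> tuple[float, float]:
    """Linear growth rates of the spatially uniform steady states n=0 and n=kappa.

    Linearising the production term n(kappa - n) gives dGamma/dn = kappa at
    n = 0 and -kappa at n = kappa: extinction is stable for kappa < 0 and
    the carrying-capacity state n = kappa is stable for kappa > 0.
    """
    return float(kappa), float(-kappa)
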