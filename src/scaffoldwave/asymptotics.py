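"""Closed-form solutions of the growth model for |kappa| << 1.

When the net growth parameter is small the substitution

    n = e^{kappa t} N(x, T),      T = (e^{kappa t} - 1) / kappa,

maps the model (with phi ~ 1, valid since n << 1 at large time) onto the
kappa = 0 problem

    dN/dT = d/dx(N dN/dx) - N^2,      dL/dT = -dN/dx(L, T).

This problem admits an exact two-mode closure N = A(T) - B(T) cosh(x/sqrt 2)
with

    dA/dT = -A^2 - B^2/2,     dB/dT = -3 A B / 2,
    L(T) = sqrt(2) acosh(A/B),

whose implicit solution is

    N(x,T) = (alpha/2) csch^3(L/sqrt2) [cosh(L/sqrt2) - cosh(x/sqrt2)],
    sinh(sqrt2 L) - sqrt2 L = alpha T + beta,

with alpha = 2 B0^{-2} (A0^2 - B0^2)^{3/2} and
beta = sinh(sqrt2 L0) - sqrt2 L0 fixed by the initial amplitudes.  Mapping
back gives explicit large-time laws: the front grows logarithmically with
slope 1/sqrt(2) in ln T, travels at c ~ kappa/sqrt(2) for 0 < kappa << 1,
and stalls at a finite L_infinity for kappa < 0.  For general initial data
the same structure emerges with a single data-dependent constant m
(N ~ 1/T - m cosh(x/sqrt2) T^{-3/2}); ``fit_m`` estimates m from a
simulated trajectory.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .pde_solver import Trajectory

__all__ = [
    "AsymptoticParameters",
    "CoshModeState",
    "transform_time",
    "alpha_beta",
    "solve_L_implicit",
    "N_profile",
    "AB_from_L",
    "closure_residual",
    "integrate_AB",
    "L_largeT",
    "L_smallkappa",
    "L_infinity",
    "n_smallkappa",
    "interior_layer_f",
    "general_ic_forms",
    "fit_m",
]

SQRT2 = np.sqrt(2.0)


@dataclass(frozen=True)
class AsymptoticParameters:
    """Constants of the cosh-mode closure fixed by the initial amplitudes."""

    A0: float
    B0: float
    alpha: float
    beta: float
    L0: float
    m: float | None = None


@dataclass(frozen=True)
class CoshModeState:
    """Amplitudes of the two-mode ansatz at transformed times T."""

    T: np.ndarray
    A: np.ndarray
    B: np.ndarray


def transform_time(t, kappa: float):
    """Transformed time T = (e^{kappa t} - 1)/kappa, with T = t at kappa = 0.

    Uses expm1 so the small-|kappa t| limit is free of cancellation; for
    kappa < 0, T saturates at 1/|kappa| as t -> infinity.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    if kappa == 0:
        out = t.copy()
    else:
        out = np.expm1(kappa * t) / kappa
    return out if out.shape else float(out)


def alpha_beta(A0: float, B0: float) -> AsymptoticParameters:
    """Closure constants alpha, beta and implied front L0 from (A0, B0)."""
    if not 0 < B0 < A0:
        raise ValueError(f"amplitudes must satisfy 0 < B0 < A0, got {(A0, B0)}")
    L0 = SQRT2 * np.arccosh(A0 / B0)
    alpha = 2.0 * B0**-2 * (A0**2 - B0**2) ** 1.5
    beta = np.sinh(SQRT2 * L0) - SQRT2 * L0
    return AsymptoticParameters(A0=A0, B0=B0, alpha=alpha, beta=beta, L0=float(L0))


def _implicit_lhs(L: float) -> float:
    return np.sinh(SQRT2 * L) - SQRT2 * L


def solve_L_implicit(T, ap: AsymptoticParameters):
    """Front position from the implicit law sinh(sqrt2 L) - sqrt2 L = alpha T + beta.

    The left side is a strictly increasing bijection on L > 0, so the root
    is unique.  Solved by bracketed Brent iteration seeded by the large-T
    expansion (the right side spans many decades).
    """
    T_arr = np.atleast_1d(np.asarray(T, dtype=float))
    if np.any(T_arr < 0):
        raise ValueError("transformed time T must be >= 0")
    out = np.empty_like(T_arr)
    for i, Ti in enumerate(T_arr):
        rhs = ap.alpha * Ti + ap.beta
        if rhs <= 0:
            out[i] = 0.0
            continue
        # seed from the exponential-dominated inversion, with a safe bracket
        seed = np.log(2.0 * rhs + 2.0) / SQRT2 + 1.0
        lo, hi = 0.0, max(seed, ap.L0 + 1.0)
        while _implicit_lhs(hi) < rhs:
            hi *= 2.0
        out[i] = brentq(lambda L: _implicit_lhs(L) - rhs, lo, hi, xtol=1e-13)
    return out if np.asarray(T).shape else float(out[0])


def N_profile(x, L: float, ap: AsymptoticParameters):
    """Cosh-mode profile N(x) at front position L; N(L) = 0, maximal at x = 0."""
    x = np.asarray(x, dtype=float)
    u = L / SQRT2
    csch3 = 1.0 / np.sinh(u) ** 3
    out = 0.5 * ap.alpha * csch3 * (np.cosh(u) - np.cosh(x / SQRT2))
    return out if out.shape else float(out)


def AB_from_L(L, ap: AsymptoticParameters):
    """Amplitudes (A, B) read off the implicit solution at front position L."""
    L = np.asarray(L, dtype=float)
    u = L / SQRT2
    B = 0.5 * ap.alpha / np.sinh(u) ** 3
    A = B * np.cosh(u)
    return A, B


def closure_residual(T, ap: AsymptoticParameters) -> tuple[np.ndarray, np.ndarray]:
    """Residuals of dA/dT = -A^2 - B^2/2 and dB/dT = -3AB/2 along the
    implicit solution.

    Differentiating the implicit front law gives
    dL/dT = alpha / (sqrt2 (cosh(sqrt2 L) - 1)); chaining through
    (A, B)(L) yields analytic time derivatives to compare against the
    planar ODE system.  The closure is exact, so the residuals are zero up
    to rounding.
    """
    T = np.atleast_1d(np.asarray(T, dtype=float))
    L = np.atleast_1d(solve_L_implicit(T, ap))
    u = L / SQRT2
    A, B = AB_from_L(L, ap)
    dLdT = ap.alpha / (SQRT2 * (np.cosh(SQRT2 * L) - 1.0))
    # d/dL of B = (alpha/2) csch^3(u), A = B cosh(u), with du/dL = 1/sqrt2
    dBdL = -3.0 * B * np.cosh(u) / np.sinh(u) / SQRT2
    dAdL = dBdL * np.cosh(u) + B * np.sinh(u) / SQRT2
    res_A = dAdL * dLdT - (-(A**2) - B**2 / 2.0)
    res_B = dBdL * dLdT - (-1.5 * A * B)
    return res_A, res_B


def integrate_AB(
    A0: float, B0: float, T_end: float, T_eval=None, rtol: float = 1e-11, atol: float = 1e-14
) -> CoshModeState:
    """Numerically integrate the planar amplitude system from (A0, B0)."""
    if not 0 < B0 < A0:
        raise ValueError(f"amplitudes must satisfy 0 < B0 < A0, got {(A0, B0)}")

    def rhs(T, y):
        A, B = y
        return [-(A**2) - B**2 / 2.0, -1.5 * A * B]

    sol = solve_ivp(
        rhs, (0.0, T_end), [A0, B0], method="LSODA", rtol=rtol, atol=atol, t_eval=T_eval
    )
    if not sol.success:
        raise RuntimeError(f"amplitude integration failed: {sol.message}")
    return CoshModeState(T=sol.t, A=sol.y[0], B=sol.y[1])


def L_largeT(T, ap: AsymptoticParameters):
    """Two-term large-T front law L ~ ln(2 alpha T)/sqrt2 * (1 + 1/(alpha T))."""
    T = np.asarray(T, dtype=float)
    if np.any(2.0 * ap.alpha * T <= 1.0):
        raise ValueError("L_largeT requires 2 alpha T > 1")
    out = np.log(2.0 * ap.alpha * T) / SQRT2 * (1.0 + 1.0 / (ap.alpha * T))
    return out if out.shape else float(out)


def _validity_warning(t, kappa: float) -> None:
    # the small-kappa forms require t >> 1 (and |kappa| << 1); warn, never
    # refuse — callers may deliberately probe the crossover
    if np.min(np.asarray(t, dtype=float)) < 1.0:
        warnings.warn(
            "small-kappa asymptotics requested at t < 1; the forms hold for t >> 1",
            stacklevel=3,
        )
    if abs(kappa) > 0.1:
        warnings.warn(
            f"small-kappa asymptotics requested at |kappa| = {abs(kappa)}; "
            "accuracy degrades unless mu << 1 and eta >> 1",
            stacklevel=3,
        )


def L_smallkappa(t, kappa: float, ap: AsymptoticParameters):
    """Front position for |kappa| << 1 and t >> 1.

    L ~ (1/sqrt2) ln(2 alpha (e^{kappa t}-1)/kappa)
        * (1 + kappa/(alpha (e^{kappa t}-1))).

    For kappa > 0 this crosses over from logarithmic growth to the linear
    law L ~ kappa t / sqrt2 at t = O(1/kappa); for kappa < 0 it saturates
    at L_infinity.  At kappa = 0 it reduces to the large-T law with T = t.
    """
    t = np.asarray(t, dtype=float)
    _validity_warning(t, kappa)
    if kappa == 0:
        return L_largeT(t, ap)
    u = kappa * t
    # log T = log(|expm1(u)|/|kappa|), in log space so large kappa*t cannot
    # overflow: for u > 0, log(expm1(u)) = u + log1p(-e^{-u})
    if kappa > 0:
        log_T = u + np.log1p(-np.exp(-u)) - np.log(kappa)
    else:
        log_T = np.log(-np.expm1(u) / abs(kappa))
    inv_alphaT = np.exp(-log_T) / ap.alpha
    out = (np.log(2.0 * ap.alpha) + log_T) / SQRT2 * (1.0 + inv_alphaT)
    return out if out.shape else float(out)


def L_infinity(kappa: float, alpha: float) -> float:
    """Stationary front position for kappa < 0, |kappa| << 1:
    L_inf ~ (1/sqrt2) ln(2 alpha/|kappa|) (1 + |kappa|/alpha)."""
    if kappa >= 0:
        raise ValueError("the stationary front exists only for kappa < 0")
    ak = abs(kappa)
    return float(np.log(2.0 * alpha / ak) / SQRT2 * (1.0 + ak / alpha))


def n_smallkappa(x, t, kappa: float, ap: AsymptoticParameters):
    """Large-time cell fraction for |kappa| << 1.

    kappa > 0:  n ~ kappa - sqrt(2 kappa^3/alpha) cosh(x/sqrt2) e^{-kappa t/2}
    kappa < 0:  n ~ |k| e^{-|k|t}/(1-e^{-|k|t})
                    [1 - sqrt(2|k|/(alpha(1-e^{-|k|t}))) cosh(x/sqrt2)]
    kappa = 0:  the general form N ~ 1/t - m cosh(x/sqrt2) t^{-3/2} with
                m = sqrt(2/alpha).
    """
    x = np.asarray(x, dtype=float)
    t_arr = np.asarray(t, dtype=float)
    _validity_warning(t_arr, kappa)
    if kappa > 0:
        out = kappa - np.sqrt(2.0 * kappa**3 / ap.alpha) * np.cosh(x / SQRT2) * np.exp(
            -kappa * t_arr / 2.0
        )
    elif kappa < 0:
        ak = abs(kappa)
        decay = np.exp(-ak * t_arr)
        pref = ak * decay / (1.0 - decay)
        out = pref * (
            1.0 - np.sqrt(2.0 * ak / (ap.alpha * (1.0 - decay))) * np.cosh(x / SQRT2)
        )
    else:
        m = np.sqrt(2.0 / ap.alpha)
        N, _ = general_ic_forms(float(t_arr), m, x=x)
        out = np.asarray(N)
    return out if out.shape else float(out)


def interior_layer_f(theta):
    """Similarity profile f(theta) = 1 - e^{theta/sqrt2} in the layer at the
    front (theta = x - L <= 0); the layer fixes the logarithmic front
    coefficient b = 1/sqrt2."""
    theta = np.asarray(theta, dtype=float)
    if np.any(theta > 1e-12):
        raise ValueError("layer coordinate theta must be <= 0")
    out = 1.0 - np.exp(theta / SQRT2)
    return out if out.shape else float(out)


def general_ic_forms(T: float, m: float, x=None):
    """Large-T forms for general initial data with constant m:

    N(x, T) = 1/T - m cosh(x/sqrt2) T^{-3/2},
    L(T) = sqrt2 acosh(sqrt(T)/m).

    Returns ``(N, L)``; N is evaluated on ``x`` (defaults to a uniform grid
    on [0, L]).
    """
    if m <= 0:
        raise ValueError("m must be > 0")
    if T <= m**2:
        raise ValueError("general_ic_forms requires T > m^2 (front exists)")
    L = float(SQRT2 * np.arccosh(np.sqrt(T) / m))
    if x is None:
        x = np.linspace(0.0, L, 201)
    x = np.asarray(x, dtype=float)
    N = 1.0 / T - m * np.cosh(x / SQRT2) * T ** -1.5
    return (N if N.shape else float(N)), L


def fit_m(
    tr_or_TL: "Trajectory | tuple[np.ndarray, np.ndarray]",
    tail_fraction: float = 0.5,
    min_decade: bool = True,
) -> tuple[float, float]:
    """Estimate the initial-data constant m from the tail of L(T).

    Inverts the front law through y = ln cosh(L/sqrt2) = 0.5 ln T - ln m
    and fits ln m by least squares in (ln T, y) with the slope pinned at
    1/2 (the law is linear in ln T at large T, so the fit is
    deterministic).  Returns ``(m, residual)`` where the residual is the
    RMS deviation of y around the fitted line; warns when the tail spans
    less than a decade.
    """
    if isinstance(tr_or_TL, tuple):
        T, L = tr_or_TL
    else:
        T, L = tr_or_TL.times, tr_or_TL.L_values
    T = np.asarray(T, dtype=float)
    L = np.asarray(L, dtype=float)
    mask = T >= (1 - tail_fraction) * T[-1]
    mask &= T > 0
    Tt, Lt = T[mask], L[mask]
    if Tt.size < 3:
        raise ValueError("fit_m needs at least three tail samples")
    if min_decade and Tt[-1] / Tt[0] < 2.0:
        warnings.warn("fit_m tail spans less than a factor of 2 in T", stacklevel=2)
    y = np.log(np.cosh(Lt / SQRT2))
    ln_m = float(np.mean(0.5 * np.log(Tt) - y))
    resid = float(np.sqrt(np.mean((y - (0.5 * np.log(Tt) - ln_m)) ** 2)))
    return float(np.exp(ln_m)), resid
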