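"""Travelling-wave speed by phase-plane shooting.

For kappa > 0 the tissue edge advances as a semi-infinite travelling wave
n(z), z = x - c t <= 0, connecting the carrying-capacity state n = kappa
far behind the front to the sharp edge n(0) = 0.  With the flux variable
q(z) = phi(n) dn/dz the wave is a heteroclinic orbit of

    dq/dn = -[ q (c + q) + n (kappa - n) phi(n) ] / (q n),

from (n, q) = (kappa, 0) to (0, -c): the unknown speed c is the value for
which the orbit launched from the saddle at (kappa, 0) lands exactly on
q = -c as n -> 0.  Both endpoints are singular, so the orbit is launched a
small offset epsilon below kappa along the local linearisation (slope
lambda solving kappa lambda^2 + c lambda - kappa phi(kappa) = 0) and
integrated down to a small floor in n; c is then found by bisecting on the
terminal mismatch q + c.  Orbits with c too large stay too shallow and
curve up to q = 0 before reaching n = 0 (overshoot); orbits with c too
small dive to q -> -infinity (blow-up).  The sign convention
F(c) = q_terminal + c (> 0 for c too large) is verified empirically when
the bracket is built rather than assumed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.integrate import solve_ivp

from .model import NondimParameters, phi

__all__ = [
    "PhasePlaneProblem",
    "WaveSpeedResult",
    "BracketError",
    "phase_rhs",
    "series_start",
    "integrate_heteroclinic",
    "wave_speed_shooting",
    "wave_profile",
]

Outcome = Literal["reached_axis", "overshoot", "blow_up", "failure"]


class BracketError(RuntimeError):
    """The candidate-speed bracket does not straddle the heteroclinic."""


@dataclass(frozen=True)
class PhasePlaneProblem:
    """Shooting setup for the (n, q) phase plane.

    ``epsilon`` is the launch offset below the saddle n = kappa and
    ``n_floor`` the small positive value of n at which the orbit is
    evaluated against q = -c; results must be insensitive to halving both.
    """

    params: NondimParameters
    epsilon: float | None = None
    n_floor: float | None = None
    c_bracket: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.params.kappa <= 0:
            raise ValueError("travelling waves require kappa > 0")
        eps = self.epsilon if self.epsilon is not None else self.params.kappa * 1e-4
        floor = self.n_floor if self.n_floor is not None else self.params.kappa * 1e-6
        if not 0 < eps < self.params.kappa:
            raise ValueError("epsilon must lie in (0, kappa)")
        if not 0 < floor < self.params.kappa - eps:
            raise ValueError("n_floor must lie in (0, kappa - epsilon)")
        object.__setattr__(self, "epsilon", eps)
        object.__setattr__(self, "n_floor", floor)
        if self.c_bracket is not None:
            lo, hi = self.c_bracket
            if not 0 < lo < hi:
                raise ValueError("c_bracket must satisfy 0 < low < high")


@dataclass(frozen=True)
class WaveSpeedResult:
    """Shooting output: the wave speed and heteroclinic diagnostics."""

    c: float
    mismatch: float
    n_profile: np.ndarray
    q_profile: np.ndarray
    iterations: int
    params: NondimParameters


def phase_rhs(n: float, q: float, c: float, params: NondimParameters) -> float:
    """dq/dn along a phase-plane orbit; singular at n = 0 and q = 0."""
    if n == 0 or q == 0:
        raise ZeroDivisionError("phase_rhs is singular at n = 0 or q = 0")
    return -(q * (c + q) + n * (params.kappa - n) * phi(n, params)) / (q * n)


def series_start(c: float, pp: PhasePlaneProblem) -> tuple[float, float]:
    """Launch point on the local linearisation of the saddle (kappa, 0).

    Near n = kappa the orbit behaves as q ~ lambda (n - kappa) with lambda
    the positive root of kappa lambda^2 + c lambda - kappa phi(kappa) = 0.
    """
    if c <= 0:
        raise ValueError("wave speed candidate must be > 0")
    kappa = pp.params.kappa
    phik = float(phi(kappa, pp.params))
    lam = (-c + np.sqrt(c * c + 4 * kappa * kappa * phik)) / (2 * kappa)
    n_start = kappa - pp.epsilon
    q_start = lam * (n_start - kappa)
    return n_start, q_start


def integrate_heteroclinic(
    c: float, pp: PhasePlaneProblem, rtol: float = 1e-10, atol: float = 1e-14
) -> tuple[float, Outcome, np.ndarray, np.ndarray]:
    """Integrate the orbit from n = kappa - epsilon down to the n floor.

    Returns ``(q_terminal, outcome, n_path, q_path)``.  ``overshoot`` means
    q reached 0 at positive n (c too large); ``blow_up`` means q escaped
    below a large bound (c too small).
    """
    n_start, q_start = series_start(c, pp)
    q_bound = 50.0 * max(c, pp.params.kappa, 1.0)

    def rhs(n, y):
        q = y[0]
        return [-(q * (c + q) + n * (pp.params.kappa - n) * phi(n, pp.params)) / (q * n)]

    def hit_zero(n, y):
        return y[0] + 1e-13

    hit_zero.terminal = True
    hit_zero.direction = 1

    def blow_up(n, y):
        return y[0] + q_bound

    blow_up.terminal = True
    blow_up.direction = -1

    sol = solve_ivp(
        rhs,
        (n_start, pp.n_floor),
        [q_start],
        method="LSODA",
        rtol=rtol,
        atol=atol,
        events=(hit_zero, blow_up),
        dense_output=False,
    )
    n_path = sol.t
    q_path = sol.y[0]
    if sol.status == 1:  # event hit
        if sol.t_events[0].size:
            return 0.0, "overshoot", n_path, q_path
        return float(q_path[-1]), "blow_up", n_path, q_path
    if not sol.success:
        return float(q_path[-1]) if q_path.size else q_start, "failure", n_path, q_path
    return float(q_path[-1]), "reached_axis", n_path, q_path


def _mismatch(c: float, pp: PhasePlaneProblem) -> tuple[float, Outcome, np.ndarray, np.ndarray]:
    q_term, outcome, n_path, q_path = integrate_heteroclinic(c, pp)
    if outcome == "overshoot":
        return c, outcome, n_path, q_path  # q_term = 0 -> F = c > 0
    if outcome == "failure":
        raise RuntimeError(f"phase-plane integration failed at c = {c}")
    return q_term + c, outcome, n_path, q_path


def _default_bracket(params: NondimParameters) -> tuple[float, float]:
    kappa = params.kappa
    grid = np.linspace(0.0, kappa, 64)
    phimax = float(np.max(phi(grid, params)))
    hi = 2.0 * max(np.sqrt(kappa * phimax), kappa)
    return 1e-3 * kappa, hi


def wave_speed_shooting(
    params: NondimParameters,
    tol: float = 1e-8,
    epsilon: float | None = None,
    n_floor: float | None = None,
    c_bracket: tuple[float, float] | None = None,
    max_widen: int = 8,
) -> WaveSpeedResult:
    """Wave speed c(kappa, s, mu, eta) by bisection on the terminal mismatch.

    The bracket defaults to [1e-3 kappa, 2 max(sqrt(kappa phimax), kappa)],
    covering both the small-kappa law c ~ kappa/sqrt(2) and Fisher-like
    2 sqrt(kappa) scalings, and widens geometrically if both ends give the
    same mismatch sign.
    """
    pp = PhasePlaneProblem(
        params=params, epsilon=epsilon, n_floor=n_floor, c_bracket=c_bracket
    )
    lo, hi = pp.c_bracket if pp.c_bracket is not None else _default_bracket(params)

    f_lo, out_lo, _, _ = _mismatch(lo, pp)
    f_hi, out_hi, _, _ = _mismatch(hi, pp)
    widened = 0
    while f_lo * f_hi > 0 and widened < max_widen:
        if f_lo > 0:  # even the low end is too fast
            lo *= 0.25
            f_lo, out_lo, _, _ = _mismatch(lo, pp)
        else:
            hi *= 4.0
            f_hi, out_hi, _, _ = _mismatch(hi, pp)
        widened += 1
    if f_lo * f_hi > 0:
        raise BracketError(
            f"no sign change on [{lo:.3g}, {hi:.3g}] "
            f"(F = {f_lo:.3g}, {f_hi:.3g}; outcomes {out_lo}, {out_hi})"
        )
    if not (f_lo < 0 < f_hi):
        raise BracketError(
            "mismatch sign convention violated: expected F(low) < 0 < F(high); "
            f"got F({lo:.3g}) = {f_lo:.3g}, F({hi:.3g}) = {f_hi:.3g}"
        )

    iterations = 0
    best = None
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        f_mid, outcome, n_path, q_path = _mismatch(mid, pp)
        iterations += 1
        if outcome == "reached_axis":
            best = (mid, f_mid, n_path, q_path)
        if f_mid > 0:
            hi = mid
        else:
            lo = mid
        if iterations > 200:
            break
    c = 0.5 * (lo + hi)
    f_c, outcome, n_path, q_path = _mismatch(c, pp)
    if outcome != "reached_axis" and best is not None:
        c, f_c, n_path, q_path = best
    return WaveSpeedResult(
        c=float(c),
        mismatch=float(f_c),
        n_profile=n_path,
        q_profile=q_path,
        iterations=iterations,
        params=params,
    )


def wave_profile(
    res: WaveSpeedResult, params: NondimParameters | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Reconstruct the wave shape n(z) from the heteroclinic path.

    Inverts q = phi(n) dn/dz by quadrature: z(n) = int phi/q dn along the
    orbit, anchored so that z = 0 at the edge n -> 0.  Returns ``(z, n)``
    with z <= 0 and n monotone decreasing in z.
    """
    p = params if params is not None else res.params
    n = res.n_profile[::-1]  # ascending in n: edge -> saddle
    q = res.q_profile[::-1]
    integrand = phi(n, p) / q  # negative
    # z decreases as n increases away from the edge
    dz = 0.5 * (integrand[1:] + integrand[:-1]) * np.diff(n)
    z = np.concatenate([[0.0], np.cumsum(dz)])
    return z, n
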