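"""Method-of-lines solver for the moving-boundary cell growth model.

The reduced model is a degenerate reaction--diffusion equation on a growing
interval [0, L(t)]:

    dn/dt = d/dx( n phi(n) dn/dx ) + n (kappa - n),     0 < x < L(t),
    dL/dt = -dn/dx (L, t),     n(L, t) = 0,     zero flux at x = 0.

The moving boundary is immobilised with xi = x / L(t), giving

    dn/dt = (xi/L) L'(t) dn/dxi + (1/L^2) d/dxi( n phi(n) dn/dxi )
            + n (kappa - n),
    dL/dt = -(1/L) dn/dxi (1, t),

on the fixed interval xi in [0, 1] at the cost of an advective term.
Spatial discretisation: conservative second-order fluxes at midpoints for
the diffusion term, second-order upwind-biased differences for the
advection term (direction switched adaptively on the sign of dL/dt, which
can be negative during the kappa < 0 transient), a ghost-node reflection
at xi = 0 and a pinned
n = 0 row at xi = 1 whose edge gradient is taken from a second-order
one-sided three-point stencil.  L is an extra state variable, integrated
monolithically with the nodal values so the xi L' coupling carries no
splitting error.  Time stepping uses SciPy's implicit BDF with a sparse
Jacobian pattern (the problem is stiff through the degenerate diffusion).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
from scipy import sparse
from scipy.integrate import solve_ivp

from .model import NondimParameters, phi

__all__ = [
    "InitialCondition",
    "SolverSettings",
    "Trajectory",
    "RegimeClassification",
    "SolverError",
    "solve_moving_boundary",
    "total_mass",
    "front_speed",
    "classify_regime",
    "edge_gradient",
]


class SolverError(RuntimeError):
    """Integration failure; carries the last valid state when available."""

    def __init__(self, message: str, partial: "Trajectory | None" = None):
        super().__init__(message)
        self.partial = partial


@dataclass(frozen=True)
class InitialCondition:
    """Initial cell profile on the fixed coordinate xi in [0, 1].

    ``profile`` maps xi to the cell fraction at t = 0; it must vanish at
    xi = 1 (the tissue edge carries no cells) and stay inside [0, 1 - s).
    ``descriptor`` records the generating family (quadratic / cosh /
    custom) for manifests.
    """

    profile: Callable[[np.ndarray], np.ndarray]
    L0: float
    descriptor: str = "custom"

    def __post_init__(self) -> None:
        if self.L0 <= 0:
            raise ValueError(f"initial front position L0 must be > 0, got {self.L0}")
        edge = float(np.asarray(self.profile(np.asarray([1.0])))[0])
        if abs(edge) > 1e-12:
            raise ValueError(
                f"initial profile must vanish at the tissue edge xi=1, got {edge}"
            )


@dataclass(frozen=True)
class SolverSettings:
    """Numerical controls for the moving-boundary integration.

    ``n_grid`` nodes are placed uniformly on xi in [0, 1] (401 for
    production runs, 101 is adequate for tests).  ``reaction_on=False``
    switches off the production term, turning the model into a pure
    conservation law used by the mass-audit diagnostics.
    """

    n_grid: int = 401
    t_end: float = 50.0
    output_times: Sequence[float] | None = None
    rel_tol: float = 1e-8
    abs_tol: float = 1e-10
    reaction_on: bool = True

    def __post_init__(self) -> None:
        if self.n_grid < 3:
            raise ValueError("n_grid must be >= 3")
        if self.t_end <= 0:
            raise ValueError("t_end must be > 0")
        if self.rel_tol <= 0 or self.abs_tol <= 0:
            raise ValueError("tolerances must be > 0")
        if self.output_times is not None:
            ts = np.asarray(self.output_times, dtype=float)
            if ts.size == 0 or np.any(np.diff(ts) <= 0):
                raise ValueError("output_times must be non-empty and increasing")
            if ts[0] < 0 or ts[-1] > self.t_end:
                raise ValueError("output_times must lie within [0, t_end]")

    def resolve_times(self) -> np.ndarray:
        if self.output_times is not None:
            return np.asarray(self.output_times, dtype=float)
        return np.linspace(0.0, self.t_end, 201)


@dataclass(frozen=True)
class Trajectory:
    """A moving-boundary solution sampled at report times.

    ``n_values[k, i]`` is the cell fraction at time ``times[k]`` and node
    ``xi[i]``; ``L_values`` and ``dLdt_values`` track the tissue edge.
    """

    xi: np.ndarray
    times: np.ndarray
    n_values: np.ndarray
    L_values: np.ndarray
    dLdt_values: np.ndarray
    params: NondimParameters
    settings: SolverSettings
    ic_descriptor: str = "custom"

    def index_of(self, at: float) -> int:
        k = int(np.argmin(np.abs(self.times - at)))
        if not np.isclose(self.times[k], at, rtol=1e-9, atol=1e-12):
            raise ValueError(f"time {at} is not a report time")
        return k


@dataclass(frozen=True)
class RegimeClassification:
    """Outcome of the large-time regime trichotomy.

    ``label`` is the reconciled verdict (linear / logarithmic / stationary,
    or inconclusive when the sign rule and the fit evidence disagree).
    """

    label: Literal["linear", "logarithmic", "stationary", "inconclusive"]
    sign_label: str
    fit_label: str
    evidence: dict


def _edge_gradient_nodes(n_last3: np.ndarray, h: float) -> float:
    # second-order one-sided stencil at xi = 1 with the edge pinned to 0:
    # n_xi(1) ~ (3*0 - 4 n_{M-2} + n_{M-3}) / (2h)
    return (-4.0 * n_last3[1] + n_last3[0]) / (2.0 * h)


def _make_rhs(q: NondimParameters, st: SolverSettings):
    M = st.n_grid
    h = 1.0 / (M - 1)
    xi_int = np.arange(M - 1) * h  # nodes 0 .. M-2 carried in the state
    kappa = q.kappa
    react = st.reaction_on

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        n = y[:-1]
        L = y[-1]
        # full nodal vector with the pinned edge value
        nf = np.empty(M)
        nf[:-1] = n
        nf[-1] = 0.0
        dLdt = -_edge_gradient_nodes(nf[-3:], h) / L

        # conservative diffusive flux at midpoints; degenerate mobility
        # n*phi(n) is evaluated with n clipped at 0 so that tolerance-level
        # undershoots cannot produce negative mobility
        nm = 0.5 * (nf[:-1] + nf[1:])
        mob = np.clip(nm, 0.0, None) * phi(np.clip(nm, 0.0, q.n_max - 1e-9), q)
        flux = mob * (nf[1:] - nf[:-1]) / h  # flux at i+1/2, i = 0..M-2
        div = np.empty(M - 1)
        div[0] = 2.0 * flux[0] / h  # ghost reflection: zero flux at xi=0
        div[1:] = (flux[1:] - flux[:-1]) / h

        # advection (xi/L) L' dn/dxi, second-order upwind-biased on the sign
        # of L' (central at the node next to the incoming boundary)
        grad = np.empty(M - 1)
        if dLdt >= 0:
            # information enters from the edge: forward-biased stencil
            grad[: M - 3] = (-3.0 * nf[: M - 3] + 4.0 * nf[1 : M - 2] - nf[2 : M - 1]) / (
                2.0 * h
            )
            grad[M - 3] = (nf[M - 2] - nf[M - 4]) / (2.0 * h)
            grad[M - 2] = (nf[M - 1] - nf[M - 3]) / (2.0 * h)
        else:
            grad[0] = 0.0  # xi = 0: the advective term vanishes anyway
            grad[1] = (nf[2] - nf[0]) / (2.0 * h)
            grad[2:] = (3.0 * nf[2 : M - 1] - 4.0 * nf[1 : M - 2] + nf[: M - 3]) / (
                2.0 * h
            )
        adv = xi_int / L * dLdt * grad

        dn = adv + div / L**2
        if react:
            dn = dn + nf[:-1] * (kappa - nf[:-1])

        out = np.empty(M)
        out[:-1] = dn
        out[-1] = dLdt
        return out

    return rhs, h


def _jac_sparsity(M: int) -> sparse.csr_matrix:
    # tridiagonal nodal coupling + every row couples to L and, through the
    # dL/dt stencil, to the last two free nodes
    N = M  # M-1 nodes + L
    rows, cols = [], []
    for i in range(M - 1):
        for j in (i - 2, i - 1, i, i + 1, i + 2):
            if 0 <= j < M - 1:
                rows.append(i)
                cols.append(j)
        for j in (M - 3, M - 2, N - 1):
            rows.append(i)
            cols.append(j)
    for j in (M - 3, M - 2, N - 1):
        rows.append(N - 1)
        cols.append(j)
    data = np.ones(len(rows))
    return sparse.csr_matrix((data, (rows, cols)), shape=(N, N))


def solve_moving_boundary(
    q: NondimParameters, ic: InitialCondition, st: SolverSettings
) -> Trajectory:
    """Integrate the boundary-fixed moving-boundary system.

    Returns the solution sampled at ``st.output_times`` (or a uniform
    default grid).  Raises :class:`SolverError` on integrator failure or if
    the cell fraction leaves [0, 1 - s) by more than tolerance-level noise.
    """
    M = st.n_grid
    xi = np.linspace(0.0, 1.0, M)
    n0 = np.asarray(ic.profile(xi), dtype=float)
    if np.any(n0 < 0) or np.any(n0 >= q.n_max):
        raise ValueError("initial profile must lie in [0, 1 - s)")
    rhs, h = _make_rhs(q, st)
    y0 = np.concatenate([n0[:-1], [ic.L0]])
    times = st.resolve_times()

    sol = solve_ivp(
        rhs,
        (times[0], times[-1]),
        y0,
        method="BDF",
        t_eval=times,
        rtol=st.rel_tol,
        atol=st.abs_tol,
        jac_sparsity=_jac_sparsity(M),
    )
    if not sol.success:
        raise SolverError(f"moving-boundary integration failed: {sol.message}")

    n_vals = np.zeros((len(sol.t), M))
    n_vals[:, :-1] = sol.y[:-1, :].T
    L_vals = sol.y[-1, :]
    dLdt = np.array(
        [-_edge_gradient_nodes(n_vals[k, -3:], h) / L_vals[k] for k in range(len(sol.t))]
    )

    tr = Trajectory(
        xi=xi,
        times=sol.t,
        n_values=n_vals,
        L_values=L_vals,
        dLdt_values=dLdt,
        params=q,
        settings=st,
        ic_descriptor=ic.descriptor,
    )
    # invariant audit: undershoot beyond integrator noise is a failure
    if n_vals.min() < -1e3 * st.abs_tol or n_vals.max() >= q.n_max:
        raise SolverError(
            f"cell fraction left [0, 1-s): min={n_vals.min():.3e}, "
            f"max={n_vals.max():.3e}",
            partial=tr,
        )
    return tr


def total_mass(tr: Trajectory, at: float) -> float:
    """Total cell mass L(t) * int_0^1 n(xi, t) dxi (trapezoid, matching the
    second-order spatial scheme)."""
    k = tr.index_of(at)
    return float(tr.L_values[k] * np.trapezoid(tr.n_values[k], tr.xi))


def edge_gradient(tr: Trajectory, at: float) -> float:
    """One-sided dn/dxi at the tissue edge, same stencil as the solver."""
    k = tr.index_of(at)
    h = tr.xi[1] - tr.xi[0]
    return _edge_gradient_nodes(tr.n_values[k, -3:], h)


def front_speed(
    tr: Trajectory, window: tuple[float, float], flatness_warn: float = 0.2
) -> tuple[float, float]:
    """Least-squares front speed over a time window.

    Returns ``(c, flatness)`` where ``c`` is the slope of L against t and
    ``flatness`` is max - min of dL/dt over the window (a convergence
    diagnostic for the travelling-wave plateau).  Warns when the window is
    not flat relative to the estimate.
    """
    t0, t1 = window
    mask = (tr.times >= t0) & (tr.times <= t1)
    if mask.sum() < 2:
        raise ValueError("front-speed window must contain at least two report times")
    t = tr.times[mask]
    L = tr.L_values[mask]
    c = float(np.polyfit(t, L, 1)[0])
    v = tr.dLdt_values[mask]
    flatness = float(v.max() - v.min())
    if abs(c) > 0 and flatness > flatness_warn * abs(c):
        warnings.warn(
            f"front speed window not converged: dL/dt varies by {flatness:.3g} "
            f"against estimate {c:.3g}",
            stacklevel=2,
        )
    return c, flatness


def classify_regime(
    q: NondimParameters,
    tr: Trajectory,
    tail_fraction: float = 0.2,
    speed_floor: float = 1e-3,
    stationary_tol: float = 1e-4,
    flatness_tol: float = 0.25,
) -> RegimeClassification:
    """Label the large-time behaviour of the tissue edge.

    Three regimes occur: for kappa > 0 the edge advances linearly (a
    travelling wave), for kappa = 0 logarithmically, and for kappa < 0 it
    stalls at a finite position.  The sign of kappa predicts the label; the
    verdict is corroborated by late-time evidence: a flat positive dL/dt
    (linear), a flat positive t * dL/dt (logarithmic; L ~ b ln t), or a
    vanishing dL/dt (stationary).  A disagreement yields ``inconclusive``.
    """
    if q.kappa > 0:
        sign_label = "linear"
    elif q.kappa < 0:
        sign_label = "stationary"
    else:
        sign_label = "logarithmic"

    t_end = tr.times[-1]
    mask = tr.times >= (1 - tail_fraction) * t_end
    t = tr.times[mask]
    v = tr.dLdt_values[mask]
    v_mean = float(np.mean(v))
    v_spread = float(v.max() - v.min())
    tv = t * v
    tv_mean = float(np.mean(tv))
    tv_spread = float(tv.max() - tv.min())

    if v_mean > speed_floor and v_spread < flatness_tol * v_mean:
        fit_label = "linear"
    elif tv_mean > speed_floor and tv_spread < flatness_tol * tv_mean:
        fit_label = "logarithmic"
    elif abs(v_mean) < stationary_tol:
        fit_label = "stationary"
    else:
        fit_label = "unresolved"

    label = sign_label if fit_label in (sign_label, "unresolved") else "inconclusive"
    if fit_label == "unresolved":
        # short runs: trust the fits only if they exist; flag the verdict
        label = sign_label
    evidence = {
        "dLdt_mean": v_mean,
        "dLdt_spread": v_spread,
        "t_dLdt_mean": tv_mean,
        "t_dLdt_spread": tv_spread,
        "window": (float(t[0]), float(t[-1])),
    }
    return RegimeClassification(
        label=label, sign_label=sign_label, fit_label=fit_label, evidence=evidence
    )
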