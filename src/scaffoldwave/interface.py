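"""Configuration, standard initial conditions, experiment drivers and I/O.

The two initial-condition families used throughout are the quadratic seed
profile n0(x) = omega (1 - x^2) with L0 = 1 (the standard seeding of a
scaffold, omega the centre cell fraction) and the cosh-mode profile
N(x, 0) = A0 - B0 cosh(x/sqrt2), which starts the solver exactly on the
closed-form asymptotic branch.

Configs are flat TOML files (key = number); exactly one of a
nondimensional block (kappa, s, mu, eta) or a dimensional block
(r_m, r_a, K, mu_n, mu_w, delta, nu, chi, s) must be present.  Every run
writes CSV data plus a JSON manifest embedding the fully resolved
configuration, so any run can be reproduced from its manifest alone.
"""

from __future__ import annotations

import json
import tomllib
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import asymptotics as asym
from . import travelling_wave as tw
from .model import DimensionalParameters, NondimParameters, nondimensionalise
from .pde_solver import (
    InitialCondition,
    SolverSettings,
    Trajectory,
    classify_regime,
    front_speed,
    solve_moving_boundary,
)

__all__ = [
    "RunConfig",
    "load_params",
    "make_ic_quadratic",
    "make_ic_cosh",
    "make_ic_from_table",
    "regime_report",
    "write_outputs",
    "read_trajectory",
]

_NONDIM_KEYS = {"kappa", "s", "mu", "eta"}
_DIM_KEYS = {"r_m", "r_a", "K", "mu_n", "mu_w", "delta", "nu", "chi", "s"}

#: CSV float format: full double precision so re-runs byte-reproduce
FLOAT_FMT = "%.17g"


@dataclass(frozen=True)
class RunConfig:
    """Resolved description of one experiment (any mode)."""

    mode: str
    parameters: NondimParameters | DimensionalParameters
    ic_spec: dict = field(default_factory=dict)
    solver: SolverSettings = field(default_factory=SolverSettings)
    output_dir: str | None = None
    seed: int = 0  # reserved; every computation here is deterministic


def load_params(path: str | Path) -> NondimParameters | DimensionalParameters:
    """Read model parameters from a flat TOML config.

    The file may contain the keys at top level or under a ``[model]``
    table.  Nondimensional and dimensional keys are mutually exclusive.
    """
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    table = raw.get("model", raw)
    keys = set(table) & (_NONDIM_KEYS | _DIM_KEYS)
    has_nondim = "kappa" in keys
    has_dim = bool(keys & (_DIM_KEYS - {"s"}))
    if has_nondim and has_dim:
        raise ValueError(
            "config mixes nondimensional (kappa, ...) and dimensional "
            "(r_m, ...) parameter blocks; supply exactly one"
        )
    if has_nondim:
        return NondimParameters(**{k: float(table[k]) for k in _NONDIM_KEYS & set(table)})
    if has_dim:
        missing = _DIM_KEYS - set(table)
        if missing:
            raise ValueError(f"dimensional config missing keys: {sorted(missing)}")
        return DimensionalParameters(**{k: float(table[k]) for k in _DIM_KEYS})
    raise ValueError("config contains no recognised parameter block")


def make_ic_quadratic(omega: float = 0.03, L0: float = 1.0, s: float = 0.2) -> InitialCondition:
    """Quadratic seeding profile n0 = omega (1 - xi^2) on the unit interval.

    ``omega`` is the centre cell fraction; the profile vanishes at the
    tissue edge by construction.  Defaults match the standard scaffold
    seeding used across the regime experiments (omega = 0.03, s = 0.2,
    L0 = 1).
    """
    if not 0 < omega < 1 - s:
        raise ValueError(f"omega must lie in (0, 1 - s), got {omega}")

    def profile(xi):
        return omega * (1.0 - np.asarray(xi) ** 2)

    return InitialCondition(profile=profile, L0=L0, descriptor=f"quadratic(omega={omega})")


def make_ic_cosh(A0: float = 0.05, B0: float = 0.01) -> InitialCondition:
    """Cosh-mode profile N(x, 0) = A0 - B0 cosh(x/sqrt2), mapped to xi = x/L0.

    The front starts at L0 = sqrt2 acosh(A0/B0) where the profile crosses
    zero exactly, so the run begins on the closed-form asymptotic branch.
    """
    ap = asym.alpha_beta(A0, B0)
    L0 = ap.L0

    def profile(xi):
        x = np.asarray(xi) * L0
        val = A0 - B0 * np.cosh(x / np.sqrt(2.0))
        return np.clip(val, 0.0, None)  # exact zero at xi = 1, no -0 noise

    return InitialCondition(profile=profile, L0=L0, descriptor=f"cosh(A0={A0},B0={B0})")


def make_ic_from_table(path: str | Path, L0: float) -> InitialCondition:
    """Custom initial profile from a two-column CSV (xi, n), linearly interpolated."""
    df = pd.read_csv(path)
    xi = df.iloc[:, 0].to_numpy(float)
    nv = df.iloc[:, 1].to_numpy(float)
    if xi[0] > 0 or xi[-1] < 1:
        raise ValueError("custom IC table must cover xi in [0, 1]")

    def profile(x):
        return np.interp(np.asarray(x, dtype=float), xi, nv)

    return InitialCondition(profile=profile, L0=L0, descriptor=f"custom({Path(path).name})")


def _default_t_end(kappa: float) -> float:
    return max(50.0, 10.0 / abs(kappa)) if kappa != 0 else 2000.0


def regime_report(
    kappas,
    s: float = 0.2,
    mu: float = 1.0,
    eta: float = 1.0,
    omega: float = 0.03,
    L0: float = 1.0,
    n_grid: int = 101,
    t_end: float | None = None,
) -> pd.DataFrame:
    """Run the solver + classifier (+ shooting and asymptotics where they
    apply) over a kappa sweep and tabulate one row per kappa.

    Columns: regime, c_PDE (late-time front speed), c_shooting (kappa > 0),
    L_end, L_inf prediction (kappa < 0, from the fitted alpha of the
    quadratic IC is not available so reported only when |kappa| <= 0.01),
    and the shooting/PDE agreement.  Per-row failures are recorded in the
    ``error`` column and the sweep continues.
    """
    rows = []
    for kappa in kappas:
        row: dict = {"kappa": kappa}
        try:
            q = NondimParameters(kappa=float(kappa), s=s, mu=mu, eta=eta)
            ic = make_ic_quadratic(omega=omega, L0=L0, s=s)
            te = t_end if t_end is not None else _default_t_end(kappa)
            st = SolverSettings(n_grid=n_grid, t_end=te)
            tr = solve_moving_boundary(q, ic, st)
            cls = classify_regime(q, tr)
            c_pde, flat = front_speed(tr, (0.8 * te, te), flatness_warn=np.inf)
            row.update(
                regime=cls.label,
                c_PDE=c_pde,
                dLdt_flatness=flat,
                L_end=float(tr.L_values[-1]),
            )
            if kappa > 0:
                res = tw.wave_speed_shooting(q)
                row["c_shooting"] = res.c
                row["c_rel_err"] = abs(res.c - c_pde) / res.c
            if kappa < 0 and abs(kappa) <= 0.01:
                # the closed-form stationary front needs the cosh-mode alpha;
                # report it for the matching cosh IC
                ap = asym.alpha_beta(0.05, 0.01)
                row["L_inf_prediction"] = asym.L_infinity(kappa, ap.alpha)
            row["error"] = ""
        except Exception as exc:  # per-row failure, keep sweeping
            row["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)
    return pd.DataFrame(rows)


def _manifest_params(p) -> dict:
    d = asdict(p)
    d["type"] = type(p).__name__
    return d


def write_outputs(obj, out_dir: str | Path, tag: str = "run") -> Path:
    """Write a Trajectory / WaveSpeedResult / report DataFrame plus manifest.

    A timestamped subdirectory is created so repeated runs never overwrite;
    numbers are written at full double precision so identical configs give
    identical CSV bytes.  Returns the created directory.
    """
    out_dir = Path(out_dir)
    stamp = datetime.now(timezone.utc).strftime("%Y%m%dT%H%M%S.%f")
    run_dir = out_dir / f"{tag}-{stamp}"
    run_dir.mkdir(parents=True, exist_ok=False)
    manifest: dict = {"tag": tag}

    if isinstance(obj, Trajectory):
        pd.DataFrame(
            {"t": obj.times, "L": obj.L_values, "dLdt": obj.dLdt_values}
        ).to_csv(run_dir / "front.csv", index=False, float_format=FLOAT_FMT)
        snap = pd.DataFrame(obj.n_values, columns=[f"{x:.17g}" for x in obj.xi])
        snap.insert(0, "t", obj.times)
        snap.to_csv(run_dir / "profiles.csv", index=False, float_format=FLOAT_FMT)
        manifest.update(
            kind="trajectory",
            parameters=_manifest_params(obj.params),
            settings={
                **{
                    k: getattr(obj.settings, k)
                    for k in ("n_grid", "t_end", "rel_tol", "abs_tol", "reaction_on")
                },
                "output_times": list(map(float, obj.times)),
            },
            ic_descriptor=obj.ic_descriptor,
        )
    elif isinstance(obj, tw.WaveSpeedResult):
        pd.DataFrame({"n": obj.n_profile, "q": obj.q_profile}).to_csv(
            run_dir / "heteroclinic.csv", index=False, float_format=FLOAT_FMT
        )
        z, n = tw.wave_profile(obj)
        pd.DataFrame({"z": z, "n": n}).to_csv(
            run_dir / "wave_profile.csv", index=False, float_format=FLOAT_FMT
        )
        manifest.update(
            kind="wave_speed",
            parameters=_manifest_params(obj.params),
            c=obj.c,
            mismatch=obj.mismatch,
            iterations=obj.iterations,
        )
    elif isinstance(obj, pd.DataFrame):
        obj.to_csv(run_dir / "report.csv", index=False, float_format=FLOAT_FMT)
        manifest.update(kind="report", columns=list(obj.columns))
    else:
        raise TypeError(f"don't know how to write a {type(obj).__name__}")

    with open(run_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)
    return run_dir


def read_trajectory(run_dir: str | Path) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Read back (front, profiles, manifest) written by :func:`write_outputs`."""
    run_dir = Path(run_dir)
    front = pd.read_csv(run_dir / "front.csv", float_precision="round_trip")
    profiles = pd.read_csv(run_dir / "profiles.csv", float_precision="round_trip")
    with open(run_dir / "manifest.json") as fh:
        manifest = json.load(fh)
    return front, profiles, manifest
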