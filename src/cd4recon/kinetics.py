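"""Single-compartment CD4 reconstitution model after HSCT.

The state X(t) is the peripheral-blood CD4 concentration (cells/uL) at time
t days after transplant for a child aged ``age_at_hsct + t`` days:

    dX/dt = lambda0 * lambda_age(tau) * Delta(t)  -  d(X, tau) X  +  p(X, tau) X

with density-dependent (homeostatic) proliferation and loss

    p = p0 * y(tau) * exp(cp * (1 - X / N(tau)))
    d = d0 * y(tau) * exp(cd * (X / N(tau) - 1))

and a sigmoidal recovery Delta(t) of thymic output after the transplant.
The child ages along the trajectory, so all reference curves are evaluated
at tau = age_at_hsct + t.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .reference import (
    DEFAULT_CONSTANTS,
    AgeReferenceConstants,
    expected_total_cd4,
    ki67_fraction,
    thymic_output_for_age,
)

__all__ = [
    "StructuralParameters",
    "Trajectory",
    "SolverError",
    "thymic_recovery",
    "proliferation_rate",
    "loss_rate",
    "solve_trajectory",
    "time_to_threshold",
    "thymic_output_curve",
    "mean_lifespan",
]

# Numerical guard on the per-capita proliferation and loss rates (per day).
# Biologically plausible values are well below 0.1/day; the cap only bites
# for extreme random-effect draws in the tails of importance-sampling
# proposals, where it keeps explicit integrators stable without measurably
# changing any likelihood that carries weight.  Kept identical in the
# production and batched solvers so they integrate the same vector field.
RATE_CAP = 0.5

#: Exponent clip protecting exp() from overflow in the rate terms.
_EXP_CLIP = 50.0


@dataclass(frozen=True)
class StructuralParameters:
    """One individual's parameters of the reconstitution model.

    lambda0   -- dimensionless scale on the theoretical thymic output
    d0        -- scale on the expected loss rate (/day)
    p0        -- scale on the expected proliferation rate (/day)
    x0        -- CD4 concentration at t=0 (cells/uL)
    lambda_h  -- time scale of post-transplant thymic recovery (days)
    lambda_r  -- steepness of the thymic recovery sigmoid (dimensionless)
    cp, cd    -- competition strengths; fixed to 1 (not estimated) because
                 their effect on the trajectory is absorbed by the scales.
    """

    lambda0: float
    d0: float
    p0: float
    x0: float
    lambda_h: float
    lambda_r: float
    cp: float = 1.0
    cd: float = 1.0

    def __post_init__(self) -> None:
        # lambda0, d0 and p0 may be exactly zero: these are the degenerate
        # limits (no thymic output / no loss / no proliferation) used by
        # closed-form oracles.
        for name in ("lambda0", "d0", "p0"):
            value = getattr(self, name)
            if not (np.isfinite(value) and value >= 0):
                raise ValueError(f"{name} must be finite and non-negative")
        for name in ("x0", "lambda_h", "lambda_r", "cp", "cd"):
            value = getattr(self, name)
            if not (np.isfinite(value) and value > 0):
                raise ValueError(f"{name} must be finite and strictly positive")


@dataclass(frozen=True)
class Trajectory:
    """A solved concentration curve on a time grid (days post-HSCT)."""

    times: np.ndarray
    concentrations: np.ndarray
    age_at_hsct: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times, float)
        x = np.asarray(self.concentrations, float)
        if t.shape != x.shape:
            raise ValueError("times and concentrations must have equal length")
        if t[0] != 0 or np.any(np.diff(t) <= 0):
            raise ValueError("times must start at 0 and be strictly increasing")
        if np.any(x <= 0):
            raise ValueError("concentrations must be strictly positive")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", x)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"time_days": self.times, "cd4_cells_per_ul": self.concentrations}
        )


class SolverError(RuntimeError):
    """Raised when the ODE solver fails; carries the solver's diagnostics."""


def thymic_recovery(t, lambda_h: float, lambda_r: float):
    """Sigmoidal recovery of thymic output after transplant, in [0, 1).

    Delta(t) = (1 - exp(-2 t / lambda_h)) / (1 + exp(lambda_r (1 - t / lambda_h)))

    Zero exactly at t=0 (thymic output is abolished by conditioning), tends
    to 1, and is kept overflow-safe for large lambda_r by clipping the
    logistic exponent.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    if not (np.all(np.asarray(lambda_h) > 0) and np.all(np.asarray(lambda_r) > 0)):
        raise ValueError("lambda_h and lambda_r must be positive")
    num = -np.expm1(-2.0 * t / lambda_h)
    den = 1.0 + np.exp(np.clip(lambda_r * (1.0 - t / lambda_h), -700.0, 700.0))
    return num / den


def proliferation_rate(x, age, p0: float, cp: float = 1.0,
                       consts: AgeReferenceConstants = DEFAULT_CONSTANTS):
    """Per-capita proliferation rate p(X, tau) (/day); decreasing in X."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("concentration must be strictly positive")
    ratio = x / expected_total_cd4(age, consts)
    return p0 * ki67_fraction(age, consts) * np.exp(
        np.clip(cp * (1.0 - ratio), -_EXP_CLIP, _EXP_CLIP)
    )


def loss_rate(x, age, d0: float, cd: float = 1.0,
              consts: AgeReferenceConstants = DEFAULT_CONSTANTS):
    """Per-capita loss rate d(X, tau) (/day); increasing in X."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("concentration must be strictly positive")
    ratio = x / expected_total_cd4(age, consts)
    return d0 * ki67_fraction(age, consts) * np.exp(
        np.clip(cd * (ratio - 1.0), -_EXP_CLIP, _EXP_CLIP)
    )


def _rhs(t, x, params: StructuralParameters, age0: float,
         consts: AgeReferenceConstants):
    tau = age0 + t
    y = ki67_fraction(tau, consts)
    n = expected_total_cd4(tau, consts)
    ratio = np.maximum(x, 1e-12) / n
    p = params.p0 * y * np.exp(np.clip(params.cp * (1.0 - ratio), -_EXP_CLIP, _EXP_CLIP))
    d = params.d0 * y * np.exp(np.clip(params.cd * (ratio - 1.0), -_EXP_CLIP, _EXP_CLIP))
    p = np.minimum(p, RATE_CAP)
    d = np.minimum(d, RATE_CAP)
    lam = params.lambda0 * thymic_output_for_age(tau, consts) * thymic_recovery(
        t, params.lambda_h, params.lambda_r
    )
    return lam + (p - d) * x


def _solve_dense(params: StructuralParameters, age_at_hsct: float, horizon: float,
                 consts: AgeReferenceConstants, rtol: float, atol: float):
    if age_at_hsct < 0:
        raise ValueError("age_at_hsct must be non-negative")
    sol = solve_ivp(
        _rhs,
        (0.0, float(horizon)),
        [params.x0],
        method="LSODA",
        rtol=rtol,
        atol=atol,
        dense_output=True,
        args=(params, float(age_at_hsct), consts),
    )
    if not sol.success:
        raise SolverError(f"ODE solver failed: {sol.message} (nfev={sol.nfev})")
    return sol


def solve_trajectory(params: StructuralParameters, age_at_hsct: float,
                     horizon: float, grid=None,
                     consts: AgeReferenceConstants = DEFAULT_CONSTANTS,
                     rtol: float = 1e-8, atol: float = 1e-6) -> Trajectory:
    """Solve the reconstitution model on a time grid.

    ``grid`` defaults to daily points over the horizon.  Raises
    :class:`SolverError` (never returns NaN) if integration fails.
    """
    if not horizon > 0:
        raise ValueError("horizon must be positive")
    if grid is None:
        grid = np.arange(0.0, float(horizon) + 0.5, 1.0)
    grid = np.asarray(grid, dtype=float)
    if grid[0] != 0.0:
        grid = np.concatenate([[0.0], grid])
    sol = _solve_dense(params, age_at_hsct, max(horizon, grid[-1]), consts, rtol, atol)
    values = sol.sol(grid)[0]
    if not np.all(np.isfinite(values)):
        raise SolverError("non-finite concentrations in solution")
    return Trajectory(grid, np.maximum(values, 1e-12), float(age_at_hsct))


def time_to_threshold(params: StructuralParameters, age_at_hsct: float,
                      threshold: float, relative: bool = False,
                      horizon: float = 2557.0,
                      consts: AgeReferenceConstants = DEFAULT_CONSTANTS) -> float:
    """First time the trajectory reaches a CD4 threshold.

    ``threshold`` is either an absolute concentration (cells/uL) or, with
    ``relative=True``, a fraction of the age-expected concentration
    N(age_at_hsct + t) at the crossing time.  The crossing is located on the
    solver's dense output by bisection (much finer than the +-0.5 day
    contract).  Returns ``nan`` if the threshold is never reached within the
    horizon.
    """
    if not threshold > 0:
        raise ValueError("threshold must be positive")
    sol = _solve_dense(params, age_at_hsct, horizon, consts, 1e-8, 1e-6)

    def gap(t):
        target = (
            threshold * expected_total_cd4(age_at_hsct + t, consts)
            if relative
            else threshold
        )
        return sol.sol(t)[0] - target

    ts = np.linspace(0.0, horizon, 4096)
    gaps = np.array([gap(t) for t in ts])
    if gaps[0] >= 0:
        return 0.0
    above = np.nonzero(gaps >= 0)[0]
    if len(above) == 0:
        return math.nan
    i = above[0]
    return brentq(gap, ts[i - 1], ts[i], xtol=1e-3)


def thymic_output_curve(params: StructuralParameters, age_at_hsct: float,
                        grid, consts: AgeReferenceConstants = DEFAULT_CONSTANTS):
    """Post-transplant thymic output lambda0 * lambda_age(tau) * Delta(t).

    Returns the production rate (cells/uL/day) on the grid; zero at t=0,
    rising with the recovery sigmoid and ultimately declining with thymic
    involution.
    """
    grid = np.asarray(grid, dtype=float)
    return (
        params.lambda0
        * thymic_output_for_age(age_at_hsct + grid, consts)
        * thymic_recovery(grid, params.lambda_h, params.lambda_r)
    )


def mean_lifespan(age, d0: float, occupancy: float = 0.9, cd: float = 1.0,
                  consts: AgeReferenceConstants = DEFAULT_CONSTANTS):
    """Mean CD4 T-cell lifespan (days) implied by the loss rate.

    The reciprocal of the per-capita loss rate evaluated at
    X = occupancy * N(age).  The occupancy convention is an explicit
    argument; 0.9 (the model's long-run level relative to a healthy child)
    is the documented default.  Lifespan increases with age because cell
    turnover slows as Ki67 expression declines.
    """
    if not occupancy > 0:
        raise ValueError("occupancy must be positive")
    x = occupancy * expected_total_cd4(age, consts)
    return 1.0 / loss_rate(x, age, d0, cd, consts)
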