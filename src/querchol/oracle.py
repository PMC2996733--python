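"""Numerical integration of the full coupled reaction network.

The vector field assembles the four simultaneous rate equations —

* dQ/dt  = -ki Q                       (overall quercetin depletion)
* dA/dt  = -k5 A                       (cholesterol thermal degradation)
* dA'/dt = k1 A' (1 - A'/A'max) / (kf Q)   (inhibited peroxidation)
* dE/dt  = k4 A A' / (kf Q)            (inhibited epoxidation)

— and, in control mode (no quercetin), replaces the inhibited forms by the
plain logistic dA'/dt = k1 A' (1 - A'/A'max) and dE/dt = k4 A A', with Q held
constant.  Degraded product pools are tracked implicitly by mass difference
rather than as state variables.

This trajectory is the canonical model of the package: every closed form in
:mod:`querchol.model` is validated against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.integrate import solve_ivp

from .model import InitialConditions, RateConstants

__all__ = ["Trajectory", "integrate_system", "max_relative_deviation"]


@dataclass
class Trajectory:
    """Solver output on a fixed grid, one array per species (hours / declared unit)."""

    t: np.ndarray
    Q: np.ndarray
    A: np.ndarray
    Aprime: np.ndarray
    E: np.ndarray
    control: bool
    diagnostics: dict = field(default_factory=dict)

    def species(self, name: str) -> np.ndarray:
        try:
            return {
                "quercetin": self.Q,
                "cholesterol": self.A,
                "hydroperoxide_7OOH": self.Aprime,
                "epoxide_56EP": self.E,
            }[name]
        except KeyError:
            raise KeyError(f"species {name!r} not in trajectory") from None


def integrate_system(
    rc: RateConstants,
    ic: InitialConditions,
    t_grid,
    control: bool = False,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate the reaction network on ``t_grid`` (hours, ascending from 0).

    ``control=True`` selects the no-quercetin vector field.  Raises a
    RuntimeError echoing the parameters if the solver fails.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid[0] != 0.0 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be 1-d, strictly ascending and start at 0")

    M = ic.Aprime_max

    if control:

        def rhs(t, y):
            Q, A, Ap, E = y
            growth = rc.k1 * Ap * (1.0 - Ap / M)
            return [0.0, -rc.k5 * A, growth, rc.k4 * A * Ap]

    else:
        if (rc.k1 > 0 or rc.k4 > 0) and rc.kf == 0:
            raise ValueError(
                "inhibited kinetics require kf > 0 when k1 or k4 is non-zero"
            )

        def rhs(t, y):
            Q, A, Ap, E = y
            inhib = rc.kf * Q if (rc.k1 or rc.k4) else 1.0
            growth = rc.k1 * Ap * (1.0 - Ap / M) / inhib if rc.k1 else 0.0
            epox = rc.k4 * A * Ap / inhib if rc.k4 else 0.0
            return [-rc.ki * Q, -rc.k5 * A, growth, epox]

    y0 = [ic.Q0, ic.A0, ic.Aprime0, ic.E0]
    sol = solve_ivp(
        rhs,
        (t_grid[0], t_grid[-1]),
        y0,
        t_eval=t_grid,
        method="LSODA",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(
            f"ODE integration failed: {sol.message} "
            f"(rc={rc!r}, ic={ic!r}, control={control})"
        )
    Q, A, Ap, E = sol.y
    return Trajectory(
        t=t_grid,
        Q=Q,
        A=A,
        Aprime=Ap,
        E=E,
        control=control,
        diagnostics={
            "nfev": sol.nfev,
            "njev": sol.njev,
            "nlu": sol.nlu,
            "rtol": rtol,
            "atol": atol,
            "message": sol.message,
        },
    )


def max_relative_deviation(
    closed_form: Callable[[np.ndarray], np.ndarray],
    traj: Trajectory,
    species: str,
    eps: float = 1e-12,
) -> float:
    """Max over the grid of |closed(t) - numeric| / max(|numeric|, eps)."""
    numeric = traj.species(species)
    closed = np.asarray(closed_form(traj.t), dtype=float)
    denom = np.maximum(np.abs(numeric), eps)
    return float(np.max(np.abs(closed - numeric) / denom))
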