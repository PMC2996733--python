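"""Rate-constant estimation from concentration time series.

Two estimator families, matching how such constants are conventionally
obtained:

* first-order constants (quercetin depletion, cholesterol thermal loss) by
  log-linear regression of -ln(value / value at t0) on time, by default
  through the origin (the integrated first-order law forces a zero
  intercept);
* the hydroperoxide and epoxide constants by Levenberg-Marquardt nonlinear
  least squares (``scipy.optimize.least_squares(method="lm")``) on the
  closed forms of :mod:`querchol.model`, with positivity enforced by
  log-parameterisation and a deterministic multi-start grid.

Approximate standard errors come from the Gauss-Newton curvature at the
optimum and are flagged when the normal matrix is ill-conditioned.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares
from scipy.special import expit, logit

from .model import (
    InitialConditions,
    RateConstants,
    TimeSeries,
    epoxide_quadrature,
    epoxide_taylor,
    hydroperoxide_conc,
    hydroperoxide_logistic_control,
)

__all__ = [
    "ConvergenceError",
    "FitResult",
    "goodness_of_fit",
    "fit_first_order",
    "fit_hydroperoxide",
    "fit_epoxidation",
    "fit_logistic_control",
    "subtraction_constants",
]

#: Condition number of the Gauss-Newton normal matrix above which standard
#: errors are flagged as approximate.
SE_CONDITION_LIMIT = 1e8

#: Default optimizer tolerances (cost) and iteration cap for Marquardt fits.
FIT_TOL = 1e-10
FIT_MAX_NFEV = 2000


class ConvergenceError(RuntimeError):
    """No optimizer start converged; carries per-start diagnostics."""

    def __init__(self, message: str, diagnostics: list | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


@dataclass
class FitResult:
    """Point estimates and fit diagnostics for one fitted reaction."""

    params: dict[str, float]
    stderr: dict[str, float]
    r2: float
    residuals: np.ndarray
    n_obs: int
    method: str
    converged: bool
    window: tuple[float, float] | None = None
    extras: dict = field(default_factory=dict)

    def k(self, name: str | None = None) -> float:
        """The (single) estimated constant, or a named one."""
        if name is None:
            if len(self.params) != 1:
                raise ValueError("fit has several parameters; name one")
            return next(iter(self.params.values()))
        return self.params[name]


def goodness_of_fit(observed, predicted) -> float:
    """Coefficient of determination r^2 = 1 - SS_res / SS_tot.

    SS_tot is taken about the observed mean.  Raises if the observed values
    have zero variance (r^2 undefined).
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape or observed.ndim != 1 or len(observed) < 2:
        raise ValueError("observed and predicted must be equal-length 1-d, n >= 2")
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("undefined r^2: observed values have zero variance")
    ss_res = float(np.sum((observed - predicted) ** 2))
    return 1.0 - ss_res / ss_tot


# ---------------------------------------------------------------------------
# First-order (log-linear) fits
# ---------------------------------------------------------------------------


def fit_first_order(
    ts: TimeSeries,
    window: float | None = None,
    through_origin: bool = True,
) -> FitResult:
    """Estimate a first-order rate constant from a decaying series.

    Regresses y = -ln(value / value_at_t0) on time (hours); the slope is the
    rate constant in h^-1.  ``window`` restricts to times <= window (hours).
    Replicates are pooled.  r^2 is computed on the log scale.
    """
    if window is not None:
        ts = ts.windowed(window)
    if np.any(ts.values <= 0):
        raise ValueError("first-order fit requires strictly positive concentrations")
    min_n = 2 if through_origin else 3
    if len(ts) < min_n:
        raise ValueError(f"need at least {min_n} points, got {len(ts)}")
    t = ts.times
    v0 = ts.value_at_t0()
    y = -np.log(ts.values / v0)

    if through_origin:
        stt = float(t @ t)
        if stt == 0.0:
            raise ValueError("all observations at t = 0: slope undefined")
        k = float(t @ y) / stt
        method = "log-linear-origin"
        dof = len(t) - 1
    else:
        slope, intercept = np.polyfit(t, y, 1)
        k = float(slope)
        method = "log-linear-intercept"
        dof = len(t) - 2

    if k < 0:
        warnings.warn(
            f"negative first-order slope {k:.4g} clipped to 0 (rising series?)",
            stacklevel=2,
        )
        k = 0.0

    pred = k * t if through_origin else slope * t + intercept
    resid = y - pred
    s2 = float(resid @ resid) / dof if dof > 0 else float("nan")
    if through_origin:
        se = float(np.sqrt(s2 / stt)) if dof > 0 else float("nan")
    else:
        sxx = float(np.sum((t - t.mean()) ** 2))
        se = float(np.sqrt(s2 / sxx)) if dof > 0 else float("nan")
    try:
        r2 = goodness_of_fit(y, pred)
    except ValueError:
        r2 = float("nan")
    return FitResult(
        params={"k": k},
        stderr={"k": se},
        r2=r2,
        residuals=resid,
        n_obs=len(t),
        method=method,
        converged=True,
        window=(0.0, float(t.max())),
        extras={"value_at_t0": v0, "log_scale_r2": True},
    )


# ---------------------------------------------------------------------------
# Marquardt machinery
# ---------------------------------------------------------------------------


def _run_starts(residual_fn, starts, n_obs):
    """Run least_squares from each start; return best solution + diagnostics."""
    best = None
    diagnostics = []
    for x0 in starts:
        x0 = np.asarray(x0, dtype=float)
        method = "lm" if n_obs >= len(x0) else "trf"
        try:
            sol = least_squares(
                residual_fn,
                x0,
                method=method,
                ftol=FIT_TOL,
                xtol=FIT_TOL,
                gtol=FIT_TOL,
                max_nfev=FIT_MAX_NFEV,
            )
        except Exception as exc:  # singular model evaluation at this start
            diagnostics.append({"x0": x0.tolist(), "error": str(exc)})
            continue
        diagnostics.append(
            {"x0": x0.tolist(), "cost": sol.cost, "success": bool(sol.success)}
        )
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise ConvergenceError("no optimizer start converged", diagnostics)
    return best, diagnostics


def _gauss_newton_se(jac, resid, n_params):
    """Approximate parameter SEs (in optimizer coordinates) and condition flag."""
    n = len(resid)
    jtj = jac.T @ jac
    try:
        cond = float(np.linalg.cond(jtj))
    except np.linalg.LinAlgError:
        cond = float("inf")
    approximate = cond > SE_CONDITION_LIMIT
    dof = n - n_params
    if dof <= 0:
        return np.full(n_params, np.nan), approximate, cond
    s2 = float(resid @ resid) / dof
    try:
        cov = s2 * np.linalg.pinv(jtj)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(n_params, np.nan)
    return se, approximate, cond


def _log_start_grid(centers: dict[str, float], n_per_param: int) -> list[np.ndarray]:
    """Deterministic multi-start grid: log-spaced multipliers around each center."""
    if n_per_param < 1:
        raise ValueError("need at least one start per parameter")
    mult = (
        np.logspace(-2, 2, n_per_param) if n_per_param > 1 else np.array([1.0])
    )
    axes = [np.log(np.maximum(c, 1e-300) * mult) for c in centers.values()]
    return [np.array(combo) for combo in itertools.product(*axes)]


# ---------------------------------------------------------------------------
# Hydroperoxide (inhibited logistic) fit
# ---------------------------------------------------------------------------


def fit_hydroperoxide(
    ts: TimeSeries,
    ic: InitialConditions,
    fixed: dict[str, float],
    free: tuple[str, ...] = ("k1", "kf", "aprime_max"),
    n_starts_per_param: int = 5,
) -> FitResult:
    """Fit the inhibited hydroperoxide law to a 7-OOH series.

    ``fixed`` must determine the quercetin depletion constant: either ``ki``
    directly, or ``kd`` and ``ko`` so that ki = kd + ko + kf tracks a free
    ``kf``.  Free parameters (any of ``k1``, ``kf``, ``aprime_max``) are
    log-parameterised; ``aprime_max`` is additionally bounded below by the
    largest observed value.  Deterministic multi-start; the lowest-cost
    converged run wins.

    Note: with ``ki`` fixed independently and both ``k1`` and ``kf`` free,
    only the ratio k1/kf is identifiable (they enter the law solely through
    k1/(kf ki Q0)); the returned pair is then one point on the ridge.
    """
    if ts.species != "hydroperoxide_7OOH":
        raise ValueError(f"expected a hydroperoxide_7OOH series, got {ts.species!r}")
    free = tuple(free)
    unknown = set(free) - {"k1", "kf", "aprime_max"}
    if unknown:
        raise ValueError(f"unknown free parameters: {sorted(unknown)}")
    if "ki" not in fixed and not {"kd", "ko"} <= fixed.keys():
        raise ValueError("fixed must supply ki, or kd and ko")
    if "kf" not in free and "kf" not in fixed:
        raise ValueError("kf must be free or fixed")
    if len(ts) < len(free):
        raise ValueError(f"{len(ts)} observations cannot determine {len(free)} parameters")

    t, y = ts.times, ts.values
    amax_lower = max(float(y.max()), ic.Aprime0)

    def build(p: dict[str, float]) -> tuple[RateConstants, InitialConditions]:
        k1 = p.get("k1", fixed.get("k1", 0.0))
        kf = p.get("kf", fixed.get("kf"))
        kwargs = dict(k1=k1, kf=kf, kd=fixed.get("kd", 0.0), ko=fixed.get("ko", 0.0))
        if "ki" in fixed:
            kwargs["ki"] = fixed["ki"]
        rc = RateConstants(**kwargs)
        ic2 = ic
        if "aprime_max" in p:
            ic2 = replace(ic, Aprime_max=p["aprime_max"])
        return rc, ic2

    def unpack(theta: np.ndarray) -> dict[str, float]:
        p = {}
        with np.errstate(over="ignore"):
            for name, th in zip(free, theta):
                if name == "aprime_max":
                    p[name] = amax_lower + float(np.exp(min(th, 700.0)))
                else:
                    p[name] = float(np.exp(min(th, 700.0)))
        return p

    def residual(theta: np.ndarray) -> np.ndarray:
        try:
            with np.errstate(over="ignore", invalid="ignore"):
                rc, ic2 = build(unpack(theta))
                r = hydroperoxide_conc(rc, ic2, t) - y
            return np.where(np.isfinite(r), r, 1e6)
        except (ValueError, OverflowError, ZeroDivisionError):
            return np.full(len(t), 1e6)

    # Data-driven start centers: the early specific growth rate of A'
    # approximates m3 (1 - m2) = k1 (1 - m2) / (kf Q0).
    nonzero = t > 0
    if np.any(nonzero) and y[np.argmin(t)] > 0:
        t1 = t[nonzero].min()
        v1 = float(np.mean(y[t == t1]))
        growth = max(np.log(max(v1, 1e-12) / ts.value_at_t0()) / t1, 1e-3)
    else:
        growth = 1.0
    kf_center = fixed.get("kf") or max(fixed.get("ki", 1.0) / 2.0, 0.1)
    centers = {}
    for name in free:
        if name == "k1":
            centers[name] = growth * kf_center * ic.Q0
        elif name == "kf":
            centers[name] = kf_center
        else:
            centers[name] = amax_lower  # offset above the lower bound
    starts = _log_start_grid(centers, n_starts_per_param)

    best, diagnostics = _run_starts(residual, starts, len(t))
    p = unpack(best.x)
    rc, ic2 = build(p)
    pred = hydroperoxide_conc(rc, ic2, t)
    resid = pred - y
    se_theta, approx, cond = _gauss_newton_se(best.jac, resid, len(free))
    stderr = {}
    for i, name in enumerate(free):
        scale = p[name] - amax_lower if name == "aprime_max" else p[name]
        stderr[name] = float(abs(scale) * se_theta[i])
    try:
        r2 = goodness_of_fit(y, pred)
    except ValueError:
        r2 = float("nan")
    return FitResult(
        params={**p, "ki": rc.ki},
        stderr=stderr,
        r2=r2,
        residuals=resid,
        n_obs=len(t),
        method="hydroperoxide-marquardt",
        converged=True,
        window=(0.0, float(t.max())),
        extras={
            "cost": float(best.cost),
            "n_starts": len(starts),
            "se_approximate": approx,
            "condition_number": cond,
            "start_diagnostics": diagnostics,
            "fixed": dict(fixed),
        },
    )


# ---------------------------------------------------------------------------
# Epoxidation fit (one-dimensional, linear in k4)
# ---------------------------------------------------------------------------


def fit_epoxidation(
    ts: TimeSeries,
    ic: InitialConditions,
    fixed: RateConstants,
    backend: str = "quadrature",
) -> FitResult:
    """Least-squares estimate of the epoxidation constant k4.

    All other constants (k1, kf, k5, ki) are fixed.  The epoxide excess
    E(t) - E0 is exactly proportional to k4, so the least-squares minimiser
    has the closed form k4 = sum(g (y - E0)) / sum(g^2) with g the model
    curve at k4 = 1, clipped at 0.  ``backend`` selects the exact quadrature
    (default: it matches the canonical ODE) or the quadratic Taylor form.
    """
    if ts.species != "epoxide_56EP":
        raise ValueError(f"expected an epoxide_56EP series, got {ts.species!r}")
    if backend not in ("quadrature", "taylor"):
        raise ValueError(f"backend must be 'quadrature' or 'taylor', got {backend!r}")
    rc1 = replace(fixed, k4=1.0, ki=fixed.ki if fixed.ki_supplied else None)
    t, y = ts.times, ts.values
    if backend == "quadrature":
        g = np.array([epoxide_quadrature(rc1, ic, tj).value - ic.E0 for tj in t])
    else:
        g = np.asarray(epoxide_taylor(rc1, ic, t)) - ic.E0
    sgg = float(g @ g)
    if sgg == 0.0:
        raise ConvergenceError("model curve is flat: k4 not identifiable on this grid")
    k4 = float(g @ (y - ic.E0)) / sgg
    if k4 < 0:
        warnings.warn(f"negative k4 estimate {k4:.4g} clipped to 0", stacklevel=2)
        k4 = 0.0
    pred = ic.E0 + k4 * g
    resid = pred - y
    dof = len(t) - 1
    se = float(np.sqrt((resid @ resid) / dof / sgg)) if dof > 0 else float("nan")
    try:
        r2 = goodness_of_fit(y, pred)
    except ValueError:
        r2 = float("nan")
    return FitResult(
        params={"k4": k4},
        stderr={"k4": se},
        r2=r2,
        residuals=resid,
        n_obs=len(t),
        method=f"epoxide-{backend}",
        converged=True,
        window=(0.0, float(t.max())),
        extras={"fixed": {k: getattr(fixed, k) for k in ("k1", "kf", "k5", "ki")}},
    )


# ---------------------------------------------------------------------------
# Plain logistic (control) fit
# ---------------------------------------------------------------------------


def fit_logistic_control(
    ts: TimeSeries,
    n_starts_per_param: int = 5,
) -> FitResult:
    """Fit A'0, A'max and k1 of the plain logistic to a control 7-OOH series."""
    if ts.species != "hydroperoxide_7OOH":
        raise ValueError(f"expected a hydroperoxide_7OOH series, got {ts.species!r}")
    if len(ts) < 3:
        raise ConvergenceError(
            f"under-determined: {len(ts)} observations for 3 parameters"
        )
    t, y = ts.times, ts.values
    amax_lower = float(y.max())

    def unpack(theta):
        amax = amax_lower + np.exp(theta[1])
        a0 = amax * expit(theta[0])
        k1 = np.exp(theta[2])
        return a0, amax, k1

    def residual(theta):
        try:
            with np.errstate(over="ignore", invalid="ignore"):
                a0, amax, k1 = unpack(theta)
                r = hydroperoxide_logistic_control(a0, amax, k1, t) - y
            return np.where(np.isfinite(r), r, 1e6)
        except (ValueError, OverflowError):
            return np.full(len(t), 1e6)

    v0 = max(ts.value_at_t0(), 1e-9)
    amax_center = 1.5 * amax_lower
    nonzero = t > 0
    t1 = t[nonzero].min()
    v1 = float(np.mean(y[t == t1]))
    odds = lambda v, m: max(v, 1e-12) / max(m - v, 1e-12)
    k1_center = max(np.log(odds(v1, amax_center) / odds(v0, amax_center)) / t1, 1e-2)
    theta0_a0 = float(logit(np.clip(v0 / amax_center, 1e-9, 1 - 1e-9)))
    mult = np.logspace(-2, 2, n_starts_per_param) if n_starts_per_param > 1 else [1.0]
    starts = [
        np.array([theta0_a0, np.log(amax_center - amax_lower), np.log(k1_center * m)])
        for m in mult
    ]
    # a second sweep over the plateau guess, which is weakly informed by data
    starts += [
        np.array([theta0_a0, np.log((amax_center - amax_lower) * m), np.log(k1_center)])
        for m in (0.1, 10.0)
    ]

    best, diagnostics = _run_starts(residual, starts, len(t))
    a0, amax, k1 = unpack(best.x)
    pred = hydroperoxide_logistic_control(a0, amax, k1, t)
    resid = pred - y
    se_theta, approx, cond = _gauss_newton_se(best.jac, resid, 3)
    stderr = {
        "aprime0": float(a0 * (1.0 - a0 / amax) * se_theta[0]),
        "aprime_max": float((amax - amax_lower) * se_theta[1]),
        "k1": float(k1 * se_theta[2]),
    }
    try:
        r2 = goodness_of_fit(y, pred)
    except ValueError:
        r2 = float("nan")
    return FitResult(
        params={"aprime0": float(a0), "aprime_max": float(amax), "k1": float(k1)},
        stderr=stderr,
        r2=r2,
        residuals=resid,
        n_obs=len(t),
        method="logistic-control",
        converged=True,
        window=(0.0, float(t.max())),
        extras={
            "cost": float(best.cost),
            "n_starts": len(starts),
            "se_approximate": approx,
            "condition_number": cond,
            "start_diagnostics": diagnostics,
        },
    )


# ---------------------------------------------------------------------------
# Subtraction arithmetic between atmosphere fits
# ---------------------------------------------------------------------------


def _rate_of(fit) -> float:
    if isinstance(fit, FitResult):
        return fit.k("k") if "k" in fit.params else fit.k()
    return float(fit)


def subtraction_constants(fit_oxygen, fit_nitrogen, fit_combo) -> dict[str, float]:
    """Split the atmosphere fits into component constants.

    kd is the nitrogen constant; ko = k(oxygen) - k(nitrogen); kf =
    k(oxygen+cholesterol) - k(oxygen); ki is the combined constant.  Negative
    differences are clipped to 0 with a warning.  Arguments may be FitResults
    or plain rate constants (h^-1).
    """
    k_n2 = _rate_of(fit_nitrogen)
    k_ox = _rate_of(fit_oxygen)
    k_all = _rate_of(fit_combo)
    ko = k_ox - k_n2
    kf = k_all - k_ox
    if ko < 0:
        warnings.warn(f"ko = {ko:.4g} < 0 clipped to 0", stacklevel=2)
        ko = 0.0
    if kf < 0:
        warnings.warn(f"kf = {kf:.4g} < 0 clipped to 0", stacklevel=2)
        kf = 0.0
    return {"kd": k_n2, "ko": ko, "kf": kf, "ki": k_all}
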