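"""Integrated rate laws for quercetin degradation and cholesterol oxidation at 150 °C.

Species follow the standard notation of cholesterol-oxidation kinetics:

* ``Q``  -- quercetin (free-radical scavenger), depleted by thermal degradation
  (``kd``), oxidative degradation (``ko``) and radical scavenging (``kf``);
  the overall depletion constant is ``ki = kd + ko + kf``.
* ``A``  -- cholesterol, lost to first-order thermal degradation (``k5``).
* ``A'`` -- 7-hydroperoxycholesterol (7-OOH), formed by the free-radical chain
  reaction (``k1``) and inhibited by quercetin; bounded by the logistic
  plateau ``A'_max``.
* ``E``  -- 5,6-epoxycholesterol (5,6-EP), formed from cholesterol and 7-OOH
  (``k4``), likewise inhibited by quercetin.

All rate constants are per hour and time is in hours everywhere in this
package; concentrations are either percent of the initial amount or
mg per 100 g cholesterol, carried explicitly by :class:`TimeSeries`.

The closed forms here are exact integrals of the governing rate equations
(with the exception of the epoxide Taylor form, a quadratic-in-time
approximation) and are cross-validated against the numerical integration in
:mod:`querchol.oracle`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
from scipy.integrate import quad

__all__ = [
    "SPECIES",
    "TREATMENTS",
    "UNITS",
    "TAYLOR_DEGENERACY_THRESHOLD",
    "SingularParameterError",
    "QuadratureError",
    "RateConstants",
    "InitialConditions",
    "TaylorCoefficients",
    "TimeSeries",
    "QuadratureValue",
    "quercetin_decay",
    "cholesterol_decay",
    "omega",
    "hydroperoxide_conc",
    "hydroperoxide_logistic_control",
    "epoxide_quadrature",
    "epoxide_taylor",
    "taylor_coefficients",
]

# ---------------------------------------------------------------------------
# Module-level configuration (vocabulary and numerical thresholds)
# ---------------------------------------------------------------------------

#: Recognised species labels for measured or simulated trajectories.
SPECIES = frozenset(
    {"quercetin", "cholesterol", "hydroperoxide_7OOH", "epoxide_56EP", "total_COPs"}
)

#: Recognised treatment labels. The first three are the quercetin-alone
#: atmospheres; the last two are the cholesterol heating treatments.
TREATMENTS = frozenset(
    {"nitrogen", "oxygen", "oxygen_cholesterol", "control_no_quercetin", "with_quercetin"}
)

#: Concentration units carried by a TimeSeries.
UNITS = frozenset({"percent_of_initial", "mg_per_100g_cholesterol"})

#: |ki - k5| below this (h^-1) makes the epoxide Taylor form numerically
#: singular (it divides by ki - k5); callers are directed to the quadrature.
TAYLOR_DEGENERACY_THRESHOLD = 1e-6


class SingularParameterError(ValueError):
    """A parameter combination makes a closed form singular (division by ~0)."""


class QuadratureError(RuntimeError):
    """Numerical quadrature failed to converge to the requested tolerance."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RateConstants:
    """The rate constants of the coupled quercetin/cholesterol network.

    ``ki`` may be supplied independently (``ki_supplied`` records this) because
    published values of ``ki`` and of ``kd + ko + kf`` need not be consistent;
    when omitted it is derived as the sum. ``kp = ki * kf`` is always derived.

    ``q_convention`` records the scale on which quercetin concentration is
    expressed ("percent" for Q0 = 100, "mass_fraction" for Q0 = 0.02): the
    scavenging constant ``kf`` and chain constant ``k1`` are only meaningful
    together with this convention.
    """

    k1: float = 0.0
    k4: float = 0.0
    k5: float = 0.0
    kd: float = 0.0
    ko: float = 0.0
    kf: float = 0.0
    ki: float | None = None
    q_convention: str = "percent"
    ki_supplied: bool = field(init=False, default=False)

    def __post_init__(self) -> None:
        for name in ("k1", "k4", "k5", "kd", "ko", "kf"):
            v = getattr(self, name)
            if not (v >= 0.0):
                raise ValueError(f"rate constant {name} must be >= 0, got {v}")
        if self.ki is None:
            object.__setattr__(self, "ki", self.kd + self.ko + self.kf)
        else:
            if not (self.ki >= 0.0):
                raise ValueError(f"rate constant ki must be >= 0, got {self.ki}")
            object.__setattr__(self, "ki_supplied", True)

    @property
    def kp(self) -> float:
        """Composite constant ki * kf (h^-2), as used in the hydroperoxide law."""
        return self.ki * self.kf


@dataclass(frozen=True)
class InitialConditions:
    """Concentrations at zero heating time defining one scenario.

    All values must be strictly positive: the hydroperoxide law divides by
    ``Aprime0`` and the inhibited rate equations divide by the quercetin
    concentration.
    """

    A0: float
    Aprime0: float
    Aprime_max: float
    E0: float
    Q0: float
    unit: str = "percent_of_initial"

    def __post_init__(self) -> None:
        for name in ("A0", "Aprime0", "Aprime_max", "E0", "Q0"):
            v = getattr(self, name)
            if not (v > 0.0):
                raise ValueError(f"initial condition {name} must be > 0, got {v}")
        if self.Aprime0 > self.Aprime_max:
            raise ValueError(
                f"Aprime0 ({self.Aprime0}) must not exceed Aprime_max ({self.Aprime_max})"
            )


class TaylorCoefficients(NamedTuple):
    """Coefficients of the quadratic-in-time epoxide approximation.

    m2 = A'0 / A'max (dimensionless), m3 = k1 / (kf * Q0) (h^-1, the initial
    specific growth rate of 7-OOH), m4 (h^-2) the quadratic coefficient.
    """

    m2: float
    m3: float
    m4: float


@dataclass
class TimeSeries:
    """One species' measured or simulated trajectory.

    ``times`` are hours, non-negative and strictly ascending within each
    replicate; ``values`` are concentrations in ``unit`` and must be
    non-negative.
    """

    species: str
    treatment: str
    times: np.ndarray
    values: np.ndarray
    replicates: np.ndarray | None = None
    unit: str = "percent_of_initial"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.species not in SPECIES:
            raise ValueError(f"unknown species {self.species!r}")
        if self.treatment not in TREATMENTS:
            raise ValueError(f"unknown treatment {self.treatment!r}")
        if self.unit not in UNITS:
            raise ValueError(f"unknown unit {self.unit!r}")
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be 1-d arrays of equal length")
        if self.replicates is None:
            self.replicates = np.ones(self.times.shape, dtype=int)
        else:
            self.replicates = np.asarray(self.replicates)
            if self.replicates.shape != self.times.shape:
                raise ValueError("replicates must match times in length")
        if np.any(self.times < 0):
            raise ValueError("times must be >= 0")
        if np.any(self.values < 0):
            raise ValueError("values must be >= 0")
        if np.any(~np.isfinite(self.times)) or np.any(~np.isfinite(self.values)):
            raise ValueError("times and values must be finite")
        for rep in np.unique(self.replicates):
            t = self.times[self.replicates == rep]
            if np.any(np.diff(t) <= 0):
                raise ValueError(f"times must be strictly ascending within replicate {rep}")

    def __len__(self) -> int:
        return len(self.times)

    def value_at_t0(self) -> float:
        """Mean measured value at the earliest time point (across replicates)."""
        t0 = self.times.min()
        return float(self.values[self.times == t0].mean())

    def windowed(self, t_max_hours: float) -> "TimeSeries":
        """Restrict the series to times <= ``t_max_hours``."""
        keep = self.times <= t_max_hours
        if not np.any(keep):
            raise ValueError(f"window 0-{t_max_hours} h excludes all data")
        return replace(
            self,
            times=self.times[keep],
            values=self.values[keep],
            replicates=self.replicates[keep],
        )


class QuadratureValue(NamedTuple):
    """An epoxide concentration with its quadrature error estimate."""

    value: float
    abserr: float


# ---------------------------------------------------------------------------
# First-order decays (quercetin, cholesterol)
# ---------------------------------------------------------------------------


def _check_time(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    return t


def quercetin_decay(Q0: float, rate: float, t) -> np.ndarray | float:
    """Residual quercetin Q0 * exp(-rate * t).

    The same exponential covers thermal degradation alone (rate = kd, under
    nitrogen), thermal plus oxidative degradation (rate = kd + ko, under
    oxygen) and the overall depletion (rate = ki, with oxygen and cholesterol).
    """
    if not (Q0 > 0):
        raise ValueError(f"Q0 must be > 0, got {Q0}")
    if not (rate >= 0):
        raise ValueError(f"rate must be >= 0, got {rate}")
    t = _check_time(t)
    out = Q0 * np.exp(-rate * t)
    return out if out.ndim else float(out)


def cholesterol_decay(A0: float, k5: float, t) -> np.ndarray | float:
    """Residual cholesterol A0 * exp(-k5 * t) (first-order thermal loss)."""
    if not (A0 > 0):
        raise ValueError(f"A0 must be > 0, got {A0}")
    if not (k5 >= 0):
        raise ValueError(f"k5 must be >= 0, got {k5}")
    t = _check_time(t)
    out = A0 * np.exp(-k5 * t)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Hydroperoxide (7-OOH) formation under quercetin inhibition
# ---------------------------------------------------------------------------


def omega(k1: float, kp: float, Q0: float, ki: float, t) -> np.ndarray | float:
    """Inhibition factor of the integrated hydroperoxide law.

    omega(t) = exp[(k1 / (Q0 * kp)) * (1 - e^{ki t})], obtained by separating
    variables in the inhibited logistic rate equation with the quercetin
    trajectory Q(t) = Q0 e^{-ki t} substituted in (kp = ki * kf).  It equals 1
    at t = 0 and decreases monotonically towards 0; uses expm1 so the
    ki -> 0 limit (plain logistic with rate k1 / (kf Q0)) is reached smoothly.
    """
    if Q0 == 0 or kp == 0:
        raise SingularParameterError("omega requires Q0 > 0 and kp > 0")
    if not (Q0 > 0 and kp > 0 and k1 >= 0 and ki >= 0):
        raise ValueError("omega requires k1, ki >= 0 and Q0, kp > 0")
    t = _check_time(t)
    exponent = -(k1 / (Q0 * kp)) * np.expm1(ki * t)
    out = np.exp(exponent)
    return out if out.ndim else float(out)


def hydroperoxide_conc(rc: RateConstants, ic: InitialConditions, t) -> np.ndarray | float:
    """7-OOH concentration under quercetin inhibition.

    A'(t) = A'max / [1 - (1 - A'max/A'0) * omega(t)]; equals A'0 at t = 0 and
    approaches A'max as omega -> 0.
    """
    w = omega(rc.k1, rc.kp, ic.Q0, rc.ki, t)
    denom = 1.0 - (1.0 - ic.Aprime_max / ic.Aprime0) * w
    if np.any(denom <= 0):
        raise ValueError("hydroperoxide denominator <= 0: invalid parameters")
    out = ic.Aprime_max / denom
    return out if np.ndim(out) else float(out)


def hydroperoxide_logistic_control(
    Aprime0: float, Aprime_max: float, k1: float, t
) -> np.ndarray | float:
    """7-OOH formation without quercetin: the plain logistic.

    A'(t) = A'max / [1 + (A'max/A'0 - 1) * e^{-k1 t}].
    """
    if not (0 < Aprime0 <= Aprime_max):
        raise ValueError(
            f"need 0 < Aprime0 <= Aprime_max, got {Aprime0}, {Aprime_max}"
        )
    if not (k1 >= 0):
        raise ValueError(f"k1 must be >= 0, got {k1}")
    t = _check_time(t)
    out = Aprime_max / (1.0 + (Aprime_max / Aprime0 - 1.0) * np.exp(-k1 * t))
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Epoxide (5,6-EP) formation
# ---------------------------------------------------------------------------


def _epoxide_scale(rc: RateConstants, prefactor: str) -> float:
    # Direct substitution of the quercetin and hydroperoxide solutions into the
    # epoxidation rate equation puts kf in the denominator; "printed" selects
    # the kp variant for comparison with the published form.
    if prefactor == "derived":
        return rc.kf
    if prefactor == "printed":
        return rc.kp
    raise ValueError(f"prefactor must be 'derived' or 'printed', got {prefactor!r}")


def epoxide_quadrature(
    rc: RateConstants,
    ic: InitialConditions,
    t: float,
    prefactor: str = "derived",
    epsabs: float = 1e-10,
    epsrel: float = 1e-10,
) -> QuadratureValue:
    """5,6-EP concentration by numerical quadrature of the exact integral.

    E(t) = E0 + (k4 A0 A'max / (c Q0)) * integral_0^t e^{(ki-k5)s} /
    [1 - (1 - A'max/A'0) omega(s)] ds, with c = kf (derived form) or kp
    (printed variant).  Returns the value together with the quadrature's
    absolute-error estimate.
    """
    t = float(t)
    if t < 0:
        raise ValueError("time must be >= 0")
    if rc.k4 == 0.0 or t == 0.0:
        return QuadratureValue(ic.E0, 0.0)
    c = _epoxide_scale(rc, prefactor)
    if c <= 0:
        raise SingularParameterError("epoxide prefactor requires kf > 0 (or kp > 0)")
    lam = rc.ki - rc.k5
    shape = 1.0 - ic.Aprime_max / ic.Aprime0

    def integrand(s: float) -> float:
        w = math.exp(-(rc.k1 / (ic.Q0 * rc.kp)) * math.expm1(rc.ki * s))
        return math.exp(lam * s) / (1.0 - shape * w)

    value, abserr = quad(integrand, 0.0, t, epsabs=epsabs, epsrel=epsrel, limit=200)
    scale = rc.k4 * ic.A0 * ic.Aprime_max / (c * ic.Q0)
    if abserr > max(epsabs, epsrel * abs(value)) * 100:
        raise QuadratureError(
            f"quadrature error estimate {abserr:.3e} too large for integral {value:.6e} "
            f"(t={t}, ki={rc.ki}, k5={rc.k5})"
        )
    return QuadratureValue(ic.E0 + scale * value, scale * abserr)


def taylor_coefficients(rc: RateConstants, ic: InitialConditions) -> TaylorCoefficients:
    """Coefficients m2, m3, m4 of the quadratic epoxide approximation.

    m2 = A'0/A'max, m3 = k1/(kf Q0), and
    m4 = m3 (2 m3 m2^2 - m2 ki - 3 m2 m3 + ki + m3).
    """
    if rc.kf <= 0 or ic.Q0 <= 0:
        raise SingularParameterError("taylor coefficients require kf > 0 and Q0 > 0")
    m2 = ic.Aprime0 / ic.Aprime_max
    m3 = rc.k1 / (rc.kf * ic.Q0)
    m4 = m3 * (2.0 * m3 * m2**2 - m2 * rc.ki - 3.0 * m2 * m3 + rc.ki + m3)
    return TaylorCoefficients(m2=m2, m3=m3, m4=m4)


def epoxide_taylor(
    rc: RateConstants, ic: InitialConditions, t, prefactor: str = "derived"
) -> np.ndarray | float:
    """5,6-EP concentration from the quadratic Taylor-series closed form.

    Replaces the hydroperoxide factor in the epoxidation integral by its
    quadratic expansion about t = 0, giving an elementary antiderivative.
    Valid only near the start of heating (the fitting window); requires
    |ki - k5| above :data:`TAYLOR_DEGENERACY_THRESHOLD` because the closed
    form divides by ki - k5.
    """
    t = _check_time(t)
    lam = rc.ki - rc.k5
    if abs(lam) < TAYLOR_DEGENERACY_THRESHOLD:
        raise SingularParameterError(
            f"|ki - k5| = {abs(lam):.2e} < {TAYLOR_DEGENERACY_THRESHOLD}: "
            "the Taylor form is singular; use epoxide_quadrature"
        )
    if rc.k4 == 0.0:
        out = np.full_like(np.asarray(t, dtype=float), ic.E0)
        return out if out.ndim else float(out)
    c = _epoxide_scale(rc, prefactor)
    if c <= 0:
        raise SingularParameterError("epoxide prefactor requires kf > 0 (or kp > 0)")
    m2, m3, m4 = taylor_coefficients(rc, ic)
    a = m3 * (1.0 - m2)
    e = np.exp(lam * t)
    bracket = (
        (1.0 + a * t + m4 * t**2) * e
        - ((a + 2.0 * m4 * t) / lam) * e
        + (2.0 * m4 / lam**2) * e
        - 1.0
        + a / lam
        - 2.0 * m4 / lam**2
    )
    out = ic.E0 + rc.k4 * ic.A0 * ic.Aprime0 / (c * ic.Q0 * lam) * bracket
    return out if np.ndim(out) else float(out)
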