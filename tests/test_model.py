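"""Closed-form rate laws: frozen examples, identities, and invariants."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from querchol.model import (
    InitialConditions,
    RateConstants,
    SingularParameterError,
    TimeSeries,
    cholesterol_decay,
    epoxide_quadrature,
    epoxide_taylor,
    hydroperoxide_conc,
    hydroperoxide_logistic_control,
    omega,
    quercetin_decay,
    taylor_coefficients,
)


# ---------------------------------------------------------------------------
# First-order decays
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "fn, c0, rate, t, expected",
    [
        # zero-rate identities
        (quercetin_decay, 100.0, 0.0, 2.0, 100.0),
        (cholesterol_decay, 96.9, 0.0, 5.0, 96.9),
        # hand-evaluated exponentials: c0 * exp(-rate * t)
        (quercetin_decay, 100.0, 0.868, 1.0, 41.979029),
        (quercetin_decay, 100.0, 0.253, 2.0, 60.290237),
        (cholesterol_decay, 96.9, 0.19, 1.0, 80.132340),
        (cholesterol_decay, 97.9, 0.94, 0.5, 61.187722),
    ],
)
def test_first_order_decay_values(fn, c0, rate, t, expected):
    assert fn(c0, rate, t) == pytest.approx(expected, abs=1e-5)


def test_decay_rejects_invalid_domain():
    with pytest.raises(ValueError):
        quercetin_decay(100.0, 0.5, -1.0)
    with pytest.raises(ValueError):
        quercetin_decay(100.0, -0.5, 1.0)
    with pytest.raises(ValueError):
        quercetin_decay(0.0, 0.5, 1.0)
    with pytest.raises(ValueError):
        cholesterol_decay(96.9, -0.1, 1.0)


def test_decay_strictly_decreasing_with_positive_rate():
    t = np.linspace(0, 2, 50)
    v = quercetin_decay(100.0, 0.7, t)
    assert np.all(np.diff(v) < 0)
    assert np.all(v > 0)


# ---------------------------------------------------------------------------
# Inhibition factor omega
# ---------------------------------------------------------------------------


def test_omega_is_one_at_time_zero_and_without_chain_reaction():
    assert omega(1.8e-4, 23.5176, 100.0, 7.17, 0.0) == pytest.approx(1.0, abs=0)
    assert omega(0.0, 23.5176, 100.0, 7.17, 3.0) == pytest.approx(1.0, abs=0)


def test_omega_hand_value():
    # exp[(k1/(Q0 kp)) (1 - e^{ki t})] at k1=1.8e-4, ki=7.17, kf=3.28, t=0.5
    got = omega(1.8e-4, 7.17 * 3.28, 100.0, 7.17, 0.5)
    assert got == pytest.approx(0.9999973170749034, rel=1e-12)


def test_omega_monotone_nonincreasing_in_unit_interval():
    t = np.linspace(0, 1, 40)
    w = omega(600.0, 4.148 * 3.28, 100.0, 4.148, t)
    assert np.all(np.diff(w) <= 0)
    assert np.all((w > 0) & (w <= 1.0))


def test_omega_singular_parameters():
    with pytest.raises(SingularParameterError):
        omega(1.0, 0.0, 100.0, 1.0, 0.5)
    with pytest.raises(SingularParameterError):
        omega(1.0, 1.0, 0.0, 1.0, 0.5)


# ---------------------------------------------------------------------------
# Hydroperoxide closed forms
# ---------------------------------------------------------------------------


def test_hydroperoxide_endpoints(recovery_truth):
    rc, ic = recovery_truth.rc, recovery_truth.ic
    assert hydroperoxide_conc(rc, ic, 0.0) == pytest.approx(ic.Aprime0, rel=1e-14)
    assert hydroperoxide_conc(rc, ic, 50.0) == pytest.approx(ic.Aprime_max, rel=1e-9)
    t = np.linspace(0, 2, 100)
    a = hydroperoxide_conc(rc, ic, t)
    assert np.all(np.diff(a) >= 0)
    assert np.all(a <= ic.Aprime_max * (1 + 1e-12))


def test_hydroperoxide_reduces_to_logistic_as_ki_vanishes():
    # with quercetin not depleted (ki -> 0) the inhibited law is a plain
    # logistic with effective rate k1/(kf Q0)
    rc = RateConstants(k1=600.0, kf=3.28, ki=1e-8)
    ic = InitialConditions(A0=96.9, Aprime0=0.13, Aprime_max=20.0, E0=0.46, Q0=100.0)
    t = np.linspace(0, 2, 50)
    inhibited = hydroperoxide_conc(rc, ic, t)
    logistic = hydroperoxide_logistic_control(
        ic.Aprime0, ic.Aprime_max, rc.k1 / (rc.kf * ic.Q0), t
    )
    assert np.max(np.abs(inhibited - logistic) / logistic) < 1e-6


def test_logistic_control_identities():
    assert hydroperoxide_logistic_control(0.82, 25.0, 488.2, 0.0) == pytest.approx(0.82)
    assert hydroperoxide_logistic_control(0.82, 25.0, 488.2, 10.0) == pytest.approx(25.0)
    # symmetric midpoint: A'0 = A'max/2 gives A'max / (1 + e^{-k1 t})
    t = 0.3
    got = hydroperoxide_logistic_control(12.5, 25.0, 4.0, t)
    assert got == pytest.approx(25.0 / (1.0 + math.exp(-4.0 * t)), rel=1e-14)


def test_logistic_control_rejects_start_above_plateau():
    with pytest.raises(ValueError):
        hydroperoxide_logistic_control(26.0, 25.0, 1.0, 0.5)


# ---------------------------------------------------------------------------
# Taylor coefficients and epoxide forms
# ---------------------------------------------------------------------------


def test_taylor_coefficients_identities():
    ic_sat = InitialConditions(A0=96.9, Aprime0=20.0, Aprime_max=20.0, E0=0.46, Q0=100.0)
    rc = RateConstants(k1=1.0, kf=2.0, kd=0.1)
    assert taylor_coefficients(rc, ic_sat).m2 == pytest.approx(1.0)
    rc0 = RateConstants(k1=0.0, kf=2.0, kd=0.1)
    m = taylor_coefficients(rc0, ic_sat)
    assert m.m3 == 0.0 and m.m4 == 0.0


def test_taylor_coefficients_published_constants(published_truth):
    # hand arithmetic: m3 = 1.8e-4/(3.28*100); m4 = m3(2 m3 m2^2 - m2 ki
    # - 3 m2 m3 + ki + m3) with m2 = 0.13/20, ki = 7.17
    m = taylor_coefficients(published_truth.rc, published_truth.ic)
    assert m.m2 == pytest.approx(0.0065, rel=1e-12)
    assert m.m3 == pytest.approx(5.487804878e-07, rel=1e-9)
    assert m.m4 == pytest.approx(3.909180478e-06, rel=1e-9)


def test_epoxide_forms_return_e0_at_t0_and_with_k4_zero(recovery_truth):
    rc, ic = recovery_truth.rc, recovery_truth.ic
    assert epoxide_quadrature(rc, ic, 0.0).value == ic.E0
    assert epoxide_taylor(rc, ic, 0.0) == pytest.approx(ic.E0, rel=1e-12)
    rc0 = RateConstants(
        k1=rc.k1, k4=0.0, k5=rc.k5, kd=rc.kd, ko=rc.ko, kf=rc.kf
    )
    assert epoxide_quadrature(rc0, ic, 0.4).value == ic.E0
    assert epoxide_taylor(rc0, ic, 0.4) == pytest.approx(ic.E0)


def test_epoxide_taylor_matches_quadrature_on_published_bundle(published_truth):
    # quadratic truncation error is tiny here (m3 ~ 5e-7); pinned regression
    # bound well inside the 2% contract
    rc, ic = published_truth.rc, published_truth.ic
    for t in (0.05, 0.167, 0.5):
        quad = epoxide_quadrature(rc, ic, t).value
        tay = epoxide_taylor(rc, ic, t)
        assert abs(tay - quad) / quad < 1e-6
        assert abs(tay - quad) / quad < 0.02


def test_epoxide_taylor_degenerate_rates_raise():
    rc = RateConstants(k1=1.0, k4=0.5, k5=0.5, kd=0.2, ko=0.2, kf=0.1)
    assert abs(rc.ki - rc.k5) < 1e-6
    ic = InitialConditions(A0=96.9, Aprime0=0.13, Aprime_max=20.0, E0=0.46, Q0=100.0)
    with pytest.raises(SingularParameterError):
        epoxide_taylor(rc, ic, 0.3)
    # the quadrature has no such singularity
    assert epoxide_quadrature(rc, ic, 0.3).value > ic.E0


def test_epoxide_quadrature_monotone_with_error_estimate(recovery_truth):
    rc, ic = recovery_truth.rc, recovery_truth.ic
    values = [epoxide_quadrature(rc, ic, t) for t in (0.1, 0.2, 0.3, 0.5)]
    es = [v.value for v in values]
    assert all(np.diff(es) > 0)
    assert all(v.abserr < 1e-6 * v.value for v in values)


def test_printed_prefactor_variant_scales_by_ki(recovery_truth):
    # derived form divides by kf, printed variant by kp = ki kf: the excess
    # over E0 differs exactly by the factor ki
    rc, ic = recovery_truth.rc, recovery_truth.ic
    d = epoxide_quadrature(rc, ic, 0.3, prefactor="derived").value - ic.E0
    p = epoxide_quadrature(rc, ic, 0.3, prefactor="printed").value - ic.E0
    assert d / p == pytest.approx(rc.ki, rel=1e-10)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


def test_rate_constants_ki_derivation_and_override():
    rc = RateConstants(kd=0.253, ko=0.615, kf=3.28)
    assert rc.ki == pytest.approx(4.148)
    assert not rc.ki_supplied
    assert rc.kp == pytest.approx(rc.ki * rc.kf)
    rc2 = RateConstants(kd=0.253, ko=0.615, kf=3.28, ki=7.17)
    assert rc2.ki == 7.17 and rc2.ki_supplied
    with pytest.raises(ValueError):
        RateConstants(k1=-1.0)


def test_initial_conditions_validation():
    with pytest.raises(ValueError):
        InitialConditions(A0=96.9, Aprime0=0.0, Aprime_max=20.0, E0=0.46, Q0=100.0)
    with pytest.raises(ValueError):
        InitialConditions(A0=96.9, Aprime0=21.0, Aprime_max=20.0, E0=0.46, Q0=100.0)


def test_timeseries_validation():
    with pytest.raises(ValueError):
        TimeSeries("quercetin", "nitrogen", [0.0, 0.5, 0.5], [1, 2, 3])
    with pytest.raises(ValueError):
        TimeSeries("quercetin", "nitrogen", [0.0, 0.5], [1.0, -2.0])
    with pytest.raises(ValueError):
        TimeSeries("unobtainium", "nitrogen", [0.0], [1.0])
    ts = TimeSeries(
        "quercetin", "nitrogen", [0.0, 0.5, 0.0, 0.5], [10, 9, 10.5, 9.2], [1, 1, 2, 2]
    )
    assert ts.value_at_t0() == pytest.approx(10.25)
    with pytest.raises(ValueError):
        ts.windowed(-1.0)


# ---------------------------------------------------------------------------
# Property tests
# ---------------------------------------------------------------------------


@given(
    k1=st.floats(1e-6, 1e4),
    kf=st.floats(0.05, 50.0),
    kd=st.floats(0.0, 10.0),
    ko=st.floats(0.0, 10.0),
    a0_frac=st.floats(1e-4, 1.0),
)
def test_hydroperoxide_bounded_monotone_positive(k1, kf, kd, ko, a0_frac):
    rc = RateConstants(k1=k1, kf=kf, kd=kd, ko=ko)
    ic = InitialConditions(
        A0=96.9, Aprime0=20.0 * a0_frac, Aprime_max=20.0, E0=0.46, Q0=100.0
    )
    t = np.linspace(0, 2, 30)
    a = hydroperoxide_conc(rc, ic, t)
    assert a[0] == pytest.approx(ic.Aprime0, rel=1e-12)
    assert np.all(np.diff(a) >= -1e-12)
    assert np.all(a > 0)
    assert np.all(a <= ic.Aprime_max * (1 + 1e-12))


def test_hydroperoxide_invariants_random_sweep():
    # 1,000 random valid parameter sets on a dense grid, single seeded sweep
    rng = np.random.default_rng(20260922)
    t = np.linspace(0.0, 2.0, 41)
    for _ in range(1000):
        rc = RateConstants(
            k1=float(10 ** rng.uniform(-4, 3.5)),
            kf=float(10 ** rng.uniform(-1.5, 1.5)),
            kd=float(rng.uniform(0, 5)),
            ko=float(rng.uniform(0, 5)),
        )
        aprime0 = float(rng.uniform(1e-3, 20.0))
        ic = InitialConditions(
            A0=96.9, Aprime0=aprime0, Aprime_max=20.0, E0=0.46, Q0=100.0
        )
        a = hydroperoxide_conc(rc, ic, t)
        assert a[0] == pytest.approx(aprime0, rel=1e-12)
        assert np.all(np.diff(a) >= -1e-9)
        assert np.all((a > 0) & (a <= 20.0 * (1 + 1e-12)))
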