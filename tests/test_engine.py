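"""Forward/inverse LMS transforms, percentile conversion, derived measures."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

import agrowth as ag


def node(L=1.0, M=86.0, S=3.0, age=5.0):
    return ag.LMSNode(age=age, L=L, M=M, S=S)


# ------------------------------------------------------- identity z-score

@pytest.mark.parametrize("X, M, S, expected", [
    (86.0, 86.0, 3.0, 0.0),     # at the median
    (89.0, 86.0, 3.0, 1.0),     # one SD above
    (92.0, 86.0, 3.0, 2.0),
])
def test_zscore_identity(X, M, S, expected):
    assert ag.zscore_identity(X, node(M=M, S=S)) == pytest.approx(expected)


def test_zscore_identity_rejects_nonpositive_S():
    with pytest.raises(ag.InvalidCoefficientError):
        ag.zscore_identity(86.0, node(S=0.0))


# -------------------------------------------------------- Box-Cox z-score

def test_zscore_boxcox_zero_at_median():
    for L in (-2.0, -0.5, 0.0, 1.0, 2.0):
        assert ag.zscore_boxcox(16.0, node(L=L, M=16.0, S=0.11)) == 0.0


def test_zscore_boxcox_L1_reduces_to_relative_deviation():
    # with L = 1: ((X/M) - 1)/S = (X - M)/(M*S)
    n = node(L=1.0, M=16.0, S=0.11)
    X = 18.3
    assert ag.zscore_boxcox(X, n) == pytest.approx(
        (X - 16.0) / (16.0 * 0.11), rel=1e-12)


def test_zscore_boxcox_log_limit():
    n = node(L=1e-9, M=16.0, S=0.11)
    X = 16.0 * math.exp(0.11)
    assert ag.zscore_boxcox(X, n) == pytest.approx(1.0, abs=1e-6)


def test_zscore_boxcox_frozen_value():
    # ((12/16)^-1.5 - 1)/(-1.5 * 0.11), evaluated independently with
    # 40-digit arithmetic
    z = ag.zscore_boxcox(12.0, node(L=-1.5, M=16.0, S=0.11))
    assert z == pytest.approx(-3.270307380842437, abs=1e-12)


def test_zscore_boxcox_domain_errors():
    with pytest.raises(ag.DomainError):
        ag.zscore_boxcox(0.0, node(L=-1.0, M=16.0, S=0.11))
    with pytest.raises(ag.InvalidCoefficientError):
        ag.zscore_boxcox(12.0, node(L=-1.0, M=-1.0, S=0.11))


@pytest.mark.parametrize("eps", [1e-4, 1e-6])
def test_boxcox_continuity_in_L_near_zero(eps):
    """|z(L=eps) - ln(X/M)/S| is O(eps): the two branches meet smoothly."""
    M, S = 16.0, 0.11
    for X in (10.0, 14.0, 16.0, 20.0, 25.0):
        z_log = math.log(X / M) / S
        for L in (eps, -eps):
            z = ag.zscore_boxcox(X, node(L=L, M=M, S=S))
            assert abs(z - z_log) <= 5.0 * eps


# ------------------------------------------------- percentile conversion

def test_percentile_of_zero_is_fifty():
    assert ag.percentile_from_z(0.0) == pytest.approx(50.0, abs=1e-12)


def test_percentile_frozen_value():
    assert ag.percentile_from_z(1.959964) == pytest.approx(97.5, abs=1e-3)


@settings(derandomize=True, max_examples=200)
@given(z=st.floats(min_value=-8.0, max_value=8.0))
def test_percentile_symmetry_and_bounds(z):
    p, q = ag.percentile_from_z(z), ag.percentile_from_z(-z)
    assert 0.0 < p < 100.0
    assert p + q == pytest.approx(100.0, abs=1e-10)


def test_percentile_matches_numerical_integration_of_the_density():
    """Independent oracle: adaptive quadrature of the standard normal pdf."""
    pdf = lambda t: math.exp(-t * t / 2.0) / math.sqrt(2.0 * math.pi)
    for z in np.arange(-6.0, 6.01, 0.5):
        tail, _ = quad(pdf, -math.inf, z)
        assert ag.percentile_from_z(float(z)) == pytest.approx(
            100.0 * tail, abs=1e-7)


def test_percentile_rejects_nonfinite():
    with pytest.raises(ag.DomainError):
        ag.percentile_from_z(math.nan)


def test_z_from_percentile_round_trip():
    assert ag.z_from_percentile(50.0) == pytest.approx(0.0, abs=1e-12)
    p = ag.percentile_from_z(1.3)
    assert ag.z_from_percentile(p) == pytest.approx(1.3, abs=1e-9)
    assert ag.z_from_percentile(2.5) == pytest.approx(-1.959964, abs=1e-3)
    for bad in (0.0, 100.0, -1.0):
        with pytest.raises(ag.DomainError):
            ag.z_from_percentile(bad)


# ---------------------------------------------------- inverse transform

def test_measurement_from_z_examples():
    assert ag.measurement_from_z(0.0, node(M=86.0, S=3.0), "identity") == 86.0
    assert ag.measurement_from_z(0.0, node(L=-1.2, M=16.0, S=0.11),
                                 "boxcox") == 16.0
    assert ag.measurement_from_z(2.0, node(M=86.0, S=3.0),
                                 "identity") == pytest.approx(92.0)
    # M*(1 + L*S*z)^(1/L), evaluated independently with 40-digit arithmetic
    assert ag.measurement_from_z(1.5, node(L=-1.2, M=16.0, S=0.11),
                                 "boxcox") == pytest.approx(
        19.229795943260275, rel=1e-12)


def test_measurement_from_z_outside_boxcox_support():
    with pytest.raises(ag.InvertibilityError):
        ag.measurement_from_z(4.0, node(L=-2.0, M=16.0, S=0.3), "boxcox")


@settings(derandomize=True, max_examples=200)
@given(
    z=st.floats(min_value=-4.0, max_value=4.0),
    L=st.floats(min_value=-1.5, max_value=1.5),
    M=st.floats(min_value=1.0, max_value=150.0),
    S=st.floats(min_value=0.02, max_value=0.15),
)
def test_inverse_consistency_boxcox(z, L, M, S):
    """measurement_from_z then zscore_boxcox recovers z within 1e-9."""
    n = node(L=L, M=M, S=S)
    if 1.0 + L * S * z <= 1e-6:
        return  # outside the transform's support
    X = ag.measurement_from_z(z, n, "boxcox")
    assert ag.zscore_boxcox(X, n) == pytest.approx(z, abs=1e-9)


@settings(derandomize=True, max_examples=100)
@given(z=st.floats(min_value=-5.0, max_value=5.0),
       M=st.floats(min_value=10.0, max_value=150.0),
       S=st.floats(min_value=0.5, max_value=6.0))
def test_inverse_consistency_identity(z, M, S):
    n = node(M=M, S=S)
    X = ag.measurement_from_z(z, n, "identity")
    assert ag.zscore_identity(X, n) == pytest.approx(z, abs=1e-9)


@settings(derandomize=True, max_examples=100)
@given(
    x=st.floats(min_value=1.0, max_value=100.0),
    dx=st.floats(min_value=1e-3, max_value=50.0),
    L=st.floats(min_value=-2.0, max_value=2.0),
)
def test_zscore_strictly_increasing_in_measurement(x, dx, L):
    n_id = node(M=50.0, S=4.0)
    n_bc = node(L=L, M=50.0, S=0.1)
    assert ag.zscore_identity(x + dx, n_id) > ag.zscore_identity(x, n_id)
    assert ag.zscore_boxcox(x + dx, n_bc) > ag.zscore_boxcox(x, n_bc)


# ------------------------------------------------------ derived measures

def test_derive_bmi():
    assert ag.derive_bmi(16.0, 100.0) == pytest.approx(16.0)
    assert ag.derive_bmi(20.0, 100.0) == pytest.approx(20.0)
    # 18.5/0.9025, hand arithmetic
    assert ag.derive_bmi(18.5, 95.0) == pytest.approx(20.498614958448755,
                                                      rel=1e-12)
    with pytest.raises(ag.DomainError):
        ag.derive_bmi(-1.0, 100.0)


def test_derive_proportions():
    assert ag.derive_proportions(100.0, 60.0) == pytest.approx((40.0, 60.0))
    assert ag.derive_proportions(120.0, 60.0) == pytest.approx((60.0, 50.0))
    leg, rsh = ag.derive_proportions(113.4, 66.3)
    assert leg == pytest.approx(47.1, abs=1e-9)
    assert rsh == pytest.approx(58.46560846560847, rel=1e-12)
    with pytest.raises(ag.DomainError):
        ag.derive_proportions(100.0, 100.0)


# -------------------------------------------------------------- evaluate

def test_evaluate_at_median_on_grid(ref):
    curve = ref.get_curve("height", "male")
    n = curve.nodes[6]
    res = ag.evaluate(
        ag.Measurement("height", "male", n.age, n.M), ref)
    assert res.z == 0.0
    assert res.percentile == pytest.approx(50.0)
    assert "interpolated_age" not in res.flags


def test_evaluate_flags_off_grid_age(ref):
    n = ag.interpolate_lms(ref.get_curve("height", "male"), 2.3)
    res = ag.evaluate(ag.Measurement("height", "male", 2.3, n.M), ref)
    assert res.z == pytest.approx(0.0, abs=1e-12)
    assert "interpolated_age" in res.flags


def test_evaluate_flags_extreme_percentile(ref):
    n = ag.interpolate_lms(ref.get_curve("height", "male"), 5.0)
    X = n.M + 3.5 * n.S
    res = ag.evaluate(ag.Measurement("height", "male", 5.0, X), ref)
    assert "extreme_percentile" in res.flags
    near = ag.evaluate(ag.Measurement("height", "male", 5.0, n.M + n.S), ref)
    assert "extreme_percentile" not in near.flags


def test_evaluate_equals_manual_two_step_pipeline(ref):
    """evaluate() is exactly interpolate -> zscore -> percentile."""
    cases = [
        ("height", "male", 7.3, 95.0, "identity"),
        ("weight", "female", 1.25, 9.5, "boxcox"),
        ("foot_length", "male", 12.8, 15.0, "identity"),
        ("bmi", "male", 16.0, 24.0, "boxcox"),
    ]
    for param, sex, age, X, mode in cases:
        n = ag.interpolate_lms(ref.get_curve(param, sex), age)
        z = (ag.zscore_boxcox(X, n) if mode == "boxcox"
             else ag.zscore_identity(X, n))
        res = ag.evaluate(ag.Measurement(param, sex, age, X), ref)
        assert res.z == z
        assert res.percentile == ag.percentile_from_z(z)
        assert res.lms_used == n


def test_evaluate_errors(ref):
    with pytest.raises(ag.OutOfDomainError):
        ag.evaluate(ag.Measurement("foot_length", "male", 1.0, 10.0), ref)
    with pytest.raises(ag.MissingCurveError):
        ag.evaluate(ag.Measurement("height", "male", 5.0, 90.0),
                    ag.ReferenceSet())


def test_decimal_age_from_dates():
    from datetime import date
    assert ag.decimal_age(date(2020, 1, 1), date(2021, 1, 1)) == pytest.approx(
        366 / 365.25)  # 2020 is a leap year
    with pytest.raises(ag.DomainError):
        ag.decimal_age(date(2021, 1, 1), date(2020, 1, 1))
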