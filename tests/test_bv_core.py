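"""Unit and property tests for the closed-form BV statistics.

Quantile checks use oracles independent of scipy's inverse CDFs: a bisection
on the error function for the normal quantile and numeric integration of the
t density for the Student quantile.  Formula checks compare against a
separately coded plain-math evaluation of the same algebra.
"""

import math

import pytest
from hypothesis import given, settings, strategies as st

from persoref import (
    BVProfile,
    HSPEstimate,
    bv_core,
)

# ---------------------------------------------------------------------------
# independent oracles


def z_oracle(coverage: float) -> float:
    """Two-sided normal quantile by bisection on the erf-based CDF."""
    target = 0.5 + coverage / 2.0
    lo, hi = 0.0, 10.0
    for _ in range(200):
        mid = (lo + hi) / 2.0
        if 0.5 * (1.0 + math.erf(mid / math.sqrt(2.0))) < target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def t_oracle(coverage: float, df: int) -> float:
    """Two-sided t quantile by Simpson integration of the density + bisection."""
    c = math.gamma((df + 1) / 2.0) / (math.sqrt(df * math.pi) * math.gamma(df / 2.0))

    def density(x: float) -> float:
        return c * (1.0 + x * x / df) ** (-(df + 1) / 2.0)

    def cdf_half(x: float, steps: int = 4000) -> float:
        h = x / steps
        s = density(0.0) + density(x)
        for i in range(1, steps):
            s += (4 if i % 2 else 2) * density(i * h)
        return s * h / 3.0

    target = coverage / 2.0
    lo, hi = 0.0, 200.0
    for _ in range(100):
        mid = (lo + hi) / 2.0
        if cdf_half(mid) < target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def prri_oracle(mean, n, cv, quantile):
    """Plain-math evaluation of the interval algebra."""
    half = quantile * mean * (cv / 100.0) * math.sqrt(1.0 + 1.0 / n)
    return mean - half, mean + half


# ---------------------------------------------------------------------------
# cv algebra


@pytest.mark.parametrize("mean, sd, expected", [
    (0.420, 0.020, 4.76),   # hematocrit steady-state history
    (4.45, 0.17, 3.82),     # erythrocytes
    (100.0, 0.0, 0.0),
])
def test_cv_total_examples(mean, sd, expected):
    assert bv_core.cv_total(mean, sd) == pytest.approx(expected, abs=0.005)


def test_cv_total_rejects_nonpositive_mean():
    with pytest.raises(ValueError):
        bv_core.cv_total(0.0, 1.0)


@pytest.mark.parametrize("cv_t, cv_a, expected, warned", [
    (5.0, 3.0, 4.0, False),
    (9.45, 1.26, math.sqrt(9.45**2 - 1.26**2), False),
    (0.0, 14.35, 0.0, True),   # analytical noise exceeds observed total variation
])
def test_cv_within_person(cv_t, cv_a, expected, warned):
    value, warnings = bv_core.cv_within_person(cv_t, cv_a)
    assert value == pytest.approx(expected, rel=1e-12, abs=1e-12)
    assert bool(warnings) is warned


@given(st.floats(0.1, 50), st.floats(0.1, 200), st.floats(0, 30))
@settings(derandomize=True, max_examples=50)
def test_cv_round_trip(mean, sd, cv_a):
    """Decomposing CV_T into CV_P and recombining recovers CV_T when CV_T >= CV_A."""
    cv_t = bv_core.cv_total(mean, sd)
    cv_p, _ = bv_core.cv_within_person(cv_t, cv_a)
    if cv_t >= cv_a:
        assert math.hypot(cv_p, cv_a) == pytest.approx(cv_t, rel=1e-10)
    else:
        assert cv_p == 0.0


# ---------------------------------------------------------------------------
# quantiles


@pytest.mark.parametrize("coverage, expected", [
    (0.95, 1.959964), (0.99, 2.575829), (0.6827, 1.000)])
def test_quantile_z_against_erf_bisection(coverage, expected):
    assert bv_core.quantile_z(coverage) == pytest.approx(z_oracle(coverage), abs=1e-9)
    assert bv_core.quantile_z(coverage) == pytest.approx(expected, abs=5e-4)


@pytest.mark.parametrize("df, expected", [(2, 4.302653), (4, 2.776445)])
def test_quantile_t_against_integration(df, expected):
    assert bv_core.quantile_t(0.95, df) == pytest.approx(t_oracle(0.95, df), abs=1e-6)
    assert bv_core.quantile_t(0.95, df) == pytest.approx(expected, abs=1e-6)


def test_quantile_t_normal_limit():
    assert bv_core.quantile_t(0.95, 10**7) == pytest.approx(1.959964, abs=1e-5)


@pytest.mark.parametrize("bad", [0.0, 1.0, -0.5, 1.5])
def test_quantile_domain(bad):
    with pytest.raises(ValueError):
        bv_core.quantile_z(bad)
    with pytest.raises(ValueError):
        bv_core.quantile_t(0.95, 0)


# ---------------------------------------------------------------------------
# personalized intervals


def _profile(cv_i, cv_a, name="x"):
    return BVProfile(name, "U", cv_i, 10.0, cv_a, 0.0, 1000.0)


def test_prri_pop_erythrocytes_case():
    hsp = HSPEstimate(4.45, 0.17, 3)
    iv = bv_core.prri_pop(hsp, _profile(2.80, 0.67))
    rounded = bv_core.round_interval(iv, 2)
    assert (rounded.lower, rounded.upper) == (4.16, 4.74)


def test_prri_pop_platelets_unrounded():
    hsp = HSPEstimate(217.0, 25.0, 3, cv_t=11.43)
    iv = bv_core.prri_pop(hsp, _profile(6.40, 0.17))
    assert iv.lower == pytest.approx(185.56, abs=0.05)
    assert iv.upper == pytest.approx(248.44, abs=0.05)


def test_prri_pop_zero_variation_collapses():
    hsp = HSPEstimate(5.0, 0.0, 3)
    iv = bv_core.prri_pop(hsp, _profile(0.0, 0.0))
    assert iv.lower == iv.upper == 5.0


def test_prri_ind_hemoglobin_case():
    hsp = HSPEstimate(141.0, 5.0, 3, cv_t=3.36)
    iv = bv_core.prri_ind(hsp)
    assert iv.lower == pytest.approx(117.46, abs=0.01)
    assert iv.upper == pytest.approx(164.54, abs=0.01)


def test_prri_ind_leukocytes_case():
    hsp = HSPEstimate(4.8, 0.5, 3, cv_t=9.45)
    iv = bv_core.prri_ind(hsp)
    assert iv.lower == pytest.approx(2.55, abs=0.01)
    assert iv.upper == pytest.approx(7.05, abs=0.01)


def test_prri_ind_zero_cv_t_warns():
    hsp = HSPEstimate(0.04, 0.0, 3, cv_t=0.0)
    iv = bv_core.prri_ind(hsp)
    assert iv.lower == iv.upper == 0.04
    assert iv.warnings


def test_negative_lower_limit_reported_then_clamped():
    hsp = HSPEstimate(0.3, 0.073, 3, cv_t=24.24)  # monocyte-like
    iv = bv_core.prri_ind(hsp)
    assert iv.lower < 0
    clamped = bv_core.prri_ind(hsp, clamp_at_zero=True)
    assert clamped.lower == 0.0 and clamped.warnings


@given(
    mean=st.floats(0.01, 1e3), sd_frac=st.floats(0.0, 0.5),
    cv_i=st.floats(0.0, 30.0), cv_a=st.floats(0.0, 15.0),
    n=st.integers(2, 50), coverage=st.floats(0.5, 0.999),
)
@settings(derandomize=True, max_examples=100)
def test_interval_oracle_equivalence_and_symmetry(mean, sd_frac, cv_i, cv_a, n, coverage):
    """Both routes match an independently coded evaluation and are symmetric
    about the set point."""
    hsp = HSPEstimate(mean, mean * sd_frac, n)
    profile = _profile(cv_i, cv_a)
    pop = bv_core.prri_pop(hsp, profile, coverage)
    exp = prri_oracle(mean, n, math.hypot(cv_i, cv_a), bv_core.quantile_z(coverage))
    assert pop.lower == pytest.approx(exp[0], rel=1e-10, abs=1e-12)
    assert pop.upper == pytest.approx(exp[1], rel=1e-10, abs=1e-12)
    ind = bv_core.prri_ind(hsp, coverage=coverage)
    exp_i = prri_oracle(mean, n, hsp.cv_t, bv_core.quantile_t(coverage, n - 1))
    assert ind.lower == pytest.approx(exp_i[0], rel=1e-10, abs=1e-12)
    assert ind.upper == pytest.approx(exp_i[1], rel=1e-10, abs=1e-12)
    for iv in (pop, ind):
        assert (iv.lower + iv.upper) / 2.0 == pytest.approx(mean, rel=1e-9)


def test_width_monotonicity():
    """Interval width grows with the CV and the set point, shrinks with n."""
    hsp = HSPEstimate(5.0, 0.5, 3)
    base = bv_core.prri_pop(hsp, _profile(10.0, 2.0)).width
    assert bv_core.prri_pop(hsp, _profile(12.0, 2.0)).width > base
    assert bv_core.prri_pop(HSPEstimate(6.0, 0.5, 3), _profile(10.0, 2.0)).width > base
    assert bv_core.prri_pop(HSPEstimate(5.0, 0.5, 10), _profile(10.0, 2.0)).width < base
    ind_base = bv_core.prri_ind(HSPEstimate(5.0, 0.5, 5)).width
    assert bv_core.prri_ind(HSPEstimate(5.0, 0.6, 5)).width > ind_base


def test_t_route_converges_to_z_route():
    """With a huge history and CV_T = sqrt(CV_I^2+CV_A^2) the two routes agree."""
    n = 10**6
    cv_i, cv_a = 8.0, 2.0
    cv_t = math.hypot(cv_i, cv_a)
    hsp = HSPEstimate(5.0, 5.0 * cv_t / 100.0, n, cv_t=cv_t)
    pop = bv_core.prri_pop(hsp, _profile(cv_i, cv_a))
    ind = bv_core.prri_ind(hsp)
    assert abs(ind.width - pop.width) / pop.width < 1e-3


# ---------------------------------------------------------------------------
# reference change values


@pytest.mark.parametrize("cv_i, cv_a, expected", [
    (11.10, 1.26, 30.96),   # leukocytes
    (2.80, 0.54, 7.90),     # hematocrit
    (0.0, 0.0, 0.0),
])
def test_rcv_pop_examples(cv_i, cv_a, expected):
    rcv = bv_core.rcv_pop(_profile(cv_i, cv_a))
    assert round(rcv.threshold, 2) == pytest.approx(expected, abs=0.005)
    assert rcv.basis == "pop"


@pytest.mark.parametrize("cv_t, expected, warned", [
    (37.50, 103.94, False),  # eosinophils
    (0.0, 0.0, True),        # basophils: not applicable
    (10.0, 27.72, False),    # 1.959964*sqrt(2)*10
])
def test_rcv_ind_examples(cv_t, expected, warned):
    rcv = bv_core.rcv_ind(HSPEstimate(1.0, cv_t / 100.0, 3, cv_t=cv_t))
    assert round(rcv.threshold, 2) == pytest.approx(expected, abs=0.005)
    assert bool(rcv.warnings) is warned


@given(st.floats(0.0, 40.0), st.floats(0.0, 20.0), st.floats(0.5, 0.999))
@settings(derandomize=True, max_examples=50)
def test_rcv_basis_consistency(cv_i, cv_a, coverage):
    """rcv_ind equals rcv_pop when CV_T carries the same combined variation."""
    cv_t = math.hypot(cv_i, cv_a)
    pop = bv_core.rcv_pop(_profile(cv_i, cv_a), coverage)
    ind = bv_core.rcv_ind(HSPEstimate(1.0, cv_t / 100.0, 3, cv_t=cv_t), coverage)
    assert ind.threshold == pytest.approx(pop.threshold, rel=1e-12, abs=1e-12)


def test_rcv_monotone_in_cv():
    assert (bv_core.rcv_pop(_profile(12.0, 2.0)).threshold
            > bv_core.rcv_pop(_profile(10.0, 2.0)).threshold)
    assert (bv_core.rcv_pop(_profile(10.0, 3.0)).threshold
            > bv_core.rcv_pop(_profile(10.0, 2.0)).threshold)


# ---------------------------------------------------------------------------
# index of individuality and applicability


def test_index_of_individuality_variants():
    assert bv_core.index_of_individuality(_profile(10.0, 0.0)) == pytest.approx(1.0)
    p = BVProfile("x", "U", 10.0, 20.0, 2.0, 0.0, 10.0)
    assert bv_core.index_of_individuality(p) == pytest.approx(0.5)
    p345 = BVProfile("x", "U", 3.0, 10.0, 4.0, 0.0, 10.0)
    assert bv_core.index_of_individuality(p345, "noise_adjusted") == pytest.approx(0.5)


def test_index_round_trip_from_case(case_by_name):
    """CV_G back-derived as CV_I/II reproduces the published II."""
    leuk = case_by_name["leukocytes"].profile
    assert bv_core.index_of_individuality(leuk) == pytest.approx(0.65, abs=0.005)


@pytest.mark.parametrize("cv_i, cv_a, n, route", [
    (11.10, 1.26, 3, "population"),   # short history: population route
    (15.00, 16.70, 3, "rcv_only"),    # analytical noise dominates
    (10.0, 1.0, 10, "individual"),
    (35.0, 1.0, 10, "none"),          # CV_I too high for personalized limits
])
def test_check_applicability_routes(cv_i, cv_a, n, route):
    verdict = bv_core.check_applicability(
        _profile(cv_i, cv_a), HSPEstimate(5.0, 0.5, n))
    assert verdict.recommended_route == route
    assert verdict.messages


# ---------------------------------------------------------------------------
# rounding


@pytest.mark.parametrize("limits, decimals, expected", [
    ((4.1601, 4.7400), 2, (4.16, 4.74)),
    ((117.46, 164.54), 0, (117.0, 165.0)),   # half-up, not banker's
    ((0.0, 0.0), 2, (0.0, 0.0)),
])
def test_round_interval(limits, decimals, expected):
    from persoref.types import ReferenceInterval

    iv = ReferenceInterval(*limits, "prRI_pop")
    out = bv_core.round_interval(iv, decimals)
    assert (out.lower, out.upper) == expected
    assert out.unrounded == limits
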