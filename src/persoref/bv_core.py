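"""Closed-form biological-variation statistics.

Personalized reference intervals (prRIs) place limits around an individual's
homeostatic set point (HSP) instead of around a population mean.  Two routes
are provided:

* **population route** — the dispersion comes from population biological
  variation (CV_I) combined with analytical variation (CV_A), and a standard
  normal quantile is used::

      prRI_pop = HSP ± z · HSP · √(CV_I² + CV_A²)/100 · √(1 + 1/n)

* **individual route** — the dispersion is the individual's own total
  variation CV_T (estimated from n steady-state results), and a Student-t
  quantile with n−1 degrees of freedom accounts for the small sample::

      prRI_ind = HSP ± t(n−1) · HSP · CV_T/100 · √(1 + 1/n)

The √(1 + 1/n) factor inflates the limits for the sampling error of the
estimated set point.  Reference change values (RCVs) use the same dispersion
sources for the delta-check criterion RCV = z·√2·CV.

All quantiles are full precision internally (z = 1.959964 at 95% coverage);
the familiar 1.96 appears only in documentation.
"""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal

from scipy import stats

from .types import ApplicabilityVerdict, BVProfile, HSPEstimate, RCVEstimate, ReferenceInterval

DEFAULT_COVERAGE = 0.95

__all__ = [
    "cv_total",
    "cv_within_person",
    "quantile_z",
    "quantile_t",
    "prri_pop",
    "prri_ind",
    "pop_interval",
    "rcv_pop",
    "rcv_ind",
    "index_of_individuality",
    "check_applicability",
    "round_interval",
    "round_half_up",
    "DEFAULT_COVERAGE",
]


def cv_total(mean: float, sd: float) -> float:
    """Total variation CV_T (%) of a steady-state history: 100·sd/mean.

    CV_T combines the person's own biological variation (CV_P) with the
    analytical variation (CV_A) of the measurement procedure.
    """
    if mean <= 0:
        raise ValueError("CV undefined for non-positive mean")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    return 100.0 * sd / mean


def cv_within_person(cv_t: float, cv_a: float) -> tuple[float, tuple[str, ...]]:
    """Within-person biological variation CV_P = √(CV_T² − CV_A²).

    When analytical noise exceeds the observed total variation the difference
    is negative; CV_P is then reported as 0 with a warning rather than
    raising, since this occurs in practice for near-zero analytes (e.g.
    basophil counts) where CV_A dominates.
    """
    if cv_t < 0 or cv_a < 0:
        raise ValueError("CVs must be >= 0")
    diff = cv_t * cv_t - cv_a * cv_a
    if diff < 0:
        return 0.0, (f"CV_A ({cv_a}%) exceeds CV_T ({cv_t}%); CV_P set to 0",)
    return math.sqrt(diff), ()


def quantile_z(coverage: float = DEFAULT_COVERAGE) -> float:
    """Two-sided standard-normal quantile for the given central coverage."""
    if not 0.0 < coverage < 1.0:
        raise ValueError("coverage must be in (0, 1)")
    return float(stats.norm.ppf(0.5 + coverage / 2.0))


def quantile_t(coverage: float, df: int) -> float:
    """Two-sided Student-t quantile with ``df`` degrees of freedom."""
    if not 0.0 < coverage < 1.0:
        raise ValueError("coverage must be in (0, 1)")
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(stats.t.ppf(0.5 + coverage / 2.0, df))


def _small_n_factor(n: int) -> float:
    return math.sqrt(1.0 + 1.0 / n)


def prri_pop(
    hsp: HSPEstimate, profile: BVProfile, coverage: float = DEFAULT_COVERAGE,
    clamp_at_zero: bool = False,
) -> ReferenceInterval:
    """Personalized reference interval from population BV data.

    Limits are HSP ± z·HSP·(√(CV_I²+CV_A²)/100)·√(1+1/n).  Limits are kept
    unrounded; use :func:`round_interval` for display.
    """
    if hsp.mean <= 0:
        raise ValueError("HSP mean must be > 0")
    z = quantile_z(coverage)
    factor = _small_n_factor(hsp.n)
    tv = math.hypot(profile.cv_i, profile.cv_a) / 100.0
    half = z * hsp.mean * tv * factor
    return _build_interval(hsp.mean, half, "prRI_pop", z, factor, clamp_at_zero)


def prri_ind(
    hsp: HSPEstimate, profile: BVProfile | None = None,
    coverage: float = DEFAULT_COVERAGE, clamp_at_zero: bool = False,
) -> ReferenceInterval:
    """Personalized reference interval from the individual's own variation.

    Limits are HSP ± t(coverage, n−1)·HSP·(CV_T/100)·√(1+1/n).  ``profile``
    is accepted for interface symmetry but unused: CV_T already contains the
    analytical component.  Negative lower limits are reported as computed
    (physically a concentration cannot be negative, but the symmetric model
    can produce them at high CV_T); pass ``clamp_at_zero=True`` to clip.
    """
    if hsp.mean <= 0:
        raise ValueError("HSP mean must be > 0")
    t = quantile_t(coverage, hsp.n - 1)
    factor = _small_n_factor(hsp.n)
    half = t * hsp.mean * (hsp.cv_t / 100.0) * factor
    warnings: tuple[str, ...] = ()
    if hsp.cv_t == 0:
        warnings = ("CV_T is 0: interval collapses to the set point; method not applicable",)
    iv = _build_interval(hsp.mean, half, "prRI_ind", t, factor, clamp_at_zero)
    return ReferenceInterval(
        iv.lower, iv.upper, iv.method, iv.coverage_quantile, iv.small_n_factor,
        warnings + iv.warnings, iv.unrounded,
    )


def _build_interval(
    center: float, half: float, method: str, quantile: float, factor: float,
    clamp_at_zero: bool,
) -> ReferenceInterval:
    lower, upper = center - half, center + half
    warnings: tuple[str, ...] = ()
    if clamp_at_zero and lower < 0:
        warnings = (f"negative lower limit {lower:.6g} clamped to 0",)
        lower = 0.0
    return ReferenceInterval(lower, upper, method, quantile, factor, warnings)  # type: ignore[arg-type]


def pop_interval(profile: BVProfile) -> ReferenceInterval:
    """The conventional population-based reference interval, as an interval object."""
    return ReferenceInterval(profile.pop_ri_lower, profile.pop_ri_upper, "popRI")


def rcv_pop(profile: BVProfile, coverage: float = DEFAULT_COVERAGE) -> RCVEstimate:
    """Reference change value from population BV: z·√2·√(CV_I²+CV_A²)."""
    z = quantile_z(coverage)
    return RCVEstimate(z * math.sqrt(2.0) * math.hypot(profile.cv_i, profile.cv_a), "pop", z)


def rcv_ind(hsp: HSPEstimate, coverage: float = DEFAULT_COVERAGE) -> RCVEstimate:
    """Reference change value from the individual's total variation: z·√2·CV_T.

    CV_T already contains analytical variation, so no further CV_A term is
    added.  A CV_T of 0 yields a threshold of 0 with a not-applicable
    warning — every change would exceed it.
    """
    if hsp.cv_t < 0:
        raise ValueError("cv_t must be >= 0")
    z = quantile_z(coverage)
    warnings: tuple[str, ...] = ()
    if hsp.cv_t == 0:
        warnings = ("CV_T is 0: RCV of 0% is not applicable as a change criterion",)
    return RCVEstimate(z * math.sqrt(2.0) * hsp.cv_t, "ind", z, warnings)


def index_of_individuality(profile: BVProfile, variant: str = "simple") -> float:
    """Index of individuality II.

    ``simple`` returns CV_I/CV_G (the primary definition); ``noise_adjusted``
    returns √(CV_I²+CV_A²)/CV_G.  Values below ~0.6 mean population reference
    intervals are insensitive for monitoring an individual.
    """
    if profile.cv_g <= 0:
        raise ValueError("cv_g must be > 0")
    if variant == "simple":
        return profile.cv_i / profile.cv_g
    if variant == "noise_adjusted":
        return math.hypot(profile.cv_i, profile.cv_a) / profile.cv_g
    raise ValueError(f"unknown II variant {variant!r}")


CV_I_MAX = 30.0        # above this, BV-based personalized limits are unsuitable
CV_A_RATIO_MAX = 0.5   # analytical noise should not exceed half the biological signal
N_MIN_INDIVIDUAL = 5   # steady-state results needed before the t-based route is trusted


def check_applicability(profile: BVProfile, hsp: HSPEstimate) -> ApplicabilityVerdict:
    """Suitability checks for personalized intervals and route recommendation.

    Route logic: CV_I > 30% rules the method out entirely; CV_A > 0.5·CV_I
    means the analytical noise swamps the biological signal and only a
    change criterion (RCV) remains informative; with fewer than 5
    steady-state results the individually estimated CV_T is too uncertain and
    the population route is recommended; otherwise the individual route.
    """
    ratio = profile.cv_a / profile.cv_i if profile.cv_i > 0 else math.inf
    cv_a_ok = ratio <= CV_A_RATIO_MAX
    cv_i_ok = profile.cv_i <= CV_I_MAX
    n_ok = hsp.n >= N_MIN_INDIVIDUAL
    messages: list[str] = []
    if not cv_i_ok:
        messages.append(
            f"CV_I {profile.cv_i}% exceeds {CV_I_MAX}%: measurand unsuitable for "
            "personalized reference intervals"
        )
        route = "none"
    elif not cv_a_ok:
        messages.append(
            f"CV_A/CV_I = {ratio:.2f} exceeds {CV_A_RATIO_MAX}: analytical noise too "
            "high; a reference change value criterion is the more suitable alternative"
        )
        route = "rcv_only"
    elif not n_ok:
        messages.append(
            f"only {hsp.n} steady-state results (< {N_MIN_INDIVIDUAL}): population-BV "
            "route recommended over the individual route"
        )
        route = "population"
    else:
        messages.append("all checks passed: individual route applicable")
        route = "individual"
    return ApplicabilityVerdict(ratio, cv_i_ok, cv_a_ok, n_ok, route, tuple(messages))  # type: ignore[arg-type]


def round_half_up(value: float, decimals: int) -> float:
    """Decimal half-up rounding (0.5 always away from zero), as laboratories report."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def round_interval(interval: ReferenceInterval, decimals: int) -> ReferenceInterval:
    """Round both limits half-up to the display decimals, keeping the originals."""
    if decimals < 0:
        raise ValueError("decimals must be >= 0")
    unrounded = interval.unrounded or (interval.lower, interval.upper)
    return ReferenceInterval(
        round_half_up(unrounded[0], decimals),
        round_half_up(unrounded[1], decimals),
        interval.method,
        interval.coverage_quantile,
        interval.small_n_factor,
        interval.warnings,
        unrounded,
    )
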