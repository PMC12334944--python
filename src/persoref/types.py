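"""Domain types for biological-variation statistics.

All coefficients of variation (CVs) are expressed in percent, the convention
used throughout laboratory medicine: ``cv_i`` is the within-subject biological
variation, ``cv_g`` the between-subject variation, ``cv_a`` the analytical
imprecision of the measuring system, and ``cv_t`` the total variation of one
individual's steady-state results (biological plus analytical noise).
Concentrations are in whatever unit the measurand is reported in.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import math

IntervalMethod = Literal["popRI", "prRI_pop", "prRI_ind"]
RCVBasis = Literal["pop", "ind"]
Route = Literal["population", "individual", "rcv_only", "none"]


@dataclass(frozen=True)
class BVProfile:
    """Biological-variation parameters of one measurand.

    ``pop_ri_lower``/``pop_ri_upper`` are the conventional population-based
    reference interval limits; ``display_decimals`` is the number of decimals
    the laboratory uses when reporting this measurand.
    """

    measurand_name: str
    units: str
    cv_i: float
    cv_g: float
    cv_a: float
    pop_ri_lower: float
    pop_ri_upper: float
    display_decimals: int = 2

    def __post_init__(self) -> None:
        if self.cv_i < 0:
            raise ValueError(f"{self.measurand_name}: cv_i must be >= 0")
        if self.cv_g <= 0:
            raise ValueError(f"{self.measurand_name}: cv_g must be > 0")
        if self.cv_a < 0:
            raise ValueError(f"{self.measurand_name}: cv_a must be >= 0")
        if not self.pop_ri_lower < self.pop_ri_upper:
            raise ValueError(
                f"{self.measurand_name}: pop_ri_lower must be < pop_ri_upper"
            )
        if self.display_decimals < 0:
            raise ValueError(f"{self.measurand_name}: display_decimals must be >= 0")


@dataclass(frozen=True)
class HSPEstimate:
    """Summary of a patient's steady-state history.

    ``mean`` estimates the homeostatic set point (HSP), the concentration the
    individual regulates around; ``cv_t`` = 100·sd/mean is the total variation
    of the history, combining the person's own biological variation with
    analytical noise.  When ``cv_t`` is supplied explicitly it takes
    precedence over the ratio of the stored summaries: published summaries
    typically print mean and SD at coarser precision than the CV they were
    computed from, so the explicit value is treated as the authoritative
    full-precision one.
    """

    mean: float
    sd: float
    n: int
    cv_t: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("at least 2 steady-state results are required")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.cv_t is None:
            if self.mean <= 0:
                raise ValueError("mean must be > 0 to derive cv_t")
            object.__setattr__(self, "cv_t", 100.0 * self.sd / self.mean)
        elif self.cv_t < 0:
            raise ValueError("cv_t must be >= 0")


@dataclass(frozen=True)
class ReferenceInterval:
    """A lower/upper limit pair with the method that produced it.

    ``coverage_quantile`` is the two-sided quantile used (z for the
    population route, Student-t with n−1 df for the individual route) and
    ``small_n_factor`` the √(1 + 1/n) inflation for the uncertainty of the
    estimated set point. ``unrounded`` keeps the full-precision limits when
    the interval has been rounded for display.
    """

    lower: float
    upper: float
    method: IntervalMethod
    coverage_quantile: float = float("nan")
    small_n_factor: float = 1.0
    warnings: tuple[str, ...] = ()
    unrounded: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError("lower must be <= upper")

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def contains(self, value: float) -> bool:
        """Strict out-of-range convention: boundary values are in-range."""
        return self.lower <= value <= self.upper


@dataclass(frozen=True)
class RCVEstimate:
    """Reference change value: the minimum percent difference between two
    consecutive results that exceeds combined analytical and biological noise
    at the stated coverage."""

    threshold: float
    basis: RCVBasis
    quantile: float
    warnings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")


@dataclass(frozen=True)
class ApplicabilityVerdict:
    """Outcome of the suitability checks for personalized intervals."""

    ratio_cv_a_cv_i: float
    cv_i_ok: bool
    cv_a_ok: bool
    n_ok: bool
    recommended_route: Route
    messages: tuple[str, ...] = ()


@dataclass(frozen=True)
class ResultSeries:
    """Ordered longitudinal results for one measurand.

    ``points`` are (day_index, value) pairs with day 0 an anchoring event
    (symptom onset in the motivating case); day indices strictly increase.
    """

    measurand_name: str
    points: tuple[tuple[int, float], ...]

    def __post_init__(self) -> None:
        days = [d for d, _ in self.points]
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError(f"{self.measurand_name}: day indices must strictly increase")
        for d, v in self.points:
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{self.measurand_name}: value {v} at day {d} invalid")

    @property
    def days(self) -> tuple[int, ...]:
        return tuple(d for d, _ in self.points)

    @property
    def values(self) -> tuple[float, ...]:
        return tuple(v for _, v in self.points)

    def __len__(self) -> int:
        return len(self.points)


def series_from_values(name: str, days: Sequence[int], values: Sequence[float]) -> ResultSeries:
    if len(days) != len(values):
        raise ValueError("days and values must have equal length")
    return ResultSeries(name, tuple(zip([int(d) for d in days], [float(v) for v in values])))
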