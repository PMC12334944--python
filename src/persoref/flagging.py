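"""Flag longitudinal results against interval and change criteria.

A point is interval-flagged when it falls strictly outside a reference
interval (population-based or personalized); it is RCV-flagged when the
percent change from the previous result strictly exceeds the reference change
value.  Values exactly on a limit or exactly at the threshold are in-range by
default (configurable).  RCV flags are attributed to the later point of each
consecutive pair, and summary ratios are reported against the full point
count so that all criteria share one denominator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping

from .types import RCVEstimate, ReferenceInterval, ResultSeries

logger = logging.getLogger(__name__)

Direction = Literal["above", "below", "rise", "fall"]


@dataclass(frozen=True)
class PointFlag:
    day: int
    value: float
    flagged: bool
    direction: Direction | None = None
    note: str | None = None


@dataclass
class FlagReport:
    """Per-point flags for one measurand under several criteria."""

    measurand_name: str
    flags: dict[str, list[PointFlag]] = field(default_factory=dict)

    def count(self, criterion: str) -> tuple[int, int]:
        pts = self.flags[criterion]
        return sum(p.flagged for p in pts), len(pts)


def flag_interval(
    series: ResultSeries, interval: ReferenceInterval, strict: bool = True
) -> list[PointFlag]:
    """Flag each point outside the interval limits.

    With ``strict=True`` (default) boundary values are in-range; with
    ``strict=False`` they are flagged too.
    """
    if interval.lower > interval.upper:
        raise ValueError("interval.lower must be <= interval.upper")
    out: list[PointFlag] = []
    for day, value in series.points:
        below = value < interval.lower if strict else value <= interval.lower
        above = value > interval.upper if strict else value >= interval.upper
        direction: Direction | None = "below" if below else "above" if above else None
        out.append(PointFlag(day, value, below or above, direction))
    return out


def flag_rcv(
    series: ResultSeries,
    rcv: RCVEstimate,
    reference: Literal["previous", "mean"] = "previous",
    strict: bool = True,
) -> list[PointFlag]:
    """Flag points whose change from the previous result exceeds the RCV.

    Percent change is 100·|Δ|/reference where the reference is the earlier
    value (default) or the pair mean.  The first point has no predecessor and
    is never flagged; a zero reference makes the relative change undefined, so
    that pair is skipped with a warning note.
    """
    if len(series) < 2:
        raise ValueError("RCV flagging needs at least 2 points")
    out: list[PointFlag] = [PointFlag(series.points[0][0], series.points[0][1], False)]
    for (d_prev, x_prev), (d_curr, x_curr) in zip(series.points, series.points[1:]):
        ref = x_prev if reference == "previous" else (x_prev + x_curr) / 2.0
        if ref == 0:
            logger.warning(
                "%s: zero reference value at day %s; RCV pair (%s, %s) skipped",
                series.measurand_name, d_prev, d_prev, d_curr,
            )
            out.append(PointFlag(d_curr, x_curr, False, None, "skipped: zero reference"))
            continue
        pct = 100.0 * abs(x_curr - x_prev) / ref
        exceeded = pct > rcv.threshold if strict else pct >= rcv.threshold
        direction: Direction | None = None
        if exceeded:
            direction = "rise" if x_curr > x_prev else "fall"
        out.append(PointFlag(d_curr, x_curr, exceeded, direction))
    return out


def evaluate_series(
    series: ResultSeries,
    intervals: Mapping[str, ReferenceInterval],
    rcvs: Mapping[str, RCVEstimate],
    strict: bool = True,
    rcv_reference: Literal["previous", "mean"] = "previous",
) -> FlagReport:
    """Evaluate one series under every supplied criterion."""
    report = FlagReport(series.measurand_name)
    for name, interval in intervals.items():
        report.flags[name] = flag_interval(series, interval, strict=strict)
    for name, rcv in rcvs.items():
        report.flags[name] = flag_rcv(series, rcv, reference=rcv_reference, strict=strict)
    return report


def summarize_flags(reports: Iterable[FlagReport]) -> dict[str, dict[str, object]]:
    """Pool flag counts across measurands per criterion.

    All measurands must share the same criteria and the same time grid; the
    denominator is measurands × time points for every criterion, including
    the RCV criteria (whose flags sit on the later point of each pair).
    Returns {criterion: {"flagged": k, "total": N, "ratio": "k/N"}}.
    """
    reports = list(reports)
    if not reports:
        return {}
    criteria = list(reports[0].flags)
    grid = [p.day for p in reports[0].flags[criteria[0]]]
    totals: dict[str, dict[str, object]] = {}
    for rep in reports:
        if sorted(rep.flags) != sorted(criteria):
            raise ValueError(f"{rep.measurand_name}: criteria differ across measurands")
        for crit in criteria:
            if [p.day for p in rep.flags[crit]] != grid:
                raise ValueError(f"{rep.measurand_name}: time grid differs across measurands")
    for crit in criteria:
        k = sum(rep.count(crit)[0] for rep in reports)
        n = sum(rep.count(crit)[1] for rep in reports)
        totals[crit] = {"flagged": k, "total": n, "ratio": f"{k}/{n}"}
    return totals
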