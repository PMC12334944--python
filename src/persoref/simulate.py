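"""Seeded generator of longitudinal blood-count panels.

Emulates the data structure the interval analysis assumes: each measurand
fluctuates multiplicatively around a fixed homeostatic set point with
within-person biological noise (cv_p) and analytical noise (cv_a), except
inside configurable excursion windows where the set point is scaled by a
fold-change (a piecewise-constant stand-in for a disease episode).  Every
simulated value is

    value = true_hsp · fold(day) · (1 + e_P) · (1 + e_A)

with e_P ~ N(0, cv_p/100) and e_A ~ N(0, cv_a/100) independent across
points (a log-normal alternative is available via ``noise="lognormal"``).
The default configuration mirrors the motivating case: a 10-measurand
CBC/differential panel observed at 11 time points from day −10 to day 115
around a respiratory-infection episode, with a 3-result steady-state history
per measurand.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence
import warnings as _warnings

import numpy as np

from . import bv_core
from .types import HSPEstimate, ResultSeries, series_from_values

DEFAULT_DAYS: tuple[int, ...] = (-10, 0, 3, 7, 10, 14, 21, 30, 60, 90, 115)


@dataclass(frozen=True)
class MeasurandSim:
    """True generating parameters for one measurand."""

    true_hsp: float
    cv_p: float
    cv_a: float

    def __post_init__(self) -> None:
        if self.true_hsp <= 0:
            raise ValueError("true_hsp must be > 0")
        if self.cv_p < 0 or self.cv_a < 0:
            raise ValueError("CVs must be >= 0")

    @property
    def cv_t(self) -> float:
        """Model total variation √(cv_p² + cv_a²) that steady-state data recover."""
        return float(np.hypot(self.cv_p, self.cv_a))


@dataclass(frozen=True)
class Excursion:
    """Piecewise-constant fold-change applied to one measurand inside [start_day, end_day]."""

    measurand: str
    start_day: int
    end_day: int
    fold: float

    def __post_init__(self) -> None:
        if self.fold <= 0:
            raise ValueError("fold-change must be > 0")
        if self.end_day < self.start_day:
            raise ValueError("end_day must be >= start_day")


@dataclass(frozen=True)
class SimulationConfig:
    measurands: dict[str, MeasurandSim]
    days: tuple[int, ...] = DEFAULT_DAYS
    excursions: tuple[Excursion, ...] = ()
    n_hsp_history: int = 3
    seed: int = 0
    noise: Literal["normal", "lognormal"] = "normal"

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.days, self.days[1:])):
            raise ValueError("day grid must strictly increase")
        if self.n_hsp_history < 2:
            raise ValueError("n_hsp_history must be >= 2")
        known = set(self.measurands)
        for exc in self.excursions:
            if exc.measurand not in known:
                raise ValueError(f"excursion references unknown measurand {exc.measurand!r}")


# The case panel: set points from the patient's steady-state history, cv_p
# back-derived from the observed total variation (cv_p = sqrt(CV_T^2 - CV_A^2),
# floored at 0), cv_a the laboratory's analytical imprecision.
_CASE_MEASURANDS: dict[str, MeasurandSim] = {
    "leukocytes": MeasurandSim(4.8, 9.366, 1.26),
    "neutrophils": MeasurandSim(3.0, 9.721, 1.46),
    "lymphocytes": MeasurandSim(1.4, 5.588, 3.55),
    "monocytes": MeasurandSim(0.3, 23.183, 7.08),
    "eosinophils": MeasurandSim(0.1, 33.576, 16.70),
    "basophils": MeasurandSim(0.04, 0.0, 14.35),
    "erythrocytes": MeasurandSim(4.45, 3.761, 0.67),
    "hematocrit": MeasurandSim(0.420, 4.729, 0.54),
    "hemoglobin": MeasurandSim(141.0, 3.351, 0.25),
    "platelets": MeasurandSim(217.0, 11.429, 0.17),
}

# Acute-phase fold-changes typical of a viral respiratory episode:
# neutrophilia and monocytosis with transient lymphopenia and eosinopenia.
_CASE_EXCURSIONS: tuple[Excursion, ...] = (
    Excursion("leukocytes", 0, 14, 1.35),
    Excursion("neutrophils", 0, 14, 1.60),
    Excursion("lymphocytes", 0, 14, 0.55),
    Excursion("monocytes", 0, 14, 1.50),
    Excursion("eosinophils", 0, 14, 0.40),
)


def case_config(seed: int = 0) -> SimulationConfig:
    """Default configuration emulating the motivating 10×11 observation."""
    return SimulationConfig(dict(_CASE_MEASURANDS), DEFAULT_DAYS, _CASE_EXCURSIONS, 3, seed)


@dataclass(frozen=True)
class SimulatedPanel:
    """Output of one simulation: history, longitudinal series and truth labels."""

    config: SimulationConfig
    hsp_history: dict[str, tuple[float, ...]]
    series: dict[str, ResultSeries]
    in_excursion: dict[str, tuple[bool, ...]]
    fold_applied: dict[str, tuple[float, ...]]

    @property
    def n_results(self) -> int:
        return sum(len(s) for s in self.series.values())


def _noisy(rng: np.random.Generator, center: np.ndarray, cv_p: float, cv_a: float,
           noise: str) -> np.ndarray:
    size = center.shape
    if noise == "lognormal":
        # log-normal with matching CV on each component
        s_p = np.sqrt(np.log1p((cv_p / 100.0) ** 2))
        s_a = np.sqrt(np.log1p((cv_a / 100.0) ** 2))
        vals = center * rng.lognormal(-s_p**2 / 2, s_p, size) * rng.lognormal(-s_a**2 / 2, s_a, size)
    else:
        vals = (center
                * (1.0 + rng.normal(0.0, cv_p / 100.0, size))
                * (1.0 + rng.normal(0.0, cv_a / 100.0, size)))
    if np.any(vals < 0):
        _warnings.warn("negative simulated values truncated at 0", stacklevel=3)
        vals = np.clip(vals, 0.0, None)
    return vals


def simulate_panel(config: SimulationConfig) -> SimulatedPanel:
    """Generate one panel; identical seeds give identical panels."""
    rng = np.random.default_rng(config.seed)
    history: dict[str, tuple[float, ...]] = {}
    series: dict[str, ResultSeries] = {}
    in_exc: dict[str, tuple[bool, ...]] = {}
    folds: dict[str, tuple[float, ...]] = {}
    days = np.asarray(config.days)
    for name, m in config.measurands.items():
        hist = _noisy(rng, np.full(config.n_hsp_history, m.true_hsp), m.cv_p, m.cv_a,
                      config.noise)
        fold = np.ones(len(days))
        for exc in config.excursions:
            if exc.measurand == name:
                fold[(days >= exc.start_day) & (days <= exc.end_day)] *= exc.fold
        vals = _noisy(rng, m.true_hsp * fold, m.cv_p, m.cv_a, config.noise)
        history[name] = tuple(float(v) for v in hist)
        series[name] = series_from_values(name, config.days, vals)
        in_exc[name] = tuple(bool(f != 1.0) for f in fold)
        folds[name] = tuple(float(f) for f in fold)
    return SimulatedPanel(config, history, series, in_exc, folds)


def estimate_hsp(history: Sequence[float]) -> HSPEstimate:
    """Summarize a steady-state history: mean, sample SD (n−1), n, CV_T."""
    vals = np.asarray(history, dtype=float)
    if vals.size < 2:
        raise ValueError("at least 2 history values are required")
    if np.any(vals <= 0):
        raise ValueError("history values must be positive")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    return HSPEstimate(mean=mean, sd=sd, n=int(vals.size))


def recovery_experiment(
    config: SimulationConfig,
    replicates: int,
    n_small: int = 3,
    n_large: int = 10,
    coverage: float = bv_core.DEFAULT_COVERAGE,
) -> dict[str, dict[str, float]]:
    """Monte-Carlo check of the small-history warning and interval coverage.

    For each replicate and measurand, draws steady-state histories of size
    ``n_small`` and ``n_large``, computes the individual-route prRI from
    each, and records (a) interval widths — the small history should give a
    far wider, often uselessly wide, interval because of the t quantile and
    the 1/n factor — and (b) the fraction of fresh steady-state points (one
    per grid day) covered by each interval type.  Returns per-quantity means
    and Monte-Carlo standard errors across replicates.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(config.seed)
    rows: dict[str, list[float]] = {
        "width_ind_small": [], "width_ind_large": [],
        "coverage_pop_small": [], "coverage_ind_small": [],
        "wider_small_than_large": [],
    }
    steady = replace(config, excursions=())
    for _ in range(replicates):
        widths_s, widths_l, cov_pop, cov_ind, wider = [], [], [], [], []
        for name, m in steady.measurands.items():
            hist_s = _noisy(rng, np.full(n_small, m.true_hsp), m.cv_p, m.cv_a, config.noise)
            hist_l = _noisy(rng, np.full(n_large, m.true_hsp), m.cv_p, m.cv_a, config.noise)
            pts = _noisy(rng, np.full(len(config.days), m.true_hsp), m.cv_p, m.cv_a,
                         config.noise)
            # summaries built directly: a truncated-at-zero draw (possible at
            # extreme CVs) would violate estimate_hsp's positivity contract
            hsp_s = HSPEstimate(float(hist_s.mean()), float(hist_s.std(ddof=1)), n_small)
            hsp_l = HSPEstimate(float(hist_l.mean()), float(hist_l.std(ddof=1)), n_large)
            iv_s = _prri_ind_raw(hsp_s, coverage)
            iv_l = _prri_ind_raw(hsp_l, coverage)
            # population route: the generator's cv_p plays the population CV_I
            z = bv_core.quantile_z(coverage)
            half = z * hsp_s.mean * (m.cv_t / 100.0) * np.sqrt(1 + 1 / n_small)
            widths_s.append(iv_s.width)
            widths_l.append(iv_l.width)
            wider.append(float(iv_s.width > iv_l.width))
            cov_pop.append(float(np.mean((pts >= hsp_s.mean - half) & (pts <= hsp_s.mean + half))))
            cov_ind.append(float(np.mean((pts >= iv_s.lower) & (pts <= iv_s.upper))))
        rows["width_ind_small"].append(float(np.mean(widths_s)))
        rows["width_ind_large"].append(float(np.mean(widths_l)))
        rows["wider_small_than_large"].append(float(np.mean(wider)))
        rows["coverage_pop_small"].append(float(np.mean(cov_pop)))
        rows["coverage_ind_small"].append(float(np.mean(cov_ind)))
    out: dict[str, dict[str, float]] = {}
    for key, vals in rows.items():
        arr = np.asarray(vals)
        out[key] = {
            "mean": float(arr.mean()),
            "mc_se": float(arr.std(ddof=1) / np.sqrt(replicates)) if replicates > 1 else 0.0,
        }
    return out


def _prri_ind_raw(hsp: HSPEstimate, coverage: float):
    t = bv_core.quantile_t(coverage, hsp.n - 1)
    half = t * hsp.mean * (hsp.cv_t / 100.0) * np.sqrt(1 + 1 / hsp.n)
    from .types import ReferenceInterval

    return ReferenceInterval(hsp.mean - half, hsp.mean + half, "prRI_ind", t,
                             float(np.sqrt(1 + 1 / hsp.n)))
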