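"""File formats, run configuration and the table-level pipeline.

All tabular formats are long-format UTF-8 CSV with a dot decimal separator:

* BV parameter table — ``measurand, units, cv_i, cv_g, cv_a, pop_ri_lower,
  pop_ri_upper, display_decimals``
* steady-state history — either raw (``measurand, value``; N rows per
  measurand) or pre-summarized (``measurand, mean, sd, n``)
* result series — ``measurand, day, value`` with integer days relative to
  the anchoring event (day 0)

Simulation configs are YAML.  Schema violations raise :class:`SchemaError`
with line-level detail; the CLI maps it to exit code 2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import pandas as pd
import yaml

from . import bv_core, flagging
from .simulate import Excursion, MeasurandSim, SimulatedPanel, SimulationConfig
from .types import BVProfile, HSPEstimate, ResultSeries, series_from_values


class SchemaError(ValueError):
    """An input file does not match its expected schema."""


@dataclass(frozen=True)
class RunConfig:
    """Conventions of one analysis run; the defaults are the published ones."""

    coverage: float = bv_core.DEFAULT_COVERAGE
    rcv_reference: Literal["previous", "mean"] = "previous"
    clamp_negative_limits: bool = False
    strict_boundaries: bool = True
    seed: int = 0
    verbosity: int = 0


_BV_COLUMNS = ["measurand", "units", "cv_i", "cv_g", "cv_a",
               "pop_ri_lower", "pop_ri_upper", "display_decimals"]


def _read_csv(path: str | Path, required: list[str], what: str) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except (pd.errors.EmptyDataError, FileNotFoundError) as exc:
        raise SchemaError(f"{path}: cannot read {what}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: {what} is missing columns {missing}")
    if df.empty:
        raise SchemaError(f"{path}: {what} has no data rows")
    return df


def read_bv_table(path: str | Path) -> list[BVProfile]:
    df = _read_csv(path, _BV_COLUMNS, "BV parameter table")
    profiles = []
    for i, r in df.iterrows():
        try:
            profiles.append(BVProfile(
                str(r["measurand"]), str(r["units"]), float(r["cv_i"]),
                float(r["cv_g"]), float(r["cv_a"]), float(r["pop_ri_lower"]),
                float(r["pop_ri_upper"]), int(r["display_decimals"]),
            ))
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"{path}: row {i + 2}: {exc}") from exc
    return profiles


def read_hsp_history(path: str | Path) -> dict[str, HSPEstimate]:
    """Read a steady-state history, raw or pre-summarized (auto-detected)."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except (pd.errors.EmptyDataError, FileNotFoundError) as exc:
        raise SchemaError(f"{path}: cannot read HSP history: {exc}") from exc
    out: dict[str, HSPEstimate] = {}
    try:
        if {"measurand", "value"} <= set(df.columns):
            for name, grp in df.groupby("measurand", sort=False):
                vals = grp["value"].astype(float)
                if len(vals) < 2:
                    raise SchemaError(f"{path}: {name}: needs >= 2 history values")
                out[str(name)] = HSPEstimate(float(vals.mean()),
                                             float(vals.std(ddof=1)), int(len(vals)))
        elif {"measurand", "mean", "sd", "n"} <= set(df.columns):
            for i, r in df.iterrows():
                cv_t = float(r["cv_t"]) if "cv_t" in df.columns and pd.notna(r.get("cv_t")) else None
                out[str(r["measurand"])] = HSPEstimate(
                    float(r["mean"]), float(r["sd"]), int(r["n"]), cv_t)
        else:
            raise SchemaError(
                f"{path}: HSP history needs columns (measurand, value) or "
                "(measurand, mean, sd, n)")
    except (ValueError, TypeError) as exc:
        raise SchemaError(f"{path}: {exc}") from exc
    if not out:
        raise SchemaError(f"{path}: HSP history has no data rows")
    return out


def read_result_series(path: str | Path) -> dict[str, ResultSeries]:
    df = _read_csv(path, ["measurand", "day", "value"], "result series")
    out: dict[str, ResultSeries] = {}
    for name, grp in df.groupby("measurand", sort=False):
        grp = grp.sort_values("day")
        try:
            out[str(name)] = series_from_values(
                str(name), grp["day"].astype(int).tolist(),
                grp["value"].astype(float).tolist())
        except ValueError as exc:
            raise SchemaError(f"{path}: {exc}") from exc
    return out


def write_result_series(series: dict[str, ResultSeries], path: str | Path) -> None:
    rows = [(name, d, v) for name, s in series.items() for d, v in s.points]
    pd.DataFrame(rows, columns=["measurand", "day", "value"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# pipeline

def compute_parameters(
    profiles: list[BVProfile], hsps: dict[str, HSPEstimate],
    config: RunConfig = RunConfig(),
) -> pd.DataFrame:
    """Full parameter table: personalized intervals, RCVs, II and route advice.

    One row per measurand; interval limits are reported both unrounded and
    rounded to the measurand's display decimals.
    """
    rows = []
    for p in profiles:
        if p.measurand_name not in hsps:
            raise SchemaError(f"no HSP history for measurand {p.measurand_name!r}")
        h = hsps[p.measurand_name]
        pop = bv_core.prri_pop(h, p, config.coverage, config.clamp_negative_limits)
        ind = bv_core.prri_ind(h, p, config.coverage, config.clamp_negative_limits)
        pop_r = bv_core.round_interval(pop, p.display_decimals)
        ind_r = bv_core.round_interval(ind, p.display_decimals)
        verdict = bv_core.check_applicability(p, h)
        rows.append({
            "measurand": p.measurand_name, "units": p.units,
            "hsp": h.mean, "hsp_sd": h.sd, "n": h.n,
            "cv_i": p.cv_i, "cv_a": p.cv_a, "cv_t": h.cv_t,
            "cv_p": bv_core.cv_within_person(h.cv_t, p.cv_a)[0],
            "ii": bv_core.index_of_individuality(p),
            "pop_ri_lower": p.pop_ri_lower, "pop_ri_upper": p.pop_ri_upper,
            "prri_pop_lower": pop_r.lower, "prri_pop_upper": pop_r.upper,
            "prri_pop_lower_raw": pop.lower, "prri_pop_upper_raw": pop.upper,
            "rcv_pop": bv_core.rcv_pop(p, config.coverage).threshold,
            "prri_ind_lower": ind_r.lower, "prri_ind_upper": ind_r.upper,
            "prri_ind_lower_raw": ind.lower, "prri_ind_upper_raw": ind.upper,
            "rcv_ind": bv_core.rcv_ind(h, config.coverage).threshold,
            "recommended_route": verdict.recommended_route,
            "notes": "; ".join(verdict.messages + pop.warnings + ind.warnings),
        })
    return pd.DataFrame(rows)


def flag_panel(
    series: dict[str, ResultSeries], profiles: list[BVProfile],
    hsps: dict[str, HSPEstimate], config: RunConfig = RunConfig(),
) -> tuple[list[flagging.FlagReport], dict[str, dict[str, object]]]:
    """Evaluate every series under popRI, both prRIs and both RCVs."""
    by_name = {p.measurand_name: p for p in profiles}
    unknown = sorted(set(series) - set(by_name))
    if unknown:
        raise SchemaError(f"measurands without BV parameters: {unknown}")
    reports = []
    for name, s in series.items():
        p, h = by_name[name], hsps[name]
        intervals = {
            "popRI": bv_core.pop_interval(p),
            "prRI_pop": bv_core.prri_pop(h, p, config.coverage, config.clamp_negative_limits),
            "prRI_ind": bv_core.prri_ind(h, p, config.coverage, config.clamp_negative_limits),
        }
        rcvs = {
            "RCV_pop": bv_core.rcv_pop(p, config.coverage),
            "RCV_ind": bv_core.rcv_ind(h, config.coverage),
        }
        reports.append(flagging.evaluate_series(
            s, intervals, rcvs, strict=config.strict_boundaries,
            rcv_reference=config.rcv_reference))
    return reports, flagging.summarize_flags(reports)


def write_flag_report(
    reports: list[flagging.FlagReport], summary: dict[str, dict[str, object]],
    csv_path: str | Path, json_path: str | Path,
) -> None:
    rows = [
        {"measurand": rep.measurand_name, "criterion": crit, "day": pf.day,
         "value": pf.value, "flagged": pf.flagged,
         "direction": pf.direction or "", "note": pf.note or ""}
        for rep in reports for crit, pts in rep.flags.items() for pf in pts
    ]
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    Path(json_path).write_text(json.dumps(summary, indent=2) + "\n")


# ---------------------------------------------------------------------------
# simulation config / panel files

def read_sim_config(path: str | Path) -> SimulationConfig:
    try:
        raw = yaml.safe_load(Path(path).read_text())
    except (OSError, yaml.YAMLError) as exc:
        raise SchemaError(f"{path}: cannot read simulation config: {exc}") from exc
    if not isinstance(raw, dict) or "measurands" not in raw:
        raise SchemaError(f"{path}: config must be a mapping with a 'measurands' key")
    known = {"measurands", "days", "excursions", "n_hsp_history", "seed", "noise"}
    bad = set(raw) - known
    if bad:
        raise SchemaError(f"{path}: unknown config keys {sorted(bad)}")
    try:
        measurands = {
            name: MeasurandSim(float(m["true_hsp"]), float(m["cv_p"]), float(m["cv_a"]))
            for name, m in raw["measurands"].items()
        }
        excursions = tuple(
            Excursion(e["measurand"], int(e["start_day"]), int(e["end_day"]),
                      float(e["fold"]))
            for e in raw.get("excursions", [])
        )
        return SimulationConfig(
            measurands=measurands,
            days=tuple(int(d) for d in raw.get("days", SimulationConfig.days)),
            excursions=excursions,
            n_hsp_history=int(raw.get("n_hsp_history", 3)),
            seed=int(raw.get("seed", 0)),
            noise=raw.get("noise", "normal"),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise SchemaError(f"{path}: invalid simulation config: {exc}") from exc


def write_panel(panel: SimulatedPanel, outdir: str | Path) -> dict[str, Path]:
    """Write results, history and truth labels; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "results": outdir / "results.csv",
        "hsp_history": outdir / "hsp_history.csv",
        "truth": outdir / "truth_labels.csv",
    }
    write_result_series(panel.series, paths["results"])
    hist_rows = [(name, v) for name, vals in panel.hsp_history.items() for v in vals]
    pd.DataFrame(hist_rows, columns=["measurand", "value"]).to_csv(
        paths["hsp_history"], index=False)
    truth_rows = [
        (name, day, exc, fold)
        for name, s in panel.series.items()
        for (day, _), exc, fold in zip(s.points, panel.in_excursion[name],
                                       panel.fold_applied[name])
    ]
    pd.DataFrame(truth_rows, columns=["measurand", "day", "in_excursion",
                                      "fold_applied"]).to_csv(paths["truth"], index=False)
    return paths
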