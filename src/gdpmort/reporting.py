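"""Aggregation and table rendering for scenario and Monte Carlo results.

Sums are taken over unrounded country values; rounding happens only at
render time (deaths half-up to integers, percentages to one decimal).
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import AggregationError
from .montecarlo import MonteCarloSummary
from .scenarios import ScenarioResult

DEFAULT_TOP_N = 10


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal half-up rounding (5 rounds away from zero)."""
    q = decimal.Decimal(1).scaleb(-ndigits)
    d = decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP)
    return float(d)


def percent_increase(additional_total: float, baseline_total: float) -> float:
    """Percent increase of total deaths above baseline, to one decimal."""
    if baseline_total <= 0:
        raise ValueError("baseline_total must be positive")
    return round_half_up(100.0 * additional_total / baseline_total, 1)


@dataclass
class AggregateReport:
    """Grouped totals, shares of additional deaths, and a top-N table."""

    by: str
    totals: pd.DataFrame       # group × r: deaths, additional_deaths
    shares: pd.DataFrame       # group × r: share_pct of additional deaths
    global_totals: pd.DataFrame
    percent_increases: dict[float, float]
    top_countries: pd.DataFrame


def aggregate(
    result: ScenarioResult,
    by: str = "region",
    top_n: int = DEFAULT_TOP_N,
    top_scenario: Optional[float] = None,
) -> AggregateReport:
    """Aggregate a scenario result by region, income group, or globally."""
    if by not in ("region", "income_group", "global"):
        raise ValueError(f"unknown grouping {by!r}")
    table = result.table
    if table.empty:
        raise AggregationError("empty scenario result")
    if by != "global":
        missing = table.loc[table[by].isna(), "country_id"].unique()
        if len(missing):
            raise AggregationError(
                f"countries without {by} label: " + ", ".join(sorted(missing))
            )

    key = by if by != "global" else None
    group_cols = ([key] if key else []) + ["r"]
    totals = (
        table.groupby(group_cols, sort=True)
        .agg(deaths=("deaths", "sum"), additional_deaths=("additional_deaths", "sum"))
        .reset_index()
    )
    global_totals = (
        table.groupby("r", sort=True)
        .agg(deaths=("deaths", "sum"), additional_deaths=("additional_deaths", "sum"))
        .reset_index()
    )

    shares_rows = []
    for r, grp in totals.groupby("r"):
        tot = global_totals.set_index("r").loc[r, "additional_deaths"]
        for _, row in grp.iterrows():
            share = 100.0 * row["additional_deaths"] / tot if tot != 0 else np.nan
            shares_rows.append(
                {
                    **({key: row[key]} if key else {}),
                    "r": r,
                    "share_pct": share,
                }
            )
    shares = pd.DataFrame(shares_rows)

    increases = {}
    gset = global_totals.set_index("r")
    baseline = float(gset.loc[0.0, "deaths"]) if 0.0 in gset.index else np.nan
    for r in gset.index:
        if r == 0.0 or not baseline > 0:
            continue
        increases[float(r)] = percent_increase(
            float(gset.loc[r, "additional_deaths"]), baseline
        )

    reductions = [r for r in sorted(table["r"].unique()) if r > 0]
    chosen = top_scenario if top_scenario is not None else (max(reductions) if reductions else 0.0)
    top = (
        table[table["r"] == chosen]
        .sort_values(["additional_deaths", "country_id"], ascending=[False, True])
        .head(top_n)
        .reset_index(drop=True)
    )
    return AggregateReport(
        by=by,
        totals=totals,
        shares=shares,
        global_totals=global_totals,
        percent_increases=increases,
        top_countries=top,
    )


def _scenario_block(r: float) -> str:
    return "baseline" if r == 0.0 else f"{100 * r:g}pct"


def render_tables(
    result: ScenarioResult,
    out_dir,
    report: Optional[AggregateReport] = None,
    mc_summary: Optional[MonteCarloSummary] = None,
) -> list[Path]:
    """Write scenario / aggregate / MC tables as CSV; returns written paths.

    The per-country table mirrors the wide layout of published lives-lost
    tables: one row per country with a deaths / additional-deaths / CI block
    per scenario.  Deaths are rendered half-up to integers.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    wide_rows: dict[str, dict] = {}
    for _, row in result.table.iterrows():
        block = _scenario_block(row["r"])
        entry = wide_rows.setdefault(
            row["country_id"],
            {"country_id": row["country_id"], "region": row["region"],
             "income_group": row["income_group"]},
        )
        entry[f"deaths_{block}"] = round_half_up(row["deaths"])
        entry[f"lower_{block}"] = round_half_up(row["lower"])
        entry[f"upper_{block}"] = round_half_up(row["upper"])
        if row["r"] > 0:
            entry[f"additional_{block}"] = round_half_up(row["additional_deaths"])

    cols = ["country_id", "region", "income_group"]
    for r in sorted(result.table["r"].unique()) if not result.table.empty else []:
        block = _scenario_block(r)
        cols += [f"deaths_{block}", f"lower_{block}", f"upper_{block}"]
        if r > 0:
            cols.append(f"additional_{block}")
    wide = pd.DataFrame(list(wide_rows.values()), columns=cols)
    if not wide.empty:
        wide = wide.sort_values("country_id").reset_index(drop=True)
    path = out_dir / "scenario_table.csv"
    wide.to_csv(path, index=False)
    written.append(path)

    if report is not None:
        t = report.totals.copy()
        t["deaths"] = t["deaths"].map(round_half_up)
        t["additional_deaths"] = t["additional_deaths"].map(round_half_up)
        p = out_dir / f"aggregate_{report.by}.csv"
        t.to_csv(p, index=False)
        written.append(p)
        s = report.shares.copy()
        if not s.empty:
            s["share_pct"] = s["share_pct"].map(lambda v: round_half_up(v, 1))
        p = out_dir / f"shares_{report.by}.csv"
        s.to_csv(p, index=False)
        written.append(p)

    if mc_summary is not None:
        rows = []
        for r, s in sorted(mc_summary.per_scenario.items()):
            rows.append(
                {
                    "scenario": _scenario_block(r),
                    "point_additional_deaths": round_half_up(
                        mc_summary.point_estimates.get(r, np.nan)
                    ),
                    "mc_mean": round_half_up(s["mean"]),
                    "mc_sd": round_half_up(s["sd"]),
                    "lower95": round_half_up(s["lower"]),
                    "upper95": round_half_up(s["upper"]),
                }
            )
        p = out_dir / "mc_summary.csv"
        pd.DataFrame(rows).to_csv(p, index=False)
        written.append(p)
    return written
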