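"""Counterfactual GDP-reduction scenarios and lives-lost accounting.

A scenario removes a fraction ``r`` of each country's base-year GDP per
capita.  Predicted log U5MR is retransformed naively (``exp``, no smearing
correction), so scenario deaths relate to baseline deaths through the exact
elasticity identity ``deaths(r) = deaths(0) * (1 - r) ** beta``.  Deaths are
U5MR × under-5 population / 1000 — the under-5 population, not live births,
is the weight.  Per-country 95% bounds are log-symmetric:
``exp(log prediction ± 1.96 · s_pred)`` with ``s_pred`` the log-scale
prediction standard error composed from the conditional covariance of the
country's (intercept, slope) BLUP plus the residual variance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .elasticity import ModelFit
from .errors import ProjectionError
from .panel import Panel

logger = logging.getLogger(__name__)

CANONICAL_REDUCTIONS = (0.0, 0.05, 0.10, 0.15)
Z95 = 1.959963984540054  # scipy.stats.norm.ppf(0.975)


@dataclass(frozen=True)
class Scenario:
    """A fractional reduction of base-year GDP per capita."""

    r: float
    label: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.r < 1.0:
            raise ProjectionError(f"reduction must be in [0, 1); got {self.r}")
        if not self.label:
            object.__setattr__(self, "label", f"{self.r:.0%} reduction")


def make_scenarios(reductions: Iterable[float] = CANONICAL_REDUCTIONS) -> list[Scenario]:
    return [Scenario(float(r)) for r in reductions]


@dataclass
class ScenarioResult:
    """Per-country, per-scenario deaths with 95% bounds and totals.

    ``table`` is tidy with one row per (country, scenario): columns
    ``country_id, region, income_group, r, u5mr, deaths, additional_deaths,
    lower, upper, under5_pop``.  The ``r == 0`` rows are the baseline.
    """

    table: pd.DataFrame
    base_year: int
    pop_year: int
    excluded: list[str] = field(default_factory=list)

    @property
    def reductions(self) -> list[float]:
        return sorted(self.table["r"].unique())

    def country(self, country_id: str) -> pd.DataFrame:
        return self.table[self.table["country_id"] == country_id]

    def totals(self) -> pd.DataFrame:
        """Total and additional deaths per scenario, summed over countries."""
        g = self.table.groupby("r", sort=True)
        out = g.agg(
            deaths=("deaths", "sum"), additional_deaths=("additional_deaths", "sum")
        ).reset_index()
        return out

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


# ---------------------------------------------------------------- primitives
def project_u5mr(
    fit: ModelFit,
    country_id: str,
    base_gdp: float,
    r: float,
    covariates: Optional[dict[str, float]] = None,
) -> float:
    """Predicted U5MR (per 1,000) at a fraction ``r`` off ``base_gdp``."""
    if base_gdp <= 0:
        raise ProjectionError(f"base_gdp must be positive; got {base_gdp}")
    if not 0.0 <= r < 1.0:
        raise ProjectionError(f"reduction must be in [0, 1); got {r}")
    if country_id not in fit.effects:
        raise KeyError(f"country {country_id!r} not in fit")
    eff = fit.effects[country_id]
    lp = eff.alpha + eff.beta * math.log((1.0 - r) * base_gdp)
    if covariates:
        for name, coef in fit.covariate_coefs.items():
            if name not in covariates:
                raise ProjectionError(
                    f"covariate {name!r} required for model-{fit.model_id} projection"
                )
            lp += coef * covariates[name]
    elif fit.covariate_coefs:
        raise ProjectionError(
            "fit has covariate terms; covariate values must be supplied"
        )
    return math.exp(lp)


def scenario_deaths(u5mr: float, under5_pop: float) -> float:
    """Deaths implied by a mortality rate per 1,000 and a population count."""
    if u5mr < 0 or under5_pop < 0:
        raise ProjectionError("u5mr and under5_pop must be non-negative")
    return u5mr * under5_pop / 1000.0


def _log_pred_se(fit: ModelFit, country_id: str, log_gdp: float) -> float:
    """Log-scale prediction SE: x' Vc x + sigma^2 with x = (1, log gdp) and
    Vc the conditional covariance of the country's BLUP."""
    e = fit.effects[country_id]
    var = (
        e.cvar_aa
        + 2.0 * log_gdp * e.cvar_ab
        + log_gdp * log_gdp * e.cvar_bb
        + fit.sigma2
    )
    return math.sqrt(max(var, 0.0))


# -------------------------------------------------------------------- runner
def run_scenarios(
    fit: ModelFit,
    panel: Panel,
    scenarios: Optional[Sequence[Scenario]] = None,
    base_year: int = 2019,
    pop_year: int = 2020,
) -> ScenarioResult:
    """Project deaths for every fitted country under each scenario.

    Requires base-year GDP (and, for model 2, base-year covariates) plus
    pop-year under-5 population; countries lacking these after imputation are
    listed in ``excluded`` and dropped from totals with a warning.
    """
    if scenarios is None:
        scenarios = make_scenarios()
    scenarios = list(scenarios)
    if not any(s.r == 0.0 for s in scenarios):
        scenarios = [Scenario(0.0, "baseline")] + scenarios

    df = panel.data
    base = df[df["year"] == base_year].set_index("country_id")
    pop = df[df["year"] == pop_year].set_index("country_id")

    rows = []
    excluded = []
    for cid in fit.countries:
        eff = fit.effects[cid]
        gdp = base["gdp_pc"].get(cid, np.nan) if cid in base.index else np.nan
        u5pop = pop["under5_pop"].get(cid, np.nan) if cid in pop.index else np.nan
        covs = None
        if fit.covariate_coefs:
            if cid in base.index:
                covs = {
                    k: float(base.loc[cid, k]) for k in fit.covariate_coefs
                }
            if covs is None or any(np.isnan(v) for v in covs.values()):
                excluded.append(cid)
                continue
        if np.isnan(gdp) or np.isnan(u5pop):
            excluded.append(cid)
            continue
        for sc in scenarios:
            u5mr = project_u5mr(fit, cid, float(gdp), sc.r, covs)
            deaths = scenario_deaths(u5mr, float(u5pop))
            s_pred = _log_pred_se(fit, cid, math.log((1.0 - sc.r) * float(gdp)))
            rows.append(
                {
                    "country_id": cid,
                    "region": eff.region,
                    "income_group": eff.income_group,
                    "r": sc.r,
                    "u5mr": u5mr,
                    "deaths": deaths,
                    "lower": deaths * math.exp(-Z95 * s_pred),
                    "upper": deaths * math.exp(Z95 * s_pred),
                    "under5_pop": float(u5pop),
                }
            )
    if excluded:
        logger.warning(
            "countries excluded from projection (missing base GDP/covariates "
            "or population): %s",
            ", ".join(excluded),
        )
    if not rows:
        table = pd.DataFrame(
            columns=[
                "country_id", "region", "income_group", "r", "u5mr", "deaths",
                "additional_deaths", "lower", "upper", "under5_pop",
            ]
        )
        return ScenarioResult(table, base_year, pop_year, excluded)

    table = pd.DataFrame(rows)
    baseline = table[table["r"] == 0.0].set_index("country_id")["deaths"]
    table["additional_deaths"] = table.apply(
        lambda row: row["deaths"] - baseline[row["country_id"]], axis=1
    )
    cols = [
        "country_id", "region", "income_group", "r", "u5mr", "deaths",
        "additional_deaths", "lower", "upper", "under5_pop",
    ]
    table = table[cols].sort_values(["country_id", "r"]).reset_index(drop=True)
    return ScenarioResult(table, base_year, pop_year, excluded)


def additional_deaths(baseline_deaths: float, scenario_deaths_: float) -> float:
    """Scenario-minus-baseline lives lost."""
    return scenario_deaths_ - baseline_deaths
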