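"""Monte Carlo propagation of slope uncertainty into total-deaths estimates.

Each iteration draws every country's elasticity from
``Normal(beta_j, se_j^2)`` independently, holds intercepts and covariate
coefficients at their point estimates, recomputes baseline and scenario
deaths, and records total additional deaths per scenario.  Per-country
random-number substreams are derived from the root seed and the country id,
so results do not depend on country ordering.
"""

from __future__ import annotations

import json
import math
import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .elasticity import ModelFit
from .errors import ProjectionError
from .panel import Panel
from .scenarios import Scenario, ScenarioResult, make_scenarios, run_scenarios

DEFAULT_N_ITER = 500


@dataclass
class MonteCarloSummary:
    """Per-scenario summary of the simulated total additional deaths."""

    per_scenario: dict[float, dict[str, float]]  # r -> mean/sd/lower/upper
    point_estimates: dict[float, float]          # r -> point additional deaths
    n_iter: int
    seed: Optional[int]
    iteration_totals: Optional[dict[float, np.ndarray]] = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "n_iter": self.n_iter,
            "seed": self.seed,
            "scenarios": [
                {
                    "r": r,
                    "point_additional_deaths": self.point_estimates.get(r),
                    "mean": s["mean"],
                    "sd": s["sd"],
                    "lower95": s["lower"],
                    "upper95": s["upper"],
                }
                for r, s in sorted(self.per_scenario.items())
            ],
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text


def summarize_iterations(
    totals: Sequence[float], level: float = 0.95
) -> tuple[float, float, float, float]:
    """Sample mean, SD (n−1), and empirical percentile interval."""
    x = np.asarray(totals, dtype=float)
    if x.size < 2:
        raise ValueError("at least 2 iteration values are required")
    tail = 100.0 * (1.0 - level) / 2.0
    lower, upper = np.percentile(x, [tail, 100.0 - tail])
    return float(x.mean()), float(x.std(ddof=1)), float(lower), float(upper)


def _country_stream(seed: Optional[int], country_id: str) -> np.random.Generator:
    # stable per-country substream: root seed + CRC32 of the id
    tag = zlib.crc32(country_id.encode("utf-8"))
    entropy = [tag] if seed is None else [int(seed), tag]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def run_mc(
    fit: ModelFit,
    panel: Panel,
    scenarios: Optional[Sequence[Scenario]] = None,
    n_iter: int = DEFAULT_N_ITER,
    seed: Optional[int] = None,
    base_year: int = 2019,
    pop_year: int = 2020,
    keep_totals: bool = False,
) -> MonteCarloSummary:
    """Run the slope-sampling Monte Carlo experiment."""
    if n_iter < 2:
        raise ValueError("n_iter must be at least 2")
    for cid in fit.countries:
        if fit.effects[cid].se_beta < 0:
            raise ProjectionError(f"negative se for {cid}")
    if scenarios is None:
        scenarios = make_scenarios()
    scenarios = list(scenarios)
    if not any(s.r == 0.0 for s in scenarios):
        scenarios = [Scenario(0.0, "baseline")] + scenarios

    point = run_scenarios(fit, panel, scenarios, base_year, pop_year)
    included = sorted(set(point.table["country_id"]))
    if not included:
        raise ProjectionError("no countries available for Monte Carlo")

    base_rows = point.table[point.table["r"] == 0.0].set_index("country_id")
    df = panel.data
    gdp_by_cid = (
        df[df["year"] == base_year].set_index("country_id")["gdp_pc"].to_dict()
    )

    reductions = sorted({s.r for s in scenarios})
    # totals[r] accumulates per-iteration total deaths for each scenario
    totals = {r: np.zeros(n_iter) for r in reductions}
    for cid in included:
        eff = fit.effects[cid]
        log_gdp = math.log(float(gdp_by_cid[cid]))
        # constant part of the log prediction (intercept + covariate terms),
        # recovered from the point baseline so covariates need no re-lookup
        base_u5mr = float(base_rows.loc[cid, "u5mr"])
        const = math.log(base_u5mr) - eff.beta * log_gdp
        pop = float(base_rows.loc[cid, "under5_pop"])
        draws = (
            np.full(n_iter, eff.beta)
            if eff.se_beta == 0.0
            else _country_stream(seed, cid).normal(eff.beta, eff.se_beta, n_iter)
        )
        for r in reductions:
            x = log_gdp + math.log1p(-r)
            totals[r] += np.exp(const + draws * x) * pop / 1000.0

    baseline_totals = totals[0.0]
    per_scenario: dict[float, dict[str, float]] = {}
    point_estimates: dict[float, float] = {}
    point_totals = point.totals().set_index("r")
    iteration_totals: dict[float, np.ndarray] = {}
    for r in reductions:
        if r == 0.0:
            continue
        additional = totals[r] - baseline_totals
        mean, sd, lower, upper = summarize_iterations(additional)
        per_scenario[r] = {"mean": mean, "sd": sd, "lower": lower, "upper": upper}
        point_estimates[r] = float(point_totals.loc[r, "additional_deaths"])
        if keep_totals:
            iteration_totals[r] = additional
    return MonteCarloSummary(
        per_scenario=per_scenario,
        point_estimates=point_estimates,
        n_iter=n_iter,
        seed=seed,
        iteration_totals=iteration_totals if keep_totals else None,
    )
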