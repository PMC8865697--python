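"""Synthetic country-panel generator with known ground truth.

Emulates a WDI-style 129-country, 1990–2020 panel: lognormal GDP-per-capita
growth paths, covariates with mild dependence on log GDP, a log-log mortality
process with country-varying elasticities, configurable per-variable
missingness (MCAR by default, optionally GDP-dependent), income/region
labels, GNI classification values, and under-5 populations spanning small
states to India-scale countries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .elasticity import CountryEffect, ModelFit
from .panel import GNI_THRESHOLD, H_COVARIATES, Panel, Z_COVARIATES

DEFAULT_REGIONS = {
    "Sub-Saharan Africa": 0.35,
    "South Asia": 0.10,
    "East Asia & Pacific": 0.15,
    "Latin America & Caribbean": 0.15,
    "Middle East & North Africa": 0.10,
    "Europe & Central Asia": 0.15,
}
DEFAULT_INCOME_GROUPS = {"low": 0.25, "lower-middle": 0.40, "upper-middle": 0.35}

#: default covariate coefficients of the generating mortality process
DEFAULT_BETA_Z = {
    "electric_power_kwh_pc": -2.0e-5,
    "women_parliament_pct": -1.0e-3,
    "total_fertility": 5.0e-2,
}
DEFAULT_BETA_H = {
    "physicians_per_1000": -2.0e-2,
    "dpt_coverage_pct": -2.0e-3,
}

#: missing-cell rates loosely calibrated to WDI-like coverage gaps; keys may
#: map to a flat rate or to {year: rate} overrides
DEFAULT_MISSING_RATES: dict = {
    "gdp_pc": {2010: 0.0233, 2015: 0.0465, 2019: 0.1085, "default": 0.02},
    "physicians_per_1000": {2010: 0.1705, 2015: 0.5349, 2019: 1.0, "default": 0.15},
    "electric_power_kwh_pc": {2010: 0.3256, 2015: 1.0, 2019: 1.0, "default": 0.25},
    "women_parliament_pct": {2010: 0.0388, 2015: 0.0233, 2019: 0.0078, "default": 0.03},
    "dpt_coverage_pct": {2010: 0.0078, 2015: 0.0, 2019: 1.0, "default": 0.01},
}


@dataclass
class GeneratorConfig:
    n_countries: int = 129
    years: tuple[int, int] = (1990, 2020)
    regions: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_REGIONS))
    income_groups: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_INCOME_GROUPS)
    )
    lmic_share: float = 1.0          # share of countries with GNI below threshold
    mu_beta: float = -0.2845         # mean GDP elasticity of U5MR
    tau_beta: float = 0.05           # SD of country elasticities
    mu_alpha: float = 6.5            # mean country intercept (log U5MR scale)
    tau_alpha: float = 0.30
    sigma: float = 0.05              # residual SD on the log scale
    beta_z: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BETA_Z))
    beta_h: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BETA_H))
    gdp0_log_mean: float = math.log(2000.0)
    gdp0_log_sd: float = 0.9
    gdp_growth_mean: float = 0.02    # mean annual log growth
    gdp_growth_sd: float = 0.10      # volatile paths keep country slopes identifiable
    pop_log10_range: tuple[float, float] = (5.0, 7.3)  # under-5 population
    missing_rates: dict = field(default_factory=lambda: dict(DEFAULT_MISSING_RATES))
    missing_on_gdp: bool = False     # MAR: missingness increases for poorer countries
    seed: int = 0

    def __post_init__(self) -> None:
        if self.years[0] > self.years[1]:
            raise ValueError("invalid year range")
        if self.sigma < 0 or self.tau_beta < 0:
            raise ValueError("sigma and tau_beta must be non-negative")
        if not 0.0 <= self.lmic_share <= 1.0:
            raise ValueError("lmic_share must be in [0, 1]")
        for probs in (self.regions, self.income_groups):
            if any(p < 0 or p > 1 for p in probs.values()):
                raise ValueError("label probabilities must be in [0, 1]")


@dataclass
class GroundTruth:
    """Generating parameters plus the complete (pre-missingness) panel."""

    alpha: dict[str, float]
    beta: dict[str, float]
    beta_z: dict[str, float]
    beta_h: dict[str, float]
    sigma: float
    complete_panel: Panel


def _rate_for(rates, var: str, year: int) -> float:
    spec = rates.get(var)
    if spec is None:
        return 0.0
    if isinstance(spec, dict):
        return float(spec.get(year, spec.get("default", 0.0)))
    return float(spec)


def generate_panel(config: GeneratorConfig) -> tuple[Panel, GroundTruth]:
    """Simulate a panel and return it with its ground truth."""
    rng = np.random.default_rng(config.seed)
    y0, y1 = config.years
    years = np.arange(y0, y1 + 1)
    n_years = len(years)
    n = config.n_countries
    cids = [f"C{i:03d}" for i in range(n)]

    region_names = list(config.regions)
    region_p = np.array(list(config.regions.values()), dtype=float)
    region_p = region_p / region_p.sum()
    income_names = list(config.income_groups)
    income_p = np.array(list(config.income_groups.values()), dtype=float)
    income_p = income_p / income_p.sum()
    regions = rng.choice(region_names, size=n, p=region_p)
    incomes = rng.choice(income_names, size=n, p=income_p)

    alphas = rng.normal(config.mu_alpha, config.tau_alpha, n)
    betas = rng.normal(config.mu_beta, config.tau_beta, n)

    # GDP paths: lognormal initial level, lognormal annual growth
    log_gdp0 = rng.normal(config.gdp0_log_mean, config.gdp0_log_sd, n)
    growth = rng.normal(config.gdp_growth_mean, config.gdp_growth_sd, (n, n_years - 1))
    log_gdp = np.concatenate(
        [log_gdp0[:, None], log_gdp0[:, None] + np.cumsum(growth, axis=1)], axis=1
    )
    gdp = np.exp(log_gdp)

    # covariates: mild dependence on log GDP so model 2 is distinguishable
    elec = np.exp(1.0 + 0.75 * log_gdp + rng.normal(0, 0.2, (n, n_years)))
    women = np.clip(
        5.0
        + 0.5 * (years - y0)[None, :]
        + 1.0 * (log_gdp - log_gdp.mean())
        + rng.normal(0, 2.0, (n, n_years)),
        0.0,
        100.0,
    )
    fert = np.clip(
        9.0 - 0.7 * log_gdp + rng.normal(0, 0.3, (n, n_years)), 0.8, 9.0
    )
    phys = np.exp(-4.5 + 0.55 * log_gdp + rng.normal(0, 0.2, (n, n_years)))
    dpt = np.clip(
        30.0 + 7.0 * log_gdp + rng.normal(0, 4.0, (n, n_years)), 0.0, 100.0
    )
    Z = {"electric_power_kwh_pc": elec, "women_parliament_pct": women, "total_fertility": fert}
    H = {"physicians_per_1000": phys, "dpt_coverage_pct": dpt}

    lp = alphas[:, None] + betas[:, None] * log_gdp
    for v, c in config.beta_z.items():
        lp = lp + c * Z[v]
    for v, c in config.beta_h.items():
        lp = lp + c * H[v]
    eps = rng.normal(0.0, config.sigma, (n, n_years)) if config.sigma > 0 else 0.0
    log_u5mr = lp + eps
    if np.any(log_u5mr > 50):
        raise ValueError("config produces degenerate u5mr scale (overflow)")
    u5mr = np.exp(log_u5mr)

    lo10, hi10 = config.pop_log10_range
    pop = 10.0 ** rng.uniform(lo10, hi10, n)

    n_lmic = int(round(config.lmic_share * n))
    is_lmic = np.zeros(n, dtype=bool)
    is_lmic[rng.permutation(n)[:n_lmic]] = True
    gni = np.where(
        is_lmic,
        rng.uniform(300.0, GNI_THRESHOLD - 1.0, n),
        rng.uniform(GNI_THRESHOLD, 80000.0, n),
    )

    frames = []
    for i, cid in enumerate(cids):
        frames.append(
            pd.DataFrame(
                {
                    "country_id": cid,
                    "year": years,
                    "u5mr": u5mr[i],
                    "gdp_pc": gdp[i],
                    "electric_power_kwh_pc": elec[i],
                    "women_parliament_pct": women[i],
                    "total_fertility": fert[i],
                    "physicians_per_1000": phys[i],
                    "dpt_coverage_pct": dpt[i],
                    "under5_pop": pop[i],
                    "gni_pc": gni[i],
                    "region": regions[i],
                    "income_group": incomes[i],
                }
            )
        )
    complete = pd.concat(frames, ignore_index=True)
    complete_panel = Panel(complete)

    # missingness masks
    masked = complete.copy()
    mask_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    # MAR weight: poorer countries more likely to have gaps
    if config.missing_on_gdp:
        rel = (log_gdp.mean(axis=1) - log_gdp.mean()) / max(log_gdp.std(), 1e-9)
        country_w = 1.0 / (1.0 + np.exp(rel))  # in (0, 1), higher for poor
        country_w = country_w / country_w.mean()
    else:
        country_w = np.ones(n)
    for var in masked.columns:
        if var in ("country_id", "year", "region", "income_group", "u5mr",
                   "under5_pop", "gni_pc", "total_fertility"):
            continue
        for yi, year in enumerate(years):
            rate = _rate_for(config.missing_rates, var, int(year))
            if rate <= 0:
                continue
            p = np.clip(rate * country_w, 0.0, 1.0)
            hit = mask_rng.random(n) < p
            if hit.any():
                idx = masked.index[
                    (masked["year"] == year)
                    & masked["country_id"].isin(np.array(cids)[hit])
                ]
                masked.loc[idx, var] = np.nan

    truth = GroundTruth(
        alpha={cid: float(alphas[i]) for i, cid in enumerate(cids)},
        beta={cid: float(betas[i]) for i, cid in enumerate(cids)},
        beta_z=dict(config.beta_z),
        beta_h=dict(config.beta_h),
        sigma=config.sigma,
        complete_panel=complete_panel,
    )
    return Panel(masked), truth


def make_fixture_table2_country(
    baseline_deaths: float,
    slope: float,
    country_id: str = "FIX",
    base_gdp: float = 1.0,
    under5_pop: float = 1.0e7,
    base_year: int = 2019,
    pop_year: int = 2020,
) -> tuple[Panel, ModelFit]:
    """One-country panel plus a fit stub reproducing
    ``deaths(r) = baseline_deaths * (1 - r) ** slope`` exactly.

    With the default ``base_gdp = 1`` the baseline deaths do not depend on
    the slope, which keeps Monte Carlo baselines fixed under slope draws.
    """
    if baseline_deaths <= 0:
        raise ValueError("baseline_deaths must be positive")
    if not math.isfinite(slope):
        raise ValueError("slope must be finite")
    u5mr0 = baseline_deaths * 1000.0 / under5_pop
    alpha = math.log(u5mr0) - slope * math.log(base_gdp)
    rows = []
    for year in sorted({base_year, pop_year}):
        rows.append(
            {
                "country_id": country_id,
                "year": year,
                "u5mr": u5mr0,
                "gdp_pc": base_gdp,
                "under5_pop": under5_pop,
                "region": "Fixture Region",
                "income_group": "low",
                "gni_pc": 1000.0,
            }
        )
    panel = Panel(pd.DataFrame(rows))
    fit_stub = ModelFit(
        model_id=1,
        effects={
            country_id: CountryEffect(
                alpha=alpha,
                beta=slope,
                se_beta=0.0,
                n_obs=len(rows),
                region="Fixture Region",
                income_group="low",
            )
        },
        covariate_coefs={},
        fixed_intercept=alpha,
        fixed_slope=slope,
        fixed_slope_se=0.0,
        group_effect_coefs={},
        reference_levels={},
        tau_alpha2=0.0,
        tau_beta2=0.0,
        tau_alphabeta=0.0,
        sigma2=0.0,
        loglike=float("nan"),
        notes=["fixture stub"],
    )
    return panel, fit_stub
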