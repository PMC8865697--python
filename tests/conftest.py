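import warnings

import numpy as np
import pandas as pd
import pytest

from gdpmort.panel import Panel
from gdpmort.synthetic import GeneratorConfig, generate_panel

warnings.filterwarnings("ignore", message=".*convergence.*")


@pytest.fixture
def three_country_csv(tmp_path):
    """Long CSV: 3 countries x 31 years, fully observed except one GDP cell."""
    rows = []
    rng = np.random.default_rng(42)
    for cid, region, income, gni in [
        ("AAA", "Sub-Saharan Africa", "low", 900.0),
        ("BBB", "South Asia", "lower-middle", 2500.0),
        ("CCC", "East Asia & Pacific", "upper-middle", 8000.0),
    ]:
        for year in range(1990, 2021):
            rows.append(
                {
                    "country_id": cid,
                    "year": year,
                    "u5mr": round(float(50 + rng.uniform(-5, 5)), 4),
                    "gdp_pc": "" if (cid == "AAA" and year == 2019) else round(float(2000 + rng.uniform(-100, 100)), 4),
                    "electric_power_kwh_pc": round(float(800 + rng.uniform(-50, 50)), 4),
                    "women_parliament_pct": round(float(rng.uniform(5, 40)), 4),
                    "total_fertility": round(float(rng.uniform(2, 6)), 4),
                    "physicians_per_1000": round(float(rng.uniform(0.1, 3)), 4),
                    "dpt_coverage_pct": round(float(rng.uniform(50, 99)), 4),
                    "under5_pop": 1_000_000,
                    "gni_pc": gni,
                    "region": region,
                    "income_group": income,
                }
            )
    path = tmp_path / "panel3.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


@pytest.fixture(scope="session")
def noisy_panel():
    """20-country panel with known truth, no missingness."""
    cfg = GeneratorConfig(n_countries=20, sigma=0.05, seed=7, missing_rates={})
    return generate_panel(cfg)


@pytest.fixture(scope="session")
def noisefree_panel():
    cfg = GeneratorConfig(n_countries=8, sigma=0.0, seed=11, missing_rates={})
    return generate_panel(cfg)


def exact_line_panel(slopes, alphas=None, years=(2000, 2020), gdp0=1000.0):
    """Hand-built noise-free panel: per-country exact log-log lines, no
    covariate effects on mortality (independent oracle for fitting)."""
    alphas = alphas if alphas is not None else [6.0] * len(slopes)
    rows = []
    rng = np.random.default_rng(0)
    for i, (a, b) in enumerate(zip(alphas, slopes)):
        gdp = gdp0 * np.exp(np.cumsum(rng.normal(0.03, 0.08, years[1] - years[0] + 1)))
        for t, year in enumerate(range(years[0], years[1] + 1)):
            rows.append(
                {
                    "country_id": f"X{i:02d}",
                    "year": year,
                    "u5mr": float(np.exp(a + b * np.log(gdp[t]))),
                    "gdp_pc": float(gdp[t]),
                    "under5_pop": 500_000.0,
                    "gni_pc": 1000.0,
                    "region": "R1",
                    "income_group": "low",
                }
            )
    return Panel(pd.DataFrame(rows))
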