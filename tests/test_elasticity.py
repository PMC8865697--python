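import json

import numpy as np
import pandas as pd
import pytest

from gdpmort.elasticity import (
    ModelFit,
    ModelSpec,
    build_design,
    country_slope,
    fit,
)
from gdpmort.errors import DesignError, FitError
from gdpmort.panel import Panel
from gdpmort.synthetic import GeneratorConfig, generate_panel

from conftest import exact_line_panel


class TestModelSpec:
    def test_model1_has_no_covariates(self):
        spec = ModelSpec(model_id=1)
        assert spec.covariates == []
        assert not spec.group_fixed_effects

    def test_model2_has_all_covariates(self):
        spec = ModelSpec(model_id=2)
        assert len(spec.covariates) == 5
        assert spec.group_fixed_effects

    def test_invalid_model_id(self):
        with pytest.raises(ValueError):
            ModelSpec(model_id=3)


class TestBuildDesign:
    def test_model1_matrix_columns(self, noisy_panel):
        panel, _ = noisy_panel
        d = build_design(panel, ModelSpec(model_id=1))
        assert list(d.X.columns) == ["intercept", "log_gdp"]

    def test_log_transforms_applied(self, noisy_panel):
        panel, _ = noisy_panel
        d = build_design(panel, ModelSpec(model_id=1))
        df = panel.data
        np.testing.assert_allclose(d.y, np.log(df["u5mr"].to_numpy()))
        np.testing.assert_allclose(d.log_gdp, np.log(df["gdp_pc"].to_numpy()))

    def test_dummy_coding_reference_levels(self):
        rows = []
        for i, (reg, inc) in enumerate(
            [("RA", "low"), ("RB", "lower-middle"), ("RC", "upper-middle")] * 2
        ):
            for year in range(2000, 2010):
                rows.append(
                    {
                        "country_id": f"C{i}",
                        "year": year,
                        "u5mr": 40.0 + i,
                        "gdp_pc": 1000.0 + 10 * year,
                        "electric_power_kwh_pc": 500.0,
                        "women_parliament_pct": 20.0,
                        "total_fertility": 3.0,
                        "physicians_per_1000": 1.0,
                        "dpt_coverage_pct": 80.0,
                        "region": reg,
                        "income_group": inc,
                    }
                )
        d = build_design(Panel(pd.DataFrame(rows)), ModelSpec(model_id=2))
        dummies = [c for c in d.X.columns if "[" in c]
        # 3 regions and 3 income groups -> 2 + 2 dummies, first-sorted ref
        assert sorted(dummies) == [
            "income_group[lower-middle]",
            "income_group[upper-middle]",
            "region[RB]",
            "region[RC]",
        ]
        assert d.reference_levels == {"region": "RA", "income_group": "low"}

    def test_nonpositive_gdp_raises(self, noisy_panel):
        panel, _ = noisy_panel
        broken = panel.data.copy()
        # bypass Panel validation to exercise the design-level guard
        hacked = Panel(broken)
        hacked._df.loc[0, "gdp_pc"] = 0.0
        with pytest.raises(DesignError, match="non-positive"):
            build_design(hacked, ModelSpec(model_id=1))

    def test_rows_with_missing_covariates_dropped(self, noisy_panel):
        panel, _ = noisy_panel
        df = panel.data.copy()
        df.loc[df.index[:10], "total_fertility"] = np.nan
        d = build_design(Panel(df), ModelSpec(model_id=2))
        assert d.n_dropped_missing == 10

    def test_thin_countries_excluded(self, noisy_panel):
        panel, _ = noisy_panel
        df = panel.data.copy()
        cid = panel.countries[0]
        df = df[~((df["country_id"] == cid) & (df["year"] > 1993))]
        d = build_design(Panel(df), ModelSpec(model_id=1))
        assert cid in d.excluded_countries
        assert cid not in set(d.groups)


class TestFitNoiseFree:
    def test_exact_recovery_distinct_slopes(self):
        panel = exact_line_panel([-0.5, -0.3, -0.1], alphas=[6.0, 5.5, 5.0])
        result = fit(panel, ModelSpec(model_id=1))
        for cid, b_true, a_true in zip(
            result.countries, [-0.5, -0.3, -0.1], [6.0, 5.5, 5.0]
        ):
            assert result.effects[cid].beta == pytest.approx(b_true, abs=1e-6)
            assert result.effects[cid].alpha == pytest.approx(a_true, abs=1e-6)
            assert result.effects[cid].se_beta == 0.0

    def test_generator_noise_free_recovery(self, noisefree_panel):
        panel, truth = noisefree_panel
        result = fit(panel, ModelSpec(model_id=2))
        for cid in result.countries:
            assert result.effects[cid].beta == pytest.approx(
                truth.beta[cid], abs=1e-6
            )

    def test_gdp_rescaling_identity(self):
        panel = exact_line_panel([-0.5, -0.3, -0.1])
        c = 7.3
        df = panel.data.copy()
        df["gdp_pc"] = df["gdp_pc"] * c
        result0 = fit(panel, ModelSpec(model_id=1))
        result1 = fit(Panel(df), ModelSpec(model_id=1))
        for cid in result0.countries:
            b0 = result0.effects[cid].beta
            assert result1.effects[cid].beta == pytest.approx(b0, abs=1e-6)
            assert result1.effects[cid].alpha == pytest.approx(
                result0.effects[cid].alpha - b0 * np.log(c), abs=1e-6
            )


class TestFitNoisy:
    def test_common_slope_within_2se(self):
        cfg = GeneratorConfig(
            n_countries=15, sigma=0.05, tau_beta=0.0, seed=21, missing_rates={}
        )
        panel, truth = generate_panel(cfg)
        result = fit(panel, ModelSpec(model_id=2))
        for cid in result.countries:
            beta, se = result.country_slope(cid)
            assert abs(beta - (-0.2845)) <= 2.0 * max(se, 1e-12) + 5e-3

    def test_variance_components_valid(self, noisy_panel):
        panel, _ = noisy_panel
        result = fit(panel, ModelSpec(model_id=2))
        assert result.tau_alpha2 >= 0
        assert result.tau_beta2 >= 0
        assert result.sigma2 > 0
        denom = np.sqrt(result.tau_alpha2 * result.tau_beta2)
        if denom > 0:
            assert abs(result.tau_alphabeta) <= denom + 1e-12

    def test_permutation_invariance(self, noisy_panel):
        panel, _ = noisy_panel
        shuffled = Panel(panel.data.sample(frac=1.0, random_state=5))
        r1 = fit(panel, ModelSpec(model_id=2))
        r2 = fit(shuffled, ModelSpec(model_id=2))
        for cid in r1.countries:
            assert r2.effects[cid].beta == pytest.approx(
                r1.effects[cid].beta, abs=1e-8
            )

    def test_shrinkage_reduces_slope_dispersion(self, noisy_panel):
        # The joint (intercept, slope) BLUP is not always between the
        # country OLS slope and the pooled slope, but shrinkage must reduce
        # cross-country slope dispersion relative to per-country OLS.
        panel, _ = noisy_panel
        result = fit(panel, ModelSpec(model_id=1))
        df = panel.data
        ols = []
        blup = []
        for cid in result.countries:
            sub = df[df["country_id"] == cid]
            ols.append(
                np.polyfit(np.log(sub["gdp_pc"]), np.log(sub["u5mr"]), 1)[0]
            )
            blup.append(result.effects[cid].beta)
        assert np.var(blup) < np.var(ols)
        assert np.corrcoef(ols, blup)[0, 1] > 0.5

    def test_constant_covariates_reduce_model2_to_model1(self):
        panel = exact_line_panel([-0.4, -0.25, -0.15])
        df = panel.data.copy()
        noise = np.random.default_rng(2).normal(0, 0.03, len(df))
        df["u5mr"] = df["u5mr"] * np.exp(noise)
        for col, val in [
            ("electric_power_kwh_pc", 500.0),
            ("women_parliament_pct", 20.0),
            ("total_fertility", 3.0),
            ("physicians_per_1000", 1.0),
            ("dpt_coverage_pct", 80.0),
        ]:
            df[col] = val
        p = Panel(df)
        r1 = fit(p, ModelSpec(model_id=1))
        r2 = fit(p, ModelSpec(model_id=2))
        for cid in r1.countries:
            assert r2.effects[cid].beta == pytest.approx(
                r1.effects[cid].beta, abs=1e-6
            )

    def test_fewer_than_two_countries(self):
        panel = exact_line_panel([-0.3])
        with pytest.raises(FitError):
            fit(panel, ModelSpec(model_id=1))


class TestCountrySlope:
    def test_unknown_country(self, noisefree_panel):
        panel, _ = noisefree_panel
        result = fit(panel, ModelSpec(model_id=1))
        with pytest.raises(KeyError):
            country_slope(result, "ZZZ")

    def test_noise_free_zero_se(self):
        # model-1 noise-free requires no covariate contribution to mortality
        panel = exact_line_panel([-0.5, -0.3, -0.1])
        result = fit(panel, ModelSpec(model_id=1))
        for cid in result.countries:
            beta, se = country_slope(result, cid)
            assert se == 0.0

    def test_positive_se_with_noise(self, noisy_panel):
        panel, _ = noisy_panel
        result = fit(panel, ModelSpec(model_id=2))
        for cid in result.countries:
            _, se = country_slope(result, cid)
            assert se > 0


class TestSerialization:
    def test_json_roundtrip(self, noisy_panel, tmp_path):
        panel, _ = noisy_panel
        result = fit(panel, ModelSpec(model_id=2))
        path = tmp_path / "fit.json"
        result.to_json(path)
        back = ModelFit.from_json(path)
        assert back.countries == result.countries
        for cid in result.countries:
            assert back.effects[cid].beta == result.effects[cid].beta
            assert back.effects[cid].se_beta == result.effects[cid].se_beta
        assert back.sigma2 == result.sigma2
        assert back.reference_levels == result.reference_levels

    def test_schema_version_checked(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text(json.dumps({"schema_version": 99}))
        with pytest.raises(ValueError, match="schema"):
            ModelFit.from_json(path)
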