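"""Multilevel mixed-effects log-log elasticity models of under-5 mortality.

Model 1 regresses log U5MR on log GDP per capita with a correlated random
intercept and random slope per country.  Model 2 adds socio-economic (Z) and
health-service (H) covariates plus region and income-group fixed effects.
Per-country elasticities are the fixed mean slope plus each country's BLUP
(best linear unbiased predictor) slope deviation; their standard errors
combine the fixed-slope sampling variance with the conditional variance of
the BLUP.

Estimation is REML via :class:`statsmodels.regression.mixed_linear_model.MixedLM`,
with two fallbacks:

* if the pooled within-country residual variance is numerically zero (a
  noise-free panel), the saturated per-country OLS solution is exact and is
  returned directly with zero standard errors;
* if the correlated random-effects fit fails to converge, the model is refit
  with independent intercept and slope components.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import DesignError, FitError
from .panel import H_COVARIATES, Panel, Z_COVARIATES

logger = logging.getLogger(__name__)

MIN_ROWS_PER_COUNTRY = 5
_NOISE_FREE_TOL = 1e-10

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class ModelSpec:
    """Which model to fit: 1 (GDP only) or 2 (covariates + group fixed effects)."""

    model_id: int = 2

    def __post_init__(self) -> None:
        if self.model_id not in (1, 2):
            raise ValueError("model_id must be 1 or 2")

    @property
    def covariates(self) -> list[str]:
        return [] if self.model_id == 1 else Z_COVARIATES + H_COVARIATES

    @property
    def group_fixed_effects(self) -> bool:
        return self.model_id == 2


@dataclass
class DesignMatrices:
    """Model matrices with row bookkeeping."""

    y: np.ndarray                 # log u5mr
    X: pd.DataFrame               # fixed-effects matrix (intercept first)
    log_gdp: np.ndarray
    groups: np.ndarray            # country id per row
    row_index: pd.DataFrame       # (country_id, year) per retained row
    n_dropped_missing: int
    excluded_countries: list[str]
    reference_levels: dict[str, str]


@dataclass
class CountryEffect:
    """Composed per-country intercept/slope with uncertainty pieces.

    ``alpha`` includes the global intercept, the country's region and
    income-group fixed effects, and the BLUP intercept deviation — but not
    covariate terms, which are applied at projection time.  ``cvar_*`` are the
    entries of the conditional covariance of the (intercept, slope) BLUP.
    """

    alpha: float
    beta: float
    se_beta: float
    n_obs: int
    cvar_aa: float = 0.0
    cvar_ab: float = 0.0
    cvar_bb: float = 0.0
    region: Optional[str] = None
    income_group: Optional[str] = None


@dataclass
class ModelFit:
    """Fitted elasticity model."""

    model_id: int
    effects: dict[str, CountryEffect]
    covariate_coefs: dict[str, float]
    fixed_intercept: float
    fixed_slope: float
    fixed_slope_se: float
    group_effect_coefs: dict[str, float]
    reference_levels: dict[str, str]
    tau_alpha2: float
    tau_beta2: float
    tau_alphabeta: float
    sigma2: float
    loglike: float
    converged: bool = True
    notes: list[str] = field(default_factory=list)

    @property
    def countries(self) -> list[str]:
        return sorted(self.effects)

    def country_slope(self, country_id: str) -> tuple[float, float]:
        """Return (elasticity, standard error) for a fitted country."""
        if country_id not in self.effects:
            raise KeyError(f"country {country_id!r} not in fit")
        e = self.effects[country_id]
        return e.beta, e.se_beta

    # ----------------------------------------------------------- persistence
    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "model_id": self.model_id,
            "fixed": {
                "intercept": self.fixed_intercept,
                "log_gdp": self.fixed_slope,
                "log_gdp_se": self.fixed_slope_se,
                "covariates": self.covariate_coefs,
                "group_effects": self.group_effect_coefs,
                "reference_levels": self.reference_levels,
            },
            "variance_components": {
                "tau_alpha2": self.tau_alpha2,
                "tau_beta2": self.tau_beta2,
                "tau_alphabeta": self.tau_alphabeta,
                "sigma2": self.sigma2,
            },
            "loglike": self.loglike,
            "converged": self.converged,
            "notes": self.notes,
            "countries": {
                cid: {
                    "alpha": e.alpha,
                    "beta": e.beta,
                    "se_beta": e.se_beta,
                    "n_obs": e.n_obs,
                    "cvar_aa": e.cvar_aa,
                    "cvar_ab": e.cvar_ab,
                    "cvar_bb": e.cvar_bb,
                    "region": e.region,
                    "income_group": e.income_group,
                }
                for cid, e in sorted(self.effects.items())
            },
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "ModelFit":
        if d.get("schema_version") != SCHEMA_VERSION:
            raise ValueError(f"unsupported fit schema: {d.get('schema_version')}")
        effects = {
            cid: CountryEffect(
                alpha=e["alpha"],
                beta=e["beta"],
                se_beta=e["se_beta"],
                n_obs=e["n_obs"],
                cvar_aa=e.get("cvar_aa", 0.0),
                cvar_ab=e.get("cvar_ab", 0.0),
                cvar_bb=e.get("cvar_bb", 0.0),
                region=e.get("region"),
                income_group=e.get("income_group"),
            )
            for cid, e in d["countries"].items()
        }
        fx = d["fixed"]
        vc = d["variance_components"]
        return cls(
            model_id=d["model_id"],
            effects=effects,
            covariate_coefs=dict(fx["covariates"]),
            fixed_intercept=fx["intercept"],
            fixed_slope=fx["log_gdp"],
            fixed_slope_se=fx["log_gdp_se"],
            group_effect_coefs=dict(fx["group_effects"]),
            reference_levels=dict(fx["reference_levels"]),
            tau_alpha2=vc["tau_alpha2"],
            tau_beta2=vc["tau_beta2"],
            tau_alphabeta=vc["tau_alphabeta"],
            sigma2=vc["sigma2"],
            loglike=d.get("loglike", float("nan")),
            converged=d.get("converged", True),
            notes=list(d.get("notes", [])),
        )

    @classmethod
    def from_json(cls, path) -> "ModelFit":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


# -------------------------------------------------------------------- design
def build_design(panel: Panel, spec: ModelSpec) -> DesignMatrices:
    """Assemble log-transformed response and fixed-effect matrices.

    Rows with any missing required variable are dropped (and counted);
    countries left with fewer than :data:`MIN_ROWS_PER_COUNTRY` usable rows
    are excluded entirely.  Region and income-group dummies use the
    first-sorted level as reference.
    """
    df = panel.data.copy()
    required = ["u5mr", "gdp_pc"] + spec.covariates
    if spec.group_fixed_effects:
        if df["region"].isna().any() or df["income_group"].isna().any():
            bad = df.loc[
                df["region"].isna() | df["income_group"].isna(), "country_id"
            ].unique()
            raise DesignError(
                "region/income_group labels required for model 2; missing for: "
                + ", ".join(sorted(map(str, bad)))
            )

    nonpos = (df["u5mr"].notna() & (df["u5mr"] <= 0)) | (
        df["gdp_pc"].notna() & (df["gdp_pc"] <= 0)
    )
    if nonpos.any():
        row = df.loc[nonpos.idxmax()]
        raise DesignError(
            f"non-positive u5mr/gdp_pc at ({row['country_id']}, {row['year']})"
        )

    usable = df[required].notna().all(axis=1)
    n_dropped = int((~usable).sum())
    df = df[usable]

    counts = df.groupby("country_id").size()
    excluded = sorted(counts[counts < MIN_ROWS_PER_COUNTRY].index)
    if excluded:
        logger.warning(
            "excluding countries with < %d usable rows: %s",
            MIN_ROWS_PER_COUNTRY,
            ", ".join(excluded),
        )
        df = df[~df["country_id"].isin(excluded)]
    if df.empty:
        raise DesignError("no usable rows after filtering")

    df = df.sort_values(["country_id", "year"], kind="mergesort").reset_index(drop=True)
    y = np.log(df["u5mr"].to_numpy(dtype=float))
    log_gdp = np.log(df["gdp_pc"].to_numpy(dtype=float))

    X = pd.DataFrame({"intercept": np.ones(len(df)), "log_gdp": log_gdp})
    reference_levels: dict[str, str] = {}
    if spec.model_id == 2:
        for cov in spec.covariates:
            X[cov] = df[cov].to_numpy(dtype=float)
        for label in ("region", "income_group"):
            levels = sorted(df[label].dropna().unique())
            reference_levels[label] = levels[0] if levels else ""
            for lev in levels[1:]:
                X[f"{label}[{lev}]"] = (df[label] == lev).astype(float).to_numpy()

    return DesignMatrices(
        y=y,
        X=X,
        log_gdp=log_gdp,
        groups=df["country_id"].to_numpy(),
        row_index=df[["country_id", "year"]].copy(),
        n_dropped_missing=n_dropped,
        excluded_countries=excluded,
        reference_levels=reference_levels,
    )


# ----------------------------------------------------------------- fitting
def _collinear_columns(X: np.ndarray, tol: float = 1e-8) -> list[int]:
    """Indices of columns to drop so the remainder has full rank (greedy QR)."""
    drop: list[int] = []
    keep: list[int] = []
    for j in range(X.shape[1]):
        cand = X[:, keep + [j]]
        if np.linalg.matrix_rank(cand, tol=tol * max(1.0, np.abs(cand).max())) == len(keep) + 1:
            keep.append(j)
        else:
            drop.append(j)
    return drop


def _saturated_ols(design: DesignMatrices) -> tuple[dict, dict, float, np.ndarray]:
    """Fully interacted per-country OLS: country dummies and country slopes
    plus shared covariate columns.  Exact when residuals are zero."""
    groups = design.groups
    countries = sorted(set(groups))
    n = len(design.y)
    # group dummies are collinear with country dummies and are absorbed by them
    cov_cols = [
        c
        for c in design.X.columns
        if c not in ("intercept", "log_gdp")
        and not c.startswith(("region[", "income_group["))
    ]
    blocks = []
    for cid in countries:
        m = (groups == cid).astype(float)
        blocks.append(m)
        blocks.append(m * design.log_gdp)
    Xs = np.column_stack(blocks + [design.X[c].to_numpy() for c in cov_cols])
    coef, _, rank, _ = np.linalg.lstsq(Xs, design.y, rcond=None)
    resid = design.y - Xs @ coef
    dof = max(n - rank, 1)
    sigma2 = float(resid @ resid) / dof
    alphas = {cid: float(coef[2 * i]) for i, cid in enumerate(countries)}
    betas = {cid: float(coef[2 * i + 1]) for i, cid in enumerate(countries)}
    cov_coefs = {
        c: float(coef[2 * len(countries) + k]) for k, c in enumerate(cov_cols)
    }
    return alphas, betas, sigma2, cov_coefs


def fit(panel: Panel, spec: ModelSpec, correlated_re: bool = False) -> ModelFit:
    """Fit the elasticity model by REML and compose per-country slopes.

    ``correlated_re=True`` estimates a full 2×2 random-effects covariance;
    the default is independent intercept and slope components, which proved
    markedly better calibrated (the correlated structure tends to a unit
    intercept-slope correlation on panels like these, collapsing the
    conditional slope variance).  If the correlated structure hits that
    boundary it falls back to independent components automatically.
    """
    design = build_design(panel, spec)
    countries = sorted(set(design.groups))
    if len(countries) < 2:
        raise FitError("at least 2 countries are required")

    labels = panel.country_labels().set_index("country_id")
    n_obs = pd.Series(design.groups).value_counts().to_dict()

    alphas_sat, betas_sat, sigma2_sat, cov_coefs_sat = _saturated_ols(design)
    if sigma2_sat < _NOISE_FREE_TOL:
        # degenerate noise-free panel: the saturated OLS solution is exact and
        # shrinkage vanishes, so report it directly with zero uncertainty
        effects = {}
        for cid in countries:
            effects[cid] = CountryEffect(
                alpha=alphas_sat[cid],
                beta=betas_sat[cid],
                se_beta=0.0,
                n_obs=int(n_obs[cid]),
                region=labels.loc[cid, "region"] if cid in labels.index else None,
                income_group=labels.loc[cid, "income_group"] if cid in labels.index else None,
            )
        betas = np.array([betas_sat[c] for c in countries])
        alphs = np.array([alphas_sat[c] for c in countries])
        # group fixed effects are absorbed into the per-country alphas here,
        # so the composed alpha is authoritative and group coefs are empty
        return ModelFit(
            model_id=spec.model_id,
            effects=effects,
            covariate_coefs=cov_coefs_sat,
            fixed_intercept=float(alphs.mean()),
            fixed_slope=float(betas.mean()),
            fixed_slope_se=0.0,
            group_effect_coefs={},
            reference_levels=design.reference_levels,
            tau_alpha2=float(alphs.var()),
            tau_beta2=float(betas.var()),
            tau_alphabeta=float(np.cov(alphs, betas, bias=True)[0, 1]) if len(countries) > 1 else 0.0,
            sigma2=sigma2_sat,
            loglike=float("nan"),
            notes=["noise-free panel: exact saturated OLS solution"],
        )

    from statsmodels.regression.mixed_linear_model import MixedLM, MixedLMParams
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    exog = design.X.reset_index(drop=True)
    dropped_cols = _collinear_columns(exog.to_numpy(dtype=float))
    if dropped_cols:
        names = [exog.columns[i] for i in dropped_cols]
        exog = exog.drop(columns=names)
    exog_names = list(exog.columns)
    exog_re = pd.DataFrame(
        {"re_intercept": np.ones(len(design.y)), "re_log_gdp": design.log_gdp}
    )
    model = MixedLM(
        pd.Series(design.y, name="log_u5mr"),
        exog,
        groups=design.groups,
        exog_re=exog_re,
    )
    notes: list[str] = []
    if dropped_cols:
        names = [c for c in design.X.columns if c not in exog_names]
        notes.append("dropped collinear fixed-effect columns: " + ", ".join(names))
        logger.warning(notes[-1])
    free_diag = MixedLMParams.from_components(
        fe_params=np.ones(exog.shape[1]), cov_re=np.eye(2)
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        result = None
        if correlated_re:
            result = model.fit(reml=True)
            corr_ok = result.converged and np.all(np.isfinite(result.cov_re))
            if corr_ok:
                # boundary check: a near-unit intercept-slope correlation
                # collapses the conditional slope variance and wrecks interval
                # calibration; treat it as a boundary
                cre = np.asarray(result.cov_re)
                denom = np.sqrt(cre[0, 0] * cre[1, 1])
                corr_ok = denom == 0 or abs(cre[0, 1] / denom) < 0.95
            if not corr_ok:
                notes.append("correlated random effects hit boundary; refit independent")
                logger.warning(notes[-1])
                result = None
        if result is None:
            result = model.fit(free=free_diag, reml=True)
            if not result.converged:
                for method in ("lbfgs", "cg", "powell"):
                    result = model.fit(free=free_diag, reml=True, method=method)
                    if result.converged:
                        break
    if not result.converged:
        raise FitError("REML optimization failed to converge")

    fe = dict(zip(exog_names, np.asarray(result.fe_params, dtype=float)))
    slope_idx = exog_names.index("log_gdp")
    cov_re = np.asarray(result.cov_re, dtype=float)
    tau_beta2 = float(cov_re[1, 1])
    if tau_beta2 <= 1e-12:
        notes.append("random-slope variance collapsed to ~0; slopes shrink to the mean")
        logger.info(notes[-1])

    # pieces for the Kackar-Harville prediction-error variance of the
    # composed slope: var = u' A u + condvar, u = c - T_g' c_b, where A is the
    # fixed-effects covariance and T_g = G Z_g' V_g^-1 X_g links the BLUP to
    # the fixed-effect estimate
    p = exog.shape[1]
    A = np.asarray(result.cov_params(), dtype=float)[:p, :p]
    sigma2_hat = float(result.scale)
    exog_arr = exog.to_numpy(dtype=float)
    c_fixed = np.zeros(p)
    c_fixed[slope_idx] = 1.0
    c_blup = np.array([0.0, 1.0])

    effects: dict[str, CountryEffect] = {}
    for cid in countries:
        re = np.asarray(result.random_effects[cid], dtype=float)
        re_cov = np.asarray(result.random_effects_cov[cid], dtype=float)
        beta = float(fe["log_gdp"] + re[1])
        mask = design.groups == cid
        Xg = exog_arr[mask]
        Zg = np.column_stack([np.ones(mask.sum()), design.log_gdp[mask]])
        Vg = Zg @ cov_re @ Zg.T + sigma2_hat * np.eye(int(mask.sum()))
        Tg = cov_re @ Zg.T @ np.linalg.solve(Vg, Xg)
        u = c_fixed - Tg.T @ c_blup
        se = float(np.sqrt(max(u @ A @ u + max(re_cov[1, 1], 0.0), 0.0)))
        alpha = float(fe["intercept"] + re[0])
        reg = inc = None
        if cid in labels.index:
            reg = labels.loc[cid, "region"]
            inc = labels.loc[cid, "income_group"]
        if spec.group_fixed_effects:
            for label, val in (("region", reg), ("income_group", inc)):
                key = f"{label}[{val}]"
                if key in fe:
                    alpha += float(fe[key])
        effects[cid] = CountryEffect(
            alpha=alpha,
            beta=beta,
            se_beta=se,
            n_obs=int(n_obs[cid]),
            cvar_aa=float(max(re_cov[0, 0], 0.0)),
            cvar_ab=float(re_cov[0, 1]),
            cvar_bb=float(max(re_cov[1, 1], 0.0)),
            region=reg,
            income_group=inc,
        )

    covariate_coefs = {
        c: float(fe[c]) for c in exog_names if c in spec.covariates
    }
    group_effect_coefs = {
        c: float(fe[c])
        for c in exog_names
        if c.startswith(("region[", "income_group["))
    }
    return ModelFit(
        model_id=spec.model_id,
        effects=effects,
        covariate_coefs=covariate_coefs,
        fixed_intercept=float(fe["intercept"]),
        fixed_slope=float(fe["log_gdp"]),
        fixed_slope_se=float(np.asarray(result.bse_fe)[slope_idx]),
        group_effect_coefs=group_effect_coefs,
        reference_levels=design.reference_levels,
        tau_alpha2=float(cov_re[0, 0]),
        tau_beta2=tau_beta2,
        tau_alphabeta=float(cov_re[0, 1]),
        sigma2=float(result.scale),
        loglike=float(result.llf),
        converged=bool(result.converged),
        notes=notes,
    )


def country_slope(fit_result: ModelFit, country_id: str) -> tuple[float, float]:
    """Module-level convenience wrapper around :meth:`ModelFit.country_slope`."""
    return fit_result.country_slope(country_id)
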