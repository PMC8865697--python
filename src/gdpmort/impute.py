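"""Missing-data completion for country panels.

Two imputers:

* GDP per capita — trailing five-year moving average, filled left-to-right so
  that later fills may use earlier imputed values; leading gaps (no
  predecessors) are back-filled from the mean of the earliest ``window``
  available values.
* Covariates — an iterative chained linear-Gaussian scheme: missing cells are
  initialized at the variable mean, then each incomplete variable is
  regressed on the other covariates plus log GDP and year, and missing cells
  are replaced by conditional-mean predictions until the largest absolute
  change (on a standardized scale) drops below tolerance.  A ``stochastic``
  switch adds residual-scale Gaussian noise to the fills.

Observed cells are never altered by either imputer.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ImputationError
from .panel import H_COVARIATES, Panel, Z_COVARIATES

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 5
DEFAULT_MAX_ITER = 50
DEFAULT_TOL = 1e-6


@dataclass
class ImputationReport:
    """Bookkeeping for one imputation run."""

    imputed_counts: dict[str, int] = field(default_factory=dict)
    iterations: int = 0
    max_abs_change: float = 0.0
    converged: bool = True
    seed: Optional[int] = None
    warnings: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "imputed_counts": self.imputed_counts,
                "iterations": self.iterations,
                "max_abs_change": self.max_abs_change,
                "converged": self.converged,
                "seed": self.seed,
                "warnings": self.warnings,
            },
            indent=2,
        )


def moving_average_fill(values: Sequence[float], window: int = DEFAULT_WINDOW) -> np.ndarray:
    """Fill missing entries of a year-ordered series with trailing means.

    Each missing value is replaced by the mean of the ``window`` most recent
    preceding non-missing values (original or previously imputed), proceeding
    left to right.  Leading missing values, which have no predecessors, are
    back-filled with the mean of the earliest ``window`` values available
    after the forward pass.
    """
    x = np.asarray(values, dtype=float).copy()
    if np.all(np.isnan(x)):
        raise ImputationError("series is entirely missing")
    obs_idx = np.flatnonzero(~np.isnan(x))
    first = obs_idx[0]
    for i in range(first + 1, len(x)):
        if np.isnan(x[i]):
            pred = x[first:i]
            pred = pred[~np.isnan(pred)]
            x[i] = pred[-window:].mean()
    if first > 0:
        head = x[first : first + window]
        x[:first] = head.mean()
    return x


def impute_gdp_moving_average(
    panel: Panel, window: int = DEFAULT_WINDOW
) -> tuple[Panel, ImputationReport]:
    """Complete ``gdp_pc`` per country with the trailing moving average."""
    df = panel.data.copy()
    report = ImputationReport()
    n_filled = 0
    for cid, grp in df.groupby("country_id", sort=True):
        series = grp.sort_values("year")["gdp_pc"]
        if series.isna().all():
            raise ImputationError(f"gdp_pc entirely missing for {cid}")
        if series.isna().any():
            filled = moving_average_fill(series.to_numpy(), window=window)
            n_filled += int(series.isna().sum())
            df.loc[series.index, "gdp_pc"] = filled
    report.imputed_counts["gdp_pc"] = n_filled
    return Panel(df), report


def impute_covariates_mvn(
    panel: Panel,
    variables: Optional[Sequence[str]] = None,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
    seed: Optional[int] = None,
    stochastic: bool = False,
) -> tuple[Panel, ImputationReport]:
    """Iteratively impute covariates by multivariate-normal regression.

    Requires ``gdp_pc`` to be complete (run the moving-average imputer first).
    Deterministic by default; with ``stochastic=True``, fills receive
    Gaussian noise at the residual scale drawn from ``seed``.
    """
    if variables is None:
        variables = Z_COVARIATES + H_COVARIATES
    variables = list(variables)
    df = panel.data.copy()
    if df["gdp_pc"].isna().any():
        raise ImputationError("gdp_pc must be complete before covariate imputation")
    report = ImputationReport(seed=seed)
    rng = np.random.default_rng(seed)

    obs_masks = {v: df[v].notna().to_numpy() for v in variables}
    for v in variables:
        frac = obs_masks[v].mean()
        if frac < 0.30:
            raise ImputationError(
                f"{v} has only {frac:.0%} observed cells (< 30% required)"
            )
    incomplete = [v for v in variables if not obs_masks[v].all()]
    report.imputed_counts = {v: int((~obs_masks[v]).sum()) for v in variables}
    if not incomplete:
        return panel, report

    work = df[variables].to_numpy(dtype=float)
    col_of = {v: i for i, v in enumerate(variables)}
    # scale for the convergence criterion: observed-cell SD, floor at 1
    scales = np.array(
        [max(np.nanstd(df[v].to_numpy(dtype=float)), 1e-12) for v in variables]
    )
    # mean initialization
    for v in incomplete:
        j = col_of[v]
        work[~obs_masks[v], j] = np.nanmean(work[obs_masks[v], j])

    log_gdp = np.log(df["gdp_pc"].to_numpy(dtype=float))
    year = df["year"].to_numpy(dtype=float)
    year_c = year - year.mean()

    last_change = np.inf
    for it in range(1, max_iter + 1):
        change = 0.0
        for v in incomplete:
            j = col_of[v]
            others = [col_of[u] for u in variables if u != v]
            X = np.column_stack(
                [np.ones(len(work)), work[:, others], log_gdp, year_c]
            )
            obs = obs_masks[v]
            coef, _, rank, _ = np.linalg.lstsq(X[obs], work[obs, j], rcond=None)
            if rank < X.shape[1]:
                msg = f"singular design for {v}; rank-deficient least squares used"
                if msg not in report.warnings:
                    report.warnings.append(msg)
                    logger.warning(msg)
            pred = X[~obs] @ coef
            if stochastic:
                resid = work[obs, j] - X[obs] @ coef
                sigma = resid.std(ddof=min(len(resid) - 1, X.shape[1]))
                pred = pred + rng.normal(0.0, sigma, size=pred.shape)
            delta = np.abs(pred - work[~obs, j]) / scales[j]
            if delta.size:
                change = max(change, float(delta.max()))
            work[~obs, j] = pred
        report.iterations = it
        report.max_abs_change = change
        if change < tol:
            break
        last_change = change
    else:
        report.converged = False
        report.warnings.append(
            f"covariate imputation did not converge in {max_iter} iterations "
            f"(last max change {report.max_abs_change:.3e})"
        )
        logger.warning(report.warnings[-1])

    for v in variables:
        df[v] = work[:, col_of[v]]
    # percentage covariates are clipped into their legal range
    for v in ("women_parliament_pct", "dpt_coverage_pct"):
        if v in variables:
            df[v] = df[v].clip(0.0, 100.0)
    return Panel(df), report
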