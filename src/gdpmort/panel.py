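"""Country-year panel container, CSV I/O, validation, and the LMIC income filter.

The canonical on-disk layout is *long*: one row per (country, year) with one
column per variable.  A *wide* layout (one column per year, rows keyed by
country and variable name) is accepted on read only, because that is how WDI
extracts usually ship.  Missing numeric cells are empty strings or the literal
``NA`` on disk and ``NaN`` in memory — never 0, since 0 is a legal value for
several covariates.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import numpy as np
import pandas as pd

from .errors import ClassificationError, PanelFormatError, PanelValidationError

#: covariates entering the extended model as socio-economic controls (Z)
Z_COVARIATES = ["electric_power_kwh_pc", "women_parliament_pct", "total_fertility"]
#: covariates entering the extended model as health-service controls (H)
H_COVARIATES = ["physicians_per_1000", "dpt_coverage_pct"]

NUMERIC_COLUMNS = [
    "u5mr",
    "gdp_pc",
    *Z_COVARIATES,
    *H_COVARIATES,
    "under5_pop",
    "gni_pc",
]
LABEL_COLUMNS = ["region", "income_group"]
KEY_COLUMNS = ["country_id", "year"]
ALL_COLUMNS = KEY_COLUMNS + NUMERIC_COLUMNS + LABEL_COLUMNS

#: income-group labels that qualify as LMIC
LMIC_LABELS = {"low", "lower-middle", "upper-middle"}
#: default GNI-per-capita cutoff (current US$) for LMIC classification
GNI_THRESHOLD = 12375.0

# columns where a [0, 100] percentage bound applies
_PERCENT_COLUMNS = ["dpt_coverage_pct", "women_parliament_pct"]
_POSITIVE_COLUMNS = ["u5mr", "gdp_pc"]


@dataclass(frozen=True)
class CountryYearRecord:
    """A single country-year observation.  ``None`` marks a missing value."""

    country_id: str
    year: int
    u5mr: Optional[float] = None
    gdp_pc: Optional[float] = None
    electric_power_kwh_pc: Optional[float] = None
    women_parliament_pct: Optional[float] = None
    total_fertility: Optional[float] = None
    physicians_per_1000: Optional[float] = None
    dpt_coverage_pct: Optional[float] = None
    under5_pop: Optional[float] = None
    gni_pc: Optional[float] = None
    region: Optional[str] = None
    income_group: Optional[str] = None


class Panel:
    """Validated collection of country-year records.

    Wraps a long-format :class:`pandas.DataFrame` sorted by (country_id, year)
    with ``NaN`` missing markers.  At most one record per (country, year).
    """

    def __init__(self, data: pd.DataFrame) -> None:
        df = data.copy()
        for col in ALL_COLUMNS:
            if col not in df.columns:
                df[col] = np.nan
        df = df[ALL_COLUMNS]
        df["country_id"] = df["country_id"].astype(str)
        df["year"] = df["year"].astype(int)
        for col in NUMERIC_COLUMNS:
            df[col] = pd.to_numeric(df[col], errors="coerce").astype(float)
        dup = df.duplicated(subset=KEY_COLUMNS)
        if dup.any():
            key = tuple(df.loc[dup.idxmax(), KEY_COLUMNS])
            raise PanelValidationError(f"duplicate (country, year) key: {key}")
        self._validate_ranges(df)
        self._df = df.sort_values(KEY_COLUMNS, kind="mergesort").reset_index(drop=True)

    @staticmethod
    def _validate_ranges(df: pd.DataFrame) -> None:
        for col in _POSITIVE_COLUMNS:
            bad = df[col] <= 0
            if bad.any():
                key = tuple(df.loc[bad.idxmax(), KEY_COLUMNS])
                raise PanelValidationError(f"non-positive {col} at {key}")
        for col in _PERCENT_COLUMNS:
            bad = (df[col] < 0) | (df[col] > 100)
            if bad.any():
                key = tuple(df.loc[bad.idxmax(), KEY_COLUMNS])
                raise PanelValidationError(f"{col} outside [0, 100] at {key}")
        bad = df["under5_pop"] < 0
        if bad.any():
            key = tuple(df.loc[bad.idxmax(), KEY_COLUMNS])
            raise PanelValidationError(f"negative under5_pop at {key}")

    # ------------------------------------------------------------------ views
    @property
    def data(self) -> pd.DataFrame:
        """The underlying long DataFrame (copy-on-write discipline: do not mutate)."""
        return self._df

    @property
    def countries(self) -> list[str]:
        return sorted(self._df["country_id"].unique())

    @property
    def year_range(self) -> tuple[int, int]:
        return int(self._df["year"].min()), int(self._df["year"].max())

    @property
    def n_records(self) -> int:
        return len(self._df)

    def country_labels(self) -> pd.DataFrame:
        """One row per country with its region / income_group / gni_pc.

        Labels are taken from the first non-missing value per country; gni_pc
        from the most recent non-missing classification value.
        """
        rows = []
        for cid, grp in self._df.groupby("country_id", sort=True):
            region = grp["region"].dropna()
            income = grp["income_group"].dropna()
            gni = grp.loc[grp["gni_pc"].notna()]
            rows.append(
                {
                    "country_id": cid,
                    "region": region.iloc[0] if len(region) else None,
                    "income_group": income.iloc[0] if len(income) else None,
                    "gni_pc": float(gni["gni_pc"].iloc[-1]) if len(gni) else np.nan,
                }
            )
        return pd.DataFrame(rows)

    def record(self, country_id: str, year: int) -> CountryYearRecord:
        sel = self._df[
            (self._df["country_id"] == country_id) & (self._df["year"] == year)
        ]
        if sel.empty:
            raise KeyError((country_id, year))
        row = sel.iloc[0]

        def _get(col):
            v = row[col]
            if isinstance(v, float) and math.isnan(v):
                return None
            if v is None or (isinstance(v, float) and pd.isna(v)):
                return None
            return v

        return CountryYearRecord(
            country_id=country_id,
            year=int(year),
            **{c: _get(c) for c in NUMERIC_COLUMNS},
            region=_get("region"),
            income_group=_get("income_group"),
        )

    def __iter__(self) -> Iterator[CountryYearRecord]:
        for _, row in self._df.iterrows():
            yield self.record(row["country_id"], int(row["year"]))

    def __len__(self) -> int:
        return len(self._df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Panel):
            return NotImplemented
        return self._df.equals(other._df)

    def with_data(self, df: pd.DataFrame) -> "Panel":
        return Panel(df)


# ---------------------------------------------------------------------- I/O
def load_panel(path, layout: str = "long") -> Panel:
    """Read a panel CSV.

    Parameters
    ----------
    path:
        CSV file path (UTF-8, comma-separated, header required).
    layout:
        ``"long"`` — columns ``country_id, year, <variables...>``;
        ``"wide"`` — columns ``country_id, variable, <year>, <year>, ...``.
    """
    if layout not in ("long", "wide"):
        raise ValueError(f"unknown layout {layout!r}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df.columns = [c.strip() for c in df.columns]
    if layout == "wide":
        df = _wide_to_long(df)
    missing_cols = [c for c in KEY_COLUMNS if c not in df.columns]
    if missing_cols:
        raise PanelFormatError(f"missing required column(s): {', '.join(missing_cols)}")
    unknown = [
        c for c in df.columns if c not in ALL_COLUMNS and not c.startswith("_")
    ]
    if unknown:
        raise PanelFormatError(f"unrecognized column(s): {', '.join(unknown)}")

    out = {}
    out["country_id"] = df["country_id"].str.strip()
    years = pd.to_numeric(df["year"].str.strip(), errors="coerce")
    keep = out["country_id"].ne("") & years.notna()
    out["year"] = years
    for col in NUMERIC_COLUMNS:
        if col in df.columns:
            raw = df[col].str.strip().replace({"": np.nan, "NA": np.nan})
            out[col] = pd.to_numeric(raw, errors="coerce")
    for col in LABEL_COLUMNS:
        if col in df.columns:
            out[col] = df[col].str.strip().replace({"": None, "NA": None})
    frame = pd.DataFrame(out)[keep.values]
    frame["year"] = frame["year"].astype(int)
    return Panel(frame)


def _wide_to_long(df: pd.DataFrame) -> pd.DataFrame:
    for col in ("country_id", "variable"):
        if col not in df.columns:
            raise PanelFormatError(f"wide layout requires column {col!r}")
    year_cols = [c for c in df.columns if c.isdigit()]
    if not year_cols:
        raise PanelFormatError("wide layout has no year columns")
    label_vars = set(LABEL_COLUMNS)
    melted = df.melt(
        id_vars=["country_id", "variable"],
        value_vars=year_cols,
        var_name="year",
        value_name="value",
    )
    bad = ~melted["variable"].isin(NUMERIC_COLUMNS + LABEL_COLUMNS)
    if bad.any():
        raise PanelFormatError(
            f"unrecognized variable(s): {sorted(melted.loc[bad, 'variable'].unique())}"
        )
    long = melted.pivot_table(
        index=["country_id", "year"],
        columns="variable",
        values="value",
        aggfunc="first",
    ).reset_index()
    long.columns.name = None
    # label variables survive the pivot as object columns; numeric parsing is
    # deferred to Panel construction
    for col in long.columns:
        if col in label_vars:
            long[col] = long[col].replace({"": None, "NA": None})
        elif col not in ("country_id", "year"):
            long[col] = long[col].replace({"": np.nan, "NA": np.nan})
    return long


def write_panel(panel: Panel, path) -> None:
    """Write a panel in canonical long CSV with empty-cell missing markers."""
    df = panel.data.copy()
    df.to_csv(path, index=False, na_rep="", float_format="%.12g")


# ------------------------------------------------------------------- filters
def filter_lmic(panel: Panel, gni_threshold: float = GNI_THRESHOLD) -> Panel:
    """Retain countries classified as low / lower-middle / upper-middle income.

    A country is retained when its classification GNI per capita is strictly
    below ``gni_threshold``; when no GNI value is present, a recognized LMIC
    ``income_group`` label is authoritative.  Countries with neither raise
    :class:`ClassificationError`.
    """
    labels = panel.country_labels()
    keep: list[str] = []
    unclassifiable: list[str] = []
    for _, row in labels.iterrows():
        gni = row["gni_pc"]
        if not pd.isna(gni):
            if float(gni) < gni_threshold:
                keep.append(row["country_id"])
        elif row["income_group"] is not None:
            if str(row["income_group"]) in LMIC_LABELS:
                keep.append(row["country_id"])
        else:
            unclassifiable.append(row["country_id"])
    if unclassifiable:
        raise ClassificationError(
            "countries without gni_pc or income_group: " + ", ".join(unclassifiable)
        )
    df = panel.data[panel.data["country_id"].isin(keep)]
    return Panel(df)


# ------------------------------------------------------------------ summary
def panel_summary(panel: Panel, years: Iterable[int]) -> pd.DataFrame:
    """Per-variable, per-year mean, SD, and percent-missing table.

    Missing share is ``100 * n_missing / n_countries`` where the denominator
    is the number of countries in the panel (a country with no record at all
    for a year counts as missing).
    """
    lo, hi = panel.year_range
    years = list(years)
    for y in years:
        if y < lo or y > hi:
            raise ValueError(f"year {y} outside panel range [{lo}, {hi}]")
    n_countries = len(panel.countries)
    rows = []
    df = panel.data
    for year in years:
        sub = df[df["year"] == year]
        for var in NUMERIC_COLUMNS:
            vals = sub[var].dropna()
            n_missing = n_countries - len(vals)
            rows.append(
                {
                    "variable": var,
                    "year": year,
                    "mean": float(vals.mean()) if len(vals) else np.nan,
                    "sd": float(vals.std(ddof=1)) if len(vals) > 1 else (0.0 if len(vals) == 1 else np.nan),
                    "missing_pct": 100.0 * n_missing / n_countries,
                }
            )
    return pd.DataFrame(rows)
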