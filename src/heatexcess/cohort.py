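"""Data model, file I/O, validation and covariate encoding for case/control pools.

A *case pool* holds every adult death that occurred during the extreme
hot-weather event window; a *control pool* holds deaths from a comparison
period of typical summer weather.  Each decedent record carries the five
covariates the framework analyses: age (dichotomised at 75 years), location
of death (four categories, hospital as reference), neighbourhood deprivation
quintile, neighbourhood population-density quintile, and residential
greenness (NDVI, a continuous index in [-1, 1]).
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LOCATION_CATEGORIES = ("hospital", "residential_institution", "home", "other")
#: Reference category for the location-of-death factor.
LOCATION_REFERENCE = "hospital"

#: The five analysis variables, by the names used throughout the package.
VARIABLES = ("age", "location", "deprivation", "density", "ndvi")

#: Design-matrix columns contributed by each variable.  Location of death
#: expands to three indicators against the hospital reference.
VARIABLE_COLUMNS = {
    "age": ("age_lt75",),
    "location": ("loc_residential_institution", "loc_home", "loc_other"),
    "deprivation": ("deprivation",),
    "density": ("density_q",),
    "ndvi": ("ndvi",),
}

REQUIRED_COLUMNS = (
    "record_id",
    "death_date",
    "age_years",
    "location_of_death",
    "deprivation_quintile",
    "ndvi",
)


class SchemaError(ValueError):
    """A pool file is missing a required column."""


class ValidationError(ValueError):
    """One or more records violate a field constraint."""


@dataclass
class DeathRecord:
    """One decedent with the five analysis covariates.

    ``population_density`` (persons/km^2) may be given instead of
    ``density_quintile``; quintiles are then derived over the pooled
    case+control densities (see :func:`quintile_bin`).
    """

    record_id: str
    group: str  # "case" or "control"
    death_date: _dt.date
    age_years: int
    location_of_death: str
    deprivation_quintile: int
    ndvi: float
    population_density: float | None = None
    density_quintile: int | None = None
    sex: str | None = None  # read if present, never analysed


@dataclass
class Cohort:
    """Validated case and control pools plus the event window.

    ``event_dates`` is the ordered, closed interval of calendar dates
    defining the hot-weather event.  Every case death date must fall inside
    it and every control death date outside it.
    """

    cases: pd.DataFrame
    controls: pd.DataFrame
    event_dates: list[_dt.date]
    provenance: str = ""

    def __post_init__(self) -> None:
        self.validate()

    @property
    def n_cases(self) -> int:
        return len(self.cases)

    @property
    def n_controls(self) -> int:
        return len(self.controls)

    def validate(self) -> None:
        if len(self.cases) == 0 or len(self.controls) == 0:
            raise ValidationError("case and control pools must be non-empty")
        ids = pd.concat([self.cases["record_id"], self.controls["record_id"]])
        if ids.duplicated().any():
            dupes = ids[ids.duplicated()].unique()[:5]
            raise ValidationError(f"record_id not unique across pools: {list(dupes)}")
        event = set(self.event_dates)
        bad_case = ~self.cases["death_date"].isin(event)
        if bad_case.any():
            raise ValidationError(
                "case death dates outside the event window: "
                f"{list(self.cases.loc[bad_case, 'record_id'].head())}"
            )
        bad_ctrl = self.controls["death_date"].isin(event)
        if bad_ctrl.any():
            raise ValidationError(
                "control death dates inside the event window: "
                f"{list(self.controls.loc[bad_ctrl, 'record_id'].head())}"
            )


def _parse_dates(series: pd.Series) -> pd.Series:
    parsed = pd.to_datetime(series, format="%Y-%m-%d", errors="coerce")
    return parsed.dt.date


def read_pool(path, group: str) -> pd.DataFrame:
    """Read and validate one pool CSV.

    Parameters
    ----------
    path : str or file-like
        Delimited text file with a header row.  Column order is free; the
        required columns are ``record_id, death_date, age_years,
        location_of_death, deprivation_quintile, ndvi`` plus either
        ``population_density`` or ``density_quintile`` (or both).
    group : {"case", "control"}
        Pool membership recorded on every returned row.

    Returns
    -------
    pandas.DataFrame
        Validated records with a ``group`` column.  Rows with any missing
        analysis variable are dropped with a logged count; rows with
        out-of-range values raise :class:`ValidationError` naming the
        offending record ids.
    """
    if group not in ("case", "control"):
        raise ValueError(f"group must be 'case' or 'control', got {group!r}")
    df = pd.read_csv(path, dtype={"record_id": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"pool file missing required column(s): {missing}")
    if "population_density" not in df.columns and "density_quintile" not in df.columns:
        raise SchemaError(
            "pool file must provide population_density or density_quintile"
        )

    df = df.copy()
    date_given = df["death_date"].notna()
    df["death_date"] = _parse_dates(df["death_date"])
    unparseable = date_given & df["death_date"].isna()
    if unparseable.any():
        ids = list(df.loc[unparseable, "record_id"].head(10))
        raise ValidationError(
            f"unparseable death_date (expect YYYY-MM-DD): {ids}")

    analysis_cols = [c for c in df.columns if c in REQUIRED_COLUMNS] + [
        c for c in ("population_density", "density_quintile") if c in df.columns
    ]
    incomplete = df[analysis_cols].isna().any(axis=1)
    if "population_density" in df.columns and "density_quintile" in df.columns:
        # either density field satisfies the requirement
        incomplete = df[[c for c in analysis_cols
                         if c not in ("population_density", "density_quintile")]].isna().any(axis=1)
        incomplete |= df["population_density"].isna() & df["density_quintile"].isna()
    if incomplete.any():
        logger.warning(
            "dropping %d record(s) with missing analysis variables from %s pool",
            int(incomplete.sum()), group,
        )
        df = df.loc[~incomplete].reset_index(drop=True)

    problems: list[str] = []

    def _check(mask: pd.Series, message: str) -> None:
        if mask.any():
            ids = list(df.loc[mask, "record_id"].head(10))
            problems.append(f"{message}: {ids}")

    _check(df["record_id"].duplicated(), "duplicate record_id")
    _check(df["age_years"] < 0, "negative age_years")
    _check(~df["location_of_death"].isin(LOCATION_CATEGORIES),
           f"location_of_death outside {LOCATION_CATEGORIES}")
    _check(~df["deprivation_quintile"].isin([1, 2, 3, 4, 5]),
           "deprivation_quintile outside 1-5")
    _check((df["ndvi"] < -1.0) | (df["ndvi"] > 1.0), "ndvi outside [-1, 1]")
    if "density_quintile" in df.columns:
        present = df["density_quintile"].notna()
        _check(present & ~df["density_quintile"].isin([1, 2, 3, 4, 5]),
               "density_quintile outside 1-5")
    if "population_density" in df.columns:
        present = df["population_density"].notna()
        _check(present & (df["population_density"] < 0), "negative population_density")
    if problems:
        raise ValidationError("; ".join(problems))

    df["group"] = group
    df["age_years"] = df["age_years"].astype(int)
    df["deprivation_quintile"] = df["deprivation_quintile"].astype(int)
    return df.reset_index(drop=True)


def write_pool(df: pd.DataFrame, path) -> None:
    """Write a pool back to CSV; round-trips all analysis fields exactly."""
    out = df.drop(columns=["group"], errors="ignore")
    out.to_csv(path, index=False)


def quintile_bin(values: Sequence[float]) -> np.ndarray:
    """Assign sample quintile bins 1-5 to a vector of values.

    Bin ``k`` contains the values lying between the (k-1)/5 and k/5 sample
    quantiles.  The assignment is monotone, and a value falling exactly on a
    boundary quantile goes to the lower bin, so completely tied input ends
    up entirely in bin 1.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size < 5:
        raise ValueError("quintile_bin requires at least 5 one-dimensional values")
    if np.isnan(arr).any():
        raise ValueError("quintile_bin does not accept missing values")
    bounds = np.quantile(arr, [0.2, 0.4, 0.6, 0.8])
    # strict comparison sends boundary ties to the lower bin
    return (arr[:, None] > bounds[None, :]).sum(axis=1).astype(int) + 1


def assign_bins(values: Sequence[float], upper_bounds: Sequence[float]) -> np.ndarray:
    """Assign bins from explicit upper boundaries (ties go to the lower bin).

    ``upper_bounds`` are the inclusive upper edges of bins 1..k-1; values
    above the last edge fall into bin k.  Useful for applying published
    quintile boundaries to new values.
    """
    edges = np.asarray(upper_bounds, dtype=float)
    return np.searchsorted(edges, np.asarray(values, dtype=float), side="left") + 1


def ensure_density_quintile(cases: pd.DataFrame, controls: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fill ``density_quintile`` from raw density where absent.

    Quintiles are computed once over the pooled case+control densities, so a
    decedent's bin is a fixed attribute of their neighbourhood rather than a
    per-resample quantity.
    """
    need_cases = "density_quintile" not in cases.columns or cases["density_quintile"].isna().any()
    need_ctrls = "density_quintile" not in controls.columns or controls["density_quintile"].isna().any()
    if not (need_cases or need_ctrls):
        cases = cases.copy()
        controls = controls.copy()
        cases["density_quintile"] = cases["density_quintile"].astype(int)
        controls["density_quintile"] = controls["density_quintile"].astype(int)
        return cases, controls
    for df in (cases, controls):
        if "population_density" not in df.columns:
            raise SchemaError(
                "population_density required to derive missing density quintiles"
            )
    pooled = np.concatenate([
        cases["population_density"].to_numpy(float),
        controls["population_density"].to_numpy(float),
    ])
    bins = quintile_bin(pooled)
    cases = cases.copy()
    controls = controls.copy()
    cases["density_quintile"] = bins[: len(cases)]
    controls["density_quintile"] = bins[len(cases):]
    return cases, controls


def encode_design(records: pd.DataFrame, variables: Iterable[str] = VARIABLES) -> pd.DataFrame:
    """Encode decedent records into the logistic-regression design table.

    One row per record, in input order.  Age is dichotomised at 75 years
    (``age_lt75 = 1`` iff age < 75); location of death becomes three
    indicators with hospital as the reference; deprivation and density
    quintiles enter as 1-5 integers treated as continuous; NDVI enters as
    is.  ``outcome`` is 1 for cases, 0 for controls.
    """
    variables = list(variables)
    if not variables:
        raise ValueError("at least one analysis variable must be requested")
    unknown = [v for v in variables if v not in VARIABLES]
    if unknown:
        raise ValueError(f"unknown variable(s) {unknown}; choose from {VARIABLES}")

    out = pd.DataFrame(index=records.index)
    for var in variables:
        if var == "age":
            out["age_lt75"] = (records["age_years"] < 75).astype(int)
        elif var == "location":
            loc = records["location_of_death"]
            bad = ~loc.isin(LOCATION_CATEGORIES)
            if bad.any():
                raise ValueError(f"invalid location_of_death values: {loc[bad].unique()}")
            for cat in LOCATION_CATEGORIES[1:]:
                out[f"loc_{cat}"] = (loc == cat).astype(int)
        elif var == "deprivation":
            out["deprivation"] = records["deprivation_quintile"].astype(int)
        elif var == "density":
            if "density_quintile" not in records.columns or records["density_quintile"].isna().any():
                raise ValueError(
                    "density_quintile absent; derive it first (ensure_density_quintile)"
                )
            out["density_q"] = records["density_quintile"].astype(int)
        elif var == "ndvi":
            out["ndvi"] = records["ndvi"].astype(float)
    out["outcome"] = (records["group"] == "case").astype(int)
    return out.reset_index(drop=True)


def build_cohort(cases: pd.DataFrame, controls: pd.DataFrame,
                 event_dates: Sequence[_dt.date], provenance: str = "") -> Cohort:
    """Assemble a validated :class:`Cohort`, deriving density quintiles if needed."""
    cases, controls = ensure_density_quintile(cases, controls)
    return Cohort(cases=cases, controls=controls,
                  event_dates=list(event_dates), provenance=provenance)
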