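"""Synthetic case/control pools with known excess/expected ground truth.

The generator emulates the statistical structure the classification
framework assumes: *expected* deaths during the event are exchangeable with
control-period deaths on the five analysis covariates, while *excess*
deaths are drawn from covariate distributions perturbed towards the profile
of heat-vulnerable decedents (younger, dying at home, deprived, densely
populated, less green neighbourhoods) and towards the hotter days of the
event.  Because every generated case carries a ground-truth label, the full
pipeline — resampling, tallying, ranking, classification — can be scored
against a known answer, which the observational study design itself can
never provide.

Covariates are generated independently per record: the generator is
parameterised by marginal distributions only, with no within-person
correlation structure.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort, LOCATION_CATEGORIES, build_cohort

#: Ground truth is a mapping record_id -> "excess" | "expected" over cases.
GroundTruth = pd.Series

_PROB_TOL = 1e-9


class ParameterError(ValueError):
    """A scenario parameter is invalid (e.g. probabilities do not sum to 1)."""


@dataclass
class Marginals:
    """Marginal covariate distributions for one sub-population.

    ``p_location``, ``p_deprivation`` and ``p_density`` are category
    probability vectors (locations ordered as
    hospital/residential_institution/home/other; quintiles ordered 1..5).
    NDVI is drawn from a normal distribution truncated to [-1, 1].
    """

    p_age_lt75: float
    p_location: np.ndarray
    p_deprivation: np.ndarray
    p_density: np.ndarray
    ndvi_mean: float
    ndvi_sd: float

    def __post_init__(self) -> None:
        self.p_location = np.asarray(self.p_location, dtype=float)
        self.p_deprivation = np.asarray(self.p_deprivation, dtype=float)
        self.p_density = np.asarray(self.p_density, dtype=float)
        if not 0.0 <= self.p_age_lt75 <= 1.0:
            raise ParameterError("p_age_lt75 must lie in [0, 1]")
        for name, vec, k in (
            ("p_location", self.p_location, 4),
            ("p_deprivation", self.p_deprivation, 5),
            ("p_density", self.p_density, 5),
        ):
            if vec.shape != (k,):
                raise ParameterError(f"{name} must have length {k}")
            if (vec < 0).any() or abs(vec.sum() - 1.0) > _PROB_TOL:
                raise ParameterError(f"{name} must be a probability vector summing to 1")
        if self.ndvi_sd <= 0:
            raise ParameterError("ndvi_sd must be positive")


@dataclass
class ExcessShift:
    """Per-variable perturbation applied to excess-death covariates.

    Categorical variables shift on the log-odds scale: category ``k`` of a
    probability vector ``p`` becomes ``p_k * exp(d_k)``, renormalised
    (softmax), so a shift of ``-inf`` empties a category and the all-zero
    shift is the identity.  NDVI shifts additively in the mean.
    """

    d_age: float = 0.0  # log-odds shift on P(age < 75)
    d_location: np.ndarray = field(default_factory=lambda: np.zeros(4))
    d_deprivation: np.ndarray = field(default_factory=lambda: np.zeros(5))
    d_density: np.ndarray = field(default_factory=lambda: np.zeros(5))
    d_ndvi: float = 0.0

    def __post_init__(self) -> None:
        self.d_location = np.asarray(self.d_location, dtype=float)
        self.d_deprivation = np.asarray(self.d_deprivation, dtype=float)
        self.d_density = np.asarray(self.d_density, dtype=float)

    def is_null(self) -> bool:
        return (
            self.d_age == 0.0 and self.d_ndvi == 0.0
            and not self.d_location.any() and not self.d_deprivation.any()
            and not self.d_density.any()
        )


def shift_category_probs(p: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Apply a log-odds shift to a category probability vector."""
    with np.errstate(under="ignore"):
        w = np.asarray(p, float) * np.exp(np.asarray(d, float))
    total = w.sum()
    if not np.isfinite(total) or total <= 0:
        raise ParameterError("shift empties or overflows the probability vector")
    return w / total


def shift_to_match(control_p: np.ndarray, target_p: np.ndarray) -> np.ndarray:
    """Log-odds shift vector carrying ``control_p`` onto ``target_p``.

    Zero target categories map to ``-inf`` (the category is emptied).
    """
    control_p = np.asarray(control_p, float)
    target_p = np.asarray(target_p, float)
    with np.errstate(divide="ignore"):
        return np.where(target_p > 0, np.log(target_p / control_p), -np.inf)


def shifted_marginals(base: Marginals, shift: ExcessShift) -> Marginals:
    """Marginals of the excess sub-population implied by ``base`` and ``shift``."""
    p_age = shift_category_probs(
        np.array([base.p_age_lt75, 1.0 - base.p_age_lt75]),
        np.array([shift.d_age, 0.0]),
    )[0]
    return Marginals(
        p_age_lt75=float(p_age),
        p_location=shift_category_probs(base.p_location, shift.d_location),
        p_deprivation=shift_category_probs(base.p_deprivation, shift.d_deprivation),
        p_density=shift_category_probs(base.p_density, shift.d_density),
        ndvi_mean=base.ndvi_mean + shift.d_ndvi,
        ndvi_sd=base.ndvi_sd,
    )


@dataclass
class ScenarioParams:
    """Full specification of one synthetic cohort scenario.

    ``event_day_weights_expected`` and ``event_day_weights_excess`` are
    probability vectors over ``event_dates``; control death dates are drawn
    uniformly from ``control_dates``.
    """

    n_controls: int
    n_expected_cases: int
    n_excess_cases: int
    control_marginals: Marginals
    excess_shift: ExcessShift
    event_dates: list[_dt.date]
    event_day_weights_expected: np.ndarray
    event_day_weights_excess: np.ndarray
    control_dates: list[_dt.date]
    seed: int = 0

    def __post_init__(self) -> None:
        self.event_day_weights_expected = np.asarray(self.event_day_weights_expected, float)
        self.event_day_weights_excess = np.asarray(self.event_day_weights_excess, float)
        if self.n_controls <= 0 or self.n_expected_cases <= 0 or self.n_excess_cases < 0:
            raise ParameterError("pool sizes must be positive (n_excess_cases may be 0)")
        n_days = len(self.event_dates)
        for name, w in (
            ("event_day_weights_expected", self.event_day_weights_expected),
            ("event_day_weights_excess", self.event_day_weights_excess),
        ):
            if w.shape != (n_days,):
                raise ParameterError(f"{name} must match the number of event dates")
            if (w < 0).any() or abs(w.sum() - 1.0) > _PROB_TOL:
                raise ParameterError(f"{name} must be a probability vector summing to 1")
        if set(self.control_dates) & set(self.event_dates):
            raise ParameterError("control_dates must not overlap event_dates")

    @property
    def n_cases(self) -> int:
        return self.n_expected_cases + self.n_excess_cases


# --- study-scale defaults -------------------------------------------------

#: Event window: the 7-day 2009 hot-weather event, 27 July - 2 August.
DEFAULT_EVENT_DATES = [_dt.date(2009, 7, 27) + _dt.timedelta(days=i) for i in range(7)]


def _summer_dates(years=(2010, 2011, 2012)) -> list[_dt.date]:
    out = []
    for y in years:
        d = _dt.date(y, 6, 1)
        while d <= _dt.date(y, 8, 31):
            out.append(d)
            d += _dt.timedelta(days=1)
    return out


def control_pool_marginals() -> Marginals:
    """Covariate marginals of the control pool (typical summer weather deaths).

    Age <75 in 37.4% of deaths; roughly half in hospital and few at home;
    deprivation and density quintiles near-uniform by construction; NDVI
    centred at 0.329.  The NDVI spread of 0.10 makes the excess/control
    mean gap of 0.075 about 0.75 SD — separable but not trivially so.
    """
    return Marginals(
        p_age_lt75=0.374,
        p_location=np.array([0.519, 0.309, 0.145, 0.027]),
        p_deprivation=np.array([0.207, 0.207, 0.192, 0.191, 0.202]) / 0.999,
        p_density=np.array([0.201, 0.195, 0.199, 0.198, 0.207]),
        ndvi_mean=0.329,
        ndvi_sd=0.10,
    )


def consensus_excess_marginals() -> Marginals:
    """Covariate profile of the consensus probable-excess deaths.

    Nearly all under 75, none dying in hospital or residential institutions,
    two-thirds in the most deprived quintile, concentrated in the densest
    neighbourhoods, mean NDVI 0.254.
    """
    return Marginals(
        p_age_lt75=0.967,
        p_location=np.array([0.0, 0.0, 0.800, 0.200]),
        p_deprivation=np.array([0.0, 0.0, 0.200, 0.133, 0.667]) / 1.0,
        p_density=np.array([0.0, 0.033, 0.167, 0.200, 0.600]),
        ndvi_mean=0.254,
        ndvi_sd=0.10,
    )


def consensus_excess_shift(base: Marginals | None = None) -> ExcessShift:
    """Log-odds shifts carrying the control marginals onto the consensus profile."""
    base = base or control_pool_marginals()
    target = consensus_excess_marginals()

    def _logit(p: float) -> float:
        return float(np.log(p / (1.0 - p)))

    return ExcessShift(
        d_age=_logit(target.p_age_lt75) - _logit(base.p_age_lt75),
        d_location=shift_to_match(base.p_location, target.p_location),
        d_deprivation=shift_to_match(base.p_deprivation, target.p_deprivation),
        d_density=shift_to_match(base.p_density, target.p_density),
        d_ndvi=target.ndvi_mean - base.ndvi_mean,
    )


#: Daily distribution of consensus excess deaths over the 7 event days,
#: peaking on the three hottest days (29-31 July).
CONSENSUS_EXCESS_DAY_WEIGHTS = np.array([0.067, 0.100, 0.200, 0.233, 0.200, 0.100, 0.100]) / 1.0


def _scenario(shift: ExcessShift, excess_weights: np.ndarray,
              n_controls: int, n_expected_cases: int, n_excess_cases: int,
              seed: int) -> ScenarioParams:
    return ScenarioParams(
        n_controls=n_controls,
        n_expected_cases=n_expected_cases,
        n_excess_cases=n_excess_cases,
        control_marginals=control_pool_marginals(),
        excess_shift=shift,
        event_dates=list(DEFAULT_EVENT_DATES),
        event_day_weights_expected=np.full(7, 1.0 / 7.0),
        event_day_weights_excess=excess_weights,
        control_dates=_summer_dates(),
        seed=seed,
    )


def strong_effect_scenario(n_controls: int = 11632, n_expected_cases: int = 297,
                           n_excess_cases: int = 114, seed: int = 0) -> ScenarioParams:
    """Study-scale scenario with excess deaths at the consensus vulnerable profile.

    Expected-death dates are uniform over the event (a flat baseline);
    excess-death dates follow the consensus daily weights.
    """
    w = CONSENSUS_EXCESS_DAY_WEIGHTS / CONSENSUS_EXCESS_DAY_WEIGHTS.sum()
    return _scenario(consensus_excess_shift(), w, n_controls,
                     n_expected_cases, n_excess_cases, seed)


def null_scenario(n_controls: int = 11632, n_expected_cases: int = 297,
                  n_excess_cases: int = 114, seed: int = 0) -> ScenarioParams:
    """Zero-shift scenario: excess and expected cases are exchangeable."""
    return _scenario(ExcessShift(), np.full(7, 1.0 / 7.0), n_controls,
                     n_expected_cases, n_excess_cases, seed)


# --- generation -----------------------------------------------------------

def _draw_records(marg: Marginals, n: int, rng: np.random.Generator,
                  id_prefix: str, start: int = 0) -> pd.DataFrame:
    age_lt75 = rng.random(n) < marg.p_age_lt75
    # draw an integer age consistent with the dichotomy actually analysed
    age = np.where(age_lt75, rng.integers(18, 75, n), rng.integers(75, 100, n))
    location = rng.choice(len(LOCATION_CATEGORIES), size=n, p=marg.p_location)
    deprivation = rng.choice(5, size=n, p=marg.p_deprivation) + 1
    density = rng.choice(5, size=n, p=marg.p_density) + 1
    a = (-1.0 - marg.ndvi_mean) / marg.ndvi_sd
    b = (1.0 - marg.ndvi_mean) / marg.ndvi_sd
    ndvi = stats.truncnorm.rvs(a, b, loc=marg.ndvi_mean, scale=marg.ndvi_sd,
                               size=n, random_state=rng)
    return pd.DataFrame({
        "record_id": [f"{id_prefix}{start + i:06d}" for i in range(n)],
        "age_years": age.astype(int),
        "location_of_death": [LOCATION_CATEGORIES[i] for i in location],
        "deprivation_quintile": deprivation.astype(int),
        "density_quintile": density.astype(int),
        "ndvi": ndvi,
    })


def generate_controls(params: ScenarioParams, rng: np.random.Generator) -> pd.DataFrame:
    """Draw the control pool from the control marginals.

    Death dates fall uniformly over the comparison period, outside the
    event window by construction.
    """
    df = _draw_records(params.control_marginals, params.n_controls, rng, "ctrl-")
    idx = rng.integers(0, len(params.control_dates), params.n_controls)
    df.insert(1, "death_date", [params.control_dates[i] for i in idx])
    df["group"] = "control"
    return df


def generate_cases(params: ScenarioParams, rng: np.random.Generator) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw the case pool and its ground-truth labels.

    Expected-type cases come from the control marginals (the framework's
    core exchangeability assumption); excess-type cases come from the
    shifted marginals.  Rows are shuffled so truth is not encoded in order.
    Death dates are unset until :func:`assign_event_dates`.
    """
    expected = _draw_records(params.control_marginals, params.n_expected_cases,
                             rng, "case-")
    excess_marg = shifted_marginals(params.control_marginals, params.excess_shift)
    excess = _draw_records(excess_marg, params.n_excess_cases, rng, "case-",
                           start=params.n_expected_cases)
    df = pd.concat([expected, excess], ignore_index=True)
    labels = np.array(["expected"] * params.n_expected_cases
                      + ["excess"] * params.n_excess_cases)
    order = rng.permutation(len(df))
    df = df.iloc[order].reset_index(drop=True)
    labels = labels[order]
    df["group"] = "case"
    truth = pd.Series(labels, index=df["record_id"].to_numpy(), name="truth_label")
    return df, truth


def assign_event_dates(cases: pd.DataFrame, truth: GroundTruth,
                       params: ScenarioParams, rng: np.random.Generator) -> pd.DataFrame:
    """Draw death dates over the event window, by ground-truth type.

    Expected cases follow ``event_day_weights_expected`` (a flat baseline by
    default); excess cases follow ``event_day_weights_excess`` so they
    concentrate on the hottest days.
    """
    cases = cases.copy()
    n = len(cases)
    is_excess = truth.loc[cases["record_id"]].to_numpy() == "excess"
    day_idx = np.empty(n, dtype=int)
    n_exp = int((~is_excess).sum())
    if n_exp:
        day_idx[~is_excess] = rng.choice(len(params.event_dates), size=n_exp,
                                         p=params.event_day_weights_expected)
    if n - n_exp:
        day_idx[is_excess] = rng.choice(len(params.event_dates), size=n - n_exp,
                                        p=params.event_day_weights_excess)
    dates = [params.event_dates[i] for i in day_idx]
    if "death_date" in cases.columns:
        cases["death_date"] = dates
    else:
        cases.insert(1, "death_date", dates)
    return cases


def generate_cohort(params: ScenarioParams,
                    rng: np.random.Generator | None = None) -> tuple[Cohort, GroundTruth]:
    """Generate a full synthetic cohort; deterministic given params and seed."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    controls = generate_controls(params, rng)
    cases, truth = generate_cases(params, rng)
    cases = assign_event_dates(cases, truth, params, rng)
    cohort = build_cohort(cases, controls, params.event_dates,
                          provenance=f"synthetic scenario seed={params.seed}")
    return cohort, truth


def scenario_to_dict(params: ScenarioParams) -> dict:
    """Serialise a scenario to plain types (for YAML/JSON round-trips)."""
    m, s = params.control_marginals, params.excess_shift
    return {
        "n_controls": params.n_controls,
        "n_expected_cases": params.n_expected_cases,
        "n_excess_cases": params.n_excess_cases,
        "control_marginals": {
            "p_age_lt75": m.p_age_lt75,
            "p_location": m.p_location.tolist(),
            "p_deprivation": m.p_deprivation.tolist(),
            "p_density": m.p_density.tolist(),
            "ndvi_mean": m.ndvi_mean,
            "ndvi_sd": m.ndvi_sd,
        },
        "excess_shift": {
            "d_age": s.d_age,
            "d_location": [float(x) for x in s.d_location],
            "d_deprivation": [float(x) for x in s.d_deprivation],
            "d_density": [float(x) for x in s.d_density],
            "d_ndvi": s.d_ndvi,
        },
        "event_dates": [d.isoformat() for d in params.event_dates],
        "event_day_weights_expected": params.event_day_weights_expected.tolist(),
        "event_day_weights_excess": params.event_day_weights_excess.tolist(),
        "control_dates": [d.isoformat() for d in params.control_dates],
        "seed": params.seed,
    }


def scenario_from_dict(d: dict) -> ScenarioParams:
    """Rebuild a :class:`ScenarioParams` from :func:`scenario_to_dict` output.

    Log-odds shifts serialised as the string ``"-inf"`` (YAML has no
    float('-inf') literal) are accepted.
    """
    def _shift_vec(v):
        return np.array([float(x) for x in v])

    m = d["control_marginals"]
    s = d["excess_shift"]
    return ScenarioParams(
        n_controls=int(d["n_controls"]),
        n_expected_cases=int(d["n_expected_cases"]),
        n_excess_cases=int(d["n_excess_cases"]),
        control_marginals=Marginals(
            p_age_lt75=float(m["p_age_lt75"]),
            p_location=np.asarray(m["p_location"], float),
            p_deprivation=np.asarray(m["p_deprivation"], float),
            p_density=np.asarray(m["p_density"], float),
            ndvi_mean=float(m["ndvi_mean"]),
            ndvi_sd=float(m["ndvi_sd"]),
        ),
        excess_shift=ExcessShift(
            d_age=float(s["d_age"]),
            d_location=_shift_vec(s["d_location"]),
            d_deprivation=_shift_vec(s["d_deprivation"]),
            d_density=_shift_vec(s["d_density"]),
            d_ndvi=float(s["d_ndvi"]),
        ),
        event_dates=[_dt.date.fromisoformat(x) for x in d["event_dates"]],
        event_day_weights_expected=np.asarray(d["event_day_weights_expected"], float),
        event_day_weights_excess=np.asarray(d["event_day_weights_excess"], float),
        control_dates=[_dt.date.fromisoformat(x) for x in d["control_dates"]],
        seed=int(d.get("seed", 0)),
    )


def write_truth(truth: GroundTruth, path) -> None:
    truth.rename_axis("record_id").to_csv(path)


def read_truth(path) -> GroundTruth:
    df = pd.read_csv(path, dtype={"record_id": str})
    return pd.Series(df["truth_label"].to_numpy(), index=df["record_id"].to_numpy(),
                     name="truth_label")
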