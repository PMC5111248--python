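"""One repetition of the case-control resampling framework.

A repetition draws the expected number of deaths from the case pool plus
4:1 matched-size controls from the control pool, fits logistic regression
model(s) of case status on the analysis covariates, and converts the fit
into a non-negative integer *significance weight* under a given modelling
combination.  Twelve combinations span model type (univariate vs
multivariate), significance tally rule, an optional requirement that
coefficients point in the a-priori expected direction, and the alpha level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import statsmodels.api as sm

from .cohort import Cohort, VARIABLES, VARIABLE_COLUMNS, encode_design

PER_MODEL = "per_model"
ANY_SIGNIFICANT = "any_significant"
COUNT_SIGNIFICANT = "count_significant"


@dataclass(frozen=True)
class CombinationSpec:
    """One modelling combination.

    ``tally_rule`` is ``per_model`` for univariate combinations (each of
    the five single-variable models contributes its own 0/1 weight, summed
    across variables downstream), and ``any_significant`` (0/1 per model)
    or ``count_significant`` (0-5 significant variables) for multivariate
    combinations.
    """

    label: str
    model_type: str  # "univariate" | "multivariate"
    tally_rule: str
    direction_required: bool
    alpha: float

    def __post_init__(self) -> None:
        if self.model_type not in ("univariate", "multivariate"):
            raise ValueError(f"bad model_type {self.model_type!r}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.model_type == "univariate" and self.tally_rule != PER_MODEL:
            raise ValueError("univariate combinations use the per_model tally rule")
        if self.model_type == "multivariate" and self.tally_rule not in (
            ANY_SIGNIFICANT, COUNT_SIGNIFICANT,
        ):
            raise ValueError(
                "multivariate combinations use any_significant or count_significant"
            )

    @property
    def max_weight(self) -> int:
        return 5 if self.tally_rule == COUNT_SIGNIFICANT else 1


def _presets() -> dict[str, CombinationSpec]:
    combos = {}
    # univariate #1-4: direction T/F crossed with alpha 0.10/0.05
    for i, (direction, alpha) in enumerate(
        [(True, 0.10), (False, 0.10), (True, 0.05), (False, 0.05)], start=1
    ):
        combos[f"uni{i}"] = CombinationSpec(
            f"uni{i}", "univariate", PER_MODEL, direction, alpha)
    # multivariate #1-4: count of significant variables; #5-8: at least one
    rows = [
        (COUNT_SIGNIFICANT, True, 0.10), (COUNT_SIGNIFICANT, False, 0.10),
        (COUNT_SIGNIFICANT, True, 0.05), (COUNT_SIGNIFICANT, False, 0.05),
        (ANY_SIGNIFICANT, True, 0.10), (ANY_SIGNIFICANT, False, 0.10),
        (ANY_SIGNIFICANT, True, 0.05), (ANY_SIGNIFICANT, False, 0.05),
    ]
    for i, (rule, direction, alpha) in enumerate(rows, start=1):
        combos[f"multi{i}"] = CombinationSpec(
            f"multi{i}", "multivariate", rule, direction, alpha)
    return combos


#: The twelve named modelling combinations, uni1-uni4 and multi1-multi8.
STANDARD_COMBINATIONS: dict[str, CombinationSpec] = _presets()


#: Expected coefficient sign per design column, from prior evidence on
#: heat-wave mortality: higher risk for the younger-senior age band, any
#: death location relative to hospital, greater deprivation and density;
#: protective (negative) effect of residential greenness.
DIRECTION_EXPECTATIONS: dict[str, int] = {
    "age_lt75": +1,
    "loc_residential_institution": +1,
    "loc_home": +1,
    "loc_other": +1,
    "deprivation": +1,
    "density_q": +1,
    "ndvi": -1,
}


@dataclass
class RepetitionSample:
    """Ids drawn (without replacement) into one repetition."""

    case_ids: np.ndarray
    control_ids: np.ndarray


@dataclass
class LogitFit:
    """Wald summaries of one fitted logistic regression.

    ``converged=False`` flags non-convergence or (quasi-)complete
    separation; such a fit contributes no significant terms.
    """

    terms: tuple[str, ...]
    coef: np.ndarray
    se: np.ndarray
    pvalues: np.ndarray
    converged: bool


class SamplingError(ValueError):
    """Requested draw exceeds a pool size."""


def draw_sample(cohort: Cohort, n_case_draw: int, control_ratio: int,
                rng: np.random.Generator) -> RepetitionSample:
    """Simple random samples without replacement from each pool."""
    n_ctrl_draw = control_ratio * n_case_draw
    if n_case_draw > cohort.n_cases:
        raise SamplingError(
            f"cannot draw {n_case_draw} cases from a pool of {cohort.n_cases}")
    if n_ctrl_draw > cohort.n_controls:
        raise SamplingError(
            f"cannot draw {n_ctrl_draw} controls from a pool of {cohort.n_controls}")
    case_idx = rng.choice(cohort.n_cases, size=n_case_draw, replace=False)
    ctrl_idx = rng.choice(cohort.n_controls, size=n_ctrl_draw, replace=False)
    return RepetitionSample(
        case_ids=cohort.cases["record_id"].to_numpy()[case_idx],
        control_ids=cohort.controls["record_id"].to_numpy()[ctrl_idx],
    )


def fit_logit(X: np.ndarray, y: np.ndarray, terms: Sequence[str]) -> LogitFit:
    """Maximum-likelihood logistic regression with an intercept.

    Per-term two-sided Wald p-values come from coefficient/SE against the
    standard normal.  Non-convergence and (quasi-)complete separation are
    reported through ``converged=False`` instead of raising, so a
    degenerate resample simply contributes weight zero.
    """
    y = np.asarray(y, float)
    if y.min() == y.max():
        raise ValueError("outcome must contain both cases and controls")
    Xc = np.column_stack([np.ones(len(y)), X])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, Xc).fit(method="newton", maxiter=100, tol=1e-8,
                                      disp=0, warn_convergence=False)
        ok = bool(res.mle_retvals.get("converged", False))
        bse = np.asarray(res.bse, float)
        ok = ok and np.all(np.isfinite(bse)) and np.all(bse < 1e3)
        return LogitFit(
            terms=tuple(terms),
            coef=np.asarray(res.params, float)[1:],
            se=bse[1:],
            pvalues=np.asarray(res.pvalues, float)[1:],
            converged=ok,
        )
    except Exception:
        k = X.shape[1] if X.ndim == 2 else 1
        nan = np.full(k, np.nan)
        return LogitFit(tuple(terms), nan, nan, nan, converged=False)


def significant_terms(fit: LogitFit, alpha: float, direction_required: bool) -> np.ndarray:
    """Boolean mask of terms significant under the combination's rules.

    A term counts iff the fit converged, its Wald p-value is below alpha,
    and — when the direction gate is on — its coefficient sign matches the
    a-priori expectation for that column.
    """
    if not fit.converged:
        return np.zeros(len(fit.terms), dtype=bool)
    sig = fit.pvalues < alpha
    if direction_required:
        signs = np.array([DIRECTION_EXPECTATIONS[t] for t in fit.terms])
        sig &= np.sign(fit.coef) == signs
    return sig


def variable_significant(fit: LogitFit, variable: str, alpha: float,
                         direction_required: bool) -> bool:
    """Whether one of the five analysis variables is significant in a fit.

    The four-level location factor counts as a single variable: it is
    significant iff any of its three indicators is (direction applied per
    indicator).
    """
    cols = set(VARIABLE_COLUMNS[variable])
    mask = significant_terms(fit, alpha, direction_required)
    return any(m and t in cols for m, t in zip(mask, fit.terms))


def evaluate_repetition(fits: LogitFit | Mapping[str, LogitFit],
                        spec: CombinationSpec) -> int | dict[str, int]:
    """Convert fit(s) into the repetition's significance weight(s).

    Multivariate specs take the single five-variable fit and return one
    integer: 1 if at least one variable is significant
    (``any_significant``) or the number of significant variables, 0-5
    (``count_significant``).  Univariate specs take a mapping
    variable -> fit and return a 0/1 weight per variable-model.
    """
    if spec.model_type == "multivariate":
        if not isinstance(fits, LogitFit):
            raise TypeError("multivariate spec expects a single LogitFit")
        flags = [variable_significant(fits, v, spec.alpha, spec.direction_required)
                 for v in VARIABLES
                 if set(VARIABLE_COLUMNS[v]) & set(fits.terms)]
        if spec.tally_rule == COUNT_SIGNIFICANT:
            return int(sum(flags))
        return int(any(flags))
    if isinstance(fits, LogitFit):
        raise TypeError("univariate spec expects a mapping variable -> LogitFit")
    return {
        var: int(variable_significant(fit, var, spec.alpha, spec.direction_required))
        for var, fit in fits.items()
    }


def design_arrays(cohort: Cohort) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Encode the full cohort once: (X, y, column names), cases first.

    Rows 0..n_cases-1 are the cases in pool order, the rest the controls,
    so repetition index draws slice this matrix directly.
    """
    import pandas as pd

    pooled = pd.concat([cohort.cases, cohort.controls], ignore_index=True)
    design = encode_design(pooled, VARIABLES)
    cols = [c for c in design.columns if c != "outcome"]
    return design[cols].to_numpy(float), design["outcome"].to_numpy(float), cols
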