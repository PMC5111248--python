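"""Orchestration of repetitions into trials and trials into combination runs.

Within a *trial*, many repetitions accumulate two tallies per case: A, the
number of times the case was drawn into a repetition, and B, the sum of
significance weights over the repetitions that contained it.  The B/A
probability ratio ranks the cases; the top ``n_cases - expected_count``
are flagged the trial's *more probable excess* deaths.  Across trials, the
percentage of trials flagging each case yields the final classification,
and the standard deviation of each case's rank measures its stability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort, VARIABLES, VARIABLE_COLUMNS
from .resample import (
    CombinationSpec,
    STANDARD_COMBINATIONS,
    SamplingError,
    design_arrays,
    evaluate_repetition,
    fit_logit,
)

logger = logging.getLogger(__name__)

EXCESS = "probable_excess"
EXPECTED = "probable_expected"


@dataclass
class TrialResult:
    """Per-case outcome of one trial, aligned to case-pool order."""

    record_ids: np.ndarray
    A: np.ndarray  # selection counts
    B: np.ndarray  # significance-weighted counts
    ratio: np.ndarray  # B/A, 0 where A == 0
    rank: np.ndarray  # 1 = highest ratio
    flag_excess: np.ndarray  # bool, exactly n_cases - expected_count set
    n_repetitions: int  # counts univariate sub-repetitions


@dataclass
class CombinationResult:
    """Cross-trial aggregation for one modelling combination.

    ``table`` has one row per case: ``pct_trials_excess``, ``mean_rank``,
    ``rank_sd`` (NaN when fewer than two trials) and ``final_label``.
    """

    spec: CombinationSpec
    table: pd.DataFrame
    n_trials: int
    n_reps: int
    seed: int

    @property
    def excess_ids(self) -> set[str]:
        mask = self.table["final_label"] == EXCESS
        return set(self.table.loc[mask, "record_id"])

    @property
    def rank_sd(self) -> np.ndarray:
        return self.table["rank_sd"].to_numpy(float)


@dataclass
class StabilitySummary:
    """Spread of per-case rank standard deviations for one combination."""

    mean_of_rank_sd: float
    sd_of_rank_sd: float
    median_of_rank_sd: float
    iqr_of_rank_sd: float


def _rank_and_flag(values: np.ndarray, n_excess: int,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Rank descending by ``values`` (1 = highest) and flag the top ``n_excess``.

    Ties are broken by a seeded random permutation so that file order never
    decides who crosses the classification boundary.
    """
    n = len(values)
    tiebreak = rng.permutation(n)
    order = np.lexsort((tiebreak, -values))
    rank = np.empty(n, dtype=int)
    rank[order] = np.arange(1, n + 1)
    return rank, rank <= n_excess


def run_trial(cohort: Cohort, spec: CombinationSpec, n_reps: int,
              n_case_draw: int, control_ratio: int,
              rng: np.random.Generator,
              design: tuple[np.ndarray, np.ndarray, list[str]] | None = None
              ) -> TrialResult:
    """Execute one trial of ``n_reps`` repetitions and rank the cases.

    ``n_case_draw`` is the expected death count: it is both the number of
    cases drawn per repetition and the classification boundary (the top
    ``n_cases - n_case_draw`` cases by B/A are flagged probable excess).
    Univariate specs fit each of the five variables in its own
    sub-repetition with a fresh case/control draw, and the tallies are
    summed across variables before the ratio is formed.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    n_cases, n_controls = cohort.n_cases, cohort.n_controls
    n_ctrl_draw = control_ratio * n_case_draw
    if n_case_draw >= n_cases:
        raise SamplingError(
            f"expected count {n_case_draw} must be below the case-pool size {n_cases}")
    if n_ctrl_draw > n_controls:
        raise SamplingError(
            f"need {n_ctrl_draw} controls per repetition, pool has {n_controls}")

    X, y, cols = design if design is not None else design_arrays(cohort)
    col_idx = {c: i for i, c in enumerate(cols)}
    var_cols = {v: [col_idx[c] for c in VARIABLE_COLUMNS[v]] for v in VARIABLES}

    A = np.zeros(n_cases, dtype=np.int64)
    B = np.zeros(n_cases, dtype=np.int64)
    n_sub = 0

    def _one_fit(case_idx: np.ndarray, ctrl_idx: np.ndarray, cidx: list[int]):
        rows = np.concatenate([case_idx, n_cases + ctrl_idx])
        terms = [cols[i] for i in cidx]
        return fit_logit(X[np.ix_(rows, cidx)], y[rows], terms)

    for _ in range(n_reps):
        if spec.model_type == "multivariate":
            case_idx = rng.choice(n_cases, size=n_case_draw, replace=False)
            ctrl_idx = rng.choice(n_controls, size=n_ctrl_draw, replace=False)
            fit = _one_fit(case_idx, ctrl_idx, list(range(len(cols))))
            w = evaluate_repetition(fit, spec)
            A[case_idx] += 1
            B[case_idx] += w
            n_sub += 1
        else:
            for var in VARIABLES:
                case_idx = rng.choice(n_cases, size=n_case_draw, replace=False)
                ctrl_idx = rng.choice(n_controls, size=n_ctrl_draw, replace=False)
                fit = _one_fit(case_idx, ctrl_idx, var_cols[var])
                w = evaluate_repetition({var: fit}, spec)[var]
                A[case_idx] += 1
                B[case_idx] += w
                n_sub += 1

    never = A == 0
    if never.any():
        logger.warning("%d case(s) never selected in this trial; ratio set to 0",
                       int(never.sum()))
    ratio = np.divide(B, A, out=np.zeros(n_cases, dtype=float), where=A > 0)
    rank, flag = _rank_and_flag(ratio, n_cases - n_case_draw, rng)
    return TrialResult(
        record_ids=cohort.cases["record_id"].to_numpy(),
        A=A, B=B, ratio=ratio, rank=rank, flag_excess=flag,
        n_repetitions=n_sub,
    )


def run_combination(cohort: Cohort, spec: CombinationSpec, n_trials: int,
                    n_reps: int, n_case_draw: int, control_ratio: int,
                    seed: int) -> CombinationResult:
    """Run ``n_trials`` independent trials and aggregate the classification.

    Each trial draws from an independently derived substream of the master
    seed, so trials are reproducible in isolation and order-independent.
    With fewer than two trials, ``rank_sd`` is NaN but labels are still
    produced.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    design = design_arrays(cohort)
    master = np.random.SeedSequence(seed)
    streams = master.spawn(n_trials + 1)

    ranks = np.empty((n_trials, cohort.n_cases), dtype=int)
    flags = np.empty((n_trials, cohort.n_cases), dtype=bool)
    for t in range(n_trials):
        trial = run_trial(cohort, spec, n_reps, n_case_draw, control_ratio,
                          np.random.default_rng(streams[t]), design=design)
        ranks[t] = trial.rank
        flags[t] = trial.flag_excess

    pct = flags.mean(axis=0) * 100.0
    mean_rank = ranks.mean(axis=0)
    if n_trials >= 2:
        rank_sd = ranks.std(axis=0, ddof=1)
    else:
        rank_sd = np.full(cohort.n_cases, np.nan)

    # Final labels: top cases by flag percentage.  With few trials the
    # percentage is coarse, so ties break first by mean rank across trials
    # (more consistently excess-like ranks win), then by a seeded random
    # permutation so input order never decides the boundary.
    n_excess = cohort.n_cases - n_case_draw
    tiebreak = np.random.default_rng(streams[-1]).permutation(cohort.n_cases)
    order = np.lexsort((tiebreak, mean_rank, -pct))
    final_flag = np.zeros(cohort.n_cases, dtype=bool)
    final_flag[order[:n_excess]] = True

    table = pd.DataFrame({
        "record_id": cohort.cases["record_id"].to_numpy(),
        "pct_trials_excess": pct,
        "mean_rank": mean_rank,
        "rank_sd": rank_sd,
        "final_label": np.where(final_flag, EXCESS, EXPECTED),
    })
    return CombinationResult(spec=spec, table=table, n_trials=n_trials,
                             n_reps=n_reps, seed=seed)


def stability_summary(result: CombinationResult | Sequence[float]) -> StabilitySummary:
    """Mean, SD, median and IQR of the per-case rank standard deviations."""
    if isinstance(result, CombinationResult):
        sds = result.rank_sd
    else:
        sds = np.asarray(result, dtype=float)
    if np.isnan(sds).any():
        raise ValueError("rank SDs undefined (need at least two trials)")
    q1, q3 = np.percentile(sds, [25, 75])
    return StabilitySummary(
        mean_of_rank_sd=float(sds.mean()),
        sd_of_rank_sd=float(sds.std(ddof=1)) if len(sds) > 1 else 0.0,
        median_of_rank_sd=float(np.median(sds)),
        iqr_of_rank_sd=float(q3 - q1),
    )


def select_most_consistent(summaries: Mapping[str, StabilitySummary],
                           specs: Mapping[str, CombinationSpec] | None = None
                           ) -> dict[str, str]:
    """Pick the most rank-stable combination within each model type.

    Minimises ``mean_of_rank_sd``; ties break by ``median_of_rank_sd``,
    then by the order the summaries were supplied in.  Returns a mapping
    model type -> winning label, covering the model types present.
    """
    if not summaries:
        raise ValueError("no stability summaries supplied")
    specs = specs or STANDARD_COMBINATIONS
    best: dict[str, tuple] = {}
    for pos, (label, summ) in enumerate(summaries.items()):
        mtype = specs[label].model_type
        key = (summ.mean_of_rank_sd, summ.median_of_rank_sd, pos)
        if mtype not in best or key < best[mtype][0]:
            best[mtype] = (key, label)
    return {mtype: label for mtype, (_, label) in best.items()}


def stability_table(summaries: Mapping[str, StabilitySummary],
                    specs: Mapping[str, CombinationSpec] | None = None) -> pd.DataFrame:
    """Tabulate combination variants and their rank-SD spread statistics."""
    specs = specs or STANDARD_COMBINATIONS
    rows = []
    for label, s in summaries.items():
        spec = specs[label]
        rows.append({
            "combination": label,
            "model_type": spec.model_type,
            "significance_tally": spec.tally_rule,
            "direction_required": spec.direction_required,
            "alpha": spec.alpha,
            "mean_of_rank_sd": s.mean_of_rank_sd,
            "sd_of_rank_sd": s.sd_of_rank_sd,
            "median_of_rank_sd": s.median_of_rank_sd,
            "iqr_of_rank_sd": s.iqr_of_rank_sd,
        })
    return pd.DataFrame(rows)


def selection_frequencies(cohort: Cohort, n_case_draw: int, control_ratio: int,
                          n_reps: int, rng: np.random.Generator) -> tuple[float, float]:
    """Empirical per-repetition selection fractions (cases, controls).

    Simulates the draws alone (no model fits): returns the average fraction
    of repetitions into which a given case, and a given control, was
    selected.  Long-run values are ``n_case_draw / n_cases`` and
    ``control_ratio * n_case_draw / n_controls``.
    """
    a_case = np.zeros(cohort.n_cases, dtype=np.int64)
    a_ctrl = np.zeros(cohort.n_controls, dtype=np.int64)
    n_ctrl_draw = control_ratio * n_case_draw
    for _ in range(n_reps):
        a_case[rng.choice(cohort.n_cases, size=n_case_draw, replace=False)] += 1
        a_ctrl[rng.choice(cohort.n_controls, size=n_ctrl_draw, replace=False)] += 1
    return float(a_case.mean() / n_reps), float(a_ctrl.mean() / n_reps)
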