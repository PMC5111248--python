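"""Post-classification assessment of probable excess / expected groups.

After the resampling framework labels cases, these routines check whether
the labels behave as the underlying theory predicts: probable excess deaths
should differ from controls on the five covariates, probable expected
deaths should not, the excess deaths should concentrate on the hottest
event days, and alternative modelling combinations should largely agree on
who they flag.  On synthetic cohorts with ground truth, standard
classification metrics score the recovery directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .engine import CombinationResult, EXCESS

logger = logging.getLogger(__name__)


def _contingency(group: pd.Series, controls: pd.Series, categories) -> np.ndarray:
    g = group.value_counts().reindex(categories, fill_value=0)
    c = controls.value_counts().reindex(categories, fill_value=0)
    tab = np.vstack([g.to_numpy(), c.to_numpy()])
    keep = tab.sum(axis=0) > 0
    if not keep.all():
        dropped = [cat for cat, k in zip(categories, keep) if not k]
        logger.info("dropping empty categories from chi-square table: %s", dropped)
    return tab[:, keep]


def compare_to_controls(group: pd.DataFrame, controls: pd.DataFrame,
                        yates_2x2: bool = True) -> pd.DataFrame:
    """Five variable-by-variable tests of a labeled group against controls.

    Welch's unequal-variance t-test for NDVI; Pearson chi-square for the
    categorical age band and location of death (Yates continuity correction
    on the 2x2 age table only, switchable); Wilcoxon rank-sum with the
    normal approximation and tie correction for the ordinal deprivation and
    density quintiles, which are heavily tied by construction.
    """
    if len(group) == 0:
        raise ValueError("group must be non-empty")
    rows = []

    age_tab = _contingency((group["age_years"] < 75).map({True: "<75", False: ">=75"}),
                           (controls["age_years"] < 75).map({True: "<75", False: ">=75"}),
                           ["<75", ">=75"])
    correction = yates_2x2 and age_tab.shape[1] == 2
    if age_tab.min() == 0 and age_tab.shape[1] < 2:
        stat, p = 0.0, 1.0
    else:
        stat, p, _, _ = stats.chi2_contingency(age_tab, correction=correction)
    rows.append(("age", "chi_square", float(stat), float(p)))

    from .cohort import LOCATION_CATEGORIES
    loc_tab = _contingency(group["location_of_death"], controls["location_of_death"],
                           list(LOCATION_CATEGORIES))
    if loc_tab.shape[1] < 2:
        stat, p = 0.0, 1.0
    else:
        stat, p, _, _ = stats.chi2_contingency(loc_tab, correction=False)
    rows.append(("location", "chi_square", float(stat), float(p)))

    for var, col in (("deprivation", "deprivation_quintile"),
                     ("density", "density_quintile")):
        res = stats.mannwhitneyu(group[col], controls[col],
                                 alternative="two-sided", method="asymptotic")
        rows.append((var, "wilcoxon_rank_sum", float(res.statistic), float(res.pvalue)))

    res = stats.ttest_ind(group["ndvi"], controls["ndvi"], equal_var=False)
    rows.append(("ndvi", "welch_t", float(res.statistic), float(res.pvalue)))

    return pd.DataFrame(rows, columns=["variable", "test", "statistic", "p_value"])


def significance_band(p: float) -> str:
    """Render a p-value into the report's significance band."""
    if p < 0.001:
        return "<0.001"
    if p < 0.01:
        return "0.001-0.01"
    if p < 0.05:
        return "0.01-0.05"
    return ">=0.05"


def overlap_percent(sets: dict[str, set[str]]) -> pd.DataFrame:
    """Pairwise percentage overlap of probable-excess sets between combinations.

    Entry (i, j) is 100 x |excess_i ∩ excess_j| / set size.  The framework
    guarantees equal set sizes; unequal inputs are compared against the
    smaller size with a warning.
    """
    labels = list(sets)
    sizes = {k: len(v) for k, v in sets.items()}
    if len(set(sizes.values())) > 1:
        logger.warning("excess sets have unequal sizes %s; using pairwise minima", sizes)
    mat = pd.DataFrame(index=labels, columns=labels, dtype=float)
    for i in labels:
        for j in labels:
            denom = min(sizes[i], sizes[j])
            mat.loc[i, j] = 100.0 * len(sets[i] & sets[j]) / denom if denom else np.nan
    return mat


def consensus_set(sets: dict[str, set[str]]) -> tuple[set[str], float]:
    """Cases flagged excess by every combination, and their share of a set.

    Returns the intersection across all supplied sets together with
    100 x |intersection| / (size of one excess set).
    """
    if len(sets) < 2:
        raise ValueError("need at least two excess sets for a consensus")
    it = iter(sets.values())
    core = set(next(it))
    for s in it:
        core &= s
    size = max(len(s) for s in sets.values())
    return core, 100.0 * len(core) / size


def daily_distribution(group: pd.DataFrame, event_dates) -> tuple[pd.Series, bool]:
    """Proportion of a group's deaths on each event day.

    Returns proportions over ``event_dates`` summing to one, plus whether
    every event day carries at least one of the group's deaths.
    """
    counts = group["death_date"].value_counts().reindex(list(event_dates), fill_value=0)
    outside = len(group) - counts.sum()
    if outside:
        raise ValueError(f"{outside} group death(s) fall outside the event window")
    props = counts / counts.sum()
    return props, bool((counts > 0).all())


@dataclass
class RecoveryMetrics:
    """Classification accuracy of probable-excess labels against ground truth."""

    sensitivity: float
    specificity: float
    ppv: float
    n_true_excess: int
    n_labeled_excess: int


def recovery_metrics(result: CombinationResult | pd.DataFrame,
                     truth: pd.Series) -> RecoveryMetrics:
    """Score probable_excess labels against the generator's ground truth."""
    table = result.table if isinstance(result, CombinationResult) else result
    ids = table["record_id"]
    missing = ~ids.isin(truth.index)
    if missing.any():
        raise ValueError(
            f"ground truth missing for {int(missing.sum())} case(s), "
            f"e.g. {list(ids[missing].head())}")
    pred = (table["final_label"] == EXCESS).to_numpy()
    true = (truth.loc[ids].to_numpy() == "excess")
    tp = int((pred & true).sum())
    tn = int((~pred & ~true).sum())
    fp = int((pred & ~true).sum())
    fn = int((~pred & true).sum())
    return RecoveryMetrics(
        sensitivity=tp / (tp + fn) if tp + fn else np.nan,
        specificity=tn / (tn + fp) if tn + fp else np.nan,
        ppv=tp / (tp + fp) if tp + fp else np.nan,
        n_true_excess=tp + fn,
        n_labeled_excess=tp + fp,
    )
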