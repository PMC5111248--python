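import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import heatexcess as hx
from heatexcess.resample import (
    ANY_SIGNIFICANT, COUNT_SIGNIFICANT, PER_MODEL, LogitFit, SamplingError,
    design_arrays, draw_sample, evaluate_repetition, fit_logit,
    significant_terms, variable_significant,
)


def irls_logit(X, y, max_iter=100, tol=1e-10):
    """Independent IRLS oracle: returns (coef, se, wald_p) including intercept."""
    X = np.column_stack([np.ones(len(y)), X])
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1 - p)
        z = eta + (y - p) / w
        WX = X * w[:, None]
        beta_new = np.linalg.solve(X.T @ WX, X.T @ (w * z))
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            break
        beta = beta_new
    p = 1.0 / (1.0 + np.exp(-(X @ beta)))
    cov = np.linalg.inv(X.T @ (X * (p * (1 - p))[:, None]))
    se = np.sqrt(np.diag(cov))
    pvals = 2 * sps.norm.sf(np.abs(beta / se))
    return beta, se, pvals


class TestCombinationPresets:
    def test_twelve_combinations_cross_structure(self):
        combos = hx.STANDARD_COMBINATIONS
        assert len(combos) == 12
        uni = [c for c in combos.values() if c.model_type == "univariate"]
        multi = [c for c in combos.values() if c.model_type == "multivariate"]
        assert len(uni) == 4 and len(multi) == 8
        assert all(c.tally_rule == PER_MODEL for c in uni)
        assert {(c.direction_required, c.alpha) for c in uni} == {
            (True, 0.10), (False, 0.10), (True, 0.05), (False, 0.05)}
        assert {(c.tally_rule, c.direction_required, c.alpha) for c in multi} == {
            (r, d, a) for r in (COUNT_SIGNIFICANT, ANY_SIGNIFICANT)
            for d in (True, False) for a in (0.10, 0.05)}

    def test_invalid_spec_combinations_rejected(self):
        with pytest.raises(ValueError):
            hx.CombinationSpec("x", "univariate", ANY_SIGNIFICANT, True, 0.1)
        with pytest.raises(ValueError):
            hx.CombinationSpec("x", "multivariate", PER_MODEL, True, 0.1)
        with pytest.raises(ValueError):
            hx.CombinationSpec("x", "multivariate", ANY_SIGNIFICANT, True, 1.5)


class TestDrawSample:
    def test_study_scale_draw_sizes(self, study_scale_cohort, rng):
        cohort, _ = study_scale_cohort
        s = draw_sample(cohort, 297, 4, rng)
        assert len(s.case_ids) == 297 and len(s.control_ids) == 1188
        assert len(set(s.case_ids)) == 297 and len(set(s.control_ids)) == 1188

    def test_exhaustive_case_draw(self, small_strong_cohort, rng):
        cohort, _ = small_strong_cohort
        s = draw_sample(cohort, cohort.n_cases, 2, rng)
        assert set(s.case_ids) == set(cohort.cases["record_id"])

    def test_oversized_control_draw_rejected(self, small_strong_cohort, rng):
        cohort, _ = small_strong_cohort
        with pytest.raises(SamplingError, match="controls"):
            draw_sample(cohort, cohort.n_cases, 1000, rng)


class TestFitLogit:
    def test_matches_irls_oracle_on_known_coefficients(self, rng):
        n = 5000
        X = np.column_stack([rng.integers(0, 2, n), rng.normal(0, 1, n)])
        beta_true = np.array([-1.0, 0.8, -0.5])
        p = 1 / (1 + np.exp(-(beta_true[0] + X @ beta_true[1:])))
        y = (rng.random(n) < p).astype(float)
        fit = fit_logit(X, y, ["b", "c"])
        assert fit.converged
        coef_o, se_o, p_o = irls_logit(X, y)
        np.testing.assert_allclose(fit.coef, coef_o[1:], atol=1e-6)
        np.testing.assert_allclose(fit.se, se_o[1:], rtol=1e-5)
        np.testing.assert_allclose(fit.pvalues, p_o[1:], atol=1e-6)
        # estimates recover the generating coefficients
        assert np.all(np.abs(fit.coef - beta_true[1:]) < 3 * fit.se)

    def test_null_covariate_has_null_coefficient(self, rng):
        n = 4000
        X = rng.integers(0, 2, (n, 1)).astype(float)
        y = (rng.random(n) < 0.3).astype(float)
        fit = fit_logit(X, y, ["b"])
        assert abs(fit.coef[0]) < 3 * fit.se[0]

    def test_perfect_separation_flagged_not_raised(self):
        X = np.linspace(-1, 1, 40).reshape(-1, 1)
        y = (X[:, 0] > 0).astype(float)
        fit = fit_logit(X, y, ["b"])
        assert not fit.converged
        assert not significant_terms(fit, 0.10, False).any()

    def test_single_class_outcome_rejected(self):
        with pytest.raises(ValueError, match="both"):
            fit_logit(np.zeros((10, 1)), np.zeros(10), ["b"])


def _fit(terms, coefs, pvals, converged=True):
    coefs = np.asarray(coefs, float)
    return LogitFit(tuple(terms), coefs, np.abs(coefs) + 0.1,
                    np.asarray(pvals, float), converged)


# variable-level p-values from a worked example: age .04 (expected sign),
# ndvi .09 (expected sign), location .20, deprivation .50, density .30
EXAMPLE_FIT = _fit(
    ["age_lt75", "loc_residential_institution", "loc_home", "loc_other",
     "deprivation", "density_q", "ndvi"],
    [0.5, 0.1, 0.1, 0.1, 0.1, 0.1, -0.2],
    [0.04, 0.20, 0.20, 0.20, 0.50, 0.30, 0.09],
)


class TestEvaluateRepetition:
    def test_count_rule_counts_sub_alpha_variables(self):
        spec = hx.CombinationSpec("m", "multivariate", COUNT_SIGNIFICANT, True, 0.10)
        assert evaluate_repetition(EXAMPLE_FIT, spec) == 2  # age + ndvi

    def test_any_rule_caps_at_one(self):
        spec = hx.CombinationSpec("m", "multivariate", ANY_SIGNIFICANT, True, 0.10)
        assert evaluate_repetition(EXAMPLE_FIT, spec) == 1

    def test_stricter_alpha_drops_borderline_variable(self):
        spec = hx.CombinationSpec("m", "multivariate", COUNT_SIGNIFICANT, True, 0.05)
        assert evaluate_repetition(EXAMPLE_FIT, spec) == 1  # ndvi at .09 drops out

    def test_direction_gate_blocks_wrong_sign(self):
        fit = _fit(["ndvi"], [0.4], [0.01])  # significant but positive: unexpected
        spec_dir = hx.CombinationSpec("u", "univariate", PER_MODEL, True, 0.05)
        spec_free = hx.CombinationSpec("u", "univariate", PER_MODEL, False, 0.05)
        assert evaluate_repetition({"ndvi": fit}, spec_dir) == {"ndvi": 0}
        assert evaluate_repetition({"ndvi": fit}, spec_free) == {"ndvi": 1}

    def test_location_counts_as_one_variable(self):
        fit = _fit(["loc_residential_institution", "loc_home", "loc_other"],
                   [0.5, 0.6, 0.7], [0.01, 0.02, 0.03])
        spec = hx.CombinationSpec("m", "multivariate", COUNT_SIGNIFICANT, True, 0.10)
        assert evaluate_repetition(fit, spec) == 1

    def test_nonconverged_fit_contributes_zero(self):
        fit = _fit(["age_lt75"], [2.0], [0.001], converged=False)
        spec = hx.CombinationSpec("u", "univariate", PER_MODEL, False, 0.10)
        assert evaluate_repetition({"age": fit}, spec) == {"age": 0}

    def test_spec_fit_mismatch_raises(self):
        spec = hx.CombinationSpec("m", "multivariate", ANY_SIGNIFICANT, True, 0.10)
        with pytest.raises(TypeError):
            evaluate_repetition({"age": EXAMPLE_FIT}, spec)


@st.composite
def random_fits(draw):
    terms = ("age_lt75", "loc_residential_institution", "loc_home", "loc_other",
             "deprivation", "density_q", "ndvi")
    coefs = np.array([draw(st.floats(-2, 2)) for _ in terms])
    pvals = np.array([draw(st.floats(0, 1)) for _ in terms])
    return LogitFit(terms, coefs, np.ones(len(terms)), pvals,
                    draw(st.booleans()))


class TestWeightProperties:
    @given(random_fits())
    @settings(deadline=None, max_examples=100)
    def test_weight_bounds_and_monotonicity(self, fit):
        for rule in (COUNT_SIGNIFICANT, ANY_SIGNIFICANT):
            cap = 5 if rule == COUNT_SIGNIFICANT else 1
            for direction in (True, False):
                w10 = evaluate_repetition(
                    fit, hx.CombinationSpec("m", "multivariate", rule, direction, 0.10))
                w05 = evaluate_repetition(
                    fit, hx.CombinationSpec("m", "multivariate", rule, direction, 0.05))
                assert 0 <= w05 <= w10 <= cap  # alpha monotone, bounded
            # dropping the direction gate never decreases the weight
            w_dir = evaluate_repetition(
                fit, hx.CombinationSpec("m", "multivariate", rule, True, 0.10))
            w_free = evaluate_repetition(
                fit, hx.CombinationSpec("m", "multivariate", rule, False, 0.10))
            assert w_dir <= w_free

    @given(random_fits())
    @settings(deadline=None, max_examples=50)
    def test_variable_significance_consistent_with_terms(self, fit):
        from heatexcess.cohort import VARIABLES, VARIABLE_COLUMNS
        mask = significant_terms(fit, 0.10, True)
        for var in VARIABLES:
            expect = any(m for m, t in zip(mask, fit.terms)
                         if t in VARIABLE_COLUMNS[var])
            assert variable_significant(fit, var, 0.10, True) == expect


class TestNullCalibration:
    def test_univariate_significance_rate_near_alpha(self):
        """On fresh null samples the per-variable Wald rejection rate tracks alpha.

        Each repetition draws a brand-new sample in which cases and controls
        come from the same covariate distribution.  (Within one finite pool
        the conditional rejection rate reflects the pool's own sampling
        fluctuation rather than alpha — the very signal the resampling
        framework exploits — so calibration is assessed marginally.)
        """
        from heatexcess.cohort import VARIABLE_COLUMNS, encode_design
        from heatexcess.simulate import control_pool_marginals, _draw_records

        marg = control_pool_marginals()
        rng = np.random.default_rng(2025)
        n_reps, alpha = 500, 0.10
        hits = {v: 0 for v in ("age", "deprivation", "density", "ndvi")}
        for _ in range(n_reps):
            recs = _draw_records(marg, 750, rng, "r")
            recs["group"] = np.r_[["case"] * 150, ["control"] * 600]
            design = encode_design(recs)
            y = design.pop("outcome").to_numpy(float)
            for var in hits:
                cols = list(VARIABLE_COLUMNS[var])
                fit = fit_logit(design[cols].to_numpy(float), y, cols)
                hits[var] += variable_significant(fit, var, alpha, False)
        se = np.sqrt(alpha * (1 - alpha) / n_reps)
        for var, h in hits.items():
            assert abs(h / n_reps - alpha) < 3 * se, (var, h / n_reps)
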