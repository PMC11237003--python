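"""GLM fitting, AIC comparison, contrasts, and Johnson-Neyman probing."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, special

from torchsearch.stats import (
    DEFAULT_LADDER,
    compare_models_aic,
    condition_contrast,
    fit_glm,
    johnson_neyman,
)


def _poisson_frame(n, rng, beta_cond=np.log(2), beta_age=0.0, beta_inter=0.0,
                   intercept=0.5):
    condition = rng.integers(0, 2, n)
    age = rng.uniform(18, 36, n)
    eta = intercept + beta_cond * condition + beta_age * age + beta_inter * condition * age
    y = rng.poisson(np.exp(eta))
    return pd.DataFrame(
        {
            "scanning_count": y,
            "condition": np.where(condition == 1, "Uniform", "Skewed"),
            "age_months": age,
            "participant_id": np.arange(n),
        }
    )


class TestFitGLM:
    def test_poisson_recovers_known_effect(self, rng):
        frame = _poisson_frame(1000, rng)
        result = fit_glm(frame, "scanning_count", "poisson", "condition")
        coef = result.coefficients["condition[T.Uniform]"]
        assert coef.estimate == pytest.approx(np.log(2), abs=3 * coef.se)

    def test_coverage_of_wald_intervals(self):
        """95% CIs for a known Poisson effect cover the truth ~95% of the
        time across replications."""
        rng = np.random.default_rng(5)
        covered = 0
        reps = 400
        for _ in range(reps):
            frame = _poisson_frame(1000, rng)
            coef = fit_glm(
                frame, "scanning_count", "poisson", "condition"
            ).coefficients["condition[T.Uniform]"]
            lo, hi = coef.estimate - 1.96 * coef.se, coef.estimate + 1.96 * coef.se
            covered += lo <= np.log(2) <= hi
        assert covered / reps == pytest.approx(0.95, abs=0.03)

    def test_aic_identity(self, rng):
        frame = _poisson_frame(20, rng)
        result = fit_glm(frame, "scanning_count", "poisson", "condition")
        assert result.aic == pytest.approx(
            2 * len(result.coefficients) - 2 * result.log_likelihood, abs=1e-8
        )

    def test_all_zero_counts_rejected(self, rng):
        frame = _poisson_frame(30, rng)
        frame["scanning_count"] = 0
        with pytest.raises(ValueError):
            fit_glm(frame, "scanning_count", "poisson", "condition")

    def test_too_few_observations_rejected(self, rng):
        frame = _poisson_frame(5, rng)
        with pytest.raises(ValueError):
            fit_glm(frame, "scanning_count", "poisson", "condition")

    def test_family_dv_mismatch_rejected(self, rng):
        frame = _poisson_frame(30, rng)
        frame["scanning_count"] = frame["scanning_count"] + 0.5
        with pytest.raises(ValueError):
            fit_glm(frame, "scanning_count", "poisson", "condition")

    def test_singleton_clusters_match_classical_ses(self, rng):
        frame = _poisson_frame(200, rng)
        classical = fit_glm(frame, "scanning_count", "poisson", "condition")
        clustered = fit_glm(
            frame, "scanning_count", "poisson", "condition",
            cluster_by="participant_id",
        )
        for term in classical.coefficients:
            se_c = classical.coefficients[term].se
            se_r = clustered.coefficients[term].se
            # HC sandwich with one observation per cluster differs from the
            # model-based SE only through the finite-sample correction.
            assert se_r == pytest.approx(se_c, rel=0.15)

    @pytest.mark.parametrize("family,invlink", [
        ("poisson", np.exp),
        ("binomial", special.expit),
    ])
    def test_irls_matches_direct_likelihood_maximization(self, rng, family, invlink):
        """Optimizer-independence oracle: IRLS estimates equal a direct
        numerical maximization of the same log-likelihood."""
        n = 50
        x = rng.normal(size=n)
        X = np.column_stack([np.ones(n), x])
        if family == "poisson":
            y = rng.poisson(np.exp(0.3 + 0.5 * x))

            def nll(b):
                eta = X @ b
                return -(y @ eta - np.exp(eta).sum())
        else:
            y = rng.binomial(1, special.expit(0.3 + 0.5 * x))

            def nll(b):
                eta = X @ b
                return -(y @ eta - np.logaddexp(0, eta).sum())

        frame = pd.DataFrame({"y": y, "x": x})
        result = fit_glm(frame, "y", family, "x")
        direct = optimize.minimize(nll, np.zeros(2), method="BFGS", tol=1e-12).x
        est = [result.coefficients["Intercept"].estimate,
               result.coefficients["x"].estimate]
        np.testing.assert_allclose(est, direct, atol=1e-6)


class TestModelComparison:
    def test_interaction_model_recovered(self, layout):
        """On cohorts generated with a condition-by-age interaction, the
        interaction model wins the AIC ladder in most replications."""
        from torchsearch.cohort import CohortConfig, generate_cohort, trials_to_frame

        rng = np.random.default_rng(20)
        wins = 0
        reps = 150
        for _ in range(reps):
            trials, _ = generate_cohort(CohortConfig(), layout, rng)
            toddlers = trials_to_frame(trials, collapse_toddlers=True).query(
                "group == 'toddler'"
            )
            table = compare_models_aic(toddlers, "scanning_count", "poisson")
            wins += table.best_model == "condition*age"
        assert wins / reps >= 0.80

    def test_identical_specifications_tie(self, rng):
        frame = _poisson_frame(100, rng)
        table = compare_models_aic(
            frame, "scanning_count", "poisson",
            ladder={"null": "1", "a": "condition", "b": "condition"},
        )
        aics = table.table.set_index("model")["aic"]
        assert aics["a"] == pytest.approx(aics["b"], abs=1e-10)

    def test_delta_aic_anchored_at_null(self, rng):
        frame = _poisson_frame(100, rng)
        table = compare_models_aic(frame, "scanning_count", "poisson")
        deltas = table.table.set_index("model")["delta_aic"]
        assert deltas["null"] == 0.0
        assert set(table.table["model"]) == set(DEFAULT_LADDER)

    def test_aic_ordering_invariant_to_age_rescaling(self, rng):
        frame = _poisson_frame(300, rng, beta_inter=0.02)
        t1 = compare_models_aic(frame, "scanning_count", "poisson")
        frame2 = frame.assign(age_months=(frame["age_months"] - 24) / 3)
        t2 = compare_models_aic(frame2, "scanning_count", "poisson")
        order1 = t1.table.sort_values("aic")["model"].tolist()
        order2 = t2.table.sort_values("aic")["model"].tolist()
        assert order1 == order2
        # models containing age have identical AIC under the affine map
        for name in ("condition+age", "condition*age"):
            a1 = t1.table.set_index("model").loc[name, "aic"]
            a2 = t2.table.set_index("model").loc[name, "aic"]
            assert a1 == pytest.approx(a2, abs=1e-6)


class TestConditionContrast:
    def _group_frame(self, rng, gap_adult=0.5, gap_toddler=0.5, n=2000):
        group = np.where(rng.integers(0, 2, n) == 1, "toddler", "adult")
        condition = np.where(rng.integers(0, 2, n) == 1, "Uniform", "Skewed")
        gap = np.where(group == "adult", gap_adult, gap_toddler)
        eta = 0.5 + gap * (condition == "Uniform")
        return pd.DataFrame(
            {
                "scanning_count": rng.poisson(np.exp(eta)),
                "condition": condition,
                "group": group,
            }
        )

    def test_equal_effects_indistinguishable(self, rng):
        frame = self._group_frame(rng)
        result = fit_glm(frame, "scanning_count", "poisson", "condition * group")
        est_a, se_a, _, _ = condition_contrast(result, "adult")
        est_t, se_t, _, _ = condition_contrast(result, "toddler")
        z = (est_a - est_t) / np.hypot(se_a, se_t)
        assert abs(z) < 3

    def test_recovers_groupwise_gaps(self, rng):
        frame = self._group_frame(rng, gap_adult=0.8, gap_toddler=0.2)
        result = fit_glm(frame, "scanning_count", "poisson", "condition * group")
        est_a, se_a, _, p_a = condition_contrast(result, "adult")
        est_t, se_t, _, _ = condition_contrast(result, "toddler")
        assert est_a == pytest.approx(0.8, abs=3 * se_a)
        assert est_t == pytest.approx(0.2, abs=3 * se_t)
        assert p_a < 0.001

    def test_null_contrast_p_uniform(self):
        rng = np.random.default_rng(9)
        pvals = []
        for _ in range(200):
            frame = self._group_frame(rng, gap_adult=0.0, gap_toddler=0.0, n=400)
            result = fit_glm(frame, "scanning_count", "poisson", "condition * group")
            pvals.append(condition_contrast(result, "adult")[3])
        # uniform p-values: rejection rate at alpha=.05 stays near 5%
        assert np.mean(np.array(pvals) < 0.05) == pytest.approx(0.05, abs=0.04)

    def test_missing_terms_rejected(self, rng):
        frame = self._group_frame(rng)
        result = fit_glm(frame, "scanning_count", "poisson", "condition")
        with pytest.raises(ValueError):
            condition_contrast(result, "adult")


class TestJohnsonNeyman:
    def test_constant_effect_boundary_at_grid_minimum(self, rng):
        frame = _poisson_frame(3000, rng, beta_cond=0.8, beta_inter=0.0)
        result = fit_glm(
            frame, "scanning_count", "poisson", "condition * age_months"
        )
        jn = johnson_neyman(result)
        assert jn.boundary == pytest.approx(18.0)
        assert jn.side == "above"
        assert jn.significant.all()

    def test_ramp_detected_from_above(self, rng):
        # conditional effect 0.03 * (age - 18): null at the youngest ages,
        # strong at the oldest
        frame = _poisson_frame(
            2000, rng, beta_cond=-0.03 * 18, beta_inter=0.03, intercept=0.3
        )
        result = fit_glm(
            frame, "scanning_count", "poisson", "condition * age_months"
        )
        jn = johnson_neyman(result)
        assert jn.side == "above"
        assert 19 <= jn.boundary <= 32

    def test_sign_flipped_ramp_detected_from_below(self, rng):
        # conditional effect 0.03 * (36 - age): significant only when young
        frame = _poisson_frame(
            2000, rng, beta_cond=0.03 * 36, beta_inter=-0.03, intercept=0.3
        )
        result = fit_glm(
            frame, "scanning_count", "poisson", "condition * age_months"
        )
        jn = johnson_neyman(result)
        assert jn.side == "below"

    def test_model_without_interaction_rejected(self, rng):
        frame = _poisson_frame(100, rng)
        result = fit_glm(frame, "scanning_count", "poisson", "condition + age_months")
        with pytest.raises(ValueError):
            johnson_neyman(result)

    def test_boundary_recovery_on_ramped_cohorts(self, layout):
        """Cohorts generated with the 24-month adaptivity ramp yield a JN
        boundary near 24 months (median across cohorts)."""
        from torchsearch.cohort import CohortConfig, generate_cohort, trials_to_frame

        boundaries = []
        for seed in range(5):
            rng = np.random.default_rng(300 + seed)
            trials, _ = generate_cohort(CohortConfig(), layout, rng)
            toddlers = trials_to_frame(trials, collapse_toddlers=True).query(
                "group == 'toddler'"
            )
            result = fit_glm(
                toddlers, "scanning_count", "poisson", "condition * age_months",
                cluster_by="participant_id",
            )
            jn = johnson_neyman(result)
            if jn.boundary is not None:
                boundaries.append(jn.boundary)
        assert len(boundaries) >= 3
        assert 22.0 <= float(np.median(boundaries)) <= 26.0
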