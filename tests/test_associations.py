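"""GLM association machinery: likelihood oracles, effect translation,
permutation inference, pruning, hazards and model comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln

from lineage_load.associations import (
    AssociationResult,
    FitError,
    ModelSpec,
    backward_prune,
    build_design,
    compare_models,
    discrete_time_hazard,
    expand_person_years,
    fit_model,
    permutation_test,
    translate_effect,
)
from lineage_load.synthetic_data import logistic_cohort


def make_result(params: dict, outcome="survival15", covariates=()) -> AssociationResult:
    """Hand-built fit object for translation tests."""
    idx = list(params)
    p = pd.Series(params)
    return AssociationResult(
        spec=ModelSpec(outcome=outcome, covariates=tuple(covariates)),
        params=p,
        bse=pd.Series(0.01, index=idx),
        conf_int=pd.DataFrame({"lower": p - 0.02, "upper": p + 0.02}),
        n_rows=100,
        loglik=0.0,
        aic=0.0,
        term_blocks={k: [k] for k in idx},
        covariate_means=pd.Series(1.0, index=idx),
        cov_params=pd.DataFrame(np.eye(len(idx)) * 1e-4, index=idx, columns=idx),
    )


SMALL_COVARS = ("social_class", "twin", "maternal_age")


class TestFitModel:
    def test_logistic_loglik_matches_bruteforce(self):
        cohort = logistic_cohort(20, 0.4, -0.03, seed=5)
        cohort["twin"] = np.tile([0, 1], 10)
        res = fit_model(cohort, ModelSpec(outcome="survival15", covariates=("twin",), cluster=None))
        y, X, _ = build_design(cohort, ModelSpec(outcome="survival15", covariates=("twin",)))
        eta = X[res.params.index].to_numpy() @ res.params.to_numpy()
        p = 1 / (1 + np.exp(-eta))
        ll = np.sum(y * np.log(p) + (1 - y) * np.log(1 - p))
        assert res.loglik == pytest.approx(ll, abs=1e-8)

    def test_poisson_loglik_matches_bruteforce(self, rng):
        cohort = logistic_cohort(20, 0.4, 0.0, seed=6)
        cohort["twin"] = np.tile([0, 1], 10)
        cohort["outcome"] = rng.poisson(3.0, size=20)
        res = fit_model(cohort, ModelSpec(outcome="lbs", covariates=("twin",), cluster=None))
        y, X, _ = build_design(cohort, ModelSpec(outcome="lbs", covariates=("twin",)))
        eta = X[res.params.index].to_numpy() @ res.params.to_numpy()
        mu = np.exp(eta)
        ll = np.sum(y * eta - mu - gammaln(y + 1))
        assert res.loglik == pytest.approx(ll, abs=1e-8)

    def test_known_slope_recovered_within_ci(self):
        cohort = logistic_cohort(4000, 1.5, -0.036, seed=7)
        res = fit_model(cohort, ModelSpec(outcome="survival15"))
        lo, hi = res.exposure_ci
        assert lo <= -0.036 <= hi

    def test_single_row_errors(self):
        cohort = logistic_cohort(1, 0.0, 0.0, seed=1)
        with pytest.raises(FitError, match="insufficient"):
            fit_model(cohort, ModelSpec(outcome="survival15"))

    def test_missing_column_errors(self):
        cohort = logistic_cohort(50, 0.0, 0.0, seed=1).drop(columns=["twin"])
        with pytest.raises(FitError, match="twin"):
            fit_model(cohort, ModelSpec(outcome="survival15"))

    def test_missing_values_rejected(self):
        cohort = logistic_cohort(50, 0.0, 0.0, seed=1)
        cohort.loc[3, "maternal_age"] = np.nan
        with pytest.raises(FitError, match="maternal_age"):
            fit_model(cohort, ModelSpec(outcome="survival15"))

    def test_collinear_design_named(self):
        cohort = logistic_cohort(100, 0.0, 0.0, seed=2)
        cohort["wmama"] = cohort["maternal_age"]  # exact copy -> rank deficient
        with pytest.raises(FitError, match="collinear"):
            fit_model(cohort, ModelSpec(outcome="survival15", covariates=("maternal_age",)))

    def test_reference_levels(self):
        cohort = logistic_cohort(500, 0.5, 0.0, seed=3)
        res = fit_model(cohort, ModelSpec(outcome="survival15"))
        # reference categories absent from the design
        assert "social_class[rich]" not in res.params.index
        assert "sex[male]" not in res.params.index
        assert "social_class[poor]" in res.params.index


class TestTranslateEffect:
    def test_hand_evaluated_inverse_logit(self):
        res = make_result({"const": 0.5, "wmama": -0.036})
        tr = translate_effect(res)
        assert tr.p_ref == pytest.approx(0.3589, abs=2e-4)
        assert tr.p_cmp == pytest.approx(0.2810, abs=2e-4)
        assert tr.relative_decline == pytest.approx(0.217, abs=2e-3)

    def test_zero_slope_zero_decline(self):
        tr = translate_effect(make_result({"const": 0.5, "wmama": 0.0}))
        assert tr.absolute_decline == pytest.approx(0.0)
        assert tr.relative_decline == pytest.approx(0.0)

    def test_consistency_identities(self):
        tr = translate_effect(make_result({"const": 1.2, "wmama": -0.05}))
        assert tr.absolute_decline == pytest.approx(tr.p_ref - tr.p_cmp)
        assert tr.relative_decline * tr.p_ref == pytest.approx(tr.absolute_decline)

    def test_monotone_decrease_for_negative_slope(self):
        res = make_result({"const": 0.5, "wmama": -0.04})
        ps = [translate_effect(res, reference=30, comparison=w).p_cmp for w in (31, 34, 37, 40)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_poisson_fit_rejected(self):
        res = make_result({"const": 0.5, "wmama": -0.04}, outcome="lbs")
        with pytest.raises(ValueError, match="binomial"):
            translate_effect(res)

    def test_ci_covers_point_estimate(self):
        cohort = logistic_cohort(2000, 1.0, -0.03, seed=9)
        res = fit_model(cohort, ModelSpec(outcome="survival15", covariates=SMALL_COVARS))
        tr = translate_effect(res, ci_draws=400, seed=1)
        lo, hi = tr.relative_decline_ci
        assert lo <= tr.relative_decline <= hi


class TestPermutationTest:
    def test_deterministic_given_seed(self):
        cohort = logistic_cohort(300, 0.5, -0.1, seed=11)
        spec = ModelSpec(outcome="survival15", covariates=SMALL_COVARS)
        p1 = permutation_test(cohort, spec, n_permutations=99, seed=4)
        p2 = permutation_test(cohort, spec, n_permutations=99, seed=4)
        assert p1 == p2

    def test_maximal_signal_attains_minimum(self, rng):
        cohort = logistic_cohort(200, 0.0, 0.0, seed=12)
        counts = rng.poisson(3.0, size=200)
        cohort["outcome"] = counts
        cohort["wmama"] = counts.astype(float)  # exposure duplicates outcome
        spec = ModelSpec(outcome="lbs", covariates=("twin",))
        p = permutation_test(cohort, spec, n_permutations=99, seed=0)
        assert p == pytest.approx(1 / 100)

    def test_too_few_permutations_rejected(self):
        cohort = logistic_cohort(100, 0.5, 0.0, seed=13)
        with pytest.raises(ValueError):
            permutation_test(cohort, ModelSpec(outcome="survival15"), n_permutations=10)

    def test_null_p_not_extreme(self):
        # independent exposure: p should rarely be tiny
        ps = []
        for seed in range(10):
            cohort = logistic_cohort(400, 0.5, 0.0, seed=100 + seed)
            ps.append(permutation_test(cohort, ModelSpec(outcome="survival15", covariates=SMALL_COVARS), 99, seed=seed))
        assert np.mean(np.array(ps) <= 0.05) <= 0.3


class TestBackwardPrune:
    def test_exposure_only_spec_unchanged(self):
        cohort = logistic_cohort(500, 0.5, -0.05, seed=14)
        spec = ModelSpec(outcome="survival15", covariates=())
        assert backward_prune(cohort, spec) == spec

    def test_null_twin_effect_pruned(self):
        cohort = logistic_cohort(
            4000, 3.5, -0.05, seed=15,
            covariate_effects={"social_class[poor]": -0.8, "maternal_age": -0.05},
        )
        spec = ModelSpec(outcome="survival15", covariates=("social_class", "twin", "maternal_age"))
        pruned = backward_prune(cohort, spec)
        assert "twin" not in pruned.covariates
        assert "social_class" in pruned.covariates
        assert pruned.exposure == "wmama"

    def test_strong_effects_all_retained(self):
        # intercept offsets the covariate means so outcome prevalence ~50%
        cohort = logistic_cohort(
            5000, 4.3, -0.05, seed=16,
            covariate_effects={"social_class[poor]": -1.0, "social_class[middle]": -0.6, "twin": -1.5, "maternal_age": -0.06},
        )
        spec = ModelSpec(outcome="survival15", covariates=("social_class", "twin", "maternal_age"))
        assert backward_prune(cohort, spec) == spec


class TestDiscreteTimeHazard:
    @staticmethod
    def hazard_cohort(n, log_hr_per_wmama, seed, base_hazard=0.035):
        cohort = logistic_cohort(n, 0.0, 0.0, seed=seed)
        rng = np.random.default_rng(seed + 1)
        h = base_hazard * np.exp(log_hr_per_wmama * (cohort["wmama"] - 33.0))
        death_age = np.full(n, np.nan)
        for year in range(15):
            dies = np.isnan(death_age) & (rng.random(n) < h)
            death_age[dies] = year + rng.uniform(0, 1, size=n)[dies]
        cohort["death_age"] = death_age
        cohort["outcome"] = np.isnan(death_age).astype(int)
        return cohort

    def test_person_year_expansion_counts(self):
        df = pd.DataFrame(
            {
                "proband_id": ["a", "b", "c"],
                "outcome": [1, 0, 0],
                "death_age": [np.nan, 2.5, 14.2],
                "wmama": [30.0, 35.0, 33.0],
            }
        )
        out = expand_person_years(df)
        # survivor contributes 15 years; deaths contribute ceil(death_age)
        assert len(out) == 15 + 3 + 15
        assert out.groupby("proband_id")["outcome"].sum().to_dict() == {"a": 0.0, "b": 1.0, "c": 1.0}

    def test_no_deaths_flagged(self):
        cohort = self.hazard_cohort(200, 0.0, seed=17, base_hazard=0.0)
        with pytest.raises(FitError, match="no deaths"):
            discrete_time_hazard(cohort, ModelSpec(outcome="hazard", covariates=("twin",)))

    def test_hazard_ratio_recovered(self):
        true_log_hr = np.log(1.05)
        cohort = self.hazard_cohort(6000, true_log_hr, seed=18)
        res = discrete_time_hazard(cohort, ModelSpec(outcome="hazard", covariates=("twin",), cluster=None))
        lo, hi = res.exposure_ci
        assert lo <= true_log_hr <= hi
        assert np.exp(res.exposure_coefficient) == pytest.approx(1.05, abs=0.03)


class TestCompareModels:
    def test_identical_specs_identical_aic(self):
        cohort = logistic_cohort(800, 0.5, -0.03, seed=19)
        spec = ModelSpec(outcome="survival15", covariates=SMALL_COVARS)
        out = compare_models(cohort, [spec, spec], labels=["a", "b"])
        assert out["aic"].iloc[0] == pytest.approx(out["aic"].iloc[1])

    def test_interaction_detected_when_generated(self):
        # strong exposure x sex interaction
        rng = np.random.default_rng(20)
        cohort = logistic_cohort(6000, 0.5, -0.01, seed=20)
        female = (cohort["sex"] == "female").to_numpy()
        eta = 0.5 - 0.01 * cohort["wmama"] - 0.12 * cohort["wmama"] * female + 2.0 * female
        cohort["outcome"] = (rng.random(6000) < 1 / (1 + np.exp(-eta))).astype(int)
        base = ModelSpec(outcome="survival15", covariates=("sex", "twin"), cluster=None)
        inter = ModelSpec(outcome="survival15", covariates=("sex", "twin"), cluster=None, interactions=("sex",))
        out = compare_models(cohort, [base, inter], labels=["base", "sex_interaction"])
        assert out["model"].iloc[0] == "sex_interaction"

    def test_no_interaction_base_wins(self):
        cohort = logistic_cohort(4000, 0.5, -0.03, seed=21)
        base = ModelSpec(outcome="survival15", covariates=("sex", "twin"), cluster=None)
        inter = ModelSpec(outcome="survival15", covariates=("sex", "twin"), cluster=None, interactions=("sex",))
        out = compare_models(cohort, [base, inter], labels=["base", "sex_interaction"])
        assert out["model"].iloc[0] == "base"
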