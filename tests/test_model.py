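import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from oracles import irls_logistic, rank_auroc
from viosna import synthetic as syn
from viosna.model import (
    LogisticModel,
    ModelError,
    ModelSpec,
    ViolenceRiskModel,
    auroc,
    cross_validated_auroc,
    design_matrix,
    fit_logistic,
    predict_probability,
    stratified_split,
)


def model_from_ors(ors: dict, intercept_or: float = 0.01) -> LogisticModel:
    """A what-if model assembled directly from odds ratios."""
    coefs = {t: np.log(v) for t, v in ors.items()}
    table = pd.DataFrame({
        "coef": pd.Series({"const": np.log(intercept_or), **coefs}),
    })
    table["se"] = 0.1
    table["or"] = np.exp(table["coef"])
    table["ci_low"] = np.exp(table["coef"] - 0.2)
    table["ci_high"] = np.exp(table["coef"] + 0.2)
    table["p"] = 0.05
    return LogisticModel(table=table, intercept=float(np.log(intercept_or)),
                         n=0, converged=True)


class TestStratifiedSplit:
    def test_study_scale_arithmetic(self):
        h = pd.DataFrame({"wvv": [True] * 580 + [False] * 124_111})
        dev, val = stratified_split(h, dev_fraction=0.75, seed=0)
        assert len(dev) == 93_519
        assert len(val) == 31_172
        assert int(val["wvv"].sum()) == 145  # 0.25 x 580, proportion kept

    def test_full_development_fraction(self):
        h = pd.DataFrame({"wvv": [True, False, False, False]})
        dev, val = stratified_split(h, dev_fraction=1.0, seed=0)
        assert len(val) == 0 and len(dev) == 4

    def test_partition_property_and_determinism(self, small_cohort):
        h, _ = small_cohort
        dev, val = stratified_split(h, 0.75, seed=5)
        assert len(dev) + len(val) == len(h)
        assert set(dev["woman_id"]).isdisjoint(val["woman_id"])
        dev2, val2 = stratified_split(h, 0.75, seed=5)
        pd.testing.assert_frame_equal(val, val2)
        # stratum proportions preserved to within one woman per stratum
        assert abs(val["wvv"].sum() - 0.25 * h["wvv"].sum()) <= 1

    def test_invalid_fraction(self):
        h = pd.DataFrame({"wvv": [True, False]})
        with pytest.raises(ValueError):
            stratified_split(h, dev_fraction=0.0)
        with pytest.raises(ValueError):
            stratified_split(h, dev_fraction=1.2)


class TestFitLogistic:
    def test_intercept_only_recovers_logit_prevalence(self, histories_factory):
        h = histories_factory([set()] * 200, wvv=[True] * 40 + [False] * 160)
        spec = ModelSpec(predictors=(), include_demographics=False)
        m = fit_logistic(h, spec)
        assert m.intercept == pytest.approx(logit(0.2), abs=1e-6)

    def test_matches_irls_reference(self):
        rng = np.random.default_rng(12)
        n = 800
        X = np.column_stack([np.ones(n), rng.random((n, 3)) < 0.3])
        beta = np.array([-1.0, 0.8, -0.5, 0.3])
        y = rng.random(n) < expit(X @ beta)
        h = pd.DataFrame({
            "infectious": X[:, 1].astype(bool),
            "psychoses": X[:, 2].astype(bool),
            "circulatory": X[:, 3].astype(bool),
            "wvv": y,
        })
        spec = ModelSpec(predictors=("infectious", "psychoses", "circulatory"),
                         include_demographics=False)
        m = fit_logistic(h, spec)
        D, yy = design_matrix(h, spec)
        ref = irls_logistic(D.to_numpy(), yy.astype(float))
        got = m.table["coef"].to_numpy()
        assert np.abs(got - ref).max() < 1e-6

    def test_single_class_outcome_raises(self, histories_factory):
        h = histories_factory([set()] * 10, wvv=[False] * 10)
        with pytest.raises(ModelError):
            fit_logistic(h, ModelSpec(predictors=(), include_demographics=False))

    def test_or_equals_exp_coef_and_ci_ordered(self, small_cohort):
        h, _ = small_cohort
        m = fit_logistic(h)
        assert np.allclose(m.table["or"], np.exp(m.table["coef"]))
        assert (m.table["ci_low"] <= m.table["ci_high"]).all()

    def test_one_seed_parameter_recovery(self):
        """Most generating log-odds fall inside their Wald intervals on a
        single study-scale replicate (full coverage sweep in acceptance)."""
        cfg = syn.default_config()
        h = syn.generate_histories(cfg, seed=0)
        m = fit_logistic(h)
        covered = sum(
            m.table.loc[t, "ci_low"] <= np.exp(b) <= m.table.loc[t, "ci_high"]
            for t, b in cfg.true_coefficients.items()
        )
        assert covered >= 14  # of 17 terms


class TestPredictProbability:
    def test_all_reference_profile(self):
        m = model_from_ors({"psychoses": 2.0})
        p = predict_probability(m, {"psychoses": 0})
        assert p == pytest.approx(0.01 / 1.01, abs=1e-12)

    def test_eta_zero_gives_half(self):
        m = model_from_ors({"psychoses": 100.0}, intercept_or=0.01)
        # intercept ln(0.01) + ln(100) = 0
        assert predict_probability(m, {"psychoses": 1}) == pytest.approx(0.5)

    def test_zero_coefficient_term_has_no_effect(self):
        m = model_from_ors({"psychoses": 2.0, "infectious": 1.0})
        a = predict_probability(m, {"psychoses": 1, "infectious": 0})
        b = predict_probability(m, {"psychoses": 1, "infectious": 1})
        assert a == pytest.approx(b)

    def test_missing_term_raises(self):
        m = model_from_ors({"psychoses": 2.0})
        with pytest.raises(KeyError):
            predict_probability(m, {})


class TestAuroc:
    def test_constant_scores_give_half(self):
        y = np.array([0, 1] * 20)
        assert auroc(y, np.ones(40)) == pytest.approx(0.5)

    def test_perfect_scores_give_one(self):
        y = np.array([0, 1] * 20)
        assert auroc(y, y.astype(float)) == pytest.approx(1.0)

    def test_matches_rank_oracle_and_monotone_invariance(self):
        rng = np.random.default_rng(8)
        y = rng.integers(0, 2, size=200)
        y[0], y[1] = 0, 1
        s = rng.normal(size=200)
        a = auroc(y, s)
        assert a == pytest.approx(rank_auroc(y, s), abs=1e-12)
        for f in (np.exp, lambda x: 3 * x + 7, np.arctan):
            assert auroc(y, f(s)) == pytest.approx(a, abs=1e-12)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            auroc(np.ones(5), np.arange(5))


class TestCrossValidatedAuroc:
    def test_stratified_cv_on_synthetic_cohort(self):
        cfg = syn.default_config(n_women=30_000)
        h = syn.generate_histories(cfg, seed=2)
        est = cross_validated_auroc(h, k=10, seed=1)
        assert len(est.per_fold) == 10
        assert est.ci_low <= est.estimate <= est.ci_high
        assert est.estimate > 0.55  # generating effects are discriminative

    def test_too_few_cases_raises(self, histories_factory):
        h = histories_factory([set()] * 50, wvv=[True] * 3 + [False] * 47)
        with pytest.raises(ValueError):
            cross_validated_auroc(h, k=10, seed=0)


def test_estimator_api_round_trip(small_cohort):
    h, _ = small_cohort
    est = ViolenceRiskModel().fit(h)
    proba = est.predict_proba(h)
    assert proba.shape == (len(h), 2)
    assert np.allclose(proba.sum(axis=1), 1.0)
    assert est.get_params()["include_demographics"]
    # monotone link between decision_function and probabilities
    df = est.decision_function(h.head(50))
    assert np.all(np.diff(proba[:50, 1][np.argsort(df)]) >= -1e-12)
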