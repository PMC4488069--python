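"""GLM engine: fits, AICc ranking, averaging, diagnostics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from lemna import glm


def loglik_oracle(beta, design, y):
    eta = design @ beta
    return float(np.sum(y * eta - np.log1p(np.exp(eta))))


def fit_by_generic_optimizer(design, y):
    """Independent oracle: direct Bernoulli log-likelihood maximization."""
    res = optimize.minimize(lambda b: -loglik_oracle(b, design, y),
                            np.zeros(design.shape[1]), method="BFGS",
                            options={"gtol": 1e-10, "maxiter": 500})
    return res.x, -res.fun


class TestFitLogistic:
    def test_intercept_only_closed_form(self):
        y = np.r_[np.ones(75), np.zeros(100)]
        fit = glm.fit_logistic(np.empty((175, 0)), y, ())
        assert fit.k == 1
        assert fit.coefficients[0] == pytest.approx(np.log(75 / 100), abs=1e-8)
        assert fit.loglik <= 0

    def test_single_binary_predictor_log_odds_ratio(self):
        # x=0: 30 present / 10 absent; x=1: 20 present / 40 absent.
        # Slope = log odds ratio = log((20/40) / (30/10)) = log(1/6).
        x = np.r_[np.zeros(40), np.ones(60)]
        y = np.r_[np.ones(30), np.zeros(10), np.ones(20), np.zeros(40)]
        fit = glm.fit_logistic(x[:, None], y, ("x",))
        assert fit.coefficient("x") == pytest.approx(np.log(1 / 6), abs=1e-6)
        assert fit.coefficient("intercept") == pytest.approx(np.log(3.0), abs=1e-6)

    def test_perfect_separation_flagged_not_fatal(self):
        x = np.r_[-np.ones(10), np.ones(10)]
        y = (x > 0).astype(float)
        fit = glm.fit_logistic(x[:, None], y, ("x",))
        assert fit.separation
        assert not fit.ok

    def test_matches_generic_optimizer(self, rng):
        for _ in range(5):
            n = 120
            X = rng.normal(size=(n, 3))
            beta_true = rng.normal(size=4)
            p = 1 / (1 + np.exp(-(beta_true[0] + X @ beta_true[1:])))
            y = (rng.random(n) < p).astype(float)
            fit = glm.fit_logistic(X, y)
            if not fit.ok:
                continue
            beta_hat, ll = fit_by_generic_optimizer(fit.design, y)
            assert np.allclose(fit.coefficients, beta_hat, atol=1e-6)
            assert fit.loglik == pytest.approx(ll, abs=1e-6)


class TestAicc:
    def test_worked_example(self):
        assert glm.aicc(-10.0, 2, 100) == pytest.approx(24 + 12 / 97)

    def test_small_sample_correction_term(self):
        # k=1, n=3: correction 2*1*2/1 = 4 on top of AIC
        assert glm.aicc(0.0, 1, 3) == pytest.approx(2 + 4)

    def test_correction_shrinks_with_n(self):
        gaps = [glm.aicc(-5, 3, n) - (-2 * -5 + 2 * 3) for n in (10, 50, 500)]
        assert gaps[0] > gaps[1] > gaps[2] > 0

    def test_undefined_when_n_too_small(self):
        with pytest.raises(ValueError):
            glm.aicc(-5, 3, 4)


@pytest.fixture(scope="module")
def data():
    rng = np.random.default_rng(77)
    n = 300
    X = pd.DataFrame(rng.uniform(size=(n, 3)), columns=["a", "b", "c"])
    p = 1 / (1 + np.exp(-(-1 + 3.0 * X["a"])))
    y = (rng.random(n) < p).astype(float)
    return X, y


class TestAllSubsets:
    def test_enumerates_all_subsets(self, data):
        X, y = data
        models = glm.all_subsets(X, y)
        assert len(models) == 8
        seen = {frozenset(m.fit.predictors) for m in models}
        expect = {frozenset(s) for r in range(4)
                  for s in itertools.combinations("abc", r)}
        assert seen == expect

    def test_best_model_has_zero_delta_and_max_weight(self, data):
        X, y = data
        models = glm.all_subsets(X, y)
        assert models[0].delta == 0
        assert models[0].weight == max(m.weight for m in models)
        assert sum(m.weight for m in models) == pytest.approx(1.0)

    def test_true_predictor_in_top_model(self):
        rng = np.random.default_rng(123)
        n = 2000
        X = pd.DataFrame(rng.uniform(size=(n, 2)), columns=["x1", "x2"])
        p = 1 / (1 + np.exp(-(-2 + 5.0 * X["x1"])))
        y = (rng.random(n) < p).astype(float)
        models = glm.all_subsets(X, y)
        assert "x1" in models[0].fit.predictors

    def test_guard_against_explosive_enumeration(self):
        X = pd.DataFrame(np.zeros((30, 21)),
                         columns=[f"v{i}" for i in range(21)])
        with pytest.raises(ValueError, match="max_predictors"):
            glm.all_subsets(X, np.zeros(30))

    def test_weights_invariant_to_aicc_shift(self, data):
        # shifting every AICc by a constant leaves weights unchanged
        X, y = data
        models = glm.all_subsets(X, y)
        deltas = np.array([m.delta for m in models])
        w = np.exp(-deltas / 2) / np.exp(-deltas / 2).sum()
        w_shift = np.exp(-(deltas + 7.3) / 2)
        w_shift /= w_shift.sum()
        assert np.allclose(w, w_shift)
        assert np.allclose(w, [m.weight for m in models])


class TestCandidateSet:
    def _mock(self, deltas):
        raw = np.exp(-np.asarray(deltas) / 2)
        w = raw / raw.sum()
        out = []
        for i, (d, wi) in enumerate(zip(deltas, w)):
            fit = glm.FitResult(predictors=(f"t{i}",), coefficients=np.zeros(2),
                                standard_errors=np.zeros(2), loglik=-1.0, k=2,
                                n=50, fitted=np.full(50, 0.5), converged=True,
                                separation=False, design=np.zeros((50, 2)),
                                response=np.zeros(50))
            out.append(glm.CandidateModel(fit=fit, aicc=100 + d, delta=d,
                                          weight=wi, index=i))
        return out

    def test_single_model_keeps_weight_one(self):
        kept = glm.candidate_set(self._mock([0.0]))
        assert len(kept) == 1 and kept[0].weight == pytest.approx(1.0)

    def test_strict_inequality_at_boundary(self):
        kept = glm.candidate_set(self._mock([0.0, 2.0]), delta_max=2.0)
        assert len(kept) == 1

    def test_two_model_weights_renormalized(self):
        kept = glm.candidate_set(self._mock([0.0, 1.0]))
        expect0 = 1 / (1 + np.exp(-0.5))
        assert kept[0].weight == pytest.approx(expect0, abs=1e-12)
        assert kept[1].weight == pytest.approx(1 - expect0, abs=1e-12)


def _candidate(predictors_, coefs, ses, weight, index=0):
    k = len(coefs)
    fit = glm.FitResult(predictors=tuple(predictors_),
                        coefficients=np.asarray(coefs, float),
                        standard_errors=np.asarray(ses, float),
                        loglik=-1.0, k=k, n=100, fitted=np.full(100, 0.5),
                        converged=True, separation=False,
                        design=np.zeros((100, k)), response=np.zeros(100))
    return glm.CandidateModel(fit=fit, aicc=0.0, delta=0.0, weight=weight,
                              index=index)


class TestModelAverage:
    def test_single_candidate_is_identity(self):
        c = _candidate(("a",), [0.5, 2.0], [0.1, 0.3], 1.0)
        avg = glm.model_average([c])
        assert avg.full["a"] == pytest.approx(2.0)
        assert avg.conditional["a"] == pytest.approx(2.0)
        assert avg.se_full["a"] == pytest.approx(0.3)
        assert avg.importance["a"] == pytest.approx(1.0)

    def test_equal_weight_hand_computation(self):
        # term in both models, beta 1 and 3, SE 0 -> mean 2, SE = 1
        c1 = _candidate(("a",), [0.0, 1.0], [0.0, 0.0], 0.5, 0)
        c2 = _candidate(("a",), [0.0, 3.0], [0.0, 0.0], 0.5, 1)
        avg = glm.model_average([c1, c2])
        assert avg.full["a"] == pytest.approx(2.0)
        assert avg.se_full["a"] == pytest.approx(1.0)
        assert avg.se_conditional["a"] == pytest.approx(1.0)

    def test_term_in_one_model_full_vs_conditional(self):
        c1 = _candidate(("a",), [0.0, 2.0], [0.0, 0.0], 0.5, 0)
        c2 = _candidate((), [0.0], [0.0], 0.5, 1)
        avg = glm.model_average([c1, c2])
        assert avg.conditional["a"] == pytest.approx(2.0)
        assert avg.full["a"] == pytest.approx(1.0)
        assert avg.importance["a"] == pytest.approx(0.5)
        # full-variant SE gets a zero pseudo-entry: 0.5*|2-1| + 0.5*|0-1| = 1
        assert avg.se_full["a"] == pytest.approx(1.0)


class TestPredictAverage:
    def test_single_member_reproduces_fitted(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame({"a": rng.uniform(size=80)})
        y = (rng.random(80) < 0.4).astype(float)
        fit = glm.fit_logistic(X, y)
        cand = glm.CandidateModel(fit=fit, aicc=0, delta=0, weight=1.0, index=0)
        avg = glm.model_average([cand])
        p = glm.predict_average(avg, X)
        assert np.allclose(p, fit.fitted, atol=1e-9)

    def test_two_member_probability_arithmetic(self):
        # members predicting 0.2 and 0.6 with equal weight -> 0.4
        X = pd.DataFrame({"a": [0.0]})
        c1 = _candidate(("a",), [np.log(0.2 / 0.8), 0.0], [0, 0], 0.5, 0)
        c2 = _candidate(("a",), [np.log(0.6 / 0.4), 0.0], [0, 0], 0.5, 1)
        avg = glm.model_average([c1, c2])
        assert glm.predict_average(avg, X)[0] == pytest.approx(0.4)

    def test_probabilities_in_unit_interval_both_modes(self, rng):
        X = pd.DataFrame({"a": rng.uniform(size=60), "b": rng.uniform(size=60)})
        y = (rng.random(60) < 0.5).astype(float)
        cand = glm.candidate_set(glm.all_subsets(X, y))
        avg = glm.model_average(cand)
        for mode in ("mean_probability", "coefficients"):
            p = glm.predict_average(avg, X, mode)
            assert np.all((p > 0) & (p < 1))

    def test_missing_column_rejected(self):
        c = _candidate(("a",), [0.0, 1.0], [0, 0], 1.0)
        avg = glm.model_average([c])
        with pytest.raises(KeyError):
            glm.predict_average(avg, pd.DataFrame({"b": [1.0]}))


class TestCooksDistance:
    def test_balanced_duplicated_design_equal_distances(self):
        x = np.r_[np.zeros(20), np.ones(20)]
        y = np.r_[np.tile([0, 1], 10), np.tile([0, 1], 10)].astype(float)
        fit = glm.fit_logistic(x[:, None], y, ("x",))
        d = glm.cooks_distance(fit)
        assert d.min() >= 0
        assert np.allclose(d, d[0])

    def test_gross_outlier_has_max_distance(self, rng):
        x = np.linspace(0, 1, 60)
        p = 1 / (1 + np.exp(-(-2 + 4 * x)))
        y = (rng.random(60) < p).astype(float)
        y[0] = 1.0  # improbable success at the low end
        y[1:10] = 0.0
        fit = glm.fit_logistic(x[:, None], y, ("x",))
        d = glm.cooks_distance(fit)
        assert np.argmax(d) == 0


class TestPseudoR2:
    def _fits(self, ll1, ll0, n):
        mk = lambda ll, k: glm.FitResult(
            predictors=tuple(f"t{i}" for i in range(k - 1)),
            coefficients=np.zeros(k), standard_errors=np.zeros(k), loglik=ll,
            k=k, n=n, fitted=np.full(n, 0.5), converged=True, separation=False,
            design=np.zeros((n, k)), response=np.zeros(n))
        return mk(ll1, 3), mk(ll0, 1)

    def test_worked_example(self):
        fit, null = self._fits(-90.0, -121.3, 175)
        assert glm.pseudo_r2(fit, null, "cox_snell") == pytest.approx(
            1 - np.exp(-2 * 31.3 / 175), abs=1e-9)

    def test_identical_fit_gives_zero_and_nagelkerke_dominates(self):
        fit, null = self._fits(-100.0, -100.0, 150)
        assert glm.pseudo_r2(fit, null, "cox_snell") == 0.0
        fit2, null2 = self._fits(-80.0, -100.0, 150)
        assert (glm.pseudo_r2(fit2, null2, "nagelkerke")
                >= glm.pseudo_r2(fit2, null2, "cox_snell"))

    def test_worse_than_null_warns(self):
        fit, null = self._fits(-105.0, -100.0, 150)
        with pytest.warns(UserWarning):
            assert glm.pseudo_r2(fit, null, "cox_snell") < 0
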