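"""AICc ranking, confidence sets, model averaging and the VIF screen."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from seedscape.inference import (
    confidence_set,
    enumerate_models,
    fit_and_rank,
    model_average,
    run_inference,
    vif_screen,
)
from seedscape.types import CandidateModel, ConfigError, GlobalModelSpec


def toy_data(rng, n=16, k=3, beta=None, noise=0.5):
    X = pd.DataFrame(
        rng.normal(size=(n, k)), columns=[f"x{j}" for j in range(k)]
    )
    if beta is None:
        beta = (1.0,) + (0.0,) * (k - 1)
    y = X.to_numpy() @ np.asarray(beta) + noise * rng.normal(size=n)
    return X, y


class TestVifScreen:
    def test_orthogonal_predictors_vif_one(self):
        X = pd.DataFrame({"a": [1.0, -1, 1, -1, 1, -1], "b": [1.0, 1, -1, -1, 1, -1]})
        # nearly orthogonal design
        vifs = vif_screen(X)
        assert (vifs < 1.5).all()

    def test_duplicate_predictor_flagged_infinite(self, rng):
        a = rng.normal(size=10)
        X = pd.DataFrame({"a": a, "b": a})
        vifs = vif_screen(X)
        assert np.isinf(vifs).all()

    def test_known_correlation_hand_value(self, rng):
        # VIF_j = 1/(1 - R2_j) from the auxiliary regression
        X, _ = toy_data(rng, n=40)
        X["x1"] = 0.8 * X["x0"] + 0.6 * rng.normal(size=40)
        vifs = vif_screen(X)
        for j, col in enumerate(X.columns):
            aux = sm.OLS(
                X[col], sm.add_constant(X.drop(columns=col))
            ).fit()
            assert vifs[col] == pytest.approx(1 / (1 - aux.rsquared), rel=1e-8)


class TestEnumerateModels:
    @pytest.mark.parametrize("k,expected", [(0, 1), (2, 4), (3, 8)])
    def test_subset_counts_include_null(self, k, expected):
        terms = tuple(f"t{j}" for j in range(k))
        models = enumerate_models(terms)
        assert len(models) == expected
        assert models[0].terms == ()

    def test_deterministic_order(self):
        assert [m.terms for m in enumerate_models(("a", "b"))] == [
            (), ("a",), ("b",), ("a", "b")
        ]


class TestFitAndRank:
    def test_weights_sum_to_one_and_deltas_ordered(self, rng):
        X, y = toy_data(rng)
        ranked = fit_and_rank(enumerate_models(tuple(X.columns)), y, X)
        w = [c.weight for c in ranked]
        assert sum(w) == pytest.approx(1.0, abs=1e-12)
        assert ranked[0].delta == 0.0
        assert all(a.aicc <= b.aicc for a, b in zip(ranked, ranked[1:]))

    def test_delta_two_weight_ratio(self):
        # two models with delta (0, 2): weights exp(0), exp(-1) normalized
        w0 = 1 / (1 + np.exp(-1))
        assert round(w0, 4) == 0.7311
        a = CandidateModel(terms=("a",), aicc=10.0, weight=w0, delta=0.0)
        b = CandidateModel(terms=("b",), aicc=12.0, weight=1 - w0, delta=2.0)
        kept = confidence_set([a, b])
        assert len(kept) == 2  # 0.7311 < 0.95 so both enter

    def test_duplicate_candidates_share_weight(self, rng):
        X, y = toy_data(rng)
        cands = enumerate_models(("x0",)) + [CandidateModel(terms=("x0",))]
        ranked = fit_and_rank(cands, y, X)
        dup = [c for c in ranked if c.terms == ("x0",)]
        assert len(dup) == 2
        assert dup[0].weight == pytest.approx(dup[1].weight, rel=1e-12)

    def test_aicc_matches_hand_formula(self, rng):
        X, y = toy_data(rng, k=2)
        ranked = fit_and_rank(enumerate_models(tuple(X.columns)), y, X)
        n = len(y)
        for c in ranked:
            Xd = sm.add_constant(X[list(c.terms)].to_numpy(), has_constant="add")
            fit = sm.OLS(y, Xd).fit()
            k = Xd.shape[1] + 1
            want = -2 * fit.llf + 2 * k + 2 * k * (k + 1) / (n - k - 1)
            assert c.aicc == pytest.approx(want, rel=1e-12)

    def test_aicc_converges_to_aic(self):
        # correction term 2k(k+1)/(n-k-1) vanishes for large n
        k, n = 4, 10**6
        assert 2 * k * (k + 1) / (n - k - 1) < 1e-3

    def test_oversized_candidate_skipped(self, rng):
        X, y = toy_data(rng, n=5, k=3)
        ranked = fit_and_rank(enumerate_models(tuple(X.columns)), y, X)
        assert all(len(c.terms) < 3 for c in ranked)

    def test_null_wins_on_pure_noise_majority(self, rng):
        wins = 0
        reps = 100
        for _ in range(reps):
            X, _ = toy_data(rng)
            y = rng.normal(size=16)
            ranked = fit_and_rank(enumerate_models(tuple(X.columns)), y, X)
            wins += any(c.terms == () and c.best_supported for c in ranked)
        assert wins > reps / 2


class TestConfidenceSet:
    def mk(self, weights):
        return [
            CandidateModel(terms=(f"t{i}",), weight=w, delta=float(i))
            for i, w in enumerate(weights)
        ]

    def test_dominant_best_model_alone(self):
        assert len(confidence_set(self.mk([0.97, 0.03]))) == 1

    def test_uniform_weights_need_everything(self):
        assert len(confidence_set(self.mk([1 / 8] * 8))) == 8

    def test_hand_cumulative_walk(self):
        assert len(confidence_set(self.mk([0.5, 0.3, 0.15, 0.05]))) == 3

    def test_never_empty(self):
        assert len(confidence_set(self.mk([1.0]))) == 1


class TestModelAverage:
    def test_single_model_passthrough(self, rng):
        X, y = toy_data(rng, k=1)
        ranked = fit_and_rank(enumerate_models(("x0",)), y, X)
        only = [c for c in ranked if c.terms == ("x0",)]
        est = model_average(only)[0]
        assert est.coefficient == pytest.approx(only[0].coef["x0"])
        assert est.use == pytest.approx(only[0].se["x0"])
        assert est.importance == 1.0

    def test_full_averaging_zero_substitution(self):
        with_term = CandidateModel(
            terms=("j",), weight=0.5, coef={"j": 1.0}, se={"j": 0.0}
        )
        without = CandidateModel(terms=(), weight=0.5, coef={}, se={})
        est = model_average([with_term, without])[0]
        # absent model contributes beta = 0: average is 0.5
        assert est.coefficient == pytest.approx(0.5)
        assert est.importance == pytest.approx(0.5)
        # USE = 0.5*sqrt(0 + 0.25) + 0.5*sqrt(0 + 0.25) = 0.5
        assert est.use == pytest.approx(0.5)
        assert not est.influential  # 0.5 +/- 0.5 touches zero

    def test_term_absent_everywhere_ignored(self):
        m = CandidateModel(terms=("a",), weight=1.0, coef={"a": 2.0}, se={"a": 0.1})
        ests = model_average([m])
        assert [e.term for e in ests] == ["a"]

    def test_averaged_magnitude_bounded(self, rng):
        X, y = toy_data(rng, beta=(1.2, 0.4, 0.0))
        ranked = fit_and_rank(enumerate_models(tuple(X.columns)), y, X)
        ests = model_average(confidence_set(ranked))
        for e in ests:
            biggest = max(
                abs(c.coef.get(e.term, 0.0)) for c in confidence_set(ranked)
            )
            assert abs(e.coefficient) <= biggest + 1e-12

    def test_duplicate_candidate_invariance(self, rng):
        # an exact copy that symmetrically splits the original's weight must
        # leave every averaged coefficient and USE unchanged
        import copy

        X, y = toy_data(rng)
        ranked = fit_and_rank(enumerate_models(tuple(X.columns)), y, X)
        ests1 = {e.term: (e.coefficient, e.use) for e in model_average(ranked)}
        half = copy.deepcopy(ranked[0])
        half.weight /= 2
        twin = copy.deepcopy(half)
        ests2 = {
            e.term: (e.coefficient, e.use)
            for e in model_average([half, twin] + list(ranked[1:]))
        }
        for t, (coef, use) in ests1.items():
            assert ests2[t][0] == pytest.approx(coef, rel=1e-12)
            assert ests2[t][1] == pytest.approx(use, rel=1e-12)


class TestRunInference:
    def metric_df(self, rng, n=16):
        rows = []
        vals = {}
        for m, r in (("AI", 600.0), ("PI", 1200.0), ("SF", 600.0)):
            vals[(m, r)] = rng.normal(size=n)
            for i in range(n):
                rows.append(
                    {"patch_id": f"p{i:02d}", "radius_m": r, "metric": m,
                     "value": vals[(m, r)][i]}
                )
        return pd.DataFrame(rows), vals

    def test_three_term_global_model_eight_candidates(self, rng):
        met, vals = self.metric_df(rng)
        y = vals[("AI", 600.0)] * 1.0 + 0.3 * rng.normal(size=16)
        div = pd.DataFrame({"patch_id": [f"p{i:02d}" for i in range(16)], "resp": y})
        spec = GlobalModelSpec("resp", (("AI", 600.0), ("PI", 1200.0), ("SF", 600.0)))
        rep = run_inference([spec], div, met)[0]
        assert rep.aborted is None
        assert len(rep.ranking) == 8
        drv = {e.term: e for e in rep.averaged}["AI_600"]
        assert drv.importance > 0.8 and drv.influential

    def test_collinear_global_model_aborts(self, rng):
        met, vals = self.metric_df(rng)
        dup = met[met["metric"] == "AI"].copy()
        dup["metric"] = "FC"
        met = pd.concat([met, dup], ignore_index=True)
        y = rng.normal(size=16)
        div = pd.DataFrame({"patch_id": [f"p{i:02d}" for i in range(16)], "resp": y})
        spec = GlobalModelSpec("resp", (("AI", 600.0), ("FC", 600.0)))
        rep = run_inference([spec], div, met)[0]
        assert rep.aborted is not None and "VIF" in rep.aborted
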