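"""Logistic models, cross-validation, permutation, relative weights."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from alphaconvert import predict
from alphaconvert.exceptions import ClassError, DegenerateOutcomeError, PairingError
from alphaconvert.predict import (
    CVResult,
    _fit_binary,
    _johnson_weights,
    compare_models,
    cv_leave10out,
    fit_logistic,
    permutation_test,
    relative_weights,
    roc_auc,
    stepwise_lr,
    youden_cutoff,
)


def _table(rng, n=34, effect=0.0, n_noise=1, balance=0.5):
    y = (rng.random(n) < balance).astype(int)
    cols = {"converter": y}
    cols["x"] = effect * y + rng.standard_normal(n)
    for j in range(n_noise):
        cols[f"noise{j}"] = rng.standard_normal(n)
    cols["icv"] = rng.normal(1.45e6, 1.4e5, n)
    return pd.DataFrame(cols)


class TestFitLogistic:
    def test_matches_statsmodels_oracle(self, rng):
        import statsmodels.api as sm

        t = _table(rng, n=120, effect=1.0)
        m = fit_logistic(t, ["x"], ["icv"])
        X = sm.add_constant(t[["icv", "x"]].to_numpy())
        sm_fit = sm.Logit(t["converter"], X).fit(disp=0)
        assert m.coefficients["x"] == pytest.approx(sm_fit.params[2], rel=1e-5, abs=1e-6)
        assert m.deviance == pytest.approx(-2 * sm_fit.llf, rel=1e-8)
        # lr_chi2 against the nuisance-only statsmodels fit
        red = sm.Logit(t["converter"], sm.add_constant(t[["icv"]].to_numpy())).fit(disp=0)
        assert m.lr_chi2 == pytest.approx(2 * (sm_fit.llf - red.llf), rel=1e-6, abs=1e-8)

    def test_deviance_matches_likelihood_grid(self, rng):
        # 8-row toy problem: refine a brute-force (intercept, slope) grid
        t = _table(rng, n=8, effect=0.8)
        m = fit_logistic(t, ["x"])
        y = t["converter"].to_numpy(float)
        x = t["x"].to_numpy()

        def dev(b0, b1):
            mu = 1 / (1 + np.exp(-(b0 + b1 * x)))
            mu = np.clip(mu, 1e-12, 1 - 1e-12)
            return -2 * np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu))

        c0, c1, w = 0.0, 0.0, 8.0
        for _ in range(8):  # successive grid refinement
            grid0 = np.linspace(c0 - w, c0 + w, 41)
            grid1 = np.linspace(c1 - w, c1 + w, 41)
            devs = [(dev(a, b), a, b) for a in grid0 for b in grid1]
            _, c0, c1 = min(devs)
            w /= 8.0
        assert m.deviance == pytest.approx(dev(c0, c1), abs=1e-4)

    def test_constant_label_raises(self, rng):
        t = _table(rng, n=12)
        t["converter"] = 1
        with pytest.raises(DegenerateOutcomeError):
            fit_logistic(t, ["x"])

    def test_null_predictor_lr_is_small(self, rng):
        t = _table(rng, n=200, effect=0.0)
        m = fit_logistic(t, ["noise0"])
        assert m.lr_chi2 < 8.0  # chi2(1) 99.5th percentile
        assert m.p > 0.001

    def test_separated_data_uses_firth_fallback(self):
        t = pd.DataFrame({"converter": [0, 0, 0, 0, 1, 1, 1, 1], "x": [-4.0, -3, -2, -1, 1, 2, 3, 4]})
        with pytest.warns(UserWarning, match="separation"):
            m = fit_logistic(t, ["x"])
        assert m.firth
        assert np.isfinite(m.coefficients["x"])


class TestStepwise:
    def test_selects_planted_predictor_among_noise(self):
        picks = 0
        n_rep = 20
        for k in range(n_rep):
            rng = np.random.default_rng(1000 + k)
            t = _table(rng, n=60, effect=2.0, n_noise=5)
            m = stepwise_lr(t, ["x"] + [f"noise{j}" for j in range(5)])
            picks += m.selected == ["x"] or (m.selected and m.selected[0] == "x")
        assert picks >= 0.9 * n_rep

    def test_duplicate_predictor_enters_once(self, rng):
        t = _table(rng, n=60, effect=2.0)
        t["x_copy"] = t["x"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = stepwise_lr(t, ["x", "x_copy"])
        assert sorted(m.selected) in (["x"], ["x_copy"], [["x"]], [["x_copy"]]) or len(m.selected) == 1

    def test_null_candidates_rarely_enter(self):
        entries = []
        for k in range(40):
            rng = np.random.default_rng(2000 + k)
            t = _table(rng, n=40, effect=0.0, n_noise=4)
            m = stepwise_lr(t, [f"noise{j}" for j in range(4)])
            entries.append(len(m.selected))
        # expected false entries per run ~ 4 * 0.05
        assert np.mean(entries) < 0.8


class TestROC:
    def test_perfect_separation(self):
        assert roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1]) == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc([5, 5, 5, 5], [0, 1, 0, 1]) == 0.5

    def test_matches_mann_whitney(self, rng):
        scores = rng.standard_normal(14)
        labels = np.array([0] * 8 + [1] * 6)
        u = stats.mannwhitneyu(scores[labels == 1], scores[labels == 0], alternative="two-sided")
        assert roc_auc(scores, labels) == pytest.approx(u.statistic / (8 * 6))

    def test_complement_symmetry(self, rng):
        scores = rng.standard_normal(20)
        labels = (rng.random(20) < 0.4).astype(int)
        labels[0], labels[1] = 0, 1
        assert roc_auc(scores, labels) + roc_auc(-scores, labels) == pytest.approx(1.0)

    def test_single_class_raises(self):
        with pytest.raises(ClassError):
            roc_auc([1.0, 2.0], [1, 1])


class TestYouden:
    def test_perfect_separation_j_is_one(self):
        res = youden_cutoff([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert res["J"] == pytest.approx(1.0)
        assert res["sensitivity"] == 1.0 and res["specificity"] == 1.0

    def test_matches_roc_curve_oracle(self, rng):
        from sklearn.metrics import roc_curve

        scores = rng.standard_normal(30)
        labels = (rng.random(30) < 0.5).astype(int)
        labels[:2] = [0, 1]
        res = youden_cutoff(scores, labels)
        fpr, tpr, _ = roc_curve(labels, scores)
        assert res["J"] == pytest.approx(np.max(tpr - fpr), abs=1e-12)
        # J is the maximum vertical ROC-diagonal distance

    def test_j_from_reported_sens_spec(self):
        res = youden_cutoff([0.1, 0.3, 0.35, 0.4, 0.6, 0.7, 0.8, 0.9, 0.2, 0.75],
                            [0, 0, 0, 0, 1, 1, 1, 1, 0, 1])
        assert res["J"] == pytest.approx(res["sensitivity"] + res["specificity"] - 1.0)


class TestCV:
    def test_separable_data_gives_high_auc(self, rng):
        t = _table(rng, n=34, effect=6.0)
        res = cv_leave10out(t, ["x"], seed=0)
        assert len(res.rounds) == 34
        assert res.mean_auc > 0.95
        for r in res.rounds:
            for k in ("auc", "accuracy", "sensitivity", "specificity"):
                assert 0.0 <= r[k] <= 1.0

    def test_null_labels_give_chance_auc(self):
        aucs = []
        for k in range(15):
            rng = np.random.default_rng(3000 + k)
            t = _table(rng, n=34, effect=0.0)
            aucs.append(cv_leave10out(t, ["x"], n_rounds=20, seed=k).mean_auc)
        assert abs(np.mean(aucs) - 0.5) < 0.08

    def test_reproducible_under_seed(self, rng):
        t = _table(rng, n=34, effect=1.0)
        a = cv_leave10out(t, ["x"], seed=5)
        b = cv_leave10out(t, ["x"], seed=5)
        assert a.rounds == b.rounds


class TestPermutation:
    def test_p_floor_when_observed_beats_all(self, rng):
        t = _table(rng, n=34, effect=6.0)
        res = permutation_test(t, ["x"], n_perm=100, n_rounds=10, seed=0)
        assert res.p == pytest.approx(1 / 101)
        assert res.q95 <= res.observed

    def test_q95_within_null_range(self, rng):
        t = _table(rng, n=34, effect=0.5)
        res = permutation_test(t, ["x"], n_perm=60, n_rounds=8, seed=1)
        assert res.null_stats.min() <= res.q95 <= res.null_stats.max()


class TestRelativeWeights:
    def test_single_predictor_is_total(self, rng):
        t = _table(rng, n=60, effect=1.5)
        res = relative_weights(t, ["x"], n_boot=50, seed=0)
        assert res.percent["x"] == pytest.approx(100.0)

    def test_symmetric_predictors_split_evenly(self):
        rng = np.random.default_rng(7)
        n = 400
        a = rng.standard_normal(n)
        b = rng.standard_normal(n)
        eta = a + b
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        t = pd.DataFrame({"converter": y, "a": a, "b": b})
        res = relative_weights(t, ["a", "b"], n_boot=50, seed=0)
        assert res.percent["a"] == pytest.approx(50.0, abs=6.0)

    def test_matches_dominance_analysis_oracle(self):
        # general dominance: average incremental McFadden R^2 over all orderings
        rng = np.random.default_rng(42)
        n = 120
        L = np.array([[1.0, 0, 0], [0.3, 1.0, 0], [0.1, 0.2, 1.0]])
        X = rng.standard_normal((n, 3)) @ L.T
        eta = 0.9 * X[:, 0] + 0.6 * X[:, 1] + 0.3 * X[:, 2] - 0.1
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)

        def r2(subset):
            Xd = np.column_stack([np.ones(n)] + [X[:, j] for j in subset])
            _, dev, _ = _fit_binary(Xd, y)
            _, dev0, _ = _fit_binary(np.ones((n, 1)), y)
            return 1.0 - dev / dev0

        gd = np.zeros(3)
        for j in range(3):
            others = [k for k in range(3) if k != j]
            by_size = {}
            for r in range(3):
                for S in itertools.combinations(others, r):
                    inc = r2(list(S) + [j]) - r2(list(S))
                    by_size.setdefault(r, []).append(inc)
            gd[j] = np.mean([np.mean(v) for v in by_size.values()])
        dominance_pct = 100 * gd / gd.sum()

        w = _johnson_weights(X, y)
        johnson_pct = 100 * w / w.sum()
        assert np.abs(johnson_pct - dominance_pct).max() < 2.0

    def test_bca_interval_brackets_point(self, rng):
        t = _table(rng, n=80, effect=1.5, n_noise=1)
        res = relative_weights(t, ["x", "noise0"], n_boot=200, seed=0)
        for name in ("x", "noise0"):
            lo, hi = res.ci_percent[name]
            assert lo <= res.percent[name] <= hi
        assert sum(res.percent.values()) == pytest.approx(100.0)


class TestCompareModels:
    def _cv(self, aucs, accs=None):
        accs = accs if accs is not None else aucs
        return CVResult(rounds=[{"auc": a, "accuracy": c} for a, c in zip(aucs, accs)])

    def test_identical_models_give_zero_chi2(self):
        r = [0.7, 0.8, 0.75, 0.9, 0.6, 0.85]
        out = compare_models({"m1": self._cv(r), "m2": self._cv(r), "m3": self._cv(r)})
        assert out["auc"]["friedman"]["chi2"] == 0.0
        for v in out["auc"]["pairwise"].values():
            assert v["p_bonferroni"] == 1.0

    def test_matches_rank_formula_on_3x6_table(self, rng):
        mat = rng.random((6, 3))
        cvs = {f"m{j}": self._cv(mat[:, j]) for j in range(3)}
        out = compare_models(cvs, metrics=("auc",))
        ranks = np.apply_along_axis(stats.rankdata, 1, mat)
        R = ranks.sum(axis=0)
        n, k = 6, 3
        chi2_oracle = 12.0 / (n * k * (k + 1)) * np.sum(R**2) - 3 * n * (k + 1)
        assert out["auc"]["friedman"]["chi2"] == pytest.approx(chi2_oracle, rel=1e-9)

    def test_bonferroni_factor_is_number_of_pairs(self, rng):
        mat = rng.random((8, 3))
        cvs = {f"m{j}": self._cv(mat[:, j]) for j in range(3)}
        out = compare_models(cvs, metrics=("auc",))
        for (a, b) in itertools.combinations(cvs, 2):
            raw = stats.wilcoxon(
                [r["auc"] for r in cvs[a].rounds], [r["auc"] for r in cvs[b].rounds],
                zero_method="wilcox",
            ).pvalue
            assert out["auc"]["pairwise"][(a, b)]["p_bonferroni"] == pytest.approx(
                min(1.0, raw * 3), rel=1e-12
            )

    def test_unequal_rounds_raise(self):
        with pytest.raises(PairingError):
            compare_models({"a": self._cv([0.5, 0.6]), "b": self._cv([0.5, 0.6, 0.7])})
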