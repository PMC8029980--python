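"""LOOCV-LDA panel scoring, exhaustive search, elbow selection."""

import numpy as np
import pandas as pd
import pytest
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from scipy.special import expit

import histoplex as hp
from histoplex.panel import CytokinePanelLDA, _panel_scores, _prepare
from histoplex.simulate import CytokineSimConfig


def _sim(seed, n_per_group=6, informative=("IFNg",), effect=3.0, markers=None):
    cfg = CytokineSimConfig(
        seed=seed, n_per_group=n_per_group, informative_set=list(informative),
        effect_size=effect, markers=markers or list(hp.vocab.CYTOKINES),
    )
    return hp.simulate_cytokines(cfg)


class TestLoocvLda:
    def test_perfect_separation(self):
        X = pd.DataFrame({"m": [-10.0, -11.0, 10.0, 11.0]})
        acc, resid, w = hp.loocv_lda(X, ["neg", "neg", "pos", "pos"], ["m"])
        assert acc == 1.0
        assert resid < 0.5
        assert w["m"] > 0

    def test_matches_sklearn_fold_by_fold(self):
        """Closed-form discriminant equals scikit-learn's LDA (lsqr solver,
        equal priors) on every LOOCV fold: decisions and posteriors."""
        rng = np.random.default_rng(42)
        for _ in range(3):
            n, m = 12, 4
            X = rng.normal(size=(n, m))
            X[6:, :2] += 1.5
            y = np.array([0] * 6 + [1] * 6)
            cache = _prepare(X, y, normalize="fold", ridge=0.0)
            scores = _panel_scores(cache, np.arange(m))
            for i in range(n):
                tr = np.ones(n, bool)
                tr[i] = False
                mu, sd = X[tr].mean(0), X[tr].std(0)
                Z = (X - mu) / sd
                lda = LinearDiscriminantAnalysis(solver="lsqr", priors=[0.5, 0.5])
                lda.fit(Z[tr], y[tr])
                assert scores[i] == pytest.approx(
                    lda.decision_function(Z[i : i + 1])[0], abs=1e-8
                )
                assert expit(scores[i]) == pytest.approx(
                    lda.predict_proba(Z[i : i + 1])[0, 1], abs=1e-8
                )

    def test_uninformative_data_near_chance(self):
        """effect_size = 0: mean LOOCV accuracy over replicates ~ 1/2."""
        accs = []
        for rep in range(100):
            X, g = _sim(rep, n_per_group=4, informative=(), effect=0.0,
                        markers=["IFNg", "IL6"])
            acc, _, _ = hp.loocv_lda(X, g, ["IFNg", "IL6"])
            accs.append(acc)
        assert np.mean(accs) == pytest.approx(0.5, abs=0.1)

    def test_fold_normalization_has_no_leakage(self):
        """Changing the held-out sample never changes that fold's training
        statistics, hence never its discriminant."""
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 3))
        y = np.array([0] * 5 + [1] * 5)
        cache = _prepare(X, y)
        X2 = X.copy()
        X2[4] += 100.0  # move one sample far away
        cache2 = _prepare(X2, y)
        # fold 4 (holding sample 4 out) must agree in its training pieces
        np.testing.assert_allclose(cache.sigma[4], cache2.sigma[4])
        np.testing.assert_allclose(cache.mean_diff[4], cache2.mean_diff[4])

    def test_empty_class_fold_raises(self):
        X = pd.DataFrame({"m": [0.0, 1.0, 2.0]})
        with pytest.raises(ValueError, match="2 samples"):
            hp.loocv_lda(X, ["a", "a", "b"], ["m"])

    def test_unknown_panel_marker_raises(self):
        X = pd.DataFrame({"m": [0.0, 1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="absent"):
            hp.loocv_lda(X, ["a", "a", "b", "b"], ["nope"])


class TestExhaustiveSearch:
    def test_combinatorial_counts_m3(self):
        X, g = _sim(0, markers=["IFNg", "IL6", "IL10"], effect=5.0)
        pareto = hp.exhaustive_panel_search(X, g)
        assert pareto["n_evaluated"].tolist() == [3, 3, 1]
        assert pareto["n_evaluated"].sum() == 7

    def test_strong_single_marker_recovered(self):
        for seed in range(5):
            X, g = _sim(seed, informative=("IFNg",), effect=10.0,
                        markers=["IFNg", "IL6", "IL10", "TNFa"])
            pareto = hp.exhaustive_panel_search(X, g)
            assert pareto.loc[pareto["size"] == 1, "markers"].iloc[0] == ("IFNg",)

    def test_residual_probability_breaks_accuracy_ties(self):
        """Two markers with perfect accuracy: the cleaner one (larger margin,
        smaller residual probability) wins even against the alphabet."""
        rng = np.random.default_rng(1)
        n = 12
        weak = np.r_[rng.normal(0, 1, 6), rng.normal(4, 1, 6)]
        strong = np.r_[rng.normal(0, 1, 6), rng.normal(12, 1, 6)]
        X = pd.DataFrame({"A_weak": weak, "Z_strong": strong})
        g = ["neg"] * 6 + ["pos"] * 6
        a_w, r_w, _ = hp.loocv_lda(X, g, ["A_weak"])
        a_s, r_s, _ = hp.loocv_lda(X, g, ["Z_strong"])
        assert a_w == a_s == 1.0 and r_s < r_w
        pareto = hp.exhaustive_panel_search(X, g)
        assert pareto.loc[pareto["size"] == 1, "markers"].iloc[0] == ("Z_strong",)

    def test_lexicographic_tie_on_duplicate_markers(self):
        X, g = _sim(3, informative=("IFNg",), effect=8.0, markers=["IFNg", "IL6"])
        X = X.rename(columns={"IL6": "ZZ"})
        X["AA"] = X["IFNg"]  # identical duplicate, alphabetically first
        pareto = hp.exhaustive_panel_search(X, g)
        assert pareto.loc[pareto["size"] == 1, "markers"].iloc[0] == ("AA",)

    def test_column_order_invariance(self):
        X, g = _sim(4, informative=("IFNg", "IL4"), effect=2.0,
                    markers=["IFNg", "IL6", "IL4", "TNFa"])
        p1 = hp.exhaustive_panel_search(X, g)
        p2 = hp.exhaustive_panel_search(X[list(X.columns)[::-1]], g)
        pd.testing.assert_frame_equal(p1, p2)

    def test_accuracy_front_may_be_non_monotone(self):
        """LOOCV accuracy need not grow with panel size; the search reports
        the front as measured instead of assuming monotonicity."""
        X, g = _sim(0, n_per_group=4, informative=("IFNg",), effect=6.0,
                    markers=["IFNg", "IL6", "IL10", "TNFa", "IL4", "CXCL10"])
        acc = hp.exhaustive_panel_search(X, g)["accuracy"].tolist()
        assert any(b < a for a, b in zip(acc, acc[1:]))

    def test_marker_cap(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(8, 21)),
                         columns=[f"m{i:02d}" for i in range(21)])
        g = ["a"] * 4 + ["b"] * 4
        with pytest.raises(ValueError, match="cap"):
            hp.exhaustive_panel_search(X, g)


class TestElbowSelect:
    def test_step_profile(self):
        assert hp.elbow_select([0.6, 1.0, 1.0, 1.0, 1.0]) == 2

    def test_linear_profile_picks_smallest(self):
        assert hp.elbow_select([0.5, 0.6, 0.7, 0.8]) == 1
        assert hp.elbow_select([0.9, 0.9, 0.9]) == 1

    def test_needs_three_sizes(self):
        with pytest.raises(ValueError, match="3"):
            hp.elbow_select([0.5, 1.0])


class TestModelInterface:
    def test_fit_summary_and_predictions(self):
        X, g = _sim(0, informative=("IFNg", "IL4"), effect=4.0)
        res = CytokinePanelLDA(X, g).fit(max_size=6)
        assert res.selected_size >= 1
        assert set(res.predictions.unique()) <= set(res.group_levels)
        # strongly separated data: in-sample discriminant separates groups
        assert (res.predictions == g).mean() == 1.0
        text = res.summary()
        assert "selected panel" in text and "LOOCV accuracy" in text

    def test_from_dataframe_roundtrip(self):
        X, g = _sim(1, informative=("IFNg",), effect=5.0,
                    markers=["IFNg", "IL6", "IL10"])
        df = X.join(g)
        res = CytokinePanelLDA.from_dataframe(df).fit()
        assert "IFNg" in res.selected_panel

    def test_missing_values_raise(self):
        X, g = _sim(0, markers=["IFNg", "IL6"])
        X.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            CytokinePanelLDA(X, g)

    def test_global_normalization_mode(self):
        X, g = _sim(2, informative=("IFNg",), effect=5.0,
                    markers=["IFNg", "IL6", "IL10"])
        res = CytokinePanelLDA(X, g, normalize="global").fit()
        assert "IFNg" in res.selected_panel
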