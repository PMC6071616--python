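"""Rejection sampling, posterior estimation and Bayes factors."""

import numpy as np
import pandas as pd
import pytest

from divabc.model_choice import (ABCModelChoice, ReferenceTable, bayes_factors,
                                 rejection_select)

from oracles import brute_rejection


def toy_table(stats: np.ndarray, labels, scheme="jsfs4",
              columns=("Sf", "Sx1", "Sx2", "Ss")) -> ReferenceTable:
    frame = pd.DataFrame(stats, columns=list(columns)[: stats.shape[1]])
    return ReferenceTable(stats=frame, labels=np.asarray(labels),
                          params=pd.DataFrame(index=range(len(frame))),
                          scheme=scheme)


def random_table(rng, n_rows, n_models=2):
    stats = rng.normal(size=(n_rows, 4)) * [5, 50, 50, 20] + [10, 100, 100, 40]
    labels = np.array([f"M{i % n_models}" for i in range(n_rows)])
    return toy_table(stats, labels)


class TestRejectionSelect:
    def test_observed_row_retained_at_distance_zero(self, rng):
        rt = random_table(rng, 100)
        obs = rt.stats.iloc[17]
        rej = rejection_select(rt, obs, tolerance=0.05)
        assert rej.indices[0] == 17
        assert rej.distances[0] == 0
        assert rej.weights[0] == rej.weights.max()

    def test_tolerance_one_retains_everything(self, rng):
        rt = random_table(rng, 50)
        rej = rejection_select(rt, rt.stats.iloc[0], tolerance=1.0)
        assert len(rej.indices) == 50

    def test_hand_ranked_five_rows(self):
        stats = np.array([[0.0], [1.0], [2.0], [10.0], [-3.0]])
        rt = toy_table(stats, ["A"] * 5, columns=("x",))
        rej = rejection_select(rt, pd.Series({"x": 0.5}), n_retain=3)
        assert list(rej.indices) == [0, 1, 2]

    def test_matches_bruteforce_on_large_table(self, rng):
        rt = random_table(rng, 10_000)
        obs = pd.Series(rng.normal(size=4) * [5, 50, 50, 20] + [10, 100, 100, 40],
                        index=rt.stats.columns)
        rej = rejection_select(rt, obs, tolerance=0.001)
        idx, dist = brute_rejection(rt.stats.to_numpy(float), obs.to_numpy(float),
                                    rej.scale.to_numpy(float), len(rej.indices))
        assert np.array_equal(rej.indices, idx)
        assert np.allclose(rej.distances, dist)

    def test_zero_variance_column_dropped_with_warning(self, rng):
        stats = rng.normal(size=(200, 4))
        stats[:, 2] = 7.0
        rt = toy_table(stats, ["A"] * 200)
        with pytest.warns(UserWarning, match="zero-variance"):
            rej = rejection_select(rt, rt.stats.iloc[0], tolerance=0.1)
        assert rej.dropped_columns == ["Sx2"]

    def test_distance_invariant_under_rescaling(self, rng):
        rt = random_table(rng, 500)
        obs = rt.stats.iloc[3]
        a = rejection_select(rt, obs, tolerance=0.02)
        scaled = rt.stats * 1000
        rt2 = ReferenceTable(stats=scaled, labels=rt.labels, params=rt.params,
                             scheme=rt.scheme)
        b = rejection_select(rt2, obs * 1000, tolerance=0.02)
        assert np.array_equal(a.indices, b.indices)
        assert np.allclose(a.distances, b.distances)


class TestModelPosterior:
    def test_rejection_is_weighted_frequency(self, rng):
        # place observed exactly on a cluster containing 70% A / 30% B
        stats = np.vstack([np.zeros((70, 4)), np.zeros((30, 4)),
                           np.full((100, 4), 50.0)])
        stats += rng.normal(scale=1e-6, size=stats.shape)
        labels = np.array(["A"] * 70 + ["B"] * 30 + ["C"] * 100)
        rt = toy_table(stats, labels)
        res = ABCModelChoice(rt, pd.Series(0.0, index=rt.stats.columns)).fit(
            method="rejection", n_retain=100)
        assert res.probabilities["A"] == pytest.approx(0.7, abs=0.02)
        assert res.probabilities["B"] == pytest.approx(0.3, abs=0.02)
        assert res.probabilities.sum() == pytest.approx(1.0, abs=1e-9)

    def test_rejection_matches_bruteforce_counting(self, rng):
        rt = random_table(rng, 5_000)
        obs = rt.stats.iloc[42]
        res = ABCModelChoice(rt, obs).fit(method="rejection", tolerance=0.01)
        rej = res.rejection
        labels = rt.labels[rej.indices]
        for m in rt.models:
            expected = rej.weights[labels == m].sum() / rej.weights.sum()
            assert res.probabilities[m] == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("method", ["mnlogistic", "neuralnet"])
    def test_separable_fixture_confident(self, rng, method):
        stats = np.vstack([rng.normal(0, 1, size=(300, 4)),
                           rng.normal(20, 1, size=(300, 4))])
        labels = np.array(["near"] * 300 + ["far"] * 300)
        rt = toy_table(stats, labels)
        obs = pd.Series(0.0, index=rt.stats.columns)
        res = ABCModelChoice(rt, obs).fit(method=method, tolerance=1.0, seed=1)
        assert res.probabilities["near"] > 0.99
        assert res.best_model == "near"

    def test_duplicated_models_split_evenly(self, rng):
        stats = rng.normal(size=(2000, 4))
        labels = np.array(["twin1", "twin2"] * 1000)
        rt = toy_table(stats, labels)
        res = ABCModelChoice(rt, pd.Series(0.0, index=rt.stats.columns)).fit(
            method="rejection", tolerance=0.25)
        assert res.probabilities["twin1"] == pytest.approx(0.5, abs=0.1)

    def test_absent_model_probability_zero_with_warning(self, rng):
        stats = np.vstack([np.zeros((50, 4)), np.full((50, 4), 100.0)])
        rt = toy_table(stats, np.array(["A"] * 50 + ["B"] * 50))
        with pytest.warns(UserWarning, match="absent"):
            res = ABCModelChoice(rt, pd.Series(0.0, index=rt.stats.columns)).fit(
                method="rejection", n_retain=10)
        assert res.probabilities["B"] == 0

    def test_neuralnet_deterministic_under_seed(self, rng):
        rt = random_table(rng, 400)
        obs = rt.stats.iloc[5]
        a = ABCModelChoice(rt, obs).fit(method="neuralnet", tolerance=0.5, seed=9)
        b = ABCModelChoice(rt, obs).fit(method="neuralnet", tolerance=0.5, seed=9)
        assert a.probabilities.equals(b.probabilities)

    def test_summary_renders(self, rng):
        rt = random_table(rng, 200)
        res = ABCModelChoice(rt, rt.stats.iloc[0]).fit(method="rejection",
                                                       tolerance=0.1)
        text = res.summary()
        assert "posterior" in text and "BF_1/2" in text


class TestBayesFactors:
    def test_arithmetic(self):
        bf = bayes_factors(pd.Series({"a": 0.6, "b": 0.3, "c": 0.1}))
        assert bf["BF_1/2"] == pytest.approx(2.0)
        assert bf["BF_1/3"] == pytest.approx(6.0)

    def test_even_pair(self):
        bf = bayes_factors(pd.Series({"a": 0.5, "b": 0.5}))
        assert bf["BF_1/2"] == pytest.approx(1.0)
        assert bf["tied"]

    def test_three_model_pattern(self):
        bf = bayes_factors(pd.Series({"PSC.hetero": 0.385, "SC.hetero": 0.318,
                                      "IM.hetero": 0.251}))
        assert bf["best"] == "PSC.hetero"
        assert bf["BF_1/2"] == pytest.approx(0.385 / 0.318, rel=1e-9)
        assert bf["BF_1/2"] == pytest.approx(1.21, abs=0.005)

    def test_zero_denominator_flagged_infinite(self):
        bf = bayes_factors(pd.Series({"a": 1.0, "b": 0.0}))
        assert np.isinf(bf["BF_1/2"]) and bf["infinite"]


class TestParameterPosterior:
    def test_weighted_summary_recovers_cluster_parameter(self, rng):
        # retained rows near the observed point carry theta ~ 5; far rows 50
        stats = np.vstack([np.zeros((100, 4)), np.full((100, 4), 80.0)])
        stats += rng.normal(scale=0.5, size=stats.shape)
        labels = np.array(["A"] * 100 + ["B"] * 100)
        frame = pd.DataFrame(stats, columns=["Sf", "Sx1", "Sx2", "Ss"])
        params = pd.DataFrame({"theta_1": [5.0] * 100 + [50.0] * 100,
                               "model_id": ["A"] * 100 + ["B"] * 100})
        rt = ReferenceTable(stats=frame, labels=labels, params=params,
                            scheme="jsfs4")
        res = ABCModelChoice(
            rt, pd.Series(0.0, index=frame.columns)).fit(
            method="rejection", n_retain=50)
        post = res.parameter_posterior()
        assert post.loc["theta_1", "mean"] == pytest.approx(5.0, abs=0.5)
        assert post.loc["theta_1", "q2.5"] <= 5.0 <= post.loc["theta_1", "q97.5"]

    def test_linear_adjustment_corrects_local_trend(self, rng):
        # parameter depends linearly on the statistic; adjustment should
        # shift draws toward the value at the observed point (x = 0)
        x = rng.uniform(-5, 5, size=500)
        stats = np.column_stack([x, rng.normal(size=500)])
        frame = pd.DataFrame(stats, columns=["s1", "s2"])
        params = pd.DataFrame({"theta_1": 10.0 + 2.0 * x})
        rt = ReferenceTable(stats=frame, labels=np.array(["A", "B"] * 250),
                            params=params, scheme="jsfs4")
        obs = pd.Series({"s1": 0.0, "s2": 0.0})
        res = ABCModelChoice(rt, obs).fit(method="rejection", tolerance=0.5)
        raw = res.parameter_posterior(model="A")
        adj = res.parameter_posterior(model="A", adjust=True)
        assert adj.loc["theta_1", "mean"] == pytest.approx(10.0, abs=0.3)
        spread_raw = raw.loc["theta_1", "q97.5"] - raw.loc["theta_1", "q2.5"]
        spread_adj = adj.loc["theta_1", "q97.5"] - adj.loc["theta_1", "q2.5"]
        assert spread_adj < spread_raw
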