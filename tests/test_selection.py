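"""Wrapper forward selection and the three univariate filter rankings."""

import numpy as np
import pytest

from enose.features import FeatureTable, FeatureId, full_catalogue
from enose.model_eval import CVConfig, cross_validate
from enose.selection import (FilterRanking, filter_select, fisher_scores,
                             forward_select, mutual_information_scores,
                             rank_features, relieff_scores,
                             repeat_selection)


def toy_table(values, labels, groups):
    values = np.asarray(values, dtype=float)
    ids = full_catalogue()[: values.shape[1]]
    return FeatureTable(values, ids, np.asarray(labels), np.asarray(groups),
                        np.asarray([f"s{i}" for i in range(values.shape[0])]))


@pytest.fixture(scope="module")
def informative_table():
    """128 samples, 32 bottles, 12 features: one strong, two weak, rest noise."""
    rng = np.random.default_rng(10)
    n = 128
    labels = np.repeat(["HQ", "AQ", "LQ", "Ea"], n // 4)
    groups = np.repeat(np.arange(32), n // 32)
    class_idx = np.repeat([0.0, 1.0, 2.0, 3.0], n // 4)
    X = rng.normal(size=(n, 12))
    X[:, 3] = class_idx + 0.05 * rng.normal(size=n)
    X[:, 7] = (class_idx > 1) + 0.3 * rng.normal(size=n)
    X[:, 9] = class_idx % 2 + 0.3 * rng.normal(size=n)
    return toy_table(X, labels, groups)


class TestForwardSelect:
    def test_step_one_matches_exhaustive_single_feature_oracle(
            self, informative_table):
        cfg = CVConfig(n_repeats=8, seed=2)
        trace = forward_select(informative_table, 1, cfg)
        # independent oracle: score every single feature through the
        # generic cross-validation path
        oracle = [cross_validate(informative_table, [j], cfg).mean_accuracy
                  for j in range(informative_table.n_features)]
        assert trace.step_mean_accuracy[0] == pytest.approx(max(oracle),
                                                            abs=1e-12)

    def test_trace_has_unique_features_and_right_length(
            self, informative_table):
        trace = forward_select(informative_table, 3,
                               CVConfig(n_repeats=5, seed=0))
        assert len(trace) == 3
        assert len(set(f.render() for f in trace.ordered_features)) == 3

    def test_perfectly_separating_feature_chosen_first(
            self, informative_table):
        trace = forward_select(informative_table, 1,
                               CVConfig(n_repeats=10, seed=1))
        assert trace.ordered_features[0] == informative_table.ids[3]
        assert trace.step_mean_accuracy[0] == 1.0

    def test_max_k_cannot_exceed_feature_count(self, informative_table):
        with pytest.raises(ValueError):
            forward_select(informative_table, 999, CVConfig(n_repeats=2))


class TestRepeatSelection:
    def test_five_traces_and_curve_length(self, informative_table):
        mean, std, traces = repeat_selection(
            informative_table, 2, CVConfig(n_repeats=4, seed=0), n_seeds=5)
        assert len(traces) == 5
        assert mean.shape == (2,)
        assert std.shape == (2,)

    def test_dominant_feature_starts_every_trace(self, informative_table):
        _, _, traces = repeat_selection(
            informative_table, 1, CVConfig(n_repeats=4, seed=0), n_seeds=5)
        firsts = {t.ordered_features[0] for t in traces}
        assert firsts == {informative_table.ids[3]}


class TestFisherScores:
    def test_hand_computed_two_class_value(self):
        # classes {0,1} and {10,11}: between = 2*25 + 2*25 = 100,
        # within = 2*0.5 + 2*0.5 = 2, so F = 50
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        y = np.array(["a", "a", "b", "b"])
        scores = fisher_scores(X, y).scores
        assert scores[0] == pytest.approx(50.0)

    def test_class_invariant_feature_scores_zero(self):
        X = np.array([[3.0], [3.0], [3.0], [3.0]])
        y = np.array(["a", "a", "b", "b"])
        assert fisher_scores(X, y).scores[0] == 0.0

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 3))
        y = np.repeat(["a", "b"], 20)
        s1 = fisher_scores(X, y).scores
        s2 = fisher_scores(X * 17.0, y).scores
        assert np.allclose(s1, s2)


class TestMutualInformation:
    def test_perfect_four_class_predictor_is_two_bits(self):
        y = np.repeat(["HQ", "AQ", "LQ", "Ea"], 25)
        X = np.repeat([0.0, 1.0, 2.0, 3.0], 25)[:, None]
        score = mutual_information_scores(X, y, n_bins=8).scores[0]
        assert score == pytest.approx(2.0)

    def test_constant_feature_is_zero(self):
        y = np.repeat(["a", "b"], 10)
        X = np.ones((20, 1))
        assert mutual_information_scores(X, y).scores[0] == 0.0

    def test_nonnegative(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(60, 10))
        y = rng.integers(0, 4, 60)
        assert np.all(mutual_information_scores(X, y).scores >= 0)


class TestReliefF:
    def test_hand_traced_toy_weights(self):
        # 6 points, 2 features, 2 classes, k = 1; expected weights from an
        # independent brute-force trace of the update rule
        X = np.array([[0.0, 0.0], [0.1, 1.0], [0.2, 0.5],
                      [0.8, 0.0], [0.9, 1.0], [1.0, 0.5]])
        y = np.array([0, 0, 0, 1, 1, 1])
        W = relieff_scores(X, y, k_neighbors=1).scores
        assert W[0] == pytest.approx(2.0 / 3.0)
        assert W[1] == pytest.approx(-0.5)

    def test_constant_feature_weight_zero(self):
        rng = np.random.default_rng(2)
        X = np.c_[np.ones(40), rng.normal(size=40)]
        y = np.repeat([0, 1], 20)
        W = relieff_scores(X, y, k_neighbors=3).scores
        assert W[0] == 0.0

    def test_informative_feature_outweighs_noise(self):
        rng = np.random.default_rng(3)
        y = np.repeat([0, 1], 30)
        X = np.c_[y + 0.1 * rng.normal(size=60), rng.normal(size=60)]
        W = relieff_scores(X, y, k_neighbors=5).scores
        assert W[0] > W[1]

    def test_small_class_raises(self):
        X = np.random.default_rng(0).normal(size=(12, 2))
        y = np.array([0] * 10 + [1] * 2)
        with pytest.raises(ValueError):
            relieff_scores(X, y, k_neighbors=5)


class TestFilterSelect:
    @pytest.fixture
    def ranking(self, informative_table):
        return rank_features(informative_table, "fisher")

    def test_all_features_when_k_is_n(self, ranking, informative_table):
        assert len(filter_select(ranking, informative_table.n_features)) \
            == informative_table.n_features

    def test_k_one_is_top_scored(self, ranking):
        top = filter_select(ranking, 1)
        assert top == [ranking.ranked_ids[0]]

    def test_output_is_prefix_of_ranking(self, ranking):
        assert filter_select(ranking, 5) == ranking.ranked_ids[:5]

    def test_ranked_order_is_descending(self, ranking):
        s = ranking.scores[ranking.ranked_order]
        assert np.all(np.diff(s) <= 0)


def test_filter_scores_invariant_to_column_permutation(informative_table):
    rng = np.random.default_rng(9)
    perm = rng.permutation(informative_table.n_features)
    X = informative_table.values
    y = informative_table.labels
    for fn in (fisher_scores, mutual_information_scores,
               lambda X, y: relieff_scores(X, y, k_neighbors=5)):
        s = fn(X, y).scores
        sp = fn(X[:, perm], y).scores
        assert np.allclose(s[perm], sp)
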