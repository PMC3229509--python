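"""Normalization, F-score selection, SVM training and the report protocol."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from tmagraph.classify import (STROMA_LABEL, TUMOR_LABEL, NormalizationBounds,
                               SvmModel, assign_truth_label,
                               classify_subgraphs, evaluate_classification,
                               f_score, propagate_to_nuclei, rank_and_select,
                               train_classifier, train_svm)
from tmagraph.segment import NucleusRecord
from tmagraph.synthetic import GroundTruth


class TestNormalization:
    def test_min_max_column(self):
        df = pd.DataFrame({"a": [2.0, 4.0, 6.0], "b": [1.0, 2.0, 4.0]})
        bounds = NormalizationBounds.fit(df)
        out = bounds.transform(df)
        assert out["a"].tolist() == [0.0, 0.5, 1.0]

    def test_out_of_range_clipped(self):
        train = pd.DataFrame({"a": [0.0, 10.0], "b": [1.0, 3.0]})
        bounds = NormalizationBounds.fit(train)
        test = pd.DataFrame({"a": [20.0, -5.0], "b": [2.0, 2.0]})
        out = bounds.transform(test)
        assert out["a"].tolist() == [1.0, 0.0]

    def test_round_trip_inverse(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.uniform(-5, 5, (20, 4)), columns=list("abcd"))
        bounds = NormalizationBounds.fit(df)
        back = bounds.inverse_transform(bounds.transform(df))
        assert np.allclose(back.to_numpy(), df.to_numpy())

    def test_constant_column_warns_all_constant_errors(self):
        with pytest.warns(UserWarning):
            NormalizationBounds.fit(pd.DataFrame({"a": [1.0, 1.0],
                                                  "b": [0.0, 2.0]}))
        with pytest.raises(ValueError):
            NormalizationBounds.fit(pd.DataFrame({"a": [1.0, 1.0]}))


class TestFScore:
    def test_hand_computed_case(self):
        x = [0, 0, 1, 1, 2, 2, 3, 3]
        y = [1, 1, 1, 1, -1, -1, -1, -1]
        assert f_score(x, y) == pytest.approx(3.0, abs=1e-12)

    def test_zero_when_class_means_coincide(self):
        x = [0, 2, 0, 2]
        y = [1, 1, -1, -1]
        assert f_score(x, y) == 0.0

    def test_monotone_in_separation(self):
        y = [1] * 4 + [-1] * 4
        base = [0.0, 0.1, -0.1, 0.05]
        f_small = f_score(base + [1 + v for v in base], y)
        f_large = f_score(base + [3 + v for v in base], y)
        assert f_large > f_small

    def test_affine_invariance(self, rng):
        x = rng.normal(size=40)
        y = np.where(rng.random(40) < 0.5, 1, -1)
        if len(set(y)) < 2 or min((y == 1).sum(), (y == -1).sum()) < 2:
            y[:2], y[-2:] = 1, -1
        assert f_score(7.5 * x - 3.0, y) == pytest.approx(f_score(x, y), rel=1e-9)

    def test_degenerate_denominator(self):
        assert f_score([1, 1, 2, 2], [1, 1, -1, -1]) == math.inf
        assert f_score([1, 1, 1, 1], [1, 1, -1, -1]) == 0.0

    def test_requires_two_per_class(self):
        with pytest.raises(ValueError):
            f_score([1, 2, 3], [1, -1, -1])


class TestRankAndSelect:
    def _planted(self, rng, n=120, n_features=22, informative=(0, 5, 13)):
        y = np.where(np.arange(n) < n // 2, 1, -1)
        x = rng.normal(size=(n, n_features))
        for j in informative:
            x[:, j] += np.where(y == 1, 2.5, -2.5)
        cols = [f"f{j:02d}" for j in range(n_features)]
        return pd.DataFrame(x, columns=cols), y, {f"f{j:02d}" for j in informative}

    def test_planted_signal_ranks_first(self, rng):
        df, y, informative = self._planted(rng)
        ranking, selected = rank_and_select(df, y, k=3)
        assert set(selected) == informative
        assert ranking["f_score"].is_monotonic_decreasing

    def test_k_equals_all(self, rng):
        df, y, _ = self._planted(rng)
        _, selected = rank_and_select(df, y, k=22)
        assert set(selected) == set(df.columns)

    def test_permuted_labels_kill_scores(self, rng):
        df, y, _ = self._planted(rng)
        y_perm = rng.permutation(y)
        ranking, _ = rank_and_select(df, y_perm, k=5)
        assert ranking["f_score"].max() < 0.5  # stochastic: no planted signal

    def test_invalid_k(self, rng):
        df, y, _ = self._planted(rng)
        with pytest.raises(ValueError):
            rank_and_select(df, y, k=0)
        with pytest.raises(ValueError):
            rank_and_select(df, y, k=23)


class TestSvm:
    def test_separable_blobs_perfect(self, rng):
        x = np.vstack([rng.normal(0.2, 0.05, (30, 2)),
                       rng.normal(0.8, 0.05, (30, 2))])
        y = np.array([1] * 30 + [-1] * 30)
        sv, coef, b = train_svm(x, y, C=1.0, gamma=1.0)
        model = SvmModel(["a", "b"],
                         NormalizationBounds(["a", "b"], np.zeros(2), np.ones(2)),
                         1.0, 1.0, sv, coef, b)
        pred = model.predict(pd.DataFrame(x, columns=["a", "b"]))
        assert (pred == y).all()

    def test_xor_needs_rbf(self, rng):
        centers = np.array([[0.2, 0.2], [0.8, 0.8], [0.2, 0.8], [0.8, 0.2]])
        labels = np.array([1, 1, -1, -1])
        x = np.vstack([c + rng.normal(0, 0.04, (25, 2)) for c in centers])
        y = np.repeat(labels, 25)
        sv, coef, b = train_svm(x, y, C=10.0, gamma=8.0)
        model = SvmModel(["a", "b"],
                         NormalizationBounds(["a", "b"], np.zeros(2), np.ones(2)),
                         8.0, 10.0, sv, coef, b)
        acc = (model.predict(pd.DataFrame(x, columns=["a", "b"])) == y).mean()
        assert acc > 0.95

    def test_label_swap_flips_predictions(self, rng):
        x = np.vstack([rng.normal(0.2, 0.08, (20, 2)),
                       rng.normal(0.8, 0.08, (20, 2))])
        y = np.array([1] * 20 + [-1] * 20)
        df = pd.DataFrame(x, columns=["a", "b"])
        m1 = train_classifier(df, y, k=2, C=1.0, gamma=1.0)
        m2 = train_classifier(df, -y, k=2, C=1.0, gamma=1.0)
        assert (m1.predict(df) == -m2.predict(df)).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_svm(np.zeros((4, 2)), np.ones(4))

    def test_json_round_trip_exact(self, rng, tmp_path):
        df = pd.DataFrame(rng.uniform(0, 1, (40, 5)),
                          columns=list("abcde"))
        y = np.where(df["a"] > 0.5, 1, -1)
        if len(set(y)) < 2:
            y[0] = -y[0]
        model = train_classifier(df, y, k=3)
        path = tmp_path / "model.json"
        model.save(path)
        loaded = SvmModel.load(path)
        assert loaded.selected == model.selected
        assert np.array_equal(loaded.decision_function(df),
                              model.decision_function(df))


class TestSubgraphLabels:
    def _graph_with_centroids(self, centroids):
        g = nx.Graph()
        for i, (r, c) in enumerate(centroids):
            rec = NucleusRecord.from_coords(i + 1, [[0, 0]])
            rec.centroid = (r, c)
            g.add_node(i + 1, record=rec)
        if len(centroids) > 1:
            nx.add_path(g, list(g.nodes))
        return g

    def _truth_with_mask(self, mask):
        return GroundTruth(label_image=np.zeros_like(mask, dtype=np.int32),
                           classes={}, subtypes={}, tumor_region_mask=mask)

    def test_majority_and_tie_break(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[:, :5] = True
        truth = self._truth_with_mask(mask)
        all_in = self._graph_with_centroids([(1, 1), (2, 2), (3, 3)])
        assert assign_truth_label(all_in, truth) == TUMOR_LABEL
        minority = self._graph_with_centroids([(1, 1), (2, 2), (1, 8), (2, 8), (3, 8)])
        assert assign_truth_label(minority, truth) == STROMA_LABEL
        tie = self._graph_with_centroids([(1, 1), (1, 8)])
        assert assign_truth_label(tie, truth) == STROMA_LABEL

    def test_propagation_covers_all_members(self):
        g1 = self._graph_with_centroids([(0, 0), (0, 1)])
        g2 = self._graph_with_centroids([(5, 5), (5, 6), (5, 7)])
        g2 = nx.relabel_nodes(g2, {1: 10, 2: 11, 3: 12})
        out = propagate_to_nuclei([g1, g2], [TUMOR_LABEL, STROMA_LABEL])
        assert out == {1: 1, 2: 1, 10: -1, 11: -1, 12: -1}


class TestEvaluateClassification:
    def test_perfect_prediction(self):
        t = pd.DataFrame({"core_id": [0] * 6,
                          "pred": [1, 1, 1, -1, -1, -1],
                          "truth": [1, 1, 1, -1, -1, -1]})
        rep = evaluate_classification(t)
        assert rep.overall_mean == 100.0
        assert rep.tumor_mean == 100.0 and rep.stroma_mean == 100.0

    def test_counting_example(self):
        pred = [1] * 8 + [-1] * 2 + [-1] * 6 + [1] * 4
        truth = [1] * 10 + [-1] * 10
        rep = evaluate_classification(pd.DataFrame(
            {"core_id": 0, "pred": pred, "truth": truth}))
        assert rep.overall_mean == pytest.approx(70.0)
        assert rep.tumor_mean == pytest.approx(80.0)
        assert rep.stroma_mean == pytest.approx(60.0)

    def test_two_core_aggregation(self):
        rows = []
        rows += [{"core_id": 0, "pred": p, "truth": 1}
                 for p in [1] * 8 + [-1] * 2]          # 80%
        rows += [{"core_id": 1, "pred": p, "truth": 1}
                 for p in [1] * 9 + [-1] * 1]          # 90%
        rep = evaluate_classification(pd.DataFrame(rows))
        assert rep.overall_mean == pytest.approx(85.0)
        assert rep.overall_sd == pytest.approx(np.std([80, 90], ddof=1))
        # no stroma nuclei anywhere -> stroma aggregate undefined
        assert math.isnan(rep.stroma_mean)

    def test_missing_class_core_excluded_from_class_mean(self):
        rows = [{"core_id": 0, "pred": 1, "truth": 1},
                {"core_id": 0, "pred": 1, "truth": 1},
                {"core_id": 1, "pred": -1, "truth": -1},
                {"core_id": 1, "pred": 1, "truth": -1}]
        rep = evaluate_classification(pd.DataFrame(rows))
        assert rep.tumor_mean == 100.0       # only core 0 has tumor nuclei
        assert rep.stroma_mean == 50.0       # only core 1 has stroma nuclei

    def test_missing_columns_error(self):
        with pytest.raises(ValueError):
            evaluate_classification(pd.DataFrame({"pred": [1]}))


def test_classify_subgraphs_deterministic_and_empty(rng):
    df = pd.DataFrame(rng.uniform(0, 1, (30, 3)), columns=list("abc"))
    y = np.where(df["a"] > 0.5, 1, -1)
    y[:2], y[-2:] = 1, -1
    model = train_classifier(df, y, k=3)
    p1 = classify_subgraphs(model, df)
    p2 = classify_subgraphs(model, df)
    assert np.array_equal(p1, p2)
    assert classify_subgraphs(model, df.iloc[:0]).size == 0
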