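import networkx as nx
import numpy as np
import pandas as pd
import pytest

from seqtox.feature_selection import (
    SelectionReport,
    correlation_filter,
    drop_zero_variance,
    gefs_top_features,
    rank_coselection,
    rfecv_select,
    select_features,
)


def _corr_abs(fm):
    return np.abs(np.corrcoef(fm.to_numpy(), rowvar=False))


class TestZeroVariance:
    def test_constant_column_dropped_and_logged(self, rng):
        fm = pd.DataFrame({"a": rng.normal(size=10), "b": np.ones(10)})
        out, report = drop_zero_variance(fm)
        assert list(out.columns) == ["a"]
        assert report.stages[0].dropped == [{"feature": "b", "reason": "zero variance"}]

    def test_no_constant_columns_is_identity(self, rng):
        fm = pd.DataFrame(rng.normal(size=(10, 4)), columns=list("abcd"))
        out, _ = drop_zero_variance(fm)
        assert out.equals(fm)

    def test_all_constant_matrix_is_an_error(self):
        fm = pd.DataFrame({"a": np.ones(5), "b": np.zeros(5)})
        with pytest.raises(ValueError, match="constant"):
            drop_zero_variance(fm)


class TestCorrelationFilter:
    def test_duplicate_and_negated_columns_are_dropped_keeping_earlier(self, rng):
        base = rng.normal(size=50)
        fm = pd.DataFrame({"a": base, "b": base.copy(), "c": -base,
                           "d": rng.normal(size=50)})
        out, report = correlation_filter(fm)
        assert list(out.columns) == ["a", "d"]
        dropped = {d["feature"]: d["partner"] for d in report.stages[0].dropped}
        assert dropped == {"b": "a", "c": "a"}

    def test_independent_noise_columns_survive(self, rng):
        fm = pd.DataFrame(rng.normal(size=(1000, 6)),
                          columns=[f"n{i}" for i in range(6)])
        out, _ = correlation_filter(fm)
        assert out.shape[1] == 6

    def test_no_surviving_pair_reaches_threshold_and_idempotent(self, rng):
        base = rng.normal(size=(200, 4))
        cols = {f"m{i}": base[:, i % 4] + rng.normal(scale=0.3, size=200)
                for i in range(12)}
        fm = pd.DataFrame(cols)
        out, _ = correlation_filter(fm, threshold=0.8)
        corr = _corr_abs(out)
        np.fill_diagonal(corr, 0.0)
        assert corr.max() < 0.8
        again, report = correlation_filter(out, threshold=0.8)
        assert again.equals(out)
        assert report.stages[0].dropped == []


class TestRankCoselection:
    def test_hand_built_graph_ranks_by_weighted_degree(self):
        g = nx.Graph()
        g.add_nodes_from("ABC")
        g.add_edge("A", "B", weight=3)  # three members selected {A, B}
        nominations = {"A": 3, "B": 3, "C": 1}  # one member selected {C} alone
        ranked, degree = rank_coselection(g, nominations)
        assert ranked == ["A", "B", "C"]
        assert degree == {"A": 3, "B": 3, "C": 0}

    def test_ties_break_by_nomination_count_then_name(self):
        g = nx.Graph()
        g.add_nodes_from("XYZ")
        nominations = {"X": 2, "Y": 5, "Z": 2}
        ranked, _ = rank_coselection(g, nominations)
        assert ranked == ["Y", "X", "Z"]


class TestGEFS:
    def test_single_member_ranking_equals_importance_order(self, toy_labelled_matrix):
        fm, y = toy_labelled_matrix
        top, graph, _ = gefs_top_features(
            fm, y, n_members=1, member_top=10, top_k=10, seed=0, n_estimators=50
        )
        assert len(top) == 10
        # with one member there are no co-selections beyond its own clique;
        # every pairwise weight is exactly 1
        assert all(d["weight"] == 1 for _, _, d in graph.edges(data=True))

    def test_warns_when_fewer_features_than_top_k(self, toy_labelled_matrix):
        fm, y = toy_labelled_matrix
        with pytest.warns(UserWarning, match="top_k"):
            gefs_top_features(fm, y, n_members=2, member_top=5, top_k=200,
                              seed=0, n_estimators=50)

    def test_informative_columns_dominate_top_of_ranking(self, toy_labelled_matrix):
        fm, y = toy_labelled_matrix
        top, _, _ = gefs_top_features(fm, y, n_members=10, member_top=8, top_k=10,
                                      seed=3, n_estimators=50)
        assert sum(f.startswith("info") for f in top[:8]) >= 4


class TestRFECV:
    def test_single_feature_passes_through(self, rng):
        y = np.array([0, 1] * 30)
        fm = pd.DataFrame({"only": rng.normal(size=60) + y})
        final, report = rfecv_select(fm, y, cv_folds=3, n_estimators=30)
        assert final == ["only"]
        assert report.final_features == ["only"]

    def test_single_class_labels_rejected(self, rng):
        fm = pd.DataFrame({"a": rng.normal(size=10)})
        with pytest.raises(ValueError, match="single class"):
            rfecv_select(fm, np.ones(10))

    def test_selected_subset_scores_within_one_se_of_full_set(self, toy_labelled_matrix):
        fm, y = toy_labelled_matrix
        final, report = rfecv_select(fm, y, cv_folds=3, seed=1, n_estimators=40)
        assert set(final) <= set(fm.columns)
        stage = report.stages[-1]
        assert stage.n_in - len(stage.dropped) == stage.n_out == len(final)
        assert sum(f.startswith("info") for f in final) >= 3


def test_full_cascade_bookkeeping_chains_between_stages(toy_labelled_matrix, rng):
    fm, y = toy_labelled_matrix
    fm = fm.copy()
    fm["const"] = 1.0
    fm["dup_info0"] = fm["info0"]
    final, report, _ = select_features(
        fm, y, n_members=5, member_top=10, top_k=15, cv_folds=3,
        seed=0, n_estimators=40,
    )
    names = [s.name for s in report.stages]
    assert names == ["zero_variance", "correlation_filter", "gefs", "rfecv"]
    for stage in report.stages:
        assert stage.n_in - len(stage.dropped) == stage.n_out
    for prev, nxt in zip(report.stages, report.stages[1:]):
        assert prev.n_out == nxt.n_in
    assert report.final_features == final
    assert "const" not in final and "dup_info0" not in final


def test_cascade_is_deterministic_given_seed(toy_labelled_matrix):
    fm, y = toy_labelled_matrix
    kwargs = dict(n_members=4, member_top=10, top_k=12, cv_folds=3,
                  seed=11, n_estimators=40)
    a, _, _ = select_features(fm, y, **kwargs)
    b, _, _ = select_features(fm, y, **kwargs)
    assert a == b


def test_selection_report_rejects_inconsistent_bookkeeping():
    report = SelectionReport()
    with pytest.raises(AssertionError):
        report.add("bad", 10, [{"feature": "x"}], 5)
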