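import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seqtox.evaluation import (
    ConfusionCounts,
    auc_from_scores,
    compare_table,
    counts_from_predictions,
    metrics_from_counts,
    round3,
)

# Blind-test comparison rows: method -> (TP, TN, FP, FN) and the published
# count-derivable measures (NPV, PPV, specificity, sensitivity, accuracy,
# MCC, OPM, F1) at 3 decimals.
PUBLISHED_ROWS = {
    "ProToxin": ((225, 457, 17, 54), (0.894, 0.930, 0.964, 0.806, 0.906, 0.797, 0.728, 0.864)),
    "XGBoost-88": ((229, 453, 21, 50), (0.901, 0.916, 0.956, 0.821, 0.906, 0.796, 0.728, 0.866)),
    "ToxinPred2": ((194, 451, 23, 85), (0.841, 0.894, 0.951, 0.695, 0.857, 0.690, 0.608, 0.782)),
    "ToxinPred2-hybrid": ((225, 430, 44, 54), (0.888, 0.836, 0.907, 0.806, 0.870, 0.719, 0.639, 0.821)),
    "ToxIBTL": ((161, 459, 15, 118), (0.795, 0.915, 0.968, 0.577, 0.823, 0.622, 0.540, 0.708)),
    "VISH-Pred": ((210, 451, 7, 67), (0.871, 0.968, 0.985, 0.758, 0.899, 0.789, 0.718, 0.850)),
    "CSM-Toxin": ((203, 469, 5, 76), (0.861, 0.976, 0.989, 0.728, 0.892, 0.774, 0.701, 0.834)),
    "MultiToxPred": ((172, 278, 196, 107), (0.722, 0.467, 0.586, 0.616, 0.598, 0.196, 0.214, 0.532)),
}
_MEASURES = ("NPV", "PPV", "specificity", "sensitivity", "accuracy", "MCC", "OPM", "F1")


@pytest.mark.parametrize("method", PUBLISHED_ROWS)
def test_published_comparison_rows_reproduce_to_three_decimals(method):
    (tp, tn, fp, fn), expected = PUBLISHED_ROWS[method]
    report = metrics_from_counts(ConfusionCounts(tp, tn, fp, fn))
    for name, value in zip(_MEASURES, expected):
        assert round3(getattr(report, name)) == value, name


def test_perfect_and_perfectly_wrong_classifiers():
    perfect = metrics_from_counts(ConfusionCounts(10, 10, 0, 0))
    assert all(getattr(perfect, m) == 1.0 for m in _MEASURES)
    wrong = metrics_from_counts(ConfusionCounts(0, 0, 10, 10))
    assert wrong.MCC == -1.0 and wrong.accuracy == 0.0 and wrong.nMCC == 0.0


def test_zero_over_zero_ratios_are_zero_and_flagged():
    report = metrics_from_counts(ConfusionCounts(0, 5, 0, 5))  # nothing predicted positive
    assert report.PPV == 0.0
    assert "PPV" in report.undefined
    with pytest.raises(ValueError):
        metrics_from_counts(ConfusionCounts(0, 0, 0, 0))


def test_metrics_match_per_sample_brute_force(rng):
    for _ in range(20):
        n = int(rng.integers(10, 60))
        y = rng.integers(0, 2, size=n)
        p = rng.integers(0, 2, size=n)
        if len(np.unique(y)) < 2:
            continue
        counts = counts_from_predictions(y, p)
        report = metrics_from_counts(counts)
        tp = sum(1 for a, b in zip(y, p) if a == 1 and b == 1)
        tn = sum(1 for a, b in zip(y, p) if a == 0 and b == 0)
        fp = sum(1 for a, b in zip(y, p) if a == 0 and b == 1)
        fn = sum(1 for a, b in zip(y, p) if a == 1 and b == 0)
        assert (counts.tp, counts.tn, counts.fp, counts.fn) == (tp, tn, fp, fn)
        assert report.accuracy == pytest.approx(np.mean(y == p))
        den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
        if den > 0:
            assert report.MCC == pytest.approx((tp * tn - fp * fn) / den)


counts_strategy = st.tuples(
    st.integers(0, 500), st.integers(0, 500), st.integers(0, 500), st.integers(0, 500)
).filter(lambda t: sum(t) > 0)


@settings(max_examples=200, deadline=None)
@given(counts_strategy)
def test_opm_bounded_by_one_and_mcc_swap_invariant(t):
    tp, tn, fp, fn = t
    report = metrics_from_counts(ConfusionCounts(tp, tn, fp, fn))
    assert 0.0 <= report.OPM <= 1.0
    assert report.nMCC == pytest.approx((1 + report.MCC) / 2)
    assert 2 * report.PPV * report.sensitivity == pytest.approx(
        report.F1 * (report.PPV + report.sensitivity)
    )
    swapped = metrics_from_counts(ConfusionCounts(tn, tp, fn, fp))
    assert swapped.MCC == pytest.approx(report.MCC)


def test_opm_equals_one_only_for_perfect_components():
    near = metrics_from_counts(ConfusionCounts(100, 100, 0, 1))
    assert near.OPM < 1.0


class TestAUC:
    def test_perfect_separation_and_all_ties(self):
        assert auc_from_scores([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0
        assert auc_from_scores([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_pairwise_comparison_oracle(self):
        assert auc_from_scores([0.9, 0.4, 0.6, 0.1], [1, 1, 0, 0]) == 0.75

    def test_matches_exhaustive_pairwise_count(self, rng):
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, size=40)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        wins = 0.0
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        for p in pos:
            for q in neg:
                wins += 1.0 if p > q else (0.5 if p == q else 0.0)
        assert auc_from_scores(scores, labels) == pytest.approx(
            wins / (len(pos) * len(neg))
        )

    def test_single_class_is_an_error(self):
        with pytest.raises(ValueError):
            auc_from_scores([0.5, 0.6], [1, 1])


def test_compare_table_formats_published_cells():
    entries = [
        (name, ConfusionCounts(*counts)) for name, (counts, _) in PUBLISHED_ROWS.items()
    ]
    table = compare_table(entries, n_inputs=753)
    assert table.loc["CSM-Toxin", "PPV"] == 0.976
    assert table.loc["CSM-Toxin", "specificity"] == 0.989
    assert table.loc["MultiToxPred", "accuracy"] == 0.598
    assert table.loc["MultiToxPred", "MCC"] == 0.196
    assert table.loc["ProToxin", "coverage"] == 1.0
    perfect = compare_table([("p", ConfusionCounts(5, 5, 0, 0))])
    assert set(perfect.loc["p"].drop("coverage")) == {1.0}


def test_round3_is_half_up():
    assert round3(0.0005) == 0.001
    assert round3(0.7275) == 0.728
    assert round3(-0.0004) == 0.0


def test_fractional_counts_supported_for_fold_averages():
    # fold-averaged confusion counts evaluate like integer ones; note that
    # metrics of averaged counts and averaged per-fold metrics can differ
    # in the third decimal, so only ratio-stable measures are pinned here
    report = metrics_from_counts(ConfusionCounts(366.55, 389.75, 30.85, 54.05))
    assert round3(report.accuracy) == 0.899
    assert round3(report.OPM) == 0.728
    assert abs(report.MCC - 0.800) < 2e-3
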