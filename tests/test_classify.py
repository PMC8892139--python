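"""LOF filtering, gain-ratio tree, cross-validation, metrics, comparisons."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats
from sklearn.metrics import roc_auc_score

from ivgttml.classify import (
    POSITIVE_LABEL,
    compare_bayesian,
    compare_classifiers,
    crossvalidate,
    induce_tree,
    lof_filter,
    normalize,
    performance,
    venn_counts,
)


def gaussian_matrix(n=78, p=10, seed=0, with_label=True):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        rng.standard_normal((n, p)),
        columns=[f"f{i}" for i in range(p)],
        index=[f"S{i:03d}" for i in range(n)],
    )
    if with_label:
        labels = np.array(["NON-PROG"] * n)
        labels[rng.choice(n, n // 4, replace=False)] = "PROG"
        df["label"] = labels
    return df


def separable_matrix(n=40, seed=0):
    """Two well-separated Gaussian blobs -> perfectly separable classes."""
    rng = np.random.default_rng(seed)
    half = n // 2
    x = np.vstack(
        [rng.normal(-5, 0.5, (half, 3)), rng.normal(5, 0.5, (n - half, 3))]
    )
    df = pd.DataFrame(x, columns=["a", "b", "c"],
                      index=[f"S{i:03d}" for i in range(n)])
    df["label"] = ["NON-PROG"] * half + ["PROG"] * (n - half)
    return df


class TestLofFilter:
    @pytest.mark.parametrize("n,expected", [(78, 3), (25, 1), (50, 2)])
    def test_flag_count_matches_contamination(self, n, expected):
        matrix = gaussian_matrix(n=n)
        retained, flagged = lof_filter(matrix, neighbors=20, contamination=0.04)
        assert len(flagged) == expected
        assert len(retained) == n - expected

    def test_flag_count_across_sizes(self):
        for n in range(21, 200, 13):
            _, flagged = lof_filter(gaussian_matrix(n=n, seed=n))
            assert len(flagged) == int(round(0.04 * n))

    def test_removed_cases_absent_downstream(self):
        matrix = gaussian_matrix()
        retained, flagged = lof_filter(matrix)
        assert not set(flagged) & set(retained.index)

    def test_too_few_cases_rejected(self):
        with pytest.raises(ValueError):
            lof_filter(gaussian_matrix(n=15), neighbors=20)


class TestNormalize:
    def test_zero_mean_unit_variance(self):
        out = normalize(gaussian_matrix(seed=2))
        for col in out.columns:
            if col == "label":
                continue
            assert abs(out[col].mean()) < 1e-12
            assert out[col].to_numpy().var() == pytest.approx(1.0, abs=1e-12)

    def test_constant_column_dropped(self):
        matrix = gaussian_matrix(seed=3)
        matrix["flat"] = 1.0
        with pytest.warns(UserWarning, match="zero-variance"):
            out = normalize(matrix)
        assert "flat" not in out.columns


class TestInduceTree:
    def test_separable_1d_splits_at_midpoint(self):
        values = np.array([1.0, 2.0, 3.0, 4.0, 10.0, 11.0, 12.0, 13.0])
        df = pd.DataFrame({"x": values})
        df["label"] = ["NON-PROG"] * 4 + ["PROG"] * 4
        tree = induce_tree(df)
        # brute force: best binary split of a pure separation is the midpoint
        # between the closest cross-class pair (4 and 10)
        assert tree.root.feature == "x"
        assert tree.root.threshold == pytest.approx(7.0)
        assert tree.selected_features == ["x"]

    def test_pure_input_no_split(self):
        df = pd.DataFrame({"x": np.arange(12, dtype=float)})
        df["label"] = "NON-PROG"
        tree = induce_tree(df)
        assert tree.root.is_leaf
        assert tree.selected_features == []

    def test_majority_stop_rule(self):
        # 19/20 majority (95%) -> no split even though separable
        df = pd.DataFrame({"x": np.arange(20, dtype=float)})
        df["label"] = ["PROG"] + ["NON-PROG"] * 19
        assert induce_tree(df).root.is_leaf

    def test_min_leaf_rule(self):
        # perfect split would isolate 2 cases < min_leaf=3: forbidden
        df = pd.DataFrame({"x": [1.0, 2.0, 10.0, 11.0, 12.0, 13.0, 14.0, 15.0]})
        df["label"] = ["PROG"] * 2 + ["NON-PROG"] * 6
        tree = induce_tree(df)
        assert tree.root.is_leaf or min(
            sum(tree.root.left.counts.values()), sum(tree.root.right.counts.values())
        ) >= 3

    def test_predictions_respect_splits(self):
        df = separable_matrix()
        tree = induce_tree(df)
        preds = tree.predict(df.drop(columns="label"))
        assert (preds == df["label"].to_numpy()).all()


class TestCrossvalidate:
    def test_perfect_separation_all_classifiers(self):
        df = separable_matrix()
        for name in ("tree", "naive_bayes", "logistic_l2"):
            report = crossvalidate(name, df, seed=0)
            assert report.metrics["CA"] == 1.0

    def test_deterministic_given_seed(self):
        df = gaussian_matrix(seed=5)
        a = crossvalidate("logistic_l2", df, seed=3)
        b = crossvalidate("logistic_l2", df, seed=3)
        np.testing.assert_equal(a.metrics, b.metrics)  # NaN-tolerant equality
        pd.testing.assert_frame_equal(a.predictions, b.predictions)

    def test_confusion_counts_sum_to_n(self):
        df = gaussian_matrix(seed=6)
        report = crossvalidate("naive_bayes", df, seed=1)
        assert sum(report.pooled_confusion.values()) == len(df)


class TestPerformance:
    @pytest.mark.parametrize(
        "tp,tn,fp,fn,expected", [(12, 50, 8, 5, 0.827), (13, 50, 8, 4, 0.840)]
    )
    def test_ca_from_correct_counts(self, tp, tn, fp, fn, expected):
        """62 and 63 correct cases of 75 give the published CA values."""
        metrics = performance({"TP": tp, "TN": tn, "FP": fp, "FN": fn})
        assert round(metrics["CA"], 3) == expected

    def test_perfect_classifier(self):
        conf = {"TP": 17, "TN": 58, "FP": 0, "FN": 0}
        y = ["PROG"] * 17 + ["NON-PROG"] * 58
        s = [1.0] * 17 + [0.0] * 58
        metrics = performance(conf, y, s)
        for key in ("AUC", "CA", "precision", "sensitivity", "specificity", "F1"):
            assert metrics[key] == 1.0

    @given(
        counts=st.tuples(*[st.integers(0, 60)] * 4).filter(lambda c: sum(c) > 0)
    )
    def test_weighted_recall_equals_ca(self, counts):
        tp, tn, fp, fn = counts
        metrics = performance({"TP": tp, "TN": tn, "FP": fp, "FN": fn})
        if not np.isnan(metrics["sensitivity"]):
            assert metrics["sensitivity"] == pytest.approx(metrics["CA"], rel=1e-12)

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(0)
        y = np.array(["PROG"] * 20 + ["NON-PROG"] * 30)
        s = rng.uniform(size=50)
        conf = {"TP": 1, "TN": 1, "FP": 0, "FN": 0}
        base = performance(conf, y, s)["AUC"]
        for f in (np.exp, lambda v: v**3 + v, lambda v: 1 - 1 / (2 + v)):
            assert performance(conf, y, f(s))["AUC"] == pytest.approx(base, abs=1e-12)


class TestCompareBayesian:
    def test_identical_scores(self):
        assert compare_bayesian([0.8, 0.7, 0.9, 0.6, 0.8], [0.8, 0.7, 0.9, 0.6, 0.8]) == 0.5

    def test_dominance(self):
        a = np.array([10.0, 10.001, 9.999, 10.0, 10.0])
        assert compare_bayesian(a, a - 10.0) >= 0.999

    def test_complementary(self):
        rng = np.random.default_rng(1)
        a, b = rng.uniform(size=5), rng.uniform(size=5)
        assert compare_bayesian(a, b) + compare_bayesian(b, a) == pytest.approx(1.0)

    def test_matches_monte_carlo_posterior(self):
        """Closed-form posterior tail matches sampling the shifted t."""
        rng = np.random.default_rng(7)
        a, b = rng.uniform(0.6, 0.9, 5), rng.uniform(0.6, 0.9, 5)
        k = 5
        d = a - b
        scale = np.sqrt(d.var(ddof=1) * (1 / k + (1 / k) / (1 - 1 / k)))
        draws = d.mean() + scale * rng.standard_t(df=k - 1, size=400_000)
        assert compare_bayesian(a, b) == pytest.approx((draws > 0).mean(), abs=0.01)


class TestVennCounts:
    def test_identical_predictions_all_triple(self):
        ids = set(f"S{i}" for i in range(20))
        counts = venn_counts({"t": ids, "nb": ids, "lr": ids})
        assert counts["ABC"] == 20
        assert sum(v for k, v in counts.items() if k != "names" and k != "ABC") == 0

    def test_disjoint_sets(self):
        counts = venn_counts({"t": {"a"}, "nb": {"b"}, "lr": {"c"}})
        assert counts["ABC"] == 0
        assert counts["A_only"] == counts["B_only"] == counts["C_only"] == 1

    def test_matches_brute_force_set_arithmetic(self):
        rng = np.random.default_rng(2)
        universe = [f"S{i}" for i in range(40)]
        sets = {
            name: set(rng.choice(universe, rng.integers(5, 30), replace=False))
            for name in ("t", "nb", "lr")
        }
        counts = venn_counts(sets)
        names = counts["names"]
        total = 0
        for membership in itertools.product([0, 1], repeat=3):
            if membership == (0, 0, 0):
                continue
            region = set(universe)
            for name, inside in zip(names, membership):
                region = region & sets[name] if inside else region - sets[name]
            total += len(region)
        assert (
            sum(v for k, v in counts.items() if k != "names") == total
        )


def test_compare_classifiers_end_to_end():
    # partially separated blobs: imperfect but non-degenerate predictions
    rng = np.random.default_rng(9)
    df = separable_matrix(n=60, seed=9)
    df[["a", "b", "c"]] += rng.normal(0, 4.0, (60, 3))
    reports = {
        name: crossvalidate(name, df, seed=2)
        for name in ("tree", "naive_bayes", "logistic_l2")
    }
    comparison = compare_classifiers(reports)
    for measure, table in comparison.pairwise.items():
        for a, b in itertools.permutations(table.index, 2):
            assert table.loc[a, b] + table.loc[b, a] == pytest.approx(1.0)
    n_cases = len(reports["tree"].predictions)
    total_correct = sum(
        v for k, v in comparison.venn_correct.items() if k != "names"
    )
    total_wrong = sum(
        v for k, v in comparison.venn_misclassified.items() if k != "names"
    )
    assert total_correct <= n_cases and total_wrong <= n_cases
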