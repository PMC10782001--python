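"""Calibration, residue-level and protein-level metric behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from idrbench import metrics
from idrbench.errors import ParameterError, UndefinedMetricError
from idrbench.types import ConfusionCounts, ReferenceEntry, ScoreProfile

from conftest import auc_pairwise


def _pool(scores, labels):
    """One profile + reference pair wrapping pooled arrays."""
    n = len(scores)
    entry = ReferenceEntry(id="P1", sequence="A" * n, disorder=np.asarray(labels))
    profile = ScoreProfile(id="P1", method="m", scores=np.asarray(scores, dtype=float))
    return [profile], {"P1": entry}


class TestCalibrateThreshold:
    def test_enumerated_example(self):
        profiles, refs = _pool([0.9, 0.8, 0.3, 0.1], [1, 1, 0, 0])
        t = metrics.calibrate_threshold(profiles, refs)
        assert t.threshold == pytest.approx(0.3)
        assert t.achieved_count == 2 == t.target_count

    def test_zero_native_count_uses_max_score(self):
        profiles, refs = _pool([0.9, 0.8, 0.3], [0, 0, 0])
        t = metrics.calibrate_threshold(profiles, refs)
        assert t.threshold == pytest.approx(0.9)
        assert t.achieved_count == 0

    def test_tied_pool_prefers_fewer_predicted(self):
        # all scores 0.5, target 2 of 4: strict '>' makes 2 unattainable;
        # objective ties at |0-2| and |4-2|, broken toward fewer predicted
        profiles, refs = _pool([0.5] * 4, [1, 1, 0, 0])
        t = metrics.calibrate_threshold(profiles, refs)
        assert t.threshold == pytest.approx(0.5)
        assert t.achieved_count == 0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_distinct_scores_calibrate_exactly(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 60))
        scores = rng.permutation(np.linspace(0.01, 0.99, n))  # all distinct
        labels = rng.integers(0, 2, n)
        profiles, refs = _pool(scores, labels)
        t = metrics.calibrate_threshold(profiles, refs)
        assert t.achieved_count == t.target_count
        assert (scores > t.threshold).sum() == t.target_count

    def test_tied_pool_objective_is_minimal_by_enumeration(self):
        rng = np.random.default_rng(3)
        scores = rng.choice([0.2, 0.5, 0.5, 0.8], size=40)
        labels = rng.integers(0, 2, 40)
        profiles, refs = _pool(scores, labels)
        t = metrics.calibrate_threshold(profiles, refs)
        target = int(np.sum(labels))
        best = min(
            abs(int((scores > c).sum()) - target)
            for c in np.concatenate([[0.0], np.unique(scores)])
        )
        assert abs(t.achieved_count - target) == best


class TestBinarize:
    def test_strict_above_threshold(self):
        profile = ScoreProfile(id="P", method="m", scores=[0.4, 0.5, 0.6])
        out = metrics.binarize(profile, 0.5)
        np.testing.assert_array_equal(out.binary, [0, 0, 1])  # equality -> 0


class TestRocAuc:
    @pytest.mark.parametrize(
        "scores,labels,expected",
        [
            ([0.9, 0.1], [1, 0], 1.0),
            ([0.5, 0.5, 0.5], [1, 0, 1], 0.5),  # all-tied convention
            ([0.9, 0.4, 0.6, 0.2], [1, 1, 0, 0], 0.75),
        ],
    )
    def test_known_values(self, scores, labels, expected):
        assert metrics.roc_auc(scores, labels) == pytest.approx(expected)

    def test_degenerate_labels_are_error(self):
        with pytest.raises(UndefinedMetricError):
            metrics.roc_auc([0.1, 0.9], [1, 1])

    @given(st.integers(0, 2**31 - 1), st.integers(2, 12))
    @settings(max_examples=100, deadline=None)
    def test_matches_pairwise_enumeration(self, seed, n):
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 2, n)
        labels[:2] = [0, 1]
        scores = rng.choice(np.linspace(0, 1, 5), size=n)  # force ties
        assert metrics.roc_auc(scores, labels) == pytest.approx(
            auc_pairwise(scores, labels)
        )

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_invariant_under_increasing_transform(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        labels = rng.integers(0, 2, n)
        labels[:2] = [0, 1]
        scores = rng.random(n)
        transformed = np.expm1(3 * scores)  # strictly increasing
        assert metrics.roc_auc(scores, labels) == pytest.approx(
            metrics.roc_auc(transformed, labels)
        )


class TestPrAuc:
    def test_perfect_separation(self):
        assert metrics.pr_auc([0.9, 0.8, 0.1], [1, 1, 0]) == pytest.approx(1.0)

    def test_single_positive_ranked_second(self):
        # ranked list: 0.8 (neg), 0.2 (pos); precision at the positive = 1/2
        assert metrics.pr_auc([0.2, 0.8], [1, 0]) == pytest.approx(0.5)

    def test_random_scores_approach_prevalence(self):
        rng = np.random.default_rng(0)
        n = 10_000
        labels = (rng.random(n) < 0.2).astype(int)
        scores = rng.random(n)
        prevalence = labels.mean()
        assert metrics.pr_auc(scores, labels) == pytest.approx(prevalence, abs=0.03)

    def test_no_positives_is_error(self):
        with pytest.raises(UndefinedMetricError):
            metrics.pr_auc([0.2, 0.8], [0, 0])


class TestBinaryMetrics:
    def test_worked_example(self):
        m = metrics.binary_metrics(ConfusionCounts(tp=8, tn=80, fp=10, fn=2))
        assert m.f1 == pytest.approx(16 / 28)
        assert m.mcc == pytest.approx(620 / np.sqrt(1_328_400))
        assert m.sensitivity == pytest.approx(0.8)
        assert not m.degenerate

    def test_perfect_prediction(self):
        m = metrics.binary_metrics(ConfusionCounts(tp=5, tn=5, fp=0, fn=0))
        assert (m.mcc, m.f1, m.sensitivity) == (1.0, 1.0, 1.0)

    def test_all_negative_prediction_flags_degenerate(self):
        m = metrics.binary_metrics(ConfusionCounts(tp=0, tn=8, fp=0, fn=2))
        assert m.sensitivity == 0.0 and m.f1 == 0.0 and m.mcc == 0.0
        assert m.degenerate

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=100, deadline=None)
    def test_matches_sklearn_on_random_tables(self, seed):
        from sklearn.metrics import f1_score, matthews_corrcoef, recall_score

        rng = np.random.default_rng(seed)
        tp, tn, fp, fn = (int(v) for v in rng.integers(1, 30, 4))
        m = metrics.binary_metrics(ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn))
        y_true = np.array([1] * tp + [0] * tn + [0] * fp + [1] * fn)
        y_pred = np.array([1] * tp + [0] * tn + [1] * fp + [0] * fn)
        assert m.mcc == pytest.approx(matthews_corrcoef(y_true, y_pred))
        assert m.f1 == pytest.approx(f1_score(y_true, y_pred))
        assert m.sensitivity == pytest.approx(recall_score(y_true, y_pred))


class TestContentMetrics:
    @pytest.mark.parametrize(
        "series,expected", [([0, 0, 0, 0], 0.0), ([1, 1, 1, 1], 1.0), ([1, 0, 1, 0, 1], 0.6)]
    )
    def test_disorder_content(self, series, expected):
        assert metrics.disorder_content(series) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "pred,native,expected",
        [([0.3, 0.7], [0.3, 0.7], 0.0), ([0.5], [0.2], 0.3), ([0, 1], [1, 0], 1.0)],
    )
    def test_content_mae(self, pred, native, expected):
        assert metrics.content_mae(pred, native) == pytest.approx(expected)

    def test_content_mae_length_mismatch(self):
        with pytest.raises(ParameterError):
            metrics.content_mae([0.1], [0.1, 0.2])

    @pytest.mark.parametrize(
        "pred,native,expected",
        [
            ([1, 2, 3, 4], [1, 2, 3, 4], 1.0),
            ([1, 2, 3, 4], [4, 3, 2, 1], -1.0),
            ([1, 2, 3, 4], [1, 3, 2, 4], 1 - 6 * 2 / (4 * 15)),  # d^2 sum = 2
        ],
    )
    def test_content_scc_rank_formula(self, pred, native, expected):
        assert metrics.content_scc(pred, native) == pytest.approx(expected)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_scc_equals_no_tie_formula_on_tie_free_input(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 30))
        pred = rng.permutation(np.arange(n)) + rng.random(n) * 0.1
        native = rng.permutation(np.arange(n)) + rng.random(n) * 0.1
        from scipy.stats import rankdata

        d = rankdata(pred) - rankdata(native)
        expected = 1 - 6 * np.sum(d**2) / (n * (n**2 - 1))
        assert metrics.content_scc(pred, native) == pytest.approx(expected)

    def test_scc_zero_variance_is_error(self):
        with pytest.raises(UndefinedMetricError):
            metrics.content_scc([0.5, 0.5], [0.1, 0.9])


class TestFdpEval:
    def test_perfect_prediction(self):
        native = [1.0, 0.95, 0.3]
        f1, sens = metrics.fdp_eval(native, native, 0.90)
        assert f1 == 1.0 and sens == 1.0

    def test_confusion_enumeration(self):
        f1, sens = metrics.fdp_eval([1.0, 1.0], [1.0, 0.5], 0.90)
        assert f1 == pytest.approx(2 / 3)  # TP=1, FP=1, FN=0
        assert sens == pytest.approx(1.0)

    def test_no_native_fdps_is_error(self):
        with pytest.raises(UndefinedMetricError):
            metrics.fdp_eval([1.0], [0.5], 0.90)

    def test_predicted_sets_nest_across_cutoffs(self):
        rng = np.random.default_rng(1)
        pred = rng.random(200)
        sets = [set(np.nonzero(pred > c)[0]) for c in (0.99, 0.90, 0.80)]
        assert sets[0] <= sets[1] <= sets[2]


class TestMetricRanges:
    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_outputs_respect_declared_ranges(self, seed):
        rng = np.random.default_rng(seed)
        n = 40
        labels = rng.integers(0, 2, n)
        labels[:2] = [0, 1]
        scores = rng.random(n)
        assert 0.0 <= metrics.roc_auc(scores, labels) <= 1.0
        assert 0.0 <= metrics.pr_auc(scores, labels) <= 1.0
        binary = (scores > 0.5).astype(int)
        m = metrics.binary_metrics(metrics.confusion(binary, labels))
        assert -1.0 <= m.mcc <= 1.0
        assert 0.0 <= m.f1 <= 1.0
        assert 0.0 <= m.sensitivity <= 1.0
        assert metrics.content_mae(rng.random(5), rng.random(5)) >= 0.0
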