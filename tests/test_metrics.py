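"""Confusion-matrix construction and precision/recall/F1 scoring."""

import numpy as np
import pytest
from sklearn.metrics import precision_recall_fscore_support

import ecgleads as eg
from ecgleads.core import CLASS_NAMES

# A published-style 9-class test-set confusion matrix (rows = true labels in
# canonical order) used as a fixed scoring fixture.
REFERENCE_CM = np.array(
    [
        [3189, 9, 9, 0, 18, 30, 26, 26, 7],
        [20, 2823, 47, 4, 62, 81, 86, 40, 5],
        [6, 49, 2043, 0, 12, 14, 24, 9, 2],
        [0, 9, 1, 544, 1, 1, 6, 4, 0],
        [7, 53, 10, 1, 4818, 24, 37, 9, 0],
        [34, 119, 35, 1, 21, 1974, 55, 52, 2],
        [47, 96, 25, 9, 35, 56, 2506, 63, 5],
        [19, 26, 12, 0, 20, 38, 53, 2485, 0],
        [7, 4, 3, 0, 2, 3, 2, 3, 595],
    ]
)


def brute_force_confusion(true, pred):
    C = np.zeros((9, 9), dtype=int)
    for t, p in zip(true, pred):
        C[CLASS_NAMES.index(t), CLASS_NAMES.index(p)] += 1
    return C


class TestConfusion:
    def test_matches_enumeration_oracle(self, rng):
        labels = rng.choice(CLASS_NAMES, size=200)
        preds = rng.choice(CLASS_NAMES, size=200)
        cm = eg.confusion(labels, preds)
        np.testing.assert_array_equal(cm.C, brute_force_confusion(labels, preds))

    def test_perfect_predictions_are_diagonal(self, rng):
        labels = rng.choice(CLASS_NAMES, size=50)
        cm = eg.confusion(labels, labels)
        assert np.all(cm.C == np.diag(np.diag(cm.C)))
        assert cm.total == 50

    def test_empty_input_gives_zero_matrix(self):
        cm = eg.confusion([], [])
        assert cm.total == 0

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            eg.confusion(["N"], ["XYZ"])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            eg.confusion(["N", "AF"], ["N"])


class TestScore:
    def test_reference_matrix_lbbb_row(self):
        m = eg.score(eg.ConfusionMatrix(REFERENCE_CM))
        assert m.precision["LBBB"] == 97.32
        assert m.recall["LBBB"] == 96.11
        assert m.f1["LBBB"] == 0.9671

    def test_reference_matrix_macro_averages(self):
        m = eg.score(eg.ConfusionMatrix(REFERENCE_CM))
        assert m.macro_recall == 93.03
        assert m.macro_f1 == 0.9313
        assert m.macro_precision == 93.25

    def test_diagonal_matrix_scores_100(self):
        m = eg.score(eg.ConfusionMatrix(np.diag(np.arange(1, 10))))
        assert all(v == 100.0 for v in m.precision.values())
        assert all(v == 100.0 for v in m.recall.values())
        assert all(v == 1.0 for v in m.f1.values())

    def test_cross_check_against_sklearn(self, rng):
        labels = rng.choice(CLASS_NAMES, size=500)
        preds = rng.choice(CLASS_NAMES, size=500)
        m = eg.score(eg.confusion(labels, preds))
        p, r, f, _ = precision_recall_fscore_support(
            labels, preds, labels=list(CLASS_NAMES), zero_division=0
        )
        for i, c in enumerate(CLASS_NAMES):
            assert m.precision[c] == pytest.approx(100 * p[i], abs=0.005)
            assert m.recall[c] == pytest.approx(100 * r[i], abs=0.005)
            assert m.f1[c] == pytest.approx(f[i], abs=0.00005)

    def test_class_permutation_invariance_of_macro(self, rng):
        perm = rng.permutation(9)
        C = REFERENCE_CM
        m1 = eg.score(eg.ConfusionMatrix(C))
        m2 = eg.score(
            eg.ConfusionMatrix(C[np.ix_(perm, perm)],
                               class_names=tuple(CLASS_NAMES[i] for i in perm))
        )
        assert m1.macro_f1 == m2.macro_f1
        assert m1.macro_recall == m2.macro_recall
        for c in CLASS_NAMES:
            assert m1.f1[c] == m2.f1[c]

    def test_f1_is_harmonic_mean(self):
        m = eg.score(eg.ConfusionMatrix(REFERENCE_CM))
        for c in CLASS_NAMES:
            p, r = m.precision[c], m.recall[c]
            assert m.f1[c] == pytest.approx(2 * p * r / (p + r) / 100, abs=1e-4)
            # harmonic mean lies between the two rates
            assert min(p, r) / 100 - 1e-9 <= m.f1[c] <= max(p, r) / 100 + 1e-9

    def test_undefined_rates_flagged_as_zero(self):
        C = np.zeros((9, 9), dtype=int)
        C[0, 0] = 5  # only class N present or predicted
        m = eg.score(eg.ConfusionMatrix(C))
        assert m.precision["AF"] == 0.0 and m.recall["AF"] == 0.0
        assert "AF" in m.undefined

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            eg.score(eg.ConfusionMatrix(np.zeros((9, 9), dtype=int)))


class TestScoreProperties:
    """Property-based checks on arbitrary confusion matrices."""

    from hypothesis import given, settings
    from hypothesis import strategies as st
    from hypothesis.extra.numpy import arrays

    @given(
        arrays(np.int64, (9, 9), elements=st.integers(0, 500)),
        st.randoms(use_true_random=False),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_macro_averages_invariant_under_class_relabelling(self, C, rnd):
        if C.sum() == 0:
            C[0, 0] = 1
        perm = list(range(9))
        rnd.shuffle(perm)
        m1 = eg.score(eg.ConfusionMatrix(C))
        m2 = eg.score(
            eg.ConfusionMatrix(
                C[np.ix_(perm, perm)],
                class_names=tuple(CLASS_NAMES[i] for i in perm),
            )
        )
        assert m1.macro_f1 == m2.macro_f1
        assert m1.macro_recall == m2.macro_recall
        assert m1.macro_precision == m2.macro_precision

    @given(arrays(np.int64, (9, 9), elements=st.integers(0, 300)))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_identity_predictions_score_100(self, C):
        diag = np.diag(np.maximum(np.diag(C), 1))
        m = eg.score(eg.ConfusionMatrix(diag))
        assert m.macro_f1 == 1.0 and m.macro_recall == 100.0
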