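"""Voting, dual-network decisions, metrics, and the repeated-split protocol."""

from collections import Counter

import numpy as np
import pytest
from sklearn.metrics import precision_recall_fscore_support

from gammavox.evaluate import (
    REJECT,
    RecordingFeatures,
    SplitPlan,
    compute_metrics,
    dual_decision,
    majority_vote,
    run_protocol,
    vocalization_decision,
)
from gammavox.network import NetworkConfig


def mode_oracle(labels):
    """Most frequent label, ties to the earliest first appearance."""
    counts = Counter(labels)
    best = max(counts.values())
    for lab in labels:
        if counts[lab] == best:
            return lab


class TestMajorityVote:
    def test_worked_example(self):
        labels = ["class1", "class1", "class3", "class1", "class5"]
        assert majority_vote(labels, 5) == ["class1"]

    def test_group_size_one_is_identity(self):
        labels = list("ABCAB")
        assert majority_vote(labels, 1) == labels

    def test_tie_goes_to_earliest_appearing(self):
        assert majority_vote(["A", "B", "A", "B"], 4) == ["A"]
        assert majority_vote(["B", "A", "A", "B"], 4) == ["B"]

    def test_partial_trailing_group(self):
        assert majority_vote(["A", "A", "B", "B", "B"], 3) == ["A", "B"]

    def test_matches_counting_oracle(self, rng):
        for _ in range(500):
            labels = list(rng.choice(list("ABCDE"), size=rng.integers(1, 30)))
            m = int(rng.integers(1, 8))
            got = majority_vote(labels, m)
            expected = [
                mode_oracle(labels[i : i + m]) for i in range(0, len(labels), m)
            ]
            assert got == expected

    def test_unanimous_group_returns_that_label(self):
        for m in [1, 3, 7]:
            for lab in ["X", "Y"]:
                assert majority_vote([lab] * 10, m) == [lab] * ((10 + m - 1) // m)

    def test_empty_or_bad_group_size(self):
        with pytest.raises(ValueError):
            majority_vote([], 3)
        with pytest.raises(ValueError):
            majority_vote(["A"], 0)


class TestVocalizationDecision:
    def test_unanimous(self):
        assert vocalization_decision(["dog"] * 7) == "dog"

    def test_sixty_forty(self):
        assert vocalization_decision(["cat"] * 6 + ["dog"] * 4) == "cat"

    def test_matches_mode_oracle(self, rng):
        for _ in range(300):
            labels = list(rng.choice(list("PQR"), size=rng.integers(1, 20)))
            assert vocalization_decision(labels) == mode_oracle(labels)


class TestDualDecision:
    def test_agreement_accepted(self):
        assert dual_decision("cat", "cat") == "cat"

    def test_disagreement_rejected(self):
        assert dual_decision("cat", "dog") == REJECT

    def test_agreement_rate_matches_closed_form(self, rng):
        """Two independent symmetric-confusion classifiers agree with
        probability p^2 + (1-p)^2 / (K-1)."""
        K, p, n = 5, 0.7, 40000
        truth = rng.integers(0, K, size=n)

        def noisy(true):
            correct = rng.random(n) < p
            wrong = (true + rng.integers(1, K, size=n)) % K
            return np.where(correct, true, wrong)

        a, b = noisy(truth), noisy(truth)
        agree = np.mean(a == b)
        expected = p**2 + (1 - p) ** 2 / (K - 1)
        assert agree == pytest.approx(expected, abs=4 * np.sqrt(expected / n) + 0.01)


class TestComputeMetrics:
    def test_perfect_diagonal(self):
        rep = compute_metrics(np.diag([5, 3, 7]))
        assert rep.accuracy == 1.0
        assert np.all(rep.per_class_F1 == 1.0)
        assert rep.macro_F1 == 1.0

    def test_hand_computed_two_class_example(self):
        rep = compute_metrics(np.array([[8, 2], [3, 7]]))
        assert rep.accuracy == pytest.approx(0.75)
        p1, r1 = 8 / 11, 0.8
        assert rep.per_class_precision[0] == pytest.approx(p1)
        assert rep.per_class_recall[0] == pytest.approx(r1)
        assert rep.per_class_F1[0] == pytest.approx(2 * p1 * r1 / (p1 + r1))

    def test_equal_precision_recall_gives_f1_equal_to_both(self):
        # symmetric confusion: every class has P = R = 6/10
        C = np.array([[6, 2, 2], [2, 6, 2], [2, 2, 6]])
        rep = compute_metrics(C)
        assert rep.per_class_F1 == pytest.approx(rep.per_class_precision)

    def test_never_predicted_class_gets_zero_precision_and_f1(self):
        rep = compute_metrics(np.array([[3, 0], [2, 0]]))
        assert rep.per_class_precision[1] == 0.0
        assert rep.per_class_F1[1] == 0.0

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(np.zeros((3, 3), dtype=int))

    def test_matches_sklearn_on_random_confusions(self, rng):
        for _ in range(200):
            K = int(rng.integers(2, 6))
            y_true = rng.integers(0, K, size=60)
            y_pred = rng.integers(0, K, size=60)
            C = np.zeros((K, K), dtype=int)
            for t, p in zip(y_true, y_pred):
                C[t, p] += 1
            rep = compute_metrics(C)
            P, R, F, _ = precision_recall_fscore_support(
                y_true, y_pred, labels=range(K), zero_division=0
            )
            assert rep.per_class_precision == pytest.approx(P)
            assert rep.per_class_recall == pytest.approx(R)
            assert rep.per_class_F1 == pytest.approx(F)
            assert rep.accuracy == pytest.approx(np.mean(y_true == y_pred))


def toy_features(rng, n_classes=3, n_recs=6, frames_per_rec=12, dim=6, sep=4.0):
    """Fabricated frame-granularity features with class-dependent means."""
    feats = []
    for c in range(n_classes):
        center = np.zeros(dim)
        center[c % dim] = sep
        for r in range(n_recs):
            feats.append(
                RecordingFeatures(
                    source_id=f"c{c}r{r}", label=f"class{c}",
                    matrix=center + rng.normal(size=(frames_per_rec, dim)),
                    mode="P4",
                )
            )
    return feats


class TestProtocol:
    PLAN = SplitPlan(n_repeats=2, per_class_train=4, per_class_test=2)
    NET = NetworkConfig(max_iter=60)

    def test_report_shape_and_average_consistency(self, rng):
        feats = toy_features(rng)
        res = run_protocol(feats, self.PLAN, base_seed=3, group_sizes=(5,),
                           net_config=self.NET)
        assert len(res["repeats"]) == 2
        for level in ("frame", "group_5", "vocalization"):
            mean = res["averaged"][level]["accuracy"]["mean"]
            per_repeat = [rep[level].accuracy for rep in res["repeats"]]
            assert mean == pytest.approx(np.mean(per_repeat))

    def test_identical_seeds_give_identical_repeats(self, rng):
        feats = toy_features(rng)
        plan = SplitPlan(n_repeats=2, per_class_train=4, per_class_test=2,
                         seeds=(7, 7))
        res = run_protocol(feats, plan, group_sizes=(3,), net_config=self.NET)
        r0, r1 = res["repeats"]
        assert np.array_equal(r0["frame"].confusion, r1["frame"].confusion)
        assert r0["vocalization"].accuracy == r1["vocalization"].accuracy

    def test_confusion_row_sums_equal_test_counts(self, rng):
        feats = toy_features(rng)
        res = run_protocol(feats, self.PLAN, base_seed=1, group_sizes=(),
                           net_config=self.NET)
        voc = res["repeats"][0]["vocalization"]
        assert voc.confusion.sum(axis=1).tolist() == [2, 2, 2]

    def test_insufficient_recordings_rejected(self, rng):
        feats = toy_features(rng, n_recs=3)
        with pytest.raises(ValueError, match="insufficient"):
            run_protocol(feats, self.PLAN, net_config=self.NET)

    def test_zero_test_recordings_rejected(self, rng):
        feats = toy_features(rng)
        plan = SplitPlan(n_repeats=1, per_class_train=4, per_class_test=0)
        with pytest.raises(ValueError):
            run_protocol(feats, plan, net_config=self.NET)
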