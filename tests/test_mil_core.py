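"""MIL pooling, losses, bag AUC, threshold selection and evaluation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import milenface as mf
from milenface.mil_core import instance_loss_grad


# ---------------------------------------------------------------------------
# pooling
# ---------------------------------------------------------------------------

class TestPooling:
    def test_top3_mean_example(self):
        scores = [0.72, 1.76, -1.0, -2.0, 0.5]
        assert mf.mil_pool_topk(scores, 3) == pytest.approx((1.76 + 0.72 + 0.5) / 3)

    def test_k1_reduces_to_max(self, rng):
        scores = rng.standard_normal(20)
        assert mf.mil_pool_topk(scores, 1) == mf.mil_pool_max(scores)

    def test_topk_matches_sort_oracle(self, rng):
        scores = rng.uniform(-5, 5, size=100)
        expected = float(np.mean(np.sort(scores)[-3:]))
        assert mf.mil_pool_topk(scores, 3) == pytest.approx(expected, abs=1e-12)

    def test_max_mean_examples(self):
        assert mf.mil_pool_max([-1, 0, 2]) == 2
        assert mf.mil_pool_mean([-1, 0, 2]) == pytest.approx(1 / 3)
        assert mf.mil_pool_max([3.5]) == mf.mil_pool_mean([3.5]) == 3.5

    def test_pooling_order_statistics(self, rng):
        scores = rng.standard_normal(30)
        assert (
            mf.mil_pool_max(scores)
            >= mf.mil_pool_topk(scores, 3)
            >= mf.mil_pool_mean(scores)
        )

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), k=st.integers(1, 5))
    def test_topk_is_monotone_in_every_score(self, seed, k):
        r = np.random.default_rng(seed)
        scores = r.standard_normal(8)
        base = mf.mil_pool_topk(scores, k)
        j = int(r.integers(0, 8))
        bumped = scores.copy()
        bumped[j] += abs(r.standard_normal()) + 0.01
        assert mf.mil_pool_topk(bumped, k) >= base

    def test_empty_or_bad_k_raises(self):
        with pytest.raises(ValueError):
            mf.mil_pool_topk([], 1)
        with pytest.raises(ValueError):
            mf.mil_pool_topk([1.0, 2.0], 3)
        with pytest.raises(ValueError):
            mf.mil_pool_max([])


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def _bce_oracle(logit, label):
    p = 1.0 / (1.0 + np.exp(-logit))
    return -(label * np.log(p) + (1 - label) * np.log(1 - p))


class TestInstanceLoss:
    def test_logit_zero_gives_ln2(self):
        assert mf.instance_loss([0.0], [1], 5.0) == pytest.approx(np.log(2))

    def test_saturated_positive_logit(self):
        assert mf.instance_loss([20.0], [1]) < 1e-8

    def test_unit_weight_equals_plain_mean_bce(self, rng):
        logits = rng.standard_normal(40)
        labels = rng.integers(0, 2, size=40)
        expected = np.mean([_bce_oracle(z, y) for z, y in zip(logits, labels)])
        assert mf.instance_loss(logits, labels, 1.0) == pytest.approx(expected)

    def test_weight_two_matches_duplication_oracle(self, rng):
        """2x weight on healthy instances = duplicating each label-0 instance
        once in an unweighted sum."""
        logits = rng.standard_normal(25)
        labels = rng.integers(0, 2, size=25)
        dup_logits = np.concatenate([logits, logits[labels == 0]])
        dup_labels = np.concatenate([labels, labels[labels == 0]])
        weighted_sum = mf.instance_loss(logits, labels, 2.0) * len(logits)
        dup_sum = mf.instance_loss(dup_logits, dup_labels, 1.0) * len(dup_logits)
        assert weighted_sum == pytest.approx(dup_sum)

    def test_non_binary_label_raises(self):
        with pytest.raises(ValueError):
            mf.instance_loss([0.0], [2])

    def test_gradient_matches_finite_differences(self, rng):
        logits = rng.standard_normal(10)
        labels = rng.integers(0, 2, size=10)
        _, grad = instance_loss_grad(logits, labels, 2.0)
        eps = 1e-6
        for j in (0, 4, 9):
            up, dn = logits.copy(), logits.copy()
            up[j] += eps
            dn[j] -= eps
            num = (
                mf.instance_loss(up, labels, 2.0) - mf.instance_loss(dn, labels, 2.0)
            ) / (2 * eps)
            assert num == pytest.approx(grad[j], rel=1e-5)


class TestPrepoolLoss:
    def test_single_instance_bags_reduce_to_instance_loss(self, rng):
        logits = rng.standard_normal(12)
        labels = rng.integers(0, 2, size=12)
        per_bag = [[z] for z in logits]
        assert mf.prepool_loss(per_bag, labels, "max") == pytest.approx(
            mf.instance_loss(logits, labels, 1.0)
        )

    def test_constant_bag_equals_pointwise_bce(self):
        c, label = 1.3, 1
        assert mf.prepool_loss([[c, c, c]], [label], "mean") == pytest.approx(
            _bce_oracle(c, label)
        )

    def test_mean_pooling_matches_two_step_oracle(self, rng):
        bags = [rng.standard_normal(rng.integers(2, 8)) for _ in range(10)]
        labels = rng.integers(0, 2, size=10)
        pooled = np.array([b.mean() for b in bags])
        expected = np.mean([_bce_oracle(z, y) for z, y in zip(pooled, labels)])
        assert mf.prepool_loss(bags, labels, "mean") == pytest.approx(expected)


# ---------------------------------------------------------------------------
# bag AUC
# ---------------------------------------------------------------------------

def _auc_pair_oracle(labels, scores):
    """Exhaustive Mann-Whitney pair counting with half credit for ties."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            total += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    return total / (len(pos) * len(neg))


class TestAucMil:
    def test_perfect_separation(self):
        bags = [[-3, -2], [-1, -2], [1, 0], [2, 0]]
        assert mf.auc_mil([0, 0, 1, 1], bags, "max") == 1.0

    def test_anti_separation(self):
        bags = [[3], [2], [-1], [-2]]
        assert mf.auc_mil([0, 0, 1, 1], bags, "max") == 0.0

    def test_matches_pair_counting_oracle(self, rng):
        labels = rng.integers(0, 2, size=50)
        labels[:2] = [0, 1]
        bags = [rng.choice([-1.0, 0.0, 0.5, 2.0], size=5) for _ in range(50)]
        pooled = [max(b) for b in bags]
        assert mf.auc_mil(labels, bags, "max") == pytest.approx(
            _auc_pair_oracle(labels, pooled)
        )

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_invariant_under_monotone_transforms(self, seed):
        r = np.random.default_rng(seed)
        labels = np.r_[np.ones(5, dtype=int), np.zeros(5, dtype=int)]
        bags = [r.standard_normal(4) for _ in range(10)]
        base = mf.auc_mil(labels, bags, "max")
        scale, shift = r.uniform(0.1, 3.0), r.standard_normal()
        warped = [np.exp(scale * b) + shift for b in bags]  # strictly increasing
        assert mf.auc_mil(labels, warped, "max") == pytest.approx(base)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            mf.auc_mil([1, 1], [[0.1], [0.2]], "max")


# ---------------------------------------------------------------------------
# threshold selection
# ---------------------------------------------------------------------------

def _threshold_oracle(labels, scores):
    """Exhaustive scan over all midpoints and the two sentinels."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    uniq = np.unique(scores)
    cands = [uniq[0] - 1] + list((uniq[:-1] + uniq[1:]) / 2) + [uniq[-1] + 1]
    best = None
    for t in cands:
        dec = scores > t
        tpr = dec[labels == 1].mean()
        fpr = dec[labels == 0].mean()
        g = np.sqrt(tpr * (1 - fpr))
        if best is None or g > best[0] + 1e-15 or (abs(g - best[0]) <= 1e-15 and t > best[1]):
            best = (g, t, tpr, fpr)
    return best


class TestSelectThreshold:
    def test_separable_example(self):
        res = mf.select_threshold([0, 0, 1, 1], [-2, -1, 1, 2])
        assert res.threshold == pytest.approx(0.0)
        assert res.gmean == 1.0
        assert res.tpr == 1.0 and res.fpr == 0.0

    def test_all_scores_equal_gives_zero_gmean(self):
        res = mf.select_threshold([0, 1, 0, 1], [2.0, 2.0, 2.0, 2.0])
        assert res.gmean == 0.0

    def test_matches_exhaustive_oracle(self, rng):
        labels = rng.integers(0, 2, size=200)
        labels[:2] = [0, 1]
        scores = np.round(rng.standard_normal(200), 1)  # force some ties
        g, t, tpr, fpr = _threshold_oracle(labels, scores)
        res = mf.select_threshold(labels, scores)
        assert res.gmean == pytest.approx(g)
        assert res.threshold == pytest.approx(t)
        assert res.tpr == pytest.approx(tpr)
        assert res.fpr == pytest.approx(fpr)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_gmean_is_global_maximum_over_midpoints(self, seed):
        r = np.random.default_rng(seed)
        labels = np.r_[np.ones(6, dtype=int), np.zeros(6, dtype=int)]
        scores = r.standard_normal(12)
        res = mf.select_threshold(labels, scores)
        assert res.gmean == pytest.approx(_threshold_oracle(labels, scores)[0])
        assert res.gmean == pytest.approx(np.sqrt(res.tpr * (1 - res.fpr)))

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            mf.select_threshold([1, 1, 1], [0.1, 0.2, 0.3])


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

class TestEvaluate:
    def test_f1_example(self):
        # 20 positives (19 found), 1 false alarm on 10 negatives
        labels = [1] * 20 + [0] * 10
        decisions = [1] * 19 + [0] + [1] + [0] * 9
        rep = mf.evaluate(labels, ["unknown"] * 30, decisions)
        assert (rep.tp, rep.fp, rep.fn) == (19, 1, 1)
        assert rep.f1 == pytest.approx(38 / 40)

    def test_corrected_reduces_to_plain_without_no_signs(self):
        labels = [1, 1, 0, 0]
        rep = mf.evaluate(labels, ["mild", "severe", "healthy", "healthy"], labels)
        assert rep.corrected_accuracy == rep.accuracy == 1.0

    def test_corrected_accuracy_on_fixed_ten_bag_fixture(self):
        """Two diabetic bags without visible signs, both predicted negative:
        plain accuracy counts them as misses, corrected accuracy does not."""
        labels = [1, 1, 1, 1, 1, 1, 0, 0, 0, 0]
        severities = [
            "no_signs", "no_signs", "mild", "severe", "mild", "severe",
            "healthy", "healthy", "healthy", "healthy",
        ]
        decisions = [0, 0, 1, 1, 1, 0, 0, 0, 0, 1]
        rep = mf.evaluate(labels, severities, decisions)
        # independent enumeration: plain correct = 3 TP + 3 TN = 6;
        # corrected additionally excuses the two no_signs misses
        assert rep.accuracy == pytest.approx(0.6)
        assert rep.corrected_accuracy == pytest.approx(0.8)
        assert rep.corrected_accuracy >= rep.accuracy
        assert rep.corrected_precision == pytest.approx(3 / 4)

    def test_instance_metrics(self):
        rep = mf.evaluate(
            [1, 0],
            ["mild", "healthy"],
            [1, 0],
            instance_labels=[1, 1, 0, 0],
            instance_decisions=[1, 0, 0, 1],
        )
        assert rep.instance_accuracy == pytest.approx(0.5)
        assert rep.instance_precision == pytest.approx(0.5)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            mf.evaluate([1, 0], ["mild"], [1, 0])
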