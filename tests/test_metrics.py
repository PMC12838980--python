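"""Metric panel vs hand arithmetic and brute-force oracles."""

import numpy as np
import pytest

from painattn.metrics import (EvalReport, ci_t, cohens_kappa,
                              confusion_and_prf, ece, evaluate, mcc, ovr_auc,
                              paired_ttest)

# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def oracle_kappa(y_true, y_pred):
    n = len(y_true)
    po = sum(a == b for a, b in zip(y_true, y_pred)) / n
    classes = sorted(set(y_true) | set(y_pred))
    pe = sum((sum(t == c for t in y_true) / n) *
             (sum(p == c for p in y_pred) / n) for c in classes)
    return (po - pe) / (1 - pe)


def oracle_mcc(y_true, y_pred):
    # covariance form: cov(X,Y)/sqrt(cov(X,X) cov(Y,Y)) on one-hot codes
    classes = sorted(set(y_true) | set(y_pred))
    X = np.array([[t == c for c in classes] for t in y_pred], float)
    Y = np.array([[t == c for c in classes] for t in y_true], float)
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    num = (Xc * Yc).sum()
    den = np.sqrt((Xc * Xc).sum() * (Yc * Yc).sum())
    return num / den if den else 0.0


def oracle_auc_pairs(labels, scores):
    pos = [s for l, s in zip(labels, scores) if l]
    neg = [s for l, s in zip(labels, scores) if not l]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def oracle_ece(conf, correct, n_bins):
    n = len(conf)
    total = 0.0
    for b in range(n_bins):
        lo, hi = b / n_bins, (b + 1) / n_bins
        members = [i for i, c in enumerate(conf)
                   if (c > lo or (b == 0 and c == 0)) and c <= hi]
        if not members:
            continue
        acc = sum(correct[i] for i in members) / len(members)
        avg = sum(conf[i] for i in members) / len(members)
        total += len(members) / n * abs(acc - avg)
    return total


class TestConfusionPrf:
    def test_perfect_predictions(self):
        y = [0, 1, 2, 3, 4] * 3
        out = confusion_and_prf(y, y)
        assert out["accuracy"] == 1.0
        assert out["macro_f1"] == 1.0
        assert np.array_equal(np.diag(out["confusion"]), [3] * 5)

    def test_hand_enumerated_binary_case(self):
        out = confusion_and_prf([0, 0, 1, 1], [0, 1, 1, 1], n_classes=2)
        assert out["accuracy"] == 0.75
        assert out["precision"][0] == 1.0 and out["recall"][0] == 0.5
        assert out["precision"][1] == pytest.approx(2 / 3)
        assert out["recall"][1] == 1.0

    def test_single_class_predictions(self):
        out = confusion_and_prf([0, 1, 2, 3, 4], [2, 2, 2, 2, 2])
        assert out["recall"][2] == 1.0
        assert all(out["recall"][c] == 0 for c in (0, 1, 3, 4))

    def test_normalized_rows_sum_to_one_or_zero(self, rng):
        y_true = rng.integers(0, 5, 60)
        y_pred = rng.integers(0, 5, 60)
        out = confusion_and_prf(y_true, y_pred)
        sums = np.asarray(out["confusion_normalized"]).sum(axis=1)
        present = np.bincount(y_true, minlength=5) > 0
        assert np.allclose(sums[present], 1.0)
        assert np.allclose(sums[~present], 0.0)

    def test_label_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            confusion_and_prf([0, 5], [0, 1])


class TestKappa:
    def test_perfect_agreement(self):
        assert cohens_kappa([0, 1, 2, 0], [0, 1, 2, 0]) == 1.0

    def test_hand_marginal_example(self):
        # po=.75; pe = .5*.25 + .5*.75 = .5 -> kappa = .5
        assert cohens_kappa([0, 0, 1, 1], [0, 1, 1, 1]) == pytest.approx(0.5)

    def test_independent_labels_give_near_zero(self):
        rng = np.random.default_rng(11)
        y1 = rng.integers(0, 5, 100_000)
        y2 = rng.integers(0, 5, 100_000)
        assert abs(cohens_kappa(y1, y2)) < 0.02

    def test_matches_oracle_on_fuzzed_sets(self, rng):
        for _ in range(300):
            n = rng.integers(5, 50)
            y1 = rng.integers(0, 5, n)
            y2 = rng.integers(0, 5, n)
            if (y1 == y2).all() or len(set(y1)) == 1:
                continue
            assert cohens_kappa(y1, y2) == pytest.approx(
                oracle_kappa(list(y1), list(y2)), abs=1e-9)


class TestMcc:
    def test_perfect_and_inverted(self):
        assert mcc([0, 1, 0, 1], [0, 1, 0, 1]) == 1.0
        assert mcc([0, 1, 0, 1], [1, 0, 1, 0]) == -1.0

    def test_matches_covariance_oracle(self, rng):
        for _ in range(300):
            n = rng.integers(5, 50)
            y1 = rng.integers(0, 3, n)
            y2 = rng.integers(0, 3, n)
            assert mcc(y1, y2) == pytest.approx(
                oracle_mcc(list(y1), list(y2)), abs=1e-9)

    def test_degenerate_returns_zero_with_warning(self):
        with pytest.warns(UserWarning, match="zero"):
            assert mcc([1, 1, 1], [1, 1, 1]) == 0.0


class TestOvrAuc:
    def test_one_hot_scores_are_perfect(self):
        y = np.array([0, 1, 2, 3, 4, 0, 1, 2, 3, 4])
        scores = np.eye(5)[y]
        macro, micro = ovr_auc(y, scores)
        assert macro == 1.0 and micro == 1.0

    def test_constant_scores_are_chance(self):
        y = np.array([0, 1, 2, 3, 4] * 4)
        macro, micro = ovr_auc(y, np.full((20, 5), 0.2))
        assert macro == pytest.approx(0.5)
        assert micro == pytest.approx(0.5)

    def test_six_sample_pair_counting(self):
        y = np.array([0, 0, 0, 1, 1, 1])
        s1 = np.array([0.1, 0.4, 0.35, 0.8, 0.65, 0.4])
        scores = np.stack([1 - s1, s1], axis=1)
        macro, micro = ovr_auc(y, scores, n_classes=2)
        expected = oracle_auc_pairs(y, s1)
        assert macro == pytest.approx(expected, abs=1e-9)

    def test_matches_pair_counting_on_fuzzed_scores(self, rng):
        for _ in range(100):
            n = rng.integers(8, 40)
            y = rng.integers(0, 3, n)
            if len(set(y)) < 2:
                continue
            scores = np.round(rng.random((n, 3)), 2)  # induce ties
            present = [c for c in range(3) if (y == c).any()]
            per_class = [oracle_auc_pairs(y == c, scores[:, c])
                         for c in present if not (y == c).all()]
            macro, micro = ovr_auc(y, scores, n_classes=3)
            assert macro == pytest.approx(np.mean(per_class), abs=1e-9)
            onehot = np.eye(3)[y]
            assert micro == pytest.approx(
                oracle_auc_pairs(onehot.ravel(), scores.ravel()), abs=1e-9)


class TestEce:
    def test_confident_and_correct_is_zero(self):
        value, _ = ece(np.ones(10), np.ones(10, bool))
        assert value == 0.0

    def test_single_bin_hand_arithmetic(self):
        conf = np.full(10, 0.9)
        correct = np.array([True] * 5 + [False] * 5)
        value, bins = ece(conf, correct)
        assert value == pytest.approx(0.4)
        assert bins.counts.sum() == 10

    def test_permutation_invariant(self, rng):
        conf = rng.random(50)
        correct = rng.random(50) > 0.5
        v1, _ = ece(conf, correct)
        order = rng.permutation(50)
        v2, _ = ece(conf[order], correct[order])
        assert v1 == pytest.approx(v2, abs=1e-12)

    def test_matches_bin_oracle_on_fuzzed_inputs(self, rng):
        for _ in range(100):
            n = rng.integers(1, 60)
            conf = np.round(rng.random(n), 3)
            correct = rng.random(n) > 0.4
            value, bins = ece(conf, correct, n_bins=15)
            assert value == pytest.approx(
                oracle_ece(list(conf), list(correct), 15), abs=1e-9)
            assert bins.n == n

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            ece([], [])


class TestCiT:
    def test_constant_values_zero_width(self):
        s = ci_t([3.0, 3.0, 3.0])
        assert s.low == s.high == s.mean == 3.0

    def test_five_fold_half_width(self):
        # five values centred on 83.60 with sample std 1.55
        base = np.array([-1.0, -0.5, 0.0, 0.5, 1.0])
        vals = 83.60 + base * 1.55 / base.std(ddof=1)
        s = ci_t(vals)
        assert s.std == pytest.approx(1.55)
        assert s.t_quantile == pytest.approx(2.776, abs=1e-3)
        assert (s.high - s.low) / 2 == pytest.approx(2.776 * 1.55 / np.sqrt(5),
                                                     abs=2e-3)

    def test_coverage_under_normal_sampling(self):
        rng = np.random.default_rng(5)
        mu = 10.0
        hits = 0
        n_rep = 10_000
        for _ in range(n_rep):
            s = ci_t(rng.normal(mu, 2.0, 5))
            hits += s.low <= mu <= s.high
        assert hits / n_rep == pytest.approx(0.95, abs=0.01)

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            ci_t([1.0])


class TestPairedTTest:
    def test_identical_vectors_error_not_nan(self):
        with pytest.raises(ValueError, match="zero variance"):
            paired_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_constant_shift_with_noise_matches_scipy_closed_form(self, rng):
        a = rng.normal(0, 1, 8)
        b = a - 0.5 + rng.normal(0, 0.1, 8)
        t, p = paired_ttest(a, b)
        d = a - b
        t_exp = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        assert t == pytest.approx(t_exp, abs=1e-9)
        assert 0 <= p <= 1

    def test_swapping_arguments_flips_sign(self, rng):
        a = rng.normal(0, 1, 6)
        b = rng.normal(0.5, 1, 6)
        t1, p1 = paired_ttest(a, b)
        t2, p2 = paired_ttest(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)


class TestEvalReport:
    def test_report_round_trips_through_json(self, tmp_path, rng):
        y = rng.integers(0, 5, 40)
        proba = rng.dirichlet(np.ones(5), size=40)
        report = evaluate(y, proba)
        path = tmp_path / "report.json"
        report.to_json(path)
        loaded = EvalReport.from_json(path)
        assert loaded == report

    def test_metric_ranges(self, rng):
        y = rng.integers(0, 5, 60)
        proba = rng.dirichlet(np.ones(5), size=60)
        r = evaluate(y, proba)
        assert 0 <= r.accuracy <= 1 and 0 <= r.ece <= 1
        assert -1 <= r.kappa <= 1 and -1 <= r.mcc <= 1
        assert np.asarray(r.confusion).sum() == 60
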