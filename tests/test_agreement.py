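"""Agreement statistics: hand-checked examples, brute-force oracles,
Monte-Carlo recovery, and permutation invariance."""

import numpy as np
import pytest

from swimlap.activities import LabelSequence
from swimlap.agreement import (
    AgreementReport,
    bias_ci,
    bland_altman,
    classification_report,
    mape,
    tem_ci,
)


def _ls(codes):
    return LabelSequence(np.asarray(codes), sample_rate=50.0)


def _brute_force_report(y_true, y_pred, n_classes=8):
    """Independent recomputation of the classification metrics from scratch."""
    cm = np.zeros((n_classes, n_classes), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[t, p] += 1
    precision = np.zeros(n_classes)
    recall = np.zeros(n_classes)
    f1 = np.zeros(n_classes)
    for c in range(n_classes):
        tp = cm[c, c]
        fp = cm[:, c].sum() - tp
        fn = cm[c, :].sum() - tp
        precision[c] = tp / (tp + fp) if tp + fp else 0.0
        recall[c] = tp / (tp + fn) if tp + fn else 0.0
        pr = precision[c] + recall[c]
        f1[c] = 2 * precision[c] * recall[c] / pr if pr else 0.0
    support = cm.sum(axis=1)
    weighted_f1 = (support * f1).sum() / support.sum()
    return cm, precision, recall, f1, support, weighted_f1


class TestClassificationReport:
    def test_perfect_prediction(self, rng):
        seq = _ls(rng.integers(0, 8, size=400))
        rep = classification_report(seq, seq)
        assert rep.accuracy == 1.0
        assert rep.weighted_f1 == 1.0
        assert np.all(rep.f1[rep.support > 0] == 1.0)

    def test_hand_worked_two_class_example(self):
        truth = _ls([0, 0, 1])
        pred = _ls([0, 1, 1])
        rep = classification_report(pred, truth)
        assert rep.precision[0] == 1.0 and rep.recall[0] == 0.5
        assert rep.f1[0] == pytest.approx(2 / 3)
        assert rep.precision[1] == 0.5 and rep.recall[1] == 1.0
        assert rep.f1[1] == pytest.approx(2 / 3)

    def test_matches_brute_force_on_random_sequences(self, rng):
        for _ in range(100):
            n = int(rng.integers(20, 200))
            t = rng.integers(0, 8, size=n)
            p = rng.integers(0, 8, size=n)
            rep = classification_report(_ls(p), _ls(t))
            cm, prec, rec, f1, support, wf1 = _brute_force_report(t, p)
            assert np.array_equal(rep.confusion, cm)
            assert np.allclose(rep.precision, prec)
            assert np.allclose(rep.recall, rec)
            assert np.allclose(rep.f1, f1)
            assert np.array_equal(rep.support, support)
            assert rep.weighted_f1 == pytest.approx(wf1)

    def test_confusion_rows_sum_to_support(self, rng):
        t = rng.integers(0, 8, size=500)
        p = rng.integers(0, 8, size=500)
        rep = classification_report(_ls(p), _ls(t))
        assert np.array_equal(rep.confusion.sum(axis=1), rep.support)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            classification_report(_ls([0, 1]), _ls([0, 1, 2]))


class TestBias:
    def test_identical_vectors(self):
        b, (lo, hi) = bias_ci([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert b == 0.0 and lo == 0.0 and hi == 0.0

    def test_symmetric_differences_cancel(self):
        b, _ = bias_ci([11.0, 9.0], [10.0, 10.0])
        assert b == pytest.approx(0.0)

    def test_ci_matches_bootstrap_oracle(self, rng):
        n = 500
        ref = rng.uniform(20, 26, size=n)
        pred = ref + rng.normal(0.1, 0.5, size=n)
        _, (lo, hi) = bias_ci(pred, ref)
        d = pred - ref
        boots = np.array([
            rng.choice(d, size=n, replace=True).mean() for _ in range(3000)
        ])
        blo, bhi = np.percentile(boots, [2.5, 97.5])
        width = hi - lo
        assert abs(lo - blo) < 0.05 * width + 5e-3
        assert abs(hi - bhi) < 0.05 * width + 5e-3

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError):
            bias_ci([1.0], [1.0])


class TestTem:
    def test_plus_minus_one_differences(self):
        tem, _ = tem_ci([11.0, 9.0], [10.0, 10.0])
        assert tem == pytest.approx(1.0)  # sd = sqrt(2), TEM = sd/sqrt(2)

    def test_zero_differences(self):
        tem, _ = tem_ci([5.0, 5.0, 5.0], [5.0, 5.0, 5.0])
        assert tem == 0.0

    def test_monte_carlo_recovery(self):
        rng = np.random.default_rng(8)
        sigma = 0.7
        ref = rng.uniform(20, 26, size=10_000)
        pred = ref + rng.normal(0, sigma, size=10_000)
        tem, _ = tem_ci(pred, ref)
        assert tem == pytest.approx(sigma / np.sqrt(2), rel=0.02)

    def test_ci_coverage_over_simulations(self):
        # the chi-squared CI for sigma/sqrt(2) should cover the truth ~95%
        rng = np.random.default_rng(99)
        sigma, n, sims = 0.5, 30, 200
        covered = 0
        for _ in range(sims):
            d = rng.normal(0, sigma, size=n)
            _, (lo, hi) = tem_ci(d, np.zeros(n))
            covered += lo <= sigma / np.sqrt(2) <= hi
        assert 0.92 <= covered / sims <= 0.98


class TestBlandAltman:
    def test_zero_differences(self):
        ba = bland_altman([1.0, 2.0], [1.0, 2.0])
        assert ba["bias"] == 0.0 and ba["loa_lower"] == 0.0 and ba["loa_upper"] == 0.0

    def test_limits_match_direct_recomputation(self, rng):
        ref = rng.uniform(20, 26, size=200)
        pred = ref + rng.normal(0.2, 1.0, size=200)
        ba = bland_altman(pred, ref)
        d = pred - ref
        assert ba["bias"] == pytest.approx(d.mean())
        assert ba["loa_lower"] == pytest.approx(d.mean() - 1.96 * d.std(ddof=1))
        assert ba["loa_upper"] == pytest.approx(d.mean() + 1.96 * d.std(ddof=1))
        # limits symmetric about bias
        assert ba["loa_upper"] - ba["bias"] == pytest.approx(ba["bias"] - ba["loa_lower"])


class TestMape:
    def test_exact_prediction_is_zero(self):
        m, sd, s = mape([10.0, 20.0], [10.0, 20.0])
        assert m == 0.0 and s == 0.0

    def test_ten_percent_example(self):
        m, _, _ = mape([11.0], [10.0])
        assert m == pytest.approx(10.0)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            mape([1.0, 2.0], [1.0, 0.0])


class TestReportInvariance:
    def test_permutation_invariance(self, rng):
        ref = rng.uniform(20, 26, size=50)
        pred = ref + rng.normal(0, 0.5, size=50)
        perm = rng.permutation(50)
        a = AgreementReport.compute(pred, ref)
        b = AgreementReport.compute(pred[perm], ref[perm])
        assert a.bias == pytest.approx(b.bias)
        assert a.tem == pytest.approx(b.tem)
        assert a.mape_pct == pytest.approx(b.mape_pct)
        assert a.loa_lower == pytest.approx(b.loa_lower)
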