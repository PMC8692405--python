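"""Statistical procedures against independent oracles and exact identities."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from wsus.stats import (ContingencyTable2x2, delong_test, dice_coefficient,
                        fisher_exact_2x2, mcnemar_exact, roc_auc, sens_spec)


# --------------------------------------------------------------------------
# independent oracles

def auc_by_enumeration(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum(1.0 if x > y else 0.5 if x == y else 0.0
               for x in pos for y in neg)
    return wins / (len(pos) * len(neg))


def jackknife_var_cov(s1, s2, labels):
    """Leave-one-out jackknife variance/covariance of the two AUCs."""
    n = len(labels)
    a1 = np.empty(n)
    a2 = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        a1[i] = auc_by_enumeration(s1[keep], labels[keep])
        a2[i] = auc_by_enumeration(s2[keep], labels[keep])
    factor = (n - 1) / n
    c = np.cov(np.stack([a1, a2]), ddof=1) * (n - 1) * factor
    return c[0, 0], c[1, 1], c[0, 1]


def fisher_two_sided_by_summation(table):
    """Direct hypergeometric summation over all tables with fixed margins."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return (math.comb(r1, x) * math.comb(r2, c1 - x)) / math.comb(n, c1)

    p_obs = prob(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1)
               if prob(x) <= p_obs * (1 + 1e-7))


def mcnemar_by_summation(b, c):
    n = b + c
    if n == 0:
        return 1.0
    k = min(b, c)
    tail = sum(math.comb(n, i) for i in range(k + 1)) / 2 ** n
    return min(1.0, 2 * tail)


# --------------------------------------------------------------------------


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]).auc == 1.0

    def test_all_ties(self):
        assert roc_auc([0.5] * 6, [0, 0, 0, 1, 1, 1]).auc == 0.5

    def test_hand_enumerated_example(self):
        assert roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]).auc == 0.75

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(0)
        scores = rng.random(60)
        labels = rng.integers(0, 2, 60)
        labels[:2] = [0, 1]
        assert roc_auc(scores, labels).auc == pytest.approx(
            roc_auc_score(labels, scores))

    def test_complement_identity(self):
        rng = np.random.default_rng(1)
        scores = np.round(rng.random(40), 1)  # force ties
        labels = np.r_[np.zeros(20, int), np.ones(20, int)]
        assert (roc_auc(scores, labels).auc
                + roc_auc(-scores, labels).auc) == pytest.approx(1.0)

    def test_ci_ordering_and_clipping(self):
        est = roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert 0 <= est.ci_low <= est.auc <= est.ci_high <= 1

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])


class TestDelong:
    def test_identical_arms_p_one(self):
        s = np.array([0.1, 0.4, 0.35, 0.8])
        res = delong_test(s, s, [0, 0, 1, 1])
        assert res.p == 1.0 and res.auc1 == res.auc2

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(2)
        s1, s2 = rng.random(30), rng.random(30)
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        r = delong_test(s1, s2, labels)
        r_swap = delong_test(s1, s2, 1 - labels)
        assert abs(r.z) == pytest.approx(abs(r_swap.z), abs=1e-10)
        assert r_swap.auc1 == pytest.approx(1 - r.auc1)

    def test_variance_covariance_match_jackknife(self):
        rng = np.random.default_rng(3)
        labels = np.r_[np.zeros(10, int), np.ones(10, int)]
        s1 = rng.random(20)
        s2 = 0.6 * s1 + 0.4 * rng.random(20)
        res = delong_test(s1, s2, labels)
        v1, v2, cov = jackknife_var_cov(s1, s2, labels)
        assert res.var1 == pytest.approx(v1, rel=0.10)
        assert res.var2 == pytest.approx(v2, rel=0.10)
        assert res.cov == pytest.approx(cov, rel=0.10)

    def test_unpaired_rejected(self):
        with pytest.raises(ValueError):
            delong_test([0.1, 0.2], [0.1, 0.2, 0.3], [0, 1])


class TestMcnemar:
    def test_printed_examples(self):
        assert mcnemar_exact(0, 0) == 1.0
        assert mcnemar_exact(10, 0) == pytest.approx(2 ** -9)
        assert mcnemar_exact(7, 7) == 1.0

    def test_agrees_with_direct_summation_all_small_counts(self):
        for b in range(31):
            for c in range(31):
                assert mcnemar_exact(b, c) == pytest.approx(
                    mcnemar_by_summation(b, c), abs=1e-12)

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar
        for b, c in [(3, 9), (0, 5), (12, 4)]:
            table = [[10, b], [c, 10]]
            expected = sm_mcnemar(table, exact=True).pvalue
            assert mcnemar_exact(b, c) == pytest.approx(expected, abs=1e-12)

    def test_monotone_in_imbalance(self):
        ps = [mcnemar_exact(b, 20 - b) for b in range(11)]
        assert all(ps[i] <= ps[i + 1] + 1e-12 for i in range(10))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            mcnemar_exact(-1, 2)


class TestFisher:
    @pytest.mark.parametrize("table,expected", [
        (((96, 4), (98, 2)), 0.68),
        (((97, 3), (100, 0)), 0.25),
        (((99, 1), (100, 0)), 1.00),
    ])
    def test_reference_tables_round_to_printed_values(self, table, expected):
        p = fisher_exact_2x2(np.array(table))
        assert round(p, 2) == expected

    def test_agrees_with_direct_summation(self):
        rng = np.random.default_rng(4)
        tables = [np.array(t) for t in
                  [((96, 4), (98, 2)), ((97, 3), (100, 0)), ((50, 50), (50, 50))]]
        tables += [rng.integers(0, 40, size=(2, 2)) + 1 for _ in range(20)]
        for t in tables:
            assert fisher_exact_2x2(t) == pytest.approx(
                fisher_two_sided_by_summation(t), rel=1e-9)

    def test_identical_rows_p_one(self):
        assert fisher_exact_2x2(np.array([[50, 50], [50, 50]])) == 1.0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(np.zeros((2, 2), dtype=int))

    def test_table_type_validates(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(1, -1, 2, 2)


class TestDice:
    def test_identical_and_disjoint(self):
        a = np.zeros((10, 10), dtype=bool)
        a[2:5, 2:5] = True
        assert dice_coefficient(a, a) == 1.0
        b = np.zeros((10, 10), dtype=bool)
        b[7:9, 7:9] = True
        assert dice_coefficient(a, b) == 0.0

    def test_constructed_counts(self):
        ms = np.zeros(200, dtype=bool)
        mg = np.zeros(200, dtype=bool)
        ms[:100] = True          # |M_s| = 100
        mg[60:110] = True        # |M_g| = 50, overlap = 40
        assert dice_coefficient(ms, mg) == pytest.approx(2 * 40 / 150)

    def test_symmetry_and_iou_identity_random_pairs(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            a = rng.random((12, 12)) > 0.5
            b = rng.random((12, 12)) > 0.5
            if not (a.any() or b.any()):
                continue
            d_ab = dice_coefficient(a, b)
            assert d_ab == dice_coefficient(b, a)
            union = np.sum(a | b)
            iou = np.sum(a & b) / union if union else 0.0
            assert d_ab == pytest.approx(2 * iou / (1 + iou))

    def test_both_empty_rejected(self):
        with pytest.raises(ValueError):
            dice_coefficient(np.zeros((3, 3), bool), np.zeros((3, 3), bool))


class TestSensSpec:
    def test_perfect_scores(self):
        r = sens_spec([1, 1, 0, 0], [1, 1, 0, 0])
        assert r.sensitivity == 1.0 and r.specificity == 1.0

    def test_zero_threshold_calls_everything_positive(self):
        r = sens_spec([0.2, 0.8, 0.3, 0.9], [0, 1, 0, 1], threshold=0.0)
        assert r.sensitivity == 1.0 and r.specificity == 0.0

    def test_formatted_fraction(self):
        scores = np.r_[np.linspace(0.6, 1.0, 87), np.linspace(0.0, 0.4, 13),
                       np.zeros(100)]
        labels = np.r_[np.ones(100, int), np.zeros(100, int)]
        r = sens_spec(scores, labels)
        assert r.format()[0] == "87% (87/100)"
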