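"""Diagnostics: summaries, ROC/Youden, exact tests — each checked against
an independent brute-force oracle where one exists."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from mibgquant import diagnostics as dg
from mibgquant.errors import (
    EmptyGroup,
    EmptySample,
    LengthMismatch,
    NegativeCount,
    OneClassOnly,
    TooFewValues,
)


# --------------------------------------------------------------------------
# oracles


def auc_by_pair_enumeration(pos, neg):
    """P(neg > pos) + 0.5 P(tie) by direct enumeration of all pairs."""
    wins = ties = 0
    for p in pos:
        for n in neg:
            wins += n > p
            ties += n == p
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def mann_whitney_enumeration(x, y):
    """Exact two-sided p: fraction of rank splits at least as extreme
    (symmetric deviation of U from its mean), tie-aware."""
    n1 = len(x)
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    mu = n1 * len(y) / 2.0
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    count = total = 0
    for idx in combinations(range(len(combined)), n1):
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2.0
        count += abs(u - mu) >= abs(u_obs - mu) - 1e-12
        total += 1
    return count / total


def fisher_enumeration(table):
    """Two-sided Fisher p: sum of hypergeometric probabilities of all
    fixed-margin tables no more probable than the observed one."""
    a, b = table[0]
    c, d = table[1]
    r1, n = a + b, a + b + c + d
    c1 = a + c
    if r1 == 0 or c1 == 0 or r1 == n or c1 == n:
        return 1.0  # fixed margins admit a single table
    p_obs = stats.hypergeom.pmf(a, n, r1, c1)
    p = 0.0
    for k in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        pk = stats.hypergeom.pmf(k, n, r1, c1)
        if pk <= p_obs * (1 + 1e-9):
            p += pk
    return min(p, 1.0)


# --------------------------------------------------------------------------


class TestGroupSummary:
    def test_linear_interpolation_quartiles(self):
        s = dg.group_summary([1, 2, 3, 4, 5])
        assert (s.q1, s.median, s.q3) == (2.0, 3.0, 4.0)

    def test_shift_equivariance(self, rng):
        x = rng.normal(size=25)
        s0 = dg.group_summary(x)
        s1 = dg.group_summary(x + 10.0)
        assert s1.median == pytest.approx(s0.median + 10.0)
        assert s1.q1 == pytest.approx(s0.q1 + 10.0)
        assert s1.variance == pytest.approx(s0.variance)
        assert s1.median_ci[0] == pytest.approx(s0.median_ci[0] + 10.0)

    def test_median_ci_order_and_coverage_indices(self):
        s = dg.group_summary(np.arange(1, 21, dtype=float))
        assert s.median_ci[0] <= s.median <= s.median_ci[1]
        # binomial order-statistic bound: CDF below the lower index <= 2.5%
        lo_rank = int(np.searchsorted(np.arange(1, 21), s.median_ci[0]))
        assert stats.binom.cdf(lo_rank - 1, 20, 0.5) <= 0.025

    def test_single_value_rejected(self):
        with pytest.raises(TooFewValues):
            dg.group_summary([1.0])


class TestOverlapRange:
    @pytest.mark.parametrize(
        "lbd,non,expected",
        [
            ([1, 2], [1.5, 3], (1.5, 2.0)),
            ([1, 2], [3, 4], None),
            ([1, 3], [2, 4], (2.0, 3.0)),
        ],
    )
    def test_definition(self, lbd, non, expected):
        assert dg.overlap_range(lbd, non) == expected

    def test_empty_group_rejected(self):
        with pytest.raises(EmptyGroup):
            dg.overlap_range([], [1.0])


class TestEmpiricalRoc:
    def test_perfect_separation(self):
        scores = [0.5, 0.7, 1.5, 1.7]
        labels = ["LBD", "LBD", "non-LBD", "non-LBD"]
        assert dg.empirical_roc(scores, labels).auc == 1.0

    def test_interleaved_case(self):
        roc = dg.empirical_roc([1, 3, 2, 4], ["LBD", "LBD", "non-LBD", "non-LBD"])
        assert roc.auc == 0.75

    def test_all_ties(self):
        roc = dg.empirical_roc([2, 2, 2, 2], ["LBD", "LBD", "non-LBD", "non-LBD"])
        assert roc.auc == 0.5

    def test_one_class_rejected(self):
        with pytest.raises(OneClassOnly):
            dg.empirical_roc([1, 2], ["LBD", "LBD"])

    @given(st.data())
    def test_matches_pair_enumeration(self, data):
        n_pos = data.draw(st.integers(1, 15))
        n_neg = data.draw(st.integers(1, 15))
        vals = data.draw(
            st.lists(st.integers(0, 8), min_size=n_pos + n_neg, max_size=n_pos + n_neg)
        )
        scores = np.array(vals, dtype=float)
        labels = np.array(["LBD"] * n_pos + ["non-LBD"] * n_neg)
        roc = dg.empirical_roc(scores, labels)
        assert roc.auc == pytest.approx(
            auc_by_pair_enumeration(scores[:n_pos], scores[n_pos:]), abs=1e-12
        )


class TestYouden:
    def test_disjoint_groups_midpoint_threshold(self):
        roc = dg.empirical_roc([1, 2, 3, 4], ["LBD", "LBD", "non-LBD", "non-LBD"])
        thr, j = dg.youden_criterion(roc)
        assert thr == 2.5 and j == 1.0

    def test_identical_distributions_give_zero_j(self):
        roc = dg.empirical_roc([1, 2, 1, 2], ["LBD", "LBD", "non-LBD", "non-LBD"])
        _, j = dg.youden_criterion(roc)
        assert j == 0.0

    def test_direction_positive_below_threshold(self):
        scores = [0.5, 1.0, 1.5, 2.0]
        labels = ["LBD", "LBD", "non-LBD", "non-LBD"]
        roc = dg.empirical_roc(scores, labels)
        thr, _ = dg.youden_criterion(roc)
        m = dg.diagnostic_metrics(scores, labels, thr)
        assert m.sensitivity == 1.0 and m.specificity == 1.0

    @given(st.data())
    def test_achieves_exhaustive_scan_maximum(self, data):
        n_pos = data.draw(st.integers(1, 10))
        n_neg = data.draw(st.integers(1, 10))
        vals = data.draw(
            st.lists(st.integers(0, 6), min_size=n_pos + n_neg, max_size=n_pos + n_neg)
        )
        scores = np.array(vals, dtype=float)
        labels = np.array(["LBD"] * n_pos + ["non-LBD"] * n_neg)
        roc = dg.empirical_roc(scores, labels)
        _, j = dg.youden_criterion(roc)
        best = max(
            (scores < c).__and__(labels == "LBD").sum() / n_pos
            + (scores >= c).__and__(labels == "non-LBD").sum() / n_neg
            - 1.0
            for c in np.concatenate([scores - 0.5, scores + 0.5])
        )
        assert j == pytest.approx(best, abs=1e-12)


class TestDiagnosticMetrics:
    def test_perfect_classification(self):
        m = dg.diagnostic_metrics(
            [0.5, 1.0, 1.5, 2.0], ["LBD", "LBD", "non-LBD", "non-LBD"], 1.2
        )
        assert (m.sensitivity, m.specificity, m.ppv, m.npv, m.accuracy) == (1, 1, 1, 1, 1)

    def test_half_right(self):
        m = dg.diagnostic_metrics(
            [0.5, 1.5, 1.0, 2.0], ["LBD", "LBD", "non-LBD", "non-LBD"], 1.2
        )
        assert (m.sensitivity, m.specificity, m.ppv, m.npv, m.accuracy) == (
            0.5, 0.5, 0.5, 0.5, 0.5,
        )

    def test_no_positive_calls_flags_ppv(self):
        m = dg.diagnostic_metrics([1.0, 2.0], ["LBD", "non-LBD"], 0.5)
        assert not m.ppv_defined and np.isnan(m.ppv)
        assert m.npv_defined

    def test_confusion_identities(self, rng):
        scores = rng.normal(size=30)
        labels = np.where(rng.random(30) < 0.5, "LBD", "non-LBD")
        if (labels == "LBD").all() or (labels == "non-LBD").all():
            labels[0], labels[1] = "LBD", "non-LBD"
        m = dg.diagnostic_metrics(scores, labels, 0.1)
        P = (labels == "LBD").sum()
        N = (labels == "non-LBD").sum()
        tp = m.sensitivity * P
        tn = m.specificity * N
        assert tp == pytest.approx(round(tp))
        assert m.accuracy == pytest.approx((tp + tn) / (P + N))


class TestMannWhitney:
    def test_disjoint_small_sample(self):
        res = dg.mann_whitney_u([1, 2], [3, 4])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1 / 3)

    def test_identical_multisets_p_one(self):
        res = dg.mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert res.p_value == pytest.approx(1.0)

    def test_interleaved_small_sample(self):
        res = dg.mann_whitney_u([1, 3], [2, 4])
        assert res.statistic == 1.0
        assert res.p_value == pytest.approx(2 / 3)

    def test_empty_sample_rejected(self):
        with pytest.raises(EmptySample):
            dg.mann_whitney_u([], [1.0])

    @given(st.data())
    def test_matches_enumeration_oracle(self, data):
        n1 = data.draw(st.integers(1, 6))
        n2 = data.draw(st.integers(1, 6))
        x = data.draw(st.lists(st.integers(0, 5), min_size=n1, max_size=n1))
        y = data.draw(st.lists(st.integers(0, 5), min_size=n2, max_size=n2))
        res = dg.mann_whitney_u(np.array(x, float), np.array(y, float))
        assert res.p_value == pytest.approx(mann_whitney_enumeration(x, y), abs=1e-12)


class TestFisherExact:
    def test_balanced_sex_table(self):
        # the canonical 2x2 check: 17/20 vs 20/20 male/female split
        res = dg.fisher_exact_2x2([[17, 20], [20, 20]])
        assert res.p_value == pytest.approx(0.821, abs=5e-4)

    def test_diagonal_table(self):
        res = dg.fisher_exact_2x2([[5, 0], [0, 5]])
        assert res.p_value == pytest.approx(2 / 252, rel=1e-9)

    def test_degenerate_row_gives_p_one(self):
        assert dg.fisher_exact_2x2([[0, 0], [3, 4]]).p_value == pytest.approx(1.0)

    def test_negative_count_rejected(self):
        with pytest.raises(NegativeCount):
            dg.fisher_exact_2x2([[1, -1], [2, 3]])

    @given(
        a=st.integers(0, 6), b=st.integers(0, 6), c=st.integers(0, 6), d=st.integers(0, 6)
    )
    def test_matches_hypergeometric_enumeration(self, a, b, c, d):
        table = [[a, b], [c, d]]
        res = dg.fisher_exact_2x2(table)
        assert res.p_value == pytest.approx(fisher_enumeration(table), abs=1e-9)


class TestSpearman:
    def test_monotone_and_reverse(self):
        x = np.arange(10.0)
        assert dg.spearman_rho(x, x**3).statistic == pytest.approx(1.0)
        assert dg.spearman_rho(x, -x).statistic == pytest.approx(-1.0)

    def test_hand_computed_rank_formula(self):
        res = dg.spearman_rho([1, 2, 3], [2, 1, 3])
        assert res.statistic == pytest.approx(0.5)

    def test_length_mismatch_rejected(self):
        with pytest.raises(LengthMismatch):
            dg.spearman_rho([1, 2, 3], [1, 2])


class TestCompareAuc:
    def _labels(self, n_pos, n_neg):
        return np.array(["LBD"] * n_pos + ["non-LBD"] * n_neg)

    def test_identical_scores_p_one(self, rng):
        s = rng.normal(size=20)
        labels = self._labels(10, 10)
        res = dg.compare_auc(s, s, labels)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_swap_symmetry(self, rng):
        a = rng.normal(size=24)
        b = rng.normal(size=24)
        labels = self._labels(12, 12)
        r1 = dg.compare_auc(a, b, labels)
        r2 = dg.compare_auc(b, a, labels)
        assert r1.p_value == pytest.approx(r2.p_value)
        assert r1.statistic == pytest.approx(-r2.statistic)

    def test_detects_auc_gap_in_simulation(self):
        # true AUCs ~0.95 vs ~0.75: the paired test flags the gap
        hits = 0
        n_rep = 100
        for rep in range(n_rep):
            rng = np.random.default_rng(1000 + rep)
            n = 200
            truth = np.concatenate([np.zeros(n), np.ones(n)])
            labels = np.where(truth == 0, "LBD", "non-LBD")
            a = truth * 2.33 + rng.standard_normal(2 * n)  # AUC ~ 0.95
            b = truth * 0.95 + rng.standard_normal(2 * n)  # AUC ~ 0.75
            res = dg.compare_auc(a, b, labels)
            hits += res.p_value < 0.01
        assert hits >= 95

    def test_length_mismatch_rejected(self):
        with pytest.raises(LengthMismatch):
            dg.compare_auc([1, 2], [1, 2, 3], np.array(["LBD", "non-LBD"]))


class TestEvaluateCohort:
    def test_report_has_three_methods_with_all_metrics(self, rng):
        n = 20
        rows = []
        for i in range(n):
            g = "LBD" if i < 10 else "non-LBD"
            base = 0.6 if g == "LBD" else 1.7
            rows.append(
                {
                    "subject": f"s{i}",
                    "group": g,
                    "hm": base * 2 + rng.normal(0, 0.1),
                    "planar_index": base + rng.normal(0, 0.1),
                    "spect_index": base + rng.normal(0, 0.05),
                }
            )
        table = dg.CohortTable(pd.DataFrame(rows))
        report = dg.evaluate_cohort(table)
        frame = report.to_frame()
        assert list(frame["method"]) == ["hm", "planar_index", "spect_index"]
        for col in ("auc", "sensitivity", "specificity", "criterion", "ppv", "npv", "accuracy"):
            assert col in frame.columns and frame[col].notna().all()
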