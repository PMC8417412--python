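import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import comb
from sklearn.metrics import roc_auc_score

from neolos.stats import (
    TwoByTwo,
    chi_square_or_fisher,
    diagnostic_metrics,
    odds_ratio,
    ordinal_auc,
    roc_and_youden,
    round_half_up,
)


def brute_force_auc(group_counts):
    """Pairwise-comparison oracle: expand every case and control to its
    risk level and count winning/tied pairs directly."""
    levels = range(len(group_counts) - 1, -1, -1)  # high risk = high number
    cases = [lvl for lvl, (c, _) in zip(levels, group_counts) for _ in range(c)]
    controls = [lvl for lvl, (_, k) in zip(levels, group_counts) for _ in range(k)]
    wins = sum(1.0 if a > b else 0.5 if a == b else 0.0 for a in cases for b in controls)
    return wins / (len(cases) * len(controls))


class TestOddsRatio:
    def test_crp_row(self):
        res = odds_ratio(TwoByTwo(30, 3, 10, 62))
        assert round_half_up(res.odds_ratio, 1) == 62.0
        assert round_half_up(res.ci_low, 1) == 15.9
        assert round_half_up(res.ci_high, 1) == 242.0
        assert not res.corrected

    def test_haldane_correction_on_zero_cell(self):
        res = odds_ratio(TwoByTwo(33, 0, 17, 55))
        assert res.corrected
        assert res.odds_ratio == pytest.approx((33.5 * 55.5) / (0.5 * 17.5))
        assert round_half_up(res.odds_ratio, 1) == 212.5

    def test_symmetric_table_is_null(self):
        assert odds_ratio(TwoByTwo(1, 1, 1, 1)).odds_ratio == 1.0

    def test_zero_cell_without_correction_raises(self):
        with pytest.raises(ValueError, match="undefined"):
            odds_ratio(TwoByTwo(5, 0, 3, 4), correction="none")

    @given(st.tuples(*[st.integers(1, 60)] * 4))
    @settings(derandomize=True, max_examples=60)
    def test_transposed_exposure_inverts_or(self, cells):
        a, b, c, d = cells
        fwd = odds_ratio(TwoByTwo(a, b, c, d), correction="none")
        rev = odds_ratio(TwoByTwo(b, a, d, c), correction="none")
        assert fwd.odds_ratio * rev.odds_ratio == pytest.approx(1.0)
        assert fwd.ci_low <= fwd.odds_ratio <= fwd.ci_high

    def test_ci_widens_as_cells_shrink(self):
        wide = odds_ratio(TwoByTwo(3, 2, 2, 3))
        narrow = odds_ratio(TwoByTwo(30, 20, 20, 30))
        assert (wide.ci_high / wide.ci_low) > (narrow.ci_high / narrow.ci_low)


class TestDiagnosticMetrics:
    @pytest.mark.parametrize(
        "tp,fp,tn,fn,expected",
        [
            (33, 18, 54, 0, (100.0, 75.0, 64.7, 100.0)),
            (30, 10, 62, 3, (90.9, 86.1, 75.0, 95.4)),
        ],
    )
    def test_published_rows(self, tp, fp, tn, fn, expected):
        m = diagnostic_metrics(tp, fp, tn, fn).rounded()
        assert (m["sensitivity"], m["specificity"], m["ppv"], m["npv"]) == expected

    def test_undefined_ppv_flagged(self):
        m = diagnostic_metrics(0, 0, 1, 1)
        assert m.sensitivity == 0.0 and m.specificity == 100.0
        assert m.ppv is None

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            diagnostic_metrics(-1, 0, 1, 1)

    @given(st.tuples(*[st.integers(1, 500)] * 4))
    @settings(derandomize=True, max_examples=100)
    def test_bayes_consistency(self, counts):
        tp, fp, tn, fn = counts
        m = diagnostic_metrics(tp, fp, tn, fn)
        prev = (tp + fn) / (tp + fp + tn + fn)
        se, sp = m.sensitivity / 100, m.specificity / 100
        expected_ppv = 100 * se * prev / (se * prev + (1 - sp) * (1 - prev))
        assert m.ppv == pytest.approx(expected_ppv, rel=1e-10)


class TestOrdinalAuc:
    def test_decision_tree_nodes(self):
        assert ordinal_auc([(21, 2), (12, 16), (0, 54)]) == pytest.approx(
            brute_force_auc([(21, 2), (12, 16), (0, 54)])
        )
        assert round_half_up(ordinal_auc([(21, 2), (12, 16), (0, 54)]), 2) == 0.94

    def test_binary_predictor_equals_mean_of_se_sp(self):
        # NLR row: se = 1, sp = 55/72
        auc = ordinal_auc([(33, 17), (0, 55)])
        assert auc == pytest.approx((1.0 + 55 / 72) / 2)

    def test_no_discrimination(self):
        assert ordinal_auc([(10, 20), (10, 20)]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ordinal_auc([(5, 0), (3, 0)])

    @given(
        st.lists(
            st.tuples(st.integers(0, 20), st.integers(0, 20)),
            min_size=2,
            max_size=5,
        )
    )
    @settings(derandomize=True, max_examples=150)
    def test_matches_pairwise_oracle(self, counts):
        n_cases = sum(c for c, _ in counts)
        n_controls = sum(k for _, k in counts)
        if n_cases == 0 or n_controls == 0 or n_cases + n_controls > 200:
            return
        assert ordinal_auc(counts) == pytest.approx(brute_force_auc(counts))


class TestRocAndYouden:
    def test_perfect_separation(self):
        values = [1, 2, 3, 10, 11, 12]
        labels = [False] * 3 + [True] * 3
        curve, cutoff = roc_and_youden(values, labels)
        assert curve.auc == pytest.approx(1.0)
        assert cutoff.youden == pytest.approx(1.0)
        assert 3 <= cutoff.threshold < 10

    def test_agrees_with_sklearn_auc(self):
        rng = np.random.default_rng(7)
        labels = rng.random(300) < 0.4
        values = rng.normal(loc=labels.astype(float), scale=1.0)
        curve, _ = roc_and_youden(values, labels)
        assert curve.auc == pytest.approx(roc_auc_score(labels, values), abs=1e-10)

    def test_null_predictor_auc_near_half(self):
        rng = np.random.default_rng(11)
        labels = np.arange(2000) % 2 == 0
        values = rng.normal(size=2000)
        curve, _ = roc_and_youden(values, labels)
        assert curve.auc == pytest.approx(0.5, abs=0.05)

    def test_crp_like_sample_selects_published_cutoff_region(self):
        # cases/controls whose exceedance above 0.75 matches the CRP table
        # row (30/33 vs 10/72); exhaustive threshold scan confirms the
        # interval containing 0.75 maximises Youden
        case_vals = [0.1] * 3 + [5.0] * 30
        control_vals = [0.3] * 62 + [5.0] * 10
        values = np.array(case_vals + control_vals)
        labels = np.array([True] * 33 + [False] * 72)
        best = max(
            ((t, np.mean(values[labels] > t) + np.mean(~(values[~labels] > t)) - 1)
             for t in np.unique(values)),
            key=lambda tv: tv[1],
        )
        _, cutoff = roc_and_youden(values, labels)
        assert cutoff.youden == pytest.approx(best[1])
        assert cutoff.youden == pytest.approx(30 / 33 + 62 / 72 - 1)
        assert 0.3 <= cutoff.threshold < 5.0  # the interval holding 0.75

    def test_constant_predictor_warns(self):
        with pytest.warns(UserWarning, match="degenerate"):
            roc_and_youden([1.0, 1.0, 1.0], [True, False, True])


class TestChiSquareOrFisher:
    def test_independence(self):
        res = chi_square_or_fisher(TwoByTwo(10, 10, 10, 10))
        assert res.test_used == "chi_square"
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_fisher_on_sparse_table(self):
        res = chi_square_or_fisher(TwoByTwo(5, 0, 0, 5))
        assert res.test_used == "fisher"
        # exact hypergeometric enumeration: only the two perfectly
        # concordant tables are as extreme, out of C(10,5) arrangements
        assert res.p_value == pytest.approx(2 / comb(10, 5), rel=1e-12)

    def test_strong_association_large_table(self):
        res = chi_square_or_fisher(TwoByTwo(80, 20, 20, 80))
        assert res.test_used == "chi_square"
        assert res.p_value < 0.001
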