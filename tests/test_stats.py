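import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import rankdata

from pedfem.stats import (
    bonferroni_alpha,
    cohort_compare,
    lin_ccc,
    mcbride_grade,
    wilcoxon_signed_rank,
)


def brute_force_wilcoxon(pre, post):
    """Independent oracle: enumerate every sign vector explicitly."""
    d = np.asarray(post, float) - np.asarray(pre, float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(sum(r for r, s in zip(ranks, signs) if s))
    ws = np.array(ws)
    m = len(ws)
    lo = np.count_nonzero(ws <= w_obs + 1e-9) / m
    hi = np.count_nonzero(ws >= w_obs - 1e-9) / m
    return min(1.0, 2 * min(lo, hi))


class TestLinCCC:
    def test_perfect_concordance(self):
        assert lin_ccc([1, 2, 3], [1, 2, 3]).ccc == pytest.approx(1.0)

    def test_hand_example_shifted_line(self):
        # x=(1,2,3), y=x+1: population moments give 2*(2/3)/(2/3+2/3+1)=4/7
        r = lin_ccc([1, 2, 3], [2, 3, 4])
        assert r.ccc == pytest.approx(4.0 / 7.0)

    def test_symmetry_and_pearson_bound(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=30)
        y = 0.8 * x + rng.normal(size=30) * 0.3 + 0.5
        assert lin_ccc(x, y).ccc == pytest.approx(lin_ccc(y, x).ccc)
        assert abs(lin_ccc(x, y).ccc) <= abs(np.corrcoef(x, y)[0, 1]) + 1e-12

    def test_constant_vectors_rejected(self):
        with pytest.raises(ValueError):
            lin_ccc([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])


class TestMcBride:
    @pytest.mark.parametrize("ccc,grade", [
        (0.999, "excellent"), (0.995, "excellent"), (0.985, "good"),
        (0.93, "moderate"), (0.88, "poor"),
        # boundary values fall to the lower grade
        (0.99, "good"), (0.95, "moderate"), (0.90, "poor"),
    ])
    def test_thresholds(self, ccc, grade):
        assert mcbride_grade(ccc) == grade


class TestWilcoxon:
    def test_n8_one_sided_extreme(self):
        """Eight untied positive differences: p = 2/256 = 0.00781."""
        pre = np.arange(8.0)
        post = pre + np.linspace(1.0, 1.7, 8)
        p = wilcoxon_signed_rank(pre, post)
        assert p == pytest.approx(2.0 / 256.0)
        assert float(f"{p:.3g}") == 0.00781

    def test_n3_hand_enumeration(self):
        # differences (1,2,3): W+=6 occurs once of 8; two-sided 2/8
        p = wilcoxon_signed_rank([0, 0, 0], [1, 2, 3])
        assert p == pytest.approx(0.25)

    def test_all_zero_differences_undefined(self):
        assert np.isnan(wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0]))

    @settings(deadline=None, max_examples=40)
    @given(st.lists(st.integers(-6, 6), min_size=2, max_size=10))
    def test_matches_brute_force_enumeration(self, diffs):
        """Exact p equals the explicit 2^n oracle, ties and zeros included."""
        pre = np.zeros(len(diffs))
        post = np.array(diffs, dtype=float)
        if np.all(post == 0):
            assert np.isnan(wilcoxon_signed_rank(pre, post))
        else:
            assert wilcoxon_signed_rank(pre, post) == \
                pytest.approx(brute_force_wilcoxon(pre, post))

    def test_matches_scipy_exact_no_ties(self):
        from scipy.stats import wilcoxon as scipy_wilcoxon

        rng = np.random.default_rng(11)
        for n in (6, 9, 12):
            d = rng.normal(size=n)
            d[d == 0] = 0.1
            ours = wilcoxon_signed_rank(np.zeros(n), d)
            ref = scipy_wilcoxon(d, mode="exact").pvalue
            assert ours == pytest.approx(ref)

    def test_type_one_error_calibration(self):
        """Null rejection rate at alpha=0.0167 over 2000 simulations lies
        in [0.008, 0.026] (discreteness keeps it below nominal)."""
        rng = np.random.default_rng(2024)
        alpha = bonferroni_alpha(0.05, 3)
        rejections = 0
        nsim = 2000
        for _ in range(nsim):
            d = rng.normal(size=8)
            p = wilcoxon_signed_rank(np.zeros(8), d)
            rejections += p < alpha
        rate = rejections / nsim
        assert 0.008 <= rate <= 0.026


class TestBonferroni:
    def test_paper_threshold(self):
        assert bonferroni_alpha(0.05, 3) == 0.0167

    def test_single_comparison(self):
        assert bonferroni_alpha(0.05, 1) == 0.05

    def test_direct_division(self):
        assert bonferroni_alpha(0.01, 5) == 0.002

    def test_zero_comparisons_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_alpha(0.05, 0)


class TestCohortCompare:
    def _pre(self):
        return pd.DataFrame({
            "C5MH": [4.9, 3.2, 9.5, 5.1, 6.0, 4.4, 7.7, 5.5],
            "CP": [13.5, 9.5, 15.8, 12.0, 14.2, 10.8, 13.0, 12.5],
        })

    def test_identical_cohorts_not_significant(self):
        pre = self._pre()
        table = cohort_compare(pre, {4.0: pre.copy(), 8.0: pre.copy(),
                                     12.0: pre.copy()})
        assert not table.filter(like="sig_").to_numpy().any()

    def test_planted_shift_significant_at_n8(self):
        pre = self._pre()
        post = {d: pre + 0.5 * d for d in (4.0, 8.0, 12.0)}
        table = cohort_compare(pre, post)
        assert table.loc["C5MH", "p_vs_8mm"] == pytest.approx(0.00781,
                                                              abs=5e-6)
        assert bool(table.loc["C5MH", "sig_vs_8mm"])

    def test_three_p_values_per_parameter(self):
        pre = self._pre()
        table = cohort_compare(pre, {d: pre + 1.0 for d in (4.0, 8.0, 12.0)})
        pcols = [c for c in table.columns if c.startswith("p_vs_")]
        assert len(pcols) == 3

    def test_length_mismatch_rejected(self):
        pre = self._pre()
        with pytest.raises(ValueError):
            cohort_compare(pre, {4.0: pre.iloc[:5]})
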