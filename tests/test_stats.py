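"""Statistical primitives against independent oracles (scipy, statsmodels,
exhaustive enumeration, hand calculation)."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from triomics.stats import (
    DegenerateMarginError,
    OrderTestError,
    _enumerate_assignments,
    _jt_moments,
    _jt_statistic,
    bh_adjust,
    chi_square_contingency,
    fisher_exact_2x2,
    fold_change,
    jonckheere_terpstra,
    kruskal_wallis,
    t_test_welch,
    wilcoxon_rank_sum,
)


class TestWilcoxon:
    def test_complete_separation_exact(self):
        # n=m=3: only 2 of the C(6,3)=20 rank assignments are as extreme
        res = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert res.p_value == pytest.approx(0.1)
        assert res.direction == 1

    def test_identical_groups(self):
        res = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
        assert res.p_value == 1.0
        assert res.direction == 0

    def test_all_constant(self):
        res = wilcoxon_rank_sum([5, 5, 5], [5, 5])
        assert res.p_value == 1.0 and res.direction == 0

    def test_exact_matches_scipy(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.normal(size=5)
            y = rng.normal(size=6)
            ours = wilcoxon_rank_sum(x, y)
            ref = sps.mannwhitneyu(y, x, alternative="two-sided", method="exact")
            assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-10)
            assert ours.statistic == pytest.approx(ref.statistic)

    def test_normal_approx_close_to_scipy(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            x = rng.normal(size=25)
            y = rng.normal(size=30) + 0.3
            ours = wilcoxon_rank_sum(x, y)
            ref = sps.mannwhitneyu(
                y, x, alternative="two-sided", method="asymptotic"
            )
            assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_direction_antisymmetric(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=15), rng.normal(size=15) + 1
        a = wilcoxon_rank_sum(x, y)
        b = wilcoxon_rank_sum(y, x)
        assert a.direction == -b.direction
        assert a.p_value == pytest.approx(b.p_value)


class TestWelch:
    def test_statistic_matches_definitional_formula(self):
        x = np.array([1.0, 2, 3, 4])
        y = np.array([2.0, 4, 6, 8])
        res = t_test_welch(x, y)
        se = np.sqrt(x.var(ddof=1) / 4 + y.var(ddof=1) / 4)
        assert res.statistic == pytest.approx((y.mean() - x.mean()) / se, abs=1e-12)

    def test_matches_scipy(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=10), rng.normal(size=14) * 2 + 1
        res = t_test_welch(x, y)
        ref = sps.ttest_ind(y, x, equal_var=False)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-10)

    def test_identical_groups(self):
        assert t_test_welch([1.0, 2, 3], [1.0, 2, 3]).p_value == 1.0

    def test_growing_separation_drives_p_down(self):
        rng = np.random.default_rng(4)
        base = rng.normal(size=8, scale=0.01)
        p_prev = 1.0
        for shift in (0.05, 0.5, 5.0):
            p = t_test_welch(base, base + shift).p_value
            assert p < p_prev
            p_prev = p


class TestKruskal:
    def test_identical_groups(self):
        g = [1.0, 2, 3]
        assert kruskal_wallis([g, g, g]).p_value == 1.0

    def test_h_matches_rank_formula(self):
        groups = [[1, 2], [3, 4], [5, 6]]
        res = kruskal_wallis(groups)
        # definitional: 12/(N(N+1)) * sum n_i (Rbar_i - (N+1)/2)^2
        h = 12 / (6 * 7) * 2 * ((1.5 - 3.5) ** 2 + 0 + (5.5 - 3.5) ** 2)
        assert res.statistic == pytest.approx(h, abs=1e-12)

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(5)
        groups = [rng.integers(0, 5, size=12).astype(float) for _ in range(4)]
        res = kruskal_wallis(groups)
        ref = sps.kruskal(*groups)
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-10)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-10)


class TestJonckheereTerpstra:
    def test_maximal_ordered_statistic(self):
        res = jonckheere_terpstra([[1, 2], [3, 4], [5, 6]])
        assert res.statistic == 12  # 4 + 4 + 4 pairwise counts
        assert res.direction == 1
        # only the 2 fully ordered arrangements of 90 are as extreme
        assert res.p_value == pytest.approx(2 / 90)

    def test_all_equal(self):
        res = jonckheere_terpstra([[1, 1], [1, 1], [1, 1]])
        assert res.p_value == 1.0 and res.direction == 0

    def test_reversal_negates_direction_preserves_p(self):
        rng = np.random.default_rng(6)
        groups = [rng.normal(loc=i, size=4) for i in range(3)]
        fwd = jonckheere_terpstra(groups)
        rev = jonckheere_terpstra(groups[::-1])
        assert fwd.direction == -rev.direction
        assert fwd.p_value == pytest.approx(rev.p_value, abs=1e-12)

    def test_too_few_groups(self):
        with pytest.raises(OrderTestError):
            jonckheere_terpstra([[1, 2], [3, 4]])

    def test_exact_matches_independent_enumeration(self):
        """Exact path agrees with a from-scratch brute-force oracle."""
        rng = np.random.default_rng(7)
        for sizes in [(2, 3, 3), (2, 2, 4)]:
            data = [rng.normal(size=s) for s in sizes]
            res = jonckheere_terpstra(data)
            pooled = np.concatenate(data)
            mu = (len(pooled) ** 2 - sum(s**2 for s in sizes)) / 4
            dev = abs(res.statistic - mu)
            total = hits = 0
            for perm in itertools.permutations(range(len(pooled))):
                gs, off = [], 0
                for s in sizes:
                    gs.append(pooled[list(perm[off : off + s])])
                    off += s
                jt = sum(
                    (gs[j][:, None] > gs[i][None, :]).sum()
                    + 0.5 * (gs[j][:, None] == gs[i][None, :]).sum()
                    for i in range(3)
                    for j in range(i + 1, 3)
                )
                total += 1
                hits += abs(jt - mu) >= dev - 1e-12
            assert res.p_value == pytest.approx(hits / total, abs=1e-12)

    @pytest.mark.parametrize("total", [7, 8, 9, 10])
    def test_normal_approx_near_exact(self, total):
        """Tie-adjusted normal approximation tracks exhaustive enumeration."""
        rng = np.random.default_rng(total)
        for a in range(2, total - 3):
            for b in range(2, total - a - 1):
                c = total - a - b
                if c < 2:
                    continue
                for _ in range(5):
                    data = [rng.normal(size=s) for s in (a, b, c)]
                    exact = jonckheere_terpstra(data).p_value
                    approx = jonckheere_terpstra(data, exact_max_n=0).p_value
                    assert abs(exact - approx) <= 0.02

    def test_normal_approx_at_minimum_size(self):
        # (2,2,2) is too coarse for the 0.02 band; 0.03 is attainable
        rng = np.random.default_rng(99)
        for _ in range(20):
            data = [rng.normal(size=2) for _ in range(3)]
            exact = jonckheere_terpstra(data).p_value
            approx = jonckheere_terpstra(data, exact_max_n=0).p_value
            assert abs(exact - approx) <= 0.03


class TestContingency:
    # printed baseline-table rows: counts of positives per group out of
    # group totals (36, 64, 46); expected p-values to 3 decimals
    TABLE_ROWS = [
        ("gender", (22, 51, 36), 0.097),
        ("current_smoker", (14, 39, 26), 0.097),
        ("stroke", (0, 2, 6), 0.020),
        ("diabetes", (5, 18, 17), 0.066),
        ("pad", (1, 20, 13), 0.003),
        ("metformin", (2, 11, 7), 0.251),
        ("ppi", (2, 10, 7), 0.309),
    ]

    @pytest.mark.parametrize("name,pos,expected", TABLE_ROWS)
    def test_three_group_rows_reproduce(self, name, pos, expected):
        totals = np.array([36, 64, 46])
        pos = np.array(pos)
        table = np.stack([pos, totals - pos], axis=1)
        res = chi_square_contingency(table)
        assert round(res.p_value, 3) == expected

    def test_identical_rows(self):
        res = chi_square_contingency([[5, 5], [5, 5]])
        assert res.statistic == 0 and res.p_value == 1.0

    def test_zero_margin_raises(self):
        with pytest.raises(DegenerateMarginError):
            chi_square_contingency([[0, 0], [3, 4]])

    def test_matches_scipy_no_correction(self):
        rng = np.random.default_rng(8)
        t = rng.integers(1, 30, size=(3, 4))
        res = chi_square_contingency(t)
        chi2, p, *_ = sps.chi2_contingency(t, correction=False)
        assert res.statistic == pytest.approx(chi2, rel=1e-12)
        assert res.p_value == pytest.approx(p, rel=1e-12)


class TestFisher:
    def test_hypergeometric_summation(self):
        res = fisher_exact_2x2([[1, 9], [11, 3]])
        assert res.p_value == pytest.approx(0.00276, abs=5e-6)

    def test_matches_scipy(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            t = rng.integers(1, 15, size=(2, 2))
            res = fisher_exact_2x2(t)
            ref = sps.fisher_exact(t)
            assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_balanced_table(self):
        assert fisher_exact_2x2([[5, 5], [5, 5]]).p_value == 1.0

    def test_requires_2x2(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1, 2, 3], [4, 5, 6]])

    def test_zero_margin_raises(self):
        with pytest.raises(DegenerateMarginError):
            fisher_exact_2x2([[0, 0], [1, 2]])


class TestFoldChange:
    def test_boundary_value(self):
        assert fold_change([10, 10], [12, 12]) == pytest.approx(1.2)

    def test_identity(self):
        assert fold_change([3, 4], [3, 4]) == 1.0

    def test_inverse_near_low_gate(self):
        fc = fold_change([12, 12], [10, 10])
        assert fc == pytest.approx(10 / 12)
        assert not fc < 0.83  # 0.8333 does not pass the strict "<0.83" gate

    def test_zero_means_need_pseudocount(self):
        with pytest.raises(ZeroDivisionError):
            fold_change([0, 0], [0, 0], pseudocount=0)
        assert fold_change([0, 0], [1, 1], pseudocount=0.5) == 3.0


class TestBHAdjust:
    def test_single_p_identity(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_computed_stepup(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_all_equal(self):
        np.testing.assert_allclose(bh_adjust([0.2] * 5), [0.2] * 5)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(10)
        for _ in range(50):
            p = rng.random(size=rng.integers(2, 40))
            ours = bh_adjust(p)
            ref = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(ours, ref, atol=1e-12)

    def test_rejection_set_matches_brute_force(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            p = rng.random(size=20)
            alpha = 0.1
            # definitional step-up: largest k with p_(k) <= k/m * alpha
            srt = np.sort(p)
            ks = np.nonzero(srt <= (np.arange(1, 21) / 20) * alpha)[0]
            brute = set()
            if len(ks):
                thresh = srt[ks.max()]
                brute = set(np.nonzero(p <= thresh)[0])
            ours = set(np.nonzero(bh_adjust(p) <= alpha)[0])
            assert ours == brute

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    @settings(max_examples=100, deadline=None)
    def test_q_never_below_p_and_bounded(self, p):
        q = bh_adjust(p)
        assert (q >= np.asarray(p) - 1e-15).all()
        assert (q <= 1.0).all()

    def test_rejects_invalid_p(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestEnumerationHelpers:
    def test_assignment_count_is_multinomial(self):
        pooled = np.arange(7, dtype=float)
        count = sum(1 for _ in _enumerate_assignments(pooled, [2, 2, 3]))
        assert count == 210  # 7!/(2!2!3!)

    def test_jt_moments_match_simulation(self):
        rng = np.random.default_rng(12)
        groups = [rng.normal(size=s) for s in (5, 6, 7)]
        mu, var = _jt_moments(groups)
        pooled = np.concatenate(groups)
        sims = []
        for _ in range(4000):
            rng.shuffle(pooled)
            gs = [pooled[:5], pooled[5:11], pooled[11:]]
            sims.append(_jt_statistic(gs))
        assert np.mean(sims) == pytest.approx(mu, rel=0.02)
        assert np.var(sims) == pytest.approx(var, rel=0.1)
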