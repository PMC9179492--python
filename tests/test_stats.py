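import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from sexlink import catt, catt_trend, expected_spurious, kruskal_tiers, pic, \
    spurious_probability


def trend_2x2(a, b, c, d):
    """Independent closed-form oracle: N(ad−bc)²/(R₁R₂C₁C₂)."""
    N = a + b + c + d
    return N * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))


def permutation_chi2_p(a, b, c, d, reps, rng):
    """Permutation null for the 2×2 trend statistic, shuffling sex labels."""
    carriers = np.concatenate([np.ones(a + c, dtype=np.int8),
                               np.zeros(b + d, dtype=np.int8)])
    # observed male carrier count after relabeling: draw who is male
    n_m = a + b
    obs = catt(a, b, c, d)[0]
    tiled = np.tile(carriers, (reps, 1))
    perm = rng.permuted(tiled, axis=1)
    a_p = perm[:, :n_m].sum(axis=1)
    c_p = (a + c) - a_p
    b_p = n_m - a_p
    d_p = (b + d) - (b_p)
    with np.errstate(invalid="ignore", divide="ignore"):
        N = a + b + c + d
        denom = (a_p + b_p) * (c_p + d_p) * (a_p + c_p) * (b_p + d_p)
        stat = np.where(denom > 0, N * (a_p * d_p - b_p * c_p) ** 2 / denom, 0.0)
    # mid-p handles the discreteness of the permutation distribution
    return float((stat > obs + 1e-9).mean() + 0.5 * (np.abs(stat - obs) <= 1e-9).mean())


class TestCatt:
    def test_known_2x2_value(self):
        chi2, p = catt(4, 1, 1, 4)
        assert chi2 == pytest.approx(3.6)
        assert p == pytest.approx(sps.chi2.sf(3.6, 1))

    def test_no_trend_is_zero(self):
        chi2, _ = catt(6, 4, 3, 2)  # 60% carriers in both sexes
        assert chi2 == pytest.approx(0.0)

    def test_perfect_association_equals_n(self):
        chi2, _ = catt(40, 0, 0, 35)
        assert chi2 == pytest.approx(75.0)

    def test_degenerate_margins_flagged(self):
        assert math.isnan(catt(5, 0, 5, 0)[0])   # everyone a carrier
        assert math.isnan(catt(5, 3, 0, 0)[0])   # one sex absent

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            catt(-1, 2, 3, 4)

    @settings(max_examples=50, deadline=None)
    @given(a=st.integers(0, 30), b=st.integers(0, 30),
           c=st.integers(0, 30), d=st.integers(0, 30))
    def test_matches_closed_form(self, a, b, c, d):
        chi2, _ = catt(a, b, c, d)
        if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
            assert math.isnan(chi2)
        else:
            assert chi2 == pytest.approx(trend_2x2(a, b, c, d))

    def test_binary_equals_trend_with_01_scores(self):
        direct = catt(7, 3, 2, 8)
        via_trend = catt_trend(np.array([[7, 3], [2, 8]]), scores=(0, 1))
        assert direct == pytest.approx(via_trend)

    def test_permutation_null_agreement(self):
        """Asymptotic p within Monte-Carlo error of a permutation null."""
        rng = np.random.default_rng(7)
        for _ in range(5):
            n_m, n_f = rng.integers(15, 30, size=2)
            a = int(rng.binomial(n_m, 0.6))
            c = int(rng.binomial(n_f, 0.4))
            p_asym = catt(a, n_m - a, c, n_f - c)[1]
            p_perm = permutation_chi2_p(a, n_m - a, c, n_f - c, 4000, rng)
            assert abs(p_asym - p_perm) < 0.05


class TestCattTrend:
    def test_genotype_scores(self):
        # males enriched for alt genotypes
        table = np.array([[2, 5, 13], [12, 6, 2]], dtype=float)
        chi2, p = catt_trend(table, scores=(0, 1, 2))
        # independent computation of the canonical closed form
        s = np.array([0.0, 1.0, 2.0])
        n = table.sum(axis=0)
        N, R = table.sum(), table[0].sum()
        num = N * (s * table[0]).sum() - R * (s * n).sum()
        den = R * (N - R) * (N * (s**2 * n).sum() - ((s * n).sum()) ** 2)
        assert chi2 == pytest.approx(N * num**2 / den)
        assert 0 < p < 0.05

    def test_score_free_table_undefined(self):
        chi2, _ = catt_trend(np.array([[5, 0, 0], [3, 0, 0]]))
        assert math.isnan(chi2)


class TestPic:
    def test_biallelic_even(self):
        assert pic([0.5, 0.5]) == pytest.approx((0.375, 0.5))

    def test_monomorphic_zero(self):
        assert pic([1.0]) == (0.0, 0.0)

    def test_he_max_for_biallelic_is_half(self):
        # the printed 0.50 ceiling is attainable only by expected
        # heterozygosity, not Botstein PIC
        p_grid = np.linspace(0.01, 0.99, 99)
        hes = [pic([p, 1 - p])[1] for p in p_grid]
        pics = [pic([p, 1 - p])[0] for p in p_grid]
        assert max(hes) == pytest.approx(0.5)
        assert max(pics) == pytest.approx(0.375)

    def test_sum_validation(self):
        with pytest.raises(ValueError, match="sum"):
            pic([0.5, 0.4])

    @settings(max_examples=60, deadline=None)
    @given(st.lists(st.floats(0.01, 1.0), min_size=1, max_size=6))
    def test_pic_bounded_by_he(self, weights):
        p = np.array(weights) / np.sum(weights)
        pic_v, he = pic(p.tolist(), tol=1e-6)
        assert 0.0 <= he < 1.0
        assert pic_v <= he + 1e-12


class TestSpuriousModel:
    def test_cohort_probability(self):
        assert spurious_probability(75) == pytest.approx(2.65e-23, rel=5e-3)

    def test_cohort_expectation(self):
        assert expected_spurious(23_509, 75) == pytest.approx(6.22e-19, rel=5e-3)

    @pytest.mark.parametrize("n, expected", [(1, 0.5), (10, 9.765625e-4)])
    def test_closed_form(self, n, expected):
        assert spurious_probability(n) == expected

    def test_two_sided_doubles(self):
        assert expected_spurious(100, 10, two_sided=True) == \
            pytest.approx(2 * expected_spurious(100, 10))

    def test_zero_individuals_rejected(self):
        with pytest.raises(ValueError):
            spurious_probability(0)


class TestKruskal:
    def test_identical_groups_degenerate(self):
        assert kruskal_tiers([[1.0, 1.0], [1.0, 1.0, 1.0]]) == (0.0, 1.0)

    def test_fully_separated_two_groups(self):
        """H equals its closed-form value from the rank sums directly."""
        g1, g2 = [1.0, 2.0, 3.0], [10.0, 11.0, 12.0, 13.0]
        h, p = kruskal_tiers([g1, g2])
        n1, n2, N = 3, 4, 7
        r1 = (1 + 2 + 3) / n1
        r2 = (4 + 5 + 6 + 7) / n2
        h_direct = 12 / (N * (N + 1)) * (n1 * (r1 - (N + 1) / 2) ** 2
                                         + n2 * (r2 - (N + 1) / 2) ** 2)
        assert h == pytest.approx(h_direct)

    def test_null_rejection_rate(self):
        """Groups from one distribution reject at ≈ the nominal 5% level."""
        rng = np.random.default_rng(11)
        rejected = 0
        n_sim = 2000
        for _ in range(n_sim):
            groups = [rng.normal(size=10) for _ in range(3)]
            _, p = kruskal_tiers(groups)
            rejected += p < 0.05
        rate = rejected / n_sim
        # 99% binomial band around 0.05 (H is discrete, slightly conservative)
        assert 0.03 < rate < 0.07

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_tiers([[1.0, 2.0]])
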