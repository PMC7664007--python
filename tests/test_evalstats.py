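"""Qseg, Pearson validation, Gaussian LRT and PERMANOVA."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from ippkit import evalstats
from ippkit.errors import InvalidInputError, InvalidMatrixError, UndefinedMetricError


class TestQseg:
    def test_identical_masks_score_one(self, rng):
        m = rng.uniform(size=(10, 10)) > 0.5
        assert evalstats.qseg(m, m) == 1.0

    def test_disjoint_masks_score_zero(self):
        a = np.zeros((4, 4), bool)
        b = np.zeros((4, 4), bool)
        a[0, 0], b[3, 3] = True, True
        assert evalstats.qseg(a, b) == 0.0

    def test_drawn_example_matches_pixel_counts(self):
        # 4x4 example: |A| = 6, |B| = 4, overlap 3 -> 3 / (6 + 4 - 3)
        a = np.array(
            [[1, 1, 0, 0],
             [1, 1, 0, 0],
             [1, 1, 0, 0],
             [0, 0, 0, 0]], bool)
        b = np.array(
            [[0, 1, 1, 0],
             [0, 1, 0, 0],
             [0, 1, 0, 0],
             [0, 0, 0, 0]], bool)
        assert int(a.sum()) == 6 and int(b.sum()) == 4 and int((a & b).sum()) == 3
        assert evalstats.qseg(a, b) == pytest.approx(3 / 7)

    def test_symmetry(self, rng):
        a = rng.uniform(size=(8, 8)) > 0.5
        b = rng.uniform(size=(8, 8)) > 0.5
        assert evalstats.qseg(a, b) == evalstats.qseg(b, a)

    def test_background_variant_is_pixel_accuracy(self):
        a = np.eye(4, dtype=bool)
        b = np.zeros((4, 4), bool)
        assert evalstats.qseg(a, b, include_background=True) == pytest.approx(12 / 16)

    def test_both_empty_rejected(self):
        with pytest.raises(UndefinedMetricError):
            evalstats.qseg(np.zeros((3, 3), bool), np.zeros((3, 3), bool))


class TestPearsonValidation:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        res = evalstats.pearson_validation(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.slope == pytest.approx(2.0) and res.intercept == pytest.approx(1.0)

    def test_perfect_negative_relation(self):
        x = np.arange(5.0)
        assert evalstats.pearson_validation(x, -x).r == pytest.approx(-1.0)

    def test_matches_sum_formula_oracle(self, rng):
        cov = [[1, 0.9], [0.9, 1]]
        xy = rng.multivariate_normal([0, 0], cov, size=10)
        x, y = xy[:, 0], xy[:, 1]
        res = evalstats.pearson_validation(x, y)
        n = len(x)
        num = n * (x * y).sum() - x.sum() * y.sum()
        den = math.sqrt(n * (x**2).sum() - x.sum() ** 2) * math.sqrt(n * (y**2).sum() - y.sum() ** 2)
        assert res.r == pytest.approx(num / den, abs=1e-12)
        assert res.r_squared == pytest.approx((num / den) ** 2, abs=1e-12)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(InvalidInputError):
            evalstats.pearson_validation([1, 2], [3, 4])


class TestGroupEffectLRT:
    def test_constant_data_rejected(self):
        with pytest.raises(InvalidInputError):
            evalstats.group_effect_lrt([1.0] * 6, ["a"] * 3 + ["b"] * 3)

    def test_permuted_identical_groups_give_zero_statistic(self):
        vals = np.array([0.3, 1.2, -0.7, 2.0])
        values = np.r_[vals, vals[::-1]]  # both groups hold the same multiset
        stat, df, p = evalstats.group_effect_lrt(values, ["a"] * 4 + ["b"] * 4)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert df == 1 and p == pytest.approx(1.0)

    def test_matches_loglik_oracle(self, rng):
        values = np.concatenate([rng.normal(m, 1.0, 20) for m in (0.0, 0.5, 1.0)])
        groups = np.repeat(["a", "b", "c"], 20)

        def loglik(v, mean_per_point):
            resid = v - mean_per_point
            sigma2 = (resid**2).mean()
            return stats.norm.logpdf(v, mean_per_point, math.sqrt(sigma2)).sum()

        mu_null = np.full_like(values, values.mean())
        mu_full = np.concatenate([np.full(20, values[groups == g].mean()) for g in ("a", "b", "c")])
        expected = 2 * (loglik(values, mu_full) - loglik(values, mu_null))
        stat, df, p = evalstats.group_effect_lrt(values, groups)
        assert stat == pytest.approx(expected, abs=1e-9)
        assert df == 2

    def test_shift_and_scale_invariance(self, rng):
        values = rng.normal(0, 1, 30)
        groups = np.repeat(["a", "b", "c"], 10)
        s0, _, _ = evalstats.group_effect_lrt(values, groups)
        s1, _, _ = evalstats.group_effect_lrt(5.0 + values, groups)
        s2, _, _ = evalstats.group_effect_lrt(3.0 * values, groups)
        assert s1 == pytest.approx(s0, abs=1e-9)
        assert s2 == pytest.approx(s0, abs=1e-9)


def brute_force_permanova_p(d, n1):
    """Exact two-group permutation p by explicit enumeration, formulas written out."""
    d = np.asarray(d, float)
    n = d.shape[0]
    d2 = d**2

    def f_stat(g1):
        g1 = set(g1)
        g2 = [i for i in range(n) if i not in g1]
        ss_t = sum(d2[i, j] for i in range(n) for j in range(i + 1, n)) / n
        ss_w = (
            sum(d2[i, j] for i in g1 for j in g1 if i < j) / n1
            + sum(d2[i, j] for i in g2 for j in g2 if i < j) / (n - n1)
        )
        ss_b = ss_t - ss_w
        if ss_w <= 0:
            return math.inf
        return (ss_b / 1) / (ss_w / (n - 2))

    f_obs = f_stat(range(n1))
    combos = list(itertools.combinations(range(n), n1))
    count = sum(1 for c in combos if f_stat(c) >= f_obs - 1e-12)
    return count / len(combos), f_obs


class TestPermanova:
    def test_pseudo_f_matches_scikit_bio(self, rng):
        from skbio.stats.distance import DistanceMatrix as SkbioDM
        from skbio.stats.distance import permanova as skbio_permanova

        pts = rng.normal(size=(12, 4))
        pts[6:] += 0.8
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        groups = ["a"] * 6 + ["b"] * 6
        ours = evalstats.pseudo_f(d, groups)
        ref = skbio_permanova(SkbioDM(d), grouping=groups, permutations=9)["test statistic"]
        assert ours == pytest.approx(float(ref), abs=1e-9)

    def test_exhaustive_p_matches_enumeration_oracle(self, rng):
        pts = rng.normal(size=(7, 3))
        pts[3:] += 0.5
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        f, p, n_used, method = evalstats.permanova(d, ["a"] * 3 + ["b"] * 4)
        p_oracle, f_oracle = brute_force_permanova_p(d, 3)
        assert method == "exhaustive" and n_used == math.comb(7, 3)
        assert f == pytest.approx(f_oracle, abs=1e-9)
        assert p == pytest.approx(p_oracle, abs=1e-12)

    def test_separated_groups_exhaustive_floor(self):
        d = np.zeros((6, 6))
        d[:3, 3:] = d[3:, :3] = 1.0
        f, p, n_used, method = evalstats.permanova(d, ["a"] * 3 + ["b"] * 3)
        # only the true split and its mirror reach the observed statistic
        assert method == "exhaustive"
        assert p == pytest.approx(2 / math.comb(6, 3))

    def test_sampled_p_has_resolution_floor(self, rng):
        pts = rng.normal(size=(14, 3))
        pts[7:] += 3.0
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        f, p, _, method = evalstats.permanova(
            d, ["a"] * 7 + ["b"] * 7, n_permutations=99, seed=0, exhaustive_limit=0
        )
        assert method == "sampled" and p >= 1 / 100

    def test_pairwise_runs_all_pairs_with_bonferroni(self, rng):
        pts = rng.normal(size=(15, 3))
        pts[5:10] += 2.0
        pts[10:] += 4.0
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        groups = ["a"] * 5 + ["b"] * 5 + ["c"] * 5
        results = evalstats.permanova_pairwise(d, groups, n_permutations=199, seed=1)
        assert [(r.group_a, r.group_b) for r in results] == [("a", "b"), ("a", "c"), ("b", "c")]
        for r in results:
            assert r.p_adjusted == pytest.approx(min(1.0, r.p * 3))

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(InvalidMatrixError):
            evalstats.permanova(d, ["a", "b"])
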