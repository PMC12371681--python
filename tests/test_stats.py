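"""Cohort statistics against brute-force enumeration oracles."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from circavar.stats import (
    cohens_d,
    exclude_outliers,
    paired_cohens_d,
    paired_seizure_test,
    ranksum_test,
    seizure_frequency_correlation,
    signed_rank_test,
    subsample_comparison,
)
from circavar.variability import PROPERTIES, ParticipantSummary


# ------------------------------------------------------------------- oracles
# Independent of the implementation: statistics are computed from pairwise
# comparisons (Mann-Whitney U as the count of a-beats-b pairs) rather than
# from rank sums, and the null is enumerated directly.

def oracle_u(a, b):
    return sum(
        1.0 if x > y else 0.5 if x == y else 0.0 for x in a for y in b
    )


def oracle_ranksum_p(a, b):
    pooled = list(a) + list(b)
    na = len(a)
    mu = na * len(b) / 2.0
    u_obs = oracle_u(a, b)
    hits = total = 0
    for pick in itertools.combinations(range(len(pooled)), na):
        rest = [pooled[i] for i in range(len(pooled)) if i not in pick]
        u = oracle_u([pooled[i] for i in pick], rest)
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-9:
            hits += 1
    return hits / total


def oracle_signed_rank_p(diff):
    d = [x for x in diff if x != 0]
    n = len(d)
    if n == 0:
        return 1.0
    ranks = sps.rankdata(np.abs(d))
    w_obs = float(ranks[np.array(d) > 0].sum())
    mu = n * (n + 1) / 4.0
    hits = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = float(np.dot(signs, ranks))
        if abs(w - mu) >= abs(w_obs - mu) - 1e-9:
            hits += 1
    return hits / 2**n


class TestCohensD:
    def test_identical_groups_zero(self):
        assert cohens_d([1.0, 2, 3], [1.0, 2, 3]) == 0.0

    def test_pooled_sd_formula(self):
        # direct evaluation: means 3 and 2, pooled SD sqrt(2)
        assert cohens_d([2.0, 4.0], [1.0, 3.0]) == pytest.approx(
            1.0 / np.sqrt(2.0)
        )

    def test_antisymmetry(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 10), rng.normal(1, 2, 8)
        assert cohens_d(a, b) == pytest.approx(-cohens_d(b, a))

    def test_zero_pooled_sd_flagged(self):
        assert np.isnan(cohens_d([1.0, 1.0], [2.0, 2.0]))


class TestRankSum:
    def test_separated_groups_exact_p(self):
        # U = 0; 2 of the 20 rank assignments are as extreme
        _, p = ranksum_test([1.0, 2, 3], [4.0, 5, 6])
        assert p == pytest.approx(0.1)

    def test_identical_multisets_p_one(self):
        _, p = ranksum_test([1.0, 2, 3], [1.0, 2, 3])
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_enumeration_oracle_small_n(self, seed):
        rng = np.random.default_rng(seed)
        na = rng.integers(2, 5)
        nb = rng.integers(2, 9 - na)
        # integer draws so ties occur
        a = rng.integers(0, 5, na).astype(float)
        b = rng.integers(0, 5, nb).astype(float)
        _, p = ranksum_test(a, b)
        assert p == pytest.approx(oracle_ranksum_p(a, b), abs=1e-12)

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 1, 5)
        b = rng.normal(0.5, 1, 6)
        _, p = ranksum_test(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_large_sample_uses_normal_approximation(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0, 1, 40)
        b = rng.normal(0.8, 1, 35)
        _, p = ranksum_test(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert p == pytest.approx(ref.pvalue, rel=1e-9)


class TestSignedRank:
    def test_identical_pairs(self):
        w, p = signed_rank_test(np.zeros(6))
        assert (w, p) == (0.0, 1.0)

    def test_all_positive_small_sample(self):
        # 2 of the 32 sign assignments are as extreme
        _, p = signed_rank_test(np.array([1.0, 2, 3, 4, 5]))
        assert p == pytest.approx(0.0625)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_sign_flip_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(3, 11)
        diff = rng.integers(-4, 5, n).astype(float)
        _, p = signed_rank_test(diff)
        assert p == pytest.approx(oracle_signed_rank_p(diff), abs=1e-12)

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(9)
        diff = rng.normal(0.3, 1, 12)
        _, p = signed_rank_test(diff)
        ref = sps.wilcoxon(diff, alternative="two-sided", method="exact")
        assert p == pytest.approx(ref.pvalue, abs=1e-12)


class TestSubsample:
    def test_full_subsample_reduces_to_single_test(self):
        rng = np.random.default_rng(1)
        pwe = rng.normal(1, 1, 12)
        ctrl = rng.normal(0, 1, 10)
        res = subsample_comparison(pwe, ctrl, n_sub=12, iterations=50, seed=0)
        _, p_full = ranksum_test(pwe, ctrl)
        assert np.allclose(res.p_values, p_full)
        assert np.allclose(res.d_values, cohens_d(pwe, ctrl))

    def test_seed_reproducible(self):
        rng = np.random.default_rng(2)
        pwe = rng.normal(0, 1, 40)
        ctrl = rng.normal(0, 1, 15)
        r1 = subsample_comparison(pwe, ctrl, n_sub=28, iterations=200, seed=7)
        r2 = subsample_comparison(pwe, ctrl, n_sub=28, iterations=200, seed=7)
        assert np.array_equal(r1.p_values, r2.p_values)
        assert np.array_equal(r1.d_values, r2.d_values)

    def test_too_small_case_group_rejected(self):
        with pytest.raises(ValueError):
            subsample_comparison(np.ones(10), np.ones(5), n_sub=28)


class TestExcludeOutliers:
    def test_all_equal_nobody_excluded(self):
        mask, _ = exclude_outliers(np.ones((5, 3)))
        assert mask.all()

    def test_single_extreme_value_z_below_three_retained(self):
        # {0 x 9, 100}: z of the 100 is 2.846 with the sample SD, so the
        # |z| > 3 rule keeps everyone
        vals = np.array([[0.0]] * 9 + [[100.0]])
        mask, z = exclude_outliers(vals)
        assert z[-1, 0] == pytest.approx((100 - 10) / np.std(vals, ddof=1))
        assert mask.all()

    def test_any_property_excludes_whole_participant(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(0, 1, (30, 2))
        vals[0, 1] = 50.0  # outlying in property B only
        mask, _ = exclude_outliers(vals)
        assert not mask[0]
        assert mask[1:].all()


def summary(pid, var, freq, group="pwe"):
    return ParticipantSummary(
        participant_id=pid,
        group=group,
        n_segments=10,
        averages={p: 0.0 for p in PROPERTIES},
        variability={p: v for p, v in zip(PROPERTIES, var)},
        seizure_frequency=freq,
    )


class TestSeizureCorrelation:
    def test_perfect_linear_relation(self):
        freqs = [0.5, 1.0, 2.0, 4.0, 8.0]
        ss = [
            summary(f"P{i}", (10 + 5 * np.log10(f),) * 3, f)
            for i, f in enumerate(freqs)
        ]
        out = seizure_frequency_correlation(ss)
        for prop in PROPERTIES:
            assert out[prop]["r"] == pytest.approx(1.0)

    def test_zero_seizure_participants_removed(self):
        ss = [summary(f"P{i}", (float(i),) * 3, 1.0 + i) for i in range(6)]
        ss.append(summary("Z", (100.0,) * 3, 0.0))
        out = seizure_frequency_correlation(ss)
        assert out["period"]["n"] == 6

    def test_null_relation_centers_on_zero(self):
        rs = []
        for rep in range(100):
            rng = np.random.default_rng(rep)
            ss = [
                summary(f"P{i}", rng.normal(50, 5, 3), float(rng.lognormal(0, 1)))
                for i in range(30)
            ]
            rs.append(seizure_frequency_correlation(ss)["period"]["r"])
        assert abs(np.mean(rs)) < 0.03

    def test_too_few_participants_rejected(self):
        with pytest.raises(ValueError):
            seizure_frequency_correlation(
                [summary("A", (1.0,) * 3, 1.0), summary("B", (2.0,) * 3, 2.0)]
            )


class TestPairedSeizureTest:
    def test_identical_pairs_p_one_d_zero(self):
        pairs = [
            (summary(f"P{i}", (5.0, 6.0, 7.0), 1.0),
             summary(f"P{i}", (5.0, 6.0, 7.0), 1.0))
            for i in range(6)
        ]
        out = paired_seizure_test(pairs)
        for res in out.values():
            assert res["p"] == 1.0
            assert res["d"] == 0.0

    def test_consistent_positive_differences(self):
        pairs = []
        for i in range(5):
            c = summary(f"P{i}", (10.0 + i + 1, 5.0, 5.0), 1.0)
            f = summary(f"P{i}", (10.0, 5.0, 5.0), 1.0)
            pairs.append((c, f))
        out = paired_seizure_test(pairs)
        assert out["variability_period"]["p"] == pytest.approx(0.0625)
        assert out["variability_period"]["d"] > 0

    def test_paired_d_formula(self):
        diff = np.array([1.0, 2.0, 3.0])
        assert paired_cohens_d(diff) == pytest.approx(2.0 / 1.0)
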