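"""Top-k estimator, Student's t comparisons, and the projection bias oracle."""

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from loopdist.estimator import (
    compare_conditions,
    estimator_bias_oracle,
    significance_tier,
    students_t,
    topk_distances,
)
from loopdist.fish_sim import GENOTYPES, PAIRS, simulate_cohort


class TestTopK:
    def test_constant_input(self):
        res = topk_distances([1.7] * 200)
        assert res.mean == pytest.approx(1.7)
        assert res.sd == 0.0
        assert res.k == 40 and res.n_total == 200

    def test_integers_1_to_200(self):
        res = topk_distances(list(range(1, 201)), k=40)
        assert res.mean == pytest.approx(180.5)  # mean of 161..200
        assert res.values[0] == 200 and res.values[-1] == 161

    def test_too_few_measurements(self):
        with pytest.raises(ValueError, match="more nuclei"):
            topk_distances([1.0] * 30, k=40)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            topk_distances([-1.0] + [1.0] * 50, k=40)

    @settings(max_examples=100, deadline=None)
    @given(
        st.lists(st.floats(0, 1e3), min_size=1, max_size=1000),
        st.data(),
    )
    def test_against_brute_force_sort(self, xs, data):
        k = data.draw(st.integers(1, len(xs)))
        res = topk_distances(xs, k=k)
        expected = sorted(xs, reverse=True)[:k]
        assert list(res.values) == expected
        assert res.mean == pytest.approx(np.mean(expected))

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(st.floats(0.01, 100), min_size=45, max_size=300),
        st.floats(0.1, 10),
    )
    def test_scale_equivariance_and_monotonicity(self, xs, c):
        base = topk_distances(xs, k=40)
        scaled = topk_distances([c * x for x in xs], k=40)
        assert scaled.mean == pytest.approx(c * base.mean, rel=1e-9)
        bumped = topk_distances([x + 1.0 for x in xs], k=40)
        assert bumped.mean >= base.mean

    @pytest.mark.parametrize("mu", [0.7, 1.3, 2.2])
    def test_recovers_true_separation_in_rigid_mode(self, mu):
        # the rationale for the rule: the top 40 of 200 projected distances
        # select near-in-plane orientations, so their mean ~ the 3D separation
        from loopdist.fish_sim import DistanceModel

        t = simulate_cohort(
            (2, 3), "AA", 200, model=DistanceModel(mu={((2, 3), "AA"): mu}), seed=17
        )
        from loopdist.fish_sim import pair_distances

        res = topk_distances(pair_distances(t), k=40)
        assert res.mean == pytest.approx(mu, rel=0.05)


class TestStudentsT:
    def test_identical_groups(self):
        res = students_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0 and res.p == pytest.approx(1.0) and res.tier == "ns"

    def test_hand_computed_example(self):
        res = students_t([1, 2, 3, 4, 5], [2, 3, 4, 5, 6])
        assert res.t == pytest.approx(-1.0)
        assert res.df == 8
        assert res.p == pytest.approx(0.3466, abs=2e-4)
        assert res.tier == "ns"

    def test_zero_variance_degenerate_cases(self):
        same = students_t([2.0, 2.0], [2.0, 2.0])
        assert (same.t, same.p, same.tier) == (0.0, 1.0, "ns")
        diff = students_t([2.0, 2.0], [3.0, 3.0])
        assert diff.p == 0.0 and diff.tier == "****"

    def test_agrees_with_scipy_reference(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            na, nb = rng.integers(2, 30, size=2)
            a = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 2), na)
            b = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 2), nb)
            mine = students_t(a, b)
            ref = scipy.stats.ttest_ind(a, b, equal_var=True)
            assert mine.t == pytest.approx(ref.statistic, abs=1e-10)
            assert mine.p == pytest.approx(ref.pvalue, abs=1e-10)

    @pytest.mark.parametrize(
        "p,tier",
        [(0.5, "ns"), (0.04, "*"), (0.005, "**"), (5e-4, "***"), (5e-5, "****")],
    )
    def test_tier_ladder(self, p, tier):
        assert significance_tier(p) == tier


@pytest.fixture(scope="module")
def cohorts():
    return {
        (p, g): simulate_cohort(p, g, 200, seed=1000 + 10 * PAIRS.index(p) + GENOTYPES.index(g))
        for p in PAIRS
        for g in GENOTYPES
    }


class TestCompareConditions:
    def test_aa_interior_pair_farther_than_anchor_pair(self, cohorts):
        res = compare_conditions(cohorts, k=40)
        s = res["summary"].set_index(["pair", "genotype"])["topk_mean_um"]
        assert s[("2-3", "AA")] > s[("1-4", "AA")]
        assert res["summary"].set_index("genotype")["loop_signature"]["AA"].all()

    def test_gg_pairs_nearly_equidistant(self, cohorts):
        res = compare_conditions(cohorts, k=40)
        s = res["summary"].set_index(["pair", "genotype"])["topk_mean_um"]
        assert abs(s[("2-3", "GG")] - s[("1-4", "GG")]) <= 0.15

    def test_overlapping_pair_genotype_invariant_within_5pct(self, cohorts):
        res = compare_conditions(cohorts, k=40)
        s = res["summary"].set_index(["pair", "genotype"])["topk_mean_um"]
        means = [s[("4-5", g)] for g in GENOTYPES]
        assert max(means) / min(means) <= 1.05

    def test_aa_contrast_highly_significant(self, cohorts):
        res = compare_conditions(cohorts, k=40)
        wg = res["within_genotype"].set_index(["genotype", "pair_a", "pair_b"])
        assert wg.loc[("AA", "2-3", "1-4"), "tier"] == "****"
        assert wg.loc[("AA", "2-3", "1-4"), "p"] < 1e-4

    def test_missing_condition_named(self, cohorts):
        partial = {k: v for k, v in cohorts.items() if k != ((1, 4), "GG")}
        with pytest.raises(KeyError, match="1-4.*GG"):
            compare_conditions(partial, k=40)

    def test_accepts_plain_distance_arrays(self):
        rng = np.random.default_rng(4)
        arrays = {
            (p, g): rng.uniform(0, 2, size=200) for p in PAIRS for g in GENOTYPES
        }
        res = compare_conditions(arrays, k=40)
        assert len(res["summary"]) == 9
        assert len(res["within_genotype"]) == 9  # 3 pairwise x 3 genotypes
        assert len(res["within_pair"]) == 9


class TestBiasOracle:
    def test_full_sample_mean_is_pi_over_4(self):
        ratio, se = estimator_bias_oracle(n=200, k=200, reps=2000, seed=0)
        assert abs(ratio - np.pi / 4) < 3 * se + 1e-4

    def test_single_draw_same_limit(self):
        ratio, se = estimator_bias_oracle(n=1, k=1, reps=20_000, seed=1)
        assert abs(ratio - np.pi / 4) < 3 * se

    def test_top_quintile_nearly_unbiased(self):
        # closed form: E[mean of top 20% of projection factors] ~ 0.9933
        ratio, _ = estimator_bias_oracle(n=200, k=40, reps=2000, seed=2)
        assert 0.98 <= ratio <= 1.00
        assert ratio == pytest.approx(0.9933, abs=0.003)

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            estimator_bias_oracle(n=10, k=20)
        with pytest.raises(ValueError):
            estimator_bias_oracle(reps=0)
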