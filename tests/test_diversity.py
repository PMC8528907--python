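import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from divshift import (
    AbundanceVector,
    chao_shen_effective_functions,
    expected_coverage_at_size,
    good_turing_coverage,
    hill_number,
    inverse_simpson,
    rarefied_inverse_simpson,
    rarefy_to_common_coverage,
    size_at_coverage,
    subsample_without_replacement,
)
from divshift.diversity import DegenerateCoverageWarning

from conftest import random_vector

count_lists = st.lists(st.integers(min_value=1, max_value=60), min_size=2, max_size=25)


def vec(*counts, sample_id=""):
    return AbundanceVector.from_counts(list(counts), sample_id=sample_id)


class TestAbundanceVector:
    def test_frequency_counts_partition_total(self):
        v = vec(4, 3, 2, 1, 1)
        assert v.n == 11
        assert v.f1 == 2
        assert sum(k * v.f(k) for k in range(1, 5)) == v.n

    def test_zero_and_empty_rejected(self):
        with pytest.raises(ValueError):
            AbundanceVector(np.array([2, 0]))
        with pytest.raises(ValueError):
            AbundanceVector.from_counts([0, 0])


class TestGoodTuringCoverage:
    @pytest.mark.parametrize(
        "counts, expected",
        [((5, 5), 1.0), ((2, 1, 1), 0.5)],
    )
    def test_singleton_fraction(self, counts, expected):
        assert good_turing_coverage(vec(*counts)).value == pytest.approx(expected)

    def test_all_singletons_triggers_adjustment(self):
        with pytest.warns(DegenerateCoverageWarning):
            c = good_turing_coverage(vec(1, 1, 1))
        assert c.value == pytest.approx(1 / 3)  # f1 -> n-1 substitution


class TestExpectedCoverage:
    def test_direct_formula_small_case(self):
        assert expected_coverage_at_size(vec(2, 1), 1).value == pytest.approx(1 / 3)

    def test_good_turing_identity_at_full_size(self):
        v = vec(3, 1)
        assert expected_coverage_at_size(v, 3).value == pytest.approx(0.75, abs=1e-12)

    def test_identity_on_random_vectors(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            v = random_vector(rng)
            expected = 1 - v.f1 / v.n
            got = expected_coverage_at_size(v, v.n - 1).value
            assert got == pytest.approx(expected, abs=1e-12)

    def test_non_decreasing_in_m(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            v = random_vector(rng, max_features=10, max_count=10)
            cov = [expected_coverage_at_size(v, m).value for m in range(1, v.n)]
            assert all(b >= a - 1e-12 for a, b in zip(cov, cov[1:]))

    def test_out_of_range_m(self):
        with pytest.raises(ValueError):
            expected_coverage_at_size(vec(2, 1), 3)
        with pytest.raises(ValueError):
            expected_coverage_at_size(vec(2, 1), 0)


class TestSizeAtCoverage:
    def test_smallest_size_reaching_target(self):
        v = vec(2, 1)
        # C(1) = 1/3, C(2) = 2/3
        assert size_at_coverage(v, 0.5) == 2

    def test_zero_target_gives_smallest_size(self):
        assert size_at_coverage(vec(2, 1), 0.0) == 1

    def test_unattainable_target_instructs_clamping(self):
        with pytest.raises(ValueError, match="clamp"):
            size_at_coverage(vec(2, 1), 0.99)

    def test_minimality_by_enumeration(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            v = random_vector(rng, max_features=8, max_count=8)
            target = 0.7 * expected_coverage_at_size(v, v.n - 1).value
            m = size_at_coverage(v, target)
            assert expected_coverage_at_size(v, m).value >= target
            if m > 1:
                assert expected_coverage_at_size(v, m - 1).value < target


class TestHillNumber:
    def test_uniform_gives_richness_for_any_order(self):
        p = np.full(10, 0.1)
        for q in (0, 0.5, 1, 2, 3):
            assert hill_number(p, q) == pytest.approx(10.0)

    def test_order_two_by_hand(self):
        assert hill_number([0.4, 0.3, 0.2, 0.1], 2) == pytest.approx(1 / 0.30)

    def test_order_one_is_exp_shannon(self):
        p = [0.4, 0.3, 0.2, 0.1]
        h = -sum(x * math.log(x) for x in p)
        assert hill_number(p, 1) == pytest.approx(math.exp(h))
        assert h == pytest.approx(1.27985, abs=1e-5)

    def test_continuity_at_q_equal_one(self):
        rng = np.random.default_rng(2)
        p = rng.dirichlet(np.ones(12))
        lo = hill_number(p, 1 - 1e-7)
        hi = hill_number(p, 1 + 1e-7)
        at = hill_number(p, 1.0)
        assert lo == pytest.approx(at, rel=1e-5)
        assert hi == pytest.approx(at, rel=1e-5)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(count_lists)
    def test_non_increasing_in_q(self, counts):
        p = np.asarray(counts, dtype=float)
        p /= p.sum()
        values = [hill_number(p, q) for q in (0, 0.5, 1, 2, 3)]
        assert all(b <= a * (1 + 1e-10) for a, b in zip(values, values[1:]))
        assert values[-1] >= 1.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            hill_number([0.5, 0.4], 2)  # not normalized
        with pytest.raises(ValueError):
            hill_number([1.5, -0.5], 2)


class TestInverseSimpson:
    @pytest.mark.parametrize(
        "counts, expected",
        [((10,), 1.0), ((4, 3, 2, 1), 100 / 30), ((5, 5, 5, 5), 4.0)],
    )
    def test_known_values(self, counts, expected):
        assert inverse_simpson(vec(*counts)).value == pytest.approx(expected)


class TestRarefiedInverseSimpson:
    def test_plugin_identity_at_full_size(self, vec4321):
        full = rarefied_inverse_simpson(vec4321, vec4321.n).value
        assert full == pytest.approx(inverse_simpson(vec4321).value, abs=1e-12)

    def test_hand_computed_small_subsample(self, vec4321):
        # sum X(X-1) = 20, n(n-1) = 90
        got = rarefied_inverse_simpson(vec4321, 2).value
        assert got == pytest.approx(1 / (0.5 + 0.5 * 20 / 90))

    def test_single_feature_is_one_at_any_size(self):
        v = vec(10)
        for m in (1, 5, 10):
            assert rarefied_inverse_simpson(v, m).value == pytest.approx(1.0)

    def test_non_decreasing_in_m(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            v = random_vector(rng)
            vals = [rarefied_inverse_simpson(v, m).value for m in range(1, v.n + 1)]
            assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_matches_subsampling_oracle(self):
        """The interpolated Simpson concentration is the exact expectation of
        the subsampled plugin concentration, so the brute-force subsampling
        mean must agree within 3 SE on the concentration scale (comparing on
        the inverse scale would add a known Jensen bias to the oracle)."""
        rng = np.random.default_rng(100)
        v = random_vector(rng, max_features=12, max_count=15)
        m = max(2, v.n // 3)
        reps = 2000
        draws = np.array([
            1.0 / inverse_simpson(subsample_without_replacement(v, m, rng)).value
            for _ in range(reps)
        ])
        se = draws.std(ddof=1) / math.sqrt(reps)
        analytic_conc = 1.0 / rarefied_inverse_simpson(v, m).value
        assert abs(analytic_conc - draws.mean()) < 3 * se


class TestSubsample:
    def test_full_size_returns_same_vector(self, vec4321):
        assert subsample_without_replacement(vec4321, vec4321.n, 0) is vec4321

    def test_deterministic_under_seed(self, vec4321):
        a = subsample_without_replacement(vec4321, 5, 123)
        b = subsample_without_replacement(vec4321, 5, 123)
        assert np.array_equal(a.counts, b.counts)

    def test_hypergeometric_marginal(self):
        """Drawing 2 of (2,1) keeps both doubleton reads with probability 1/3.

        Equivalent to the single-read marginal (doubleton drawn w.p. 2/3):
        P(subsample of 2 has richness 1) = C(2,2)/C(3,2) = 1/3.
        """
        v = vec(2, 1)
        rng = np.random.default_rng(7)
        hits = sum(
            subsample_without_replacement(v, 2, rng).richness == 1
            for _ in range(10_000)
        )
        assert hits / 10_000 == pytest.approx(1 / 3, abs=0.02)

    def test_oversized_subsample_rejected(self, vec4321):
        with pytest.raises(ValueError):
            subsample_without_replacement(vec4321, vec4321.n + 1, 0)


class TestRarefyToCommonCoverage:
    def test_identical_samples_share_size_and_value(self):
        a = vec(4, 3, 2, 1, sample_id="a")
        b = vec(4, 3, 2, 1, sample_id="b")
        res = rarefy_to_common_coverage([a, b])
        assert res[0].value == pytest.approx(res[1].value)
        assert res[0].rarefied_to == res[1].rarefied_to == a.n - 1

    def test_deep_sample_rarefied_down_to_shallow_coverage(self):
        deep = AbundanceVector.from_counts([10] * 10, sample_id="deep")  # C = 1
        shallow = vec(2, 1, sample_id="shallow")  # C(n-1) = 2/3
        res = {r.sample_id: r for r in rarefy_to_common_coverage([deep, shallow])}
        assert res["shallow"].rarefied_to == 2  # n - 1
        assert res["deep"].coverage == pytest.approx(2 / 3)
        assert res["deep"].rarefied_to < deep.n - 1

    def test_degenerate_sample_named_in_error(self):
        good = vec(5, 5, sample_id="good")
        with pytest.raises(ValueError, match="bad"):
            # an all-singleton sample has zero estimated coverage and cannot
            # anchor the common target
            rarefy_to_common_coverage([good, vec(1, 1, 1, sample_id="bad")])

    def test_montecarlo_mode_close_to_analytic(self):
        rng = np.random.default_rng(21)
        samples = [random_vector(rng, max_features=10, max_count=20) for _ in range(3)]
        samples = [AbundanceVector(s.counts, sample_id=f"s{i}")
                   for i, s in enumerate(samples)]
        analytic = rarefy_to_common_coverage(samples, mode="analytic")
        mc = rarefy_to_common_coverage(samples, mode="montecarlo", reps=2000, seed=5)
        for a, m in zip(analytic, mc):
            assert m.value == pytest.approx(a.value, rel=0.1)

    def test_requires_two_samples(self, vec4321):
        with pytest.raises(ValueError):
            rarefy_to_common_coverage([vec4321])


class TestChaoShen:
    def test_single_feature_has_zero_entropy(self):
        r = chao_shen_effective_functions(vec(17))
        assert r.entropy == pytest.approx(0.0, abs=1e-12)
        assert r.value == pytest.approx(1.0)

    def test_four_term_hand_computation(self, vec4321):
        r = chao_shen_effective_functions(vec4321)
        assert r.coverage == pytest.approx(0.9)
        assert r.entropy == pytest.approx(1.454, abs=2e-3)
        assert r.value == pytest.approx(4.28, abs=5e-3)

    def test_uniform_large_sample_recovers_richness(self):
        v = AbundanceVector.from_counts([200] * 50)
        assert chao_shen_effective_functions(v).value == pytest.approx(50, rel=0.01)

    def test_at_least_plugin_shannon_when_fully_covered(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            counts = rng.integers(2, 40, size=rng.integers(2, 15))
            v = AbundanceVector.from_counts(counts)
            plugin = hill_number(v.proportions, 1)
            assert chao_shen_effective_functions(v).value >= plugin * (1 - 1e-9)

    def test_all_singletons_warns_and_stays_finite(self):
        with pytest.warns(DegenerateCoverageWarning):
            r = chao_shen_effective_functions(vec(1, 1, 1, 1))
        assert np.isfinite(r.value) and r.value >= 1.0


class TestEstimatorInvariances:
    """All estimators ignore feature order and appended zero-count features."""

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(count_lists, st.randoms(use_true_random=False))
    @pytest.mark.filterwarnings("ignore::divshift.diversity.DegenerateCoverageWarning")
    def test_permutation_and_zero_padding(self, counts, rnd):
        base = AbundanceVector.from_counts(counts)
        shuffled = list(counts)
        rnd.shuffle(shuffled)
        padded = AbundanceVector.from_counts(shuffled + [0, 0, 0])
        for est in (
            lambda v: good_turing_coverage(v).value,
            lambda v: inverse_simpson(v).value,
            lambda v: rarefied_inverse_simpson(v, max(1, v.n // 2)).value,
            lambda v: chao_shen_effective_functions(v).value
            if v.f1 < v.n else None,
        ):
            a, b = est(base), est(padded)
            if a is not None:
                assert b == pytest.approx(a, rel=1e-12)
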