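import itertools
from math import comb

import numpy as np
import pytest
import scipy.optimize
import scipy.stats
from sympy.functions.combinatorial.numbers import partition as npartitions

from gametokit.core_io import RunConfig
from gametokit.errors import DomainError
from gametokit.esf import (
    esf_config_probability,
    esf_expected_counts,
    esf_expected_k,
    esf_neutrality_test,
    esf_partition_test,
    expected_category_probs,
    fit_theta_grid,
    iter_partitions,
    multinomial_gof_test,
)
from gametokit.haplotypes import SpectrumConfig
from gametokit.synth import sample_crp_sizes_batch


def spectrum_from_partition(n, mult):
    a = [0] * n
    for part, m in mult.items():
        a[part - 1] = m
    return SpectrumConfig(n=n, a=tuple(a))


class TestConfigProbability:
    def test_two_singletons_theta_one(self):
        spec = SpectrumConfig(n=2, a=(2, 0))
        assert esf_config_probability(spec, 1.0) == pytest.approx(0.5)

    def test_one_doubleton_theta_one(self):
        spec = SpectrumConfig(n=2, a=(0, 1))
        assert esf_config_probability(spec, 1.0) == pytest.approx(0.5)

    def test_single_individual_is_certain(self):
        spec = SpectrumConfig(n=1, a=(1,))
        for theta in (0.1, 1.0, 50.0):
            assert esf_config_probability(spec, theta) == pytest.approx(1.0)

    def test_nonpositive_theta_rejected(self):
        spec = SpectrumConfig(n=2, a=(2, 0))
        with pytest.raises(DomainError):
            esf_config_probability(spec, 0.0)

    @pytest.mark.parametrize("theta", [0.5, 1.0, 5.0])
    @pytest.mark.parametrize("n", range(1, 9))
    def test_sums_to_one_over_all_partitions(self, n, theta):
        parts = list(iter_partitions(n))
        assert len(parts) == int(npartitions(n))  # independent partition count
        total = sum(
            esf_config_probability(spectrum_from_partition(n, p), theta)
            for p in parts
        )
        assert total == pytest.approx(1.0, abs=1e-12)


class TestExpectedCounts:
    def test_hand_example_n2(self):
        e = esf_expected_counts(2, 1.0)
        assert e == pytest.approx([1.0, 0.5])

    def test_matches_enumeration_n2(self):
        # E[a_1] = 2*P(two singletons), E[a_2] = P(one doubleton)
        p_sing = esf_config_probability(SpectrumConfig(n=2, a=(2, 0)), 1.0)
        p_doub = esf_config_probability(SpectrumConfig(n=2, a=(0, 1)), 1.0)
        assert esf_expected_counts(2, 1.0) == pytest.approx(
            [2 * p_sing, p_doub]
        )

    def test_n1(self):
        assert esf_expected_counts(1, 3.0) == pytest.approx([1.0])

    @pytest.mark.parametrize("n,theta", [(5, 0.5), (20, 3.0), (50, 20.0)])
    def test_sum_equals_expected_k(self, n, theta):
        assert esf_expected_counts(n, theta).sum() == pytest.approx(
            esf_expected_k(n, theta), abs=1e-9
        )

    def test_matches_crp_mean_within_3se(self, rng):
        n, theta, reps = 8, 2.0, 100_000
        counts = sample_crp_sizes_batch(n, theta, reps, rng)
        expected = esf_expected_counts(n, theta)
        for j in range(1, n + 1):
            a_j = (counts == j).sum(axis=1)
            se = a_j.std(ddof=1) / np.sqrt(reps)
            assert abs(a_j.mean() - expected[j - 1]) < 3 * se + 1e-12


class TestExpectedK:
    def test_hand_example(self):
        assert esf_expected_k(2, 1.0) == pytest.approx(1.5)

    def test_limits(self):
        assert esf_expected_k(1, 7.0) == pytest.approx(1.0)
        assert esf_expected_k(5, 1e9) == pytest.approx(5.0, abs=5e-6)

    def test_monotone_in_theta(self):
        values = [esf_expected_k(30, t) for t in (0.5, 1, 2, 5, 20, 100)]
        assert all(b > a for a, b in zip(values, values[1:]))


class TestFitThetaGrid:
    def test_boundary_minimum(self):
        spec = SpectrumConfig(n=2, a=(0, 1))  # k=1, likelihood decreasing
        assert fit_theta_grid(spec, [float(t) for t in range(1, 101)]) == 1.0

    def test_boundary_maximum(self):
        spec = SpectrumConfig(n=2, a=(2, 0))  # k=2, likelihood increasing
        assert fit_theta_grid(spec, [float(t) for t in range(1, 101)]) == 100.0

    def test_matches_expected_k_root(self):
        # ML theta solves E[K](n, theta) = k; grid 1..200 picks the nearest
        # integer to the root of sum_{i<10} theta/(theta+i) = 5
        root = scipy.optimize.brentq(
            lambda t: esf_expected_k(10, t) - 5.0, 0.01, 100.0
        )
        spec = SpectrumConfig.from_counts([5, 2, 1, 1, 1])
        theta_hat = fit_theta_grid(spec, [float(t) for t in range(1, 201)])
        assert theta_hat == float(round(root))

    def test_k_is_sufficient(self):
        grid = [float(t) for t in range(1, 201)]
        same_nk = [
            SpectrumConfig.from_counts([5, 2, 1, 1, 1]),
            SpectrumConfig.from_counts([4, 3, 1, 1, 1]),
            SpectrumConfig.from_counts([6, 1, 1, 1, 1]),
        ]
        fits = {fit_theta_grid(s, grid) for s in same_nk}
        assert len(fits) == 1

    def test_recovers_planted_theta_within_30pct(self, rng):
        n, theta = 50, 20.0
        grid = [float(t) for t in range(1, 201)]
        counts = sample_crp_sizes_batch(n, theta, 200, rng)
        estimates = [
            fit_theta_grid(
                SpectrumConfig.from_counts([int(x) for x in c if x > 0]), grid
            )
            for c in counts
        ]
        assert abs(np.median(estimates) - theta) <= 0.3 * theta


class TestExpectedCategoryProbs:
    def test_single_class(self):
        assert expected_category_probs(10, 1, 2.0) == pytest.approx([1.0])

    def test_all_singletons_uniform(self):
        assert expected_category_probs(6, 6, 2.0) == pytest.approx([1 / 6] * 6)

    def test_self_consistency_across_seeds(self):
        a = expected_category_probs(10, 3, 1.0, reps=40_000, seed=1)
        b = expected_category_probs(10, 3, 1.0, reps=40_000, seed=2)
        assert a == pytest.approx(b, abs=0.01)
        assert a.sum() == pytest.approx(1.0)
        assert all(x >= y for x, y in zip(a, a[1:]))  # non-increasing ranks

    def test_k_exceeding_n_rejected(self):
        with pytest.raises(DomainError):
            expected_category_probs(3, 4, 1.0)


def multinomial_exact_oracle(observed, probs):
    """Independent enumeration with scipy's multinomial pmf."""
    n = sum(observed)
    k = len(observed)
    p_obs = scipy.stats.multinomial.pmf(observed, n, probs)
    total = 0.0
    for x in itertools.product(range(n + 1), repeat=k):
        if sum(x) != n:
            continue
        px = scipy.stats.multinomial.pmf(x, n, probs)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return total


class TestMultinomialGof:
    @pytest.mark.parametrize(
        "observed,probs,expected",
        [
            ([2, 0], [0.5, 0.5], 0.5),
            ([1, 1], [0.5, 0.5], 1.0),
            ([7], [1.0], 1.0),
        ],
    )
    def test_hand_examples(self, observed, probs, expected):
        assert multinomial_gof_test(observed, probs, method="exact") == pytest.approx(
            expected
        )

    @pytest.mark.parametrize(
        "observed,probs",
        [
            ([5, 3, 2], [0.2, 0.3, 0.5]),
            ([12, 0, 0], [0.6, 0.3, 0.1]),
            ([3, 3, 3, 3], [0.25, 0.25, 0.25, 0.25]),
            ([1, 2, 3, 4], [0.4, 0.3, 0.2, 0.1]),
        ],
    )
    def test_exact_equals_enumeration_oracle(self, observed, probs):
        ours = multinomial_gof_test(observed, probs, method="exact")
        assert ours == pytest.approx(multinomial_exact_oracle(observed, probs))

    def test_monte_carlo_converges_to_exact(self):
        observed, probs = [8, 1, 1], [0.5, 0.3, 0.2]
        exact = multinomial_gof_test(observed, probs, method="exact")
        reps = 100_000
        mc = multinomial_gof_test(
            observed, probs, method="monte_carlo", reps=reps, seed=13
        )
        se = np.sqrt(exact * (1 - exact) / reps)
        assert abs(mc - exact) < 3 * se

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(DomainError):
            multinomial_gof_test([1, 2], [0.5, 0.25, 0.25])


class TestNeutralityTest:
    def test_modal_configuration_gives_p_one(self):
        # all singletons at the grid's top theta is the modal configuration
        spec = SpectrumConfig.from_counts([1] * 6)
        res = esf_neutrality_test(spec, RunConfig(seed=1))
        assert res.theta_hat == 200.0
        assert res.p_value == pytest.approx(1.0, abs=1e-9)

    def test_dominant_class_among_many_singletons_rejects(self):
        # one haplotype in 18 genomes plus 25 singletons: with k=26 the
        # fitted theta is large and an 18-fold class is wildly unexpected
        spec = SpectrumConfig.from_counts([18] + [1] * 25)
        res = esf_neutrality_test(spec, RunConfig(seed=1))
        assert res.p_value < 1e-3

    def test_dominant_class_with_few_singletons_is_not_extreme(self):
        # same 18-fold class but k=3: theta-hat is ~1 and a dominant class
        # is then typical of neutrality; the test must NOT reject
        spec = SpectrumConfig.from_counts([18, 1, 1])
        res = esf_neutrality_test(spec, RunConfig(seed=1))
        assert res.theta_hat == 1.0
        assert res.p_value > 0.5

    def test_ranked_multinomial_variant_runs(self):
        spec = SpectrumConfig.from_counts([3, 2, 1])
        res = esf_neutrality_test(
            spec, RunConfig(seed=5), test="ranked_multinomial", crp_reps=2000
        )
        assert 0.0 < res.p_value <= 1.0
        assert res.method == "exact_enumeration"

    def test_partition_mc_agrees_with_exact(self):
        spec = SpectrumConfig.from_counts([4, 2, 1, 1])
        theta = fit_theta_grid(spec, [float(t) for t in range(1, 201)])
        exact = esf_partition_test(spec, theta, method="exact")
        reps = 20_000
        mc = esf_partition_test(
            spec, theta, method="monte_carlo", reps=reps, seed=3
        )
        se = np.sqrt(exact * (1 - exact) / reps)
        assert abs(mc - exact) < 4 * se

    def test_neutral_calibration(self):
        """Under CRP data the default test's p-values are near-uniform:
        rejection rate at 0.05 within the binomial CI over 200 replicates."""
        rng = np.random.default_rng(42)
        counts = sample_crp_sizes_batch(30, 5.0, 200, rng)
        cfg = RunConfig(seed=7)
        ps = []
        for row in counts:
            spec = SpectrumConfig.from_counts([int(x) for x in row if x > 0])
            ps.append(esf_neutrality_test(spec, cfg).p_value)
        rate = np.mean(np.asarray(ps) <= 0.05)
        half_width = 3 * np.sqrt(0.05 * 0.95 / 200)
        assert abs(rate - 0.05) <= half_width
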