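"""Intersection counts and the Poisson-binomial / Le Cam null distribution."""

from itertools import combinations

import numpy as np
import pytest
from scipy import stats

from asset.matrix import (
    intersection_matrix,
    lecam_pmf,
    pair_probability,
    poisson_binomial_pmf,
    probability_matrix,
)
from asset.rates import true_rates
from asset.simulate import generate_model
from asset.spikedata import BinConfig, BinnedSpikes, bin_spike_trains


def _binned(occ, width=0.005):
    occ = np.asarray(occ, bool)
    return BinnedSpikes(occ, BinConfig(width, occ.shape[1]))


class TestIntersectionMatrix:
    def test_set_intersection_count(self):
        occ = np.zeros((6, 2), bool)
        occ[[1, 2, 3], 0] = True   # S_0 = {1,2,3}
        occ[[2, 3, 5], 1] = True   # S_1 = {2,3,5}
        m = intersection_matrix(_binned(occ))
        assert m.counts[0, 1] == 2
        assert m.counts[0, 0] == 3 and m.counts[1, 1] == 3  # population histogram

    def test_empty_bin_gives_zero_row(self):
        occ = np.zeros((4, 3), bool)
        occ[:2, 0] = True
        m = intersection_matrix(_binned(occ))
        assert not m.counts[:, 1].any() and not m.counts[1, :].any()

    def test_brute_force_oracle(self, poisson_set):
        b = bin_spike_trains(poisson_set, 0.01)
        m = intersection_matrix(b).counts
        sets = b.bin_sets()
        for i in range(0, b.n_bins, 13):
            for j in range(0, b.n_bins, 17):
                assert m[i, j] == len(sets[i] & sets[j])

    def test_symmetry(self, poisson_set):
        m = intersection_matrix(bin_spike_trains(poisson_set, 0.005)).counts
        np.testing.assert_array_equal(m, m.T)


class TestPairProbability:
    def test_printed_jump_value(self):
        # 100 Hz in both bins at 5 ms: each factor 1 - e^-0.5 ~ 0.39
        p = pair_probability(100.0, 100.0, 0.005)
        assert p == pytest.approx((1 - np.exp(-0.5)) ** 2)
        assert p == pytest.approx(0.155, abs=0.001)

    def test_zero_rate(self):
        assert pair_probability(0.0, 50.0, 0.005) == 0.0

    def test_saturates_at_one(self):
        assert pair_probability(1e9, 1e9, 0.005) == pytest.approx(1.0)


class TestPoissonBinomial:
    def test_single_fair_bernoulli(self):
        np.testing.assert_allclose(poisson_binomial_pmf([0.5]), [0.5, 0.5])

    def test_two_fair_coins(self):
        np.testing.assert_allclose(poisson_binomial_pmf([0.5, 0.5]), [0.25, 0.5, 0.25])

    def test_equal_p_matches_binomial(self):
        pmf = poisson_binomial_pmf(np.full(100, 0.01))
        expected = stats.binom.pmf(np.arange(101), 100, 0.01)
        np.testing.assert_allclose(pmf, expected, atol=1e-12)

    def test_sums_to_one(self, rng):
        p = rng.uniform(0, 1, 50)
        assert poisson_binomial_pmf(p).sum() == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("n", [5, 9, 12])
    def test_subset_enumeration_oracle(self, rng, n):
        """Exact convolution equals the 2^N subset-sum definition."""
        p = rng.uniform(0, 0.9, n)
        pmf = poisson_binomial_pmf(p)
        for xi in range(n + 1):
            total = 0.0
            for subset in combinations(range(n), xi):
                s = set(subset)
                term = 1.0
                for k in range(n):
                    term *= p[k] if k in s else 1 - p[k]
                total += term
            assert pmf[xi] == pytest.approx(total, abs=1e-12)

    def test_invalid_parameter(self):
        with pytest.raises(ValueError):
            poisson_binomial_pmf([0.5, 1.2])


class TestLeCam:
    def test_poisson_closed_form(self):
        assert lecam_pmf(1.0, [0])[0] == pytest.approx(np.exp(-1))

    def test_zero_rate_point_mass(self):
        np.testing.assert_allclose(lecam_pmf(0.0, [0, 1, 2]), [1, 0, 0])

    @pytest.mark.parametrize(
        "p", [np.full(100, 0.01), np.arange(1, 101) * 0.001], ids=["equal", "ramp"]
    )
    def test_integrated_absolute_error_bound(self, p):
        """Both printed parameter sets stay below the 0.04 IAE bound."""
        exact = poisson_binomial_pmf(p)
        approx = lecam_pmf(p.sum(), np.arange(exact.size))
        assert np.abs(exact - approx).sum() < 0.04

    def test_total_variation_le_cam_bound(self, rng):
        """TV distance <= sum of squared Bernoulli parameters."""
        for _ in range(10):
            p = rng.uniform(0, 0.2, 60)
            exact = poisson_binomial_pmf(p)
            support = np.arange(200)
            approx = lecam_pmf(p.sum(), support)
            tv = 0.5 * (
                np.abs(exact - approx[: exact.size]).sum() + approx[exact.size:].sum()
            )
            assert tv <= np.square(p).sum() + 1e-12


class TestProbabilityMatrix:
    def _setup(self, n_neurons=5, n_bins=8, seed=0, rate=40.0):
        data = generate_model(0, seed=seed, n_neurons=n_neurons, t_stop=0.2, rate=rate)
        binned = bin_spike_trains(data, 0.025)
        bins = binned.config
        rates = true_rates(np.full((n_neurons, bins.n_bins), rate), bins)
        return binned, rates

    def test_zero_count_zero_probability(self):
        binned, rates = self._setup()
        pm = probability_matrix(intersection_matrix(binned), rates, method="exact")
        im = intersection_matrix(binned).counts
        triu = np.triu_indices(im.shape[0], k=1)
        zero = im[triu] == 0
        assert np.all(pm.probs[triu][zero] == 0.0)

    def test_full_count_below_one(self):
        occ = np.ones((4, 3), bool)
        binned = _binned(occ)
        rates = true_rates(np.full((4, 3), 200.0), binned.config)
        pm = probability_matrix(intersection_matrix(binned), rates, method="exact")
        assert 0.0 < pm.probs[0, 1] < 1.0

    def test_exact_matches_subset_enumeration(self, rng):
        binned, rates = self._setup(n_neurons=5, seed=3)
        im = intersection_matrix(binned)
        pm = probability_matrix(im, rates, method="exact")
        q = 1 - np.exp(-rates.rates * binned.config.bin_width)
        i, j = 1, 4
        pvec = q[:, i] * q[:, j]
        # brute-force P(X < I_ij) by 2^N enumeration
        total = 0.0
        for xi in range(im.counts[i, j]):
            for subset in combinations(range(5), xi):
                s = set(subset)
                term = 1.0
                for k in range(5):
                    term *= pvec[k] if k in s else 1 - pvec[k]
                total += term
        assert pm.probs[i, j] == pytest.approx(total, abs=1e-12)

    def test_auto_switches_on_neuron_count(self):
        binned, rates = self._setup(n_neurons=5)
        assert probability_matrix(intersection_matrix(binned), rates).method == "exact"
        binned2, rates2 = self._setup(n_neurons=40, rate=10.0)
        assert probability_matrix(intersection_matrix(binned2), rates2).method == "lecam"

    def test_lecam_rate_is_sum_of_pair_probabilities(self):
        binned, rates = self._setup(n_neurons=40, rate=10.0)
        pm = probability_matrix(intersection_matrix(binned), rates, method="lecam")
        q = 1 - np.exp(-rates.rates * binned.config.bin_width)
        np.testing.assert_allclose(pm.lecam_rate[2, 5], (q[:, 2] * q[:, 5]).sum())

    def test_symmetric_mode_populates_upper_triangle_only(self):
        binned, rates = self._setup()
        pm = probability_matrix(intersection_matrix(binned), rates, method="exact")
        assert not np.tril(pm.probs).any()


def test_pvalue_conservative_under_null(rng):
    """On stationary data with true rates, Pr(1 - P <= y) <= y + slack."""
    tails = []
    for _ in range(5):
        data = generate_model(0, seed=rng, n_neurons=100, t_stop=0.5)
        binned = bin_spike_trains(data, 0.005)
        rates = true_rates(np.full((100, binned.n_bins), 15.0), binned.config)
        pm = probability_matrix(intersection_matrix(binned), rates, method="lecam")
        triu = np.triu_indices(binned.n_bins, k=1)
        tails.append(1.0 - pm.probs[triu])
    tails = np.concatenate(tails)
    for y in (0.01, 0.05, 0.1, 0.3):
        emp = np.mean(tails <= y)
        se = np.sqrt(y * (1 - y) / tails.size)
        assert emp <= y + 3 * se
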