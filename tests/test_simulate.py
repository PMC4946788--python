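"""Background-model generators and SSE injection."""

import numpy as np
import pytest

from asset.simulate import (
    ModelSpec,
    PiecewiseRate,
    SSESpec,
    compound_poisson,
    gamma_renewal,
    generate_model,
    inject_sse,
    multiple_sip,
    poisson_process,
    rate_jump_propagation,
    true_rate_profiles,
)
from asset.spikedata import BinConfig, bin_spike_trains


class TestPoissonProcess:
    def test_zero_rate_empty(self):
        assert poisson_process(0.0, t_stop=1.0, seed=0).size == 0

    def test_mean_count_matches_rate(self, rng):
        counts = [poisson_process(15.0, 1.0, rng).size for _ in range(2000)]
        mean = np.mean(counts)
        se = np.std(counts) / np.sqrt(len(counts))
        assert abs(mean - 15.0) < 3 * se + 1e-9

    def test_model1_profile_time_average(self, rng):
        # 10 Hz + 50 Hz on (600, 700) ms -> average 15 Hz over 1 s
        profile = PiecewiseRate.with_jumps(10.0, [(0.6, 0.7, 50.0)], 1.0)
        assert profile.integral() == pytest.approx(15.0)
        counts = [poisson_process(profile, 1.0, rng).size for _ in range(2000)]
        assert abs(np.mean(counts) - 15.0) < 0.3

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            PiecewiseRate.constant(-1.0, 1.0)


class TestGammaRenewal:
    def test_shape_one_is_exponential(self, rng):
        t = gamma_renewal(1.0, 1 / 15, t_stop=200.0, seed=rng)
        isi = np.diff(t)
        cv = isi.std() / isi.mean()
        assert abs(cv - 1.0) < 0.03

    def test_cv_matches_one_over_sqrt_shape(self, rng):
        t = gamma_renewal(5.0, 1 / 15, t_stop=300.0, seed=rng)
        isi = np.diff(t)
        assert abs(isi.std() / isi.mean() - 1 / np.sqrt(5)) < 0.02
        assert abs(isi.mean() - 1 / 15) < 3 * isi.std() / np.sqrt(isi.size)

    def test_equilibrium_start_stationary_count_rate(self, rng):
        # count rate in the FIRST 50 ms equals the nominal rate from t=0
        first = [
            (gamma_renewal(5.0, 1 / 15, t_stop=0.05, seed=rng).size)
            for _ in range(4000)
        ]
        mean = np.mean(first)
        assert abs(mean - 15 * 0.05) < 3 * np.std(first) / np.sqrt(4000)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            gamma_renewal(0.5, 0.1)
        with pytest.raises(ValueError):
            gamma_renewal(2.0, -0.1)


class TestCompoundPoisson:
    def test_degenerate_amplitude_is_independent_poisson(self, rng):
        s = compound_poisson(10, {1: 1.0}, rate=20.0, t_stop=5.0, seed=rng)
        rates = s.rates()
        assert abs(rates.mean() - 20.0) < 3 * rates.std() / np.sqrt(10) + 1.5

    def test_marginal_rate_matching(self, rng):
        s = compound_poisson(100, {1: 0.938, 5: 0.062}, rate=15.0, t_stop=20.0, seed=rng)
        mean_rate = s.rates().mean()
        assert abs(mean_rate - 15.0) < 0.3

    def test_size5_event_rate(self, rng):
        # events of size 5 occur at lambda_m * A(5) per second
        amp = {1: 0.938, 5: 0.062}
        t_stop = 20.0
        s = compound_poisson(100, amp, rate=15.0, t_stop=t_stop, seed=rng)
        lam_m = 100 * 15.0 / (0.938 + 5 * 0.062)
        # count times shared by exactly 5 trains
        from collections import Counter

        c = Counter(t for train in s.trains for t in train)
        n5 = sum(1 for v in c.values() if v == 5)
        expect = lam_m * amp[5] * t_stop
        assert abs(n5 - expect) < 4 * np.sqrt(expect)

    def test_support_exceeding_n_rejected(self):
        with pytest.raises(ValueError):
            compound_poisson(4, {5: 1.0}, rate=10.0)


class TestMultipleSip:
    def test_zero_events_pure_background(self, rng):
        s = multiple_sip(20, n_groups=2, group_size=3, events_per_group=0,
                         rate=10.0, seed=rng)
        assert abs(s.rates().mean() - 10.0) < 2.5

    def test_group_members_synchronous_in_event_bins(self, rng):
        s = multiple_sip(100, seed=rng)
        binned = bin_spike_trains(s, 0.005)
        # each default group (top ids) must share >= 2 fully synchronous bins
        for g in range(7):
            members = range(65 + 5 * g, 65 + 5 * (g + 1))
            joint = np.logical_and.reduce([binned.occupancy[k] for k in members])
            assert joint.sum() >= 2

    def test_total_rate(self, rng):
        s = multiple_sip(100, rate=15.0, t_stop=1.0, seed=rng)
        assert abs(s.rates().mean() - 15.0) < 0.5

    def test_overlapping_groups_rejected(self):
        with pytest.raises(ValueError):
            multiple_sip(10, n_groups=2, group_size=3,
                         groups=[(0, 1, 2), (2, 3, 4)])


class TestRateJump:
    def test_jump_probability_closed_form(self):
        # per-bin firing probabilities: 1 - exp(-lambda * 5 ms)
        assert 1 - np.exp(-100 * 0.005) == pytest.approx(0.39, abs=0.005)
        assert 1 - np.exp(-14 * 0.005) == pytest.approx(0.067, abs=0.001)

    def test_staggered_schedule_elevates_right_bins(self, rng):
        # aggregate over reps: group 3 (neurons 15-19) jumps at bins 13 and 103
        hits, reps = 0, 200
        for _ in range(reps):
            s = rate_jump_propagation(n_neurons=20, group_size=5, seed=rng)
            b = bin_spike_trains(s, 0.005)
            hits += b.occupancy[15:20, 13].sum()
        p_hat = hits / (5 * reps)
        assert abs(p_hat - 0.39) < 0.05

    def test_degenerate_jump_equals_baseline(self, rng):
        s = rate_jump_propagation(n_neurons=10, group_size=5, base_rate=14.0,
                                  jump_rate=14.0, seed=rng)
        assert abs(s.rates().mean() - 14.0) < 4.0


class TestGenerateModel:
    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(model_id=10)

    def test_seed_reproducibility(self):
        a = generate_model(4, seed=33)
        b = generate_model(4, seed=33)
        for x, y in zip(a.trains, b.trains):
            np.testing.assert_array_equal(x, y)

    @pytest.mark.parametrize("model_id,expected", [(0, 15.0), (9, 15.0)])
    def test_population_mean_rate(self, model_id, expected, rng):
        # the 15 Hz time average holds on the nominal 1 s window
        spec = ModelSpec(model_id=model_id, t_stop=1.0)
        rates = [generate_model(spec, seed=rng).rates().mean() for _ in range(15)]
        assert abs(np.mean(rates) - expected) < 0.4

    def test_model2_neuron99_rate(self, rng):
        spec = ModelSpec(model_id=2, t_stop=20.0)
        r = np.mean([generate_model(spec, seed=rng).trains[99].size / 20.0
                     for _ in range(3)])
        assert abs(r - 25.0) < 2.0

    def test_true_profiles_match_generators(self, bins_1s):
        prof = true_rate_profiles(1, bins_1s)
        assert prof.shape == (100, 200)
        assert prof[0, 0] == pytest.approx(10.0)
        assert prof[0, 125] == pytest.approx(60.0)  # inside (600, 700) ms
        prof6 = true_rate_profiles(6, bins_1s)
        assert prof6[0, 10] == pytest.approx(100.0)  # group 0 jump at 50 ms
        assert prof6[7, 11] == pytest.approx(100.0)  # group 1 jump at 55 ms
        assert prof6[0, 11] == pytest.approx(14.0)


class TestInjectSse:
    def test_consecutive_injection_ground_truth(self):
        silent = generate_model(0, seed=1, rate=0.0)
        data, truth = inject_sse(silent, SSESpec(), starts=[20, 100])
        assert len(truth) == 1
        ds = truth[0]
        assert ds == [(20 + e, 100 + e) for e in range(7)]
        binned = bin_spike_trains(data, 0.005)
        for e, (i, j) in enumerate(ds):
            group = frozenset(range(5 * e, 5 * (e + 1)))
            assert binned.bin_set(i) == group
            assert binned.bin_set(j) == group

    def test_truth_spans_one_diagonal(self):
        _, truth = inject_sse(generate_model(0, seed=2), SSESpec(), seed=3)
        lags = {j - i for i, j in truth[0]}
        assert len(lags) == 1  # w_DS = 1

    def test_hole_creates_two_diagonals(self):
        offsets = np.zeros((2, 7), int)
        offsets[0, 3:] = 1  # hole after event 3 in repetition 1 only
        sse = SSESpec(offsets=offsets)
        _, truth = inject_sse(generate_model(0, seed=4), sse, starts=[10, 100])
        lags = {j - i for i, j in truth[0]}
        assert len(lags) == 2  # w_DS = 2

    def test_spatiotemporal_pattern_injection(self):
        sse = SSESpec(n_events=7, event_size=1)
        data, truth = inject_sse(generate_model(0, seed=5, n_neurons=10), sse,
                                 starts=[30, 120])
        assert len(truth[0]) == 7
        binned = bin_spike_trains(data, 0.005)
        for e, (i, j) in enumerate(truth[0]):
            assert e in binned.bin_set(i) and e in binned.bin_set(j)

    def test_ground_truth_superset_on_background(self, injected_model0):
        data, truth = injected_model0
        binned = bin_spike_trains(data, 0.005)
        for e, (i, j) in enumerate(truth[0]):
            group = set(range(5 * e, 5 * (e + 1)))
            inter = binned.bin_set(i) & binned.bin_set(j)
            assert group <= inter

    def test_overlapping_starts_rejected(self):
        with pytest.raises(ValueError):
            inject_sse(generate_model(0, seed=6), SSESpec(), starts=[10, 12])

    def test_three_repetitions_yield_three_structures(self):
        sse = SSESpec(n_repetitions=3)
        _, truth = inject_sse(generate_model(0, seed=7), sse,
                              starts=[10, 60, 140])
        assert len(truth) == 3  # one DS per ordered repetition pair
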