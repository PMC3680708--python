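"""Synthetic pulse-train generators: determinism, distributions, behaviour."""

import numpy as np
import pytest
from scipy import stats

from sonarchannel.simulate import (
    NoiseResponseParams, SuppressionParams, gen_group_suppression,
    gen_noise_response_train, gen_solitary, gen_stimulus,
)
from sonarchannel.interference import rate_by_state


class TestSolitary:
    def test_deterministic_for_fixed_seed(self):
        a = gen_solitary(5.0, 10.0, "poisson", seed=1)
        b = gen_solitary(5.0, 10.0, "poisson", seed=1)
        assert np.array_equal(a.onsets, b.onsets)
        assert np.array_equal(a.durations_ms, b.durations_ms)
        c = gen_solitary(5.0, 10.0, "poisson", seed=2)
        assert not np.array_equal(a.onsets, c.onsets)

    def test_poisson_counts_follow_poisson_law(self):
        """Counts over 1000 seeds are consistent with Poisson(r0*T)."""
        counts = np.array([len(gen_solitary(5.0, 10.0, "poisson", seed=s))
                           for s in range(1000)])
        mu = 50.0
        assert abs(counts.mean() - mu) < 3 * np.sqrt(mu / 1000)
        # chi-square GOF on binned counts, expected from Poisson(50)
        edges = np.array([0, 40, 45, 48, 50, 52, 55, 60, np.inf])
        obs, _ = np.histogram(counts, bins=edges)
        cdf = stats.poisson(mu).cdf
        probs = np.diff([0] + [cdf(e - 0.5) for e in edges[1:-1]] + [1])
        chi2 = ((obs - 1000 * probs) ** 2 / (1000 * probs)).sum()
        assert chi2 < stats.chi2(len(obs) - 1).ppf(0.99)

    def test_tiny_epoch_is_usually_empty_never_an_error(self):
        counts = [len(gen_solitary(5.0, 0.001, "poisson", seed=s))
                  for s in range(50)]
        assert max(counts) <= 1 and min(counts) == 0

    def test_empirical_rate_converges_to_r0(self):
        total = sum(len(gen_solitary(5.0, 10.0, "poisson", seed=s))
                    for s in range(2000))
        assert abs(total / (2000 * 10.0) - 5.0) / 5.0 < 0.02

    def test_durations_within_species_range(self):
        t = gen_solitary(5.0, 10.0, seed=7)
        assert np.all((t.durations_ms >= 4.0) & (t.durations_ms <= 8.0))

    @pytest.mark.parametrize("r0,T", [(0, 10), (-1, 10), (5, 0)])
    def test_nonpositive_inputs_rejected(self, r0, T):
        with pytest.raises(ValueError):
            gen_solitary(r0, T, seed=0)


class TestGroupSuppression:
    def test_deterministic_for_fixed_seed(self):
        a = gen_group_suppression(3, seed=5)
        b = gen_group_suppression(3, seed=5)
        for ta, tb in zip(a.trains, b.trains):
            assert np.array_equal(ta.onsets, tb.onsets)

    def test_single_bat_matches_solitary_distribution(self):
        """n=1 has no one to hear: rates match the solitary generator."""
        params = SuppressionParams()
        grp = [gen_group_suppression(1, params, seed=s).total_pulses
               for s in range(200)]
        sol = [len(gen_solitary(5.0, 10.0, "gamma", seed=10_000 + s))
               for s in range(200)]
        assert stats.mannwhitneyu(grp, sol).pvalue > 0.01

    def test_pair_rate_below_solitary_rate(self):
        r1 = np.mean([gen_group_suppression(1, seed=s).total_pulses / 10.0
                      for s in range(200)])
        r2 = np.mean([gen_group_suppression(2, seed=s).total_pulses / 20.0
                      for s in range(200)])
        assert r2 < r1

    def test_rate_non_increasing_in_suppression_delay(self):
        means = []
        for delay in (0.0, 40.0, 80.0, 160.0):
            params = SuppressionParams(suppression_delay_ms=delay)
            means.append(np.mean([
                gen_group_suppression(3, params, seed=s).total_pulses
                for s in range(200)]))
        assert all(m2 <= m1 for m1, m2 in zip(means, means[1:]))

    def test_deaf_group_equals_independent_solitary(self):
        """hearing_prob=0: distribution matches n independent solitary bats."""
        params = SuppressionParams(hearing_prob=0.0)
        grp = [gen_group_suppression(4, params, seed=s).total_pulses
               for s in range(200)]
        ind = [sum(len(gen_solitary(5.0, 10.0, "gamma", seed=7_000 + 4 * s + i))
                   for i in range(4)) for s in range(200)]
        assert stats.mannwhitneyu(grp, ind).pvalue > 0.01

    def test_additive_mode_suppresses_more_than_restart(self):
        rates = {}
        for mode in ("restart", "additive"):
            params = SuppressionParams(postpone_mode=mode)
            rates[mode] = np.mean([
                gen_group_suppression(5, params, seed=s).total_pulses
                for s in range(100)])
        assert rates["additive"] < rates["restart"]

    def test_zero_bats_rejected(self):
        with pytest.raises(ValueError):
            gen_group_suppression(0, seed=0)


class TestStimulus:
    @pytest.mark.parametrize("burst,silent,duty", [
        (10.0, 90.0, 0.10),
        (10.0, 10.0, 0.50),
        (10.0, 40.0, 0.20),
        (10.0, 1.1, 10.0 / 11.1),
        (0.0, 100.0, 0.0),
    ])
    def test_duty_cycle(self, burst, silent, duty):
        assert gen_stimulus(burst, silent, 10.0).duty_cycle == pytest.approx(duty)

    def test_tiles_epoch_without_gaps(self):
        sch = gen_stimulus(10.0, 90.0, 10.0)
        assert sch.intervals[0][0] == 0.0
        assert sch.duration_T == pytest.approx(10.0)
        for (s0, e0, _), (s1, _, _) in zip(sch.intervals, sch.intervals[1:]):
            assert e0 == pytest.approx(s1)

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError):
            gen_stimulus(0.0, 0.0, 10.0)


class TestNoiseResponse:
    def test_all_silence_behaves_as_solitary(self):
        sch = gen_stimulus(0.0, 100.0, 10.0)
        noisy = [len(gen_noise_response_train(5.0, sch, seed=s,
                                              ipi_model="poisson"))
                 for s in range(200)]
        sol = [len(gen_solitary(5.0, 10.0, "poisson", seed=5_000 + s))
               for s in range(200)]
        assert stats.mannwhitneyu(noisy, sol).pvalue > 0.01

    def test_high_duty_noise_facilitates_at_multiplier(self):
        """Duty 90 %: noise-interval rate / silence-interval rate ~ 2.3/1.8."""
        sch = gen_stimulus(10.0, 1.1, 10.0)
        noise_c = sil_c = 0.0
        for s in range(500):
            tr = gen_noise_response_train(1.8, sch, seed=s, ipi_model="poisson")
            r = rate_by_state(tr, sch)
            noise_c += r["noise"]
            sil_c += r["silence"]
        assert noise_c / sil_c == pytest.approx(2.3 / 1.8, rel=0.10)

    def test_low_duty_noise_suppresses_mean_rate(self):
        """Duty 10 %: burst-triggered postponement pulls the rate below r0."""
        sch = gen_stimulus(10.0, 90.0, 10.0)
        rates = [len(gen_noise_response_train(5.0, sch, seed=s)) / 10.0
                 for s in range(200)]
        assert np.mean(rates) < 5.0

    def test_deterministic_for_fixed_seed(self):
        sch = gen_stimulus(10.0, 10.0, 10.0)
        a = gen_noise_response_train(1.8, sch, seed=11)
        b = gen_noise_response_train(1.8, sch, seed=11)
        assert np.array_equal(a.onsets, b.onsets)

    def test_invalid_multiplier_rejected(self):
        with pytest.raises(ValueError):
            NoiseResponseParams(noise_rate_multiplier=0.0)
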