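import numpy as np
import pytest

from heraldspec import (
    ExperimentConfig,
    channel_times,
    conditional_g2,
    eta_for_herald_rate,
    expected_e_hf,
    expected_herald_rate,
    fit_geometric,
    gated_counts,
    heralded_g2_theory,
    herald_count_distribution,
    simulate,
    simulate_pn_experiment,
)


def measured_e_hf(stream, gate_ps=10_000):
    dist = herald_count_distribution(stream, gate_ps=gate_ps)
    return dist.total_events / dist.total_heralds, dist.total_events


class TestConfig:
    def test_rejects_bad_probability(self):
        with pytest.raises(ValueError):
            ExperimentConfig(eta_herald=1.5)

    def test_rejects_negative_rate(self):
        with pytest.raises(ValueError):
            ExperimentConfig(n_p=-0.1)

    def test_rejects_unknown_herald_model(self):
        with pytest.raises(ValueError):
            ExperimentConfig(herald_model="telepathy")

    def test_dict_round_trip(self):
        cfg = ExperimentConfig(dark_rates={2: 100.0}, splitter=True, seed=9)
        assert ExperimentConfig.from_dict(cfg.to_dict()) == cfg

    def test_requires_at_least_one_pulse(self):
        with pytest.raises(ValueError, match="pulse"):
            simulate(ExperimentConfig(duration_s=1e-9))


class TestSimulate:
    def test_vacuum_source_only_dark_counts(self):
        cfg = ExperimentConfig(n_p=0.0, dark_rates={2: 1000.0}, duration_s=0.1, seed=1)
        s = simulate(cfg)
        assert set(np.unique(s.channels)) <= {2}
        n = len(s)
        assert abs(n - 100) < 4 * np.sqrt(100)

    def test_bit_reproducible(self):
        cfg = ExperimentConfig(duration_s=0.02, p_detect_fluor=0.05, splitter=True, seed=42)
        a, b = simulate(cfg), simulate(cfg)
        np.testing.assert_array_equal(a.times, b.times)
        np.testing.assert_array_equal(a.channels, b.channels)

    def test_different_seeds_differ(self):
        cfg = ExperimentConfig(duration_s=0.01, seed=1)
        cfg2 = ExperimentConfig(duration_s=0.01, seed=2)
        assert not np.array_equal(simulate(cfg).times, simulate(cfg2).times)

    @pytest.mark.parametrize("model", ["per-pulse", "per-photon"])
    def test_herald_rate_matches_expectation(self, model):
        cfg = ExperimentConfig(duration_s=0.2, p_detect_fluor=0.0, herald_model=model, seed=3)
        s = simulate(cfg)
        n_h = channel_times(s, 1).size
        expect = expected_herald_rate(cfg) * cfg.duration_s
        assert abs(n_h - expect) < 4 * np.sqrt(expect)

    def test_herald_clicks_bernoulli_per_pulse_block(self):
        # split the run into blocks; herald counts should be binomial with
        # index dispersion 1 - P(click) ~ 1 (3 sigma band for 100 blocks)
        cfg = ExperimentConfig(duration_s=0.1, p_detect_fluor=0.0, seed=8)
        s = simulate(cfg)
        h = channel_times(s, 1)
        n_blocks = 100
        edges = np.linspace(0, cfg.duration_s * 1e12, n_blocks + 1)
        counts, _ = np.histogram(h, bins=edges)
        mean, var = counts.mean(), counts.var(ddof=1)
        band = 3.0 * np.sqrt(2.0 / (n_blocks - 1))
        assert 1.0 - band < var / mean < 1.0 + band

    def test_fluorescence_delays_exponential(self):
        # jitter off, dark off: delay MLE (sample mean) recovers tau_fl
        cfg = ExperimentConfig(
            duration_s=0.05, p_detect_fluor=0.2, irf_sigma=0.0, seed=5
        )
        s = simulate(cfg)
        h = channel_times(s, 1)
        f = channel_times(s, 2)
        idx = np.searchsorted(h, f, side="right") - 1
        ok = idx >= 0
        delays = f[ok] - h[idx[ok]]
        delays = delays[(delays >= 0) & (delays < 10_000)]
        n = delays.size
        assert n > 5_000
        # truncated-exponential correction is tiny at 10 ns; use plain mean
        mean = delays.mean()
        se = mean / np.sqrt(n)
        assert abs(mean - cfg.tau_fl) < 3.5 * se

    def test_tags_within_acquisition_window(self):
        cfg = ExperimentConfig(duration_s=0.01, p_detect_fluor=0.1, seed=6)
        s = simulate(cfg)
        assert s.times.min() >= 0
        assert s.times.max() <= cfg.duration_s * 1e12

    def test_trajectory_log_detections_in_stream(self):
        cfg = ExperimentConfig(duration_s=0.005, p_detect_fluor=0.3, irf_sigma=0.0, seed=7)
        s, log = simulate(cfg, return_log=True)
        assert log.herald_click.sum() == channel_times(s, 1).size
        assert log.n_pairs.min() >= 1
        # every heralded pulse in the log has its tag at the pulse time
        period = 1e12 / cfg.R_r
        t_click = np.round(log.pulse_index[log.herald_click] * period).astype(np.int64)
        np.testing.assert_array_equal(np.sort(t_click), channel_times(s, 1))

    def test_dead_time_enforced(self):
        cfg = ExperimentConfig(
            duration_s=0.01, p_detect_fluor=0.0, dead_time=5e6, dark_rates={2: 50_000.0}, seed=9
        )
        s = simulate(cfg)
        d2 = channel_times(s, 2)
        assert np.all(np.diff(d2) >= 5e6)

    def test_splitter_routes_both_channels(self):
        cfg = ExperimentConfig(duration_s=0.02, p_detect_fluor=0.2, splitter=True, seed=10)
        s = simulate(cfg)
        n2, n3 = channel_times(s, 2).size, channel_times(s, 3).size
        assert n2 > 0 and n3 > 0
        assert abs(n2 - n3) < 4 * np.sqrt(n2 + n3)


class TestRatesContracts:
    def test_printed_e_hf_recovered_at_rate1(self):
        # rate-1 settings with the printed channel efficiency
        cfg = ExperimentConfig(
            n_p=0.0458,
            eta_herald=eta_for_herald_rate(9.73e5, 0.0458),
            p_detect_fluor=1.244e-4,
            duration_s=10.0,
            seed=12,
        )
        s = simulate(cfg)
        e_meas, n_events = measured_e_hf(s)
        sd = np.sqrt(n_events) / channel_times(s, 1).size
        assert n_events > 500
        assert abs(e_meas - 1.244e-4) < 3 * sd

    def test_e_hf_tracks_p_detect(self):
        cfg = ExperimentConfig(duration_s=0.5, p_detect_fluor=0.01, seed=13)
        s = simulate(cfg)
        e_meas, n_events = measured_e_hf(s)
        # oracle: exact model value corrected for the probability that the
        # emission delay (plus jitter) falls outside the [0, gate) window
        from scipy import integrate, stats as sps

        def integrand(d):
            return sps.expon.pdf(d, scale=cfg.tau_fl) * (
                sps.norm.cdf((-0.5 - d) / cfg.irf_sigma)
                + sps.norm.sf((cfg.gate_fluor - 0.5 - d) / cfg.irf_sigma)
            )

        miss, _ = integrate.quad(integrand, 0, 50 * cfg.tau_fl)
        expect = expected_e_hf(cfg) * (1.0 - miss)
        sd = np.sqrt(n_events) / channel_times(s, 1).size
        assert abs(e_meas - expect) < 3 * sd

    def test_e_hf_constant_across_rates(self):
        # the linearity check: e_hf essentially constant over a 4x rate range
        estimates = []
        for i, n_p in enumerate((0.0458, 0.0214, 0.0103)):
            cfg = ExperimentConfig(
                n_p=n_p, p_detect_fluor=0.02, duration_s=0.3 * 0.0458 / n_p, seed=20 + i
            )
            e_meas, n_events = measured_e_hf(simulate(cfg))
            estimates.append((e_meas, e_meas / np.sqrt(n_events)))
        for (e_a, s_a), (e_b, s_b) in zip(estimates, estimates[1:]):
            assert abs(e_a - e_b) < 3 * np.hypot(s_a, s_b) + 0.04 * e_a

    def test_loss_invariance_of_g2(self):
        # halving both efficiencies leaves conditional g2 unchanged within errors
        results = []
        for i, scale in enumerate((1.0, 0.5)):
            cfg = ExperimentConfig(
                splitter=True,
                eta_herald=0.2804 * scale,
                p_detect_fluor=0.2 * scale,
                duration_s=0.4 / scale,
                seed=30 + i,
            )
            g2 = conditional_g2(gated_counts(simulate(cfg), gate_ps=10_000))
            results.append(g2)
        a, b = results
        assert abs(a.value - b.value) < 3 * np.hypot(a.sd, b.sd)


class TestPnExperiment:
    def test_perfect_detection_all_n1(self):
        cfg = ExperimentConfig(p_detect_fluor=1.0, irf_sigma=0.0, duration_s=0.001, seed=14)
        dist = simulate_pn_experiment(cfg)
        # only the exp(-gate/tau) ~ 2.4e-4 late-emission tail breaks N = 1
        assert dist.probabilities[1] > 0.995

    def test_consistent_with_geometric_model(self):
        cfg = ExperimentConfig(p_detect_fluor=0.02, splitter=True, duration_s=0.3, seed=15)
        dist = simulate_pn_experiment(cfg)
        fit = fit_geometric(dist)
        # stream-measured efficiency agrees with the geometric MLE
        e_stream = dist.total_events / dist.total_heralds
        assert abs(fit.e_hf - e_stream) < 4 * fit.se + 1e-4

    def test_repeats_are_independent(self):
        cfg = ExperimentConfig(p_detect_fluor=0.05, duration_s=0.02, seed=16)
        dists = simulate_pn_experiment(cfg, repeats=3)
        assert len(dists) == 3
        totals = [d.total_events for d in dists]
        assert len(set(totals)) > 1  # overwhelmingly likely for distinct seeds

    def test_noise_shrinks_with_integration_time(self):
        cfg = ExperimentConfig(p_detect_fluor=0.05, splitter=True, duration_s=0.02, seed=17)
        d_short = simulate_pn_experiment(cfg)
        import dataclasses

        d_long = simulate_pn_experiment(dataclasses.replace(cfg, duration_s=0.5, seed=18))
        ratio = d_short.poisson_sd[1] / d_long.poisson_sd[1]
        assert 3.0 < ratio < 8.5  # ~sqrt(25) = 5 expected

    def test_invalid_repeats(self):
        with pytest.raises(ValueError):
            simulate_pn_experiment(ExperimentConfig(duration_s=0.001), repeats=0)
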