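"""Exactness, determinism, and statistics of the stochastic simulator."""

import numpy as np
import pytest
from scipy import stats as sps

from fluorstat import gillespie
from fluorstat.photophysics import ExcitationProfile, absorption_cross_section


def _flux_for_rate(fl, r_x):
    return r_x / absorption_cross_section(fl.epsilon)


class TestDeterminism:
    def test_identical_seed_gives_identical_log(self, fast_fluorophore):
        profile = ExcitationProfile.constant(_flux_for_rate(fast_fluorophore, 1e5))
        a = gillespie.simulate_ssa(fast_fluorophore, profile, 20, 1e-3, seed=7)
        b = gillespie.simulate_ssa(fast_fluorophore, profile, 20, 1e-3, seed=7)
        np.testing.assert_array_equal(a.times, b.times)
        np.testing.assert_array_equal(a.types, b.types)

    def test_trials_are_independent_streams(self, fast_fluorophore):
        profile = ExcitationProfile.constant(_flux_for_rate(fast_fluorophore, 1e5))
        ens = gillespie.simulate_trials(fast_fluorophore, profile, 20, 2e-4, 3, seed=7)
        assert not np.array_equal(ens.logs[0].times, ens.logs[1].times)


class TestExactness:
    def test_zero_flux_ground_start_is_silent(self, fast_fluorophore):
        log = gillespie.simulate_ssa(
            fast_fluorophore, ExcitationProfile.constant(0.0), 100, 1e-3, seed=1
        )
        assert log.times.size == 0

    def test_pure_death_matches_exponential_decay(self, fast_fluorophore):
        """With no excitation and all N initially excited, the mean excited
        population decays as N·e^{−t/τ_l}."""
        n, trials = 50, 400
        tau = fast_fluorophore.lifetime
        ens = gillespie.simulate_trials(
            fast_fluorophore,
            ExcitationProfile.constant(0.0),
            n,
            5 * tau,
            trials,
            seed=11,
            initial_state=(0, n, 0),
        )
        grid = np.linspace(0.2 * tau, 4 * tau, 12)
        summary = gillespie.trial_statistics(ens, grid)
        expected = n * np.exp(-grid / tau)
        se = np.sqrt(summary.variance["excited"] / trials)
        assert np.all(np.abs(summary.mean["excited"] - expected) <= 3 * se + 1e-9)

    def test_interevent_times_are_conditionally_exponential(self, fast_fluorophore):
        """Rescaling each waiting time by its total propensity must give an
        i.i.d. unit-exponential sample (KS test, α = 0.01)."""
        fl = fast_fluorophore
        r_x = 1e5
        profile = ExcitationProfile.constant(_flux_for_rate(fl, r_x))
        n = 20
        log = gillespie.simulate_ssa(fl, profile, n, 0.3, seed=3)
        assert log.times.size > 10_000
        times = log.times[:10_001]
        # state immediately before each event
        before = log.state_trace(np.concatenate(([log.t_start], times[:-1])))
        a0 = r_x * before[:, 0] + fl.relaxation_rate * before[:, 1]
        u = a0 * np.diff(np.concatenate(([log.t_start], times)))
        assert sps.kstest(u, "expon").pvalue > 0.01

    def test_conservation_with_bleaching(self, fast_fluorophore):
        fl = fast_fluorophore.with_bleaching(2e4)
        profile = ExcitationProfile.constant(_flux_for_rate(fl, 1e5))
        log = gillespie.simulate_ssa(fl, profile, 30, 2e-3, seed=5)
        trace = log.state_trace(np.linspace(0, 2e-3, 50))
        np.testing.assert_array_equal(trace.sum(axis=1), 30)
        assert np.all(trace >= 0)
        # bleached population never shrinks
        assert np.all(np.diff(trace[:, 2]) >= 0)


class TestCounting:
    def test_empty_log_counts_zero(self, fast_fluorophore):
        log = gillespie.simulate_ssa(
            fast_fluorophore, ExcitationProfile.constant(0.0), 10, 1e-3, seed=1
        )
        assert gillespie.count_photons(log, mode="cw", window=(0.0, 1e-3)) == 0

    def test_window_outside_horizon_rejected(self, fast_fluorophore):
        log = gillespie.simulate_ssa(
            fast_fluorophore, ExcitationProfile.constant(0.0), 10, 1e-3, seed=1
        )
        with pytest.raises(ValueError):
            gillespie.count_photons(log, mode="cw", window=(0.0, 2e-3))

    def test_tg_gates_partition_photons(self, fast_fluorophore):
        fl = fast_fluorophore
        profile = ExcitationProfile.pulse_train(
            _flux_for_rate(fl, 1e5), period=1e-4, duty=5e-5, cycles=3
        )
        log = gillespie.simulate_ssa(fl, profile, 50, 3e-4, seed=9)
        gated = gillespie.count_photons(
            log, mode="tg", shutoff=5e-5, gate_delay=0.0,
            t_int=5e-5, shots=3, period=1e-4,
        )
        on = sum(
            gillespie.count_photons(log, mode="cw", window=(k * 1e-4, k * 1e-4 + 5e-5))
            for k in range(3)
        )
        assert gated + on == log.photon_times.size


class TestTrialStatistics:
    def test_single_trial_mean_is_the_trial(self, fast_fluorophore):
        profile = ExcitationProfile.constant(_flux_for_rate(fast_fluorophore, 1e5))
        ens = gillespie.simulate_trials(fast_fluorophore, profile, 10, 2e-4, 1, seed=2)
        grid = np.linspace(0, 2e-4, 9)
        summary = gillespie.trial_statistics(ens, grid)
        trace = ens.logs[0].state_trace(grid)
        np.testing.assert_array_equal(summary.mean["excited"], trace[:, 1])

    def test_histograms_sum_to_trial_count(self, fast_fluorophore):
        profile = ExcitationProfile.constant(_flux_for_rate(fast_fluorophore, 1e5))
        ens = gillespie.simulate_trials(fast_fluorophore, profile, 10, 2e-4, 25, seed=2)
        summary = gillespie.trial_statistics(
            ens, np.linspace(0, 2e-4, 5), time_points=[1e-4, 2e-4]
        )
        for hist in summary.histograms["excited"].values():
            assert hist.sum() == 25
        assert all(np.all(v >= 0) for v in summary.variance.values())


class TestEmpiricalPSD:
    def test_poisson_null_is_flat_at_twice_rate(self, rng):
        """Homogeneous Poisson photon times have a white spectrum at 2λ."""
        rate, horizon, trials = 1e5, 1.0, 8
        times = [
            np.sort(rng.uniform(0, horizon, rng.poisson(rate * horizon)))
            for _ in range(trials)
        ]
        spec = gillespie.empirical_psd(times, horizon, 1e-5, deconvolve=False)
        per_trial = []
        for t in times:
            s = gillespie.empirical_psd(t, horizon, 1e-5, deconvolve=False)
            per_trial.append(s.density.mean())
        per_trial = np.array(per_trial)
        se = per_trial.std(ddof=1) / np.sqrt(trials)
        assert abs(spec.density.mean() - 2 * rate) <= 3 * se

    def test_few_photons_warns(self):
        with pytest.warns(UserWarning):
            gillespie.empirical_psd(np.array([1e-3, 2e-3]), 1.0, 1e-3)

    def test_bad_bin_width_rejected(self):
        with pytest.raises(ValueError):
            gillespie.empirical_psd(np.array([0.5]), 1.0, -1.0)


class TestWindowCounts:
    def test_reproducible_and_well_shaped(self, fast_fluorophore):
        kw = dict(t_int=2e-4, n_windows=10, n_trials=5, seed=31)
        flux = _flux_for_rate(fast_fluorophore, 1e5)
        a = gillespie.steady_state_window_counts(fast_fluorophore, flux, 20, **kw)
        b = gillespie.steady_state_window_counts(fast_fluorophore, flux, 20, **kw)
        np.testing.assert_array_equal(a, b)
        assert a.shape == (5, 10)
        assert np.all(a >= 0)

    def test_mean_matches_renewal_prediction(self, fast_fluorophore):
        from fluorstat import counting

        fl = fast_fluorophore
        r_x = 1e5
        flux = _flux_for_rate(fl, r_x)
        counts = gillespie.steady_state_window_counts(
            fl, flux, 20, t_int=2e-4, n_windows=20, n_trials=20, seed=17
        )
        model = counting.eigenrates(r_x, fl.relaxation_rate, fl.quantum_yield)
        expected = counting.cw_count_stats(model, 2e-4, n_total=20)
        flat = counts.ravel().astype(float)
        se = flat.std(ddof=1) / np.sqrt(flat.size)
        assert abs(flat.mean() - expected.mean) <= 3 * se

    def test_bleaching_rejected(self, fast_fluorophore):
        with pytest.raises(ValueError):
            gillespie.steady_state_window_counts(
                fast_fluorophore.with_bleaching(10.0), 1e20, 10,
                t_int=1e-4, n_windows=2, n_trials=1, seed=1,
            )
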