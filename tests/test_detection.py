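"""QSNR/SNR structure, OD behavior, detection limits, and spot scaling."""

import math
import warnings

import numpy as np
import pytest

from fluorstat import counting, detection
from fluorstat.counting import CountStatistics
from fluorstat.photophysics import excitation_rate


@pytest.fixture(scope="module")
def imager():
    return detection.builtin_imager()


@pytest.fixture(scope="module")
def ru_cw_stats(operating_points):
    op = operating_points["[Ru(bpy)3]Br2"]
    r_x = excitation_rate(op.flux, op.fluorophore)
    model = counting.eigenrates(
        r_x, op.fluorophore.relaxation_rate, op.fluorophore.quantum_yield
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return counting.cw_count_stats(model, op.t_int_cw, n_total=op.n_total)


class TestQSNR:
    def test_doubling_pixels_adds_3db(self, imager):
        stats = CountStatistics(mean=1e4, variance=9e3)
        import dataclasses

        double = dataclasses.replace(imager, pixels=imager.pixels * 2)
        assert detection.qsnr(stats, double) - detection.qsnr(stats, imager) == \
            pytest.approx(10 * math.log10(2), rel=1e-9)

    def test_poisson_simplification(self, imager):
        """For Poisson statistics the QSNR collapses to 10log10(G·γη·⟨n⟩)."""
        stats = CountStatistics(mean=5e4, variance=5e4)
        ge = imager.emission_coupling * imager.qe_emission
        assert detection.qsnr(stats, imager) == pytest.approx(
            10 * math.log10(imager.pixels * ge * stats.mean), rel=1e-12
        )

    def test_zero_mean_rejected(self, imager):
        with pytest.raises(ValueError):
            detection.qsnr(CountStatistics(mean=0.0, variance=1.0), imager)

    def test_ru_cw_benchmark_regression(self, ru_cw_stats, imager):
        """Pipeline-composed QSNR at the Ru CW benchmark point (golden value)."""
        assert detection.qsnr(ru_cw_stats, imager) == pytest.approx(35.0744, abs=5e-3)
        assert detection.qsnr(ru_cw_stats, imager) > 0

    def test_saturation_warning(self, imager):
        stats = CountStatistics(mean=1e12, variance=1e12)
        with pytest.warns(UserWarning):
            detection.qsnr(stats, imager)


class TestSNRCW:
    def test_noiseless_limit_recovers_qsnr(self, ru_cw_stats, imager):
        import dataclasses

        clean = dataclasses.replace(imager, read_noise=0.0, dark_current=0.0, filter_od=300.0)
        res = detection.snr_cw(ru_cw_stats, clean, 1.28e21 * 1e-4, 20e-6)
        assert abs(res.snr_db - res.qsnr_db) < 1e-9

    def test_background_dominated_decays_10db_per_od(self, ru_cw_stats, imager):
        snrs = {
            od: detection.snr_cw(
                ru_cw_stats, imager.with_od(od), 1.28e21 * 1e-4, 20e-6
            ).snr_db
            for od in (3, 4, 5)
        }
        assert snrs[4] - snrs[3] == pytest.approx(10.0, abs=0.1)
        assert snrs[5] - snrs[4] == pytest.approx(10.0, abs=0.1)

    def test_flattens_when_background_free(self, ru_cw_stats, imager):
        """Above the OD where the background falls below 10% of the quantum
        variance, successive OD steps change the SNR by < 0.5 dB."""
        prev = None
        for od in range(3, 14):
            res = detection.snr_cw(ru_cw_stats, imager.with_od(od), 1.28e21 * 1e-4, 20e-6)
            if prev is not None and prev.background_electrons < 0.1 * prev.quantum_variance:
                assert abs(res.snr_db - prev.snr_db) < 0.5
            prev = res

    def test_snr_never_exceeds_qsnr(self, ru_cw_stats, imager, rng):
        for _ in range(50):
            od = rng.uniform(0, 10)
            flux = 10 ** rng.uniform(14, 20)
            res = detection.snr_cw(ru_cw_stats, imager.with_od(od), flux, 20e-6)
            assert res.snr_db <= res.qsnr_db + 1e-12


@pytest.fixture(scope="module")
def tg_stats(operating_points):
    op = operating_points["[Ru(bpy)3]Br2"]
    r_x = excitation_rate(op.flux, op.fluorophore)
    return counting.tg_count_stats(
        op.fluorophore, r_x, op.shots, op.gate_delay, op.t_int_tg, n_total=op.n_total
    )


class TestSNRTG:
    def test_zero_tail_means_zero_leakage(self, tg_stats, imager):
        import dataclasses

        no_tail = dataclasses.replace(imager, excitation_tail=0.0)
        res = detection.snr_tg(tg_stats, no_tail, 1.28e21 * 1e-4, 10, 250e-9, 4.75e-6)
        assert res.background_electrons == 0.0

    def test_long_delay_gates_out_background(self, tg_stats, imager):
        far = detection.snr_tg(tg_stats, imager, 1.28e21 * 1e-4, 10, 100 * imager.excitation_tail, 4.75e-6)
        assert far.background_electrons == pytest.approx(0.0, abs=1e-20)
        # read/dark limited value
        expected = far.qsnr_db - 10 * math.log10(
            1 + (far.read_variance + far.dark_electrons) / far.quantum_variance
        )
        assert far.snr_db == pytest.approx(expected, rel=1e-12)

    def test_delay_extends_flat_region_to_lower_od(self, tg_stats, imager):
        """Growing ΔT_D/τ_s must monotonically lower the OD at which the SNR
        becomes background-free."""
        ods = np.arange(0.0, 10.5, 0.5)

        def od_flat(delay):
            for od in ods:
                res = detection.snr_tg(
                    tg_stats, imager.with_od(float(od)), 1.28e21 * 1e-4, 10, delay, 4.75e-6
                )
                if res.background_electrons < 0.1 * res.quantum_variance:
                    return od
            return ods[-1]

        tau_s = imager.excitation_tail
        thresholds = [od_flat(r * tau_s) for r in (0.0, 2.0, 4.0, 8.0)]
        assert all(b <= a for a, b in zip(thresholds, thresholds[1:]))
        assert thresholds[-1] < thresholds[0]

    def test_cw_and_tg_share_qsnr_without_extrinsics(self, tg_stats, imager):
        import dataclasses

        clean = dataclasses.replace(imager, read_noise=0.0, dark_current=0.0, filter_od=300.0)
        cw = detection.snr_cw(tg_stats, clean, 1e15, 1e-5)
        tg = detection.snr_tg(tg_stats, clean, 1e15, 10, 250e-9, 1e-5)
        assert cw.snr_db == pytest.approx(tg.snr_db, abs=1e-9)
        assert cw.snr_db == pytest.approx(cw.qsnr_db, abs=1e-9)


class TestMDL:
    def test_quantum_limited_floor_is_one(self, ru, imager):
        import dataclasses

        clean = dataclasses.replace(imager, read_noise=0.0, dark_current=0.0, filter_od=300.0)
        n_min = detection.minimum_detection_limit(
            ru, 1.28e21, clean, mode="cw", t_int=1.0
        )
        assert n_min == 1

    def test_mdl_decreases_with_excitation_power(self, ru, imager):
        fluxes = [1e19, 1e20, 1e21]
        mdls = [
            detection.minimum_detection_limit(ru, f, imager, mode="cw", t_int=20e-6)
            for f in fluxes
        ]
        assert mdls[0] >= mdls[1] >= mdls[2]
        assert mdls[0] > mdls[2]

    def test_read_noise_never_helps(self, ru, imager):
        import dataclasses

        noisy = dataclasses.replace(imager, read_noise=2 * imager.read_noise)
        base = detection.minimum_detection_limit(ru, 1e20, imager, mode="cw", t_int=20e-6)
        worse = detection.minimum_detection_limit(ru, 1e20, noisy, mode="cw", t_int=20e-6)
        assert worse >= base

    def test_bracket_error(self, ru, imager):
        with pytest.raises(ValueError):
            detection.minimum_detection_limit(
                ru, 1e20, imager, mode="cw", t_int=20e-6, bracket=(1e-3, 1e-2)
            )

    def test_tg_mode_runs(self, ru, imager):
        n_min = detection.minimum_detection_limit(
            ru, 1e20, imager, mode="tg", t_int=4.75e-6, shots=100, gate_delay=250e-9
        )
        assert n_min >= 1


class TestSpotScaling:
    def test_alpha_one_gives_half_total_time(self, ru, imager):
        scen = detection.ScalingScenario(alphas=(1.0,), total_time=1.0, n_values=(1e4,))
        table = detection.spot_scaling_sweep(scen, ru, 1.28e21, imager)
        assert table["t_int"].iloc[0] == pytest.approx(0.5)

    def test_qsnr_monotone_in_n_and_alpha(self, ru, imager):
        scen = detection.ScalingScenario(
            alphas=(0.1, 0.3, 1.0), total_time=1.0, n_values=(1e3, 1e4, 1e5)
        )
        table = detection.spot_scaling_sweep(scen, ru, 1.28e21, imager)
        for alpha, grp in table.groupby("alpha"):
            assert grp.sort_values("n")["qsnr_db"].is_monotonic_increasing
        for n, grp in table.groupby("n"):
            assert grp.sort_values("alpha")["qsnr_db"].is_monotonic_increasing

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            detection.ScalingScenario(alphas=(1.5,), total_time=1.0, n_values=(10,))
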