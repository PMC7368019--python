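"""Spectral feature extraction: binning, normalisation, SNR, pools."""

import math

import numpy as np
import pytest

import veptools as vt
from veptools.errors import ConfigurationError, DataError
from veptools.simulate import SimulationConfig
from veptools.spectral import (
    BinSpectrum,
    amplitude_spectrum,
    build_feature_pools,
    compute_snr,
    side_bin_noise,
    trim_and_bin,
)

from conftest import make_recording, make_sample_table


def dtft_amplitude(x, f, fs):
    """Independent single-sided amplitude oracle: direct Fourier sum."""
    n = np.arange(len(x))
    coeff = np.sum(x * np.exp(-2j * np.pi * f * n / fs)) / len(x)
    return 2 * abs(coeff) if f > 0 else abs(coeff)


class TestTrimAndBin:
    @pytest.mark.parametrize(
        "duration, expected", [(100.0, 90), (11.0, 1), (12.5, 2)]
    )
    def test_bin_counts_depend_only_on_duration(self, duration, expected):
        rec = make_recording(np.zeros(int(duration * 1000)))
        assert trim_and_bin(rec).shape == (1, expected, 1000)

    def test_too_short_recording_names_minimum(self):
        rec = make_recording(np.zeros(10_000))
        with pytest.raises(ConfigurationError, match="11"):
            trim_and_bin(rec)

    def test_segments_start_at_trim_boundary(self):
        x = np.arange(20_000, dtype=float)
        rec = make_recording(x)
        segs = trim_and_bin(rec)
        assert segs[0, 0, 0] == 5000.0
        assert segs.shape[1] == 10


class TestAmplitudeSpectrum:
    def test_pure_sinusoid_maps_to_peak_amplitude(self):
        t = np.arange(1000) / 1000.0
        spec = amplitude_spectrum(3.0 * np.sin(2 * np.pi * 14 * t), 1000.0)
        assert spec.amplitudes[spec.at(14.0)] == pytest.approx(3.0, abs=1e-9)
        others = np.delete(spec.amplitudes, spec.at(14.0))
        assert np.all(others <= 1e-9)

    def test_constant_signal_is_pure_dc(self):
        spec = amplitude_spectrum(np.full(1000, -2.5), 1000.0)
        assert spec.amplitudes[0] == pytest.approx(2.5)
        assert np.all(spec.amplitudes[1:] <= 1e-12)

    def test_pulse_train_matches_fourier_sum_oracle(self):
        """14-Hz train of 10-ms unit pulses: harmonics vs direct DTFT sum
        and, more loosely, the continuous pulse-train Fourier series."""
        fs, f0, width = 1000.0, 14.0, 0.010
        t = np.arange(1000) / fs
        x = ((t % (1 / f0)) < width).astype(float)
        spec = amplitude_spectrum(x, fs)
        for k in (1, 2):
            got = spec.amplitudes[spec.at(k * f0)]
            oracle = dtft_amplitude(x, k * f0, fs)
            assert got == pytest.approx(oracle, rel=1e-9)
            # continuous-time Fourier series 2*d*f0*sinc(k*d*f0); the
            # sampled staircase deviates at O((f/fs)^2)
            cont = 2 * width * f0 * abs(np.sinc(k * width * f0))
            assert got == pytest.approx(cont, rel=1e-2)

    def test_parseval_identity_on_noiseless_signals(self):
        t = np.arange(1000) / 1000.0
        x = (
            1.5
            + 3.0 * np.sin(2 * np.pi * 14 * t)
            + 1.0 * np.cos(2 * np.pi * 28 * t + 0.7)
        )
        spec = amplitude_spectrum(x, 1000.0)
        amps = spec.amplitudes
        # DC and Nyquist enter once, interior bins as A^2/2
        power = amps[0] ** 2 + amps[-1] ** 2 + np.sum(amps[1:-1] ** 2) / 2
        assert power == pytest.approx(np.mean(x**2), rel=1e-6)

    def test_phase_equivariance(self):
        t = np.arange(1000) / 1000.0
        x = np.sin(2 * np.pi * 14 * t)
        spec = amplitude_spectrum(x, 1000.0)
        scaled = amplitude_spectrum(5.0 * x, 1000.0)
        assert scaled.phases[spec.at(14.0)] == pytest.approx(
            spec.phases[spec.at(14.0)]
        )
        dt_shift = 0.003
        shifted = amplitude_spectrum(
            np.sin(2 * np.pi * 14 * (t - dt_shift)), 1000.0
        )
        dphi = shifted.phases[spec.at(14.0)] - spec.phases[spec.at(14.0)]
        expected = -2 * np.pi * 14 * dt_shift
        assert math.remainder(dphi - expected, 2 * np.pi) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_non_finite_samples_rejected(self):
        x = np.zeros(1000)
        x[3] = np.nan
        with pytest.raises(DataError, match="finite"):
            amplitude_spectrum(x, 1000.0)


def flat_spectrum(value, n=501):
    freqs = np.arange(n, dtype=float)
    return BinSpectrum(
        frequencies=freqs,
        amplitudes=np.full(n, float(value)),
        phases=np.zeros(n),
    )


class TestSNR:
    def test_side_bin_rms_of_constants(self):
        assert side_bin_noise(flat_spectrum(3.0), 14.0) == pytest.approx(3.0)

    def test_side_bin_rms_hand_value(self):
        spec = flat_spectrum(0.0)
        # four bins at 4, four at 0 -> RMS = sqrt(16*4/8) = sqrt(8)
        for f in (10, 11, 12, 13):
            spec.amplitudes[f] = 4.0
        assert side_bin_noise(spec, 14.0) == pytest.approx(math.sqrt(8))
        assert side_bin_noise(spec, 14.0, method="mean") == pytest.approx(2.0)

    def test_all_zero_side_bins(self):
        assert side_bin_noise(flat_spectrum(0.0), 14.0) == 0.0

    def test_side_bins_out_of_range_rejected(self):
        with pytest.raises(ConfigurationError, match="side bins"):
            side_bin_noise(flat_spectrum(1.0), 2.0)
        with pytest.raises(ConfigurationError, match="side bins"):
            side_bin_noise(flat_spectrum(1.0, n=18), 14.0)

    @pytest.mark.parametrize(
        "amp, noise, expected",
        [(5.0, 2.5, 2.0), (3.0, 3.0, 1.0), (0.0, 3.0, 0.0)],
    )
    def test_snr_values(self, amp, noise, expected):
        assert compute_snr(amp, noise) == expected

    def test_snr_sentinels_and_errors(self):
        assert compute_snr(1.0, 0.0) == math.inf
        assert math.isnan(compute_snr(0.0, 0.0))
        with pytest.raises(ConfigurationError):
            compute_snr(-1.0, 1.0)


class TestExtraction:
    def test_noiseless_recording_fully_retained(self, quiet_config):
        quiet_config.run_duration = 100.0
        rec = vt.generate_ssvep_recording(
            quiet_config, seed=0, electrodes=("SC_L",), meta={"rat_id": "r1"}
        )
        df = vt.extract_harmonic_samples(rec)
        assert len(df) == 90 * 2
        assert df["retained"].all()
        for k, amp in quiet_config.harmonic_amplitudes.items():
            got = df[df.harmonic == k]["amplitude_uV"]
            np.testing.assert_allclose(got, amp, rtol=1e-6)
        assert df["bin"].max() == 89  # 100 bins enumerated, 90 analysed

    def test_snr_equal_one_is_retained(self):
        df = make_sample_table(n_rats=1, n_bins=1, harmonics=(1,))
        assert df["retained"].all()
        assert (compute_snr(2.0, 2.0) >= 1.0) is True

    def test_pure_noise_retention_matches_rayleigh_oracle(self):
        """White-noise-only input: retention ~ P(Rayleigh peak >= side RMS),
        estimated by an independent Monte-Carlo on the noise model."""
        cfg = SimulationConfig(
            run_duration=110.0,
            harmonic_amplitudes={1: 0.0, 2: 0.0},
            noise_pink_scale=0.0,
            noise_white_scale=20.0,
        )
        rates = []
        for seed in (9, 10, 11):
            rec = vt.generate_ssvep_recording(
                cfg, seed=seed, electrodes=("SC_L",)
            )
            rates.append(vt.extract_harmonic_samples(rec)["retained"].mean())
        measured = float(np.mean(rates))
        rng = np.random.default_rng(123)
        draws = rng.rayleigh(1.0, size=(20_000, 9))
        oracle = np.mean(
            draws[:, 0] >= np.sqrt(np.mean(draws[:, 1:] ** 2, axis=1))
        )
        assert measured < 1.0
        assert abs(measured - oracle) < 0.1

    def test_off_grid_stimulus_frequency_rejected(self, quiet_config):
        rec = vt.generate_ssvep_recording(quiet_config, seed=0)
        rec.meta["stim_freq_hz"] = 14.5
        with pytest.raises(ConfigurationError, match="grid"):
            vt.extract_harmonic_samples(rec)

    def test_wrong_paradigm_rejected(self, quiet_config):
        rec = vt.generate_vep_trials(quiet_config, seed=0)
        with pytest.raises(DataError, match="SSVEP"):
            vt.extract_harmonic_samples(rec)


class TestFeaturePools:
    def test_full_pools_have_1170_samples(self):
        df = make_sample_table(n_rats=13, n_bins=90)
        pools = build_feature_pools(df, group="alpha_syn")
        assert len(pools) == 40
        assert all(len(p) == 1170 for p in pools.values())

    def test_exclusions_shrink_pool(self):
        df = make_sample_table(
            n_rats=1, n_bins=90, electrodes=("SC_L",), wavelengths=("red",),
            harmonics=(1,), excluded_bins=12
        )
        pools = build_feature_pools(df)
        assert len(pools[("SC_L", "red", 1)]) == 78

    def test_empty_pool_error_names_feature(self):
        df = make_sample_table(
            n_rats=1, n_bins=5, electrodes=("SC_L",), wavelengths=("red",),
            harmonics=(1,), excluded_bins=5
        )
        with pytest.raises(DataError, match="SC_L"):
            build_feature_pools(df)

    def test_mixed_weeks_rejected(self):
        df = make_sample_table(n_rats=1, n_bins=2)
        other = make_sample_table(n_rats=1, n_bins=2, week=3)
        import pandas as pd

        with pytest.raises(DataError, match="single week"):
            build_feature_pools(pd.concat([df, other]))

    def test_retained_amplitude_never_below_its_noise(self):
        cfg = SimulationConfig(run_duration=20.0)
        rec = vt.generate_ssvep_recording(cfg, seed=4, electrodes=("SC_L",))
        df = vt.extract_harmonic_samples(rec)
        assert (df.loc[df.retained, "snr"] >= 1.0).all()
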