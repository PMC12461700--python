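"""Frequency-tagging pipeline: epoching, FFT, noise correction, z-scores."""

import numpy as np
import pandas as pd
import pytest

import rhythmsync as rs
from rhythmsync.core import SAMPLE_RATE
from rhythmsync.spectral import (FREQ_RESOLUTION_HZ, PowerSpectrum,
                                 clean_taps, epoch_average, fft_power,
                                 smooth_neighbors, subtract_noise)


def flat_spectrum(value=1.0, n=601):
    freqs = np.arange(n) * FREQ_RESOLUTION_HZ
    return PowerSpectrum(freqs=freqs, power=np.full(n, value))


class TestFFTPower:
    def test_frequency_resolution_is_one_over_24s(self):
        spec = fft_power(np.random.default_rng(0).standard_normal(512))
        assert spec.freq_resolution == pytest.approx(1.0 / 24.0)
        assert np.allclose(np.diff(spec.freqs), 1.0 / 24.0)

    def test_pure_tone_lands_in_exact_bin(self):
        t = np.arange(int(24 * SAMPLE_RATE)) / SAMPLE_RATE
        spec = fft_power(np.sin(2 * np.pi * 2.5 * t))
        assert np.argmax(spec.power) == 60  # 2.5 Hz * 24 s
        others = np.delete(spec.power, 60)
        assert others.max() < 1e-6 * spec.power[60]

    def test_constant_signal_has_zero_spectrum(self):
        spec = fft_power(np.full(1000, 5.0))
        assert np.allclose(spec.power, 0.0)

    def test_parseval_identity(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(int(12 * SAMPLE_RATE))
        spec = fft_power(x)
        n = int(24 * SAMPLE_RATE)
        # rfft double-counts interior bins in the energy sum
        weights = np.full(spec.power.size, 2.0)
        weights[0] = 1.0
        weights[-1] = 1.0 if n % 2 == 0 else 2.0
        energy_spec = (weights * spec.power).sum() / n
        assert energy_spec == pytest.approx(np.sum((x - x.mean()) ** 2),
                                            rel=1e-9)

    def test_empty_signal_rejected(self):
        with pytest.raises(ValueError):
            fft_power(np.array([]))


class TestNoiseSubtraction:
    def test_flat_spectrum_goes_to_zero(self):
        out = subtract_noise(flat_spectrum(3.0))
        assert np.allclose(out.power, 0.0)

    def test_isolated_peak_preserved_neighbors_dip(self):
        spec = flat_spectrum(0.0)
        spec.power[100] = 8.0
        out = subtract_noise(spec)
        assert out.power[100] == 8.0
        assert out.power[98] == -4.0
        assert out.power[102] == -4.0

    def test_pink_background_suppressed(self):
        # the smooth 1/f background (seed-averaged spectrum) is removed
        # almost entirely; single-seed periodograms stay noisy
        spectra = [fft_power(rs.pink_noise(int(24 * SAMPLE_RATE), 1.0,
                                           seed)).power
                   for seed in range(50)]
        mean_spec = PowerSpectrum(freqs=np.arange(len(spectra[0]))
                                  * FREQ_RESOLUTION_HZ,
                                  power=np.mean(spectra, axis=0))
        corrected = subtract_noise(mean_spec)
        sel = slice(10, 200)
        assert (np.abs(corrected.power[sel]).mean()
                < 0.3 * mean_spec.power[sel].mean())

    def test_unbiased_at_frequencies_of_interest(self):
        # spec-level invariant: on pure pink noise the mean corrected
        # power at FOI bins is statistically indistinguishable from zero
        fset = rs.frequency_set(600.0)
        bins = np.round(np.array(fset.all_frequencies)
                        / FREQ_RESOLUTION_HZ).astype(int)
        means = []
        for seed in range(100):
            x = rs.pink_noise(int(24 * SAMPLE_RATE), 1.0, seed)
            corrected = subtract_noise(fft_power(x))
            means.append(corrected.power[bins].mean())
        means = np.asarray(means)
        se = means.std(ddof=1) / np.sqrt(means.size)
        assert abs(means.mean()) < 2 * se


class TestSmoothing:
    def test_flat_spectrum_unchanged(self):
        out = smooth_neighbors(flat_spectrum(2.0))
        assert np.allclose(out.power, 2.0)

    def test_isolated_peak_spread_to_third(self):
        spec = flat_spectrum(0.0)
        spec.power[50] = 9.0
        out = smooth_neighbors(spec)
        assert out.power[50] == pytest.approx(3.0)
        assert out.power[49] == pytest.approx(3.0)
        assert out.power[51] == pytest.approx(3.0)

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            smooth_neighbors(PowerSpectrum(np.arange(2.0), np.ones(2)))


class TestEpochAverage:
    def test_periodic_signal_average_equals_single_epoch(self, stimuli_full,
                                                         kernel):
        model = rs.convolve_evoked(stimuli_full.onsets[600.0], kernel)
        avg = epoch_average(model)
        # 12 s = 5 patterns = exactly 6144 samples, so the signal is
        # sample-periodic at the epoch length; any steady-state epoch
        # equals the average past the first kernel-length transient
        onset0 = model.pattern_onsets[5]
        n = int(12 * SAMPLE_RATE)
        epoch = model.values[onset0:onset0 + n]
        assert np.allclose(avg[kernel.n_lags:], epoch[kernel.n_lags:],
                           atol=1e-9)

    def test_90s_600ms_block_has_seven_epochs(self, stimuli_full):
        # 12 s is exactly 5 patterns at the 600-ms grid, so epochs tile
        # the block: floor(91.2 / 12) = 7 of them. A time ramp makes the
        # epoch count observable: the average's first sample equals the
        # mean of the 7 epoch start times 0, 12, ..., 72 s.
        block = stimuli_full.onsets[600.0]
        ramp = rs.ModelOutput(SAMPLE_RATE,
                              np.arange(block.n_samples) / SAMPLE_RATE,
                              block.pattern_onsets)
        avg = epoch_average(ramp)
        assert avg[0] == pytest.approx(np.mean(np.arange(7) * 12.0))

    def test_noise_average_shrinks_with_epoch_count(self):
        # phase-random noise: averaging n epochs shrinks amplitude ~ 1/sqrt(n)
        rng = np.random.default_rng(0)
        n_ep_short, n_ep_long = 4, 16
        ratios = []
        for _ in range(30):
            plen = int(2.4 * SAMPLE_RATE)
            n_pat = 5 * n_ep_long
            onsets = np.arange(n_pat) * plen
            sig = rng.standard_normal(n_pat * plen)
            mk = lambda k: rs.ModelOutput(
                SAMPLE_RATE, sig[: 5 * k * plen], onsets[: 5 * k])
            amp_s = np.std(epoch_average(mk(n_ep_short)))
            amp_l = np.std(epoch_average(mk(n_ep_long)))
            ratios.append(amp_s / amp_l)
        expected = np.sqrt(n_ep_long / n_ep_short)
        assert np.mean(ratios) == pytest.approx(expected, rel=0.15)

    def test_block_shorter_than_epoch_rejected(self):
        short = rs.ModelOutput(SAMPLE_RATE, np.zeros(1000), np.array([0]))
        with pytest.raises(ValueError):
            epoch_average(short)


class TestZScoreCategories:
    def test_mean_zero_sd_one_over_frequency_pool(self, stimuli_full,
                                                  evoked_outputs):
        for tempo, model in evoked_outputs.items():
            fset = stimuli_full.fsets[tempo]
            sig = model.values[int(2.4 * SAMPLE_RATE):int(26.4 * SAMPLE_RATE)]
            spec = smooth_neighbors(fft_power(sig))
            bins = np.round(np.array(fset.all_frequencies)
                            / FREQ_RESOLUTION_HZ).astype(int)
            z = (spec.power[bins] - spec.power[bins].mean()) \
                / spec.power[bins].std()
            assert z.mean() == pytest.approx(0.0, abs=1e-12)
            assert z.std() == pytest.approx(1.0)

    def test_equal_power_raises(self):
        fset = rs.frequency_set(600.0)
        with pytest.raises(ValueError):
            rs.zscore_categories(flat_spectrum(1.0), fset)

    def test_dominant_frequency_positive_others_negative(self):
        fset = rs.frequency_set(600.0)
        spec = flat_spectrum(0.0)
        grid_bin = round(fset.grid_hz / FREQ_RESOLUTION_HZ)
        spec.power[grid_bin] = 10.0
        z = rs.zscore_categories(spec, fset)
        assert z["grid"] > 0
        assert z["sub1"] < 0 and z["sub2"] < 0 and z["unrelated"] < 0


class TestTapping:
    def test_refractory_taps_removed(self):
        kept = clean_taps(np.array([0.0, 0.030, 0.600]))
        assert np.allclose(kept, [0.0, 0.600])

    def test_too_few_taps_rejected(self):
        fset = rs.frequency_set(600.0)
        with pytest.raises(ValueError):
            rs.tapping_power(np.array([0.0, 0.01]), fset)

    def test_slow_grid_tapping_peaks_at_grid(self):
        taps = rs.simulate_tapping(600.0, "grid", motor_noise_sd_ms=0.0,
                                   duration_s=30.0, seed=0)
        z = rs.tapping_power(taps, rs.frequency_set(600.0))
        assert z.idxmax() == "grid"

    def test_beat_period_tapping_under_fast_grid_maps_to_sub2(self):
        # 600-ms tap period in the 150-ms condition = second subharmonic
        taps = rs.simulate_tapping(150.0, "sub2", motor_noise_sd_ms=0.0,
                                   duration_s=30.0, seed=0)
        z = rs.tapping_power(taps, rs.frequency_set(150.0))
        assert z[["grid", "sub1", "sub2"]].idxmax() == "sub2"

    @pytest.mark.parametrize("tempo", rs.GRID_INTERVALS_MS)
    @pytest.mark.parametrize("level", ["grid", "sub1", "sub2"])
    def test_recovers_generated_metrical_level(self, tempo, level):
        taps = rs.simulate_tapping(tempo, level, motor_noise_sd_ms=20.0,
                                   duration_s=30.0, seed=7)
        z = rs.tapping_power(taps, rs.frequency_set(tempo))
        assert z[["grid", "sub1", "sub2"]].idxmax() == level


class TestModelPower:
    def test_analysis_window_is_24s(self):
        assert rs.spectral.MODEL_WINDOW_S == (2.4, 26.4)
        assert (26.4 - 2.4) == pytest.approx(rs.spectral.FFT_LEN_S)

    def test_short_block_rejected(self, kernel):
        onsets = rs.make_block(rs.RhythmSpec(600.0, n_repetitions=5))
        model = rs.convolve_evoked(onsets, kernel)
        fset = rs.frequency_set(600.0)
        with pytest.raises(ValueError):
            rs.model_power(model, fset)

    def test_evoked_tempo_shift(self, evoked_power_table):
        piv = evoked_power_table.pivot(index="tempo_ms", columns="category",
                                       values="z")
        related = ["grid", "sub1", "sub2"]
        assert piv.loc[600.0, related].idxmax() == "grid"
        assert piv.loc[150.0, related].idxmax() in ("sub1", "sub2")
        # grid dominance decreases monotonically in rank toward fast tempi
        assert piv.loc[600.0, "grid"] > piv.loc[600.0, "sub2"]
        assert piv.loc[150.0, "sub2"] > piv.loc[150.0, "grid"]


class TestPipelineClosure:
    def test_noiseless_evoked_eeg_reproduces_model_table(self, stimuli_full,
                                                         kernel):
        # EEG generated exactly as onsets (*) kernel: the EEG branch
        # (12-s averaged epochs, zero-padded FFT, background subtraction)
        # reproduces the model branch (24-s window) up to spectral
        # leakage of the half-length padding
        for tempo in (150.0, 400.0, 600.0):
            onsets = stimuli_full.onsets[tempo]
            eeg = rs.simulate_eeg(onsets, rs.SimParams(kernel=kernel))
            z_eeg = rs.eeg_power(eeg, stimuli_full.fsets[tempo])
            model = rs.convolve_evoked(onsets, kernel)
            z_model = rs.model_power(model, stimuli_full.fsets[tempo])
            assert np.abs(z_eeg - z_model).max() < 0.05

    def test_oscillatory_component_raises_power_at_its_frequency(
            self, stimuli_full, kernel):
        onsets = stimuli_full.onsets[600.0]
        fset = stimuli_full.fsets[600.0]
        base = rs.SimParams(kernel=kernel, noise_amp=0.5, seed=11)
        with_osc = rs.SimParams(kernel=kernel, noise_amp=0.5, seed=11,
                                osc_freq=fset.grid_hz, osc_amp=1.0)
        z0 = rs.eeg_power(rs.simulate_eeg(onsets, base), fset)
        z1 = rs.eeg_power(rs.simulate_eeg(onsets, with_osc), fset)
        assert z1["grid"] > z0["grid"]
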