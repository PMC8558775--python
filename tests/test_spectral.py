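import math

import numpy as np
import pytest

from pupvox.audio import CallAnnotation, CallClip, Waveform
from pupvox.calibration import spl_to_rms
from pupvox.spectral import (
    DiscardReason,
    NoiseProfile,
    apply_gain_compensation,
    average_power_spectrum,
    call_intensity,
    call_tilt_measures,
    estimate_session_gain,
    octave_slope,
    r14,
    spectral_subtract,
    third_octave_centers,
    third_octave_energies,
)
from pupvox.synth import (
    SynthCallParams,
    assemble_session,
    make_session_design,
    schedule_calls,
    synth_call,
    synth_noise,
)


def _clip(x, noise, fs=16000.0):
    ann = CallAnnotation(
        session_id="S0", seal_id="a", condition="high",
        trial_index=0, onset_s=0.0, offset_s=len(x) / fs,
    )
    return CallClip(ann, Waveform(x, fs), Waveform(noise, fs))


class TestAveragePowerSpectrum:
    def test_zeros(self, fs):
        s = average_power_spectrum(Waveform(np.zeros(2048), fs))
        assert np.all(s.power == 0)

    def test_too_short_raises(self, fs):
        with pytest.raises(ValueError):
            average_power_spectrum(Waveform(np.zeros(100), fs))

    def test_sine_at_bin_center_concentrates(self, fs):
        # bin spacing fs/512 = 31.25 Hz; 1000 Hz = bin 32 exactly
        t = np.arange(int(fs)) / fs
        s = average_power_spectrum(Waveform(0.2 * np.sin(2 * np.pi * 1000 * t), fs))
        peak = int(np.argmax(s.power))
        assert s.freqs[peak] == pytest.approx(1000.0)
        assert s.power[peak - 1 : peak + 2].sum() / s.power.sum() >= 0.95

    def test_parseval_normalization(self, fs, rng):
        x = rng.standard_normal(8192)
        s = average_power_spectrum(Waveform(x, fs))
        win = np.hamming(512)
        frames = np.stack(
            [x[i : i + 512] for i in range(0, len(x) - 512 + 1, 256)]
        )
        direct = np.mean(
            np.sum((frames * win) ** 2, axis=1) / np.sum(win**2)
        )
        assert s.power.sum() == pytest.approx(direct, rel=1e-6)


class TestSessionGain:
    def test_identity_when_session_is_reference(self, cal, fs, small_session):
        design, _, _, annots, noise = small_session
        g = estimate_session_gain(
            noise, annots, design.block_bounds(),
            [c for c, _ in design.blocks], noise,
        )
        assert g == pytest.approx(1.0)

    def test_amplitude_doubling_gives_power_four(self, cal, fs, small_session):
        design, _, session, annots, noise = small_session
        doubled = Waveform(noise.samples * 2.0, fs)
        g = estimate_session_gain(
            doubled, annots, design.block_bounds(),
            [c for c, _ in design.blocks], noise,
        )
        assert g == pytest.approx(4.0)
        comp = apply_gain_compensation(doubled, g)
        np.testing.assert_allclose(comp.samples, noise.samples)

    def test_low_and_high_blocks_agree(self, cal, fs, small_session):
        # both noisy conditions share one true preamp factor by construction
        design, _, session, annots, noise = small_session
        scaled = Waveform(session.samples * 1.3, fs)
        args = (annots, design.block_bounds(), [c for c, _ in design.blocks], noise)
        g_low = estimate_session_gain(scaled, *args, conditions=("low",))
        g_high = estimate_session_gain(scaled, *args, conditions=("high",))
        assert g_low / g_high == pytest.approx(1.0, rel=0.05)

    def test_no_nonvocal_audio_raises(self, cal, fs, small_session):
        design, _, session, annots, noise = small_session
        wall_to_wall = [
            CallAnnotation(
                session_id="S0", seal_id="a", condition="high", trial_index=0,
                onset_s=0.0, offset_s=session.duration,
            )
        ]
        with pytest.raises(ValueError):
            estimate_session_gain(
                session, wall_to_wall, design.block_bounds(),
                [c for c, _ in design.blocks], noise,
            )


class TestSpectralSubtraction:
    def test_call_equals_noise_gives_zero(self, fs, rng):
        x = rng.standard_normal(4096)
        s = average_power_spectrum(Waveform(x, fs))
        d = spectral_subtract(s, s)
        np.testing.assert_allclose(d.power, 0.0, atol=1e-20)

    def test_zero_noise_is_identity(self, fs, rng):
        x = rng.standard_normal(4096)
        s = average_power_spectrum(Waveform(x, fs))
        z = average_power_spectrum(Waveform(np.zeros(4096), fs))
        np.testing.assert_array_equal(spectral_subtract(s, z).power, s.power)

    def test_shape_mismatch_raises(self, fs, rng):
        x = rng.standard_normal(4096)
        a = average_power_spectrum(Waveform(x, fs))
        b = average_power_spectrum(Waveform(x, fs), n_fft=256, hop=128)
        with pytest.raises(ValueError):
            spectral_subtract(a, b)

    def test_mean_recovery_under_independent_noise(self, cal, fs):
        # the expectation of subtracted spectra equals the clean spectrum
        params = SynthCallParams()
        bands = [(400.0, 1000.0), (1000.0, 2000.0), (2000.0, 4000.0)]
        clean_e = np.zeros(len(bands))
        sub_e = np.zeros(len(bands))
        n = 200
        for i in range(n):
            w, truth = synth_call(params, "high", cal, fs, 4000 + i)
            noise = synth_noise(
                "high", truth.duration_s + 0.05, fs, cal, 6000 + i
            ).samples[: len(w.samples)]
            other = synth_noise(
                "high", truth.duration_s + 0.05, fs, cal, 8000 + i
            ).samples[: len(w.samples)]
            cs = average_power_spectrum(Waveform(w.samples + noise, fs))
            ns = average_power_spectrum(Waveform(other, fs))
            d = spectral_subtract(cs, ns)
            clean = average_power_spectrum(w)
            for j, (lo, hi) in enumerate(bands):
                clean_e[j] += clean.band_energy(lo, hi)
                sub_e[j] += d.band_energy(lo, hi)
        rel = np.abs(sub_e - clean_e) / clean_e
        assert np.all(rel < 0.10)


class TestIntensity:
    def test_noise_only_centered_on_zero(self, cal, fs):
        vals = []
        for seed in range(30):
            a = synth_noise("high", 0.8, fs, cal, seed).samples
            b = synth_noise("high", 0.8, fs, cal, 1000 + seed).samples
            vals.append(call_intensity(_clip(a, b)).call_intensity)
        p_noise = spl_to_rms(65.0, cal) ** 2
        assert abs(np.mean(vals)) < 0.2 * p_noise

    def test_clean_call_zero_noise_exact(self, cal, fs, default_params):
        w, _ = synth_call(default_params, "high", cal, fs, 9)
        res = call_intensity(_clip(w.samples, np.zeros_like(w.samples)))
        assert res.call_intensity == pytest.approx(np.mean(w.samples**2))
        assert not res.snr_defined  # zero noise power -> snr undefined guard

    def test_snr_of_75db_call_over_65db_noise(self, cal, fs, default_params):
        snrs = []
        for seed in range(25):
            w, truth = synth_call(default_params, "high", cal, fs, 200 + seed)
            noise = synth_noise(
                "high", truth.duration_s + 0.05, fs, cal, 400 + seed
            ).samples[: len(w.samples)]
            res = call_intensity(_clip(w.samples + noise, noise))
            snrs.append(res.snr_db)
        assert np.mean(snrs) == pytest.approx(10.0, abs=0.5)


class TestThirdOctave:
    def _flat(self, fs=16000.0):
        from pupvox.spectral import PowerSpectrum

        return PowerSpectrum(
            freqs=np.fft.rfftfreq(512, 1 / fs),
            power=np.ones(257),
            n_fft=512, hop=256, sample_rate=fs, n_frames=1,
        )

    def test_centers_include_1khz_and_start_at_500(self):
        c = third_octave_centers(400.0, 8000.0)
        assert 1000.0 in c
        assert c[0] == pytest.approx(500.0, rel=1e-6)
        # the 397 Hz and 315 Hz centers fall at or below the 400 Hz cut
        assert np.all(c > 400.0)

    def test_flat_spectrum_energy_tracks_bandwidth(self, fs):
        s = self._flat()
        centers, energies = third_octave_energies(s)
        # bandwidth doubles per octave: energies three bands apart double
        # (skip the lowest band, which holds only 3 of the 31.25 Hz bins and
        # is dominated by bin quantization)
        for i in range(1, len(centers) - 3):
            assert energies[i + 3] / energies[i] == pytest.approx(2.0, rel=0.15)

    def test_halving_energies_slope(self):
        centers = 1000.0 * 2.0 ** (np.arange(6) / 3.0)
        energies = 2.0 ** -np.arange(6)
        slope, n_pos, reason = octave_slope(centers, energies)
        # closed form: -3.0103 dB per band step, 3 steps per octave
        assert slope == pytest.approx(-30.0 * math.log10(2.0), abs=1e-9)
        assert n_pos == 6 and reason is DiscardReason.NONE

    def test_flat_energies_zero_slope(self):
        centers = 1000.0 * 2.0 ** (np.arange(5) / 3.0)
        slope, _, _ = octave_slope(centers, np.ones(5))
        assert slope == pytest.approx(0.0, abs=1e-12)

    def test_single_positive_band_undefined(self):
        centers = 1000.0 * 2.0 ** (np.arange(3) / 3.0)
        slope, n_pos, reason = octave_slope(
            centers, np.array([1.0, -0.5, -0.2])
        )
        assert math.isnan(slope)
        assert reason is DiscardReason.TOO_FEW_POSITIVE_BANDS


class TestR14:
    def _spectrum(self, power, fs=16000.0):
        from pupvox.spectral import PowerSpectrum

        return PowerSpectrum(
            freqs=np.fft.rfftfreq(512, 1 / fs), power=power,
            n_fft=512, hop=256, sample_rate=fs, n_frames=1,
        )

    def test_flat_spectrum_bandwidth_ratio(self):
        s = self._spectrum(np.ones(257))
        val, reason = r14(s)
        # continuum value -6.99 dB; 31.25 Hz bin edges shift it slightly
        assert val == pytest.approx(10 * math.log10(600 / 3000), abs=0.25)
        assert reason is DiscardReason.NONE

    def test_no_high_band_energy_undefined(self, fs):
        power = np.zeros(257)
        freqs = np.fft.rfftfreq(512, 1 / fs)
        power[np.abs(freqs - 500.0) < 40] = 1.0
        val, reason = r14(self._spectrum(power))
        assert math.isnan(val)
        assert reason is DiscardReason.NONPOSITIVE_BAND_ENERGY

    def test_boosting_high_band_lowers_r14(self, fs):
        freqs = np.fft.rfftfreq(512, 1 / fs)
        vals = []
        for boost in (1.0, 2.0, 4.0):
            power = np.ones(257)
            power[(freqs > 1000) & (freqs <= 4000)] *= boost
            vals.append(r14(self._spectrum(power))[0])
        assert vals[0] > vals[1] > vals[2]


class TestGainEquivariance:
    def test_features_invariant_to_recording_scale(self, cal, fs, small_session):
        design, _, session, annots, noise = small_session
        results = []
        for c in (1.0, 3.7):
            scaled = Waveform(session.samples * c, fs)
            gain = estimate_session_gain(
                scaled, annots, design.block_bounds(),
                [cc for cc, _ in design.blocks], noise,
            )
            comp = apply_gain_compensation(scaled, gain)
            feats = []
            for a in annots[:5]:
                clip = CallClip(
                    a,
                    comp.slice_seconds(a.onset_s, a.offset_s),
                    noise.slice_seconds(a.onset_s, a.offset_s),
                )
                res = call_intensity(clip)
                tm = call_tilt_measures(clip)
                feats.append(
                    (res.call_intensity, tm.octave_slope_db_per_oct, tm.r14_db)
                )
            results.append(np.array(feats))
        np.testing.assert_allclose(results[0], results[1], rtol=1e-6)
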