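"""Stimulus synthesis: noise, Huggins pairs, AP and BT trials, ramps, pools."""

import dataclasses

import numpy as np
import pytest

from dichotic import (
    APConfig,
    BTConfig,
    HPConfig,
    StereoWaveform,
    apply_ramp,
    build_trial_pool,
    generate_white_noise,
    make_ap_trial,
    make_bt_trial,
    make_example_trial,
    make_hp_trial,
    make_huggins_pair,
)
from dichotic.stimuli import RMS_REFERENCE, raised_cosine_envelope


class TestWhiteNoise:
    def test_length_matches_duration(self):
        assert generate_white_noise(1.0, 44100, seed=1).size == 44100
        assert generate_white_noise(0.25, 8000, seed=1).size == 2000

    def test_deterministic_given_seed(self):
        a = generate_white_noise(0.5, 44100, seed=7)
        b = generate_white_noise(0.5, 44100, seed=7)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, generate_white_noise(0.5, 44100, seed=8))

    def test_normalised_rms(self):
        x = generate_white_noise(1.0, 44100, seed=3)
        assert np.sqrt(np.mean(x ** 2)) == pytest.approx(RMS_REFERENCE, rel=1e-12)

    def test_flat_spectrum(self):
        # Averaged periodogram over 200 seeds: power below 5 kHz matches
        # power in 5-10 kHz within 5% for spectrally flat noise.
        rate, n = 44100, 44100
        freqs = np.fft.rfftfreq(n, 1 / rate)
        accum = np.zeros(freqs.size)
        for seed in range(200):
            accum += np.abs(np.fft.rfft(generate_white_noise(1.0, rate, seed))) ** 2
        low = accum[(freqs > 0) & (freqs < 5000)].mean()
        high = accum[(freqs >= 5000) & (freqs < 10000)].mean()
        assert low == pytest.approx(high, rel=0.05)

    @pytest.mark.parametrize("duration,rate", [(0.0, 44100), (-1.0, 44100), (1.0, 0)])
    def test_invalid_parameters(self, duration, rate):
        with pytest.raises(ValueError):
            generate_white_noise(duration, rate, seed=0)


@pytest.fixture(scope="module")
def pair(hp_cfg):
    noise = generate_white_noise(1.0, hp_cfg.rate, seed=11)
    return make_huggins_pair(noise, hp_cfg)


@pytest.fixture(scope="module")
def ap_trial(ap_cfg):
    return make_ap_trial(ap_cfg, target_position=2, seed=0)


class TestHugginsPair:
    def test_band_span_covers_564_to_636(self, hp_cfg):
        assert hp_cfg.band_lo_hz == pytest.approx(564.0)
        assert hp_cfg.band_hi_hz == pytest.approx(636.0)

    def test_in_band_bins_inverted_out_of_band_identical(self, pair, hp_cfg):
        left = np.fft.rfft(pair.left)
        right = np.fft.rfft(pair.right)
        freqs = np.fft.rfftfreq(pair.n_samples, 1 / hp_cfg.rate)
        band = (freqs >= hp_cfg.band_lo_hz) & (freqs <= hp_cfg.band_hi_hz)
        scale = np.abs(left).max()
        assert np.allclose(right[band], -left[band], atol=1e-9 * scale)
        assert np.allclose(right[~band], left[~band], atol=1e-9 * scale)

    def test_magnitude_spectra_equal_everywhere(self, pair):
        mag_l = np.abs(np.fft.rfft(pair.left))
        mag_r = np.abs(np.fft.rfft(pair.right))
        assert np.allclose(mag_r, mag_l, rtol=1e-9, atol=1e-9 * mag_l.max())

    def test_zero_band_fraction_is_noop(self):
        cfg = HPConfig(band_fraction=0.0)
        noise = generate_white_noise(1.0, cfg.rate, seed=2)
        pair = make_huggins_pair(noise, cfg)
        assert np.array_equal(pair.left, pair.right)

    def test_summed_channels_show_antiphase_notch(self, pair, hp_cfg):
        # In the shifted band left + right cancels; outside it they add
        # coherently, quadrupling power.
        left = np.fft.rfft(pair.left)
        total = np.fft.rfft(pair.left + pair.right)
        freqs = np.fft.rfftfreq(pair.n_samples, 1 / hp_cfg.rate)
        band = (freqs >= hp_cfg.band_lo_hz) & (freqs <= hp_cfg.band_hi_hz)
        in_band_sum = np.sum(np.abs(total[band]) ** 2)
        in_band_left = np.sum(np.abs(left[band]) ** 2)
        assert in_band_sum < 1e-6 * in_band_left
        out_sum = np.sum(np.abs(total[~band]) ** 2)
        out_left = np.sum(np.abs(left[~band]) ** 2)
        assert out_sum == pytest.approx(4.0 * out_left, rel=1e-9)

    def test_band_beyond_nyquist_rejected(self):
        with pytest.raises(ValueError):
            HPConfig(center_hz=21000.0, band_fraction=0.06)


class TestHPTrial:
    def test_only_target_interval_is_dichotic(self, hp_cfg):
        trial = make_hp_trial(hp_cfg, target_position=2, seed=0)
        for pos, w in enumerate(trial.intervals, start=1):
            if pos == 2:
                assert not np.array_equal(w.left, w.right)
            else:
                assert w.is_diotic()

    def test_exactly_one_interval_carries_interaural_energy(self, hp_cfg):
        trial = make_hp_trial(hp_cfg, target_position=3, seed=5)
        energies = [np.sum((w.left - w.right) ** 2) for w in trial.intervals]
        assert sum(e > 0 for e in energies) == 1
        assert int(np.argmax(energies)) + 1 == 3

    def test_interval_duration_one_second(self, hp_cfg):
        trial = make_hp_trial(hp_cfg, target_position=1, seed=0)
        assert all(w.n_samples == round(hp_cfg.duration_s * hp_cfg.rate)
                   for w in trial.intervals)

    def test_invalid_target_position(self, hp_cfg):
        with pytest.raises(ValueError):
            make_hp_trial(hp_cfg, target_position=4, seed=0)


class TestAPTrial:
    def _parts(self, trial):
        foil_pos = trial.metadata["foil_position"]
        target = trial.intervals[trial.target_position - 1]
        foil = trial.intervals[foil_pos - 1]
        (standard,) = [w for i, w in enumerate(trial.intervals, start=1)
                       if i not in (trial.target_position, foil_pos)]
        return standard, target, foil

    def test_target_is_6_db_below_standard(self, ap_trial):
        standard, target, _ = self._parts(ap_trial)
        ratio = (np.sqrt(np.mean(target.left ** 2))
                 / np.sqrt(np.mean(standard.left ** 2)))
        assert ratio == pytest.approx(10 ** (-6 / 20), rel=1e-9)

    def test_foil_is_exactly_antiphase(self, ap_trial):
        _, _, foil = self._parts(ap_trial)
        assert np.array_equal(foil.left + foil.right, np.zeros(foil.n_samples))

    def test_foil_amplitude_matches_standard(self, ap_trial):
        standard, _, foil = self._parts(ap_trial)
        std_rms = np.sqrt(np.mean(standard.left ** 2))
        for chan in (foil.left, foil.right):
            assert np.sqrt(np.mean(chan ** 2)) == pytest.approx(std_rms, rel=1e-9)

    def test_target_and_standard_are_diotic(self, ap_trial):
        standard, target, _ = self._parts(ap_trial)
        assert standard.is_diotic() and target.is_diotic()

    def test_foil_slot_randomised_across_seeds(self, ap_cfg):
        slots = {make_ap_trial(ap_cfg, 2, seed=s).metadata["foil_position"]
                 for s in range(20)}
        assert slots == {1, 3}

    def test_zero_target_level_rejected(self):
        with pytest.raises(ValueError):
            APConfig(target_level_db=0.0)


class TestBTTrial:
    def test_tone_separation_is_beat_rate(self, bt_cfg):
        # The dichotic target carries f1 in one ear, f1 + 30 Hz in the other.
        for seed in range(5):
            trial = make_bt_trial(bt_cfg, target_position=1, seed=seed)
            f1 = trial.metadata["f1_hz"]
            assert bt_cfg.f1_min_hz <= f1 <= bt_cfg.f1_max_hz
            target = trial.intervals[0]
            peaks = []
            for chan in (target.left, target.right):
                spec = np.abs(np.fft.rfft(chan))
                freqs = np.fft.rfftfreq(chan.size, 1 / bt_cfg.rate)
                peaks.append(freqs[np.argmax(spec)])
            assert abs(abs(peaks[1] - peaks[0]) - bt_cfg.beat_hz) < 1.5

    def test_rove_bounds_pairwise_level_differences(self, bt_cfg):
        for seed in range(10):
            trial = make_bt_trial(bt_cfg, target_position=2, seed=seed)
            levels = [20 * np.log10(np.sqrt(np.mean(w.left ** 2)))
                      for w in trial.intervals]
            assert max(levels) - min(levels) <= bt_cfg.rove_db_max + 1e-9

    def test_standard_beats_and_target_is_smooth(self, bt_cfg):
        from scipy.signal import hilbert

        trial = make_bt_trial(bt_cfg, target_position=3, seed=1)
        trim = round(bt_cfg.ramp_s * bt_cfg.rate)
        period = bt_cfg.rate / bt_cfg.beat_hz

        def depth(x):
            env = np.abs(hilbert(x))[trim:-trim]
            env = env[: int(env.size // period * period)]
            t = np.arange(env.size) / bt_cfg.rate
            comp = np.mean(env * np.exp(-2j * np.pi * bt_cfg.beat_hz * t))
            return 2 * np.abs(comp) / np.mean(env)

        standard = trial.intervals[0]
        # The diotic pair's envelope modulates strongly at the beat rate ...
        assert depth(standard.left) > 0.5
        env = np.abs(hilbert(standard.left))[trim:-trim]
        t = np.arange(env.size) / bt_cfg.rate
        probe = np.array([
            2 * abs(np.mean((env - env.mean()) * np.exp(-2j * np.pi * f * t)))
            for f in (10.0, 20.0, 30.0, 40.0, 50.0)
        ])
        assert np.argmax(probe) == 2  # strongest modulation at 30 Hz
        # ... while each single-tone target channel is essentially flat.
        target = trial.intervals[2]
        assert depth(target.left) < 0.01
        assert depth(target.right) < 0.01

    def test_target_channels_carry_one_tone_each(self, bt_cfg):
        trial = make_bt_trial(bt_cfg, target_position=1, seed=4)
        target = trial.intervals[0]
        assert not np.array_equal(target.left, target.right)
        for w in trial.intervals[1:]:
            assert w.is_diotic()


class TestRamp:
    def test_endpoints_and_midpoint(self):
        env = raised_cosine_envelope(44100, 4410)
        assert env[0] == 0.0 and env[-1] == 0.0
        mid = env[: 4410][round(4410 / 2)]
        assert mid == pytest.approx(0.5, abs=1.0 / 4410)

    def test_100ms_ramp_spans_4410_samples(self):
        env = raised_cosine_envelope(44100, round(0.1 * 44100))
        assert np.all(env[:4410] <= 1.0)
        assert np.all(env[4410:-4410] == 1.0)  # interior unmodified

    def test_stereo_ramp_preserves_diotic_identity(self):
        mono = generate_white_noise(0.2, 44100, seed=1)
        ramped = apply_ramp(StereoWaveform.diotic(mono, 44100), 0.01)
        assert ramped.is_diotic()
        assert ramped.left[0] == 0.0 and ramped.left[-1] == 0.0

    def test_overlong_ramp_rejected(self):
        with pytest.raises(ValueError):
            apply_ramp(np.ones(100), ramp_s=0.6, rate=100)

    def test_zero_ramp_is_noop(self):
        x = generate_white_noise(0.1, 44100, seed=2)
        assert np.array_equal(apply_ramp(x, 0.0, 44100), x)


class TestExampleTrials:
    @pytest.mark.parametrize("kind", ["HP", "AP", "BT"])
    def test_examples_are_fully_diotic(self, kind):
        trial = make_example_trial(kind, seed=0)
        assert all(w.is_diotic() for w in trial.intervals)

    def test_hp_example_has_tone_peak_in_target(self, hp_cfg):
        trial = make_example_trial("HP", hp_cfg, target_position=2, seed=0)
        spec = np.abs(np.fft.rfft(trial.intervals[1].left)) ** 2
        freqs = np.fft.rfftfreq(trial.intervals[1].n_samples, 1 / hp_cfg.rate)
        tone_bin = np.argmin(np.abs(freqs - hp_cfg.center_hz))
        noise_floor = np.median(spec[freqs < 5000])
        assert spec[tone_bin] > 100 * noise_floor

    def test_ap_example_target_is_softer(self, ap_cfg):
        trial = make_example_trial("AP", ap_cfg, target_position=3)
        rms = [np.sqrt(np.mean(w.left ** 2)) for w in trial.intervals]
        assert rms[2] == pytest.approx(rms[0] * 10 ** (ap_cfg.target_level_db / 20),
                                       rel=1e-9)
        assert rms[0] == pytest.approx(rms[1], rel=1e-9)


class TestTrialPool:
    @pytest.mark.parametrize("kind", ["HP", "AP", "BT"])
    def test_pool_size_and_position_balance(self, kind):
        pool = build_trial_pool(kind, seed=3)
        assert len(pool) == 12
        positions = [t.target_position for t in pool.trials]
        assert sorted(positions).count(1) == 4
        assert sorted(positions).count(2) == 4
        assert sorted(positions).count(3) == 4

    def test_pool_reproducible_byte_for_byte(self, hp_cfg):
        a = build_trial_pool("HP", hp_cfg, seed=9)
        b = build_trial_pool("HP", hp_cfg, seed=9)
        for ta, tb in zip(a.trials, b.trials):
            assert ta.target_position == tb.target_position
            for wa, wb in zip(ta.intervals, tb.intervals):
                assert np.array_equal(wa.left, wb.left)
                assert np.array_equal(wa.right, wb.right)

    def test_different_seeds_share_no_noise_segment(self, hp_cfg):
        a = build_trial_pool("HP", hp_cfg, seed=1)
        b = build_trial_pool("HP", hp_cfg, seed=2)
        for ta in a.trials:
            for tb in b.trials:
                for wa, wb in zip(ta.intervals, tb.intervals):
                    assert not np.array_equal(wa.left, wb.left)

    def test_noise_differs_across_trials_within_pool(self, hp_cfg):
        pool = build_trial_pool("HP", hp_cfg, seed=4)
        firsts = [t.intervals[0].left[:64].tobytes() for t in pool.trials]
        assert len(set(firsts)) == 12
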