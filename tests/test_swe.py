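import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from slocad.io import EegRecording, Hypnogram
from slocad.swe import (SweDetector, bandpass_slow, compute_involvement,
                        compute_slopes, detect_half_waves, detect_swes,
                        negative_envelope, synchronization_score)

from conftest import make_envelope


def sine_recording(freq, sfreq=200.0, duration=10.0, amp=10.0, n_channels=4):
    t = np.arange(int(duration * sfreq)) / sfreq
    return EegRecording(data=np.tile(amp * np.sin(2 * np.pi * freq * t),
                                     (n_channels, 1)), sfreq=sfreq)


class TestBandpassSlow:
    def test_in_band_passthrough(self):
        rec = bandpass_slow(sine_recording(1.0))
        mid = rec.data[0, 400:1600]
        assert np.abs(mid).max() == pytest.approx(10.0, rel=0.05)

    def test_stop_band_attenuation(self):
        rec = bandpass_slow(sine_recording(30.0))
        # steady state away from the filtfilt edge transients
        assert np.abs(rec.data[0, 400:1600]).max() < 1.0  # > 90% attenuation

    def test_zero_in_zero_out(self):
        rec = EegRecording(data=np.zeros((4, 1000)), sfreq=200.0)
        assert np.allclose(bandpass_slow(rec).data, 0)

    def test_low_sampling_rate_rejected(self):
        rec = EegRecording(data=np.zeros((4, 100)), sfreq=6.0)
        with pytest.raises(ValueError, match="too low"):
            bandpass_slow(rec)


class TestNegativeEnvelope:
    def test_hand_example_drop_min_average_next_three(self):
        # mirrored sample pair keeps the series zero-mean, so centering
        # leaves the hand-computed value intact
        data = np.array([[-10.0, 10.0], [-8.0, 8.0], [-6.0, 6.0],
                         [-5.0, 5.0], [3.0, -3.0]])
        env = negative_envelope(EegRecording(data=data, sfreq=200.0))
        assert env.values[0] == pytest.approx((-8 - 6 - 5) / 3)

    def test_identical_channels_give_the_signal_back(self):
        t = np.arange(1000) / 200.0
        s = np.sin(2 * np.pi * 1.0 * t)
        rec = EegRecording(data=np.tile(s, (5, 1)), sfreq=200.0)
        env = negative_envelope(rec)
        np.testing.assert_allclose(env.values, s - s.mean(), atol=1e-12)

    def test_output_is_centered(self):
        rng = np.random.default_rng(0)
        rec = EegRecording(data=rng.normal(size=(6, 500)), sfreq=200.0)
        assert abs(negative_envelope(rec).values.mean()) < 1e-9

    def test_requires_four_channels(self):
        rec = EegRecording(data=np.zeros((3, 100)), sfreq=200.0)
        with pytest.raises(ValueError, match="4 channels"):
            negative_envelope(rec)

    @settings(derandomize=True, max_examples=50)
    @given(hnp.arrays(np.float64, (6, 100),
                      elements=st.floats(-50, 50, allow_nan=False)))
    def test_matches_bruteforce_loop(self, data):
        rec = EegRecording(data=data, sfreq=100.0)
        env = negative_envelope(rec)
        brute = np.array([np.mean(sorted(data[:, i])[1:4])
                          for i in range(data.shape[1])])
        np.testing.assert_allclose(env.values, brute - brute.mean(),
                                   atol=1e-9)


class TestDetectHalfWaves:
    def test_analytic_half_wave(self):
        sf = 200.0
        t = np.arange(0, 0.5 + 1 / sf, 1 / sf)
        wave = -20.0 * np.sin(2 * np.pi * 1.0 * t)
        env, offset = make_envelope(wave, sfreq=sf)
        [hw] = detect_half_waves(env)
        assert hw.onset == pytest.approx(offset, abs=1 / sf)
        assert hw.neg_peak_time - hw.onset == pytest.approx(0.25, abs=2 / sf)
        assert hw.offset - hw.onset == pytest.approx(0.5, abs=2 / sf)
        assert hw.neg_peak_amp == pytest.approx(-20.0, abs=0.1)

    @pytest.mark.parametrize("amp, dur, n_expected", [
        (-20.0, 0.5, 1),
        (-4.0, 0.5, 0),    # trough above the -5 uV threshold
        (-20.0, 1.2, 0),   # longer than the 1 s bound
        (-20.0, 0.2, 0),   # shorter than the 0.25 s bound
        (-20.0, 1.0, 1),   # duration bounds are inclusive
        (-5.0, 0.5, 1),    # amplitude threshold is inclusive
    ])
    def test_duration_and_amplitude_criteria(self, amp, dur, n_expected):
        sf = 200.0
        t = np.arange(0, dur + 1 / sf, 1 / sf)
        wave = amp * np.sin(np.pi * t / dur)
        wave[np.abs(wave) < 1e-9] = 0.0  # exact zero crossings at the ends
        env, _ = make_envelope(wave, sfreq=sf)
        assert len(detect_half_waves(env)) == n_expected


class TestSlopes:
    def test_hand_gradients(self):
        assert compute_slopes(0.0, 0.25, 0.5, -20.0) == (80.0, 80.0)
        neg, _ = compute_slopes(0.0, 0.1, 0.5, -20.0)
        assert neg == pytest.approx(200.0)

    def test_linearity_in_amplitude(self):
        a = compute_slopes(0.0, 0.25, 0.5, -20.0)
        b = compute_slopes(0.0, 0.25, 0.5, -40.0)
        assert b[0] == 2 * a[0] and b[1] == 2 * a[1]

    def test_zero_length_limb_rejected(self):
        with pytest.raises(ValueError, match="zero-length"):
            compute_slopes(0.0, 0.0, 0.5, -20.0)


class TestInvolvement:
    def test_hand_count(self):
        data = np.vstack([np.full((4, 200), -10.0), np.zeros((6, 200))])
        rec = EegRecording(data=data, sfreq=200.0)
        assert compute_involvement(0.5, rec) == pytest.approx(40.0)

    def test_extremes(self):
        deep = EegRecording(data=np.full((5, 200), -50.0), sfreq=200.0)
        flat = EegRecording(data=np.full((5, 200), -5.0), sfreq=200.0)
        assert compute_involvement(0.5, deep) == 100.0
        assert compute_involvement(0.5, flat) == 0.0  # strict "below -5"

    def test_edge_window_truncates_with_warning(self):
        rec = EegRecording(data=np.full((5, 100), -10.0), sfreq=200.0)
        with pytest.warns(UserWarning, match="truncated"):
            assert compute_involvement(0.0, rec) == 100.0


class TestSynchronizationScore:
    def test_worked_example(self):
        assert synchronization_score(50.0, 200.0, 300.0) == pytest.approx(12.5)

    def test_annihilator_and_homogeneity(self):
        assert synchronization_score(0.0, 300.0, 200.0) == 0.0
        base = synchronization_score(40.0, 100.0, 150.0)
        assert synchronization_score(40.0, 200.0, 300.0) == pytest.approx(
            2 * base)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            synchronization_score(-1.0, 100.0, 100.0)


class TestDetectSwes:
    def test_recovery_of_implanted_events(self, implanted_swe_recording):
        rec, gt = implanted_swe_recording
        events = detect_swes(rec)
        matched = 0
        for onset in gt.swe_events["onset"]:
            if np.abs(events["onset"] - onset).min() < 0.1:
                matched += 1
        assert matched >= 18
        assert (events["neg_peak_amp"] <= -5).all()
        assert events["onset"].is_monotonic_increasing

    def test_threshold_monotonicity_superset(self, implanted_swe_recording):
        rec, _ = implanted_swe_recording
        lenient = detect_swes(rec, amp_threshold=-5.0)
        strict = detect_swes(rec, amp_threshold=-60.0)
        assert set(strict["onset"]) <= set(lenient["onset"])

    def test_threshold_monotonicity_strict_on_noise(self):
        rng = np.random.default_rng(0)
        rec = EegRecording(data=rng.normal(0, 40, size=(8, 60 * 200)),
                           sfreq=200.0)
        lenient = detect_swes(rec, amp_threshold=-5.0)
        strict = detect_swes(rec, amp_threshold=-60.0)
        assert len(strict) < len(lenient)
        assert set(strict["onset"]) <= set(lenient["onset"])

    def test_empty_recording_gives_empty_table(self):
        rec = EegRecording(data=np.zeros((4, 2000)), sfreq=200.0)
        events = detect_swes(rec)
        assert len(events) == 0
        assert "sync_score" in events.columns

    def test_amplitude_equivariance(self, implanted_swe_recording):
        rec, _ = implanted_swe_recording
        doubled = EegRecording(data=2 * rec.data, sfreq=rec.sfreq)
        a = detect_swes(rec)
        b = detect_swes(doubled)
        merged = a.merge(b, on="onset", suffixes=("_1", "_2"))
        assert len(merged) >= 18
        np.testing.assert_allclose(merged["neg_peak_amp_2"],
                                   2 * merged["neg_peak_amp_1"], rtol=1e-9)
        np.testing.assert_allclose(merged["neg_slope_2"],
                                   2 * merged["neg_slope_1"], rtol=1e-9)
        np.testing.assert_allclose(merged["duration_2"],
                                   merged["duration_1"], atol=1e-12)

    def test_stage_assignment_from_hypnogram(self, implanted_swe_recording):
        rec, _ = implanted_swe_recording
        n_epochs = int(np.ceil(rec.duration / 30))
        hyp = Hypnogram(stages=["N2" if i % 2 == 0 else "N3"
                                for i in range(n_epochs)])
        events = detect_swes(rec, hypnogram=hyp)
        expected = [hyp.stage_at(t) for t in events["neg_peak_time"]]
        assert list(events["stage"]) == expected
        assert {"N2", "N3"} <= set(events["stage"])

    def test_estimator_interface(self, implanted_swe_recording):
        rec, _ = implanted_swe_recording
        det = SweDetector(amp_threshold=-10.0).fit(rec)
        assert det.get_params()["amp_threshold"] == -10.0
        assert len(det.events_) > 0
        assert abs(det.envelope_.values.mean()) < 1e-9
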