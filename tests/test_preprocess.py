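"""Preprocessing chain: resampling, filtering, segmentation, artifact handling."""

import numpy as np
import pytest

from pbciscreen.preprocess import (
    bandpass,
    detect_blinks,
    lms_remove_eog,
    preprocess_recording,
    reject_segments,
    resample,
    segment,
)
from pbciscreen.recording import EEG, EOG, Recording
from pbciscreen.synthetic import CohortConfig, generate_participant, inject_blinks

from conftest import make_recording


def rms(x):
    return float(np.sqrt(np.mean(np.square(x))))


class TestResample:
    def test_2048_to_256_sample_count(self):
        rec = make_recording(duration=60.0, rate=2048.0)
        out = resample(rec, 256.0)
        assert out.n_samples == 15360
        assert out.rate == 256.0

    def test_identity_when_rates_match(self):
        rec = make_recording(duration=2.0, rate=256.0)
        out = resample(rec, 256.0)
        np.testing.assert_array_equal(out.data, rec.data)

    def test_sinusoid_amplitude_preserved(self):
        rec = make_recording(
            duration=4.0, rate=2048.0, fill=lambda t, i: np.sin(2 * np.pi * 10 * t)
        )
        out = resample(rec, 256.0)
        mid = out.data[0, 256:-256]  # skip filter edge transients
        ref = np.sin(2 * np.pi * 10 * (np.arange(out.n_samples) / 256.0))[256:-256]
        assert rms(mid) == pytest.approx(rms(ref), rel=0.01)

    def test_upsampling_rejected(self):
        rec = make_recording(duration=1.0, rate=256.0)
        with pytest.raises(ValueError, match="upsampling"):
            resample(rec, 512.0)


class TestBandpass:
    def test_stopband_50hz_suppressed(self):
        rec = make_recording(duration=8.0, fill=lambda t, i: np.sin(2 * np.pi * 50 * t))
        out = bandpass(rec, 0.5, 30.0)
        sl = slice(512, -512)  # exclude forward-backward edge transients
        assert rms(out.data[0, sl]) < 0.1 * rms(rec.data[0, sl])

    def test_passband_10hz_preserved(self):
        rec = make_recording(duration=8.0, fill=lambda t, i: np.sin(2 * np.pi * 10 * t))
        out = bandpass(rec, 0.5, 30.0)
        assert rms(out.data[0, 512:-512]) == pytest.approx(rms(rec.data[0, 512:-512]), rel=0.05)

    def test_dc_offset_removed(self):
        rec = make_recording(duration=4.0, fill=lambda t, i: 100.0 + np.sin(2 * np.pi * 10 * t))
        out = bandpass(rec, 0.5, 30.0)
        assert abs(np.mean(out.data[0])) < 1.0

    def test_invalid_edges_rejected(self):
        rec = make_recording(duration=1.0)
        for lo, hi in [(0.0, 30.0), (30.0, 0.5), (0.5, 200.0)]:
            with pytest.raises(ValueError):
                bandpass(rec, lo, hi)


class TestSegment:
    @pytest.mark.parametrize(
        "duration, expected",
        [(60.0, 119), (1.0, 1), (1.6, 2)],
    )
    def test_segment_counts(self, duration, expected):
        rec = make_recording(duration=duration)
        series = segment(rec, 1.0, 0.5)
        assert len(series) == expected
        assert series.valid.all()

    def test_start_grid(self):
        rec = make_recording(duration=1.6)
        series = segment(rec)
        np.testing.assert_allclose(series.starts, [0.0, 0.5])

    def test_too_short_recording_rejected(self):
        rec = make_recording(duration=0.5)
        with pytest.raises(ValueError, match="shorter"):
            segment(rec)


class TestDetectBlinks:
    def _clean_and_blinky(self, seed=0, rate_per_min=10.0):
        cfg = CohortConfig(
            n_participants=3, native_rate=256.0, resting_duration=60.0,
            task_durations=(("valence", 10.0),), blink_rate=0.0, seed=seed,
        )
        part = generate_participant(cfg, 0)
        clean = part.recordings["resting"]
        blinky, times = inject_blinks(clean, rate_per_min, seed=seed + 1)
        return bandpass(clean), bandpass(blinky), times

    def test_clean_recording_yields_no_intervals(self):
        clean, _, _ = self._clean_and_blinky()
        assert detect_blinks(clean) == []

    def test_injected_blinks_detected(self):
        _, blinky, times = self._clean_and_blinky(seed=3)
        intervals = detect_blinks(blinky)
        hits = sum(
            any(a <= t + 0.4 and b >= t for a, b in intervals) for t in times
        )
        assert hits >= len(times) - 1
        # at most one interval not matching any true blink
        false = sum(
            not any(a <= t + 0.4 and b >= t for t in times) for a, b in intervals
        )
        assert false <= 1

    def test_intervals_sorted_and_disjoint(self):
        _, blinky, _ = self._clean_and_blinky(seed=5)
        intervals = detect_blinks(blinky)
        for (a1, b1), (a2, b2) in zip(intervals, intervals[1:]):
            assert b1 <= a2
            assert a1 < b1


class TestRejectSegments:
    def _series(self, duration=4.0):
        return segment(make_recording(duration=duration))

    def test_empty_intervals_keep_mask(self):
        s = self._series()
        out = reject_segments(s, [])
        np.testing.assert_array_equal(out.valid, s.valid)

    def test_interval_intersection(self):
        s = self._series()
        out = reject_segments(s, [(0.25, 0.30)])
        # only the window starting at 0.0 covers [0.25, 0.30)
        assert not out.valid[0]
        assert out.valid[1:].all()

    def test_full_cover_invalidates_all(self):
        s = self._series()
        out = reject_segments(s, [(0.0, 4.0)])
        assert out.n_valid == 0

    def test_idempotent(self):
        s = self._series()
        once = reject_segments(s, [(1.2, 1.4)])
        twice = reject_segments(once, [(1.2, 1.4)])
        np.testing.assert_array_equal(once.valid, twice.valid)


class TestLms:
    def _mixed(self, seed=0, n_s=20.0, rate=256.0, gain=0.8):
        rng = np.random.default_rng(seed)
        n = int(n_s * rate)
        t = np.arange(n) / rate
        clean = np.sin(2 * np.pi * 10 * t) + 0.5 * rng.standard_normal(n)
        eog = np.zeros(n)
        for onset in rng.uniform(0, n_s - 0.5, size=int(n_s / 2)):
            i0 = int(onset * rate)
            w = int(0.3 * rate)
            eog[i0 : i0 + w] += 40 * np.hanning(w)
        eog += rng.standard_normal(n)
        rec = Recording(
            np.vstack([clean + gain * eog, eog]),
            rate,
            ["Fp1", "EOG1"],
            [EEG, EOG],
        )
        return rec, clean, eog

    def test_zero_reference_is_identity(self):
        rec = make_recording(duration=4.0, channels=("Fp1", "EOG1"))
        rec.data[1] = 0.0
        out = lms_remove_eog(rec)
        np.testing.assert_allclose(out.channel("Fp1"), rec.channel("Fp1"))

    def test_eog_contamination_removed(self):
        rec, clean, eog = self._mixed()
        out = lms_remove_eog(rec)
        sl = slice(2 * 256, None)  # discard convergence transient
        corr = np.corrcoef(out.channel("Fp1")[sl], eog[sl])[0, 1]
        assert abs(corr) < 0.1

    def test_clean_component_preserved(self):
        rec, clean, eog = self._mixed()
        out = lms_remove_eog(rec)
        sl = slice(2 * 256, None)
        resid = out.channel("Fp1")[sl] - clean[sl]
        assert rms(resid) < 0.2 * rms(0.8 * eog[sl])

    def test_missing_eog_channel_rejected(self):
        rec = make_recording(duration=1.0)
        with pytest.raises(ValueError, match="available"):
            lms_remove_eog(rec, eog_channels=["EOGX"])


class TestFullChain:
    def test_blink_samples_removed(self):
        """Detection + rejection drops nearly all samples inside blink events."""
        cfg = CohortConfig(
            n_participants=3, native_rate=256.0, resting_duration=60.0,
            task_durations=(("valence", 10.0),), seed=2,
        )
        part = generate_participant(cfg, 1)
        rec = part.recordings["resting"]
        series = preprocess_recording(rec)
        times = part.blink_times["resting"]
        assert times, "expected injected blinks"
        kept = [
            (s, s + 1.0) for s, v in zip(series.starts, series.valid) if v
        ]
        # fraction of blink time overlapping any kept window
        overlap = 0.0
        total = 0.0
        for t in times:
            t_end = t + 0.3
            total += t_end - t
            for a, b in kept:
                overlap += max(0.0, min(b, t_end) - max(a, t))
        assert overlap / total < 0.05
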