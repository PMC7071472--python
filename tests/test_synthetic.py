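"""Synthetic cohort generator: determinism, spectral fidelity, truth bookkeeping, links."""

import numpy as np
import pytest
from scipy import signal, stats

from pbciscreen.dynrange import iqr
from pbciscreen.qeeg import BANDS, band_power
from pbciscreen.synthetic import (
    BandProfile,
    CohortConfig,
    LinkSpec,
    generate_cohort,
    generate_participant,
    inject_blinks,
)

from conftest import make_recording


def quiet_config(**kw):
    base = dict(
        n_participants=3,
        native_rate=256.0,
        resting_duration=20.0,
        task_durations=(("valence", 20.0), ("relaxation", 20.0), ("attention", 20.0)),
        blink_rate=0.0,
        seed=5,
    )
    base.update(kw)
    return CohortConfig(**base)


class TestConfigValidation:
    def test_too_few_participants_rejected(self):
        with pytest.raises(ValueError, match="n_participants"):
            quiet_config(n_participants=2)

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError, match="resting_duration"):
            quiet_config(resting_duration=0.0)

    def test_nyquist_violation_rejected(self):
        with pytest.raises(ValueError, match="native_rate"):
            quiet_config(native_rate=30.0)

    def test_unknown_link_predictor_lists_valid_names(self):
        with pytest.raises(ValueError, match="112 canonical"):
            LinkSpec("FAA", "IQR-Asym-Gamma-30-40")

    def test_negative_blink_rate_rejected(self):
        with pytest.raises(ValueError, match="blink_rate"):
            quiet_config(blink_rate=-1.0)


class TestDeterminism:
    def test_same_seed_same_participant_bitwise(self):
        cfg = quiet_config(blink_rate=6.0)
        a = generate_participant(cfg, 1)
        b = generate_participant(cfg, 1)
        for session in a.recordings:
            np.testing.assert_array_equal(
                a.recordings[session].data, b.recordings[session].data
            )
        assert a.blink_times == b.blink_times

    def test_different_seeds_differ(self):
        t1 = generate_cohort(quiet_config(seed=1))[1]
        t2 = generate_cohort(quiet_config(seed=2))[1]
        assert not np.allclose(t1["true_iqr"], t2["true_iqr"])


class TestSignalContent:
    def test_alpha_only_spectrum(self):
        """With only a high-alpha oscillation, >=90% of 2-18 Hz power is in 8-12."""
        profiles = {
            "delta": BandProfile(0.0),
            "theta": BandProfile(0.0),
            "alpha_low": BandProfile(0.0),
            "alpha_high": BandProfile(4.0, 0.1, 0.2),
            "low_beta": BandProfile(0.0),
            "beta": BandProfile(0.0),
        }
        cfg = quiet_config(band_profiles=profiles, background_rms_uv=0.0)
        part = generate_participant(cfg, 0)
        x = part.recordings["resting"].channel("Fp1")
        f, psd = signal.periodogram(x, fs=256.0)
        df = f[1] - f[0]
        total = psd[(f >= 2) & (f < 18)].sum() * df
        alpha = psd[(f >= 8) & (f < 12)].sum() * df
        assert alpha / total >= 0.90

    def test_zero_modulation_depth_gives_zero_truth_iqr(self):
        profiles = {
            name: BandProfile(amp, 0.0, 0.0)
            for name, amp in [
                ("delta", 4.0), ("theta", 3.0), ("alpha_low", 3.0),
                ("alpha_high", 3.0), ("low_beta", 1.5), ("beta", 1.2),
            ]
        }
        part = generate_participant(quiet_config(band_profiles=profiles), 0)
        for tf in part.truth_features.values():
            assert tf.iqr == pytest.approx(0.0, abs=1e-12)

    def test_constant_alpha_ratio_gives_constant_faa(self):
        """Fp1 alpha amplitude e^0.5 x Fp2 and no modulation -> truth FAA == 1."""
        from pbciscreen.synthetic import _canonical_powers, _truth_feature_values

        n_seg = 30
        gen_powers = np.ones((2, n_seg, 6))
        gen_powers[0, :, 3] = np.e  # alpha_high power ratio e -> ln ratio 1
        faa = _truth_feature_values(
            "FAA", _canonical_powers(gen_powers[0]), _canonical_powers(gen_powers[1])
        )
        np.testing.assert_allclose(faa, 1.0)

    def test_truth_consistency(self):
        """Stored truth IQR equals the IQR of the stored truth series exactly."""
        parts, _ = generate_cohort(quiet_config())
        for p in parts:
            for tf in p.truth_features.values():
                assert tf.iqr == iqr(tf.values)


class TestLinks:
    def test_zero_coefficient_zero_noise_gives_common_target(self):
        cfg = quiet_config(
            links=(LinkSpec("FAA", "IQR-Asym-Alpha-10-12", 0.0, noise_sd=0.0, noise_frac=None),),
            task_durations=(("valence", 20.0),),
        )
        _, truth = generate_cohort(cfg)
        # coefficient 0 -> all targets equal (the positivity floor)
        assert truth["target_iqr"].nunique() == 1

    def test_realized_iqr_matches_target(self):
        cfg = quiet_config(task_durations=(("valence", 20.0),),
                           links=(LinkSpec("FAA", "IQR-Asym-Alpha-10-12", 1.0, noise_frac=0.1),))
        _, truth = generate_cohort(cfg)
        np.testing.assert_allclose(truth["true_iqr"], truth["target_iqr"], rtol=1e-6)

    def test_low_noise_link_is_tight_at_truth_level(self):
        cfg = quiet_config(
            n_participants=30,
            seed=9,
            task_durations=(("valence", 20.0),),
            links=(LinkSpec("FAA", "IQR-Asym-Alpha-10-12", 1.0, noise_sd=0.01, noise_frac=None),),
        )
        _, truth = generate_cohort(cfg)
        r = np.corrcoef(truth["link_predictor_value"], truth["true_iqr"])[0, 1]
        assert r > 0.9

    def test_noise_free_link_gives_r2_one(self):
        cfg = quiet_config(
            n_participants=10,
            task_durations=(("valence", 20.0),),
            links=(LinkSpec("FAA", "IQR-Asym-Alpha-10-12", 1.3, noise_sd=0.0, noise_frac=None),),
        )
        _, truth = generate_cohort(cfg)
        slope, intercept, r, *_ = stats.linregress(
            truth["link_predictor_value"], truth["true_iqr"]
        )
        assert r**2 > 0.999
        assert slope == pytest.approx(1.3, rel=1e-3)


class TestInjectBlinks:
    def test_rate_zero_is_identity(self):
        rec = make_recording(duration=5.0, channels=("Fp1", "Fp2"))
        out, times = inject_blinks(rec, 0.0, seed=0)
        np.testing.assert_array_equal(out.data, rec.data)
        assert times == []

    def test_negative_rate_rejected(self):
        rec = make_recording(duration=5.0)
        with pytest.raises(ValueError, match="blink rate"):
            inject_blinks(rec, -2.0)

    def test_events_within_bounds(self):
        rec = make_recording(duration=30.0)
        _, times = inject_blinks(rec, 20.0, seed=3)
        assert times
        assert all(0.0 <= t < 30.0 for t in times)

    def test_poisson_event_counts(self):
        """Counts over 100 seeds stay inside the Poisson 99% envelope."""
        rec = make_recording(duration=60.0)
        counts = [len(inject_blinks(rec, 12.0, seed=s)[1]) for s in range(100)]
        lo, hi = stats.poisson.ppf([0.005, 0.995], 12.0)
        mean = np.mean(counts)
        assert lo <= mean <= hi
        # and the distribution is not degenerate
        assert np.std(counts) > 0

    def test_amplitude_dominates_background(self):
        rec = make_recording(duration=20.0)
        bg_rms = float(np.sqrt(np.mean(rec.data[:2] ** 2)))
        out, times = inject_blinks(rec, 10.0, seed=1)
        assert times
        peak = np.max(np.abs(out.data[0] - rec.data[0]))
        assert peak >= 5.0 * bg_rms
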