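"""Compute the three pBCI features and their dynamic ranges for one participant.

FAA (frontal alpha asymmetry, 10-12 Hz ln power ratio Fp1/Fp2), rFTP and
rFLBP (relative theta / low-beta power over total 2-18 Hz, channel-averaged)
are computed per 1-s segment; the interquartile range of each per-segment
series is that participant's dynamic range — the quantity the screening
method predicts from resting data. The estimated IQR is compared with the
generator's ground truth (they differ by spectral-estimator noise and the
1/f background, which the truth excludes).
"""

from pbciscreen import CohortConfig, feature_series, generate_cohort, iqr, preprocess_recording
from pbciscreen.synthetic import FEATURE_SESSIONS

config = CohortConfig(n_participants=3, native_rate=256.0, seed=21)
participants, _ = generate_cohort(config)
p = participants[0]

print(f"{p.participant}: per-band modulation depths (Fp1, Fp2), nats:")
for band, (d1, d2) in p.depths.items():
    print(f"  {band:<10} {d1:.2f}  {d2:.2f}")
print()
print(f"{'feature':<7} {'session':<11} {'estimated IQR':>14} {'truth IQR':>10}")
for feature, session in FEATURE_SESSIONS.items():
    series = preprocess_recording(p.recordings[session], use_lms=(session == "attention"))
    fs = feature_series(series, feature, session=session, participant=p.participant)
    est = iqr(fs.values)
    print(f"{feature:<7} {session:<11} {est:>14.4f} {p.truth_features[feature].iqr:>10.4f}")
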