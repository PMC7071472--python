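"""Synthesize a small cohort of prefrontal EEG recordings with known ground truth.

Each participant gets a 60-s resting recording plus three task sessions
(valence / relaxation / attention analogues) on channels Fp1, Fp2, EOG1,
EOG2, with eye blinks injected. The printed table shows, per participant,
the true dynamic range (IQR) of each task feature and the resting-state
predictor value the generator linked it to: the correlation between those
two columns is the signal the whole screening method tries to exploit.
"""

from pbciscreen import CohortConfig, generate_cohort

config = CohortConfig(n_participants=6, native_rate=256.0, seed=42)
participants, truth = generate_cohort(config)

first = participants[0]
rec = first.recordings["resting"]
print(f"{len(participants)} participants, sessions: {sorted(first.recordings)}")
print(f"resting recording: {rec.data.shape[0]} channels x {rec.n_samples} samples "
      f"@ {rec.rate:.0f} Hz, {len(first.blink_times['resting'])} blinks injected")
print()
print(truth.round(4).to_string(index=False))
print()
corr = truth.groupby("feature").apply(
    lambda g: g["link_predictor_value"].corr(g["true_iqr"]), include_groups=False
)
print("cohort correlation (truth level) between linked resting predictor and task IQR:")
print(corr.round(3).to_string())
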