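"""Extract the 112 candidate resting-state predictors from a 60-s recording.

Every combination of 8 frequency bands x 7 per-segment quantities (absolute
/ relative power at Fp1, Fp2 and their mean; interhemispheric asymmetry)
x 2 statistics (mean, IQR) gives one named scalar. These are the inputs
from which a task feature's dynamic range is later predicted.
"""

from pbciscreen import (
    CohortConfig,
    extract_candidate_predictors,
    generate_participant,
    preprocess_recording,
)

config = CohortConfig(n_participants=3, native_rate=256.0, seed=5)
participant = generate_participant(config, 0)
series = preprocess_recording(participant.recordings["resting"])
vec = extract_candidate_predictors(series, participant.participant)

print(f"{len(vec.values)} predictors extracted from {series.n_valid} artifact-free segments")
show = [
    "Mean-Abs-Fp1-Alpha-10-12",  # mean absolute high-alpha power, uV^2
    "Mean-Rel-Fp12-Theta-4-8",   # mean relative theta (channel-averaged)
    "IQR-Asym-Alpha-10-12",      # variability of the alpha asymmetry
    "IQR-Rel-Fp12-Beta-12-15",   # variability of relative low-beta
    "Mean-Rel-Fp1-total",        # degenerate by construction: identically 1
    "IQR-Rel-Fp1-total",         # degenerate by construction: identically 0
]
for name in show:
    print(f"  {name:<26} {vec.values[name]:.4f}")
print("Mean-Abs-* values are in uV^2; Rel and Asym quantities are unitless "
      "(ratios and ln ratios), so they are invariant to amplifier gain.")
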