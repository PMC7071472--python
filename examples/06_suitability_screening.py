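"""Run the whole pipeline and produce a calibration-screening report.

For each participant and feature the pipeline predicts the task-session
dynamic range from 60 s of resting EEG and compares it against the cohort
threshold (mean - SD of the actual IQRs). "calibrate" flags users whose
predicted dynamic range is too small for off-the-shelf pBCI use, so an
individual calibration session would be worthwhile; everyone else can skip
it. The threshold rule is a heuristic screen, not a validated cutoff.
"""

import json
import tempfile
from pathlib import Path

from pbciscreen import RunConfig, run_pipeline

out_dir = Path(tempfile.mkdtemp()) / "screening_run"
config = RunConfig(
    mode="synthetic",
    out_dir=str(out_dir),
    n_participants=8,
    seed=1,
    native_rate=256.0,
    models=("Baseline", "MLR", "SVMR"),
    n_perm=2000,
)
summary = run_pipeline(config)

print("evaluation (nRMSE per model and feature):")
print(json.dumps(summary["evaluation"], indent=2, sort_keys=True))
print("\nscreening recommendations:")
for key, rec in sorted(summary["suitability"].items()):
    print(f"  {key:<12} {rec}")
print(f"\nall intermediate tables persisted under {out_dir}")
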