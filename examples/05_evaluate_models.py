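"""Predict task-session dynamic ranges from resting predictors, LOOCV + FSFS.

A 35-participant synthetic cohort is generated with a known link: the true
FAA dynamic range of each participant's valence session equals their
resting ``IQR-Asym-Alpha-10-12`` plus 10% noise. Working from the cohort's
ground-truth predictor table (so the only noise is the link noise itself),
support-vector regression with forward sequential feature selection under
leave-one-participant-out cross-validation is compared against the oracle
that regresses on the true predictor alone, and against a no-information
mean model. nRMSE is the prediction error as a fraction of the cohort's
IQR range; selection frequency shows how often each resting predictor was
chosen across the 35 folds.
"""

from pbciscreen import (
    CohortConfig,
    ModelSpec,
    generate_cohort_truth,
    loocv,
    paired_permutation_test,
)
from pbciscreen.synthetic import LinkSpec

TRUE = "IQR-Asym-Alpha-10-12"
config = CohortConfig(
    n_participants=35,
    native_rate=256.0,
    seed=3,
    task_durations=(("valence", 60.0),),
    links=(LinkSpec("FAA", TRUE, 1.0, noise_frac=0.1),),
)
X, truth = generate_cohort_truth(config)
y = truth.set_index("participant")["true_iqr"].loc[X.index]

svmr = loocv(X, y, ModelSpec("SVMR"), use_fsfs=True, seed=0, feature="FAA")
oracle = loocv(X[[TRUE]], y, ModelSpec("MLR"), use_fsfs=False, seed=0)
mean = loocv(X, y, ModelSpec("Mean"), seed=0)
p_val = paired_permutation_test(mean.squared_errors, svmr.squared_errors,
                                n_perm=10000, seed=0)

print(f"SVMR + FSFS          nRMSE = {svmr.nrmse:.4f}  "
      f"(mean selected set size {svmr.mean_selected_size:.2f})")
print(f"true-predictor oracle nRMSE = {oracle.nrmse:.4f}")
print(f"mean model            nRMSE = {mean.nrmse:.4f}")
print(f"one-tailed permutation p (SVMR better than mean model) = {p_val:.4f}")
print("most frequently selected predictors (% of 35 folds):")
for name, freq in list(svmr.selection_frequency.items())[:5]:
    print(f"  {name:<28} {freq:5.1f}")
print(f"\nThe generator drove the task IQR with {TRUE}; selecting it in "
      "(nearly) every fold at an nRMSE close to the oracle's means the "
      "LOOCV + FSFS machinery recovered the planted relationship.")
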