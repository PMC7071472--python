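"""End-to-end orchestration: cohort -> preprocessing -> features -> evaluation -> screening report.

``run_pipeline`` executes the full analysis on a synthetic cohort or a
directory of recordings, persists every intermediate table, and produces a
deterministic JSON summary. The final product is a *suitability report*:
for each participant and feature, the predicted dynamic range is compared
against a cohort threshold (default: mean minus one sample standard
deviation of the actual IQRs) to recommend whether that user could skip an
individual calibration session. The threshold rule is a heuristic screen,
not a validated clinical cutoff, and the report labels it as such.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dynrange import dynamic_ranges, to_frame
from .edf import read_edf, write_edf
from .evaluate import EvalResult, ModelSpec, loocv, paired_permutation_test
from .predictors import extract_candidate_predictors, predictors_to_frame
from .preprocess import preprocess_recording
from .qeeg import FEATURES, FeatureSeries, feature_series
from .recording import Recording, read_recording_csv, write_recording_csv
from .synthetic import CohortConfig, generate_cohort

__all__ = ["RunConfig", "run_pipeline", "suitability", "suitability_report"]

logger = logging.getLogger(__name__)

#: Feature -> fixed "matched" resting predictor used by the Baseline model:
#: the resting-state IQR of the very quantity whose task IQR is predicted.
BASELINE_PREDICTORS: dict[str, list[str]] = {
    "FAA": ["IQR-Asym-Alpha-10-12"],
    "rFTP": ["IQR-Rel-Fp12-Theta-4-8"],
    "rFLBP": ["IQR-Rel-Fp12-Beta-12-15"],
}

THRESHOLD_RULES = ("mean_minus_sd",)


@dataclass
class RunConfig:
    """Declarative configuration of one pipeline run."""

    mode: str = "synthetic"  # synthetic | csv-dir | edf-dir
    out_dir: str = "pbciscreen_run"
    input_dir: str | None = None
    n_participants: int = 35
    seed: int = 0
    native_rate: float = 2048.0
    target_rate: float = 256.0
    band: tuple[float, float] = (0.5, 30.0)
    models: tuple[str, ...] = ("Baseline", "MLR", "SVMR")
    use_fsfs: bool = True
    threshold_rule: str = "mean_minus_sd"
    lms_sessions: tuple[str, ...] = ("attention",)
    faa_include_resting: bool = False
    n_perm: int = 10000

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "csv-dir", "edf-dir"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode != "synthetic" and not self.input_dir:
            raise ValueError(f"mode {self.mode!r} requires input_dir")
        if self.mode != "synthetic" and not Path(self.input_dir).is_dir():
            raise ValueError(f"input_dir {self.input_dir!r} does not exist")
        if not self.models:
            raise ValueError("model list must be non-empty")
        if self.threshold_rule not in THRESHOLD_RULES:
            raise ValueError(
                f"unknown threshold rule {self.threshold_rule!r}; choose from {THRESHOLD_RULES}"
            )
        self.models = tuple(self.models)
        self.band = tuple(self.band)
        self.lms_sessions = tuple(self.lms_sessions)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def feature_session_map(config: RunConfig) -> dict[str, list[str]]:
    """Which sessions feed each feature's dynamic range.

    The relative-power features pool the task session with the resting
    period; FAA uses the task session only unless configured otherwise.
    """
    m = {
        "FAA": ["valence"] + (["resting"] if config.faa_include_resting else []),
        "rFTP": ["relaxation", "resting"],
        "rFLBP": ["attention", "resting"],
    }
    return m


def suitability(predicted_iqr: float, cohort_iqrs, rule: str = "mean_minus_sd") -> dict:
    """Screen one predicted dynamic range against the cohort threshold.

    The default rule flags a user as needing calibration when their
    predicted IQR falls below ``mean - sd`` of the cohort's actual IQRs
    (sample SD, n-1 denominator).
    """
    x = np.asarray(cohort_iqrs, dtype=np.float64)
    if x.size < 2:
        raise ValueError("threshold needs at least 2 cohort IQRs")
    if rule != "mean_minus_sd":
        raise ValueError(f"unknown threshold rule {rule!r}; choose from {THRESHOLD_RULES}")
    threshold = float(x.mean() - x.std(ddof=1))
    ok = bool(predicted_iqr >= threshold)
    return {
        "predicted_iqr": float(predicted_iqr),
        "threshold": threshold,
        "suitable": ok,
        "recommendation": "skip calibration" if ok else "calibrate",
    }


def suitability_report(
    predicted: pd.DataFrame, actual: pd.DataFrame, rule: str = "mean_minus_sd"
) -> pd.DataFrame:
    """Per participant x feature screening table.

    ``predicted``/``actual`` have columns (participant, feature, iqr). The
    threshold per feature comes from the *actual* cohort IQRs.
    """
    rows = []
    for feature, group in predicted.groupby("feature", sort=True):
        cohort = actual.loc[actual["feature"] == feature, "iqr"].to_numpy()
        for _, r in group.sort_values("participant").iterrows():
            row = suitability(r["iqr"], cohort, rule)
            rows.append({"participant": r["participant"], "feature": feature, **row})
    return pd.DataFrame(rows)


def _load_recordings(config: RunConfig) -> dict[str, dict[str, Recording]]:
    """Read ``{participant}_{session}.{csv,edf}`` files from input_dir."""
    reader = read_recording_csv if config.mode == "csv-dir" else read_edf
    suffix = ".csv" if config.mode == "csv-dir" else ".edf"
    cohort: dict[str, dict[str, Recording]] = {}
    for path in sorted(Path(config.input_dir).glob(f"*{suffix}")):
        stem = path.stem
        if stem == "ground_truth":
            continue
        if "_" not in stem:
            logger.warning("skipping %s: expected <participant>_<session> name", path.name)
            continue
        pid, session = stem.split("_", 1)
        cohort.setdefault(pid, {})[session] = reader(path)
    if not cohort:
        raise ValueError(f"no *{suffix} recordings found in {config.input_dir}")
    return cohort


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and persist artifacts under ``config.out_dir``.

    Returns the summary dict (also written as ``summary.json``). A re-run
    with an identical config reproduces the summary byte for byte.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    truth_table = None
    if config.mode == "synthetic":
        cohort_cfg = CohortConfig(
            n_participants=config.n_participants,
            native_rate=config.native_rate,
            seed=config.seed,
        )
        participants, truth_table = generate_cohort(cohort_cfg)
        recordings = {p.participant: p.recordings for p in participants}
        truth_table.to_csv(out / "ground_truth.csv", index=False)
    else:
        recordings = _load_recordings(config)

    # --- preprocess + features -------------------------------------------
    session_map = feature_session_map(config)
    feats: list[FeatureSeries] = []
    predictor_vectors = []
    seg_counts = []
    for pid in sorted(recordings):
        sessions = recordings[pid]
        series_by_session = {}
        for session, rec in sessions.items():
            try:
                series_by_session[session] = preprocess_recording(
                    rec,
                    target_rate=config.target_rate,
                    band=config.band,
                    use_lms=session in config.lms_sessions,
                )
            except Exception as exc:  # noqa: BLE001 - abort with stage context
                raise RuntimeError(
                    f"preprocessing failed at participant {pid}, session {session}: {exc}"
                ) from exc
            seg_counts.append(
                (pid, session, len(series_by_session[session]),
                 series_by_session[session].n_valid)
            )
        if "resting" in series_by_session:
            try:
                predictor_vectors.append(
                    extract_candidate_predictors(series_by_session["resting"], pid)
                )
            except Exception as exc:
                raise RuntimeError(
                    f"predictor extraction failed at participant {pid}: {exc}"
                ) from exc
        else:
            logger.warning("participant %s: no resting session; skipping predictors", pid)
        for feature in FEATURES:
            task_session = session_map[feature][0]
            if task_session not in series_by_session:
                logger.warning(
                    "participant %s: missing %s session for %s", pid, task_session, feature
                )
                continue
            present = [s for s in session_map[feature] if s in series_by_session]
            for session in present:
                feats.append(
                    feature_series(series_by_session[session], feature,
                                   session=session, participant=pid)
                )

    pd.DataFrame(
        seg_counts, columns=["participant", "session", "n_segments", "n_valid"]
    ).to_csv(out / "segment_counts.csv", index=False)

    dr = dynamic_ranges(feats)
    dr_frame = to_frame(dr)
    dr_frame.to_csv(out / "dynamic_ranges.csv", index=False)
    X_all = predictors_to_frame(predictor_vectors)
    X_all.to_csv(out / "predictors.csv")

    # --- evaluation -------------------------------------------------------
    evaluation: dict[str, dict] = {}
    results_by_feature: dict[str, dict[str, EvalResult]] = {}
    predicted_rows = []
    for feature in FEATURES:
        sub = dr_frame[dr_frame["feature"] == feature].set_index("participant")
        pids = [p for p in X_all.index if p in sub.index]
        if len(pids) < 5:  # LOOCV training folds must keep >= 4 participants
            logger.warning("feature %s: only %d complete participants; skipping", feature, len(pids))
            continue
        X = X_all.loc[pids]
        y = sub.loc[pids, "iqr"]
        feature_eval: dict[str, dict] = {}
        results: dict[str, EvalResult] = {}
        for family in config.models:
            spec = (
                ModelSpec("Baseline", {"predictors": BASELINE_PREDICTORS[feature]})
                if family == "Baseline"
                else ModelSpec(family)
            )
            res = loocv(X, y, spec, use_fsfs=config.use_fsfs, seed=config.seed,
                        feature=feature)
            results[family] = res
            res.per_participant.to_csv(
                out / f"predictions_{feature}_{family}.csv", index=False
            )
            feature_eval[family] = {
                "nrmse": round(res.nrmse, 10),
                "mean_selected_size": (
                    None if np.isnan(res.mean_selected_size)
                    else round(res.mean_selected_size, 4)
                ),
                "selection_frequency_top5": {
                    k: round(v, 2)
                    for k, v in list(res.selection_frequency.items())[:5]
                },
            }
        if "Baseline" in results:
            base = results["Baseline"]
            for family, res in results.items():
                if family == "Baseline":
                    continue
                p = paired_permutation_test(
                    base.squared_errors, res.squared_errors,
                    n_perm=config.n_perm, seed=config.seed,
                )
                feature_eval[family]["p_vs_baseline"] = round(p, 6)
        evaluation[feature] = feature_eval
        results_by_feature[feature] = results
        best = min(results, key=lambda fam: results[fam].nrmse)
        evaluation[feature]["best_model"] = best
        for _, r in results[best].per_participant.iterrows():
            predicted_rows.append((r["participant"], feature, r["predicted"]))

    with open(out / "evaluation.json", "w") as fh:
        json.dump(evaluation, fh, indent=2, sort_keys=True)

    # --- suitability screening -------------------------------------------
    report = pd.DataFrame(columns=["participant", "feature", "predicted_iqr",
                                   "threshold", "suitable", "recommendation"])
    if predicted_rows:
        predicted = pd.DataFrame(predicted_rows, columns=["participant", "feature", "iqr"])
        report = suitability_report(predicted, dr_frame, config.threshold_rule)
        report.to_csv(out / "suitability.csv", index=False)

    summary = {
        "version": __version__,
        "config": {k: list(v) if isinstance(v, tuple) else v
                   for k, v in asdict(config).items()},
        "n_participants": len(recordings),
        "n_predictor_vectors": len(predictor_vectors),
        "dynamic_ranges": {
            f"{r.participant}/{r.feature}": round(r.iqr, 10) for r in dr
        },
        "evaluation": evaluation,
        "suitability": {
            f"{r.participant}/{r.feature}": r.recommendation
            for r in report.itertuples()
        },
        "threshold_rule": f"{config.threshold_rule} (heuristic screen)",
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    config.to_yaml(out / "config.yaml")
    return summary


def export_cohort(
    cohort_cfg: CohortConfig, out_dir, fmt: str = "csv"
) -> pd.DataFrame:
    """Write a synthetic cohort to disk, one file per participant and session.

    Returns the ground-truth table (also written as ``ground_truth.csv``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if fmt not in ("csv", "edf"):
        raise ValueError(f"unknown format {fmt!r}; choose csv or edf")
    participants, truth = generate_cohort(cohort_cfg)
    writer = write_recording_csv if fmt == "csv" else write_edf
    for part in participants:
        for session, rec in part.recordings.items():
            writer(rec, out / f"{part.participant}_{session}.{fmt}")
    truth.to_csv(out / "ground_truth.csv", index=False)
    return truth
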