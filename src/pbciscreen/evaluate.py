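"""Predicting individual dynamic ranges: models, feature selection, cross-validation.

The estimation problem is small-n / wide-p: ~35 participants, 112 candidate
resting-state predictors, one scalar target per participant (the actual IQR
of a task-session feature). The workflow is:

1. leave-one-participant-out cross-validation (LOOCV);
2. within each training fold, forward sequential feature selection (FSFS):
   greedily add the predictor that most reduces the *training-fit* nRMSE,
   stop as soon as no candidate meaningfully reduces it;
3. fit the chosen model family on the selected predictors and predict the
   held-out participant;
4. score with nRMSE = RMSE / (max - min) of the actual IQRs;
5. compare two models' per-participant squared errors with a one-tailed
   paired permutation test.

Model families mirror a standard regression-toolbox lineup: multiple linear
regression (MLR), a regression tree (TR), bagged trees (ebTR), linear- and
RBF-kernel support-vector regression (SVMR / kSVMR), and Gaussian-process
regression (GPR). Predictors are standardized on the training fold only;
SVR targets are likewise standardized on the fold (and predictions mapped
back), so hyperparameter defaults are scale-free.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn import config_context
from sklearn.ensemble import BaggingRegressor
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel
from sklearn.linear_model import LinearRegression
from sklearn.svm import SVR
from sklearn.tree import DecisionTreeRegressor

__all__ = [
    "ModelSpec",
    "MODEL_FAMILIES",
    "nrmse",
    "fit_predict",
    "fsfs",
    "loocv",
    "EvalResult",
    "paired_permutation_test",
]

MODEL_FAMILIES = ("MLR", "TR", "ebTR", "SVMR", "kSVMR", "GPR", "Baseline", "Mean")

#: Families whose target is standardized on the training fold before fitting.
_SCALE_Y = {"SVMR", "kSVMR"}


@dataclass(frozen=True)
class ModelSpec:
    """A model family plus hyperparameter overrides.

    ``Baseline`` is multiple linear regression on a fixed predictor set
    (given as ``hyperparameters["predictors"]``) and is never combined with
    feature selection; it represents regressing the task feature's IQR on
    the matching resting-state quantity alone. ``Mean`` predicts the
    training-fold mean of the target (a no-information reference).
    """

    family: str
    hyperparameters: tuple = ()

    def __post_init__(self) -> None:
        if self.family not in MODEL_FAMILIES:
            raise ValueError(
                f"unknown model family {self.family!r}; choose from {MODEL_FAMILIES}"
            )
        if isinstance(self.hyperparameters, dict):
            object.__setattr__(
                self, "hyperparameters", tuple(sorted(self.hyperparameters.items()))
            )

    @property
    def params(self) -> dict:
        return dict(self.hyperparameters)


class _MeanModel:
    def fit(self, X, y):
        self.mean_ = float(np.mean(y))
        return self

    def predict(self, X):
        return np.full(np.asarray(X).shape[0], self.mean_)


def _make_estimator(spec: ModelSpec, seed: int | None):
    p = spec.params
    fam = spec.family
    if fam in ("MLR", "Baseline"):
        return LinearRegression()
    if fam == "Mean":
        return _MeanModel()
    if fam == "TR":
        return DecisionTreeRegressor(
            max_depth=p.get("max_depth", 4),
            min_samples_leaf=p.get("min_samples_leaf", 2),
            random_state=seed,
        )
    if fam == "ebTR":
        return BaggingRegressor(
            DecisionTreeRegressor(
                max_depth=p.get("max_depth", 4),
                min_samples_leaf=p.get("min_samples_leaf", 2),
            ),
            n_estimators=p.get("n_estimators", 30),
            random_state=seed,
        )
    if fam == "SVMR":
        return SVR(kernel="linear", C=p.get("C", 1.0), epsilon=p.get("epsilon", 0.1))
    if fam == "kSVMR":
        return SVR(
            kernel="rbf",
            C=p.get("C", 1.0),
            gamma=p.get("gamma", "scale"),
            epsilon=p.get("epsilon", 0.1),
        )
    if fam == "GPR":
        kernel = ConstantKernel(1.0, (1e-3, 1e5)) * RBF(1.0, (1e-2, 1e3))
        return GaussianProcessRegressor(
            kernel=kernel,
            alpha=p.get("alpha", 1e-6),
            normalize_y=True,
            n_restarts_optimizer=0,
            random_state=seed,
        )
    raise AssertionError(fam)


def nrmse(actual, predicted) -> float:
    """Normalized RMSE: root-mean-square error over the range of the actual values."""
    a = np.asarray(actual, dtype=np.float64)
    p = np.asarray(predicted, dtype=np.float64)
    if a.shape != p.shape or a.ndim != 1:
        raise ValueError(f"shape mismatch: actual {a.shape}, predicted {p.shape}")
    if a.size < 2:
        raise ValueError("need at least two participants")
    rng = a.max() - a.min()
    if rng <= 0:
        raise ValueError("actual values have zero range; nRMSE undefined")
    return float(np.sqrt(np.mean((a - p) ** 2)) / rng)


def _standardize_columns(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)  # constant (degenerate) predictors pass through as 0
    return (X - mu) / sd, mu, sd


def fit_predict(
    spec: ModelSpec,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    seed: int | None = 0,
) -> np.ndarray:
    """Fit one model on a training fold and predict test rows.

    Predictor standardization (and, for SVR families, target
    standardization) is fitted on the training fold only.
    """
    X_train = np.asarray(X_train, dtype=np.float64)
    X_test = np.asarray(X_test, dtype=np.float64)
    y_train = np.asarray(y_train, dtype=np.float64)
    if X_train.shape[1] != X_test.shape[1]:
        raise ValueError("X_test columns must match X_train")
    Xtr, mu, sd = _standardize_columns(X_train)
    Xte = (X_test - mu) / sd
    est = _make_estimator(spec, seed)
    if spec.family in _SCALE_Y:
        ym, ys = y_train.mean(), y_train.std()
        ys = ys if ys > 0 else 1.0
        est.fit(Xtr, (y_train - ym) / ys)
        return est.predict(Xte) * ys + ym
    est.fit(Xtr, y_train)
    return np.asarray(est.predict(Xte), dtype=np.float64)


def _fit_cost(est, scale_y: bool, Xtr, ytr, Xeval):
    """Fit an estimator on pre-standardized columns; return eval predictions."""
    if scale_y:
        ym, ys = ytr.mean(), ytr.std()
        ys = ys if ys > 0 else 1.0
        est.fit(Xtr, (ytr - ym) / ys)
        return est.predict(Xeval) * ys + ym
    est.fit(Xtr, ytr)
    return est.predict(Xeval)


def fsfs(
    X_train,
    y_train,
    spec: ModelSpec,
    seed: int | None = 0,
    names: list[str] | None = None,
    max_features: int | None = None,
    rel_tol: float = 0.05,
) -> list:
    """Forward sequential feature selection on the training fold.

    Starting from the empty set (criterion: nRMSE of predicting the
    training mean), each round refits the model with every remaining
    candidate appended and adds the one minimizing the training-fit nRMSE —
    but only if it reduces the current criterion by at least ``rel_tol``
    times the empty-set criterion (flexible regressors can shave the
    training fit indefinitely by tiny amounts, so "reduces" needs a
    materiality threshold to terminate on noise targets); otherwise
    selection stops. Ties break to the earliest candidate in canonical
    column order. Returns the ordered selected names (or column indices if
    ``names`` is None).
    """
    X = np.asarray(X_train, dtype=np.float64)
    y = np.asarray(y_train, dtype=np.float64)
    if X.shape[0] != y.shape[0]:
        raise ValueError("X_train and y_train row mismatch")
    if X.shape[0] < 4:
        raise ValueError("FSFS needs at least 4 training participants")
    if y.max() - y.min() <= 0:
        raise ValueError("degenerate target: zero range")
    Xs, _, _ = _standardize_columns(X)
    scale_y = spec.family in _SCALE_Y
    n, p = X.shape
    if max_features is None:
        max_features = min(n - 2, p)

    constant = Xs.std(axis=0) == 0  # degenerate predictors can never help

    selected: list[int] = []
    current = nrmse(y, np.full(n, y.mean()))
    min_gain = rel_tol * current
    with config_context(assume_finite=True):
        while len(selected) < max_features:
            cutoff = current - min_gain
            best_j, best_crit = -1, cutoff
            remaining = [j for j in range(p) if j not in selected and not constant[j]]
            for j in remaining:
                cols = selected + [j]
                est = _make_estimator(spec, seed)
                yhat = _fit_cost(est, scale_y, Xs[:, cols], y, Xs[:, cols])
                crit = nrmse(y, yhat)
                if crit < best_crit - 1e-12:
                    best_j, best_crit = j, crit
            if best_j < 0:
                break
            selected.append(best_j)
            current = best_crit
    if names is not None:
        return [names[j] for j in selected]
    return selected


@dataclass
class EvalResult:
    """LOOCV outcome for one (feature, model) pair."""

    feature: str
    model: ModelSpec
    per_participant: pd.DataFrame  # participant, actual, predicted, n_selected
    selected: dict[str, list[str]]  # participant -> ordered selected predictor names
    nrmse: float
    selection_frequency: dict[str, float]  # name -> % of folds
    mean_selected_size: float

    @property
    def squared_errors(self) -> np.ndarray:
        d = self.per_participant["actual"] - self.per_participant["predicted"]
        return (d**2).to_numpy()


def loocv(
    X: pd.DataFrame,
    y: pd.Series,
    spec: ModelSpec,
    use_fsfs: bool = True,
    seed: int | None = 0,
    feature: str = "",
) -> EvalResult:
    """Leave-one-participant-out evaluation of one model.

    For each held-out participant, feature selection (if enabled) and model
    fitting see only the remaining participants; the held-out row is
    predicted once. The final nRMSE pools all participants' predictions.
    ``Baseline`` and ``Mean`` families skip selection; Baseline instead
    uses the fixed predictor list from its spec.
    """
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X))
    y = pd.Series(np.asarray(y, dtype=np.float64), index=X.index)
    n = len(X)
    if n < 4:
        raise ValueError("LOOCV needs at least 4 participants")
    if y.isna().any():
        raise ValueError("missing targets; drop incomplete participants first")
    names = [str(c) for c in X.columns]
    Xv = X.to_numpy(dtype=np.float64)
    yv = y.to_numpy()

    if spec.family == "Baseline":
        fixed = list(spec.params.get("predictors", []))
        if not fixed:
            raise ValueError("Baseline spec requires hyperparameters['predictors']")
        missing = [f for f in fixed if f not in names]
        if missing:
            raise ValueError(f"Baseline predictors not in X: {missing}")
        use_fsfs = False

    rows = []
    selected_by_participant: dict[str, list[str]] = {}
    counts: dict[str, int] = {}
    for i in range(n):
        tr = np.arange(n) != i
        Xtr, ytr = Xv[tr], yv[tr]
        if spec.family == "Baseline":
            cols = [names.index(f) for f in fixed]
        elif spec.family == "Mean" or not use_fsfs:
            cols = list(range(len(names)))
        else:
            cols = fsfs(Xtr, ytr, spec, seed=seed)
        sel_names = [names[j] for j in cols]
        if spec.family not in ("Mean",) and use_fsfs and not cols:
            pred = float(ytr.mean())  # empty selection: no-information prediction
        else:
            pred = float(
                fit_predict(spec, Xtr[:, cols], ytr, Xv[i : i + 1, cols], seed=seed)[0]
            )
        pid = str(X.index[i])
        rows.append((pid, float(yv[i]), pred, len(sel_names)))
        if spec.family not in ("Baseline", "Mean") and use_fsfs:
            selected_by_participant[pid] = sel_names
            for s in sel_names:
                counts[s] = counts.get(s, 0) + 1
    per = pd.DataFrame(rows, columns=["participant", "actual", "predicted", "n_selected"])
    freq = {k: 100.0 * v / n for k, v in sorted(counts.items(), key=lambda kv: -kv[1])}
    sizes = [len(v) for v in selected_by_participant.values()]
    return EvalResult(
        feature=feature,
        model=spec,
        per_participant=per,
        selected=selected_by_participant,
        nrmse=nrmse(per["actual"].to_numpy(), per["predicted"].to_numpy()),
        selection_frequency=freq,
        mean_selected_size=float(np.mean(sizes)) if sizes else float("nan"),
    )


def paired_permutation_test(
    sqerr_a, sqerr_b, n_perm: int = 10000, seed: int = 0
) -> float:
    """One-tailed paired permutation test that model b improves on model a.

    The statistic is nRMSE(a) - nRMSE(b); since both models share the same
    actual values, the normalizing range cancels and RMSE difference is
    equivalent. Under the null the pairing of each participant's two squared
    errors is exchangeable, so the reference distribution swaps them with
    probability 1/2. Returns the add-one smoothed p-value
    ``(1 + #{T_perm >= T_obs}) / (n_perm + 1)``; small p means model b's
    error is credibly smaller.
    """
    a = np.asarray(sqerr_a, dtype=np.float64)
    b = np.asarray(sqerr_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired error vectors must have identical length")
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("squared errors must be non-negative")
    t_obs = np.sqrt(a.mean()) - np.sqrt(b.mean())
    rng = np.random.default_rng(seed)
    swap = rng.random((n_perm, a.size)) < 0.5
    pa = np.where(swap, b[None, :], a[None, :]).mean(axis=1)
    pb = np.where(swap, a[None, :], b[None, :]).mean(axis=1)
    t_perm = np.sqrt(pa) - np.sqrt(pb)
    return float((1 + np.sum(t_perm >= t_obs)) / (n_perm + 1))
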