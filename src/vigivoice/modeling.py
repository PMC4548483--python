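"""Repeated cross-validated prediction of fatigue measures from voice.

The experiment grid mirrors the reference analysis: for each target —
sleep latency (minutes awake), circadian phase (minutes of day), and the
four z-standardized PPT scores — null, multilinear regression (MLR) and
linear support-vector regression (SVR, C in {1, 0.01}) models are
evaluated with 100 randomized 10-fold cross-validations. PPT targets
additionally get a time-only MLR baseline using just latency and phase.

Metrics per repetition are computed on the pooled test-fold predictions:
Pearson R, mean absolute error (MAE) in target units, and relative
absolute error RAE = 100 * MAE / MAE_null, where the null model (train
mean) is trained on the identical folds. Means and SDs are reported
over repetitions. Phase is scored both naively and with the circular
(smallest time-of-day difference) error.

MLR with ~1093 features and ~61 training samples per fold is solved as
the minimum-norm least-squares solution; an optional within-fold
univariate-correlation feature-selection stage (top-k) is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVR

from .circadian import MINUTES_PER_DAY, circular_error
from .normalize import ScoreStandardizer

__all__ = [
    "ModelSpec",
    "CVProtocol",
    "CVMetrics",
    "fit_predict",
    "cross_validate",
    "range_normalized_mae",
    "denormalize_predictions",
    "evaluate_all",
    "DEFAULT_MODELS",
]


@dataclass(frozen=True)
class ModelSpec:
    """One model in the experiment grid.

    kind:
        'null' (train-mean constant), 'mlr' (minimum-norm least
        squares), or 'svr' (linear epsilon-insensitive SVR).
    inputs:
        'speech' (the gaussianized feature vector) or 'time' (latency
        and phase only).
    top_k:
        If set, keep only the k features most correlated (absolute
        Pearson) with the training target within each fold.
    """

    kind: str = "mlr"
    inputs: str = "speech"
    C: float = 1.0
    epsilon: float = 0.001
    tol: float = 1e-3
    top_k: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("null", "mlr", "svr"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.inputs not in ("speech", "time"):
            raise ValueError(f"unknown input set {self.inputs!r}")
        if self.C <= 0:
            raise ValueError("C must be > 0")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")

    @property
    def label(self) -> str:
        if self.kind == "null":
            return "null"
        if self.kind == "mlr":
            return f"{self.inputs}_mlr"
        return f"{self.inputs}_svr_C{self.C:g}"


@dataclass(frozen=True)
class CVProtocol:
    """Repeated randomized k-fold protocol (sample-level folds)."""

    repetitions: int = 100
    folds: int = 10
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.repetitions < 1 or self.folds < 2:
            raise ValueError("need >= 1 repetition and >= 2 folds")


@dataclass
class CVMetrics:
    """Mean (SD) of R, MAE, and RAE over repetitions, plus per-rep detail."""

    r_mean: float
    r_sd: float
    mae_mean: float
    mae_sd: float
    rae_mean: float
    rae_sd: float
    circular_mae_mean: float | None = None
    circular_mae_sd: float | None = None
    per_rep: pd.DataFrame = field(default_factory=pd.DataFrame, repr=False)
    pooled_predictions: np.ndarray | None = field(default=None, repr=False)

    def as_row(self) -> dict[str, float]:
        row = {
            "R": self.r_mean, "R_sd": self.r_sd,
            "MAE": self.mae_mean, "MAE_sd": self.mae_sd,
            "RAE_pct": self.rae_mean, "RAE_sd": self.rae_sd,
        }
        if self.circular_mae_mean is not None:
            row["circular_MAE"] = self.circular_mae_mean
            row["circular_MAE_sd"] = self.circular_mae_sd
        return row


def _mlr_fit(Xtr: np.ndarray, ytr: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Minimum-norm least squares on centered data; returns (beta, x_mean, y_mean)."""
    x_mean = Xtr.mean(axis=0)
    y_mean = ytr.mean()
    beta, *_ = np.linalg.lstsq(Xtr - x_mean, ytr - y_mean, rcond=None)
    return beta, x_mean, float(y_mean)


def _select_top_k(Xtr: np.ndarray, ytr: np.ndarray, k: int) -> np.ndarray:
    yc = ytr - ytr.mean()
    xc = Xtr - Xtr.mean(axis=0)
    denom = np.sqrt((xc ** 2).sum(axis=0) * (yc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.abs(xc.T @ yc) / np.where(denom > 0, denom, np.inf)
    r = np.nan_to_num(r)
    return np.argsort(r)[::-1][:k]


def fit_predict(
    model: ModelSpec,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
) -> np.ndarray:
    """Train one model and predict the test rows. Deterministic given data."""
    X_train = np.asarray(X_train, dtype=np.float64)
    X_test = np.asarray(X_test, dtype=np.float64)
    y_train = np.asarray(y_train, dtype=np.float64)
    if y_train.size == 0:
        raise ValueError("empty training set")
    if not (np.all(np.isfinite(X_train)) and np.all(np.isfinite(X_test))
            and np.all(np.isfinite(y_train))):
        raise ValueError("non-finite values in features or targets")

    if model.kind == "null":
        return np.full(X_test.shape[0], y_train.mean())

    if model.top_k is not None and model.top_k < X_train.shape[1]:
        keep = _select_top_k(X_train, y_train, model.top_k)
        X_train = X_train[:, keep]
        X_test = X_test[:, keep]

    if model.kind == "mlr":
        beta, x_mean, y_mean = _mlr_fit(X_train, y_train)
        return (X_test - x_mean) @ beta + y_mean

    svr = SVR(kernel="linear", C=model.C, epsilon=model.epsilon, tol=model.tol)
    # scale-stabilize the target for the optimizer, invert afterwards
    y_mean, y_sd = y_train.mean(), y_train.std()
    y_sd = y_sd if y_sd > 0 else 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        svr.fit(X_train, (y_train - y_mean) / y_sd)
    return svr.predict(X_test) * y_sd + y_mean


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    model: ModelSpec,
    protocol: CVProtocol | None = None,
    circular: bool = False,
) -> CVMetrics:
    """Repeated randomized k-fold evaluation of one model on one target.

    Per repetition the samples are shuffled and split into ``folds``
    test folds; test-fold predictions are pooled and scored. The null
    reference for RAE is trained on the identical folds, so the null
    model itself scores RAE = 100% with SD 0 by construction.

    With ``circular=True`` the target is minutes-of-day: predictions are
    additionally wrapped modulo 1440 and scored with the circular
    smallest-difference error.
    """
    if protocol is None:
        protocol = CVProtocol()
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n = y.size
    if n < 20:
        raise ValueError(f"need >= 20 samples for {protocol.folds}-fold CV, got {n}")
    if np.std(y) == 0:
        raise ValueError("target has zero variance")
    rng = np.random.default_rng(np.random.SeedSequence([protocol.rng_seed, 0xCF]))

    rows = []
    pooled_last = None
    for rep in range(protocol.repetitions):
        perm = rng.permutation(n)
        folds = np.array_split(perm, protocol.folds)
        preds = np.empty(n)
        null_preds = np.empty(n)
        for test_idx in folds:
            train_mask = np.ones(n, dtype=bool)
            train_mask[test_idx] = False
            preds[test_idx] = fit_predict(model, X[train_mask], y[train_mask],
                                          X[test_idx])
            null_preds[test_idx] = y[train_mask].mean()
        mae = float(np.mean(np.abs(preds - y)))
        mae_null = float(np.mean(np.abs(null_preds - y)))
        row = {
            "rep": rep,
            "R": 0.0 if model.kind == "null" else _pearson(preds, y),
            "MAE": mae,
            "RAE_pct": 100.0 * mae / mae_null if mae_null > 0 else np.nan,
        }
        if circular:
            wrapped = np.mod(preds, MINUTES_PER_DAY)
            row["circular_MAE"] = float(np.mean(
                [circular_error(p, o) for p, o in zip(wrapped, y)]))
        rows.append(row)
        pooled_last = preds
    per_rep = pd.DataFrame(rows)
    return CVMetrics(
        r_mean=float(per_rep["R"].mean()), r_sd=float(per_rep["R"].std(ddof=0)),
        mae_mean=float(per_rep["MAE"].mean()), mae_sd=float(per_rep["MAE"].std(ddof=0)),
        rae_mean=float(per_rep["RAE_pct"].mean()),
        rae_sd=float(per_rep["RAE_pct"].std(ddof=0)),
        circular_mae_mean=(float(per_rep["circular_MAE"].mean()) if circular else None),
        circular_mae_sd=(float(per_rep["circular_MAE"].std(ddof=0)) if circular else None),
        per_rep=per_rep,
        pooled_predictions=pooled_last,
    )


def range_normalized_mae(mae: float, value_range: float) -> float:
    """MAE as a percentage of the range of possible observations."""
    if value_range <= 0:
        raise ValueError(f"range must be > 0, got {value_range}")
    return 100.0 * mae / value_range


def denormalize_predictions(
    z_predictions: np.ndarray,
    subject_ids: np.ndarray,
    standardizer: ScoreStandardizer,
    test: str,
    observations: np.ndarray | None = None,
) -> tuple[np.ndarray, dict[str, float]]:
    """Map z-scale predictions back to original test units.

    Returns the de-normalized predictions and, when original-unit
    ``observations`` are given, the recomputed Pearson R and MAE. A
    subject absent from the standardizer raises KeyError.
    """
    preds = standardizer.invert(np.asarray(z_predictions, dtype=np.float64),
                                np.asarray(subject_ids), test)
    metrics: dict[str, float] = {}
    if observations is not None:
        obs = np.asarray(observations, dtype=np.float64)
        metrics["R"] = _pearson(preds, obs)
        metrics["MAE"] = float(np.mean(np.abs(preds - obs)))
    return preds, metrics


#: Model grids of the two experiments: time-and-latency targets use
#: speech models only; PPT targets add the time-only MLR baseline.
DEFAULT_MODELS = {
    "time_targets": (
        ModelSpec(kind="null"),
        ModelSpec(kind="mlr", inputs="speech"),
        ModelSpec(kind="svr", inputs="speech", C=1.0),
        ModelSpec(kind="svr", inputs="speech", C=0.01),
    ),
    "ppt_targets": (
        ModelSpec(kind="null"),
        ModelSpec(kind="mlr", inputs="time"),
        ModelSpec(kind="mlr", inputs="speech"),
        ModelSpec(kind="svr", inputs="speech", C=1.0),
        ModelSpec(kind="svr", inputs="speech", C=0.01),
    ),
}


def evaluate_all(
    speech_features: np.ndarray,
    time_features: np.ndarray,
    targets: dict[str, np.ndarray],
    protocol: CVProtocol | None = None,
    models: dict[str, tuple[ModelSpec, ...]] | None = None,
    circular_targets: tuple[str, ...] = ("phase_min",),
    ppt_targets: tuple[str, ...] = ("simple_rt_z", "planned_rt_z",
                                    "memory_z", "cognition_z"),
) -> pd.DataFrame:
    """Run the full (target x model) grid and return one row per cell.

    ``speech_features`` is the gaussianized (n x 1093) matrix;
    ``time_features`` the (n x 2) latency/phase matrix; ``targets`` maps
    target names to vectors. Targets listed in ``circular_targets`` are
    minutes-of-day and get circular scoring alongside the naive MAE.
    """
    if protocol is None:
        protocol = CVProtocol()
    if models is None:
        models = DEFAULT_MODELS
    rows = []
    for name, y in targets.items():
        grid = models["ppt_targets" if name in ppt_targets else "time_targets"]
        for spec in grid:
            X = time_features if spec.inputs == "time" and spec.kind != "null" \
                else speech_features
            try:
                m = cross_validate(X, y, spec, protocol,
                                   circular=name in circular_targets)
            except Exception as exc:
                raise RuntimeError(
                    f"cross-validation failed for target {name!r}, "
                    f"model {spec.label!r}: {exc}") from exc
            rows.append({"target": name, "model": spec.label, **m.as_row()})
    return pd.DataFrame(rows)
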