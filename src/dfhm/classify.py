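"""3-class workload SVM and the 0–100 moving-average workload index.

A support vector machine (RBF kernel, one-vs-one multiclass) labels each
DFHM segment low/moderate/high. The label stream (one label per 0.5 s)
is mapped {low → 0, moderate → 50, high → 100} and averaged over a
trailing 6-s window, giving a workload index that is 0 when every
segment in the window is low and 100 when every segment is high.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import joblib
import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC
from sklearn.utils.validation import check_array, check_X_y

__all__ = [
    "WorkloadLabel",
    "WorkloadClassifier",
    "WorkloadIndexSeries",
    "train",
    "classify",
    "workload_index",
    "condition_average",
    "save_model",
    "load_model",
]

CLASS_NAMES = ("low", "moderate", "high")
CLASS_SCORES = np.array([0.0, 50.0, 100.0])

MODEL_FORMAT = "dfhm-workload-model"
MODEL_VERSION = 1


@dataclass(frozen=True)
class WorkloadLabel:
    """One 3-class decision (0 = low, 1 = moderate, 2 = high) at a segment time."""

    value: int
    segment_time: float

    @property
    def name(self) -> str:
        return CLASS_NAMES[self.value]


class WorkloadClassifier(BaseEstimator, ClassifierMixin):
    """Multiclass SVM over DFHM vectors, sklearn estimator API.

    With ``C=None`` the regularization strength is chosen by stratified
    ``cv``-fold cross-validation over ``c_grid`` on the calibration set.
    Training is deterministic given the data and ``random_state`` (which
    seeds only the CV shuffling). Prediction uses SVC's one-vs-one
    multiclass reduction.
    """

    def __init__(
        self,
        kernel: str = "rbf",
        C: float | None = None,
        gamma="scale",
        cv: int = 5,
        c_grid: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0),
        random_state: int | None = 0,
    ):
        self.kernel = kernel
        self.C = C
        self.gamma = gamma
        self.cv = cv
        self.c_grid = c_grid
        self.random_state = random_state

    def fit(self, X, y) -> "WorkloadClassifier":
        X, y = check_X_y(X, y)
        classes = np.unique(y)
        if classes.size != 3:
            raise ValueError(
                f"need all 3 workload classes in training data, got {classes.tolist()}"
            )
        if min(np.bincount(y.astype(int), minlength=3)[classes.astype(int)]) < 2:
            raise ValueError("need >= 2 examples per class")
        if self.C is None:
            folds = StratifiedKFold(
                n_splits=self.cv, shuffle=True, random_state=self.random_state
            )
            search = GridSearchCV(
                SVC(kernel=self.kernel, gamma=self.gamma),
                {"C": list(self.c_grid)},
                cv=folds,
            )
            search.fit(X, y)
            self.C_ = float(search.best_params_["C"])
            self.cv_accuracy_ = float(search.best_score_)
            self.svm_ = search.best_estimator_
        else:
            self.C_ = float(self.C)
            self.cv_accuracy_ = None
            self.svm_ = SVC(kernel=self.kernel, C=self.C_, gamma=self.gamma).fit(X, y)
        self.classes_ = self.svm_.classes_
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"feature dimension {X.shape[1]} != model dimension "
                f"{self.n_features_in_}"
            )
        return self.svm_.predict(X)


def train(X, y, seed: int = 0, **params) -> WorkloadClassifier:
    """Fit a :class:`WorkloadClassifier` on labeled DFHM vectors."""
    return WorkloadClassifier(random_state=seed, **params).fit(X, y)


def classify(model: WorkloadClassifier, dfhms, times=None) -> list[WorkloadLabel]:
    """One :class:`WorkloadLabel` per DFHM row, at its segment time."""
    dfhms = np.asarray(dfhms, dtype=float)
    if dfhms.size == 0:
        return []
    pred = model.predict(dfhms)
    if times is None:
        times = np.arange(len(pred)) * 0.5
    times = np.asarray(times, dtype=float)
    if times.shape[0] != pred.shape[0]:
        raise ValueError("times and DFHM rows must align")
    return [WorkloadLabel(int(v), float(t)) for v, t in zip(pred, times)]


def save_model(model: WorkloadClassifier, path) -> None:
    """Versioned binary model container (joblib) with a metadata header."""
    payload = {
        "format": MODEL_FORMAT,
        "version": MODEL_VERSION,
        "metadata": {
            "kernel": model.kernel,
            "C": model.C_,
            "cv_accuracy": model.cv_accuracy_,
            "n_features": model.n_features_in_,
            "classes": model.classes_.tolist(),
            "random_state": model.random_state,
        },
        "estimator": model,
    }
    joblib.dump(payload, path)


def load_model(path) -> WorkloadClassifier:
    payload = joblib.load(path)
    if payload.get("format") != MODEL_FORMAT:
        raise ValueError("not a workload model file")
    if payload.get("version") != MODEL_VERSION:
        raise ValueError(f"unsupported model version {payload.get('version')}")
    return payload["estimator"]


@dataclass
class WorkloadIndexSeries:
    """Percentage workload index over time (trailing ``window``-s average)."""

    times: np.ndarray
    index: np.ndarray
    window: float = 6.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.index = np.asarray(self.index, dtype=float)
        if self.times.shape != self.index.shape:
            raise ValueError("times and index must align")
        if self.index.size and not (
            (self.index >= 0).all() and (self.index <= 100).all()
        ):
            raise ValueError("index must lie in [0, 100]")

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({"time": self.times, "index": self.index})


def workload_index(labels, window: float = 6.0) -> WorkloadIndexSeries:
    """Moving-average workload index from a label stream.

    ``labels`` is a list of :class:`WorkloadLabel` (or an integer array with
    implied 0.5-s spacing). The index at time t averages the class scores
    {0, 50, 100} of all labels in the trailing window (t − window, t]; it is
    defined from the first label on (a partially filled window averages the
    labels available so far).
    """
    if len(labels) == 0:
        return WorkloadIndexSeries(np.empty(0), np.empty(0), window)
    if isinstance(labels[0], WorkloadLabel):
        times = np.asarray([lb.segment_time for lb in labels], dtype=float)
        values = np.asarray([lb.value for lb in labels], dtype=int)
    else:
        values = np.asarray(labels, dtype=int)
        times = np.arange(values.size) * 0.5
    if np.any(np.diff(times) <= 0):
        raise ValueError("labels must be strictly time-ordered")
    scores = CLASS_SCORES[values]
    csum = np.concatenate([[0.0], np.cumsum(scores)])
    # left boundary: first label with time > t - window
    left = np.searchsorted(times, times - window, side="right")
    right = np.arange(1, times.size + 1)
    idx = (csum[right] - csum[left]) / (right - left)
    return WorkloadIndexSeries(times=times, index=idx, window=window)


def condition_average(
    series: WorkloadIndexSeries, intervals: dict[str, tuple[float, float]]
) -> dict[str, float]:
    """Arithmetic mean of the index over each [t0, t1) interval.

    An interval containing no samples yields NaN (flagged with a warning),
    never 0.
    """
    out: dict[str, float] = {}
    for name, (t0, t1) in intervals.items():
        mask = (series.times >= t0) & (series.times < t1)
        if not mask.any():
            warnings.warn(f"interval {name!r} contains no index samples", stacklevel=2)
            out[name] = float("nan")
        else:
            out[name] = float(series.index[mask].mean())
    return out
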