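"""SURG-TLX-targeted skill classification from approximate-entropy features.

Protocol
--------
1. Each of the six SURG-TLX questions is binarized across trials against
   its cohort mean: below the mean -> 0 (expert-like), above -> 1
   (novice-like); exact ties go to 0.
2. The time-series channels of a trial (heart rate plus hand and posture
   coordinates, eleven channels total) are each reduced to their
   approximate entropy, ApEn(m=2, r=0.2*sd), yielding one eleven-feature
   vector per trial.
3. Four classical classifiers (decision tree, k-NN, SVM, logistic
   regression) are exhaustively grid-searched over the enumerated
   parameter grids under leave-one-out or stratified k-fold
   cross-validation; the reported accuracy of a (classifier, question,
   scheme) cell is the mean out-of-fold accuracy of the best parameter
   combination.

ApEn uses Chebyshev distance with self-matches included:
``ApEn = Phi_m(r) - Phi_{m+1}(r)`` where ``Phi_m`` is the mean log
fraction of length-m templates within ``r`` of each template.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, KFold, LeaveOneOut, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .errors import (
    DegenerateTargetWarning,
    InsufficientDataError,
    MissingStreamError,
    SingleClassError,
    SurgStressError,
)
from .correlation import TrialRecord, synchronize
from .posture import RIGHT_ELBOW, RIGHT_SHOULDER

__all__ = [
    "FEATURE_COLUMNS",
    "TLX_QUESTIONS",
    "CVResult",
    "binarize_target",
    "approx_entropy",
    "build_feature_matrix",
    "dt_param_grid",
    "knn_param_grid",
    "svm_param_grid",
    "lr_param_grid",
    "grid_cardinality",
    "grid_search",
    "classification_report",
    "accuracy_matrix",
]

DEFAULT_SEED = 7919

FEATURE_COLUMNS = [
    "apen_hr",
    "apen_right_x",
    "apen_right_y",
    "apen_right_z",
    "apen_left_x",
    "apen_left_y",
    "apen_left_z",
    "apen_shoulder_x",
    "apen_shoulder_y",
    "apen_elbow_x",
    "apen_elbow_y",
]

TLX_QUESTIONS = [
    "Mental_fatigue",
    "Physical_fatigue",
    "Temporal_demands",
    "Complexity",
    "Situational_stress",
    "Distractions",
]

CLASSIFIERS = ("dt", "knn", "svm", "lr")


@dataclass(frozen=True)
class CVResult:
    """Outcome of one grid search: best parameters and their CV accuracy."""

    classifier: str
    target: str
    scheme: str
    best_params: dict
    accuracy: float


def binarize_target(scores) -> np.ndarray:
    """Binarize questionnaire responses against their mean.

    Below the mean -> 0 (expert class); above -> 1 (novice class); a score
    exactly at the mean goes to the expert class.  Emits
    :class:`DegenerateTargetWarning` if the result is single-class.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size < 2:
        raise InsufficientDataError("binarization requires >= 2 scores")
    labels = (scores > scores.mean()).astype(int)
    if np.unique(labels).size < 2:
        warnings.warn(
            "binarized target contains a single class", DegenerateTargetWarning
        )
    return labels


def _phi(dist0: np.ndarray, m: int, r: float) -> float:
    n = dist0.shape[0]
    nm = n - m + 1
    cheb = dist0[:nm, :nm].copy()
    for k in range(1, m):
        np.maximum(cheb, dist0[k : k + nm, k : k + nm], out=cheb)
    counts = (cheb <= r).sum(axis=1) / nm  # self-match included (diag = 0)
    return float(np.log(counts).mean())


def approx_entropy(series, m: int = 2, r: float | None = None) -> float:
    """Approximate entropy ApEn(m, r) with Chebyshev distance.

    ``r`` defaults to 0.2 times the population standard deviation of the
    series.  A constant series short-circuits to 0 (no information
    production).  Requires length >= m + 2.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be 1-D")
    if x.size < m + 2:
        raise InsufficientDataError(
            f"ApEn(m={m}) requires length >= {m + 2}, got {x.size}"
        )
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    if np.ptp(x) == 0:
        return 0.0
    if r is None:
        r = 0.2 * float(x.std())
    if not r > 0:
        raise ValueError("tolerance r must be positive")
    dist0 = np.abs(x[:, None] - x[None, :])
    return _phi(dist0, m, r) - _phi(dist0, m + 1, r)


def build_feature_matrix(
    trials: list[TrialRecord],
    grid_hz: float = 10.0,
    m: int = 2,
    r_factor: float = 0.2,
) -> tuple[pd.DataFrame, list[str]]:
    """One ApEn feature vector per trial from the eleven aligned channels.

    Channels: instantaneous heart rate (60000/RR, resampled onto the task
    grid), right/left hand x,y,z from the rebased trajectories, and right
    shoulder/elbow x,y from the posture stream.  Trials missing any
    channel are dropped and listed in the second return value.
    """
    rows = []
    index = []
    dropped: list[str] = []
    for i, trial in enumerate(trials):
        key = f"{trial.subject_id}/task{trial.task_id}"
        try:
            sync = synchronize(trial, grid_hz=grid_hz)
            grid = sync.left.t
            rr = trial.rr
            if rr.t[-1] < grid[0] or rr.t[0] > grid[-1]:
                raise MissingStreamError("RR series does not overlap the window")
            hr = np.interp(grid, rr.t, 60000.0 / rr.rr_ms)
            ts, xs, ys = sync.posture.for_landmark(RIGHT_SHOULDER)
            te, xe, ye = sync.posture.for_landmark(RIGHT_ELBOW)
            if ts.size == 0 or te.size == 0:
                raise MissingStreamError("posture landmarks missing")
            channels = [
                hr,
                sync.right.pos[:, 0],
                sync.right.pos[:, 1],
                sync.right.pos[:, 2],
                sync.left.pos[:, 0],
                sync.left.pos[:, 1],
                sync.left.pos[:, 2],
                xs,
                ys,
                xe,
                ye,
            ]
            rows.append(
                [
                    approx_entropy(c, m=m, r=r_factor * float(np.std(c)))
                    if np.ptp(c) > 0
                    else 0.0
                    for c in channels
                ]
            )
            index.append(key)
        except SurgStressError:
            dropped.append(key)
    features = pd.DataFrame(rows, columns=FEATURE_COLUMNS, index=index)
    return features, dropped


# --------------------------------------------------------------------------
# Parameter grids, enumerated as printed protocols enumerate them.

_C_VALUES = [1000, 500, 100, 50, 10, 5, 1, 0.5, 0.1]
_LR_C_VALUES = [0.1, 0.5, 1, 5, 10, 50, 100, 500, 1000]


def dt_param_grid() -> dict:
    """Decision-tree grid: 2 x 11 x 14 x 2 = 616 combinations.

    ``max_features`` spans None, 'sqrt', 'log2' and the fractions 0.1..0.9
    in steps of 0.1; the endpoint "1" is admitted under both readings that
    scikit-learn distinguishes -- the float 1.0 (all features) and the
    int 1 (a single feature) -- for 14 values in total.
    """
    return {
        "criterion": ["gini", "entropy"],
        "max_depth": [None, *range(1, 11)],
        "max_features": [
            None,
            "sqrt",
            "log2",
            *[round(0.1 * i, 1) for i in range(1, 10)],
            1.0,
            1,
        ],
        "splitter": ["best", "random"],
    }


def knn_param_grid(max_neighbors: int) -> dict:
    """k-NN grid; ``max_neighbors`` is the smallest training-fold size."""
    if max_neighbors < 1:
        raise ValueError("max_neighbors must be >= 1")
    return {
        "n_neighbors": list(range(1, max_neighbors + 1)),
        "weights": ["uniform", "distance"],
        "metric": ["euclidean", "manhattan", "minkowski"],
    }


def svm_param_grid() -> dict:
    """SVM grid: 9 x 4 x 11 = 396 combinations."""
    return {
        "C": _C_VALUES,
        "kernel": ["poly", "rbf", "sigmoid", "linear"],
        "gamma": ["auto", "scale", 1, 0.5, 0.1, 0.05, 0.01, 0.005, 0.001, 0.0005, 0.0001],
    }


def lr_param_grid() -> list[dict]:
    """Logistic-regression grid: 7 valid solver-penalty pairs x 9 C = 63.

    liblinear and saga admit both l1 and l2 penalties; newton-cg, lbfgs
    and sag admit l2 only, which is the usable-penalty pairing.
    """
    return [
        {
            "solver": ["liblinear", "saga"],
            "penalty": ["l1", "l2"],
            "C": _LR_C_VALUES,
        },
        {
            "solver": ["newton-cg", "lbfgs", "sag"],
            "penalty": ["l2"],
            "C": _LR_C_VALUES,
        },
    ]


def grid_cardinality(grid) -> int:
    """Number of parameter combinations in a grid (dict or list of dicts)."""
    if isinstance(grid, dict):
        return int(np.prod([len(v) for v in grid.values()]))
    return sum(grid_cardinality(g) for g in grid)


def _make_cv(scheme, n: int, y: np.ndarray, seed: int):
    """Return (cv splitter, scheme label, smallest training-fold size)."""
    if scheme == "loocv":
        return LeaveOneOut(), "LOOCV", n - 1
    k = int(scheme)
    if not 2 <= k <= n:
        raise ValueError(f"k-fold k must lie in 2..{n}, got {k}")
    if k == n:
        # singleton folds cannot be stratified; k = n is exactly LOOCV
        return KFold(n_splits=n), f"cv={k}", n - 1
    counts = np.bincount(y)
    if counts[counts > 0].min() < k:
        raise ValueError(
            f"k={k} exceeds the smallest class count ({counts[counts > 0].min()})"
        )
    max_test = math.ceil(n / k)
    return (
        StratifiedKFold(n_splits=k, shuffle=True, random_state=seed),
        f"cv={k}",
        n - max_test,
    )


def _make_search(classifier: str, max_neighbors: int, seed: int):
    if classifier == "dt":
        return DecisionTreeClassifier(random_state=seed), dt_param_grid()
    if classifier == "knn":
        return KNeighborsClassifier(), knn_param_grid(max_neighbors)
    if classifier == "svm":
        return SVC(), svm_param_grid()
    if classifier == "lr":
        return LogisticRegression(max_iter=500, random_state=seed), lr_param_grid()
    raise ValueError(f"unknown classifier '{classifier}'")


def grid_search(
    features: pd.DataFrame,
    target: np.ndarray,
    classifier: str,
    scheme="loocv",
    seed: int = DEFAULT_SEED,
    aggregate: str = "mean",
    param_grid=None,
) -> CVResult:
    """Exhaustive grid search of one classifier under one CV scheme.

    ``scheme`` is ``'loocv'`` or an integer k (stratified k-fold with
    seeded shuffling; k = n degenerates to LOOCV).  ``aggregate='mean'``
    ranks parameter combinations by mean out-of-fold accuracy (the
    default); ``'max'`` ranks by the best single fold, the alternative
    reading of reporting the best train/test split.  ``param_grid``
    overrides the enumerated default grid for the classifier.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(target, dtype=int)
    if np.unique(y).size < 2:
        raise SingleClassError("grid search requires >= 2 classes in the target")
    cv, label, min_train = _make_cv(scheme, len(y), y, seed)
    est, grid = _make_search(classifier, max_neighbors=min_train, seed=seed)
    if param_grid is not None:
        grid = param_grid
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        warnings.simplefilter("ignore", FutureWarning)
        gs = GridSearchCV(
            est,
            grid,
            scoring="accuracy",
            cv=cv,
            n_jobs=1,
            refit=False,
            error_score=np.nan,
        )
        gs.fit(X, y)
    res = gs.cv_results_
    mean = np.asarray(res["mean_test_score"], dtype=float)
    if aggregate == "mean":
        rank_scores = mean
    elif aggregate == "max":
        split_scores = np.vstack(
            [res[k] for k in sorted(res) if k.startswith("split") and k.endswith("_test_score")]
        )
        rank_scores = np.nanmax(split_scores, axis=0)
    else:
        raise ValueError("aggregate must be 'mean' or 'max'")
    best = int(np.nanargmax(rank_scores))
    return CVResult(
        classifier=classifier,
        target="",
        scheme=label,
        best_params=dict(res["params"][best]),
        accuracy=float(mean[best]),
    )


def classification_report(
    features: pd.DataFrame,
    targets: pd.DataFrame,
    classifiers=CLASSIFIERS,
    schemes=("loocv", 5, 10),
    seed: int = DEFAULT_SEED,
    aggregate: str = "mean",
) -> pd.DataFrame:
    """Grid-search every (question, classifier, scheme) cell.

    ``targets`` holds one binary column per SURG-TLX question.  Schemes
    infeasible for a target (k exceeding the smallest class count) are
    skipped.  Returns a tidy DataFrame with one row per evaluated cell.
    """
    records = []
    for question in targets.columns:
        y = np.asarray(targets[question], dtype=int)
        if np.unique(y).size < 2:
            continue
        for clf in classifiers:
            for scheme in schemes:
                try:
                    res = grid_search(
                        features, y, clf, scheme=scheme, seed=seed, aggregate=aggregate
                    )
                except (ValueError, SingleClassError):
                    continue
                records.append(
                    {
                        "target": question,
                        "classifier": clf,
                        "scheme": res.scheme,
                        "accuracy": res.accuracy,
                        "best_params": res.best_params,
                    }
                )
    return pd.DataFrame(
        records, columns=["target", "classifier", "scheme", "accuracy", "best_params"]
    )


def accuracy_matrix(records: pd.DataFrame) -> pd.DataFrame:
    """Pivot tidy CV records to a question x classifier accuracy matrix.

    Each cell holds the best scheme's accuracy, formatted
    ``"<scheme>:<accuracy to 6 decimals>"``.
    """
    def best_cell(sub: pd.DataFrame) -> str:
        top = sub.loc[sub["accuracy"].idxmax()]
        return f"{top['scheme']}:{top['accuracy']:.6f}"

    cells = {}
    for question in records["target"].unique():
        row = {}
        for clf in records["classifier"].unique():
            sub = records[(records["target"] == question) & (records["classifier"] == clf)]
            if not sub.empty:
                row[clf] = best_cell(sub)
        cells[question] = row
    return pd.DataFrame.from_dict(cells, orient="index")
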