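"""Per-group RBF-SVM classification of contact sets.

Decides, per contact set, whether a bipolar cell receives synaptic
input from a photoreceptor terminal, from the geometric feature vector
alone.  Separate classifiers are trained for the five biological
groups — OFF-CBC/cone, ON-CBC/cone, RBC/cone, OFF-CBC/rod and RBC/rod —
because the synaptic geometry differs (basal vs. invaginating, pedicle
vs. spherule).  The OFF-CBC/rod group additionally uses the distance to
the nearest synaptic RBC contact on the same rod, since basal OFF
contacts sit right next to the invaginating RBC dendrites.

Hyperparameters (C and the RBF kernel width) are selected on a fixed
logarithmic grid by maximising leave-one-out (LOO) cross-validation
accuracy; features are standardised inside each fold only, so no
information leaks from held-out samples into the scaler.  Class weights
are uniform: reported error rates are raw, as in the cross-validation
tables of the source analysis regime.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import GridSearchCV, LeaveOneOut, cross_val_predict
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .geometry import (
    FEATURE_NAMES,
    NON_SYNAPTIC,
    ROD_EXTRA_FEATURE,
    SYNAPTIC,
    ContactSet,
)

#: fixed hyperparameter grid (documented convention; the selection
#: criterion is LOO accuracy)
C_GRID = (0.1, 1.0, 10.0, 100.0)
GAMMA_GRID = (0.01, 0.1, 1.0, 10.0)


@dataclass(frozen=True)
class ClassifierGroup:
    """One of the five biological classifier groups."""

    name: str
    feature_names: tuple[str, ...]


CONE_FEATURES = FEATURE_NAMES
ROD_FEATURES = FEATURE_NAMES

GROUPS: dict[str, ClassifierGroup] = {
    "OFF_CBC_cone": ClassifierGroup("OFF_CBC_cone", CONE_FEATURES),
    "ON_CBC_cone": ClassifierGroup("ON_CBC_cone", CONE_FEATURES),
    "RBC_cone": ClassifierGroup("RBC_cone", CONE_FEATURES),
    "OFF_CBC_rod": ClassifierGroup(
        "OFF_CBC_rod", ROD_FEATURES + (ROD_EXTRA_FEATURE,)
    ),
    "RBC_rod": ClassifierGroup("RBC_rod", ROD_FEATURES),
}

#: ON-CBC cone classifiers are trained without CBCX contact sets, whose
#: contacts are atypical (mostly non-invaginating tip contacts)
ON_TRAINING_EXCLUDED_TYPES = ("CBCX",)


@dataclass
class CvReport:
    """Leave-one-out cross-validation summary.

    ``false_positive_rate`` = FP / (FP + TN), ``false_negative_rate`` =
    FN / (FN + TP) and ``total_score`` = (TP + TN) / n, with the
    synaptic class as positive.
    """

    false_positive_rate: float
    false_negative_rate: float
    total_score: float
    n_train: int
    confusion: dict[str, int]
    predictions: list[str] = field(default_factory=list)
    best_params: dict | None = None

    def as_dict(self) -> dict:
        return {
            "false_positive_rate": self.false_positive_rate,
            "false_negative_rate": self.false_negative_rate,
            "total_score": self.total_score,
            "n_train": self.n_train,
            "confusion": self.confusion,
            "best_params": self.best_params,
        }


class TrainedModel:
    """A fitted scaler+SVC pipeline plus its feature list."""

    def __init__(self, pipeline: Pipeline, group: ClassifierGroup, best_params: dict):
        self.pipeline = pipeline
        self.group = group
        self.best_params = best_params


def _design_matrix(sets: list[ContactSet], group: ClassifierGroup) -> np.ndarray:
    rows = []
    for s in sets:
        if s.features is None:
            raise ValueError(
                f"missing features for pair ({s.bc_id}, {s.terminal_id})"
            )
        try:
            rows.append([float(s.features[f]) for f in group.feature_names])
        except KeyError as e:
            raise ValueError(
                f"feature {e} missing for pair ({s.bc_id}, {s.terminal_id})"
            ) from None
    return np.array(rows, dtype=float)


def _labels(sets: list[ContactSet]) -> np.ndarray:
    y = np.array([1 if s.label == SYNAPTIC else 0 for s in sets])
    for s in sets:
        if s.label not in (SYNAPTIC, NON_SYNAPTIC):
            raise ValueError(f"unlabeled set ({s.bc_id}, {s.terminal_id})")
    return y


def _grid_search(X: np.ndarray, y: np.ndarray, seed: int) -> GridSearchCV:
    if len(np.unique(y)) < 2:
        raise ValueError("training set contains a single class")
    pipe = Pipeline(
        [("scaler", StandardScaler()), ("svc", SVC(kernel="rbf", random_state=seed))]
    )
    gs = GridSearchCV(
        pipe,
        {"svc__C": list(C_GRID), "svc__gamma": list(GAMMA_GRID)},
        cv=LeaveOneOut(),
        scoring="accuracy",
        n_jobs=1,
    )
    gs.fit(X, y)
    return gs


def train(
    labeled: list[ContactSet], group: ClassifierGroup | str, seed: int = 0
) -> TrainedModel:
    """Fit an RBF-SVM on labelled contact sets.

    Hyperparameters are selected by LOO accuracy on the fixed grid; the
    returned model carries its own standardisation (fitted on the full
    training set) for later prediction.
    """
    if isinstance(group, str):
        group = GROUPS[group]
    X = _design_matrix(labeled, group)
    y = _labels(labeled)
    gs = _grid_search(X, y, seed)
    return TrainedModel(gs.best_estimator_, group, dict(gs.best_params_))


def loo_cross_validate(
    labeled: list[ContactSet], group: ClassifierGroup | str, seed: int = 0
) -> CvReport:
    """Leave-one-out cross-validation with the selected hyperparameters.

    Each sample is predicted by a pipeline fitted on the remaining
    n − 1 samples (scaler statistics included), and the confusion
    counts are aggregated over folds.
    """
    if isinstance(group, str):
        group = GROUPS[group]
    X = _design_matrix(labeled, group)
    y = _labels(labeled)
    if len(y) < 3:
        raise ValueError("need at least 3 labelled sets for LOO validation")
    gs = _grid_search(X, y, seed)
    pipe = Pipeline(
        [
            ("scaler", StandardScaler()),
            (
                "svc",
                SVC(
                    kernel="rbf",
                    C=gs.best_params_["svc__C"],
                    gamma=gs.best_params_["svc__gamma"],
                    random_state=seed,
                ),
            ),
        ]
    )
    y_pred = cross_val_predict(pipe, X, y, cv=LeaveOneOut(), n_jobs=1)
    tp = int(np.sum((y == 1) & (y_pred == 1)))
    tn = int(np.sum((y == 0) & (y_pred == 0)))
    fp = int(np.sum((y == 0) & (y_pred == 1)))
    fn = int(np.sum((y == 1) & (y_pred == 0)))
    n = len(y)
    return CvReport(
        false_positive_rate=fp / (fp + tn) if (fp + tn) else 0.0,
        false_negative_rate=fn / (fn + tp) if (fn + tp) else 0.0,
        total_score=(tp + tn) / n,
        n_train=n,
        confusion={"tp": tp, "tn": tn, "fp": fp, "fn": fn},
        predictions=[SYNAPTIC if p else NON_SYNAPTIC for p in y_pred],
        best_params=dict(gs.best_params_),
    )


def predict(model: TrainedModel, sets: list[ContactSet]) -> list[ContactSet]:
    """Label contact sets with the trained model, preserving order."""
    if not sets:
        return []
    X = _design_matrix(sets, model.group)
    y = model.pipeline.predict(X)
    for s, p in zip(sets, y):
        s.label = SYNAPTIC if p else NON_SYNAPTIC
    return sets
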