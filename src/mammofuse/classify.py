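"""Clinical encoding, feature fusion with min-max scaling, and the linear SVM.

The combined model feeds 62 values per ROI to a linear-kernel SVM: 27 selected
deep features, 30 selected hand-crafted features and 5 ordinal-coded clinical
covariates, each scaled to [0, 1] by training-set extrema (test-time values
are clipped). The penalty C is chosen by stratified 10-fold cross-validated
grid search; ties break toward the smaller C.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

__all__ = [
    "ClinicalRecord",
    "FusedSample",
    "MinMaxScaler",
    "TrainedClassifier",
    "ARM_BLOCKS",
    "encode_clinical",
    "fuse_features",
    "train_svm",
    "predict",
]

DEFAULT_C_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)
CLINICAL_FEATURE_NAMES = ("clinical.shape", "clinical.margin", "clinical.composition", "clinical.age", "clinical.mass_size")

#: the seven model arms: which feature blocks each scheme fuses
ARM_BLOCKS = {
    "Hcr": ("hcr",),
    "Clinical": ("clinical",),
    "Hcr+Clinical": ("hcr", "clinical"),
    "Deep27": ("deep",),
    "Deep27+Hcr": ("deep", "hcr"),
    "Deep27+Clinical": ("deep", "clinical"),
    "Deep27+Clinical+Hcr": ("deep", "clinical", "hcr"),
}


@dataclass(frozen=True)
class ClinicalRecord:
    """The five clinical covariates with their ordinal codings.

    shape: 1 round, 2 oval, 3 irregular; margin: 1 clear, 2 shadow,
    3 differential leaf, 4 fuzzy, 5 glitch (spiculated); composition: 1 fatty
    … 4 extremely dense; age in years; mass size = ROI diagonal in pixels.
    """

    shape_code: int
    margin_code: int
    composition_code: int
    age_years: float
    mass_size: float

    def __post_init__(self) -> None:
        if self.shape_code not in (1, 2, 3):
            raise ValueError(f"shape_code must be in {{1,2,3}}, got {self.shape_code}")
        if self.margin_code not in (1, 2, 3, 4, 5):
            raise ValueError(f"margin_code must be in {{1..5}}, got {self.margin_code}")
        if self.composition_code not in (1, 2, 3, 4):
            raise ValueError(f"composition_code must be in {{1..4}}, got {self.composition_code}")
        if not (20.0 <= self.age_years <= 80.0):
            raise ValueError(f"age_years must lie in [20, 80], got {self.age_years}")
        if not self.mass_size > 0:
            raise ValueError(f"mass_size must be positive, got {self.mass_size}")


def encode_clinical(record: ClinicalRecord) -> np.ndarray:
    """Ordinal numeric vector (shape, margin, composition, age, mass_size)."""
    return np.array(
        [record.shape_code, record.margin_code, record.composition_code, record.age_years, record.mass_size],
        dtype=np.float64,
    )


@dataclass
class MinMaxScaler:
    """Per-feature [0, 1] rescaling by training-set extrema, clipping at test time."""

    mins: np.ndarray
    maxs: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "MinMaxScaler":
        X = np.asarray(X, dtype=np.float64)
        return cls(mins=X.min(axis=0), maxs=X.max(axis=0))

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        span = self.maxs - self.mins
        out = np.zeros_like(X)
        nz = span > 0
        out[:, nz] = (X[:, nz] - self.mins[nz]) / span[nz]
        return np.clip(out, 0.0, 1.0)


@dataclass
class FusedSample:
    values: np.ndarray  # 27 deep + 30 hand-crafted + 5 clinical, scaled to [0,1]
    roi_id: str = ""
    label: str | None = None


def fuse_features(
    deep: np.ndarray,
    hcr: np.ndarray,
    clinical: np.ndarray,
    scaler: MinMaxScaler | None = None,
    roi_ids: Sequence[str] | None = None,
    labels: Sequence | None = None,
) -> tuple[list[FusedSample], MinMaxScaler]:
    """Concatenate the three blocks (n x 27, n x 30, n x 5) and min-max scale.

    With ``scaler=None`` the extrema are fitted on the given rows (training
    mode); a fitted scaler applies training extrema and clips to [0, 1].
    """
    deep = np.atleast_2d(np.asarray(deep, dtype=np.float64))
    hcr = np.atleast_2d(np.asarray(hcr, dtype=np.float64))
    clinical = np.atleast_2d(np.asarray(clinical, dtype=np.float64))
    if deep.shape[1] != 27:
        raise ValueError(f"deep block must have 27 columns, got {deep.shape[1]}")
    if hcr.shape[1] != 30:
        raise ValueError(f"hand-crafted block must have 30 columns, got {hcr.shape[1]}")
    if clinical.shape[1] != 5:
        raise ValueError(f"clinical block must have 5 columns, got {clinical.shape[1]}")
    X = np.hstack([deep, hcr, clinical])
    if scaler is None:
        scaler = MinMaxScaler.fit(X)
    Xs = scaler.transform(X)
    n = Xs.shape[0]
    ids = list(roi_ids) if roi_ids is not None else [""] * n
    labs = list(labels) if labels is not None else [None] * n
    samples = [FusedSample(values=Xs[i], roi_id=ids[i], label=labs[i]) for i in range(n)]
    return samples, scaler


@dataclass
class TrainedClassifier:
    svc: SVC
    scaler: MinMaxScaler | None
    feature_names: list[str]
    c_grid: list[float]
    cv_table: dict[float, float]  # C -> mean CV accuracy
    best_c: float
    cv_folds: int
    seed: int

    def to_json(self, path: str | Path) -> None:
        d = {
            "feature_names": self.feature_names,
            "c_grid": self.c_grid,
            "cv_table": {str(k): v for k, v in self.cv_table.items()},
            "best_c": self.best_c,
            "cv_folds": self.cv_folds,
            "seed": self.seed,
            "coef": self.svc.coef_.ravel().tolist(),
            "intercept": float(self.svc.intercept_[0]),
            "scaler": None
            if self.scaler is None
            else {"mins": self.scaler.mins.tolist(), "maxs": self.scaler.maxs.tolist()},
        }
        Path(path).write_text(json.dumps(d, indent=2))


def _as_xy(samples, feature_names=None):
    if isinstance(samples, (list, tuple)) and samples and isinstance(samples[0], FusedSample):
        X = np.vstack([s.values for s in samples])
        y = np.array([1 if s.label == "malignant" else 0 for s in samples])
        return X, y
    raise TypeError("expected a list of FusedSample; use the array API via train_svm(X=..., y=...)")


def train_svm(
    samples=None,
    grid: Sequence[float] = DEFAULT_C_GRID,
    folds: int = 10,
    seed: int = 0,
    X: np.ndarray | None = None,
    y: np.ndarray | None = None,
    feature_names: Sequence[str] | None = None,
    scaler: MinMaxScaler | None = None,
) -> TrainedClassifier:
    """Linear-kernel SVM with stratified k-fold grid search over the penalty C.

    Accepts either a list of :class:`FusedSample` or explicit ``X``/``y``
    arrays (already scaled). On CV-accuracy ties the smaller C wins.
    """
    if samples is not None:
        X, y = _as_xy(samples)
        labs = [s.label for s in samples]
    else:
        if X is None or y is None:
            raise ValueError("provide either samples or X and y")
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("degenerate training set: a single class present")
    n_folds = min(folds, int(counts.min()))
    if n_folds < 2:
        raise ValueError(f"need at least 2 samples per class for cross-validation, got {counts.min()}")
    names = list(feature_names) if feature_names is not None else [f"x{i}" for i in range(X.shape[1])]

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    cv_table: dict[float, float] = {}
    best_c, best_acc = None, -np.inf
    for c in grid:  # ascending grid + strict improvement = ties favor small C
        accs = []
        for tr, te in splits:
            clf = SVC(kernel="linear", C=c)
            clf.fit(X[tr], y[tr])
            accs.append(float((clf.predict(X[te]) == y[te]).mean()))
        mean_acc = float(np.mean(accs))
        cv_table[float(c)] = mean_acc
        if mean_acc > best_acc:
            best_c, best_acc = float(c), mean_acc
    final = SVC(kernel="linear", C=best_c)
    final.fit(X, y)
    return TrainedClassifier(
        svc=final,
        scaler=scaler,
        feature_names=names,
        c_grid=[float(c) for c in grid],
        cv_table=cv_table,
        best_c=best_c,
        cv_folds=n_folds,
        seed=seed,
    )


def predict(
    clf: TrainedClassifier,
    samples=None,
    X: np.ndarray | None = None,
    feature_names: Sequence[str] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Thresholded labels (1 = malignant) and signed decision scores."""
    if samples is not None:
        X, _ = _as_xy(samples)
    if X is None:
        raise ValueError("provide either samples or X")
    X = np.asarray(X, dtype=np.float64)
    if feature_names is not None and list(feature_names) != clf.feature_names:
        raise ValueError("feature names do not match the trained classifier")
    if X.shape[1] != len(clf.feature_names):
        raise ValueError(
            f"expected {len(clf.feature_names)} features ({clf.feature_names[:3]}…), got {X.shape[1]}"
        )
    scores = clf.svc.decision_function(X)
    labels = (scores > 0).astype(int)
    return labels, scores
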