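"""Minimal-redundancy–maximal-relevance (mRMR) feature ranking.

Continuous features are discretized by equal-frequency binning (rank-based, so
any strictly monotone transform of a column leaves the ranking unchanged);
mutual information is measured in bits. Greedy forward selection scores each
candidate by relevance MI(x; y) penalized by its mean MI with the features
already selected — as a difference (MID) or a quotient (MIQ).

Applied per feature block: the 455 hand-crafted features are reduced to 30 and
the 1024 deep features to 27, each ranked independently on training rows only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SelectionResult",
    "discretize",
    "mutual_information",
    "mrmr_rank",
    "select_pipeline_features",
]

DEFAULT_BINS = 4
DEFAULT_K_HANDCRAFTED = 30
DEFAULT_K_DEEP = 27

@dataclass
class SelectionResult:
    ranked_names: list[str]
    scores: list[float]  # greedy objective value at each step
    k: int
    scheme: Literal["MID", "MIQ"]
    bins: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "ranked_names": self.ranked_names,
                    "scores": self.scores,
                    "k": self.k,
                    "scheme": self.scheme,
                    "bins": self.bins,
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SelectionResult":
        d = json.loads(Path(path).read_text())
        return cls(**d)


def discretize(x: np.ndarray, bins: int) -> np.ndarray:
    """Equal-frequency integer codes; constant columns collapse to one code."""
    x = np.asarray(x, dtype=np.float64)
    codes = pd.qcut(x, q=bins, labels=False, duplicates="drop")
    codes = np.asarray(codes)
    if np.isnan(codes).any():  # qcut yields NaN when all values identical
        return np.zeros(x.shape[0], dtype=np.int64)
    return codes.astype(np.int64)


def _code_mi(a: np.ndarray, b: np.ndarray) -> float:
    """Plug-in MI in bits between two integer code vectors (contingency based)."""
    na = int(a.max()) + 1
    nb = int(b.max()) + 1
    joint = np.bincount(a * nb + b, minlength=na * nb).reshape(na, nb)
    p = joint / joint.sum()
    pa = p.sum(axis=1, keepdims=True)
    pb = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float((p[nz] * np.log2(p[nz] / (pa @ pb)[nz])).sum())


def _label_codes(y: np.ndarray) -> np.ndarray:
    return np.unique(np.asarray(y), return_inverse=True)[1].astype(np.int64)


def mutual_information(x: np.ndarray, y: np.ndarray, bins: int = DEFAULT_BINS) -> float:
    """MI in bits between an equal-frequency-discretized column and labels."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape[0] != y.shape[0] or x.shape[0] < 2:
        raise ValueError("x and y must have the same length >= 2")
    return _code_mi(discretize(x, bins), _label_codes(y))


def mrmr_rank(
    features: pd.DataFrame | np.ndarray,
    labels: Sequence,
    k: int,
    scheme: Literal["MID", "MIQ"] = "MID",
    bins: int = DEFAULT_BINS,
    names: Sequence[str] | None = None,
) -> SelectionResult:
    """Greedy mRMR forward selection of ``k`` feature columns.

    The first pick maximizes relevance; each later pick maximizes
    ``relevance - mean_redundancy`` (MID) or ``relevance / mean_redundancy``
    (MIQ). Ties break deterministically toward the earlier column.
    """
    if isinstance(features, pd.DataFrame):
        names = list(features.columns)
        X = features.to_numpy(dtype=np.float64)
    else:
        X = np.asarray(features, dtype=np.float64)
        names = list(names) if names is not None else [f"f{i}" for i in range(X.shape[1])]
    if k <= 0:
        raise ValueError("k must be positive")
    if k > X.shape[1]:
        raise ValueError(f"k={k} exceeds the {X.shape[1]} available columns")
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("labels must contain at least 2 classes")
    if X.shape[0] != y.shape[0]:
        raise ValueError("features and labels are not row-aligned")

    n_feat = X.shape[1]
    ycodes = _label_codes(y)
    codes = [discretize(X[:, j], bins) for j in range(n_feat)]
    relevance = np.array([_code_mi(c, ycodes) for c in codes])

    selected: list[int] = []
    scores: list[float] = []
    # accumulated redundancy sum MI(candidate, s) over selected s
    red_sum = np.zeros(n_feat)
    remaining = list(range(n_feat))
    for step in range(k):
        if step == 0:
            obj = relevance.copy()
        else:
            mean_red = red_sum / len(selected)
            if scheme == "MID":
                obj = relevance - mean_red
            elif scheme == "MIQ":
                obj = relevance / np.maximum(mean_red, 1e-12)
            else:
                raise ValueError(f"unknown mRMR scheme: {scheme}")
        best, best_val = None, -np.inf
        for j in remaining:
            if obj[j] > best_val:
                best, best_val = j, obj[j]
        selected.append(best)
        scores.append(float(best_val))
        remaining.remove(best)
        for j in remaining:
            red_sum[j] += _code_mi(codes[j], codes[best])
    return SelectionResult(
        ranked_names=[names[j] for j in selected],
        scores=scores,
        k=k,
        scheme=scheme,
        bins=bins,
    )


def select_pipeline_features(
    handcrafted: pd.DataFrame,
    deep: pd.DataFrame | None,
    labels: Sequence,
    k_handcrafted: int = DEFAULT_K_HANDCRAFTED,
    k_deep: int = DEFAULT_K_DEEP,
    scheme: Literal["MID", "MIQ"] = "MID",
    bins: int = DEFAULT_BINS,
    joint: bool = False,
) -> tuple[SelectionResult, SelectionResult | None]:
    """Rank the hand-crafted and deep blocks independently (default) or jointly.

    Must be fitted on training rows only; callers pass training-cohort frames.
    """
    y = np.asarray(labels)
    if handcrafted.shape[0] != y.shape[0] or (deep is not None and deep.shape[0] != y.shape[0]):
        raise ValueError("feature matrices and labels are not row-aligned")
    if joint and deep is not None:
        merged = pd.concat([handcrafted, deep], axis=1)
        res = mrmr_rank(merged, y, k=k_handcrafted + k_deep, scheme=scheme, bins=bins)
        hcr_names = [n for n in res.ranked_names if n in handcrafted.columns]
        deep_names = [n for n in res.ranked_names if n in deep.columns]
        hcr = SelectionResult(hcr_names, [], len(hcr_names), scheme, bins)
        dee = SelectionResult(deep_names, [], len(deep_names), scheme, bins)
        return hcr, dee
    hcr = mrmr_rank(handcrafted, y, k=min(k_handcrafted, handcrafted.shape[1]), scheme=scheme, bins=bins)
    dee = None
    if deep is not None:
        dee = mrmr_rank(deep, y, k=min(k_deep, deep.shape[1]), scheme=scheme, bins=bins)
    return hcr, dee
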