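"""Feature selection: PCA and greedy mRMR (maximum relevance, minimum redundancy).

Both are wrapped in a common fit/transform SelectionModel that is only ever
fitted on training folds; transforming before fitting raises, which is how
test-fold leakage is made impossible at the API level.

mRMR follows the mutual-information difference (MID) criterion: the first
feature maximizes I(f; y); each subsequent feature maximizes
I(f; y) − (1/|S|) Σ_{g∈S} I(f; g). Continuous features are discretized into
three levels at mean ± SD before mutual information is computed. Greedy ties
break toward the lowest feature index, making selection deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
from sklearn.decomposition import PCA


class NotFittedError(RuntimeError):
    pass


@dataclass
class SelectionModel:
    """A fitted (or yet-unfitted) dimensionality-reduction step.

    kind: "pca", "mrmr" or "none"; k is the retained dimensionality
    (ignored for "none").
    """

    kind: str = "none"
    k: int = 1
    fitted: bool = False
    # PCA state
    components: Optional[np.ndarray] = None     # (k, p)
    train_mean: Optional[np.ndarray] = None
    explained_variance: Optional[np.ndarray] = None
    # mRMR state
    selected_indices: Optional[list[int]] = None
    mrmr_criterion: str = "mid"

    def __post_init__(self) -> None:
        if self.kind not in ("pca", "mrmr", "none"):
            raise ValueError(f"unknown selection kind: {self.kind}")
        if self.kind != "none" and self.k < 1:
            raise ValueError("k must be >= 1")

    def fit(self, X: np.ndarray, y: Optional[np.ndarray] = None) -> "SelectionModel":
        X = np.asarray(X, dtype=np.float64)
        if self.kind == "pca":
            if self.k > min(X.shape[0] - 1, X.shape[1]):
                raise ValueError(
                    f"k={self.k} exceeds min(n_samples-1, n_features)="
                    f"{min(X.shape[0] - 1, X.shape[1])}")
            p = PCA(n_components=self.k, svd_solver="full")
            p.fit(X)
            self.components = p.components_
            self.train_mean = p.mean_
            self.explained_variance = p.explained_variance_
        elif self.kind == "mrmr":
            if y is None:
                raise ValueError("mRMR requires labels")
            self.selected_indices = _mrmr_greedy(X, np.asarray(y), self.k,
                                                 criterion=self.mrmr_criterion)
        self.fitted = True
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise NotFittedError("SelectionModel.transform called before fit")
        X = np.asarray(X, dtype=np.float64)
        if self.kind == "pca":
            return (X - self.train_mean) @ self.components.T
        if self.kind == "mrmr":
            return X[:, self.selected_indices]
        return X

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X, y).transform(X)

    # --- serialization (versioned JSON artifact) -------------------------
    def to_json(self, path: str | Path) -> None:
        doc = {"format_version": 1, "kind": self.kind, "k": self.k,
               "fitted": self.fitted, "mrmr_criterion": self.mrmr_criterion}
        if self.kind == "pca" and self.fitted:
            doc["components"] = self.components.tolist()
            doc["train_mean"] = self.train_mean.tolist()
            doc["explained_variance"] = self.explained_variance.tolist()
        if self.kind == "mrmr" and self.fitted:
            doc["selected_indices"] = list(map(int, self.selected_indices))
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def from_json(cls, path: str | Path) -> "SelectionModel":
        doc = json.loads(Path(path).read_text())
        m = cls(kind=doc["kind"], k=doc["k"], mrmr_criterion=doc.get("mrmr_criterion", "mid"))
        m.fitted = doc["fitted"]
        if "components" in doc:
            m.components = np.asarray(doc["components"])
            m.train_mean = np.asarray(doc["train_mean"])
            m.explained_variance = np.asarray(doc["explained_variance"])
        if "selected_indices" in doc:
            m.selected_indices = list(doc["selected_indices"])
        return m


def discretize_msd(x: np.ndarray) -> np.ndarray:
    """Three-level discretization at mean ± SD (below / within / above)."""
    mu, sd = x.mean(), x.std()
    out = np.ones(x.shape, dtype=np.intp)
    out[x < mu - sd] = 0
    out[x > mu + sd] = 2
    return out


def mutual_information(a: np.ndarray, b: np.ndarray) -> float:
    """Mutual information (nats) of two discrete sequences."""
    a = np.asarray(a)
    b = np.asarray(b)
    ua, ia = np.unique(a, return_inverse=True)
    ub, ib = np.unique(b, return_inverse=True)
    joint = np.zeros((len(ua), len(ub)))
    np.add.at(joint, (ia, ib), 1.0)
    joint /= joint.sum()
    pa = joint.sum(axis=1, keepdims=True)
    pb = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float((joint[nz] * np.log(joint[nz] / (pa @ pb)[nz])).sum())


def _mrmr_greedy(X: np.ndarray, y: np.ndarray, k: int, criterion: str = "mid") -> list[int]:
    n, p = X.shape
    if k > p:
        raise ValueError(f"k={k} exceeds number of features {p}")
    Xd = np.column_stack([discretize_msd(X[:, j]) for j in range(p)])
    relevance = np.array([mutual_information(Xd[:, j], y) for j in range(p)])
    selected: list[int] = [int(np.argmax(relevance))]
    pair_mi = np.full((p, p), np.nan)
    while len(selected) < k:
        best_j, best_score = -1, -np.inf
        for j in range(p):
            if j in selected:
                continue
            red = 0.0
            for s in selected:
                if np.isnan(pair_mi[j, s]):
                    pair_mi[j, s] = pair_mi[s, j] = mutual_information(Xd[:, j], Xd[:, s])
                red += pair_mi[j, s]
            red /= len(selected)
            if criterion == "mid":
                score = relevance[j] - red
            elif criterion == "miq":
                score = relevance[j] / (red + 1e-12)
            else:
                raise ValueError(f"unknown mRMR criterion: {criterion}")
            if score > best_score:   # strict >: ties keep the lowest index
                best_score, best_j = score, j
        selected.append(best_j)
    return selected


# --- spec-level convenience wrappers ------------------------------------

def pca_fit(X: np.ndarray, k: int) -> SelectionModel:
    """Fit a k-component PCA on a training matrix."""
    return SelectionModel(kind="pca", k=k).fit(X)


def pca_transform(model: SelectionModel, X: np.ndarray) -> np.ndarray:
    return model.transform(X)


def mrmr_select(X: np.ndarray, y: np.ndarray, k: int, criterion: str = "mid") -> SelectionModel:
    """Greedy mRMR selection of k features against a binary target."""
    y = np.asarray(y)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("y must be binary (0/1)")
    return SelectionModel(kind="mrmr", k=k, mrmr_criterion=criterion).fit(X, y)
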