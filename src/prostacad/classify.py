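"""Classical classifiers: SVM, gradient-boosted trees (XGBoost), MLP.

All families share a probability-output contract (scores in [0, 1], label =
score >= threshold) and a feature-name contract: a trained model remembers
the names/order of the columns it was fitted on and refuses inputs that
disagree. Hyperparameter optimisation is a seeded random search over the
family's search dimensions (regularization/kernel/class weight for the SVM;
learning rate, tree depth, leaf count for the GBT; layer layout for the
MLP), scored by mean inner-CV AUC-ROC.

The packaged best whole-image SVM preset uses an RBF SVM with the
regularization parameter C = 60 ("error tolerance" 60) on 95 principal
components.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from xgboost import XGBClassifier

FAMILIES = ("svm", "gbt", "mlp")

DEFAULT_HYPERPARAMS = {
    "svm": {"C": 60.0, "kernel": "rbf", "class_weight": "balanced"},
    "gbt": {"learning_rate": 0.1, "max_depth": 3, "max_leaves": 15, "n_estimators": 200},
    "mlp": {"hidden_layer_sizes": (64, 32), "alpha": 1e-3, "max_iter": 800},
}

DEFAULT_SEARCH_SPACES = {
    "svm": {"C": [0.1, 1.0, 10.0, 60.0, 100.0],
            "kernel": ["rbf", "linear"],
            "class_weight": ["balanced", None]},
    "gbt": {"learning_rate": [0.01, 0.05, 0.1, 0.3],
            "max_depth": [2, 3, 4, 6],
            "max_leaves": [7, 15, 31]},
    "mlp": {"hidden_layer_sizes": [(32,), (64,), (64, 32), (128, 64)],
            "alpha": [1e-4, 1e-3, 1e-2]},
}


@dataclass
class ModelSpec:
    """A classifier family plus its hyperparameters and seed."""

    family: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0
    class_weighting: bool = True

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        hp = dict(DEFAULT_HYPERPARAMS[self.family])
        hp.update(self.hyperparameters)
        self.hyperparameters = hp


def best_whole_image_svm_spec(seed: int = 0) -> ModelSpec:
    """The packaged best whole-image SVM configuration (C = 60, RBF),
    intended to be paired with a 95-component PCA."""
    return ModelSpec(family="svm", hyperparameters={"C": 60.0, "kernel": "rbf"}, seed=seed)


def _build_estimator(spec: ModelSpec, y: np.ndarray):
    hp = spec.hyperparameters
    if spec.family == "svm":
        # No Platt probability calibration: SVM confidences are the decision
        # margin squashed through a logistic, keeping the family fully
        # deterministic (independent of the seed).
        return SVC(C=hp["C"], kernel=hp["kernel"],
                   class_weight=hp["class_weight"] if spec.class_weighting else None)
    if spec.family == "gbt":
        n_pos = int((y == 1).sum())
        n_neg = int((y == 0).sum())
        spw = (n_neg / n_pos) if (spec.class_weighting and n_pos > 0) else 1.0
        return XGBClassifier(
            learning_rate=hp["learning_rate"], max_depth=hp["max_depth"],
            max_leaves=hp["max_leaves"], n_estimators=hp.get("n_estimators", 200),
            scale_pos_weight=spw, tree_method="hist",
            random_state=spec.seed, n_jobs=1, eval_metric="logloss")
    if spec.family == "mlp":
        # sklearn's MLP has no class_weight; imbalance is left to the data
        return MLPClassifier(hidden_layer_sizes=tuple(hp["hidden_layer_sizes"]),
                             alpha=hp["alpha"], max_iter=hp.get("max_iter", 800),
                             random_state=spec.seed)
    raise AssertionError(spec.family)


@dataclass
class TrainedClassifier:
    spec: ModelSpec
    estimator: object
    feature_names: Optional[list[str]] = None

    def _check_contract(self, X):
        if isinstance(X, pd.DataFrame):
            if self.feature_names is not None:
                got = list(X.columns)
                if got != self.feature_names:
                    for i, (a, b) in enumerate(zip(got, self.feature_names)):
                        if a != b:
                            raise ValueError(
                                f"feature contract violated at column {i}: "
                                f"got {a!r}, expected {b!r}")
                    raise ValueError(
                        f"feature contract violated: {len(got)} columns supplied, "
                        f"{len(self.feature_names)} expected")
            return X.to_numpy(dtype=np.float64)
        X = np.asarray(X, dtype=np.float64)
        expect = len(self.feature_names) if self.feature_names is not None else X.shape[1]
        if X.shape[1] != expect:
            raise ValueError(f"expected {expect} features, got {X.shape[1]}")
        return X

    def predict_proba(self, X) -> np.ndarray:
        """Confidence for the malignant (positive) class in [0, 1], one per row."""
        Xv = self._check_contract(X)
        if isinstance(self.estimator, SVC):
            margin = self.estimator.decision_function(Xv)
            return 1.0 / (1.0 + np.exp(-margin))
        proba = self.estimator.predict_proba(Xv)
        classes = list(self.estimator.classes_)
        return np.clip(proba[:, classes.index(1)], 0.0, 1.0)

    def predict_label(self, X, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(X) >= threshold).astype(int)


def train(X, y, spec: ModelSpec, feature_names: Optional[list[str]] = None
          ) -> TrainedClassifier:
    """Fit one classifier; deterministic given (X, y, spec, spec.seed)."""
    if isinstance(X, pd.DataFrame):
        feature_names = list(X.columns)
        X = X.to_numpy(dtype=np.float64)
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    if not np.all(np.isfinite(X)):
        raise ValueError("training matrix contains non-finite values")
    est = _build_estimator(spec, y)
    est.fit(X, y)
    return TrainedClassifier(spec=spec, estimator=est, feature_names=feature_names)


def predict_proba(model: TrainedClassifier, X) -> np.ndarray:
    return model.predict_proba(X)


def _iter_space(search_space: dict) -> list[dict]:
    from itertools import product
    keys = sorted(search_space)
    return [dict(zip(keys, combo)) for combo in product(*(search_space[k] for k in keys))]


def hyperparameter_search(X, y, family: str, search_space: Optional[dict] = None,
                          budget: int = 20, seed: int = 0, n_inner_folds: int = 3
                          ) -> tuple[ModelSpec, pd.DataFrame]:
    """Seeded random search scored by mean inner-CV AUC-ROC.

    Samples up to ``budget`` distinct configurations from the search space
    (all of them if the space is smaller) and returns the best ModelSpec
    together with the full trial log.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    space = search_space if search_space is not None else DEFAULT_SEARCH_SPACES[family]
    combos = _iter_space(space)
    if not combos:
        raise ValueError("empty search space")
    rng = np.random.default_rng(seed)
    if len(combos) > budget:
        idx = rng.choice(len(combos), size=budget, replace=False)
        combos = [combos[i] for i in sorted(idx)]
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y).astype(int)
    skf = StratifiedKFold(n_splits=n_inner_folds, shuffle=True, random_state=seed)
    rows = []
    for hp in combos:
        spec = ModelSpec(family=family, hyperparameters=hp, seed=seed)
        aucs = []
        for tr, va in skf.split(X, y):
            model = train(X[tr], y[tr], spec)
            aucs.append(roc_auc_score(y[va], model.predict_proba(X[va])))
        rows.append({"hyperparameters": hp, "mean_cv_auc": float(np.mean(aucs))})
    log = pd.DataFrame(rows)
    best = log["mean_cv_auc"].idxmax()
    best_spec = ModelSpec(family=family, hyperparameters=log.loc[best, "hyperparameters"],
                          seed=seed)
    return best_spec, log
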