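"""Comparison classifiers: Random Forest, linear SVM, neural network.

These are benchmark baselines around the conditional inference forest:

* Random Forest — bagged CART trees (sklearn ``DecisionTreeClassifier``
  with sqrt(p) feature sampling, bootstrap with replacement). Bagging is
  done here rather than via ``RandomForestClassifier`` so each tree's
  bootstrap indices are retained for out-of-bag permutation importance
  (mean decrease accuracy) alongside the impurity importance (mean
  decrease Gini).
* Linear soft-margin SVM — libsvm via sklearn ``SVC(kernel="linear")``,
  cost 1, even class weights; features min-max scaled to [0, 1] on the
  training fold only. Decision values are mapped monotonically to [0, 1],
  which leaves ranking metrics such as the AUC unchanged.
* Neural network — multilayer perceptron with hidden layers (100, 50),
  logistic activations, SGD with learning rate 0.005 and momentum 0.9,
  up to 500 epochs with early stop on a training-loss plateau; no feature
  scaling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from cnvclassify.cforest import CfConfig, ConditionalForest

MODEL_KINDS = ("cforest", "rf", "svm_linear", "nn")


@dataclass
class ModelSpec:
    """A classifier kind plus its hyperparameters and seed.

    ``hyperparameters`` overrides kind-specific defaults; for
    kind="cforest" they are ``CfConfig`` fields.
    """

    kind: str = "cforest"
    hyperparameters: Dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}")


class MinMaxScaler:
    """Per-feature min-max scaler to [0, 1], fitted on training data only.

    Test values outside the training range are clipped; a constant
    training column maps to 0.
    """

    def __init__(self) -> None:
        self.min_: Optional[np.ndarray] = None
        self.range_: Optional[np.ndarray] = None

    def fit(self, X: np.ndarray) -> "MinMaxScaler":
        X = np.asarray(X, dtype=float)
        self.min_ = X.min(axis=0)
        self.range_ = X.max(axis=0) - self.min_
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.min_ is None:
            raise RuntimeError("scaler not fitted")
        X = np.asarray(X, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(self.range_ > 0, (X - self.min_) / self.range_, 0.0)
        return np.clip(out, 0.0, 1.0)


class RandomForestModel:
    """Bagged CART trees with OOB tracking for both importance metrics."""

    def __init__(self, n_trees: int = 500, seed: int = 0, max_features: str = "sqrt"):
        self.n_trees = n_trees
        self.seed = seed
        self.max_features = max_features
        self.trees_: List[DecisionTreeClassifier] = []
        self.inbag_: List[np.ndarray] = []
        self.X_: Optional[np.ndarray] = None
        self.y_: Optional[np.ndarray] = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RandomForestModel":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        rng = np.random.default_rng(self.seed)
        n = X.shape[0]
        self.trees_, self.inbag_ = [], []
        for _ in range(self.n_trees):
            inbag = rng.integers(0, n, size=n)  # bootstrap with replacement
            tree = DecisionTreeClassifier(
                max_features=self.max_features,
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            tree.fit(X[inbag], y[inbag])
            self.trees_.append(tree)
            self.inbag_.append(inbag)
        self.X_, self.y_ = X, y
        return self

    def _tree_case_prob(self, tree: DecisionTreeClassifier, X: np.ndarray) -> np.ndarray:
        proba = tree.predict_proba(X)
        if proba.shape[1] == 1:  # single-class tree
            return np.full(X.shape[0], float(tree.classes_[0]))
        return proba[:, list(tree.classes_).index(1)]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        acc = np.zeros(X.shape[0])
        for tree in self.trees_:
            acc += self._tree_case_prob(tree, X)
        return acc / len(self.trees_)

    def importances(self, seed: Optional[int] = None) -> Tuple[np.ndarray, np.ndarray]:
        """(MDA, MeanDecreaseGini) per feature.

        MDA: per-tree OOB accuracy drop after permuting the feature's OOB
        values, averaged over trees. MDG: total impurity decrease
        attributable to the feature, averaged over trees.
        """
        if self.X_ is None:
            raise RuntimeError("forest not fitted")
        rng = np.random.default_rng(self.seed + 1 if seed is None else seed)
        n, p = self.X_.shape
        mda = np.zeros(p)
        mdg = np.zeros(p)
        all_idx = np.arange(n)
        for tree, inbag in zip(self.trees_, self.inbag_):
            mdg += _unnormalized_gini_importance(tree, p)
            oob = np.setdiff1d(all_idx, np.unique(inbag))
            if len(oob) == 0:
                continue
            Xo, yo = self.X_[oob], self.y_[oob]
            base = float(((self._tree_case_prob(tree, Xo) >= 0.5).astype(int) == yo).mean())
            used = np.unique(tree.tree_.feature[tree.tree_.feature >= 0])
            for f in used:
                Xp = Xo.copy()
                Xp[:, f] = Xp[rng.permutation(len(oob)), f]
                perm = float(((self._tree_case_prob(tree, Xp) >= 0.5).astype(int) == yo).mean())
                mda[f] += base - perm
        return mda / len(self.trees_), mdg / len(self.trees_)


def _unnormalized_gini_importance(tree: DecisionTreeClassifier, p: int) -> np.ndarray:
    t = tree.tree_
    imp = np.zeros(p)
    for node in range(t.node_count):
        f = t.feature[node]
        if f < 0:
            continue
        l, r = t.children_left[node], t.children_right[node]
        dec = (
            t.weighted_n_node_samples[node] * t.impurity[node]
            - t.weighted_n_node_samples[l] * t.impurity[l]
            - t.weighted_n_node_samples[r] * t.impurity[r]
        )
        imp[f] += dec
    return imp


def rf_importances(model: RandomForestModel) -> Tuple[np.ndarray, np.ndarray]:
    """Convenience wrapper: (MDA, MeanDecreaseGini) of a fitted RF."""
    return model.importances()


def _as_arrays(X_train, y_train, X_test):
    Xtr = X_train.to_numpy(dtype=float) if isinstance(X_train, pd.DataFrame) else np.asarray(X_train, dtype=float)
    Xte = X_test.to_numpy(dtype=float) if isinstance(X_test, pd.DataFrame) else np.asarray(X_test, dtype=float)
    ytr = np.asarray(y_train, dtype=int)
    if not (np.isfinite(Xtr).all() and np.isfinite(Xte).all()):
        raise ValueError("non-finite feature values")
    return Xtr, ytr, Xte


def build_model(spec: ModelSpec):
    """Instantiate the (unfitted) classifier a ModelSpec describes."""
    hp = dict(spec.hyperparameters)
    if spec.kind == "cforest":
        hp.setdefault("seed", spec.seed)
        return ConditionalForest(CfConfig(**hp))
    if spec.kind == "rf":
        return RandomForestModel(n_trees=hp.get("n_trees", 500), seed=spec.seed)
    if spec.kind == "svm_linear":
        return SVC(kernel="linear", C=hp.get("cost", 1.0), class_weight=None, random_state=spec.seed)
    # nn
    return MLPClassifier(
        hidden_layer_sizes=hp.get("hidden_layer_sizes", (100, 50)),
        activation=hp.get("activation", "logistic"),
        solver="sgd",
        learning_rate_init=hp.get("learning_rate", 0.005),
        momentum=hp.get("momentum", 0.9),
        nesterovs_momentum=False,
        max_iter=hp.get("max_epochs", 500),
        tol=hp.get("tol", 1e-5),
        n_iter_no_change=hp.get("patience", 20),
        random_state=spec.seed,
    )


def fit_predict(spec: ModelSpec, X_train, y_train, X_test) -> np.ndarray:
    """Fit the spec'd classifier on the training fold, score the test fold.

    Returns case probabilities in [0, 1]. SVM decision values are min-max
    mapped over the test fold (rank-preserving, so AUC is unchanged).
    Everything trainable — including the SVM scaler — sees only the
    training fold.
    """
    Xtr, ytr, Xte = _as_arrays(X_train, y_train, X_test)
    model = build_model(spec)
    if spec.kind == "svm_linear":
        scaler = MinMaxScaler().fit(Xtr)
        model.fit(scaler.transform(Xtr), ytr)
        dec = model.decision_function(scaler.transform(Xte))
        lo, hi = dec.min(), dec.max()
        return (dec - lo) / (hi - lo) if hi > lo else np.full(len(dec), 0.5)
    if spec.kind == "nn":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            model.fit(Xtr, ytr)
        proba = model.predict_proba(Xte)
        return proba[:, list(model.classes_).index(1)]
    model.fit(Xtr, ytr)
    return model.predict_proba(Xte)
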