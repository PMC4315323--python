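"""From-scratch Conditional Inference Tree / Forest binary classifier.

Ordinary classification trees pick split variables by maximal impurity
decrease, which is positively biased towards features offering many cut
points. A conditional inference tree instead selects the split variable by
a permutation-test association between each candidate feature and the
label, on the samples at the node: the linear statistic

    T = sum_i x_i * 1[y_i = case]

is standardized by its exact mean and variance under random permutation of
the labels, and the feature with the smallest (Bonferroni-adjusted over the
``mtry`` candidates) p-value wins. Because every candidate is reduced to
one standardized statistic, features with different value cardinality
compete on equal footing. The cut point then maximizes the standardized
two-sample statistic among thresholds honoring the minimum child size.

The forest aggregates trees grown on subsamples drawn WITHOUT replacement
(0.632 of the data by default); out-of-bag samples support permutation
variable importance (mean decrease accuracy, MDA).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.special import erfc

__all__ = ["CfConfig", "CfTree", "ConditionalForest", "node_association_test"]

_FORMAT_VERSION = 1


@dataclass
class CfConfig:
    """Forest construction settings.

    Defaults follow the unbiased-forest convention: 500 trees, 5 candidate
    features per node, 63.2% subsampling without replacement, minimum node
    size 20 to attempt a split, minimum child size 7, and no significance
    stopping (alpha = 1 grows until the size limits bite). ``test_type``
    picks the standardized form of the node test: "quadratic" (chi-square
    of the standardized statistic) or "max_abs" (two-sided normal tail);
    for a single numeric feature against a binary label the two give the
    same p-value.
    """

    n_trees: int = 500
    mtry: int = 5
    subsample_fraction: float = 0.632
    min_split: int = 20
    min_bucket: int = 7
    alpha: float = 1.0
    test_type: str = "quadratic"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.subsample_fraction < 1):
            raise ValueError("subsample_fraction must be in (0, 1)")
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must be in (0, 1]")
        if self.mtry < 1:
            raise ValueError("mtry must be >= 1")
        if self.test_type not in ("quadratic", "max_abs"):
            raise ValueError(f"unknown test_type {self.test_type!r}")


def _standardized_stats(X: np.ndarray, y: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Standardized permutation statistic and variance per column of X.

    T_j = sum_i X_ij * y_i with y in {0,1}. Under random permutation of y,
    E[T_j] = n1 * mean(X_j) and
    Var[T_j] = n1 (n - n1) / (n (n-1)) * sum_i (X_ij - mean(X_j))^2
    (variance of a without-replacement sample sum). Returns (z, var) with
    z = 0 where var == 0 (constant column).
    """
    n = X.shape[0]
    n1 = int(y.sum())
    sumx = X.sum(axis=0)
    t = X.T @ y
    mu = n1 * sumx / n
    css = (X * X).sum(axis=0) - sumx * sumx / n  # centered sum of squares
    var = n1 * (n - n1) / (n * (n - 1)) * css
    var = np.clip(var, 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(var > 0, (t - mu) / np.sqrt(var), 0.0)
    return z, var


def _pvalues(z: np.ndarray, var: np.ndarray, test_type: str) -> np.ndarray:
    # quadratic: z^2 ~ chi2(1); max_abs: two-sided normal — identical tails
    # for a univariate statistic, kept separate for clarity of intent.
    p = erfc(np.abs(z) / math.sqrt(2.0))
    return np.where(var > 0, p, 1.0)


def node_association_test(
    x: Sequence[float], y: Sequence[int], test_type: str = "quadratic"
) -> Tuple[float, float]:
    """Permutation-based association test between one feature and the label.

    Returns (standardized statistic, asymptotic two-sided p-value). The
    statistic is z for test_type="max_abs" and z**2 for "quadratic"; the
    p-value is the same either way. Constant x returns p = 1. Raises if
    only one class is present (the caller must not test pure nodes).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if len(x) < 2:
        raise ValueError("need at least 2 samples")
    if y.min() == y.max():
        raise ValueError("single-class node: association test undefined")
    z, var = _standardized_stats(x[:, None], y)
    p = float(_pvalues(z, var, test_type)[0])
    stat = float(z[0] ** 2) if test_type == "quadratic" else float(z[0])
    return stat, p


def _best_split(x: np.ndarray, y: np.ndarray, min_bucket: int) -> Optional[Tuple[float, float]]:
    """Best threshold for one feature: maximize the standardized two-sample
    statistic over splits ``x <= t`` honoring min_bucket on both children.

    Returns (threshold, |z|) or None when no admissible split exists.
    """
    n = len(x)
    order = np.argsort(x, kind="stable")
    xs = x[order]
    ys = y[order]
    # prefix counts at the last position of each distinct value
    last = np.nonzero(np.diff(xs))[0]  # xs[last] < xs[last+1]
    if len(last) == 0:
        return None
    m = last + 1  # left-child sizes per candidate threshold
    c = np.cumsum(ys)[last]  # cases in left child
    n1 = ys.sum()
    ok = (m >= min_bucket) & (n - m >= min_bucket)
    if not ok.any():
        return None
    m, c, last = m[ok], c[ok], last[ok]
    # z for indicator split variables: T = c, E = n1 m / n,
    # Var = n1 (n-n1) m (n-m) / (n^2 (n-1))
    var = n1 * (n - n1) * m * (n - m) / (n * n * (n - 1))
    z = np.abs(c - n1 * m / n) / np.sqrt(var)
    k = int(np.argmax(z))
    thr = (xs[last[k]] + xs[last[k] + 1]) / 2.0
    return float(thr), float(z[k])


@dataclass
class CfTree:
    """A grown conditional inference tree in flat-array form.

    ``feature[i] == -1`` marks a leaf; ``prob[i]`` is the case proportion
    of the node's training samples. Internal nodes route ``x <= threshold``
    left.
    """

    feature: np.ndarray
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    prob: np.ndarray

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        node = np.zeros(X.shape[0], dtype=np.int64)
        active = self.feature[node] >= 0
        while active.any():
            rows = np.nonzero(active)[0]
            nd = node[rows]
            xv = X[rows, self.feature[nd]]
            go_left = xv <= self.threshold[nd]
            node[rows] = np.where(go_left, self.left[nd], self.right[nd])
            active = self.feature[node] >= 0
        return self.prob[node]

    def used_features(self) -> np.ndarray:
        return np.unique(self.feature[self.feature >= 0])

    def to_dict(self) -> Dict:
        return {
            "feature": self.feature.tolist(),
            "threshold": self.threshold.tolist(),
            "left": self.left.tolist(),
            "right": self.right.tolist(),
            "prob": self.prob.tolist(),
        }

    @classmethod
    def from_dict(cls, d: Dict) -> "CfTree":
        return cls(
            feature=np.asarray(d["feature"], dtype=np.int64),
            threshold=np.asarray(d["threshold"], dtype=float),
            left=np.asarray(d["left"], dtype=np.int64),
            right=np.asarray(d["right"], dtype=np.int64),
            prob=np.asarray(d["prob"], dtype=float),
        )


def _grow_tree(X: np.ndarray, y: np.ndarray, cfg: CfConfig, rng: np.random.Generator) -> CfTree:
    n_features = X.shape[1]
    mtry = min(cfg.mtry, n_features)
    feature: List[int] = []
    threshold: List[float] = []
    left: List[int] = []
    right: List[int] = []
    prob: List[float] = []

    def new_node() -> int:
        feature.append(-1)
        threshold.append(np.nan)
        left.append(-1)
        right.append(-1)
        prob.append(np.nan)
        return len(feature) - 1

    def build(idx: np.ndarray) -> int:
        node = new_node()
        yn = y[idx]
        prob[node] = float(yn.mean())
        n = len(idx)
        if n < cfg.min_split or yn.min() == yn.max():
            return node
        cand = rng.choice(n_features, size=mtry, replace=False)
        Xn = X[np.ix_(idx, cand)]
        z, var = _standardized_stats(Xn, yn.astype(float))
        if not (var > 0).any():
            return node  # all candidates constant at this node
        p = _pvalues(z, var, cfg.test_type)
        k = int(np.argmin(p))  # candidate order already rng-shuffled
        n_valid = int((var > 0).sum())
        p_adj = min(1.0, n_valid * p[k])
        if p_adj > cfg.alpha:
            return node
        split = _best_split(X[idx, cand[k]], yn.astype(float), cfg.min_bucket)
        if split is None:
            return node
        thr, _ = split
        go_left = X[idx, cand[k]] <= thr
        feature[node] = int(cand[k])
        threshold[node] = thr
        left[node] = build(idx[go_left])
        right[node] = build(idx[~go_left])
        return node

    build(np.arange(X.shape[0]))
    return CfTree(
        feature=np.asarray(feature, dtype=np.int64),
        threshold=np.asarray(threshold, dtype=float),
        left=np.asarray(left, dtype=np.int64),
        right=np.asarray(right, dtype=np.int64),
        prob=np.asarray(prob, dtype=float),
    )


class ConditionalForest:
    """Conditional inference forest for binary case/control classification.

    Labels are 0 (control) / 1 (case); ``predict_proba`` returns the case
    probability as the mean over trees of the leaf case proportion.
    Fitting is deterministic given ``config.seed``.
    """

    def __init__(self, config: Optional[CfConfig] = None):
        self.config = config or CfConfig()
        self.trees_: List[CfTree] = []
        self.inbag_: List[np.ndarray] = []
        self.feature_names_: Optional[List[str]] = None
        self.n_samples_: int = 0

    # -- helpers ----------------------------------------------------------
    def _as_array(self, X, check_names: bool) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            if check_names and self.feature_names_ is not None:
                if list(X.columns) != self.feature_names_:
                    if set(X.columns) == set(self.feature_names_):
                        X = X[self.feature_names_]
                    else:
                        raise ValueError(
                            "feature names do not match the fitted forest"
                        )
            return X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if check_names and self.feature_names_ is not None and X.shape[1] != len(self.feature_names_):
            raise ValueError("feature count does not match the fitted forest")
        return X

    # -- API --------------------------------------------------------------
    def fit(self, X, y) -> "ConditionalForest":
        if isinstance(X, pd.DataFrame):
            self.feature_names_ = list(X.columns)
        Xa = self._as_array(X, check_names=False)
        ya = np.asarray(y, dtype=int)
        if not np.isfinite(Xa).all():
            raise ValueError("non-finite feature values")
        if set(np.unique(ya)) - {0, 1}:
            raise ValueError("labels must be binary 0/1")
        n = Xa.shape[0]
        self.n_samples_ = n
        n_inbag = int(math.floor(self.config.subsample_fraction * n))
        rng = np.random.default_rng(self.config.seed)
        self.trees_ = []
        self.inbag_ = []
        for _ in range(self.config.n_trees):
            inbag = np.sort(rng.choice(n, size=n_inbag, replace=False))
            tree = _grow_tree(Xa[inbag], ya[inbag], self.config, rng)
            self.trees_.append(tree)
            self.inbag_.append(inbag)
        return self

    def predict_proba(self, X) -> np.ndarray:
        if not self.trees_:
            raise RuntimeError("forest not fitted")
        Xa = self._as_array(X, check_names=True)
        acc = np.zeros(Xa.shape[0])
        for tree in self.trees_:
            acc += tree.predict_proba(Xa)
        return acc / len(self.trees_)

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X) >= 0.5).astype(int)

    def varimp_mda(self, X, y, seed: Optional[int] = None) -> np.ndarray:
        """Out-of-bag permutation importance (mean decrease accuracy).

        Per tree: accuracy on its OOB samples minus accuracy after
        permuting one feature's OOB values; averaged over all trees (a
        tree that never uses the feature contributes exactly 0). This is
        the standard, correlation-unadjusted MDA.
        """
        if not self.trees_:
            raise RuntimeError("forest not fitted")
        Xa = self._as_array(X, check_names=True)
        ya = np.asarray(y, dtype=int)
        if Xa.shape[0] != self.n_samples_:
            raise ValueError("varimp requires the training data the forest was fitted on")
        rng = np.random.default_rng(self.config.seed + 1 if seed is None else seed)
        n, p = Xa.shape
        imp = np.zeros(p)
        all_idx = np.arange(n)
        for tree, inbag in zip(self.trees_, self.inbag_):
            oob = np.setdiff1d(all_idx, inbag, assume_unique=False)
            if len(oob) == 0:
                continue
            Xo = Xa[oob]
            yo = ya[oob]
            base_acc = float(((tree.predict_proba(Xo) >= 0.5).astype(int) == yo).mean())
            for f in tree.used_features():
                Xp = Xo.copy()
                Xp[:, f] = Xp[rng.permutation(len(oob)), f]
                perm_acc = float(((tree.predict_proba(Xp) >= 0.5).astype(int) == yo).mean())
                imp[f] += base_acc - perm_acc
        return imp / len(self.trees_)

    # -- persistence ------------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "format_version": _FORMAT_VERSION,
                "config": asdict(self.config),
                "feature_names": self.feature_names_,
                "n_samples": self.n_samples_,
                "inbag": [ib.tolist() for ib in self.inbag_],
                "trees": [t.to_dict() for t in self.trees_],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ConditionalForest":
        d = json.loads(text)
        if d.get("format_version") != _FORMAT_VERSION:
            raise ValueError("unsupported model format version")
        forest = cls(CfConfig(**d["config"]))
        forest.feature_names_ = d["feature_names"]
        forest.n_samples_ = d["n_samples"]
        forest.inbag_ = [np.asarray(ib, dtype=np.int64) for ib in d["inbag"]]
        forest.trees_ = [CfTree.from_dict(t) for t in d["trees"]]
        return forest
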