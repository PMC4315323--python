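"""Training-fold-only feature selection.

Three strategies over the gene-set burden features, always excluding the
total gene count from ranking and budget and re-appending it afterwards:

* ``mda`` — rank by a relevance score (by default the conditional
  forest's out-of-bag permutation importance) and cut to the budget.
* ``mda_decorrelated`` — walk the ranking, dropping any feature whose
  absolute Pearson correlation with an already-kept feature exceeds the
  threshold, then cut to the budget.
* ``mrmr`` — greedy minimum-redundancy maximum-relevance on mutual
  information over discretized counts: start from the most
  label-relevant feature, then repeatedly add argmax of
  relevance − mean pairwise redundancy (the MID difference criterion;
  MIQ quotient available by flag).

Selection must only ever see the training fold; the cross-validation
driver enforces this by construction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import mutual_info_score

from cnvclassify.cforest import CfConfig, ConditionalForest
from cnvclassify.features import TOTAL_FEATURE

METHODS = ("none", "manual_list", "mda", "mda_decorrelated", "mrmr")
BUDGETS = ("top20", "top15pct", "top40pct")


@dataclass
class SelectionSpec:
    """Feature-selection method, budget and numeric knobs."""

    method: str = "none"
    budget: str = "top20"
    correlation_threshold: float = 0.75
    discretization_cap: int = 3  # counts binned as {0, 1, 2, >=cap}
    mrmr_criterion: str = "mid"  # or "miq"
    manual_features: Optional[List[str]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown selection method {self.method!r}")
        if self.budget not in BUDGETS:
            raise ValueError(f"unknown budget {self.budget!r}")
        if self.mrmr_criterion not in ("mid", "miq"):
            raise ValueError(f"unknown MRMR criterion {self.mrmr_criterion!r}")


def resolve_budget(budget: str, n_features: int) -> int:
    """Number of features to keep; percentages are of the pool excluding
    the total gene count, rounded to nearest (at least 1)."""
    if budget == "top20":
        k = 20
    elif budget == "top15pct":
        k = max(1, round(0.15 * n_features))
    else:
        k = max(1, round(0.40 * n_features))
    return min(k, n_features)


def default_mda_relevance(X: pd.DataFrame, y: np.ndarray, seed: int = 0, n_trees: int = 100) -> np.ndarray:
    """Relevance via conditional-forest OOB permutation importance."""
    forest = ConditionalForest(CfConfig(n_trees=n_trees, seed=seed)).fit(X, y)
    return forest.varimp_mda(X, y)


def _discretize(x: np.ndarray, cap: int) -> np.ndarray:
    return np.minimum(np.asarray(x), cap).astype(int)


def select_features(
    spec: SelectionSpec,
    X_train: pd.DataFrame,
    y_train: Sequence[int],
    relevance_fn: Optional[Callable[[pd.DataFrame, np.ndarray], np.ndarray]] = None,
) -> List[str]:
    """Pick features on the training fold; returns ordered kept names.

    The total gene count never competes for the budget and is appended
    last if absent from the selection.
    """
    y = np.asarray(y_train, dtype=int)
    pool = [c for c in X_train.columns if c != TOTAL_FEATURE]
    has_total = TOTAL_FEATURE in X_train.columns

    if spec.method == "none":
        kept = list(pool)
    elif spec.method == "manual_list":
        if spec.manual_features is None:
            raise ValueError("manual_list selection requires manual_features")
        missing = [f for f in spec.manual_features if f not in X_train.columns]
        if missing:
            raise ValueError(f"manual features absent from the matrix: {missing[:5]}")
        kept = [f for f in spec.manual_features if f != TOTAL_FEATURE]
    else:
        k = resolve_budget(spec.budget, len(pool))
        if k >= len(pool) and spec.method != "mda_decorrelated":
            warnings.warn("selection budget covers the whole feature pool", stacklevel=2)
        if spec.method in ("mda", "mda_decorrelated"):
            fn = relevance_fn or (
                lambda X, yy: default_mda_relevance(X, yy, seed=spec.seed)
            )
            rel = np.asarray(fn(X_train[pool], y), dtype=float)
            order = np.argsort(-rel, kind="stable")
            ranked = [pool[i] for i in order]
            if spec.method == "mda":
                kept = ranked[:k]
            else:
                kept = _decorrelate(ranked, X_train, spec.correlation_threshold)[:k]
        else:  # mrmr
            kept = _mrmr(X_train[pool], y, k, spec)

    if has_total and TOTAL_FEATURE not in kept:
        kept = kept + [TOTAL_FEATURE]
    return kept


def _decorrelate(ranked: List[str], X: pd.DataFrame, threshold: float) -> List[str]:
    kept: List[str] = []
    for f in ranked:
        x = X[f].to_numpy(dtype=float)
        ok = True
        for g in kept:
            r = _pearson(x, X[g].to_numpy(dtype=float))
            if abs(r) > threshold:
                ok = False
                break
        if ok:
            kept.append(f)
    return kept


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _mrmr(X: pd.DataFrame, y: np.ndarray, k: int, spec: SelectionSpec) -> List[str]:
    cols = list(X.columns)
    disc = {c: _discretize(X[c].to_numpy(), spec.discretization_cap) for c in cols}
    relevance = {c: mutual_info_score(disc[c], y) for c in cols}
    # deterministic: ties broken by column order via max() stability
    selected = [max(cols, key=lambda c: (relevance[c], -cols.index(c)))]
    red_cache: Dict[tuple, float] = {}

    def redundancy(a: str, b: str) -> float:
        key = (a, b) if a < b else (b, a)
        if key not in red_cache:
            red_cache[key] = mutual_info_score(disc[a], disc[b])
        return red_cache[key]

    while len(selected) < min(k, len(cols)):
        best, best_score = None, -math.inf
        for c in cols:
            if c in selected:
                continue
            red = float(np.mean([redundancy(c, s) for s in selected]))
            if spec.mrmr_criterion == "mid":
                score = relevance[c] - red
            else:
                score = relevance[c] / red if red > 0 else math.inf
            if score > best_score:
                best, best_score = c, score
        selected.append(best)
    return selected
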