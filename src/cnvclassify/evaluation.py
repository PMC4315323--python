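"""Cross-validation protocol, AUC, stability-based subject prioritization.

The evaluation protocol is repeated stratified k-fold cross-validation:
each iteration re-divides the cohort into k folds with the case/control
proportion preserved, every subject receives exactly one out-of-fold case
probability per iteration, and one AUC per iteration is computed from the
pooled out-of-fold probabilities. The mean and standard deviation of the
AUC over iterations quantify the classifier's stochasticity.

Subject prioritization then asks which cases the classifier calls
confidently AND reproducibly: a subject is "stably case-predicted" at a
probability cutoff if the out-of-fold probability reaches the cutoff in at
least ``s`` of the iterations (default 15 of 20). The cutoff is scanned
over a grid; among cutoffs where the stably-predicted fraction of cases
WITHOUT pathogenic or de novo CNVs (TP*, the conservative true-positive
pool) exceeds the stably-mispredicted control fraction (FP) by more than a
ratio ``r`` (default 1.5x), the one maximizing the TP* count is reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from cnvclassify.features import FeatureMatrix
from cnvclassify.models import ModelSpec, fit_predict
from cnvclassify.selection import SelectionSpec, select_features
from cnvclassify.types import Subject

__all__ = [
    "CvConfig",
    "CvRun",
    "PrioritizationReport",
    "stratified_folds",
    "auc",
    "run_cv",
    "scan_cutoff",
    "pct_explained",
    "sex_enrichment",
]


# ---------------------------------------------------------------------------
# Folds and AUC
# ---------------------------------------------------------------------------

def stratified_folds(labels: Sequence[int], k: int, rng: np.random.Generator) -> np.ndarray:
    """Assign each subject to one of k folds, stratified by class.

    Per-class fold sizes differ by at most one; every subject lands in
    exactly one fold.
    """
    y = np.asarray(labels, dtype=int)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    folds = np.full(len(y), -1, dtype=int)
    for cls in classes:
        idx = np.nonzero(y == cls)[0]
        if k > len(idx):
            raise ValueError(f"k={k} exceeds class size {len(idx)}")
        idx = rng.permutation(idx)
        for f, chunk in enumerate(np.array_split(idx, k)):
            folds[chunk] = f
    return folds


def auc(case_scores: Sequence[float], control_scores: Sequence[float]) -> float:
    """Probability a random case outscores a random control, ties 1/2.

    The rank-sum (Mann-Whitney) form: U / (n_case * n_control).
    """
    cases = np.asarray(case_scores, dtype=float)
    controls = np.asarray(control_scores, dtype=float)
    if len(cases) == 0 or len(controls) == 0:
        raise ValueError("both classes need at least one score")
    ranks = stats.rankdata(np.concatenate([cases, controls]))
    u = ranks[: len(cases)].sum() - len(cases) * (len(cases) + 1) / 2
    return float(u / (len(cases) * len(controls)))


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CvConfig:
    """Repeated stratified CV settings: 20 iterations of 3 folds."""

    n_iterations: int = 20
    k: int = 3
    seed: int = 0


@dataclass
class CvRun:
    """Out-of-fold case probabilities and per-iteration AUCs.

    ``probs`` is subjects x iterations (one out-of-fold probability per
    subject per iteration); ``aucs`` has one entry per iteration.
    """

    probs: pd.DataFrame
    aucs: np.ndarray
    labels: pd.Series
    config: CvConfig

    @property
    def mean_auc(self) -> float:
        return float(self.aucs.mean())

    @property
    def sd_auc(self) -> float:
        return float(self.aucs.std(ddof=1))

    def summary(self) -> Dict[str, float]:
        return {
            "n_subjects": int(len(self.probs)),
            "n_iterations": int(self.config.n_iterations),
            "mean_auc": self.mean_auc,
            "sd_auc": self.sd_auc,
        }

    def to_long_frame(self) -> pd.DataFrame:
        """(iteration, subject_id, prob) long-form table for persistence."""
        long = self.probs.reset_index(names="subject_id").melt(
            id_vars="subject_id", var_name="iteration", value_name="prob"
        )
        return long.sort_values(["iteration", "subject_id"]).reset_index(drop=True)


def _derive_seed(base: int, iteration: int, fold: int) -> int:
    return (base * 100_003 + iteration * 1_009 + fold * 97 + 1) % (2**31 - 1)


def run_cv(
    features: Union[FeatureMatrix, pd.DataFrame],
    labels: Union[Mapping[str, int], pd.Series],
    model_spec: ModelSpec,
    selection_spec: Optional[SelectionSpec] = None,
    cv_config: Optional[CvConfig] = None,
    relevance_fn=None,
) -> CvRun:
    """Repeated stratified k-fold cross-validation of one model spec.

    Feature selection (if requested) and every trainable transform run
    inside each training fold only; test rows are never visible to them.
    Each iteration re-divides the cohort and each subject receives exactly
    one out-of-fold probability per iteration.
    """
    cfg = cv_config or CvConfig()
    X = features.values_df if isinstance(features, FeatureMatrix) else features
    y = pd.Series(labels).reindex(X.index)
    if y.isna().any():
        missing = list(y.index[y.isna()])[:5]
        raise ValueError(f"labels missing for subjects {missing}")
    y = y.astype(int)

    probs = pd.DataFrame(np.nan, index=X.index, columns=range(cfg.n_iterations))
    aucs = np.zeros(cfg.n_iterations)
    for it in range(cfg.n_iterations):
        rng = np.random.default_rng(_derive_seed(cfg.seed, it, 0))
        folds = stratified_folds(y.to_numpy(), cfg.k, rng)
        for f in range(cfg.k):
            test_mask = folds == f
            X_train, y_train = X.loc[~test_mask], y.loc[~test_mask]
            X_test = X.loc[test_mask]
            if selection_spec is not None and selection_spec.method != "none":
                kept = select_features(selection_spec, X_train, y_train.to_numpy(), relevance_fn)
                X_train, X_test = X_train[kept], X_test[kept]
            spec = ModelSpec(
                kind=model_spec.kind,
                hyperparameters=dict(model_spec.hyperparameters),
                seed=_derive_seed(model_spec.seed, it, f),
            )
            p = fit_predict(spec, X_train, y_train.to_numpy(), X_test)
            probs.loc[test_mask, it] = p
        col = probs[it]
        aucs[it] = auc(col[y == 1].to_numpy(), col[y == 0].to_numpy())
    return CvRun(probs=probs, aucs=aucs, labels=y, config=cfg)


# ---------------------------------------------------------------------------
# Prioritization
# ---------------------------------------------------------------------------

@dataclass
class PrioritizationReport:
    """Outcome of the stability cutoff scan."""

    cutoff: Optional[float]
    stability_threshold: int
    ratio_constraint: float
    tp_star_pct: float
    fp_pct: float
    fdr_bound: float
    prioritized_subjects: List[str]
    n_stable_cases: int
    pct_explained: float
    feasible: bool
    scan: pd.DataFrame = field(repr=False, default=None)

    def to_dict(self) -> Dict:
        return {
            "cutoff": self.cutoff,
            "stability_threshold": self.stability_threshold,
            "ratio_constraint": self.ratio_constraint,
            "tp_star_pct": self.tp_star_pct,
            "fp_pct": self.fp_pct,
            "fdr_bound": self.fdr_bound,
            "prioritized_subjects": list(self.prioritized_subjects),
            "n_stable_cases": self.n_stable_cases,
            "pct_explained": self.pct_explained,
            "feasible": self.feasible,
        }


def stable_at(cv: CvRun, cutoff: float, s: int) -> pd.Series:
    """Boolean per subject: case-predicted (prob >= cutoff) in >= s iterations."""
    return (cv.probs >= cutoff).sum(axis=1) >= s


def scan_cutoff(
    cv: CvRun,
    flags: Optional[pd.DataFrame] = None,
    s: int = 15,
    r: float = 1.5,
    grid: Optional[Sequence[float]] = None,
    study_total: Optional[int] = None,
) -> PrioritizationReport:
    """Scan probability cutoffs for stable, conservative case prediction.

    TP* is the percentage of case subjects in the run WITHOUT a pathogenic
    or de novo CNV (per ``flags`` from define_subsets) stably predicted as
    cases; FP is the percentage of control subjects stably predicted as
    cases. A cutoff is feasible when TP* > r * FP; among feasible cutoffs
    the one maximizing the stable TP* count wins (ties -> smallest
    cutoff). ``fdr_bound`` reports FP/TP*, an upper bound on the false
    discovery rate in the prioritized list.
    """
    if s > cv.config.n_iterations:
        raise ValueError("stability threshold exceeds the number of iterations")
    if grid is None:
        grid = np.round(np.arange(0.50, 0.95 + 1e-9, 0.01), 2)
    y = cv.labels
    case_ids = set(y.index[y == 1])
    control_ids = set(y.index[y == 0])
    if flags is not None:
        high_effect = set(
            flags.index[flags["pathogenic_carrier"] | flags["de_novo_carrier"]]
        )
    else:
        high_effect = set()
    tp_star_pool = sorted(case_ids - high_effect)
    if not tp_star_pool or not control_ids:
        raise ValueError("TP* pool and controls must both be non-empty")

    rows = []
    per_cutoff_stable = {}
    for theta in grid:
        stable = stable_at(cv, float(theta), s)
        stable_ids = set(stable.index[stable])
        n_tp_star = len(stable_ids & set(tp_star_pool))
        n_fp = len(stable_ids & control_ids)
        tp_pct = 100.0 * n_tp_star / len(tp_star_pool)
        fp_pct = 100.0 * n_fp / len(control_ids)
        rows.append(
            {
                "cutoff": float(theta),
                "n_tp_star": n_tp_star,
                "tp_star_pct": tp_pct,
                "n_fp": n_fp,
                "fp_pct": fp_pct,
                "feasible": tp_pct > r * fp_pct,
            }
        )
        per_cutoff_stable[float(theta)] = stable_ids
    scan = pd.DataFrame(rows)

    feasible = scan[scan["feasible"]]
    if feasible.empty:
        return PrioritizationReport(
            cutoff=None,
            stability_threshold=s,
            ratio_constraint=r,
            tp_star_pct=0.0,
            fp_pct=0.0,
            fdr_bound=math.nan,
            prioritized_subjects=[],
            n_stable_cases=0,
            pct_explained=0.0,
            feasible=False,
            scan=scan,
        )
    best = feasible.sort_values(["n_tp_star", "cutoff"], ascending=[False, True]).iloc[0]
    theta = float(best["cutoff"])
    stable_ids = per_cutoff_stable[theta]
    prioritized = sorted(stable_ids & set(tp_star_pool))
    n_stable_cases = len(stable_ids & case_ids)
    total = study_total if study_total is not None else len(case_ids)
    return PrioritizationReport(
        cutoff=theta,
        stability_threshold=s,
        ratio_constraint=r,
        tp_star_pct=float(best["tp_star_pct"]),
        fp_pct=float(best["fp_pct"]),
        fdr_bound=float(best["fp_pct"] / best["tp_star_pct"]) if best["tp_star_pct"] > 0 else math.nan,
        prioritized_subjects=prioritized,
        n_stable_cases=n_stable_cases,
        pct_explained=pct_explained(n_stable_cases, total),
        feasible=True,
        scan=scan,
    )


def pct_explained(stable_correct_count: int, study_total: int) -> float:
    """Percentage of the full study cohort stably and correctly classified.

    The denominator is the study total (including subjects excluded from
    model fitting for lack of genic rare CNVs), so the figure reads as the
    fraction of all cases the classifier accounts for.
    """
    if study_total <= 0:
        raise ValueError("study_total must be positive")
    if stable_correct_count < 0:
        raise ValueError("count must be non-negative")
    return 100.0 * stable_correct_count / study_total


def sex_enrichment(
    prioritized: Sequence[Subject], background: Sequence[Subject]
) -> Tuple[float, float]:
    """Female enrichment of the prioritized subjects vs the background.

    2x2 table: female/male x prioritized/background-rest. Returns the
    sample odds ratio and the two-sided Fisher exact p-value; a zero
    margin makes the odds ratio undefined (NaN, p = 1).
    """
    if not prioritized:
        raise ValueError("prioritized set is empty")
    pri_ids = {s.subject_id for s in prioritized}
    rest = [s for s in background if s.subject_id not in pri_ids]
    a = sum(1 for s in prioritized if s.sex == "female")
    b = sum(1 for s in prioritized if s.sex == "male")
    c = sum(1 for s in rest if s.sex == "female")
    d = sum(1 for s in rest if s.sex == "male")
    if min(a + b, c + d, a + c, b + d) == 0:
        return math.nan, 1.0
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    odds = (a * d) / (b * c) if b * c > 0 else math.inf
    return float(odds), float(p)
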