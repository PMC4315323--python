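"""CV protocol, AUC statistics, cutoff scanning, enrichment tests."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from cnvclassify import ModelSpec, Subject
from cnvclassify.evaluation import (
    CvConfig,
    CvRun,
    auc,
    pct_explained,
    run_cv,
    scan_cutoff,
    sex_enrichment,
    stable_at,
    stratified_folds,
)
from cnvclassify.selection import SelectionSpec


class TestStratifiedFolds:
    def test_balanced_cohort_splits_evenly(self):
        y = [1] * 9 + [0] * 9
        folds = stratified_folds(y, 3, np.random.default_rng(0))
        for f in range(3):
            mask = folds == f
            assert np.asarray(y)[mask].sum() == 3 and mask.sum() == 6

    def test_per_class_sizes_differ_at_most_one(self):
        y = [1] * 10 + [0] * 8
        folds = stratified_folds(y, 3, np.random.default_rng(1))
        for cls in (0, 1):
            sizes = [((folds == f) & (np.asarray(y) == cls)).sum() for f in range(3)]
            assert max(sizes) - min(sizes) <= 1

    def test_folds_partition_the_cohort(self):
        y = [1] * 13 + [0] * 17
        folds = stratified_folds(y, 3, np.random.default_rng(2))
        assert set(folds) == {0, 1, 2} and len(folds) == 30

    def test_k_larger_than_class_errors(self):
        with pytest.raises(ValueError, match="class size"):
            stratified_folds([1, 1, 0, 0], 3, np.random.default_rng(0))


class TestAuc:
    def test_all_ties_give_half(self):
        assert auc([0.5, 0.5], [0.5, 0.5, 0.5]) == 0.5

    def test_perfect_separation_gives_one(self):
        assert auc([0.9, 0.8], [0.1, 0.2]) == 1.0

    def test_pair_counting_example(self):
        # 3 of 4 (case, control) pairs concordant
        assert auc([0.9, 0.4], [0.5, 0.1]) == pytest.approx(0.75)

    def test_empty_class_errors(self):
        with pytest.raises(ValueError):
            auc([], [0.1])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        cases=st.lists(st.integers(0, 8), min_size=1, max_size=15),
        controls=st.lists(st.integers(0, 8), min_size=1, max_size=15),
    )
    def test_matches_pair_counting_and_mann_whitney(self, cases, controls):
        got = auc(cases, controls)
        pairs = [(1.0 if a > b else 0.5 if a == b else 0.0) for a in cases for b in controls]
        assert got == pytest.approx(np.mean(pairs))
        u = stats.mannwhitneyu(cases, controls, alternative="two-sided").statistic
        assert got == pytest.approx(u / (len(cases) * len(controls)))


def toy_features(seed=0, n=60):
    rng = np.random.default_rng(seed)
    y = pd.Series(
        ([1, 0] * (n // 2)), index=[f"S{i}" for i in range(n)]
    )
    df = pd.DataFrame(
        {
            "signal": y.to_numpy() * 2 + rng.integers(0, 2, size=n),
            "noise": rng.integers(0, 4, size=n),
            "total_count": rng.integers(1, 9, size=n),
        },
        index=y.index,
    )
    return df, y


class TestRunCv:
    def test_contract_shapes(self):
        df, y = toy_features()
        run = run_cv(
            df,
            y,
            ModelSpec(kind="cforest", hyperparameters={"n_trees": 10}),
            cv_config=CvConfig(n_iterations=4, seed=0),
        )
        assert len(run.aucs) == 4
        assert run.probs.shape == (60, 4)
        assert run.probs.notna().all().all()  # one OOF prob per subject per iteration
        assert run.sd_auc == pytest.approx(float(np.std(run.aucs, ddof=1)))

    def test_selection_runs_on_training_folds_only(self):
        df, y = toy_features(seed=1)
        seen = []

        def spy_relevance(X, yy):
            seen.append(set(X.index))
            return X.var(axis=0).to_numpy()

        run_cv(
            df,
            y,
            ModelSpec(kind="cforest", hyperparameters={"n_trees": 5}),
            selection_spec=SelectionSpec(method="mda"),
            cv_config=CvConfig(n_iterations=2, k=3, seed=0),
            relevance_fn=spy_relevance,
        )
        all_ids = set(df.index)
        assert len(seen) == 6
        for rows in seen:
            assert len(rows) == 40 and rows < all_ids

    def test_missing_labels_rejected(self):
        df, y = toy_features()
        with pytest.raises(ValueError, match="labels missing"):
            run_cv(df, y.iloc[:-5], ModelSpec(kind="cforest"))


def handbuilt_cv(seed=21, n_cases=20, n_controls=20, n_iter=20):
    rng = np.random.default_rng(seed)
    ids = [f"case{i}" for i in range(n_cases)] + [f"ctrl{i}" for i in range(n_controls)]
    labels = pd.Series([1] * n_cases + [0] * n_controls, index=ids)
    # cases shifted upwards so some cutoffs are feasible
    probs = pd.DataFrame(
        np.clip(
            rng.normal(
                loc=np.where(labels.to_numpy()[:, None] == 1, 0.58, 0.45), scale=0.08,
                size=(len(ids), n_iter),
            ),
            0,
            1,
        ),
        index=ids,
        columns=range(n_iter),
    )
    run = CvRun(
        probs=probs, aucs=np.full(n_iter, np.nan), labels=labels, config=CvConfig(n_iterations=n_iter)
    )
    flags = pd.DataFrame(
        False,
        index=ids,
        columns=["any_genic", "loss_carrier", "gain_carrier", "de_novo_carrier", "pathogenic_carrier"],
    )
    flags.loc[["case0", "case1"], "de_novo_carrier"] = True
    flags.loc[["case2"], "pathogenic_carrier"] = True
    return run, flags


class TestScanCutoff:
    def test_stability_boundary_fifteen_of_twenty(self):
        run, _ = handbuilt_cv()
        probs = run.probs.copy()
        probs.loc["case0"] = 0.0
        probs.loc["case0", range(15)] = 0.9
        probs.loc["case1"] = 0.0
        probs.loc["case1", range(14)] = 0.9
        run.probs = probs
        stable = stable_at(run, 0.6, 15)
        assert bool(stable["case0"]) and not bool(stable["case1"])

    def test_clean_separation_is_feasible_for_any_ratio(self):
        run, flags = handbuilt_cv()
        probs = run.probs.copy()
        probs.loc[[i for i in probs.index if i.startswith("ctrl")]] = 0.1
        probs.loc[[i for i in probs.index if i.startswith("case")]] = 0.9
        run.probs = probs
        rep = scan_cutoff(run, flags=flags, s=15, r=100.0)
        assert rep.feasible and rep.fp_pct == 0.0 and rep.tp_star_pct == 100.0

    def test_matches_exhaustive_scan_oracle(self):
        run, flags = handbuilt_cv()
        s, r = 15, 1.5
        grid = np.round(np.arange(0.50, 0.95 + 1e-9, 0.01), 2)
        tp_pool = [i for i in run.probs.index if i.startswith("case") and i not in ("case0", "case1", "case2")]
        controls = [i for i in run.probs.index if i.startswith("ctrl")]

        best = None
        for theta in grid:
            stable = {sid for sid in run.probs.index if (run.probs.loc[sid] >= theta).sum() >= s}
            tp = len(stable & set(tp_pool))
            fp = len(stable & set(controls))
            tp_pct = 100 * tp / len(tp_pool)
            fp_pct = 100 * fp / len(controls)
            if tp_pct > r * fp_pct and (best is None or tp > best[1]):
                best = (theta, tp, tp_pct, fp_pct, sorted(stable & set(tp_pool)))
        assert best is not None

        rep = scan_cutoff(run, flags=flags, s=s, r=r)
        assert rep.cutoff == pytest.approx(best[0])
        assert rep.tp_star_pct == pytest.approx(best[2])
        assert rep.fp_pct == pytest.approx(best[3])
        assert rep.prioritized_subjects == best[4]
        assert rep.fdr_bound == pytest.approx(best[3] / best[2])

    def test_no_feasible_cutoff_reported_explicitly(self):
        run, flags = handbuilt_cv()
        run.probs.loc[:, :] = 0.9  # everyone stably case-predicted
        rep = scan_cutoff(run, flags=flags, s=15, r=1.5)
        assert not rep.feasible and rep.cutoff is None and rep.prioritized_subjects == []

    def test_stable_counts_monotone_in_cutoff_and_stability(self):
        run, _ = handbuilt_cv(seed=5)
        counts_theta = [int(stable_at(run, t, 10).sum()) for t in (0.4, 0.5, 0.6, 0.7)]
        assert counts_theta == sorted(counts_theta, reverse=True)
        counts_s = [int(stable_at(run, 0.5, s).sum()) for s in (5, 10, 15, 20)]
        assert counts_s == sorted(counts_s, reverse=True)


class TestPctExplained:
    @pytest.mark.parametrize(
        "count,total,expected",
        [(12, 958, 1.25), (1916, 2342, 81.8), (0, 500, 0.0)],
    )
    def test_printed_precision(self, count, total, expected):
        assert pct_explained(count, total) == pytest.approx(expected, abs=0.05)

    def test_zero_total_errors(self):
        with pytest.raises(ValueError):
            pct_explained(1, 0)


def subjects_from_counts(f_pri, m_pri, f_rest, m_rest):
    pri = [Subject(f"p{i}", "case", "female") for i in range(f_pri)] + [
        Subject(f"q{i}", "case", "male") for i in range(m_pri)
    ]
    rest = [Subject(f"r{i}", "case", "female") for i in range(f_rest)] + [
        Subject(f"s{i}", "case", "male") for i in range(m_rest)
    ]
    return pri, pri + rest


class TestSexEnrichment:
    def test_balanced_table_is_null(self):
        pri, bg = subjects_from_counts(2, 2, 2, 2)
        odds, p = sex_enrichment(pri, bg)
        assert odds == pytest.approx(1.0) and p == pytest.approx(1.0)

    def test_exact_p_from_hypergeometric_enumeration(self):
        # table (3,1 / 1,3): enumerate all tables with margins (4,4,4,4)
        pri, bg = subjects_from_counts(3, 1, 1, 3)
        odds, p = sex_enrichment(pri, bg)
        # exhaustive: P(X in {a : P(a) <= P(3)}) under hypergeom(8,4,4)
        pmf = {a: stats.hypergeom.pmf(a, 8, 4, 4) for a in range(5)}
        p_exact = sum(v for v in pmf.values() if v <= pmf[3] + 1e-12)
        assert p == pytest.approx(p_exact)
        assert p == pytest.approx(0.485714, abs=1e-4)
        assert odds == pytest.approx(9.0)

    def test_empty_prioritized_errors(self):
        _, bg = subjects_from_counts(0, 0, 2, 2)
        with pytest.raises(ValueError, match="empty"):
            sex_enrichment([], bg)

    def test_zero_margin_reports_undefined_odds(self):
        pri, bg = subjects_from_counts(0, 3, 0, 3)  # no females anywhere
        odds, p = sex_enrichment(pri, bg)
        assert math.isnan(odds) and p == 1.0
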