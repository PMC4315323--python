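"""Shared fixtures: small synthetic cohorts and derived feature matrices.

Cohorts are generated once per session; every expensive object downstream
(gene maps, matrices) is likewise session-scoped so the suite stays fast.
"""

from __future__ import annotations

import numpy as np
import pytest

from cnvclassify import SimConfig, generate
from cnvclassify.features import build_features, define_subsets, map_cnv_to_genes

SIGNAL_SEED = 7
NULL_SEED = 13


@pytest.fixture(scope="session")
def signal_cohort():
    """Default study conditions: loss burden planted in neural sets."""
    return generate(SimConfig(seed=SIGNAL_SEED))


def null_config(seed=NULL_SEED):
    """No planted signal anywhere: burden odds flat AND no flagged
    high-effect carriers (those plant signal of their own)."""
    return SimConfig(
        seed=seed,
        burden_or=1.0,
        gain_burden_or=1.0,
        pathogenic_fraction=0.0,
        de_novo_fraction=0.0,
    )


def cohort_artifacts(cohort, scope="all"):
    gene_map = map_cnv_to_genes(cohort.records, cohort.gene_models)
    matrix = build_features(cohort.subjects, cohort.records, gene_map, cohort.gene_sets, scope=scope)
    labels = {
        s.subject_id: int(s.is_case) for s in cohort.subjects if s.subject_id in set(matrix.subjects)
    }
    return gene_map, matrix, labels


@pytest.fixture(scope="session")
def signal_artifacts(signal_cohort):
    return cohort_artifacts(signal_cohort)


@pytest.fixture(scope="session")
def signal_flags(signal_cohort):
    gene_map = map_cnv_to_genes(signal_cohort.records, signal_cohort.gene_models)
    return define_subsets(signal_cohort.subjects, signal_cohort.records, gene_map)


CURATED_SET_IDS = [
    "hi015",
    "hi035",
    "hi055",
    "ExpsNov_BrainFeAd_sp",
    "Synapse_GrantFull",
    "FMR1_Targets_Darnell",
    "FMR1_Targets_Ascano",
    "thrEXPR_log2rpkm",
    "thr4.86_log2rpkm",
    "thr3.32_log2rpkm",
    "thr0.84_log2rpkm",
    "thr.MIN_log2rpkm",
    "PhHs_NervSys_ADX",
    "PhHs_NervSys_All",
    "PhHs_MindFun_ADX",
    "PhHs_MindFun_All",
    "MmHs_Neuro_All",
    "MmHs_Extend_All",
    "NeuroF_large",
    "NeuroF_small",
]


@pytest.fixture()
def curated_gmt(tmp_path):
    """Synthetic stand-in for the curated neurally-relevant gene-set GMT:
    the 20 conventional set ids with small synthetic memberships."""
    rng = np.random.default_rng(0)
    genes = [f"G{i:03d}" for i in range(200)]
    path = tmp_path / "curated_sets_synthetic.gmt"
    with open(path, "w") as fh:
        for sid in CURATED_SET_IDS:
            members = rng.choice(genes, size=rng.integers(5, 30), replace=False)
            fh.write("\t".join([sid, f"synthetic members for {sid}", *members]) + "\n")
    return path
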