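"""Gene-set burden feature construction from rare CNV calls.

A subject's feature for gene-set ``S`` and dosage ``loss`` is the number of
DISTINCT genes of ``S`` overlapped by at least one of the subject's rare
losses (gains analogous); ``total_count`` is the number of distinct genes
hit by any rare genic CNV within the run's dosage scope. Counting distinct
genes (not events or base pairs) makes a subject with two small hits in one
gene equivalent to a subject with one hit there.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from cnvclassify.types import CnvRecord, GeneModel, GeneSetCollection, Subject

logger = logging.getLogger(__name__)

SCOPES = ("all", "loss_only", "gain_only")
TOTAL_FEATURE = "total_count"


@dataclass
class FeatureMatrix:
    """Subjects x burden-feature count matrix.

    ``values_df`` is indexed by subject_id with integer columns named
    ``<set_id>_loss`` / ``<set_id>_gain`` plus ``total_count`` (last).
    Subjects whose row would be all zero are dropped from the matrix but
    listed in ``dropped_subjects`` — they are excluded from classification
    yet still counted in cohort denominator statistics.
    """

    values_df: pd.DataFrame
    metadata: Dict[str, str] = field(default_factory=dict)
    dropped_subjects: List[str] = field(default_factory=list)

    @property
    def subjects(self) -> List[str]:
        return list(self.values_df.index)

    @property
    def feature_names(self) -> List[str]:
        return list(self.values_df.columns)

    def to_array(self) -> np.ndarray:
        return self.values_df.to_numpy(dtype=float)


def map_cnv_to_genes(
    records: Sequence[CnvRecord],
    gene_models: Sequence[GeneModel],
    mode: str = "transcript",
) -> List[FrozenSet[str]]:
    """Map each CNV to the set of genes it overlaps.

    A gene is hit when the CNV shares >= 1 bp with any transcript
    (mode="transcript") or any exon (mode="exonic") of the gene on the same
    chromosome. Returns one (possibly empty) gene-id set per input record,
    in input order.
    """
    if mode not in ("transcript", "exonic"):
        raise ValueError(f"unknown mapping mode {mode!r}")
    if mode == "exonic":
        missing = [g.gene_id for g in gene_models if g.exon_intervals is None]
        if missing:
            raise ValueError(
                f"exonic mapping requested but genes lack exon data: {missing[:5]}"
            )

    # flatten intervals per chromosome, sorted by start for a scan window
    by_chrom: Dict[str, List[Tuple[int, int, str]]] = {}
    for g in gene_models:
        intervals = g.transcript_intervals if mode == "transcript" else g.exon_intervals
        for s, e in intervals:
            by_chrom.setdefault(g.chrom, []).append((s, e, g.gene_id))
    arrays: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        arrays[chrom] = (
            np.array([s for s, _, _ in ivs]),
            np.array([e for _, e, _ in ivs]),
            np.array([gid for _, _, gid in ivs]),
        )

    out: List[FrozenSet[str]] = []
    for rec in records:
        if rec.chrom not in arrays:
            out.append(frozenset())
            continue
        starts, ends, gids = arrays[rec.chrom]
        hit = (starts < rec.end) & (ends > rec.start)
        out.append(frozenset(gids[hit]))
    return out


def build_features(
    subjects: Sequence[Subject],
    records: Sequence[CnvRecord],
    cnv_gene_map: Sequence[FrozenSet[str]],
    gene_sets: GeneSetCollection,
    scope: str = "all",
    mapping_mode: str = "transcript",
) -> FeatureMatrix:
    """Build the per-subject gene-set count matrix.

    scope="all" emits loss and gain features for every set plus the total
    distinct-gene count; "loss_only"/"gain_only" restrict both the set
    features and the total count to that dosage type.
    """
    if scope not in SCOPES:
        raise ValueError(f"unknown scope {scope!r}")
    if len(records) != len(cnv_gene_map):
        raise ValueError("records and cnv_gene_map lengths differ")
    for genes in cnv_gene_map:
        extra = genes - gene_sets.universe
        if extra:
            raise ValueError(f"mapped genes outside the universe: {sorted(extra)[:5]}")

    dosages = ("loss", "gain") if scope == "all" else ((scope.split("_")[0]),)
    # distinct genes per subject per dosage
    hit: Dict[str, Dict[str, set]] = {s.subject_id: {d: set() for d in dosages} for s in subjects}
    for rec, genes in zip(records, cnv_gene_map):
        if rec.dosage in dosages and rec.subject_id in hit:
            hit[rec.subject_id][rec.dosage].update(genes)

    set_ids = list(gene_sets)
    columns = [f"{sid}_{d}" for d in dosages for sid in set_ids] + [TOTAL_FEATURE]
    rows = {}
    for s in subjects:
        vals = []
        for d in dosages:
            genes_d = hit[s.subject_id][d]
            vals.extend(len(genes_d & gene_sets.members(sid)) for sid in set_ids)
        total = len(set().union(*(hit[s.subject_id][d] for d in dosages)))
        vals.append(total)
        rows[s.subject_id] = vals
    df = pd.DataFrame.from_dict(rows, orient="index", columns=columns).astype(int)

    nonzero = df[TOTAL_FEATURE] > 0  # genic carrier within scope
    dropped = list(df.index[~nonzero])
    df = df.loc[nonzero]
    return FeatureMatrix(
        values_df=df,
        metadata={
            "mapping_mode": mapping_mode,
            "scope": scope,
            "n_sets": str(len(set_ids)),
        },
        dropped_subjects=dropped,
    )


@dataclass(frozen=True)
class SetSizeFilter:
    """Inclusive gene-set size bounds (max_size=None means unbounded)."""

    min_size: int = 1
    max_size: Optional[int] = None

    def __post_init__(self) -> None:
        if self.max_size is not None and self.min_size > self.max_size:
            raise ValueError("min_size must not exceed max_size")


def filter_sets(collection: GeneSetCollection, size_filter: SetSizeFilter) -> GeneSetCollection:
    """Keep sets whose size lies within the inclusive bounds."""
    kept = {
        sid: entry
        for sid, entry in collection.sets.items()
        if len(entry[1]) >= size_filter.min_size
        and (size_filter.max_size is None or len(entry[1]) <= size_filter.max_size)
    }
    if not kept:
        warnings.warn("size filter removed every gene-set", stacklevel=2)
    return GeneSetCollection(sets=kept, universe=collection.universe)


def randomize_features(
    gene_sets: GeneSetCollection,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    permutation: Optional[Mapping[str, str]] = None,
) -> GeneSetCollection:
    """Permute gene identities across the universe, preserving set sizes.

    One uniform random permutation of the universe is applied to every
    set's membership, yielding size-matched null sets whose downstream
    burden counts carry no case-control signal beyond the total burden.
    """
    genes = sorted(gene_sets.universe)
    if permutation is None:
        rng = rng if rng is not None else np.random.default_rng(seed)
        shuffled = list(rng.permutation(genes))
        permutation = dict(zip(genes, shuffled))
    new_sets = {
        sid: (f"randomized: {desc}", frozenset(permutation[g] for g in members))
        for sid, (desc, members) in gene_sets.sets.items()
    }
    return GeneSetCollection(sets=new_sets, universe=gene_sets.universe)


SUBSET_FLAGS = ("any_genic", "loss_carrier", "gain_carrier", "de_novo_carrier", "pathogenic_carrier")


def define_subsets(
    subjects: Sequence[Subject],
    records: Sequence[CnvRecord],
    cnv_gene_map: Sequence[FrozenSet[str]],
) -> pd.DataFrame:
    """Per-subject analysis-subset membership flags (genic CNVs only).

    Columns: any_genic, loss_carrier, gain_carrier, de_novo_carrier,
    pathogenic_carrier — boolean, indexed by subject_id. Controls keep
    their flags too; subset comparisons always retain all controls.
    """
    flags = pd.DataFrame(
        False, index=[s.subject_id for s in subjects], columns=list(SUBSET_FLAGS)
    )
    for rec, genes in zip(records, cnv_gene_map):
        if not genes or rec.subject_id not in flags.index:
            continue
        flags.loc[rec.subject_id, "any_genic"] = True
        if rec.dosage == "loss":
            flags.loc[rec.subject_id, "loss_carrier"] = True
        else:
            flags.loc[rec.subject_id, "gain_carrier"] = True
        if rec.inheritance == "de_novo":
            flags.loc[rec.subject_id, "de_novo_carrier"] = True
        if rec.clinical_class == "pathogenic":
            flags.loc[rec.subject_id, "pathogenic_carrier"] = True
    return flags
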