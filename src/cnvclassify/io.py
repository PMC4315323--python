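"""Readers, writers and QC filters for the tabular pipeline inputs.

Formats
-------
* CNV table: TSV with header ``subject_id chrom start end dosage
  inheritance clinical_class`` (1-based inclusive coordinates), or a
  minimal BED4+ dialect (``chrom start end subject_id [dosage ...]``,
  0-based half-open).
* Subjects: TSV with header ``subject_id label sex``.
* Gene models: TSV (one transcript per row, 0-based half-open, optional
  comma-separated exon blocks) or BED12 (exons from blocks).
* Gene-sets: GMT (set_id, description, tab-separated members).
* Feature matrices: TSV with subject_id row keys.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from cnvclassify.types import (
    CLINICAL_CLASSES,
    DOSAGES,
    INHERITANCES,
    CnvRecord,
    GeneModel,
    GeneSetCollection,
    QcConfig,
    Subject,
)

logger = logging.getLogger(__name__)

CNV_COLUMNS = ["subject_id", "chrom", "start", "end", "dosage", "inheritance", "clinical_class"]


# ---------------------------------------------------------------------------
# Subjects
# ---------------------------------------------------------------------------

def read_subjects(path) -> List[Subject]:
    """Read a subject metadata TSV (subject_id, label, sex)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"subject_id", "label"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: subject table needs columns {sorted(required)}")
    if df["subject_id"].duplicated().any():
        dup = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise ValueError(f"{path}: duplicate subject_id {dup!r}")
    sexes = df["sex"] if "sex" in df.columns else ["unknown"] * len(df)
    return [
        Subject(subject_id=sid, label=lab, sex=sex)
        for sid, lab, sex in zip(df["subject_id"], df["label"], sexes)
    ]


def write_subjects(subjects: Sequence[Subject], path) -> None:
    pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in subjects],
            "label": [s.label for s in subjects],
            "sex": [s.sex for s in subjects],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# CNV tables
# ---------------------------------------------------------------------------

def read_cnv_table(path, dialect: str = "tsv") -> List[CnvRecord]:
    """Parse a CNV call table.

    dialect="tsv": headered table with 1-based inclusive coordinates,
    converted on read to the internal 0-based half-open convention.
    dialect="bed": BED4+ (chrom, start, end, subject_id, then optional
    dosage, inheritance, clinical_class columns), already 0-based.
    """
    if dialect not in ("tsv", "bed"):
        raise ValueError(f"unknown CNV table dialect {dialect!r}")
    records: List[CnvRecord] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    if dialect == "tsv":
        if not lines:
            raise ValueError(f"{path}: empty file (expected a header line)")
        header = lines[0].split("\t")
        idx = {name: i for i, name in enumerate(header)}
        missing = [c for c in CNV_COLUMNS[:5] if c not in idx]
        if missing:
            raise ValueError(f"{path}: missing columns {missing}")
        for lineno, line in enumerate(lines[1:], start=2):
            if not line.strip():
                continue
            fields = line.split("\t")
            try:
                start1 = int(fields[idx["start"]])
                end1 = int(fields[idx["end"]])
                rec = CnvRecord(
                    subject_id=fields[idx["subject_id"]],
                    chrom=fields[idx["chrom"]],
                    start=start1 - 1,  # 1-based inclusive -> 0-based half-open
                    end=end1,
                    dosage=fields[idx["dosage"]],
                    inheritance=fields[idx["inheritance"]] if "inheritance" in idx else "unknown",
                    clinical_class=fields[idx["clinical_class"]]
                    if "clinical_class" in idx
                    else "unclassified",
                )
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: malformed row at line {lineno}: {exc}") from exc
            records.append(rec)
    else:
        for lineno, line in enumerate(lines, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}: malformed BED row at line {lineno} (<4 fields)")
            try:
                rec = CnvRecord(
                    subject_id=fields[3],
                    chrom=fields[0],
                    start=int(fields[1]),
                    end=int(fields[2]),
                    dosage=fields[4] if len(fields) > 4 else "loss",
                    inheritance=fields[5] if len(fields) > 5 else "unknown",
                    clinical_class=fields[6] if len(fields) > 6 else "unclassified",
                )
            except ValueError as exc:
                raise ValueError(f"{path}: malformed BED row at line {lineno}: {exc}") from exc
            records.append(rec)
    return records


def write_cnv_table(records: Sequence[CnvRecord], path) -> None:
    """Write a CNV table in the headered TSV dialect (1-based inclusive)."""
    pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "chrom": [r.chrom for r in records],
            "start": [r.start + 1 for r in records],
            "end": [r.end for r in records],
            "dosage": [r.dosage for r in records],
            "inheritance": [r.inheritance for r in records],
            "clinical_class": [r.clinical_class for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def _reciprocal_carrier_counts(records: Sequence[CnvRecord], thr: float) -> np.ndarray:
    """Number of distinct carrier subjects per record.

    A subject carries record r if it has some CNV of the same dosage on the
    same chromosome whose reciprocal overlap with r is >= thr (the overlap
    covers at least thr of BOTH intervals). Each record's own subject counts.
    """
    counts = np.zeros(len(records), dtype=int)
    groups: Dict[Tuple[str, str], List[int]] = defaultdict(list)
    for i, r in enumerate(records):
        groups[(r.chrom, r.dosage)].append(i)
    for idxs in groups.values():
        starts = np.array([records[i].start for i in idxs], dtype=float)
        ends = np.array([records[i].end for i in idxs], dtype=float)
        lens = ends - starts
        subj = np.array([records[i].subject_id for i in idxs])
        ov = np.minimum(ends[:, None], ends[None, :]) - np.maximum(
            starts[:, None], starts[None, :]
        )
        ov = np.clip(ov, 0, None)
        mutual = (ov >= thr * lens[:, None]) & (ov >= thr * lens[None, :])
        for k, i in enumerate(idxs):
            counts[i] = len(set(subj[mutual[k]]))
    return counts


def apply_qc(
    records: Sequence[CnvRecord],
    subjects: Sequence[Subject],
    cfg: Optional[QcConfig] = None,
) -> Tuple[List[CnvRecord], List[str], Dict[str, int]]:
    """Apply rare-CNV QC: length floor, per-subject burden cap, frequency cap.

    Returns (kept records, excluded subject ids, audit counts). The audit
    maps each exclusion reason to the number of records it removed, so the
    reason counts sum to input minus kept.
    """
    cfg = cfg or QcConfig()
    known = {s.subject_id for s in subjects}
    unknown = [r.subject_id for r in records if r.subject_id not in known]
    if unknown:
        raise ValueError(f"CNV records reference unknown subjects: {sorted(set(unknown))[:5]}")

    audit: Counter = Counter(input=len(records))
    kept = list(records)

    if cfg.filter_length:
        short = [r for r in kept if r.length < cfg.min_cnv_length]
        audit["removed_short"] = len(short)
        kept = [r for r in kept if r.length >= cfg.min_cnv_length]

    excluded_subjects: List[str] = []
    if cfg.filter_burden:
        burden: Counter = Counter()
        for r in kept:
            burden[r.subject_id] += r.length
        excluded_subjects = sorted(s for s, b in burden.items() if b > cfg.max_sample_burden)
        n_before = len(kept)
        kept = [r for r in kept if r.subject_id not in set(excluded_subjects)]
        audit["removed_subject_burden"] = n_before - len(kept)
        audit["excluded_subjects"] = len(excluded_subjects)

    if cfg.filter_frequency and kept:
        carriers = _reciprocal_carrier_counts(kept, cfg.reciprocal_overlap_for_frequency)
        freq = carriers / len(subjects)
        common = freq > cfg.max_frequency
        audit["removed_common"] = int(common.sum())
        kept = [r for r, c in zip(kept, common) if not c]

    audit["kept"] = len(kept)
    logger.info("QC: %s", dict(audit))
    return kept, excluded_subjects, dict(audit)


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

def _parse_blocks(text: str) -> Tuple[int, ...]:
    return tuple(int(x) for x in text.rstrip(",").split(",") if x)


def read_gene_models(path, fmt: str = "auto") -> List[GeneModel]:
    """Read gene/transcript models from BED12 or a transcript TSV.

    TSV columns: gene_id, chrom, start, end (0-based half-open) and
    optionally exon_starts / exon_ends (comma lists, absolute coordinates);
    one row per transcript, rows of one gene merged into a single model.
    BED12 name field is taken as the gene id; blocks become exons.
    """
    path = Path(path)
    if fmt == "auto":
        fmt = "bed" if path.suffix in (".bed", ".bed12") else "tsv"
    transcripts: Dict[str, Dict] = {}

    def _add(gene_id, chrom, start, end, exons):
        entry = transcripts.setdefault(
            gene_id, {"chrom": chrom, "tx": [], "exons": [], "has_exons": True}
        )
        if entry["chrom"] != chrom:
            raise ValueError(f"gene {gene_id}: transcripts on multiple chromosomes")
        entry["tx"].append((start, end))
        if exons is None:
            entry["has_exons"] = False
        else:
            entry["exons"].extend(exons)

    if fmt == "bed":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                f = line.rstrip("\n").split("\t")
                if len(f) < 4:
                    raise ValueError(f"{path}: BED row at line {lineno} has <4 fields")
                chrom, start, end, gene_id = f[0], int(f[1]), int(f[2]), f[3]
                exons = None
                if len(f) >= 12:
                    sizes = _parse_blocks(f[10])
                    offsets = _parse_blocks(f[11])
                    exons = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
                _add(gene_id, chrom, start, end, exons)
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
        needed = {"gene_id", "chrom", "start", "end"}
        if not needed.issubset(df.columns):
            raise ValueError(f"{path}: gene model TSV needs columns {sorted(needed)}")
        has_exons = {"exon_starts", "exon_ends"}.issubset(df.columns)
        for row in df.itertuples(index=False):
            exons = None
            if has_exons and isinstance(row.exon_starts, str):
                exons = list(
                    zip(_parse_blocks(row.exon_starts), _parse_blocks(row.exon_ends))
                )
            _add(row.gene_id, row.chrom, int(row.start), int(row.end), exons)

    models = []
    for gene_id, entry in transcripts.items():
        models.append(
            GeneModel(
                gene_id=gene_id,
                chrom=entry["chrom"],
                transcript_intervals=tuple(entry["tx"]),
                exon_intervals=tuple(entry["exons"]) if entry["has_exons"] and entry["exons"] else None,
            )
        )
    return models


def write_gene_models(models: Sequence[GeneModel], path) -> None:
    """Write gene models as a transcript TSV (0-based half-open)."""
    rows = []
    for g in models:
        for s, e in g.transcript_intervals:
            rows.append(
                {
                    "gene_id": g.gene_id,
                    "chrom": g.chrom,
                    "start": s,
                    "end": e,
                    "exon_starts": ",".join(str(a) for a, _ in g.exon_intervals or ()) or np.nan,
                    "exon_ends": ",".join(str(b) for _, b in g.exon_intervals or ()) or np.nan,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GMT gene-sets
# ---------------------------------------------------------------------------

def read_gmt(path, universe: Optional[Iterable[str]] = None) -> GeneSetCollection:
    """Read a GMT file. The universe defaults to the union of all members."""
    sets: Dict[str, Tuple[str, frozenset]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: GMT line {lineno} has fewer than 3 fields")
            set_id, desc, members = fields[0], fields[1], frozenset(f for f in fields[2:] if f)
            if set_id in sets:
                raise ValueError(f"{path}: duplicate set_id {set_id!r} at line {lineno}")
            if not members:
                raise ValueError(f"{path}: gene-set {set_id!r} at line {lineno} is empty")
            sets[set_id] = (desc, members)
    if universe is None:
        uni = frozenset().union(*(m for _, m in sets.values())) if sets else frozenset()
    else:
        uni = frozenset(universe)
    return GeneSetCollection(sets=sets, universe=uni)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for set_id in collection:
            desc, members = collection.sets[set_id]
            fh.write("\t".join([set_id, desc, *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# Feature matrices
# ---------------------------------------------------------------------------

def write_feature_matrix(matrix, path) -> None:
    """Write a feature matrix as TSV (subject_id index, fixed column order)."""
    matrix.values_df.to_csv(path, sep="\t", index=True, index_label="subject_id")


def read_feature_matrix(path):
    from cnvclassify.features import FeatureMatrix

    df = pd.read_csv(path, sep="\t", index_col="subject_id")
    return FeatureMatrix(values_df=df.astype(int), metadata={})
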