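"""Core domain types: subjects, CNV calls, gene models, gene-sets, QC config.

Coordinate convention: all intervals are stored 0-based half-open
(``start`` inclusive, ``end`` exclusive), the BED convention. 1-based
inclusive coordinates are converted at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

LABELS = ("case", "control")
SEXES = ("male", "female", "unknown")
DOSAGES = ("gain", "loss")
INHERITANCES = ("de_novo", "inherited", "unknown")
CLINICAL_CLASSES = ("pathogenic", "uncertain", "benign", "unclassified")


@dataclass(frozen=True)
class Subject:
    """A cohort member with a known case/control label."""

    subject_id: str
    label: str
    sex: str = "unknown"

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r} for subject {self.subject_id}")
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r} for subject {self.subject_id}")

    @property
    def is_case(self) -> bool:
        return self.label == "case"


@dataclass(frozen=True)
class CnvRecord:
    """One rare CNV call (0-based half-open interval)."""

    subject_id: str
    chrom: str
    start: int
    end: int
    dosage: str
    inheritance: str = "unknown"
    clinical_class: str = "unclassified"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"CNV for {self.subject_id} at {self.chrom}:{self.start}-{self.end}: "
                "end must exceed start"
            )
        if self.dosage not in DOSAGES:
            raise ValueError(f"unknown dosage {self.dosage!r}")
        if self.inheritance not in INHERITANCES:
            raise ValueError(f"unknown inheritance {self.inheritance!r}")
        if self.clinical_class not in CLINICAL_CLASSES:
            raise ValueError(f"unknown clinical class {self.clinical_class!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneModel:
    """A gene with one or more transcript intervals and optional exons.

    Transcript and exon intervals are (start, end) pairs on ``chrom``;
    overlap of a CNV with any transcript (or, in exonic mode, any exon)
    maps the CNV to the gene.
    """

    gene_id: str
    chrom: str
    transcript_intervals: Tuple[Tuple[int, int], ...]
    exon_intervals: Optional[Tuple[Tuple[int, int], ...]] = None

    def __post_init__(self) -> None:
        for s, e in self.transcript_intervals:
            if e <= s:
                raise ValueError(f"gene {self.gene_id}: malformed transcript interval ({s}, {e})")
        if self.exon_intervals is not None:
            for s, e in self.exon_intervals:
                if e <= s:
                    raise ValueError(f"gene {self.gene_id}: malformed exon interval ({s}, {e})")

    @property
    def span(self) -> Tuple[int, int]:
        starts = [s for s, _ in self.transcript_intervals]
        ends = [e for _, e in self.transcript_intervals]
        return min(starts), max(ends)


@dataclass
class GeneSetCollection:
    """Named gene-sets over a gene universe.

    ``sets`` maps set_id -> (description, frozenset of member gene ids);
    every member must belong to ``universe``.
    """

    sets: Dict[str, Tuple[str, frozenset]]
    universe: frozenset

    def __post_init__(self) -> None:
        for set_id, (_, members) in self.sets.items():
            if not members:
                raise ValueError(f"gene-set {set_id!r} is empty")
            extra = members - self.universe
            if extra:
                raise ValueError(
                    f"gene-set {set_id!r} has members outside the universe: "
                    f"{sorted(extra)[:5]}"
                )

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def members(self, set_id: str) -> frozenset:
        return self.sets[set_id][1]

    def description(self, set_id: str) -> str:
        return self.sets[set_id][0]

    def sizes(self) -> Dict[str, int]:
        return {sid: len(m) for sid, (_, m) in self.sets.items()}


@dataclass
class QcConfig:
    """Rare-CNV quality-control thresholds.

    min_cnv_length: drop calls shorter than this many bp (default 30 kb).
    max_sample_burden: drop subjects whose summed CNV length exceeds this
        (default 7.5 Mb).
    max_frequency: drop CNVs whose cohort carrier frequency exceeds this
        (default 1%); carriers are grouped by mutual reciprocal overlap of
        at least ``reciprocal_overlap_for_frequency`` (default 50%).
    Each step can be switched off (inputs may arrive pre-filtered).
    """

    min_cnv_length: int = 30_000
    max_sample_burden: int = 7_500_000
    max_frequency: float = 0.01
    reciprocal_overlap_for_frequency: float = 0.5
    filter_length: bool = True
    filter_burden: bool = True
    filter_frequency: bool = True

    def __post_init__(self) -> None:
        if self.min_cnv_length <= 0:
            raise ValueError("min_cnv_length must be positive")
        if not (0 < self.max_frequency <= 1):
            raise ValueError("max_frequency must be in (0, 1]")
        if not (0 < self.reciprocal_overlap_for_frequency <= 1):
            raise ValueError("reciprocal_overlap_for_frequency must be in (0, 1]")
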