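"""Synthetic rare-CNV case-control cohort generator.

Emulates the statistical structure of a rare-CNV burden study: a cohort
slightly control-heavy (~45% cases) and male-skewed among cases; rare
(<=1% carrier frequency) CNVs of 30 kb - 7.5 Mb; roughly 80% of subjects
carrying at least one genic rare CNV; case LOSSES enriched in designated
"neural" gene-sets (the planted signal); and small case subsets flagged as
de novo or pathogenic carriers whose planted CNVs hit the neural pool hard.

The effect is planted at the gene-choice level — case losses pick their
anchor gene from the neural pool with odds multiplied by ``burden_or`` —
so any downstream signal must survive the real CNV-to-gene mapping and
counting code path. Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from cnvclassify.io import (
    _reciprocal_carrier_counts,
    write_cnv_table,
    write_gene_models,
    write_gmt,
    write_subjects,
)
from cnvclassify.types import CnvRecord, GeneModel, GeneSetCollection, Subject


@dataclass
class SimConfig:
    """Generator settings; defaults are the study conditions.

    Cohort scale is reduced (400 cases / 500 controls over 2,000 genes)
    so the full pipeline runs on one CPU in minutes; male fractions,
    carrier rate, CNV length bounds and flagged-subset fractions mirror
    the cohort structure described for the real data. ``burden_or`` tilts
    the anchor-gene odds of case losses towards neural-pool genes;
    ``gain_burden_or`` defaults to 1 (gains carry no planted signal,
    matching their limited predictive power).
    """

    n_cases: int = 400
    n_controls: int = 500
    male_fraction_cases: float = 0.858
    male_fraction_controls: float = 0.467
    n_genes: int = 2000
    n_chromosomes: int = 10
    gene_length_log_mean: float = np.log(30_000.0)
    gene_length_log_sd: float = 0.6
    gene_spacing_mean: float = 60_000.0
    neural_pool_fraction: float = 0.4
    n_neural_sets: int = 10
    n_null_sets: int = 10
    set_size_range: Tuple[int, int] = (100, 300)
    cnv_rate: float = 1.61  # mean genic CNVs per subject; P(>=1) ~ 0.80
    cnv_length_log_mean: float = np.log(100_000.0)
    cnv_length_log_sd: float = 0.8
    min_cnv_length: int = 30_000
    max_cnv_length: int = 7_500_000
    max_frequency: float = 0.01
    loss_fraction: float = 0.5
    burden_or: float = 3.0
    gain_burden_or: float = 1.0
    pathogenic_fraction: float = 0.030
    de_novo_fraction: float = 0.041
    planted_length_quantile: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "male_fraction_cases",
            "male_fraction_controls",
            "neural_pool_fraction",
            "loss_fraction",
            "pathogenic_fraction",
            "de_novo_fraction",
        ):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.burden_or < 1 or self.gain_burden_or < 1:
            raise ValueError("burden odds are interpreted as case enrichment (>= 1)")
        lo, hi = self.set_size_range
        if hi > int(self.n_genes * self.neural_pool_fraction):
            raise ValueError("set sizes exceed the neural gene pool")


@dataclass
class SyntheticCohort:
    """A generated cohort plus the ground-truth record of what was planted."""

    subjects: List[Subject]
    gene_models: List[GeneModel]
    gene_sets: GeneSetCollection
    records: List[CnvRecord]
    truth: Dict

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_subjects(self.subjects, outdir / "subjects.tsv")
        write_cnv_table(self.records, outdir / "cnv.tsv")
        write_gene_models(self.gene_models, outdir / "genes.tsv")
        write_gmt(self.gene_sets, outdir / "sets.gmt")
        with open(outdir / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=1, sort_keys=True)


def _make_genome(cfg: SimConfig, rng: np.random.Generator) -> List[GeneModel]:
    genes: List[GeneModel] = []
    per_chrom = int(np.ceil(cfg.n_genes / cfg.n_chromosomes))
    gid = 0
    for c in range(cfg.n_chromosomes):
        pos = int(rng.exponential(cfg.gene_spacing_mean)) + 10_000
        for _ in range(per_chrom):
            if gid >= cfg.n_genes:
                break
            length = int(rng.lognormal(cfg.gene_length_log_mean, cfg.gene_length_log_sd))
            length = max(length, 1_000)
            start, end = pos, pos + length
            # a few exon blocks covering ~30% of the transcript
            n_exons = 2 + int(rng.integers(0, 4))
            cuts = np.sort(rng.uniform(0, 1, size=2 * n_exons)) * length
            exons = tuple(
                (start + int(cuts[2 * i]), max(start + int(cuts[2 * i]) + 50, start + int(cuts[2 * i + 1])))
                for i in range(n_exons)
            )
            genes.append(
                GeneModel(
                    gene_id=f"G{gid:05d}",
                    chrom=f"chr{c + 1}",
                    transcript_intervals=((start, end),),
                    exon_intervals=exons,
                )
            )
            pos = end + int(rng.exponential(cfg.gene_spacing_mean)) + 1_000
            gid += 1
    return genes


def _draw_sets(
    cfg: SimConfig, rng: np.random.Generator, genes: Sequence[GeneModel]
) -> Tuple[GeneSetCollection, List[str], List[str]]:
    ids = [g.gene_id for g in genes]
    pool = ids[: int(cfg.n_genes * cfg.neural_pool_fraction)]
    sets: Dict[str, Tuple[str, frozenset]] = {}
    lo, hi = cfg.set_size_range
    for i in range(cfg.n_neural_sets):
        size = int(rng.integers(lo, hi + 1))
        members = frozenset(rng.choice(pool, size=size, replace=False))
        sets[f"neural{i + 1:02d}"] = (f"synthetic neural gene-set {i + 1}", members)
    for i in range(cfg.n_null_sets):
        size = int(rng.integers(lo, hi + 1))
        members = frozenset(rng.choice(ids, size=size, replace=False))
        sets[f"null{i + 1:02d}"] = (f"synthetic null gene-set {i + 1}", members)
    collection = GeneSetCollection(sets=sets, universe=frozenset(ids))
    return collection, pool, ids


def _cnv_interval(
    gene: GeneModel, length: int, chrom_len: int, rng: np.random.Generator
) -> Tuple[int, int]:
    gs, ge = gene.span
    lo = max(0, gs - length + 1)
    hi = max(lo + 1, min(ge, chrom_len - length))
    start = int(rng.integers(lo, hi))
    return start, start + length


def generate(cfg: Optional[SimConfig] = None) -> SyntheticCohort:
    """Generate a full synthetic cohort (subjects, genes, sets, CNVs, truth)."""
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)

    genes = _make_genome(cfg, rng)
    gene_sets, neural_pool, all_ids = _draw_sets(cfg, rng, genes)
    gene_by_id = {g.gene_id: g for g in genes}
    chrom_len = {g.chrom: 0 for g in genes}
    for g in genes:
        chrom_len[g.chrom] = max(chrom_len[g.chrom], g.span[1] + 100_000)

    subjects: List[Subject] = []
    for i in range(cfg.n_cases):
        sex = "male" if rng.random() < cfg.male_fraction_cases else "female"
        subjects.append(Subject(f"case{i:04d}", "case", sex))
    for i in range(cfg.n_controls):
        sex = "male" if rng.random() < cfg.male_fraction_controls else "female"
        subjects.append(Subject(f"ctrl{i:04d}", "control", sex))

    pool_set = set(neural_pool)
    weights_loss = np.array([cfg.burden_or if g in pool_set else 1.0 for g in all_ids])
    weights_loss /= weights_loss.sum()
    weights_gain = np.array([cfg.gain_burden_or if g in pool_set else 1.0 for g in all_ids])
    weights_gain /= weights_gain.sum()
    uniform = np.full(len(all_ids), 1.0 / len(all_ids))

    def draw_length(planted: bool) -> int:
        if planted:
            # upper tail of the length distribution: big multigenic events
            q = cfg.planted_length_quantile
            base = np.exp(cfg.cnv_length_log_mean + cfg.cnv_length_log_sd * stats.norm.ppf(q))
            length = int(base * rng.uniform(1.0, 2.0))
        else:
            length = int(rng.lognormal(cfg.cnv_length_log_mean, cfg.cnv_length_log_sd))
        return int(np.clip(length, cfg.min_cnv_length, cfg.max_cnv_length))

    def draw_record(subject: Subject, planted: bool, inheritance: str, clin: str) -> CnvRecord:
        if planted:
            # flagged high-effect events: mostly losses, always neural-pool
            dosage = "loss" if rng.random() < 0.62 else "gain"
            anchor = neural_pool[int(rng.integers(0, len(neural_pool)))]
        else:
            dosage = "loss" if rng.random() < cfg.loss_fraction else "gain"
            if subject.is_case:
                w = weights_loss if dosage == "loss" else weights_gain
            else:
                w = uniform
            anchor = all_ids[int(rng.choice(len(all_ids), p=w))]
        gene = gene_by_id[anchor]
        length = draw_length(planted)
        start, end = _cnv_interval(gene, length, chrom_len[gene.chrom], rng)
        return CnvRecord(
            subject_id=subject.subject_id,
            chrom=gene.chrom,
            start=start,
            end=end,
            dosage=dosage,
            inheritance=inheritance,
            clinical_class=clin,
        )

    n_dn = int(np.floor(cfg.de_novo_fraction * cfg.n_cases))
    n_path = int(np.floor(cfg.pathogenic_fraction * cfg.n_cases))
    case_ids = [s.subject_id for s in subjects if s.is_case]
    dn_carriers = list(rng.choice(case_ids, size=n_dn, replace=False))
    # more than half of pathogenic events are de novo
    n_path_dn = min(n_dn, (n_path + 1) // 2)
    path_from_dn = list(rng.choice(dn_carriers, size=n_path_dn, replace=False)) if n_path_dn else []
    others = [c for c in case_ids if c not in set(dn_carriers)]
    path_rest = list(rng.choice(others, size=n_path - n_path_dn, replace=False))
    path_carriers = path_from_dn + path_rest
    flagged = sorted(set(dn_carriers) | set(path_carriers))

    subj_by_id = {s.subject_id: s for s in subjects}
    records: List[CnvRecord] = []
    for s in subjects:
        for _ in range(rng.poisson(cfg.cnv_rate)):
            records.append(draw_record(s, planted=False, inheritance="inherited", clin="unclassified"))
    for sid in flagged:
        inheritance = "de_novo" if sid in set(dn_carriers) else "inherited"
        clin = "pathogenic" if sid in set(path_carriers) else "uncertain"
        records.append(draw_record(subj_by_id[sid], planted=True, inheritance=inheritance, clin=clin))

    # respect the QC burden cap: drop a subject's longest events until its
    # summed CNV length is within bounds (QC then removes nothing)
    by_subject: Dict[str, List[int]] = {}
    for i, r in enumerate(records):
        by_subject.setdefault(r.subject_id, []).append(i)
    drop: set = set()
    for sid, idxs in by_subject.items():
        idxs = sorted(idxs, key=lambda i: records[i].length, reverse=True)
        total = sum(records[i].length for i in idxs)
        while total > 7_500_000 and idxs:
            i = idxs.pop(0)
            drop.add(i)
            total -= records[i].length
    if drop:
        records = [r for i, r in enumerate(records) if i not in drop]

    # enforce the rare-variant condition: redraw any CNV whose carrier
    # frequency (50% reciprocal overlap grouping) exceeds the cap
    n_subjects = len(subjects)
    for _ in range(20):
        counts = _reciprocal_carrier_counts(records, 0.5)
        bad = np.nonzero(counts / n_subjects > cfg.max_frequency)[0]
        if len(bad) == 0:
            break
        for i in bad:
            old = records[i]
            planted = old.inheritance == "de_novo" or old.clinical_class == "pathogenic"
            records[i] = draw_record(
                subj_by_id[old.subject_id], planted, old.inheritance, old.clinical_class
            )
    else:
        counts = _reciprocal_carrier_counts(records, 0.5)
        keep = counts / n_subjects <= cfg.max_frequency
        records = [r for r, k in zip(records, keep) if k]

    truth = {
        "config": _jsonable(asdict(cfg)),
        "neural_sets": sorted(sid for sid in gene_sets if sid.startswith("neural")),
        "null_sets": sorted(sid for sid in gene_sets if sid.startswith("null")),
        "neural_pool_size": len(neural_pool),
        "de_novo_carriers": sorted(dn_carriers),
        "pathogenic_carriers": sorted(path_carriers),
        "planted_carriers": flagged,
    }
    return SyntheticCohort(
        subjects=subjects,
        gene_models=genes,
        gene_sets=gene_sets,
        records=records,
        truth=truth,
    )


def _jsonable(d: Dict) -> Dict:
    out = {}
    for k, v in d.items():
        if isinstance(v, (np.floating, np.integer)):
            v = v.item()
        elif isinstance(v, tuple):
            v = list(v)
        out[k] = v
    return out


def truth_check(
    truth: Dict,
    importances: "Dict[str, float] | None" = None,
    prioritized: Optional[Sequence[str]] = None,
    population: Optional[Sequence[str]] = None,
) -> Dict:
    """Check whether the analysis recovered what the generator planted.

    ``importances`` (feature name -> MDA) is summarized as mean ranks of
    neural-loss vs null-loss vs gain features (higher rank = more
    relevant). ``prioritized`` vs ``population`` (subject ids) yields a
    hypergeometric enrichment p-value for planted-signal carriers.
    """
    report: Dict = {}
    if importances is not None:
        import pandas as pd

        imp = pd.Series(dict(importances))
        ranks = imp.rank()  # average ranks; higher = more relevant
        neural_loss = [f"{s}_loss" for s in truth["neural_sets"]]
        null_loss = [f"{s}_loss" for s in truth["null_sets"]]
        gains = [c for c in imp.index if c.endswith("_gain")]
        report["neural_loss_mean_rank"] = float(ranks.reindex(neural_loss).mean())
        report["null_loss_mean_rank"] = float(ranks.reindex(null_loss).mean())
        report["gain_mean_rank"] = float(ranks.reindex(gains).mean()) if gains else None
        report["neural_loss_outranks_null"] = bool(
            report["neural_loss_mean_rank"] > report["null_loss_mean_rank"]
        )
        if gains:
            report["loss_outranks_gain"] = bool(
                report["neural_loss_mean_rank"] > report["gain_mean_rank"]
            )
    if prioritized is not None and population is not None:
        planted = set(truth["planted_carriers"]) & set(population)
        n_pop, n_planted = len(set(population)), len(planted)
        n_pri = len(set(prioritized))
        k = len(set(prioritized) & planted)
        p = float(stats.hypergeom.sf(k - 1, n_pop, n_planted, n_pri)) if n_pri else 1.0
        report["enrichment"] = {
            "population": n_pop,
            "planted_in_population": n_planted,
            "prioritized": n_pri,
            "planted_in_prioritized": k,
            "p_value": p,
        }
    return report
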