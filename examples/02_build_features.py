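"""From CNV calls to gene-set burden features.

Each CNV is mapped to the genes whose transcripts it overlaps; the
feature for gene-set S and dosage `loss` is the number of DISTINCT genes
of S hit by the subject's rare losses, plus one total distinct-gene
count. Subjects with no genic rare CNV have all-zero rows and are
excluded from classification (but still counted in cohort percentages).
"""

from cnvclassify import QcConfig, SimConfig, apply_qc, generate
from cnvclassify.features import build_features, map_cnv_to_genes

cohort = generate(SimConfig(seed=1))

records, excluded, audit = apply_qc(cohort.records, cohort.subjects, QcConfig())
print(f"QC audit: {audit}")  # generated data passes untouched

gene_map = map_cnv_to_genes(records, cohort.gene_models, mode="transcript")
genic = sum(1 for g in gene_map if g)
print(f"{genic}/{len(records)} CNVs overlap at least one gene transcript")

matrix = build_features(cohort.subjects, records, gene_map, cohort.gene_sets, scope="all")
print(f"feature matrix: {len(matrix.subjects)} subjects x {len(matrix.feature_names)} features")
print(f"zero-burden subjects excluded from classification: {len(matrix.dropped_subjects)}")
print()
print("first rows (loss/gain counts per set, then the total gene count):")
print(matrix.values_df.iloc[:5, [0, 1, 20, 21, -1]])
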