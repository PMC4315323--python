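"""Generate a synthetic rare-CNV case-control cohort and look at it.

The generator lays ~2,000 genes on a synthetic genome, draws neural and
null gene-sets, and gives every subject a Poisson number of rare genic
CNVs; case losses pick their anchor gene from the neural pool with odds
multiplied by `burden_or`. A small slice of cases carries flagged de novo
or pathogenic events with strong neural hits.
"""

from collections import Counter

from cnvclassify import SimConfig, generate

cohort = generate(SimConfig(seed=1))

n_cases = sum(s.is_case for s in cohort.subjects)
print(f"subjects: {len(cohort.subjects)} ({n_cases} cases / {len(cohort.subjects) - n_cases} controls)")
print(f"genes: {len(cohort.gene_models)}, gene-sets: {len(cohort.gene_sets)}")
print(f"CNV calls: {len(cohort.records)}")

by_dosage = Counter(r.dosage for r in cohort.records)
print(f"losses/gains: {by_dosage['loss']}/{by_dosage['gain']}")
print(f"flagged de novo carriers: {len(cohort.truth['de_novo_carriers'])}")
print(f"flagged pathogenic carriers: {len(cohort.truth['pathogenic_carriers'])}")

lengths = sorted(r.length for r in cohort.records)
print(f"CNV length range: {lengths[0]/1e3:.0f} kb - {lengths[-1]/1e6:.2f} Mb "
      f"(median {lengths[len(lengths)//2]/1e3:.0f} kb)")
# every event is rare (<=1% carrier frequency) and 30 kb - 7.5 Mb by
# construction, so downstream QC removes nothing

cohort.write("scratch/example_cohort")
print("cohort written to scratch/example_cohort/")
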