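# Methods

## Problem setting

A case-control cohort is observed through rare CNV calls: per subject, a
set of genomic intervals labelled loss/gain, with inheritance (de novo /
inherited / unknown) and a clinical significance tier (pathogenic /
uncertain / benign / unclassified) supplied as trusted inputs. The
analysis asks how well cases can be separated from controls using
gene-set burden counts, which dosage type carries the signal, and which
individual cases are called confidently and reproducibly enough to be
prioritized for follow-up.

## Coordinates, QC and feature construction

Intervals are stored 0-based half-open; the headered TSV dialect accepts
1-based inclusive coordinates and converts on read. QC applies three
independently switchable filters: a 30 kb length floor per call, a 7.5 Mb
cap on a subject's summed CNV length (violators lose all their calls),
and a 1% carrier-frequency cap. The frequency operator is not uniquely
defined in the field; this package counts, for each call, the distinct
subjects carrying a same-dosage call on the same chromosome with ≥ 50%
reciprocal overlap, and divides by the cohort size. Both the overlap
fraction and the cap are configurable, and inputs may arrive pre-filtered
with the corresponding filters switched off.

A CNV maps to a gene when it shares ≥ 1 bp with any transcript
(`transcript` mode) or any exon (`exonic` mode, which errors if exon
models are absent). Burden features count distinct genes, not events or
base pairs: a subject with two losses in one gene and a subject with one
loss there contribute identically. In single-dosage runs (`loss_only` /
`gain_only`) the total gene count is restricted to that dosage so all
features in a run share one scope. Zero-burden subjects are dropped from
the matrix but reported, and re-enter the denominators of
percent-explained statistics.

Randomized null features permute gene identities with one uniform
permutation of the universe applied to every set, preserving set sizes
and the correlation structure among sets; by construction they retain
total-burden information and nothing set-specific.

## Conditional inference forest

At a node with samples (x, y), the association between a candidate
feature and the binary label is measured by T = Σ xᵢ·1[yᵢ = case]. Under
random permutation of y, T is a without-replacement sample-sum with

    E[T]  = n₁ · x̄,
    Var[T] = n₁(n−n₁)/(n(n−1)) · Σ(xᵢ − x̄)²,

and z = (T − E[T])/sd is referred to the standard normal (two-sided).
The `quadratic` and `max_abs` statistic variants coincide for one numeric
feature against a binary label (z² against χ²₁ equals |z| against the
two-sided normal); both spellings are accepted. Constant features get
p = 1 by convention; pure nodes are never tested.

Growth: at each node, `mtry` features are drawn without replacement, the
minimum candidate p-value is Bonferroni-adjusted by the number of
non-constant candidates, and growth stops when the adjusted p exceeds
`alpha`, the node is smaller than `min_split`, or no cut point leaves
both children with ≥ `min_bucket` samples. The cut point maximizes the
standardized two-sample statistic over admissible thresholds (midpoints
between adjacent distinct values). Defaults follow the unbiased-forest
convention: 500 trees, mtry 5, 63.2% subsampling without replacement,
min_split 20, min_bucket 7, alpha 1 (no significance stopping). Candidate
order is already randomized by the draw, and `argmin` breaks p-value ties
by that order, which avoids a systematic index preference.

The asymptotic normal p-value replaces exhaustive permutation because
node sizes make enumeration infeasible; exact enumeration appears only as
a test oracle. At n ≤ 10 the approximation tracks the exact permutation
tail closely in *ordering* (Spearman ρ > 0.9) but its *level* can deviate
substantially on heavily tied count features, where the exact statistic
lives on a few lattice points (in the extreme, a two-valued feature makes
every outcome equally extreme and the exact two-sided tail is 1). Inside
the tree the p-value's job is ranking candidates, so ordering is the
property that matters; the tests assert level agreement (within 0.15)
only on untied instances.

Variable importance is the standard out-of-bag MDA: per tree, OOB
accuracy minus OOB accuracy after permuting one feature's OOB values,
averaged over all trees (trees not using the feature contribute exactly
0). The correlation-adjusted "conditional" MDA variant is out of scope.

## Baselines

Random Forest is bagged CART: sklearn decision trees with sqrt(p) feature
sampling on bootstrap-with-replacement samples, bagged in-repo so each
tree's in-bag indices are available for OOB MDA; mean-decrease-Gini is
the unnormalized impurity decrease averaged over trees. The linear SVM
(libsvm via sklearn, cost 1, even class weights) sees features min-max
scaled to [0, 1] by a scaler fitted on the training fold only; test
values are clipped and constant columns map to 0. Its decision values are
min-max mapped over the test fold — a strictly monotone, hence
AUC-invariant, mapping to [0, 1]. The neural network is a (100, 50)
multilayer perceptron with logistic activations trained by SGD with
learning rate 0.005 and momentum 0.9, up to 500 epochs with early
stopping on a training-loss plateau (tol 1e-5, patience 20) — the epoch
budget and stopping rule are configuration defaults recorded here, not
claims about an optimum; no feature scaling is applied.

## Feature selection

Selection runs inside each training fold only and never sees test rows;
the CV driver passes only the fold's training frame, and a property test
verifies held-out rows cannot influence the output. The total gene count
never competes for the budget and is re-appended after selection. MDA
selection ranks by a relevance function (by default the CF's own OOB
MDA) and cuts to top 20 / top 15% / top 40% of the pool excluding the
total count. Decorrelation walks the ranking and drops any feature with
|Pearson r| > 0.75 to an already-kept feature before cutting. MRMR
discretizes counts as {0, 1, 2, ≥3}, starts from the feature with
maximal mutual information with the label, and greedily adds the feature
maximizing relevance minus mean pairwise redundancy (MID; the MIQ
quotient is available by flag). The 0.75 threshold and the cap-at-3
discretization are package defaults exposed in `SelectionSpec`.

## Cross-validation and prioritization

Each iteration re-divides the cohort into k = 3 stratified folds
(per-class fold sizes differ by ≤ 1); each fold serves once as the test
set, so every subject gets exactly one out-of-fold probability per
iteration. One AUC per iteration is computed from the pooled out-of-fold
probabilities in Mann–Whitney form (ties ½); the default 20 iterations
yield the mean ± sd. Model seeds are derived per (iteration, fold) from
the run seed, so repeated runs are bit-reproducible.

Prioritization: a subject is stably case-predicted at cutoff θ if its
out-of-fold probability is ≥ θ in ≥ s of the iterations (default 15/20;
s = 10 is a supported sensitivity setting). TP* is the stably-predicted
percentage of case carriers excluding pathogenic and de novo carriers —
a conservative true-positive pool, since flagged carriers are easy — and
FP the stably-mispredicted percentage of control carriers. The scan over
θ ∈ {0.50, 0.51, …, 0.95} keeps cutoffs with TP* > 1.5·FP and reports
the one maximizing the stable TP* count (ties → smallest θ), along with
FP/TP* as an FDR-style bound. "Correctly predicted" for a case and
"incorrectly predicted" for a control are both read as probability ≥ θ.
Percent explained divides the stable-correct case count by the full
study total, including subjects excluded from fitting. Female enrichment
of the prioritized list is a two-sided Fisher exact test on the
female/male × prioritized/rest table; a zero margin yields an undefined
odds ratio and p = 1.

## Synthetic cohorts

The generator emulates the structure the analysis assumes: 400 cases /
500 controls (cases ~86% male, controls ~47%); 2,000 genes with
log-normal lengths (median 30 kb) and exponential spacing (mean 60 kb)
over 10 chromosomes; 10 "neural" sets drawn from a designated 40% gene
pool and 10 null sets drawn uniformly, 100–300 genes each; Poisson(1.61)
genic CNVs per subject, making ~80% of subjects carriers; log-normal CNV
lengths (median 100 kb) clipped to 30 kb – 7.5 Mb; losses and gains
equally likely. Case losses choose their anchor gene with odds multiplied
by `burden_or` (default 3) for neural-pool genes; gains are unbiased by
default. 4.1% of cases carry a flagged de novo event and 3.0% a
pathogenic one (more than half of pathogenic events de novo); flagged
events are mostly losses, always neural-anchored, drawn from the upper
length tail — they are planted signal, so a *null* configuration must
set both the burden odds to 1 **and** the flagged fractions to 0.
Generated cohorts satisfy the QC bounds by construction (lengths clipped,
per-subject burden trimmed, carrier frequencies enforced by redrawing
offenders), so QC is a no-op on them unless violations are injected
deliberately.

What the generator does not model: real genome coordinates and gene
density, linkage structure, recurrent CNV hotspots, array noise and call
uncertainty, ancestry stratification, and any sex-linked effect. Passing
tests therefore demonstrate that the pipeline recovers a planted
gene-choice-level burden through the full mapping/counting/classification
path — not that the method attains any particular AUC on real cohorts.

## Problem sizes and numerical notes

Test-suite simulations use 100-tree forests and 3–5 CV iterations on the
default 900-subject cohort; the acceptance script uses 200 trees and the
full 20 iterations. These sizes are the package's chosen trade-off
between statistical resolution and a desk-scale run; the contrasts they
measure (losses vs gains, curated vs randomized, flagged carriers vs all)
are several pooled sd wide at these sizes. One caveat measured during
development: the cross-validated AUC of a single finite cohort carries
dataset-level noise of about ± 0.03 at this scale — chance feature-label
correlations of the draw are shared by every fold division — so
chance-level assertions for null cohorts are made on means over several
independently generated cohorts rather than on a single draw.

Degenerate inputs are defined throughout: constant features are
untestable (p = 1) and unscalable (map to 0), single-class training sets
yield constant probability, empty prioritized sets are an error, and
zero-margin contingency tables report an undefined odds ratio.
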