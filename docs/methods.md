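# Methods

This note documents the models and procedures implemented in `p53lnc`,
their assumptions, the parameters that matter, the synthetic-data
generator, and the numerical choices made where the design was open.

## Coordinate contract

All internal coordinates are 0-based half-open. GTF input (1-based closed)
is converted on read; BED input is consumed unchanged. A gene's span is the
min/max over its transcripts and its TSS set is the deduplicated collection
of transcript starts (leftmost base on `+`, rightmost on `-`). "Within
*d* kb of a TSS" is read inclusively: position *p* qualifies when
|p − tss| ≤ d, so a TSS window spans 2d + 1 bases. Windows of a multi-TSS
gene may overlap and are deliberately not merged; assignment asks only
whether *any* window overlaps *any* site by at least one base. Chromosome
naming dialects (`chr1` vs `1`) can be reconciled with a configurable
prefix rule at BED load time.

## Expression score

For each gene the score counts datasets with a significant up-call minus
datasets with a significant down-call. Assumptions: per-dataset DE calls
are exchangeable votes; no effect-size pooling is attempted (the statistic
is deliberately a count, robust to heterogeneous designs). Parameters:

| parameter | default | meaning |
|---|---|---|
| `sig_fdr` | 0.05 | per-dataset significance on the adjusted p |
| `min_expressed` | 3 | minimum testable datasets; genes below are dropped, not scored 0 |
| `up_threshold` / `down_threshold` | +10 / −10 | inclusive recurrence cutoffs |

A significant entry with log2FC exactly 0 counts in neither direction
(its direction is undefined). Published per-dataset calls can be supplied
as a ternary `call` column (up/down/ns), which then overrides the FDR
rule; the median log2FC is always computed from the numeric column,
ignoring significance, with the even-count median taken as the midpoint of
the central pair.

## Binding-site recurrence

Recurrence is defined per base: peak sets (each merged internally first)
are partitioned into segments of constant dataset support, segments with
support ≥ k are kept and merged (book-ended only, `merge_gap = 0`, by
default). The alternative — counting whole-peak reciprocal overlaps — was
rejected because the per-base partition is what the multi-way
intersection operation computes, and it makes the recurrence set exactly
the thresholded coverage function, which is testable against a
brute-force per-base oracle. Factor thresholds default to the published
k/n values (p53 5/28, E2F4 4/9, p130/p107 2/4, RB 3/6); an
already-integrated p53 site list can be loaded instead of the 28 raw peak
sets. DREAM sites are the interval intersection of recurrent E2F4 and
p130/p107 sites, so the DREAM base set is exactly the intersection of the
parents' base sets.

## Mechanism assignment

Direct-p53 and enhancer-mediated flags are evaluated on the recurrently
up-regulated set only, DREAM/RB flags on the down-regulated set only,
mirroring the activating vs repressive arms of the network (an
`all_genes_mode` exists for exploration). Enhancer mediation requires a
high-confidence ("double-elite") enhancer link whose interval overlaps a
recurrent p53 site, and the *absence* of TSS-proximal p53 binding at every
TSS of the gene (gene-level exclusion; the per-TSS alternative would make
a gene both direct and enhancer-mediated, which the mutual-exclusion
contract forbids). Overlap is interval-vs-interval with a ≥ 1 base
criterion; peak summits are not modelled because integrated site lists do
not carry them (a midpoint mode would be a trivial extension).

## Nested co-regulation

Nesting is strand-aware span containment with an overlap fraction of 1
for the lncRNA; exon structure never gates pairing (a placement label
such as intronic/3′UTR would be descriptive only). Co-regulation is the
Spearman correlation of the paired log2FC vectors over datasets where
both genes are testable; pairs sharing fewer than 3 datasets are flagged
untestable. Ties get average ranks. The two-sided p-value uses the exact
permutation null (all n! pairings, enumerated vectorised) below n = 10
and the large-sample t approximation otherwise; the crossover keeps small
sparse pairs honest — note that with n ≤ 4 even a perfect rank agreement
cannot reach p < 0.05 under the exact null. "Significantly positively
co-regulated" means rho > 0 and p < `alpha` (default 0.05, configurable
since no alpha is canonical for this call).

## Perturbation dependence

Contrasts use a pooled-variance two-sided t-test on log2(TPM + 1) (raw
scale available); the log transform stabilises multiplicative RNA-seq
noise. Degenerate inputs are defined, not crashed on: zero pooled
variance with equal means gives t = 0, p = 1; with unequal means p = 0
flagged degenerate. A gene is **p21-dependent** when the parental line is
significantly repressed and the knockout fails to repress — not
significant, or |log2 repression| below `failure_fraction` (default 0.5)
of the parental magnitude. The quantitative branch is needed because "no
longer significant" alone would let a barely-attenuated repression count
as failure at small n; the 50 % default is exposed as configuration since
no published cutoff exists. Pocket-protein predominance is a pure
function of the per-genotype repression truth table: lost only under RB
depletion → RB-predominant; only under p130/p107 depletion →
DREAM-predominant; only in the triple → cooperative; anything else →
unresolved, and every resolved call requires loss in the triple
depletion. Detection requires mean parental-control TPM ≥ 1
(`detection_tpm`). Mediator dependence (e.g. siRFX7 vs siControl) reuses
the p21 rule verbatim with the knockdown as the "knockout" genotype.

## Survival stratification

The single-sample enrichment score ranks a sample's genes descending
(average ranks on ties; ties in the ordering broken by gene label for
determinism) and accumulates ES = Σᵢ [P_in(i) − P_out(i)], where set
genes contribute weights rank^α (the top gene carries weight N) and
non-set genes contribute uniformly. α defaults to 0.75 and the raw scores
are rescaled by the cohort's score range; both follow the behaviour
documented for the standard single-sample GSEA implementation and are
configurable. Tertiles are assigned after sorting by (score, sample id);
remainders go to the low group first, then high, so
|low| ≥ |medium|, |high|. The Cox model uses Efron tie handling with two
group indicators (reference = low), age, and a male-sex indicator; the
group effect is tested by a likelihood-ratio test against the nested
model without the indicators (χ², 2 df). Kaplan–Meier curves are full
product-limit estimates; the 5000-day horizon truncates display only.
p53-status sub-analyses recompute scores, tertiles and fits within each
sub-cohort (the alternative — freezing full-cohort tertiles — would leave
unbalanced groups after splitting); unknown-status patients are excluded
from both sub-cohorts. Gene-set overlaps use the two-sided Fisher exact
test on the 2×2 membership table over an explicit background.

## Synthetic-data generator

The generator emulates the structure of the real study inputs at their
native scales: 44 DE datasets, 28/9/4/6 peak sets, three replicates per
perturbation arm, a 600-patient cohort. Defaults and what they represent:

* DE compendium — planted up/down genes respond (significant,
  log2FC ~ N(±1.5, 0.4)) in 55 % of the datasets where they are present;
  presence is dropped at 20 % per (gene, dataset), reflecting sparse
  lncRNA detectability. With ~35 present datasets the expected score is
  ≈ 19, comfortably above the +10 cutoff, which matches the "conservative
  threshold" design of the score. Significance is generated directly
  rather than via a count-model fit because the pipeline consumes calls,
  not counts. Nested lncRNAs copy their host's fold-change up to
  N(0, 0.1) with shared presence.
* Peak compendium — truth sites (301 bp at the target TSS, or inside the
  planted enhancer) are detected per dataset with probability 0.85 and
  jittered by N(0, 10 bp); 30 decoy sites, placed ≥ 12 kb from every TSS,
  are detected at 0.05 so they essentially never reach recurrence.
* Annotation — genes sit in 60 kb slots on one chromosome; coding genes
  (15 kb, two TSSs 500 bp apart) host the nested lncRNAs (2 kb, 5 kb
  inside the host); an antisense-nested and a half-overlapping lncRNA are
  planted as deliberate non-pairs.
* TPM experiments — log2 baselines ~ N(5, 1), treatment effects ±2 log2
  units, replicate noise N(0, 0.2), n = 3 per arm.
* Cohort — exponential event times (baseline hazard 1/2000 per day),
  group hazard ratios planted at 1.0 (medium) and 2.0 (high);
  an independent exponential censoring process with rate
  baseline · c/(1−c) censors c ≈ 30 % of the baseline group. Set-gene
  expression is shifted by one noise SD per group step so enrichment
  scoring reconstructs the planted groups with ≈ 0.95+ accuracy.

A `noiseless` switch sets full response, zero missingness, perfect peak
detection and zero replicate noise, making every planted classification
recoverable with precision = recall = 1 — this is the end-to-end
correctness check. What passing on synthetic data does **not** show: the
generator has no correlated confounding between datasets, no GC/mappability
artefacts in peaks, no isoform-level complexity, and per-dataset DE calls
are conditionally independent given the plant — conclusions about
real-data operating characteristics (e.g. how many genes truly clear the
±10 cutoff) do not transfer.

## Problem sizes and determinism

Test and demonstration runs use 170 genes, 44 DE datasets, 47 peak sets
and a 600-patient cohort, sizes at which the full pipeline completes in
seconds while every planted structure remains statistically recoverable;
the Cox calibration checks use 100 independent 600-patient cohorts. All
generators are pure functions of (parameters, seed); the pipeline records
its configuration and stage counts in `manifest.json`, and reruns with
the same config and seed are byte-identical.

## Known limitations

* DE significance calls are consumed as given; heterogeneous upstream
  pipelines are not harmonised beyond the count statistic itself.
* Mechanism assignment is interval-based; no 3D contact or
  enhancer–promoter interaction evidence is used, so enhancer mediation
  is a proximity/association hypothesis, not a demonstrated loop.
* The Cox model pools the cohort; cancer-type stratification and
  competing risks are out of scope.
* p53 mutation status is taken from the cohort table; calling it from a
  variant table is reduced to a configurable non-silent classification
  list and not further curated.
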