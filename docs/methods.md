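# Methods

This note documents the models and procedures regcompare implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was genuinely open.

## Coordinate conventions

All internal coordinates are 0-based half-open (BED convention). GFF3 is
converted on read: TSS = `start − 1` on the plus strand, `end − 1` on the
minus strand. Minus-strand chain query coordinates are kept in the
chain-native reverse-complement frame exactly as parsed, with an explicit
forward-strand converter (`pos_fwd = q_size − 1 − pos_rev` for bases), so
strand handling is testable in isolation.

Signed TSS distances are 0 when the element contains the TSS, measured from
the nearer element boundary otherwise (the interval start on the left, the
exclusive end on the right), and negative when the TSS lies 5′ of the
element along the gene's strand. Ties between equidistant genes go to the
lexicographically smallest gene id. One boundary artifact of the
exclusive-end convention: a TSS exactly at `end` has distance 0 without
being contained.

## Consensus peaks

A replicate pair supports a consensus peak when the two peaks overlap by at
least `min_frac` (default 0.5) of **both** peak lengths. All peaks connected
through such mutual pairs are transitively union-merged — so a chain
A1–B1–A2 collapses into one region, matching what merging the union with
bedtools would give — into a consensus peak with the mean fold enrichment of
its members and the summit of the strongest member. Peaks without a mutual
partner are dropped (consensus support is ≥ 2 by construction). The
operation is symmetric in its replicate arguments, and raising `min_frac`
can only shrink the output. Upstream pooled-replicate machinery
(ENCODE-style overlap scripts, IDR) needs read-level data and is out of
scope; the symmetric two-replicate rule is the documented file-level
substitute using the same 50%-of-length criterion.

## Element classification

Classification is purely operational co-occupancy, no functional assay
implied:

* H3K4me3 consensus peak with no H3K27ac overlap → **promoter** (single mark);
* H3K27ac with no H3K4me3 overlap → **enhancer**;
* an H3K4me3/H3K27ac pair overlapping by ≥ `recip_frac` (default 0.5) of
  both lengths → one merged double-marked **promoter** (union span, mean
  fold); multiple mutually qualifying peaks merge transitively;
* overlapping pairs failing the reciprocal test → **ambiguous**, excluded
  downstream. This is the conservative reading: it keeps "enhancer = only
  H3K27ac" and "promoter = H3K4me3 ± co-located H3K27ac" literally true.

The reciprocal test is inclusive (≥) so boundary cases are deterministic.
Promoters are then split on |TSS distance| ≤ `max_tss_distance` (default
3 kb, configurable; the exact grouping used to produce high-confidence
promoter counts on real data is underdetermined, so the band is an explicit
knob) into high-confidence and distal sets — the distal set is returned,
not discarded. Elements link to their nearest gene when the TSS is within
`max_link_distance` (default 1 Mb); for cross-species use, pass the
ortholog-filtered gene list.

## Liftover and conservation calls

`map_interval` follows liftOver semantics: among chains covering the
source interval the highest score wins (ties by chain id); bases in aligned
blocks project to query coordinates; the mapped interval is the [min, max)
hull of projected bases on the query's forward strand; the call is
`mapped` only when the aligned fraction is ≥ `min_match` (default 0.95, the
liftOver same-species default — the appropriate value for diverged genome
pairs is lower and is a config knob). With a single covering chain the
projection cannot split across chromosomes; the `split` status is retained
in the interface for multi-chain extensions.

The units lifted are 100-bp windows centred on the element midpoint
(full-length mode behind a flag): short windows keep the aligned-fraction
criterion meaningful when element boundaries are noisy. An element is
**alignable** when A→B and B→A both map and the round-trip interval has the
same nearest-gene call (within species A, comparing within-species gene
ids). Alignable elements overlapping (≥ 1 bp) a same-class element at any
stage of the other species are **conserved**; alignable without any
same-class overlap, **species-specific**; everything else, **unalignable**.
Cross-class overlaps (mapped enhancer on a promoter) are not conserved
activity. The three labels partition every element.

## Expression thresholds

TPM and CPM are the standard identities (`tpm_gs = 10⁶·(c_gs/L_g)/Σ_g`,
`cpm_gs = 10⁶·c_gs/Σ_g`), using total gene length — no isoform model,
matching gene-level counting. Threshold rules, all strict inequalities:

* reproducibly expressed: TPM > 1 in **every** replicate of a species/stage;
* low-expression filter: CPM > 2 in ≥ 2 replicates;
* species-specific high expression: mean TPM > 10 in species A and mean
  TPM < 1 at every species-B stage, over one-to-one orthologs ("low to no
  activity" is operationalized as the same 1-TPM expressed/not-expressed
  boundary; configurable). Genes without an ortholog are excluded and
  counted.

Replicate aggregation for stage-level comparisons is the mean of replicate
TPMs.

## Temporal clustering

Dynamic genes: max over later stages of |log₂((cpm_t + 0.5)/(cpm_0 + 0.5))|
strictly above 2. This pseudocount fold-change rule replaces the
negative-binomial GLM time-course test used with count-level tooling — a
documented simplification (no dispersion estimation) that preserves the
clustering input: genes changing > 4-fold against baseline. Profiles are
log₂(CPM+1) stage means, z-scaled per gene with the population standard
deviation.

The clusterer is Bezdek fuzzy c-means (Euclidean distance; fuzzifier
m = 2, the common soft-clustering default; tolerance 1e-6 on the max center
shift; 500 iterations max). Membership rows sum to 1; a point coincident
with a center takes membership 1 there; the objective Σ u^m d² is
non-increasing across iterations. Because the objective is non-convex and a
single random initialization can merge two true clusters, the optimization
restarts `n_init = 5` times from k distinct data points (all draws from one
seeded generator) and returns the run with the lowest final objective —
the same remedy k-means implementations use.

The cluster count is selected separately, by the Calinski–Harabasz index
CH(k) = [B(k)/(k−1)]/[W(k)/(n−k)] over hard k-means partitions for k in
1..10 (CH is undefined at k = 1, which is reported as NaN and excluded from
the argmax). Selection on hard partitions with fuzzy final clustering
mirrors the two-tool procedure common in time-course packages.

## Enrichment statistics

* **2×2 tests**: two-sided Fisher exact p (equal to exhaustive
  hypergeometric enumeration); odds ratio = sample OR (a·d)/(b·c) with the
  Haldane–Anscombe +0.5 correction when any cell is zero; 95% CI by Woolf
  on the log scale. The sample-OR/Woolf pair is closed-form and
  oracle-testable; it differs from the conditional-MLE OR that R's
  `fisher.test` reports by ~2 decimals on large balanced tables.
* **Multiplicity** follows the analysis family: Holm (step-down FWER) for
  the cluster-overlap family, Benjamini–Hochberg FDR (threshold 0.01) for
  gene-set and motif families. Note neither adjustment is idempotent —
  re-adjusting adjusted values changes them — so adjusted values must be
  computed once from raw p-values.
* **Gene sets**: one-sided hypergeometric over-representation against a
  user-supplied universe; GMT input; empty sets skipped with a warning.
* **Motifs**: PWMs from JASPAR PFM or MEME minimal text; log₂-odds scores
  against the background set's base composition; a sequence is a hit
  (ZOOPS) when any window on either strand reaches 80% of the maximal
  achievable score (a standard PWM practice; per-motif configurable — no
  attempt to replicate any scanner's internal threshold optimization);
  sequence-level hit counts go into one-sided Fisher tests against a
  GC- and length-matched sampled background (per-sequence GC within ±2
  percentage points, identical lengths, seeded, bounded rejection
  sampling). Sequences with > 10% non-ACGT content are excluded.
* **Set intersections**: exclusive (upset-style) per-signature tallies;
  sizes sum to the union cardinality.

## The synthetic-data generator

The generator emulates the study conditions, not sequence evolution. Each
genome pair is built from gene-sized segments (≥ 12 kb, one gene each, TSS
placed centrally); a segment is conserved with probability
`conserved_frac`, carried unchanged into genome B as an aligned chain
block (adjacent conserved segments merge, so a fully conserved chromosome
is a single identity block), with one-to-one ortholog ids. Non-conserved
segments get independent lengths in B (0.8–1.2×) and fall into chain gaps.
The A→B and B→A chains are mutually inverse by construction, so round-trip
liftover is exactly the identity on conserved segments.

Elements are planted at fixed offset slots around their segment's TSS —
promoters within ±1.1 kb (600 bp wide), enhancers at 2.6–5.2 kb (500 bp) —
which guarantees the planted nearest gene and keeps planted promoters
inside the 3-kb high-confidence band. Conserved and species-specific
elements sit in conserved (alignable) segments; `element_conserved_frac`
(default 0.3) of them have an active partner in B. Promoters emit
co-located H3K4me3+H3K27ac peaks, enhancers H3K27ac only; per replicate,
endpoints are jittered Normal(0, `jitter_sd`) and peaks dropped
independently with probability `dropout`; fold enrichments are log-normal
(µ = 1.6, σ = 0.5 on the log scale).

Expression matrices are negative binomial (gamma–Poisson; Poisson at
dispersion 0, default dispersion 0.05) around planted TPM profiles: five
cluster shapes (late ramp, ramp-down, last-stage peak, mid peak, early
spike, all exceeding the 4-fold dynamic threshold), a flat fraction
(default 10%) excluded by the fold-change filter by construction, and a 5%
species-specific fraction planted flat at 50 TPM in A and 0.05 TPM in B. A
pool of 200 flat background genes absorbs the residual transcript mass so
that planted TPM values are realized TPM values — without it the
normalization would inflate a small gene set by orders of magnitude and the
1/10-TPM thresholds would be meaningless. Library size 2×10⁶; default
6 stages × 3 replicates.

One integer seed drives a named substream per output, so identical seeds
give byte-identical files and components are independently reproducible.

What the generator does **not** emulate — and hence what green tests do not
show about real data: nucleotide sequences and their evolution (chains are
segment bookkeeping, not alignments of real sequence), read-level noise and
mapping artifacts, peak-width and intensity distributions of real ChIP,
overlapping or nested genes, many-to-many orthology, chromosomal
rearrangements beyond segment indels (inversions appear only in hand-built
test chains), and library-composition effects in RNA-seq beyond NB noise.
Recovery results certify the interval/projection/threshold logic, not
biological discovery power.

## Evaluation of planted-truth recovery

With per-peak replicate dropout d, the probability that both replicates of
a mark survive is (1−d)², so unconditional recall is bounded by ~0.81 at
d = 0.1 regardless of implementation quality. Recovery is therefore scored
as label accuracy over elements whose *required* evidence survived: an
element enters the class denominator when both replicates of its defining
mark survived in species A (H3K27ac for enhancers, H3K4me3 for promoters),
and the conservation denominator when, in addition, its partner's defining
peaks survived in B (for planted-conserved elements). Endpoint jitter — the
noise the classifier must actually absorb — is always unconditional. The
truth manifest records every emitted peak so this conditioning is explicit
and reproducible.

## Problem sizes

The test suite and `scripts/acceptance.py` use desk-scale fixtures chosen
to exercise every code path with tight statistics: 3-chromosome genomes;
500 planted elements (30% conserved, 5-bp jitter, 10% dropout) for the
end-to-end benchmark; ~2,500 planted-profile genes (5 clusters) for
clustering recovery; 20 replicate datasets for cluster-count selection;
1,000 null draws for test calibration; ≥ 50 randomized fixtures per
brute-force oracle comparison.

## Known limitations

* The conservation call is binary per stage (≥ 1 bp same-class overlap);
  no signal-level correlation across species.
* `min_match = 0.95` is conservative for diverged genome pairs; real
  cross-species runs should lower it deliberately.
* The dynamic-gene rule ignores count dispersion; genes with low counts
  and high fold changes pass where a GLM would shrink them.
* Motif enrichment uses a fixed 80%-of-max hit threshold and ZOOPS
  counting; motifs with very different information content are not put on
  a calibrated common scale.
* The fuzzy partition depends on k; the Calinski selection is a heuristic
  and flat data yields no meaningful interior maximum.
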