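# Methods

## Locus model

A repeat locus is described entirely in amplicon space: left and right
flank sequences, the repeat unit between them, and SNP sites addressed by a
signed offset from the first repeat base (negative = upstream). Genomic
coordinates (for CTG18.1, chr18:53,253,387–53,253,458 on hg19, a 72-bp /
24-unit reference interval) are carried as metadata only; nothing in the
pipeline maps to a genome. The default locus fixes the combined flank
length at 4,332 bp so that a 25-repeat allele yields the 4,407-bp product
expected of the CTG18.1 long-range PCR design; the 24-unit reference
interval and the 25-repeat product length are both retained as metadata and
are not reconciled, since only the amplicon geometry matters downstream.
Because the true primer-to-repeat sequence is not part of the locus
definition shipped here, the default flanks are deterministic pseudo-random
stand-ins (fixed seed); the rs599550 site sits at its true −997 offset with
its true G reference base. Real analyses supply real flanks via a JSON
config; coordinates convert to 0-based half-open exactly once, at load.

## Simulator

The generator emulates the read population of a long-range-PCR + nanopore
amplicon run for a diploid genotype (n₁, n₂):

* **error channel** — i.i.d. per-base substitution / insertion / deletion
  with defaults 0.02 / 0.03 / 0.04. The indel-dominant profile mirrors
  nanopore basecalls; the exact values are free parameters of the config.
* **mosaic jitter** — each read's unit count is jittered by
  round(Normal(0, mosaic_sd·n)) before sequence construction, modelling
  genuine somatic length variation rather than sequencing noise. The
  default mosaic_sd = 0.03 is illustrative: blood-leukocyte mosaicism has
  no published quantification, so the value marks the presence of the
  phenomenon, not its measured magnitude.
* **PCR length bias** — allele choice with probability ∝
  exp(−pcr_lambda · amplicon length); default pcr_lambda = 0 (no bias), a
  positive value reproduces preferential amplification of the shorter
  allele.
* **artefacts** — a fraction (default 0.02) of reads carry 0–4 repeat
  units, reproducing the low-count artefact reads that appear in all
  samples and that the caller's floor must shed.
* **orientation and quality** — strand is uniform ±; qualities are a single
  Gaussian around mean_q = 14 (sd 3), truncated to [2, 40]. The caller uses
  only mean quality, so finer quality structure is deliberately absent.

One integer seed drives everything; identical configs produce
byte-identical FASTQ. What passing simulation tests shows is that the
caller implements its contract under this error model; it does not show
robustness to features the simulator lacks: chimeric or truncated reads,
homopolymer-context error clustering, strand-asymmetric error profiles, or
basecaller-specific artefacts.

## Read QC

Length window 4,000–6,000 bases read as inclusive (the conventional
reading of a printed range); quality floor strictly > Q10. Mean quality is
computed in error-probability space — the convention of standard long-read
filters — which is lower than the arithmetic Phred mean whenever quality
varies. Accounting is exact: kept + length-rejected + quality-rejected +
malformed = total.

## Repeat counting

Signal-space repeat quantification is replaced by a sequence-space
equivalent of its contract. The inner-most 30 bases of each flank serve as
anchors, placed by semi-global (infix) edit-distance alignment (edlib);
a placement is accepted at ≤ ⌊0.25 · anchor length⌋ edits, ties broken
leftmost. Orientation picks the strand whose two anchors cost fewer total
edits (ties → forward). The count is round-half-up(span/3) where span is
the inner distance between anchor hits; reads with crossed or missing
anchors are uncountable — there is no one-sided estimation, keeping sizing
conservative.

SNP bases are read by aligning a 31-base flank context centred on the site
within a window around its expected position. The window is widened beyond
a fixed ±5-base slack by a drift allowance proportional to the
anchor-to-site distance (pad = 5 + 0.25·d), because over the 997 bases
between the CTG18.1 anchor and rs599550 the net indel drift at default
error rates has a standard deviation of ~8 bases — a fixed small window
would silently drop most reads. The site position maps through the
alignment cigar; a deleted or unplaceable site yields an absent call rather
than a guess.

**Accuracy envelope.** Span-division counting inherits the tract's indel
noise: per-read error grows like √n (sd ≈ 1.8 units at n = 150 under
default rates) and carries a small negative bias from the net
deletion-excess of the error profile (≈ −1% of n). Per-read accuracy
within ±2 units therefore holds only for alleles up to ~50 units; larger
alleles are accurate within ±(2 + 2% of n) per read. Allele-level calls
are much tighter because the mode aggregates ~100 reads: the worked
genotypes (16,35), (29,93), (62,78) are recovered within ±2 units per
allele in ≥ 90% of seeded runs (see the acceptance tests). This envelope
is a property of any length-based counter at these error rates, not of the
implementation.

## Allele calling

The histogram procedure: drop uncountable reads and counts < 5 (artefact
floor — "below 5" is strict, a count of exactly 5 survives); smooth with a
centred moving average of width 3; take local maxima of the smoothed curve
as candidate peaks, merging peaks closer than min_separation = 8 units
(the closest distinct allele pair the procedure must separate without
phasing differs by 16; below 8 the SNP path is tried instead); report at
most two modes, each required to have strictly more than 10 assigned
reads. "Around a normal distribution" is operationalised as
smoothing + local-maximum selection; no Gaussian is fitted because none is
specified by the procedure being reproduced. The reported mode is the raw
most-frequent size within the peak's basin; ties break toward the bin with
greater mass in a ±2-unit window, then toward the smaller size. Reads are
apportioned to the nearest mode (ties to the smaller), and the depth gate
is applied per allele — both choices are artifact decisions where the
source procedure is silent, chosen for determinism and testability.

For a single mode, reads are partitioned by SNP base: two partitions each
deeper than the gate with different modal sizes give a heterozygous call
with per-allele sizes from the partitions; a SNP-heterozygous sample whose
partitions cannot be sized apart is reported `single-allele-low-confidence`;
otherwise the sample is homozygous for the modal size (both reported
alleles then share the full supporting depth, since reads cannot be
apportioned). An absent SNP signal with a unimodal histogram defaults to
homozygous with a logged caveat — the apparent-homozygote convention,
without an orthogonal confirmation assay.

Per-allele SNP consensus requires ≥ 80% agreement among that allele's
base calls; below that the phase base is reported absent. Classification:
expanded ≥ 50; intermediate 35–49 (advisory only — it never affects
carrier statistics); normal < 35. Mosaicism is flagged when < 50% of an
allele's reads lie within ±2 units of its mode, or when its basin holds a
secondary raw local maximum ≥ 30% of the modal height.

## Haplotypes and linkage

Every called allele emits one (repeat status, SNP base) haplotype.
Groups: expanded alleles; non-expanded partner alleles of carriers;
alleles of non-carrier samples. Linkage tables compare each case group's
base counts against configured reference-population allele counts (no live
database query) with the exact test; the comparison of each group against
the population is an assumption recorded in the table itself, since the
grouping defines no other natural contrast.

## Exact test and ratios

`fisher_exact` enumerates the hypergeometric distribution of the first
cell under fixed margins through log-gamma, summing probabilities ≤ the
observed table's with a 1+10⁻⁷ relative guard against floating-point ties
(the "probability ≤ observed" two-sided convention; no convention is
universal, so the choice and guard are explicit). It is validated against
exact-rational enumeration for every table with margins ≤ 30 and against
an independent library implementation at population-scale margins.
Degenerate tables (an all-zero row or column) return p = 1.0 with a
warning.

Two ratios are computed and labelled precisely, because published 2×2
summaries sometimes print the ratio of proportions under the name "odds
ratio": the carrier-proportion ratio (a/(a+b))/(c/(c+d)) — for the
CTG18.1 carrier table (87,32;1,82) this equals 60.68, matching the
published figure — and the cross-product odds ratio ad/bc (222.94 for the
same table, with an optional Haldane–Anscombe correction when a cell is
zero). The cohort report carries both.

## Problem sizes and numerical choices

Simulation-backed tests use 120–200 reads per sample — matching the depth
scale at which the procedure's > 10-read gate is meaningful — and 50 seeds
per worked genotype for recovery rates. Rounding of spans is half-up
(symmetric error treatment, deterministic); all RNG is numpy's
`default_rng` from a single integer seed; read IDs embed the seed so
distinct seeds never collide. The 6,000-base read ceiling bounds callable
alleles at roughly 500 units; nothing in the package attempts
corneal-endothelium-scale (> 1,000-unit) expansions.

## Known limitations

* Counting is length-based, not model-based: a pHMM or signal-space
  counter could beat the √n error envelope; within ±2-unit per-read
  accuracy beyond ~50 units is out of reach for span division at default
  error rates.
* The simulator's i.i.d. error channel understates real nanopore error
  clustering (homopolymers, repeat context), so real-data per-read
  accuracy may be worse than simulated at the same nominal rates.
* Homozygosity is inferred, not confirmed; an orthogonal assay
  (e.g. repeat-primed PCR) is the real-world check for apparent
  homozygotes.
* Population allele counts are config inputs; no liftover, imputation or
  genome-wide phasing is provided.
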