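# amplistr

Tandem-repeat genotyping from long-read amplicon sequencing, built around
the CTG18.1 trinucleotide repeat in intron 2 of *TCF4* — the repeat whose
expansion (≥ 50 CTG units in blood DNA) is the main genetic cause of Fuchs
endothelial corneal dystrophy (FECD). The package is for groups running
long-range-PCR + nanopore screening of repeat expansions who need a
transparent, testable sequence-space caller and the accompanying cohort
statistics.

## What it does

Given basecalled reads of a `left-flank + (CTG)ⁿ + right-flank` amplicon
(one FASTQ per demultiplexed sample), the pipeline:

1. **read QC** — keeps reads of 4,000–6,000 bases (inclusive) with mean
   quality > Q10, where read quality is the Phred transform of the mean
   per-base error probability, Q = −10·log₁₀(mean p);
2. **per-read repeat counting** — orients each read by its flanking
   anchors (semi-global edit-distance placement), then counts
   n = round(span / 3) from the inner distance between anchors, and reads
   the base of a linked SNP (rs599550, 997 bp proximal to the repeat) via a
   context alignment;
3. **allele calling** — builds the per-sample repeat-count histogram,
   discards counts < 5 as artefacts, smooths, takes up to two modal peaks
   each supported by > 10 reads, splits similar-sized alleles by SNP phase,
   classifies alleles (normal < 35, intermediate 35–49, expanded ≥ 50) and
   flags broad/multi-peaked distributions as somatic mosaicism;
4. **cohort statistics** — 2×2 carrier table with a from-first-principles
   two-sided Fisher exact test (log-gamma hypergeometric enumeration,
   stable for population-scale margins), the carrier-proportion ratio
   (a/(a+b))/(c/(c+d)) and the cross-product odds ratio (ad)/(bc);
5. **haplotype linkage** — per-allele (repeat status, SNP base) haplotypes
   in three groups (expanded; non-expanded partner alleles of carriers;
   alleles of non-carriers), tabulated against reference-population allele
   counts with exact-test p-values.

A seeded simulator (`amplistr simulate`) generates diploid amplicon reads
with nanopore-like indel-dominant errors, per-read mosaic jitter, PCR
length bias and low-count artefact reads, together with truth labels — so
every stage is verifiable end to end without patient data.

## Worked example

Simulate a biallelic-normal sample (alleles of 16 and 35 repeats), filter
and call it:

```bash
amplistr simulate --genotype 16,35 --reads 200 --seed 7 \
    --out s965.fastq --truth s965.truth.tsv
amplistr qc --in s965.fastq --out s965.kept.fastq --report qc.json
amplistr call --in s965.kept.fastq --sample-id s965
```

which prints

```
sample_id  allele1  allele2  depth1  depth2 class1       class2     zygosity  carrier  mosaic1  mosaic2 phase1 phase2
     s965       16       35      89     111 normal intermediate heterozygous        0        0        0      G      G
```

Both alleles are recovered exactly: 89 reads support the 16-repeat allele
and 111 the 35-repeat allele; neither reaches the ≥ 50-unit expansion
threshold, so the sample is not an expansion carrier (`carrier 0`). The
35-repeat allele falls in the advisory intermediate band (35–49), which
never affects carrier status. `phase1/phase2` are the SNP bases carried in
cis with each allele (both `G`, the reference base, since the simulation
did not place an alternate allele; use `--snp-phase 'rs599550=A,G'` to put
the G allele in cis with allele 2). Full runs over many samples use
`amplistr run-all`, which also writes per-sample histograms, genotype
tables, the cohort report and the linkage table.

The built-in locus ships deterministic pseudo-random flank sequences of
the correct total length (4,332 bp, so 25 repeats give the expected
4,407-bp product) with the rs599550 site at its true offset; supply a JSON
locus config with real flanks for real data (`amplistr export-locus` writes
the template).

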