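# Methods

This note documents the models, rules and numerical choices behind
`editome`, in the order data flows through the package.

## Coordinates and formats

All internal coordinates are 0-based half-open (BED convention); every
user-facing table is 1-based. SAM, VCF and FASTA are parsed with pysam
and Biopython; GTF with pyranges; repeat BEDs carry RepeatMasker names,
from which the family and Alu subfamily are taken (`AluJ*/AluS*/AluY*`;
`L1/L2/LINE*` → LINE; `(AC)n`-style → simple). Only single-end
alignments are supported: paired flags raise an error rather than being
silently mis-handled, since the duplicate-collapse key and the 5′-
distance rule are defined for single-end chemistry. Lowercase
(soft-masked) reference bases are uppercased on read so masking cannot
change calls.

## Detection model

A candidate is any (position, alternate base) with at least one
mismatching read after duplicate collapse; no minimum coverage is
imposed before the cascade, so the funnel accounts for every mismatch.

Duplicate collapse uses samtools-rmdup-like single-end semantics: reads
sharing (chromosome, strand, 5′ outer position including soft-clips)
form a group; the highest summed base quality survives, ties broken by
lexicographic read id, making the operation deterministic and
idempotent.

Filter order and rules (each stage only removes candidates):

1. **Region rules.** Simple-repeat intervals; homopolymer runs ≥ 5 bp
   *plus one flanking base on each side* (polymerase slippage errors
   concentrate at run edges; the flank is configurable); positions
   within 5 bases of an exon–intron boundary, counted so that the first
   base on either side of the cut is at distance 1 (a site 5 bp away is
   removed, 6 bp is kept); user-supplied excluded regions (mitochondrial
   genome, unplaced contigs, MHC — assembly-specific, so supplied as a
   BED, which may be empty for toy genomes).
2. **Known variants.** Position-level and allele-agnostic: a database
   entry at the position removes the site even if the recorded allele
   differs. This is the conservative reading of discarding listed SNVs.
3. **Realignment concordance** (when a secondary aligner's SAM is
   given). Per read: same chromosome, same strand, and start–stop
   interval overlap > 0.99, with the overlap fraction defined as
   intersection / max(primary span, secondary span) — the reciprocal,
   strictest reading. Reads absent from the secondary alignment are
   treated as discordant: failure to realign is itself evidence of
   ambiguity. The rule is enforced per read, not per site majority.
4. **Read evidence.** Supporting bases need quality ≥ 20 and must lie
   strictly more than 6 bases from the read's biological 5′ end
   (hexamer-priming artifacts), measured in query coordinates on the
   sequenced strand (rightmost aligned base for minus-strand reads).
   Positions whose surviving evidence still shows two or more alternate
   bases are removed entirely. A call requires at least two supporting
   reads with pairwise distinct (start, end, strand) — residual
   identical coordinates after rmdup indicate amplification artifacts.
   The edited count is the number of surviving supporting reads and the
   total is the surviving column depth, so ratio × total = edited holds
   exactly.

Region and known-variant stages are pure set intersections and commute;
a test asserts identical output under swapped order.

## Spectra, proxy FDR and summaries

Strand-specific events are reported as the transcript-strand change
(genomic T→C inside a minus-strand gene is A-to-G). Without strand
information each change merges with its reverse complement into six
classes labeled by the alphabetically first member, the canonical one
as `A-to-G(I)`. The proxy FDR divides an error-only class by the
canonical class: G-to-A / A-to-G when stranded (A-to-I editing cannot
produce G-to-A on either strand), and the C-to-G/G-to-C class over
A-to-G(I) otherwise. Reproducibility between near-replicates reports
Jaccard overlap (symmetric, single-valued) alongside both per-sample
fractions, plus Spearman correlation of ratios over shared sites
(undefined below three shared sites). Tissue specificity counts sites
detected in exactly one tissue, optionally restricted to sites in
robustly expressed genes (median RPKM > 10 by default) to control for
expression differences. RPKM = count × 10⁹ / (exon-union length ×
total mapped reads).

## Annotation and recoding

Feature labels resolve across overlapping transcripts by fixed
precedence CDS > splicing (within 2 bp of a boundary) > 3′UTR > 5′UTR >
ncRNA exon > intron > intergenic; the order is a package decision,
pinned by tests, chosen so that coding consequence outranks everything
except junction-adjacent unreliability. Repeat enrichment compares a
family's event share with its merged genomic coverage share. Recoding
locates the codon from CDS segment frames (translation order,
strand-aware), translates with the standard code (Biopython), and
classifies synonymous / nonsynonymous / stop-loss; stop→stop edits
(TAA→TGA) are synonymous, and stop gain is asserted impossible since
A→G cannot create the U that every stop codon starts with. Gene-level
summaries take the most severe transcript consequence (stop_loss >
nonsynonymous > synonymous). Selection rules are strict inequalities:
"conserved" keeps sites detected in > 20 samples with median ratio
> 0.1 in at least one tissue; recurrence keeps sites detected in > 50
samples. Only these quantitative criteria are implemented; literature-
overlap notions of conservation are out of scope.

## Association and edQTL mapping

The rank-normal transform maps non-missing values to Φ⁻¹((r − ½)/n)
with ties broken by a seeded random shuffle (distinct ranks), leaving
missing entries missing. OLS uses a QR residualization of the response
and the tested variable against [intercept, covariates]; the slope's
two-sided p comes from the t distribution on residual degrees of
freedom, and R² is the full-model coefficient of determination.
Categorical covariates (sex, laboratory, batch) are one-hot encoded
dropping one level; covariates enter the design directly rather than by
pre-residualization, keeping inference exact. Single fits are
cross-checked against statsmodels in tests; the scan core is the same
algebra vectorized across sites, because per-fit statsmodels calls are
orders of magnitude too slow inside permutation loops.

Permutations scramble the editing matrix's sample labels jointly across
sites — one relabeling per permutation — preserving inter-site
correlation while breaking the sample link. Adjusted p-values use the
+1 correction (1 + b)/(1 + N). For clinical scans the default
adjustment is maxT-style (observed p compared with the per-trait
permutation distribution of the minimum p across sites, the stricter
family-wise reading of a permutation-adjusted p); a pooled per-pair
alternative is selectable. A clinical association is significant when
adjusted p < 0.05, full-model R² > 0.4 (the full-model reading; a
partial-R² flag would be a trivial extension) and no overlapping gene's
expression associates with the trait at nominal p ≤ 0.05.

edQTL scans test all (site, SNP) pairs regardless of distance: sites
must be autosomal and detected in > 40 samples, cells with < 5 edited
reads are masked before the per-site rank-normal transform, SNPs need
MAF > 0.05, and each pair needs ≥ 20 subjects in ≥ 2 observed dosage
groups. Significance is adjusted p < 0.20; the minimum-p association
per site is the index edQTL; cis means same chromosome. eQTL overlap
re-tests each edQTL SNP against every gene overlapping the site and BH-
adjusts across all such tests (flag at adjusted p < 0.05). GWAS
intersection keeps catalog rows at p < 1e−8 for significant regulatory
SNPs and LD-prunes them greedily left-to-right per chromosome: a SNP is
dropped when its dosage r² with any retained SNP within 400 kb exceeds
0.6 (cohort dosages are used; no external reference panel).

## The synthetic cohort

The generator emulates everything downstream of an aligner. Defaults —
the study conditions of the test suite and acceptance run — are a
~190 kb genome (chr1 120 kb, chr2 60 kb, plus chrM and an unplaced
contig that exist to be excluded), 8 three-exon genes with complete
ORFs, 24 Alus (8 per subfamily), 4 LINEs, 6 (AC)n simple repeats,
60 planted sites across 11 contexts, 100 samples, Poisson(30) coverage
per site, 50 bp strand-specific reads, 0.1 % uniform base errors, 10 %
exact-copy PCR duplicates, 5 % discordant secondary alignments, and
base ratios uniform on [0.05, 1] with per-sample Gaussian wobble
(sd 0.08) clamped into (0, 1]. Edits are planted on the transcribed
strand (genomic T→C in minus-strand genes); in non-strand-specific mode
read orientation is randomized 50/50, reproducing the merged-class
mixture. Site-targeted reads are contiguous genomic (pre-mRNA-like)
fragments so intronic and intergenic sites get coverage; background
reads are drawn from spliced transcripts to exercise N-gap CIGARs.
Planted SNPs appear in reads at dosage/2 frequency and in the exclusion
VCF. Ten sites carry an additive dosage effect (β = 0.15/allele,
MAF 0.3), three drive traits (trait = 8 × ratio + covariate effects +
N(0, 0.5), sized so the planted full-model R² clearly exceeds the 0.4
criterion), and two effect-site SNPs also shift their host gene's
expression for the eQTL-overlap check. All randomness flows through one
`numpy` Generator; a fixed seed yields byte-identical files.

What the generator does **not** emulate: position- or cycle-dependent
error profiles, indels, fragment-length variation, mapping bias,
reference bias at SNPs, and real Alu sequence content (repeats are
annotation intervals over random sequence). Passing tests therefore
demonstrate the correctness of the rules and statistics, not
performance on real libraries, where alignment artifacts dominate.

For statistical calibration at larger sample sizes the package also
simulates the editing matrix directly (binomial reads around true
ratios, no read-level data): 500 null sites × 200 subjects for
permutation-FDR uniformity and 50 effect sites for recovery. Effect
sites there share one causal SNP, which keeps the all-pairs scan small;
effect-size recovery is judged on the ratio scale (observed ratio
regressed on dosage against the planted 0.15), since rank-normalization
rescales slopes by the per-site standard deviation and has no fixed
target value.

## Numerical choices and limitations

Degenerate inputs: zero-variance regressors, rank-deficient designs and
empty canonical spectrum classes raise or flag rather than return
silently wrong numbers; all-identical rank-normal input warns (ranks
are then pure noise). Permutation defaults are 10,000 (clinical) and
1,000 (edQTL), reduced to ~200 in tests and the acceptance run — at
those sizes the adjusted-p granularity is 1/201, well below the 0.20
threshold in use. Problem sizes throughout (cohort of 100 at depth 30;
calibration at n = 200) were chosen as the smallest the statistics are
stable at. Known limitations: no BAM/CRAM, paired-end, indel or
C-to-U-specific logic; genotype imputation, ancestry estimation, mixed
models and fine-mapping are out of scope (covariates and dosages are
consumed as inputs).
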