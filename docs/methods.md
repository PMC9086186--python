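# Methods

## Variant identity and shared-type removal

A mutation *type* is the tuple *(chrom, pos, ref, alt, geno)*. Including
the genotype class means the same substitution called heterozygous in
one animal and homozygous in another counts as two types; this is the
strictest reading of key-based matching and the package default. The
genotype is canonicalized to two classes — `het` (any mix of reference
and the alternate, e.g. 0/1, 1/0, 0|1, or a multiallelic 1/2 split into
two het records) and `hom_alt` (1/1, 1|1) — so keys do not depend on
caller-specific genotype syntax. `key-ignore-geno` drops the field for
callers with unreliable genotype classes.

Shared-type removal is asymmetric by necessity: treated samples subtract
the union of all control keys, but a control cannot be filtered against
a panel containing itself, so each control subtracts the union of the
*other* controls (leave-one-out). This is the simplest policy under
which per-control unique counts are well defined; an alternative
`intersection_of_group_unions` mode (subtract keys present in both
group-wide unions from everyone) is available behind a flag. Variants
shared only among treated samples are *not* removed.

### Allele normalization

Keys are only comparable after canonicalization. Alleles are uppercased,
shared suffix then prefix bases trimmed (keeping at least one base
each), and InDels left-aligned by sliding the *fixed* allele strings to
the smallest position at which they still describe the same edited
haplotype (verified locally at each step; the scan tolerates repeat
periods up to the edit length). The operation is idempotent and
haplotype-preserving, which the test suite checks by brute force on
random sequences. Note the canonical form anchors inside the repeated
motif (`TAAAC`, deleting one A → pos 2, `AA>A`), which differs from
re-anchoring normalizers that may emit `TA>T` at pos 1; mixing callers
normalized by external tools with different conventions should be
avoided, or keys compared with `key-ignore-geno` plus a re-normalization
pass.

## Annotation

Region labels partition every call: `exonic` if the position overlaps
any exon, else `intronic` inside a gene span, else `upstream` within a
strand-aware window 5′ of a transcription start (default 1,000 bp, the
convention of common annotators), else `intergenic`. Precedence across
overlapping genes is exonic > intronic > upstream.

Coding effects are defined only for SNPs inside a CDS: the containing
codon is reconstructed in transcript orientation (reverse-complementing
on the minus strand), the allele substituted, and both codons translated
with the standard genetic code. stop→stop and aa→same-aa are
`synonymous`; aa→other-aa `nonsynonymous`; non-stop→stop `stopgain`;
stop→non-stop `stoploss`. Exonic positions outside any CDS (UTR) count
as exonic in region tallies but get no effect label, because the effect
classes are codon-defined. When a SNP hits several transcripts the most
severe effect is reported (stopgain/stoploss > nonsynonymous >
synonymous) as a deterministic tie-break. InDel coding consequences
(frameshifts) are not classified; InDels are only flagged when their
affected reference interval [pos, pos+len(ref)−1] intersects a CDS
segment. Splice-site and UTR categories are deliberately not separate
labels.

Gene models come from GFF3 (gene/mRNA/exon/CDS with `Parent` links).
At load, CDS integrity (length divisible by 3, start codon, terminal
stop, no internal stop) is checked; violations are logged, not fatal.

## Burden statistics

* Mutation rate = 100 × count / clean bases, per sample. The clean-base
  total (post-QC sequenced bases) is the denominator because it
  reproduces the published per-sample rates exactly (e.g. 144,157 SNPs /
  10,730,101,234 bases = 0.001343 %); a fixed genome-size denominator is
  available for users who prefer a per-genome rate.
* The total rate is SNP rate + InDel rate per sample (same denominator),
  then averaged within groups.
* Group dispersion is the sample SD (n−1). This convention is pinned by
  the published control SNP counts, whose sample SD (10,115.5) matches
  the printed ±10,115 while the population SD (8,760) does not.
* Ts/Tv with zero transversions is reported as NaN, never an exception.
* Group comparison: Shapiro–Wilk and a Lilliefors-corrected KS test per
  group; if normality fails, square-root then natural-log transforms are
  tried, re-tested, and recorded in the result. Levene's test gates
  Student's (p > 0.05) vs Welch's t for two groups; more than two groups
  use one-way ANOVA followed by Tukey HSD. All tests two-sided at
  α = 0.05, no multiple-testing correction across summary metrics.
* Internal computation is full precision; rounding (rates to 6 decimals
  of percent, percentages to 2) happens only at presentation. One
  consequence: a published total rate formed by summing two
  independently rounded component means (0.01144 + 0.002281 = 0.013721 %)
  differs from the full-precision value (0.0137196 %) in the sixth
  decimal; the tests compare at the printed precision.

## Enrichment

P(X ≥ k) for X ~ Hypergeom(N, K, n), where N is the gene universe
(default: all genes in the annotation), K the term's genes in the
universe, n the query size, k the overlap. BH-FDR is applied within
each term category (BP/CC/MF/pathway) to mirror standard GO tooling; a
global mode exists. Term maps are plain 3-column TSVs — real GO/KEGG
databases are inputs, not dependencies. Because the hypergeometric is
discrete, the exact null rejection probability at the 0.05 level is
slightly below 0.05; the calibration test computes that exact
probability and checks the Monte-Carlo rejection rate against it, using
term and query sizes (universe 5,000; terms 200–500; query 1,000) large
enough that it sits within the 99 % binomial band around the nominal
level at 2,000 replicates.

## Exclusive screen

Presence = at least one amino-acid-changing SNP (nonsynonymous by
default plus stopgain/stoploss, toggleable) in a gene for a sample,
computed from group-specific annotated calls. A gene is
*target-exclusive* when present in ≥ `min_target_samples` target-group
samples (default 1 — the screen's source required presence "only" in the
group without saying in how many members) and absent from every sample
of every excluded group. Mapping gene IDs to names/families is an
annotation join, outside the screen.

## Synthetic cohorts

The generator emulates the post-calling variant universe of the study
design; it does not simulate reads, alignment or calling errors.

* **Genome**: random sequence at the requested GC (default 35 %, typical
  of the target taxa), two chromosomes, 1 Mb total; 60 non-overlapping
  genes with 3 exons, 150 bp CDS per exon, 120 bp introns, 30 bp UTRs,
  random strand; every CDS starts ATG, is in frame, ends in a stop and
  has no internal stop by construction.
* **Shared pool**: Poisson(rate × length) polymorphic sites, default
  5.5×10⁻³ per bp (the raw-call density of the reference screen scaled
  per bp). Each pool variant carries a population frequency drawn
  U(0.90, 1.00) and a fixed genotype class. The high frequencies are a
  deliberate idealization: they let a 4-animal control panel capture
  essentially all shared types, so that control-unique counts measure
  the configured spontaneous rate rather than panel leakage. Real
  cohorts segregate rarer variants and leak more shared types through
  the panel; the parameter-recovery tests therefore say nothing about
  panels facing a broad frequency spectrum (the `pool_freq_range`
  parameter exposes this).
* **Private mutations**: Poisson(per-base rate × length) per individual,
  independent across animals (one variant set per sequenced tissue;
  mosaicism and inheritance are not modeled). Defaults are calibrated to
  the reference screen scaled per genome bp: control 1.3×10⁻⁴,
  treated 1.17×10⁻³ (ratio 9); transition fraction 0.517 (control) /
  0.528 (treated), i.e. Ts/Tv ≈ 1.07 / 1.12; InDel share 0.24 / 0.166;
  InDel sizes geometric (p = 0.5, capped at 10 bp); CDS events thinned
  by a 0.95 depletion factor (survivor selection against coding
  damage). Transitions originate at G:C sites with probability
  `gc_at_bias` (default 0.7 treated — alkylation chemistry targets
  guanine — 0.5 control); the direction is a parameter because reported
  EMS spectra differ between sources. Private calls are het with
  probability 0.9. Clean bases per sample are Normal(11×genome length,
  8 %) clipped positive, emulating realistic coverage spread so the rate
  denominator varies by sample.
* **Planted exclusive genes**: 3 large-exclusive and 2 small-exclusive
  genes are designated; their CDS is masked from random private and pool
  mutation in *every* sample, and each target-group sample receives one
  planted nonsynonymous SNP per designated gene. Zero-false-negative
  recovery by the screen is thus a construction guarantee; false
  positives remain possible through chance private hits and shrink with
  control panel size.
* **Determinism**: one integer seed feeds spawned generators for genome,
  pool, design, clean bases and each sample; identical seeds give
  byte-identical FASTA/GFF3/VCF/TSV output.

The 1 Mb default keeps a full end-to-end run (16 samples, ~100 k calls)
under ~10 s; per-sample private counts (~1,200 treated / ~130 control)
give a fold-change standard error of a few percent, so recovery of the
configured ratio is tested within 3 relative SE, and the pooled treated
transition fraction (~12,000 SNPs) within 3 binomial SE.

## Numerical and degenerate-input choices

* Coordinates are 1-based inclusive everywhere (VCF/GFF3 convention).
* Multiallelic records are split before normalization and keying; each
  carried alternate becomes its own biallelic record (a 1/2 genotype
  yields two het calls). Missing genotypes, reference-only genotypes and
  symbolic alleles are skipped and tallied in a skip log.
* Zero denominators: class percentages and Ts/Tv return NaN markers;
  mutation rate with non-positive clean bases raises.
* Constant groups in comparisons: equal constants give p = 1, separated
  constants p = 0 with a zero-variance warning flag, never a crash.
* Hypergeometric arguments are validated; k = 0 returns exactly 1.

## Known limitations

* No read-level error model: false-positive calls, coverage-dependent
  sensitivity and genotype miscalls are not simulated, so the pipeline's
  behaviour under caller noise is untested here.
* The exclusive screen is presence/absence; it has no burden test or
  association statistic and its false-positive rate depends on cohort
  size and mutation rate.
* InDel functional consequences beyond CDS overlap are out of scope.
* Cross-caller key comparability is limited by the left-alignment
  convention noted above.
* The enrichment module does no GO DAG propagation or pathway topology;
  terms are flat gene sets.
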