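# Methods

## The problem

Outbred populations — humans, pigs, cattle — carry high heterozygosity and
unknown haplotype phase, so the low-depth genotyping-by-sequencing shortcuts
that work in inbred lines (where parental genotypes anchor every call) fail:
distinguishing a heterozygote from a homozygote requires enough independent
reads per site per individual. Genome reducing and sequencing concentrates
sequencing depth on a reproducible fraction of the genome: digest each
sample's DNA with one restriction enzyme, ligate barcoded adapters onto the
cut overhangs, size-select, pool many samples into one lane, and sequence.
Every individual then presents reads at the same restriction-fragment ends,
at medium depth (roughly 5–20× per site), which is enough for direct diploid
genotype calling without phase information.

This package implements the computational side of that design: in-silico
experiment design (digest and barcode modules), data processing (demux,
readprep), Bayesian multi-sample genotype calling with SNP validation
(genocall), and a truth-tracking simulator (simulate) that makes every stage
testable at desk scale.

## In-silico digestion

The enzyme model is a degenerate IUPAC recognition motif with top- and
bottom-strand cut offsets. The default is AvaII: motif `GGWCC` (W = A or T),
top cut after base 1 (`G^GWCC`), bottom after base 4, leaving a 3-base 5'
overhang `GWC`. Cut positions are motif-match starts plus the top offset;
overlapping matches are allowed (irrelevant for `GGWCC`, but correct for
other motifs), and ambiguity codes in the *genome* (e.g. N runs in gapped
assemblies) never match, which digests gapped assemblies conservatively.
k cuts on a contig produce k+1 fragments that tile it exactly.

Size selection keeps fragments whose length lies in an inclusive window
(default 200–300 bp — the genomic insert corresponding to 300–400 bp library
molecules once adapters are counted). Terminal contig fragments carry only
one ligatable overhang, cannot receive two adapters, and are excluded from
selection by default. "Unique fragments" are counted by distinct
coordinates; an optional sequence-deduplicated count is also reported, since
repeat-derived fragments with identical sequence would not be separable
after sequencing. Expected sequencing yield assumes paired-end reads of
length `read_len` from both fragment ends: `min(length, 2*read_len)` bases
per selected fragment.

## Barcode sets and adapters

Barcodes of mixed length (4–8 nt) stagger the invariant cut-site remnant
across sequencing cycles so no early cycle is monomorphic across the lane —
the low-diversity condition that causes cluster-phasing miscalls. Variable
length makes parsing a read prefix ambiguous in principle; a set is
*decodable* when no read prefix can parse as `barcode + remnant` under two
different barcodes. The validator checks exactly that condition pairwise
(`b1+w1` prefix-compatible with `b2+w2` for remnant words `w`), and the test
suite proves it equivalent to a brute-force enumeration of every
constructible read prefix and all its parses. Fixed-width sets are always
decodable; conflicts only arise across length classes.

The designer draws random candidates length by length, rejecting any that
(i) violate decodability against the already-chosen set, (ii) fall within
Hamming distance 2 of a same-length barcode (detection of one sequencing
error; the weakest testable robustness guarantee — error *correction* is a
non-goal), or (iii) leave any sequencing cycle monomorphic across the final
set. It is reproducible for a fixed seed and raises a capacity error naming
the best achieved count when the constraints cannot be met.

Adapter oligos follow the standard one-adapter Y design: plus strand =
Illumina stub + barcode; minus strand = `GWC` overhang + reverse complement
of the barcode + the opposite stub. The remnant expected after the barcode
during demultiplexing is `GWC` by default (matching the filter rule as
stated in terms of the first three motif bases); a strict `GWCC` mode
reflects the actual post-ligation top strand.

## Read filtering and demultiplexing

Four rules, applied in the fixed order a→b→c→d with rejection attributed to
the first failing rule (the order is a package convention; it makes per-rule
counts reproducible):

a. the read must begin with a known barcode;
b. the cut-site remnant must immediately follow the barcode;

   Rules a and b resolve jointly: candidate barcodes are tried longest
   first and one is accepted only when its remnant follows, since in a
   decodable variable-length set a shorter barcode's remnant can share
   its first bases with a longer barcode (e.g. `AAGC` + `GAC…` opening
   `AAGCG`); the remnant is what disambiguates. A read matching some
   barcode but no barcode+remnant parse is rejected under rule b.
c. no adapter or adapter-dimer contamination, operationalised as approximate
   containment of the 12-nt universal adapter stems anywhere in the read
   with at most 1 mismatch;
d. no uncalled base (N) within the first 80 bases, measured on the
   barcode-trimmed read (those are the bases that align downstream); an
   option measures on the raw read instead.

Passing reads are barcode-trimmed (the remnant is genomic and retained) and
routed to their sample. The partition property — every read lands in exactly
one sample or one rejection rule — holds by construction and is asserted in
tests. Read-count dispersion across samples is summarised by the coefficient
of variation, sample standard deviation (n−1) over mean.

Mate handling: the pipeline processes single-end reads; with paired input,
mate 1 carries the sample assignment (alignment downstream is single-end
anyway, so mate 2 adds no information the desk-scale pipeline uses).

## Alignment preparation

Production alignment belongs to an external mapper (BWA) via FASTQ/SAM
handoff files; the package implements the bespoke steps around it. Reads
that fail whole-read mapping are split at internal restriction-motif cut
points (at most the two leftmost, giving two or three sub-reads; pieces
shorter than 25 nt are dropped). The split uses the enzyme's cut offset so
sub-reads end/begin exactly at genomic fragment boundaries. Remaining reads
are probed with sliding-window sub-queries (window 50, step 10 by default —
both are configuration, as no canonical values exist) whose last window is
anchored at the read end so every base is covered.

Two internal aligners support hermetic testing: `naive_align`, an exact
occurrence scan over both strands used as the oracle, and `SeedAligner`, an
exact k-mer seed (k = 31, taken from successive read windows so one
sequencing error cannot kill every seed) with mismatch-tolerant full-length
extension (≤ 5 substitutions) and a repetitive-seed guard. The seed aligner
drives the end-to-end pipeline on simulated genomes; it is not a replacement
for a production mapper on real references.

## Genotype calling

Per site and sample, read bases are independent draws given the diploid
genotype with error `e = 10^(-Q/10)` (qualities floored at 2 and capped at
40 before conversion, guarding against `e >= 1` and overconfident bases):

    P(x | aa) = 1 - e  if x == a, else e/3
    P(x | ab) = (P(x|aa) + P(x|bb)) / 2

Log-likelihoods sum over reads; an empty pileup is uninformative (all
zeros). The two modelled alleles are the bases with the highest summed
quality at the site (ties broken lexicographically; the reference base is
the REF allele when it ranks in the top two). Sites where a third allele
carries more than 10% of total base quality are dropped as non-biallelic.

The genotype prior is Hardy–Weinberg, `{(1-f)^2, 2f(1-f), f^2}`, with the
alternate-allele frequency `f` estimated by EM over all samples jointly:
E-step, per-sample genotype posteriors under HWE(f); M-step, `f` = expected
alt dosage over `2n` chromosomes; iterate to `|Δf| < 1e-6` or 100
iterations. The observed-data log-likelihood is non-decreasing (asserted in
tests). This pooled estimate is what "improving the prior by analysing
multiple individuals" means concretely here; a flat-prior mode exists for
comparison. Initialisation is `f = 0.5`; the likelihood in `f` is unimodal
in all simulated panels examined, and the symmetric point is the natural
uninformed start.

A genotype is reported as the posterior argmax when the sample's depth
reaches `min_depth` (default 5, inclusive — "5×" read as ≥ 5, with a strict
mode available) and the maximum posterior reaches 0.9; otherwise missing.
Missingness therefore conflates low depth and low confidence, both
configurable. Validated SNPs additionally require call rate ≥ 15% and minor
allele frequency ≥ 5% (both inclusive: boundary values are kept). Output is
VCF 4.2 (GT, DP; 1-based positions) and a samples × sites dosage matrix
(0/1/2/NA) — the export surface for external imputation, which is out of
scope here.

## The simulator

The simulator is the package's instrument for study conditions, not a
generic read simulator. Defaults describe the designed experiment: 72-plex,
2×100 reads, 200–300 bp AvaII fragments, per-individual read budgets with
CV 0.43, mean per-end depth 6, substitution error 1e-3 at Phred 30 (the
observed per-base accuracy over the informative first stretch of HiSeq
reads; Q20/1e-2 is the whole-read floor).

* **Reference**: i.i.d. bases at a set GC content; motif sites planted at
  spacings drawn so ~3/4 of inter-site fragments fall in the size window
  (the rest deliberately long, to exercise selection). Spontaneous motif
  occurrences and adapter-like 12-mers (either orientation, within 1
  mismatch) are scrubbed by point changes away from planted sites, so the
  digest reproduces the planted inventory exactly and no error-free read
  can trip the contamination screen. This makes digest and demux testable
  against exact truth; it also means the simulated genome has no repeats,
  no N runs, and no residual adapter homology — properties real references
  do not share, so passing tests bound algorithmic correctness, not
  performance on repetitive genomes.
* **Population**: each position visible to a read (within `read_len` of a
  selected fragment end, outside cut-site remnants) becomes a biallelic SNP
  with probability `snp_rate` (default 0.01); `f ~ Uniform[0.05, 0.5]`;
  genotypes are independent HWE draws per individual with alt alleles on
  random haplotypes. No linkage disequilibrium is modelled — the pipeline
  never uses LD, so haploblock structure would add realism without adding
  coverage. SNPs are kept out of the restriction motifs themselves, so cut
  sites are never polymorphic in simulation; the motif-splitting rescue for
  polymorphic sites is exercised by targeted unit tests instead.
* **Library**: single-end reads `barcode + GWCC... insert` sampled uniformly
  over (selected fragment, end, haplotype). Budgets are
  `2 * mean_depth * n_fragments` per individual scaled by a mean-1
  log-normal with CV `depth_cv` (log-normal reproduces the reported
  dispersion; the empirical shape is not documented, and only the CV is
  consumed downstream), or a fixed library total split multinomially with
  the same weights. Errors are substitutions only, matching the caller's
  model; no indels, PCR duplicates, or GC bias.
* **Pileup-only mode** (`simulate_pileup`) draws per-sample depths
  Poisson(log-normal mean) and bases directly from genotypes, to exercise
  the caller in isolation at exactly controlled depth.

## Numerical and design choices

* Coordinates are 0-based half-open everywhere; 1-based only in VCF/SAM
  text. Phred+33 is fixed; offset-64 input is rejected, never guessed.
* Posteriors are computed in log space with max-subtraction; the prior is
  floored at 1e-300 before logging so `f` exactly 0 or 1 stays finite.
* Pileup assembly materialises only candidate columns (≥ 2 reads
  disagreeing with the reference); a site with fewer alternate reads
  cannot approach a 5% MAF across 72 samples, and skipping monomorphic
  columns keeps memory linear in the number of variant candidates rather
  than covered bases.
* EM accuracy is assessed against the realized sample allele frequency
  (mean dosage / 2), the quantity the pooled EM estimates; the gap to the
  population frequency is binomial sampling noise (~0.036 RMSE at n = 72),
  not estimator error.
* The read-count CV of one 72-sample draw carries ~10% relative sampling
  error of its own; tests and the acceptance script therefore average the
  demux-reported CV over six independent libraries (> 1e5 reads in total)
  when checking recovery of the configured value.
* Desk-scale problem sizes (60 kb genomes, ~130 selected fragments, 72
  samples, depth 8–20, 100–160 k reads) were chosen so every planted SNP is
  covered at realistic depth while the full suite runs in minutes; all are
  configuration, and nothing in the implementation depends on them.

## Known limitations

* Simulated sequencing errors are applied to the genomic insert only;
  barcode bases are error-free in this version, so barcode-error handling
  (rejection, never misassignment, under Hamming-distance-2 sets) is
  exercised by targeted unit tests rather than the library simulation.

* The seed aligner assumes a near-unique genome; on repetitive references
  it returns no call for ambiguous seeds rather than a mapping quality.
* Biallelic SNPs only; indels and multi-allelic sites are screened out,
  not modelled.
* The demultiplexer does no mismatch rescue of barcodes by default (exact
  match per the filter rule as stated); Hamming-distance-2 sets make
  misassignment under one error impossible, at the cost of rejecting such
  reads.
* Imputation of the ~missing genotype mass is out of scope; the dosage
  matrix is the designed handoff.
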