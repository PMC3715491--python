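# ggrs

Genotyping by genome reducing and sequencing, for outbred diploid
populations.

Outbred species — pigs, cattle, humans — carry high heterozygosity and
unknown haplotype phase, so low-depth genotyping-by-sequencing protocols
that lean on known parental genotypes cannot call genotypes reliably.
Genome *reducing* concentrates sequencing on a reproducible slice of the
genome: digest with one restriction enzyme (AvaII, motif `GGWCC`, cutting
`G^GWCC`), ligate barcoded adapters onto the `GWC` overhangs, size-select
200–300 bp fragments, pool up to 72 samples per lane, and sequence. Every
individual then presents reads at the same fragment ends at medium depth,
enough for direct Bayesian diploid genotype calling.

This package implements the computational pipeline around that design:

* **digest** — in-silico digestion with degenerate motifs, size selection,
  coverage/yield statistics for experiment design;
* **barcodes** — decodable variable-length (4–8 nt) barcode sets and the
  adapter oligo pairs they imply;
* **demux** — the four read-filtering rules (barcode, cut-site remnant,
  adapter screen, N screen) and per-sample splitting with run statistics;
* **readprep** — motif splitting and sliding-window sub-queries for the
  three-step alignment strategy (production mapping is delegated to an
  external aligner such as BWA; hermetic seed/naive aligners are included
  for testing and desk-scale runs);
* **genocall** — multi-sample genotype likelihoods, EM allele-frequency
  estimation, Hardy–Weinberg-prior posteriors, the three SNP-validation
  filters (depth ≥ 5, call rate ≥ 15%, MAF ≥ 5%), VCF and dosage-matrix
  export;
* **simulate** — synthetic references, outbred populations and multiplexed
  libraries with complete planted truth.

## The model at the core

At a site with alleles R/A, a sample's reads are independent draws given
its genotype g with per-base error ε = 10^(−Q/10):

    P(x | aa) = 1 − ε  if x = a, else ε/3
    P(x | ab) = ½ P(x|aa) + ½ P(x|bb)
    L(g) = Π_reads P(x_i | g)

The alternate-allele frequency f is estimated by EM pooled over all
samples, and the genotype prior is HWE: {(1−f)², 2f(1−f), f²}. Per-sample
posteriors P(g | reads) ∝ P(g) L(g) are reported as the argmax genotype
when depth ≥ 5 and posterior ≥ 0.9, else missing; validated SNPs need
call rate ≥ 15% and MAF = min(f, 1−f) ≥ 5%.

## Worked example

`examples/05_full_pipeline.py` simulates a 24-plex library over a 50 kb
reference (mean depth 10, error 10⁻³), demultiplexes, aligns, calls and
validates SNPs, and scores everything against the planted truth:

```
reads: 71209 total, 71023 passed demux, 71003 aligned
planted SNPs: 247, called after filters: 230
called sites that are planted SNPs: 230/230
genotype concordance with truth: 99.78%
outputs in scratch_example_run/: calls.vcf, genotypes.tsv, manifest.json
```

Every emitted site is a real planted SNP; 230 of 247 planted SNPs survive
the validation filters (the rest lack depth or drift under the MAF floor
in this draw); genotypes agree with the planted diploids at 99.8%. The
run directory holds the VCF (GT/DP per sample), the samples × sites
dosage matrix handed to downstream imputation, and a provenance manifest
(seed, parameters, output checksums) sufficient to reproduce the run
bit-identically. The other examples exercise digest design, barcode/
adapter design, demultiplexing and stand-alone calling, each printing a
short interpretation of its numbers.

The same stages are available from the shell:

```bash
ggrs digest --fasta ref.fa --enzyme GGWCC --cut 1,4 --min 200 --max 300
ggrs barcodes design --n 72 --seed 1 --out barcodes.tsv
ggrs demux --fastq run.fq.gz --barcodes barcodes.tsv --out-dir demux/
ggrs pipeline --seed 1 --out-dir run/
```

## What this is not

Wet-lab protocol details, BWA/SAMtools themselves, imputation of missing
genotypes (the dosage matrix is the designed handoff), indel calling, and
LD-aware refinement are all out of scope. See `docs/methods.md` for the
full model description, simulator assumptions, numerical choices and
limitations.
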