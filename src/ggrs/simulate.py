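"""Synthetic references, outbred populations, and sequencing libraries.

Everything the pipeline consumes can be simulated with known truth, so
each stage — digestion, demultiplexing, alignment, genotype calling —
is testable against planted answers without external downloads.

The simulated world is deliberately the smallest faithful model of a
reduced-representation experiment on an outbred diploid population:

* a random i.i.d. reference sequence with restriction-motif sites
  planted at spacings that yield a controllable inventory of
  size-selected fragments (spontaneous motif occurrences are scrubbed so
  the in-silico digest reproduces the planted inventory exactly);
* biallelic SNPs restricted to the fragment ends the library actually
  sequences, with alternate allele frequencies drawn from a minor-allele
  distribution and genotypes drawn independently per individual under
  Hardy-Weinberg equilibrium (no linkage disequilibrium);
* a multiplexed library whose reads are barcode + cut-site remnant +
  insert, with per-individual read budgets drawn log-normal at a
  configurable coefficient of variation, and uniform substitution
  errors with matching Phred qualities (no indels).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .barcodes import BarcodeSet, design_barcode_set
from .demux import default_adapter_screen
from .digest import (
    EnzymeSpec,
    Fragment,
    SizeWindow,
    digest_genome,
    expand_motif,
    select_fragments,
)
from .genocall import PileupColumn
from .seqio import GenomeIndex, SeqRecord, reverse_complement

BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Parameters of the synthetic population and library.

    Defaults describe the experiment this package is designed around: a
    72-plex 2x100 run over 200-300 bp AvaII fragments, per-individual
    read budgets varying with CV 0.43, and a substitution error rate of
    1e-3 (Phred 30, the observed per-base quality over the informative
    first stretch of HiSeq reads).
    """

    seed: int = 0
    genome_length: int = 200_000
    gc_content: float = 0.5
    enzyme: EnzymeSpec = field(default_factory=EnzymeSpec)
    size_window: SizeWindow = field(default_factory=lambda: SizeWindow(200, 300))
    n_individuals: int = 72
    snp_rate: float = 0.01
    maf_lo: float = 0.05
    maf_hi: float = 0.5
    mean_depth: float = 6.0
    depth_cv: float = 0.43
    read_len: int = 100
    error_rate: float = 0.001
    barcode_set: BarcodeSet | None = None

    def __post_init__(self) -> None:
        for name in ("gc_content", "snp_rate", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if self.depth_cv < 0:
            raise ValueError("depth_cv must be >= 0")

    def resolve_barcodes(self) -> BarcodeSet:
        if self.barcode_set is None:
            self.barcode_set = design_barcode_set(self.n_individuals, seed=self.seed)
        return self.barcode_set

    @property
    def read_qual(self) -> int:
        if self.error_rate <= 0:
            return 40
        return min(40, max(2, round(-10.0 * math.log10(self.error_rate))))


@dataclass
class TruthSNP:
    contig: str
    pos: int  # 0-based
    ref: str
    alt: str
    alt_freq: float
    genotypes: np.ndarray  # (n_individuals,) dosage 0/1/2
    hap_alt: np.ndarray  # (n_individuals, 2) bool: haplotype carries alt


@dataclass
class ReadTruth:
    sample_index: int
    contig: str
    pos: int  # 0-based leftmost genomic position of the insert
    strand: str


@dataclass
class TruthSet:
    cut_positions: list[int]
    fragments: list[Fragment]
    selected_fragments: list[Fragment]
    snps: list[TruthSNP] = field(default_factory=list)
    reads: dict[str, ReadTruth] = field(default_factory=dict)

    def genotype_matrix(self) -> np.ndarray:
        return np.array([s.genotypes for s in self.snps])  # (n_snps, n_ind)


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(BASES, size=n, p=p)


def _approx_hits(seq: str, word: str, max_mm: int) -> list[int]:
    k = len(word)
    hits = []
    for i in range(len(seq) - k + 1):
        mm = 0
        for x, y in zip(seq[i : i + k], word):
            if x != y:
                mm += 1
                if mm > max_mm:
                    break
        else:
            hits.append(i)
    return hits


def simulate_reference(
    config: SimConfig, contig_id: str = "sim1"
) -> tuple[GenomeIndex, TruthSet]:
    """A random reference with a planted, scrubbed fragment inventory.

    Motif sites are planted at spacings drawn so that roughly 3/4 of
    inter-site fragments fall inside the size window (the rest are
    deliberately long, to exercise size selection).  Afterwards the
    sequence is scrubbed: spontaneous motif occurrences away from
    planted sites are broken by point changes, as are adapter-like
    stretches that would trip the demultiplexer's contamination screen,
    so the digest of the returned genome equals the planted inventory
    and error-free simulated reads are never screen-rejected.
    """
    rng = np.random.default_rng(config.seed)
    motif_len = len(config.enzyme.recognition)
    motif_words = sorted(expand_motif(config.enzyme.recognition))
    lo, hi = config.size_window.lo, config.size_window.hi
    margin = config.read_len + 10
    seq = _random_bases(rng, config.genome_length, config.gc_content)

    # plant motif starts
    planted: list[int] = []
    pos = margin
    while pos + motif_len + margin < config.genome_length:
        planted.append(pos)
        if rng.random() < 0.75:
            spacing = int(rng.integers(lo, hi + 1))
        else:
            spacing = int(rng.integers(hi + 50, hi + 400))
        pos += spacing
    if len(planted) < 2:
        raise ValueError("genome too short to plant a fragment inventory")
    for p in planted:
        word = motif_words[int(rng.integers(len(motif_words)))]
        seq[p : p + motif_len] = list(word)

    planted_set = set(planted)
    protected = np.zeros(config.genome_length, dtype=bool)
    for p in planted:
        protected[p : p + motif_len] = True

    screen_words = default_adapter_screen()
    screen_words = sorted(set(screen_words) | {reverse_complement(w) for w in screen_words})

    # scrub spontaneous motif matches and adapter-like stretches
    for _ in range(20):
        s = "".join(seq)
        dirty = []
        for word in motif_words:
            start = s.find(word)
            while start != -1:
                if start not in planted_set:
                    dirty.append((start, motif_len))
                start = s.find(word, start + 1)
        for word in screen_words:
            dirty.extend((h, len(word)) for h in _approx_hits(s, word, 1))
        if not dirty:
            break
        for start, k in dirty:
            free = [i for i in range(start, start + k) if not protected[i]]
            if not free:  # pragma: no cover - screens never overlap planted motifs fully
                continue
            i = free[int(rng.integers(len(free)))]
            choices = [b for b in "ACGT" if b != seq[i]]
            seq[i] = choices[int(rng.integers(3))]
    else:  # pragma: no cover
        raise RuntimeError("could not scrub genome of spurious motif/adapter hits")

    genome = GenomeIndex({contig_id: "".join(seq)})
    fragments = digest_genome(genome, config.enzyme)
    cut_positions = sorted(p + config.enzyme.cut_top for p in planted)
    got = [f.end for f in fragments if f.right_is_cut]
    if got != cut_positions:  # pragma: no cover - scrubbing guarantees this
        raise RuntimeError("digest does not match planted inventory")
    selected = select_fragments(fragments, config.size_window)
    return genome, TruthSet(cut_positions, fragments, selected)


def _visible_positions(frag: Fragment, config: SimConfig) -> list[int]:
    """Positions a sequenced read can observe, excluding cut-site remnants."""
    L = config.read_len
    a, b = frag.start, frag.end
    plus = range(a + 4, min(a + L, b - 1))
    minus = range(max(b + 3 - L, a + 4), b - 1)
    return sorted(set(plus) | set(minus))


def simulate_population(
    genome: GenomeIndex, truth: TruthSet, config: SimConfig
) -> TruthSet:
    """Plant biallelic SNPs on selected fragments; draw HWE genotypes.

    Each eligible position (within the sequenced windows of a selected
    fragment, outside cut-site remnants) becomes a SNP with probability
    ``snp_rate``; its alternate allele frequency is uniform on
    [maf_lo, maf_hi] and genotypes are independent HWE draws per
    individual, alt alleles assigned to random haplotypes.
    """
    rng = np.random.default_rng(config.seed + 1)
    contig = genome.contig_ids[0]
    n = config.n_individuals
    snps: list[TruthSNP] = []
    for frag in truth.selected_fragments:
        for pos in _visible_positions(frag, config):
            if rng.random() >= config.snp_rate:
                continue
            ref = genome.fetch(contig, pos, pos + 1)
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            f = float(rng.uniform(config.maf_lo, config.maf_hi))
            hap_alt = rng.random((n, 2)) < f
            snps.append(
                TruthSNP(
                    contig=contig,
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    alt_freq=f,
                    genotypes=hap_alt.sum(axis=1),
                    hap_alt=hap_alt,
                )
            )
    truth.snps = snps
    return truth


def lognormal_factors(rng: np.random.Generator, n: int, cv: float) -> np.ndarray:
    """Mean-1 log-normal multipliers with the requested CV."""
    if cv <= 0:
        return np.ones(n)
    sigma2 = math.log(1.0 + cv * cv)
    mu = -sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=n)


def simulate_library(
    genome: GenomeIndex,
    truth: TruthSet,
    config: SimConfig,
    total_reads: int | None = None,
) -> tuple[list[SeqRecord], TruthSet]:
    """Multiplexed single-end reads: barcode + remnant + insert.

    Per-individual budgets are ``2 * mean_depth * n_selected_fragments``
    scaled by a log-normal factor with CV ``depth_cv`` (each fragment
    presents two sequencable ends, so a budget of ``2 d F`` reads gives
    about depth ``d`` at each end window).  Pass ``total_reads`` to fix
    the library size instead, keeping the same relative variation.
    Reads are sampled uniformly over (selected fragment, end,
    haplotype); substitution errors are applied at ``error_rate`` with
    Phred qualities consistent with it.
    """
    rng = np.random.default_rng(config.seed + 2)
    bset = config.resolve_barcodes()
    barcodes = [b.sequence for b in bset]
    contig = genome.contig_ids[0]
    contig_seq = genome.sequence(contig)
    n = config.n_individuals
    frags = truth.selected_fragments
    if not frags:
        raise ValueError("no selected fragments to sequence")
    L = config.read_len
    qual = config.read_qual

    factors = lognormal_factors(rng, n, config.depth_cv)
    if total_reads is None:
        base = 2.0 * config.mean_depth * len(frags)
        budgets = np.maximum(1, np.round(base * factors)).astype(int)
    else:
        w = factors / factors.sum()
        budgets = rng.multinomial(total_reads, w)

    # per-individual SNP lookup: pos -> (alt, hap_alt row)
    snp_at: dict[int, TruthSNP] = {s.pos: s for s in truth.snps}
    snp_positions = np.array(sorted(snp_at), dtype=int)

    reads: list[SeqRecord] = []
    read_truth: dict[str, ReadTruth] = {}
    ridx = 0
    for ind in range(n):
        m = budgets[ind]
        frag_idx = rng.integers(len(frags), size=m)
        strands = rng.integers(2, size=m)
        haps = rng.integers(2, size=m)
        err_mask = rng.random((m, L)) < config.error_rate
        for j in range(m):
            frag = frags[int(frag_idx[j])]
            if strands[j] == 0:
                start, strand = frag.start, "+"
            else:
                start, strand = frag.end + 3 - L, "-"
            insert = list(contig_seq[start : start + L])
            # apply this haplotype's alternate alleles
            if len(snp_positions):
                lo_i = np.searchsorted(snp_positions, start)
                hi_i = np.searchsorted(snp_positions, start + L)
                for p in snp_positions[lo_i:hi_i]:
                    s = snp_at[int(p)]
                    if s.hap_alt[ind, haps[j]]:
                        insert[int(p) - start] = s.alt
            if strand == "-":
                insert = list(reverse_complement("".join(insert)))
            if err_mask[j].any():
                for k in np.nonzero(err_mask[j])[0]:
                    others = "ACGT".replace(insert[int(k)], "")
                    insert[int(k)] = others[int(rng.integers(len(others)))]
            rid = f"r{ridx}"
            ridx += 1
            bc = barcodes[ind]
            seq = bc + "".join(insert)
            reads.append(SeqRecord(rid, seq, [qual] * len(seq)))
            read_truth[rid] = ReadTruth(ind, contig, start, strand)
    truth.reads = read_truth
    # interleave samples deterministically
    order = np.random.default_rng(config.seed + 3).permutation(len(reads))
    reads = [reads[i] for i in order]
    return reads, truth


def simulate_pileup(
    config: SimConfig,
    n_sites: int,
    mean_depth: float,
    rng: np.random.Generator | None = None,
) -> tuple[list[PileupColumn], np.ndarray, np.ndarray]:
    """Direct per-site pileup simulation for exercising the caller alone.

    Returns (columns, true genotype matrix (n_sites, n_individuals),
    true alternate allele frequencies).  Depth per sample-site is
    Poisson with a per-individual log-normal mean (CV ``depth_cv``);
    bases are drawn from the true genotype with substitution error
    ``error_rate`` at the matching Phred quality.
    """
    rng = rng or np.random.default_rng(config.seed)
    n = config.n_individuals
    e = config.error_rate
    qual = config.read_qual
    factors = lognormal_factors(rng, n, config.depth_cv)
    lam = mean_depth * factors
    freqs = rng.uniform(config.maf_lo, config.maf_hi, size=n_sites)
    genos = np.zeros((n_sites, n), dtype=int)
    columns: list[PileupColumn] = []
    for s in range(n_sites):
        ref, alt = "A", "C"
        g = rng.binomial(2, freqs[s], size=n)
        genos[s] = g
        samples = []
        for i in range(n):
            d = int(rng.poisson(lam[i]))
            if d == 0:
                samples.append(("", []))
                continue
            p_alt = g[i] / 2.0
            true_alt = rng.random(d) < p_alt
            bases = np.where(true_alt, alt, ref)
            err = rng.random(d) < e
            if err.any():
                for k in np.nonzero(err)[0]:
                    others = [b for b in "ACGT" if b != bases[k]]
                    bases[k] = others[int(rng.integers(3))]
            samples.append(("".join(bases), [qual] * d))
        columns.append(PileupColumn("sim1", s, ref, samples))
    return columns, genos, freqs
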