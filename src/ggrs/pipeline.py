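"""End-to-end orchestration: simulate -> demux -> align -> pileup -> call.

The pipeline chains the package's stages on simulated (or pre-demuxed
real) inputs.  Production alignment against a chromosome-scale
reference is an external, pluggable step: the pipeline emits FASTQ for
the mapper and ingests its pileup; when no mapper is configured it runs
the in-package seed aligner, which is exact enough for desk-scale
simulated genomes and keeps the tested core hermetic.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

from . import __version__
from .demux import DemuxStats, FilterConfig, demux_reads
from .genocall import (
    FilterCriteria,
    PileupColumn,
    VariantCall,
    call_pileup,
    write_genotype_matrix,
    write_vcf,
)
from .readprep import SeedAligner
from .seqio import GenomeIndex, SeqRecord
from .simulate import SimConfig, TruthSet, simulate_library, simulate_population, simulate_reference


@dataclass
class PipelineResult:
    genome: GenomeIndex
    truth: TruthSet
    demux_stats: DemuxStats
    n_aligned: int
    n_unaligned: int
    calls: list[VariantCall]
    sample_ids: list[str]


def build_pileup(
    per_sample: dict[str, list[SeqRecord]],
    genome: GenomeIndex,
    sample_ids: list[str],
    aligner: SeedAligner | None = None,
    min_alt_evidence: int = 2,
) -> tuple[list[PileupColumn], int, int]:
    """Align per-sample reads and assemble multi-sample pileup columns.

    Only candidate columns — positions where at least ``min_alt_evidence``
    reads disagree with the reference — are materialised; everything
    else is reference-monomorphic and could never yield a variant call.
    Returns (columns, n_aligned, n_unaligned).
    """
    import numpy as np

    from .seqio import reverse_complement

    aligner = aligner or SeedAligner(genome)
    idx_of = {sid: i for i, sid in enumerate(sample_ids)}
    n = len(sample_ids)
    n_aligned = n_unaligned = 0

    # pass 1: align everything, count reference mismatches per position
    placements: list[tuple[int, str, int, str, list[int] | None]] = []
    mismatch = {c: np.zeros(genome.length(c), dtype=np.int32) for c in genome.contig_ids}
    for sid, reads in per_sample.items():
        si = idx_of[sid]
        for read in reads:
            hit = aligner.align(read)
            if hit is None:
                n_unaligned += 1
                continue
            n_aligned += 1
            if hit.strand == "+":
                seq, quals = read.seq, read.qual
            else:
                seq = reverse_complement(read.seq)
                quals = read.qual[::-1] if read.qual else None
            ref = genome.fetch(hit.contig, hit.pos, hit.pos + len(seq))
            if seq != ref:
                for off, (a, b) in enumerate(zip(seq, ref)):
                    if a != b and a != "N":
                        mismatch[hit.contig][hit.pos + off] += 1
            placements.append((si, hit.contig, hit.pos, seq, quals))

    # pass 2: collect bases only at candidate (mismatch-bearing) columns
    cand: dict[str, np.ndarray] = {
        c: np.nonzero(arr >= min_alt_evidence)[0] for c, arr in mismatch.items()
    }
    pile: dict[tuple[str, int], list[tuple[list[str], list[int]]]] = {
        (c, int(p)): [([], []) for _ in range(n)]
        for c, positions in cand.items()
        for p in positions
    }
    for si, contig, pos, seq, quals in placements:
        positions = cand[contig]
        lo = int(np.searchsorted(positions, pos))
        hi = int(np.searchsorted(positions, pos + len(seq)))
        for p in positions[lo:hi]:
            off = int(p) - pos
            base = seq[off]
            if base == "N":
                continue
            col = pile[(contig, int(p))][si]
            col[0].append(base)
            col[1].append(quals[off] if quals else 30)
    columns = []
    for (contig, pos) in sorted(pile):
        ref_base = genome.fetch(contig, pos, pos + 1)
        samples = [("".join(b), q) for b, q in pile[(contig, pos)]]
        columns.append(PileupColumn(contig, pos, ref_base, samples))
    return columns, n_aligned, n_unaligned


def run_pipeline(
    config: SimConfig,
    criteria: FilterCriteria | None = None,
    out_dir: str | Path | None = None,
    total_reads: int | None = None,
) -> PipelineResult:
    """Simulate a library and run it through demux, alignment and calling.

    When ``out_dir`` is given, writes ref.fa, barcodes.tsv, calls.vcf,
    genotypes.tsv and a provenance manifest sufficient to reproduce the
    run (package version, full parameter set, seed, output checksums).
    """
    criteria = criteria or FilterCriteria()
    genome, truth = simulate_reference(config)
    truth = simulate_population(genome, truth, config)
    reads, truth = simulate_library(genome, truth, config, total_reads=total_reads)
    bset = config.resolve_barcodes()
    fconfig = FilterConfig(barcode_set=bset)
    per_sample, stats = demux_reads(reads, fconfig)
    sample_ids = [b.sample_id for b in bset]
    columns, n_aligned, n_unaligned = build_pileup(per_sample, genome, sample_ids)
    calls = call_pileup(columns, criteria)
    result = PipelineResult(
        genome, truth, stats, n_aligned, n_unaligned, calls, sample_ids
    )
    if out_dir is not None:
        _write_outputs(result, config, criteria, Path(out_dir))
    return result


def _file_sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_outputs(
    result: PipelineResult, config: SimConfig, criteria: FilterCriteria, out_dir: Path
) -> None:
    from .seqio import SeqRecord as _Rec, write_barcode_manifest, write_fasta

    out_dir.mkdir(parents=True, exist_ok=True)
    contig = result.genome.contig_ids[0]
    write_fasta(
        [_Rec(contig, result.genome.sequence(contig))], out_dir / "ref.fa"
    )
    write_barcode_manifest(config.barcode_set.to_rows(), out_dir / "barcodes.tsv")
    lengths = {c: result.genome.length(c) for c in result.genome.contig_ids}
    write_vcf(result.calls, result.sample_ids, out_dir / "calls.vcf", lengths)
    write_genotype_matrix(result.calls, result.sample_ids, out_dir / "genotypes.tsv")
    manifest = {
        "package": "ggrs",
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "genome_length": config.genome_length,
            "gc_content": config.gc_content,
            "enzyme": {
                "name": config.enzyme.name,
                "recognition": config.enzyme.recognition,
                "cut_top": config.enzyme.cut_top,
                "cut_bottom": config.enzyme.cut_bottom,
            },
            "size_window": [config.size_window.lo, config.size_window.hi],
            "n_individuals": config.n_individuals,
            "snp_rate": config.snp_rate,
            "maf_range": [config.maf_lo, config.maf_hi],
            "mean_depth": config.mean_depth,
            "depth_cv": config.depth_cv,
            "read_len": config.read_len,
            "error_rate": config.error_rate,
            "min_depth": criteria.min_depth,
            "min_call_rate": criteria.min_call_rate,
            "min_maf": criteria.min_maf,
            "posterior_threshold": criteria.posterior_threshold,
        },
        "outputs": {
            name: _file_sha256(out_dir / name)
            for name in ("ref.fa", "barcodes.tsv", "calls.vcf", "genotypes.tsv")
        },
        "stats": {
            "total_reads": result.demux_stats.total_reads,
            "passed_reads": result.demux_stats.passed_reads,
            "aligned_reads": result.n_aligned,
            "n_snps": len(result.calls),
        },
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
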