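"""Alignment preparation: motif splitting, window queries, test aligners.

Production alignment is delegated to an external mapper (BWA) through
plain FASTQ/SAM handoff files.  This module implements the bespoke parts
of the three-step alignment strategy around that mapper:

1. map all filtered reads;
2. split still-unmapped reads at internal restriction motifs — a read
   straddling a cut site that is polymorphic between sample and
   reference cannot map contiguously, but its pieces can;
3. probe remaining reads with sliding-window sub-queries against an
   incomplete reference.

Two aligners are included for hermetic testing: ``naive_align`` (exact
occurrence scan, the oracle) and ``SeedAligner`` (k-mer seed and
mismatch-tolerant extension, fast enough to drive the end-to-end
pipeline on simulated data).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .digest import EnzymeSpec, find_sites
from .seqio import GenomeIndex, SeqRecord, encode_quals, reverse_complement


@dataclass(frozen=True)
class SubRead:
    parent_id: str
    part_index: int
    seq: str
    qual: tuple[int, ...] | None
    origin_offset: int


@dataclass(frozen=True)
class WindowQuery:
    parent_id: str
    window_start: int
    seq: str
    qual: tuple[int, ...] | None


@dataclass(frozen=True)
class Hit:
    contig: str
    pos: int  # 0-based leftmost reference position
    strand: str  # '+' or '-'
    mismatches: int = 0


def split_read_at_motif(
    read: SeqRecord, enzyme: EnzymeSpec, min_len: int = 25, max_splits: int = 2
) -> list[SubRead]:
    """Split a read at internal restriction-motif cut points.

    Cut points use the enzyme's top-strand offset, mirroring the genomic
    fragment boundaries the digest produces, so each sub-read matches a
    reference fragment end.  At most ``max_splits`` leftmost cut points
    are applied (two or three sub-reads); sub-reads shorter than
    ``min_len`` are discarded.  Reads without an internal motif are
    returned unchanged as a single part.
    """
    cuts = [c for c in find_sites(read.seq, enzyme) if 0 < c < len(read.seq)]
    cuts = cuts[:max_splits]
    if not cuts:
        return [SubRead(read.id, 0, read.seq, tuple(read.qual) if read.qual else None, 0)]
    bounds = [0] + cuts + [len(read.seq)]
    parts = []
    for i, (a, b) in enumerate(zip(bounds[:-1], bounds[1:])):
        if b - a < min_len:
            continue
        qual = tuple(read.qual[a:b]) if read.qual is not None else None
        parts.append(SubRead(read.id, i, read.seq[a:b], qual, a))
    return parts


def window_queries(
    read: SeqRecord, window: int = 50, step: int = 10
) -> list[WindowQuery]:
    """Sliding-window sub-queries covering every base of the read.

    Starts at 0, step, 2*step, ...; a final window anchored at the read
    end is appended when the regular grid does not already reach it.  A
    window longer than the read collapses to one full-read query.
    """
    L = len(read.seq)
    if window >= L:
        return [
            WindowQuery(read.id, 0, read.seq, tuple(read.qual) if read.qual else None)
        ]
    starts = list(range(0, L - window + 1, step))
    if starts[-1] + window < L:
        starts.append(L - window)
    out = []
    for s in starts:
        qual = tuple(read.qual[s : s + window]) if read.qual is not None else None
        out.append(WindowQuery(read.id, s, read.seq[s : s + window], qual))
    return out


def naive_align(query: str, genome: GenomeIndex) -> list[Hit]:
    """All exact occurrences of a query on both strands (test oracle).

    Deterministic order: by contig order, then position, then strand.
    """
    hits = []
    rc = reverse_complement(query)
    for contig in genome.contig_ids:
        seq = genome.sequence(contig)
        for target, strand in ((query, "+"), (rc, "-")):
            start = seq.find(target)
            while start != -1:
                hits.append(Hit(contig, start, strand))
                start = seq.find(target, start + 1)
    hits.sort(key=lambda h: (h.contig, h.pos, h.strand))
    return hits


class SeedAligner:
    """Exact-seed, mismatch-tolerant single-end aligner over a k-mer index.

    Seeds are taken from the read with :func:`window_queries` (window =
    k, default step 10); the first seed with a unique consistent genome
    placement anchors the read, and the full-length extension is
    accepted if it stays within ``max_mismatch`` substitutions and read
    bounds.  Intended for desk-scale simulated genomes; a production run
    uses an external mapper instead.
    """

    def __init__(self, genome: GenomeIndex, k: int = 31, step: int = 10,
                 max_mismatch: int = 5):
        self.genome = genome
        self.k = k
        self.step = step
        self.max_mismatch = max_mismatch
        # kmer -> list of (contig, pos); REPEAT marks over-represented seeds
        self._REPEAT: list = []
        self._index: dict[str, list[tuple[str, int]]] = {}
        for contig in genome.contig_ids:
            seq = genome.sequence(contig)
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                cur = self._index.get(kmer)
                if cur is self._REPEAT:
                    continue
                if cur is None:
                    self._index[kmer] = [(contig, i)]
                elif len(cur) >= 4:  # repetitive seed: useless for unique anchoring
                    self._index[kmer] = self._REPEAT
                else:
                    cur.append((contig, i))

    def _extend(self, read_seq: str, contig: str, start: int, strand: str) -> Hit | None:
        L = len(read_seq)
        ref_len = self.genome.length(contig)
        if start < 0 or start + L > ref_len:
            return None
        ref = self.genome.fetch(contig, start, start + L)
        target = read_seq if strand == "+" else reverse_complement(read_seq)
        mm = sum(a != b for a, b in zip(target, ref))
        if mm > self.max_mismatch:
            return None
        return Hit(contig, start, strand, mm)

    def align(self, read: SeqRecord) -> Hit | None:
        seq = read.seq
        L = len(seq)
        for wq in window_queries(read, window=min(self.k, L), step=self.step):
            placements: set[tuple[str, int, str]] = set()
            fwd = self._index.get(wq.seq)
            rev = self._index.get(reverse_complement(wq.seq))
            if fwd is self._REPEAT or rev is self._REPEAT:
                continue  # repetitive seed: try the next window
            for contig, pos in fwd or ():
                placements.add((contig, pos - wq.window_start, "+"))
            for contig, pos in rev or ():
                # seed occupies read[s:s+k]; on '-' the read's 3' end maps left
                start = pos - (L - wq.window_start - len(wq.seq))
                placements.add((contig, start, "-"))
            if len(placements) == 1:
                hit = self._extend(seq, *placements.pop())
                if hit is not None:
                    return hit
        return None


def emit_unaligned_fastq(reads: Iterable[SeqRecord], path: str | Path) -> None:
    """FASTQ handoff file for an external mapper."""
    from .seqio import write_fastq

    write_fastq(reads, path)


def emit_sam(
    hits: list[tuple[SeqRecord, Hit]], genome: GenomeIndex, path: str | Path
) -> None:
    """Minimal single-end SAM: @HD/@SQ headers plus one line per hit.

    FLAG 0/16 by strand; POS is 1-based; reverse-strand reads are stored
    reverse-complemented with reversed qualities, as SAM requires.
    """
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for contig in genome.contig_ids:
            fh.write(f"@SQ\tSN:{contig}\tLN:{genome.length(contig)}\n")
        for read, hit in hits:
            flag = 0 if hit.strand == "+" else 16
            seq = read.seq if hit.strand == "+" else reverse_complement(read.seq)
            if read.qual is not None:
                quals = read.qual if hit.strand == "+" else read.qual[::-1]
                qual_str = encode_quals(quals)
            else:
                qual_str = "*"
            fh.write(
                f"{read.id}\t{flag}\t{hit.contig}\t{hit.pos + 1}\t60\t"
                f"{len(read.seq)}M\t*\t0\t0\t{seq}\t{qual_str}\tNM:i:{hit.mismatches}\n"
            )
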