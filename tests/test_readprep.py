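import pysam
import pytest

from ggrs.readprep import (
    Hit,
    SeedAligner,
    emit_sam,
    emit_unaligned_fastq,
    naive_align,
    split_read_at_motif,
    window_queries,
)
from ggrs.seqio import GenomeIndex, SeqRecord, read_fastq, reverse_complement

from conftest import random_dna


def _read(seq, qual=30, rid="r"):
    return SeqRecord(rid, seq, [qual] * len(seq))


class TestSplitReadAtMotif:
    def test_no_internal_motif_unchanged(self, avaii):
        read = _read("ACGTACGTACGTACGTACGTACGTAC")
        parts = split_read_at_motif(read, avaii, min_len=5)
        assert len(parts) == 1
        assert parts[0].seq == read.seq and parts[0].origin_offset == 0

    def test_split_at_cut_offset(self, avaii):
        read = _read("AAAAAGGACCTTTTT")
        parts = split_read_at_motif(read, avaii, min_len=1)
        assert [(p.origin_offset, p.seq) for p in parts] == [
            (0, "AAAAAG"),
            (6, "GACCTTTTT"),
        ]

    def test_two_motifs_three_subreads(self, avaii):
        seq = "A" * 30 + "GGACC" + "C" * 30 + "GGTCC" + "T" * 30
        parts = split_read_at_motif(_read(seq), avaii, min_len=10)
        assert len(parts) == 3
        # sub-reads tile the parent
        assert sum(len(p.seq) for p in parts) == len(seq)
        for p in parts:
            assert seq[p.origin_offset : p.origin_offset + len(p.seq)] == p.seq

    def test_at_most_two_leftmost_splits(self, avaii):
        seq = ("A" * 20 + "GGACC") * 4 + "A" * 20
        parts = split_read_at_motif(_read(seq), avaii, min_len=1)
        assert len(parts) == 3

    def test_short_subreads_discarded(self, avaii):
        seq = "AAG" + "GGACC" + "T" * 40  # left piece shorter than min_len
        parts = split_read_at_motif(_read(seq), avaii, min_len=25)
        assert len(parts) == 1
        assert parts[0].origin_offset == 4

    def test_qualities_sliced_with_sequence(self, avaii):
        read = SeqRecord("r", "AAAAAGGACCTTTTT", list(range(15)))
        parts = split_read_at_motif(read, avaii, min_len=1)
        assert list(parts[0].qual) == list(range(6))
        assert list(parts[1].qual) == list(range(6, 15))


class TestWindowQueries:
    def test_grid_arithmetic(self):
        wqs = window_queries(_read("A" * 100), window=50, step=25)
        assert [w.window_start for w in wqs] == [0, 25, 50]

    def test_exact_fit_single_window(self):
        wqs = window_queries(_read("A" * 50), window=50, step=10)
        assert len(wqs) == 1

    def test_tail_window_appended(self):
        wqs = window_queries(_read("A" * 103), window=50, step=10)
        assert wqs[-1].window_start == 53

    def test_window_longer_than_read(self):
        wqs = window_queries(_read("ACGTACGT"), window=50, step=10)
        assert len(wqs) == 1 and wqs[0].seq == "ACGTACGT"

    def test_every_base_covered(self, rng):
        for L in (60, 77, 100, 131):
            read = _read(random_dna(rng, L))
            covered = set()
            for w in window_queries(read, window=50, step=10):
                covered.update(range(w.window_start, w.window_start + len(w.seq)))
            assert covered == set(range(L))


class TestNaiveAlign:
    def test_forward_hit(self, rng):
        seq = random_dna(rng, 500)
        genome = GenomeIndex({"c": seq})
        hits = naive_align(seq[100:150], genome)
        assert Hit("c", 100, "+") in hits

    def test_reverse_hit(self, rng):
        seq = random_dna(rng, 500)
        genome = GenomeIndex({"c": seq})
        hits = naive_align(reverse_complement(seq[200:240]), genome)
        assert Hit("c", 200, "-") in hits

    def test_absent_query_brute_force(self, rng):
        seq = random_dna(rng, 1000)
        genome = GenomeIndex({"c": seq})
        query = random_dna(rng, 40)
        brute = []
        for target, strand in ((query, "+"), (reverse_complement(query), "-")):
            brute += [
                (i, strand)
                for i in range(len(seq) - 39)
                if seq[i : i + 40] == target
            ]
        hits = naive_align(query, genome)
        assert [(h.pos, h.strand) for h in hits] == sorted(brute)


class TestSeedAligner:
    def test_places_exact_reads_on_both_strands(self, rng):
        seq = random_dna(rng, 5000)
        genome = GenomeIndex({"c": seq})
        aligner = SeedAligner(genome)
        hit = aligner.align(_read(seq[1000:1100]))
        assert (hit.contig, hit.pos, hit.strand, hit.mismatches) == ("c", 1000, "+", 0)
        hit = aligner.align(_read(reverse_complement(seq[2000:2100])))
        assert (hit.pos, hit.strand) == (2000, "-")

    def test_tolerates_substitutions_outside_first_seed(self, rng):
        seq = random_dna(rng, 5000)
        genome = GenomeIndex({"c": seq})
        aligner = SeedAligner(genome)
        read = list(seq[3000:3100])
        read[60] = "A" if read[60] != "A" else "C"
        hit = aligner.align(_read("".join(read)))
        assert (hit.pos, hit.mismatches) == (3000, 1)

    def test_recovers_via_later_window_when_first_seed_errored(self, rng):
        seq = random_dna(rng, 5000)
        genome = GenomeIndex({"c": seq})
        aligner = SeedAligner(genome)
        read = list(seq[3000:3100])
        read[5] = "A" if read[5] != "A" else "C"  # error inside the first seed
        hit = aligner.align(_read("".join(read)))
        assert hit is not None and hit.pos == 3000

    def test_split_then_align_read_straddling_cut_site(self, avaii, rng):
        # a molecule that escaped digestion yields a read straddling a cut
        # site; its motif-split pieces map exactly to the two fragment ends
        left, right = random_dna(rng, 60), random_dna(rng, 60)
        ref = left + "GGACC" + right
        genome = GenomeIndex({"c": ref})
        read = _read(ref[20:85])
        parts = split_read_at_motif(read, avaii, min_len=10)
        assert len(parts) == 2
        placed = [naive_align(p.seq, genome) for p in parts]
        assert placed[0] and placed[0][0].pos == 20
        assert placed[1] and placed[1][0].pos == 61

    def test_split_rescues_read_with_snp_creating_cut_site(self, avaii, rng):
        # the sample carries a SNP creating a motif the reference lacks; the
        # raw read fails a strict aligner but its pieces place correctly
        # with one mismatch allowed (the variant base sits inside the motif)
        left, right = random_dna(rng, 60), random_dna(rng, 60)
        ref = left + "GGCCC" + right  # reference allele breaks the motif
        genome = GenomeIndex({"c": ref})
        strict = SeedAligner(genome, k=21, max_mismatch=0)
        sample_read = _read(left[20:] + "GGACC" + right[:20])
        assert strict.align(sample_read) is None
        parts = split_read_at_motif(sample_read, avaii, min_len=10)
        assert len(parts) == 2
        lenient = SeedAligner(genome, k=15, max_mismatch=1)
        hits = [lenient.align(SeqRecord("p", p.seq, None)) for p in parts]
        assert hits[0] and hits[0].pos == 20 and hits[0].mismatches == 0
        assert hits[1] and hits[1].pos == 61 and hits[1].mismatches == 1


class TestEmission:
    def test_sam_round_trip_through_pysam(self, tmp_path, rng):
        seq = random_dna(rng, 400)
        genome = GenomeIndex({"chr1": seq})
        reads = [_read(seq[50:130], rid="f"), _read(reverse_complement(seq[200:280]), rid="r")]
        hits = [(reads[0], Hit("chr1", 50, "+")), (reads[1], Hit("chr1", 200, "-"))]
        path = tmp_path / "out.sam"
        emit_sam(hits, genome, path)
        with pysam.AlignmentFile(str(path), "r") as sam:
            assert sam.lengths == (400,)
            alns = list(sam)
        assert [a.flag for a in alns] == [0, 16]
        assert [a.reference_start for a in alns] == [50, 200]
        # SAM stores the forward-strand sequence for reverse hits
        assert alns[1].query_sequence == seq[200:280]

    def test_zero_hits_header_only(self, tmp_path, rng):
        genome = GenomeIndex({"chr1": random_dna(rng, 100)})
        path = tmp_path / "empty.sam"
        emit_sam([], genome, path)
        with pysam.AlignmentFile(str(path), "r") as sam:
            assert list(sam) == []

    def test_unaligned_fastq_round_trip(self, tmp_path, rng):
        reads = [_read(random_dna(rng, 60), rid=f"u{i}") for i in range(25)]
        path = tmp_path / "u.fq"
        emit_unaligned_fastq(reads, path)
        back = read_fastq(path)
        assert [(r.id, r.seq, r.qual) for r in back] == [
            (r.id, r.seq, r.qual) for r in reads
        ]
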