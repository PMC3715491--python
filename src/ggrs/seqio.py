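"""Sequence I/O and shared sequence utilities.

Readers and writers for the plain-text formats the pipeline touches
(FASTA, FASTQ, barcode manifests), transparent gzip handling, and IUPAC
reverse complementation.  All coordinates in this package are 0-based,
half-open; conversion to 1-based happens only at VCF/SAM emission.

Quality scores are Phred+33 throughout.  Offset-64 input is rejected,
not auto-detected: a quality character below ``!`` is impossible in
Phred+33, and characters that only occur in offset-64 encodings are the
caller's responsibility to re-encode.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio.Seq import Seq

PHRED_OFFSET = 33

IUPAC_CODES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVN",
    "TGCAYRSWMKVHDBN",
)


class FormatError(ValueError):
    """Raised on malformed FASTA/FASTQ/manifest input."""


@dataclass
class SeqRecord:
    """A named DNA sequence with optional per-base Phred qualities."""

    id: str
    seq: str
    qual: list[int] | None = None

    def __post_init__(self) -> None:
        if not self.seq:
            raise FormatError(f"record {self.id!r}: empty sequence")
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise FormatError(
                f"record {self.id!r}: sequence length {len(self.seq)} != "
                f"quality length {len(self.qual)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


def reverse_complement(seq: str) -> str:
    """Reverse complement a DNA string over the full IUPAC alphabet.

    An involution: ``reverse_complement(reverse_complement(s)) == s``.
    Degenerate codes map to their complementary degenerate codes
    (W<->W, R<->Y, ...).
    """
    upper = seq.upper()
    bad = set(upper) - set(IUPAC_CODES)
    if bad:
        raise ValueError(f"non-IUPAC characters in sequence: {sorted(bad)}")
    return str(Seq(upper).reverse_complement())


def _complement_ok() -> None:  # sanity guard at import: Biopython agrees with table
    assert str(Seq("GGWCC").reverse_complement()) == "GGWCC"


_complement_ok()


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read a (possibly gzipped) FASTA file into SeqRecords.

    Sequences are uppercased; IUPAC ambiguity codes are preserved.
    """
    records: list[SeqRecord] = []
    with _open_text(path) as fh:
        header: str | None = None
        chunks: list[str] = []
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                if header is not None:
                    records.append(SeqRecord(header, "".join(chunks).upper()))
                header = line[1:].split()[0]
                if not header:
                    raise FormatError("FASTA header with empty id")
                chunks = []
            else:
                if header is None:
                    raise FormatError("sequence data before first FASTA header")
                chunks.append(line)
        if header is not None:
            records.append(SeqRecord(header, "".join(chunks).upper()))
    if not records:
        raise FormatError(f"no records in FASTA file {path}")
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 70) -> None:
    with _open_text(path, "wt") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def decode_quals(qual_str: str) -> list[int]:
    """Decode a Phred+33 quality string to integer scores."""
    quals = [ord(c) - PHRED_OFFSET for c in qual_str]
    if any(q < 0 for q in quals):
        raise FormatError("quality character below '!': not Phred+33")
    return quals


def encode_quals(quals: Sequence[int]) -> str:
    return "".join(chr(q + PHRED_OFFSET) for q in quals)


def iter_fastq(path: str | Path) -> Iterator[SeqRecord]:
    """Stream records from a (possibly gzipped) Phred+33 FASTQ file."""
    with _open_text(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            header = header.rstrip("\n")
            if not header.startswith("@"):
                raise FormatError(f"expected '@' header, got {header[:30]!r}")
            seq = fh.readline().rstrip("\n").upper()
            plus = fh.readline().rstrip("\n")
            qual = fh.readline().rstrip("\n")
            if not plus.startswith("+"):
                raise FormatError("malformed FASTQ: missing '+' separator")
            if len(seq) != len(qual):
                raise FormatError(
                    f"record {header[1:]!r}: seq length {len(seq)} != qual length {len(qual)}"
                )
            yield SeqRecord(header[1:].split()[0], seq, decode_quals(qual))


def read_fastq(path: str | Path) -> list[SeqRecord]:
    return list(iter_fastq(path))


def write_fastq(records: Iterable[SeqRecord], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for rec in records:
            if rec.qual is None:
                raise ValueError(f"record {rec.id!r} has no qualities")
            fh.write(f"@{rec.id}\n{rec.seq}\n+\n{encode_quals(rec.qual)}\n")


def read_barcode_manifest(path: str | Path) -> list[tuple[str, str]]:
    """Read a two-column (sample_id, barcode) delimited manifest.

    Tab or comma delimited; a header line is detected by a non-ACGT
    second column and skipped.
    """
    rows: list[tuple[str, str]] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split(",")
            if len(parts) < 2:
                raise FormatError(f"line {lineno}: expected 2 columns")
            sid, bc = parts[0].strip(), parts[1].strip().upper()
            if lineno == 1 and not set(bc) <= set("ACGT"):
                continue  # header
            rows.append((sid, bc))
    if not rows:
        raise FormatError(f"no barcodes in manifest {path}")
    return rows


def write_barcode_manifest(rows: Iterable[tuple[str, str]], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("sample_id\tbarcode\n")
        for sid, bc in rows:
            fh.write(f"{sid}\t{bc}\n")


class GenomeIndex:
    """In-memory random-access view of a genome.

    Holds ordered contigs and answers (contig, start, end) slice queries
    with bounds checking.  Suitable for the desk-scale genomes this
    package digests and simulates; file-backed access for chromosome-
    scale references goes through pyfaidx/pysam upstream of this class.
    """

    def __init__(self, contigs: dict[str, str]):
        if not contigs:
            raise ValueError("empty genome")
        for cid, seq in contigs.items():
            if len(seq) < 1:
                raise ValueError(f"contig {cid!r} has length 0")
        self._contigs = {cid: seq.upper() for cid, seq in contigs.items()}

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeIndex":
        return cls({rec.id: rec.seq for rec in read_fasta(path)})

    @classmethod
    def from_records(cls, records: Iterable[SeqRecord]) -> "GenomeIndex":
        return cls({rec.id: rec.seq for rec in records})

    @property
    def contig_ids(self) -> list[str]:
        return list(self._contigs)

    def length(self, contig: str) -> int:
        return len(self._contigs[contig])

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self._contigs.values())

    def sequence(self, contig: str) -> str:
        return self._contigs[contig]

    def fetch(self, contig: str, start: int, end: int) -> str:
        """0-based half-open slice; out-of-bounds access is an error."""
        seq = self._contigs[contig]
        if not (0 <= start < end <= len(seq)):
            raise IndexError(
                f"fetch {contig}:{start}-{end} outside contig of length {len(seq)}"
            )
        return seq[start:end]
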