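"""Read filtering and demultiplexing.

Four filtering rules are applied to every raw read, in a fixed order so
that rejection counts are reproducible:

a) the read must begin with one of the sample barcodes (longest match
   wins, which is unambiguous for a validated variable-length set);
b) the cut-site remnant (``GWC`` for AvaII, optionally the strict
   ``GWCC``) must immediately follow the barcode;
c) no adapter or adapter-dimer contamination: none of the adapter screen
   words may occur anywhere in the read with at most
   ``screen_max_mismatch`` mismatches;
d) no uncalled bases (N) within the first ``n_window`` (default 80)
   bases of the trimmed read.

Passing reads have the barcode removed (the remnant is genomic and is
retained) and are routed to their sample.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from .barcodes import MINUS_STUB, PLUS_STUB, BarcodeSet, DEFAULT_REMNANT
from .digest import expand_motif
from .seqio import SeqRecord, reverse_complement, write_fastq

RULES = ("a", "b", "c", "d")


def default_adapter_screen(k: int = 12) -> list[str]:
    """Adapter-contamination screen words: leading ``k`` nt of the minus-
    strand stub and of the reverse complement of the plus-strand stub."""
    return [MINUS_STUB[:k], reverse_complement(PLUS_STUB)[:k]]


@dataclass
class FilterConfig:
    barcode_set: BarcodeSet
    remnant_words: set[str] = field(default_factory=lambda: expand_motif(DEFAULT_REMNANT))
    n_window: int = 80
    adapter_screen: list[str] = field(default_factory=default_adapter_screen)
    screen_max_mismatch: int = 1
    trim_barcode: bool = True
    n_window_on_raw: bool = False

    def __post_init__(self) -> None:
        if self.n_window < 1:
            raise ValueError("n_window must be >= 1")
        if not self.adapter_screen:
            raise ValueError("adapter screen word list is empty")
        if not self.remnant_words:
            raise ValueError("remnant word set is empty")
        # longest-match lookup table: lengths descending
        self._lengths = sorted({len(s) for s in self.barcode_set.sequences}, reverse=True)
        self._lookup = self.barcode_set.by_sequence()


@dataclass
class Assignment:
    sample_id: str
    trimmed_read: SeqRecord


@dataclass
class Rejection:
    rule: str  # one of a/b/c/d


@dataclass
class DemuxStats:
    total_reads: int
    passed_reads: int
    rejections: dict[str, int]
    per_sample: dict[str, int]

    @property
    def mean(self) -> float:
        return float(np.mean(list(self.per_sample.values())))

    @property
    def sd(self) -> float:
        return float(np.std(list(self.per_sample.values()), ddof=1))

    @property
    def cv(self) -> float:
        return compute_cv(list(self.per_sample.values()))

    @property
    def pass_fraction(self) -> float:
        return self.passed_reads / self.total_reads if self.total_reads else 0.0


def _contains_approx(read: str, word: str, max_mismatch: int) -> bool:
    k = len(word)
    if k > len(read):
        return False
    if max_mismatch == 0:
        return word in read
    for i in range(len(read) - k + 1):
        mm = 0
        window = read[i : i + k]
        for x, y in zip(window, word):
            if x != y:
                mm += 1
                if mm > max_mismatch:
                    break
        else:
            return True
    return False


def classify_read(read: SeqRecord, config: FilterConfig) -> Assignment | Rejection:
    """Apply rules a-d in order; return the sample assignment with the
    barcode-trimmed read, or the first failing rule."""
    seq = read.seq
    # rules a+b: longest barcode match whose cut-site remnant follows.
    # A decodable set guarantees at most one barcode parses with its
    # remnant, but a shorter barcode's remnant may begin with the same
    # bases as a longer barcode, so candidates are tried longest-first
    # and a match without a remnant falls through to shorter ones.
    barcode = None
    matched_any = False
    for L in config._lengths:
        if seq[:L] not in config._lookup:
            continue
        matched_any = True
        if any(seq.startswith(w, L) for w in config.remnant_words):
            barcode = seq[:L]
            break
    if not matched_any:
        return Rejection("a")
    if barcode is None:
        return Rejection("b")
    trimmed_seq = seq[len(barcode) :]
    # rule c: adapter / adapter-dimer screen on the whole read
    if any(
        _contains_approx(seq, w, config.screen_max_mismatch)
        for w in config.adapter_screen
    ):
        return Rejection("c")
    # rule d: no N in the first n_window bases
    scan = seq if config.n_window_on_raw else trimmed_seq
    if "N" in scan[: config.n_window]:
        return Rejection("d")
    if config.trim_barcode:
        qual = read.qual[len(barcode) :] if read.qual is not None else None
        out = SeqRecord(read.id, trimmed_seq, qual)
    else:
        out = read
    return Assignment(config._lookup[barcode], out)


def demux_reads(
    reads: Iterable[SeqRecord], config: FilterConfig
) -> tuple[dict[str, list[SeqRecord]], DemuxStats]:
    """Partition reads into per-sample lists plus rejection statistics.

    Every input read lands in exactly one sample or one rejection rule,
    so ``total == passed + sum(rejections)`` always holds.
    """
    per_sample: dict[str, list[SeqRecord]] = {
        b.sample_id: [] for b in config.barcode_set
    }
    rejections = Counter({r: 0 for r in RULES})
    total = 0
    for read in reads:
        total += 1
        result = classify_read(read, config)
        if isinstance(result, Assignment):
            per_sample[result.sample_id].append(result.trimmed_read)
        else:
            rejections[result.rule] += 1
    passed = total - sum(rejections.values())
    stats = DemuxStats(
        total_reads=total,
        passed_reads=passed,
        rejections=dict(rejections),
        per_sample={sid: len(v) for sid, v in per_sample.items()},
    )
    return per_sample, stats


def run_demux(
    fastq_in: str | Path,
    config: FilterConfig,
    out_dir: str | Path,
) -> DemuxStats:
    """Demultiplex a FASTQ file into per-sample FASTQ files on disk."""
    from .seqio import iter_fastq

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    per_sample, stats = demux_reads(iter_fastq(fastq_in), config)
    for sid, recs in per_sample.items():
        if recs:
            write_fastq(recs, out_dir / f"{sid}.fq")
    return stats


def compute_cv(counts: list[int] | list[float]) -> float:
    """Coefficient of variation: sample sd (n-1 denominator) over mean."""
    if len(counts) < 2:
        raise ValueError("cv requires at least 2 samples")
    arr = np.asarray(counts, dtype=float)
    mean = arr.mean()
    if mean == 0:
        raise ValueError("cv undefined for zero mean")
    return float(arr.std(ddof=1) / mean)


def stats_table(stats: DemuxStats):
    """Per-sample read counts as a DataFrame with a summary row."""
    import pandas as pd

    rows = [
        {"sample_id": sid, "reads": n, "fraction": n / stats.total_reads if stats.total_reads else 0.0}
        for sid, n in stats.per_sample.items()
    ]
    df = pd.DataFrame(rows)
    return df
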