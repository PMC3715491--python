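"""In-silico restriction digestion and fragment statistics.

A reduced-representation experiment sequences only the genome fraction
adjacent to restriction cut sites.  This module digests a reference with
a (possibly degenerate) type II enzyme such as AvaII — recognition motif
GGWCC (W = A or T), cutting G^GWCC to leave a 3-base 5' overhang GWC —
applies a fragment-length size window, and summarises the genome
coverage and sequencing yield an experiment designed around that enzyme
and window would obtain.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

from .seqio import IUPAC_CODES, GenomeIndex


@dataclass(frozen=True)
class EnzymeSpec:
    """A restriction enzyme: degenerate recognition motif plus cut offsets.

    ``cut_top``/``cut_bottom`` are offsets of the top/bottom strand cuts
    within the motif.  The defaults describe AvaII: motif GGWCC, top cut
    after base 1 (G^GWCC), bottom cut after base 4, leaving the 5'
    overhang ``GWC``.
    """

    name: str = "AvaII"
    recognition: str = "GGWCC"
    cut_top: int = 1
    cut_bottom: int = 4

    def __post_init__(self) -> None:
        motif = self.recognition.upper()
        bad = set(motif) - set(IUPAC_CODES)
        if bad:
            raise ValueError(f"invalid IUPAC codes in motif: {sorted(bad)}")
        if not (0 <= self.cut_top <= self.cut_bottom <= len(motif)):
            raise ValueError(
                f"cut offsets ({self.cut_top},{self.cut_bottom}) outside motif "
                f"of length {len(motif)}"
            )
        object.__setattr__(self, "recognition", motif)

    @property
    def overhang(self) -> str:
        return self.recognition[self.cut_top : self.cut_bottom]

    @property
    def overhang_words(self) -> set[str]:
        return expand_motif(self.overhang)


@dataclass(frozen=True)
class Fragment:
    """A digest product on the reference plus strand (0-based half-open)."""

    contig: str
    start: int
    end: int
    left_is_cut: bool
    right_is_cut: bool

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty fragment {self.contig}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def internal(self) -> bool:
        """True when both ends are cuts, i.e. both ends carry a ligatable overhang."""
        return self.left_is_cut and self.right_is_cut


@dataclass(frozen=True)
class SizeWindow:
    """Inclusive fragment-length bounds in bp."""

    lo: int
    hi: int

    def __post_init__(self) -> None:
        if not (0 < self.lo <= self.hi):
            raise ValueError(f"invalid size window [{self.lo},{self.hi}]")

    def __contains__(self, length: int) -> bool:
        return self.lo <= length <= self.hi


@dataclass
class DigestSummary:
    n_sites: int
    n_fragments_total: int
    n_fragments_selected: int
    unique_fragment_count: int
    covered_bases: int
    coverage_fraction: float
    read_len: int
    expected_sequenced_bases: int
    sequence_unique_fragment_count: int | None = None


def expand_motif(recognition: str) -> set[str]:
    """Cartesian expansion of a degenerate IUPAC motif into concrete words.

    ``GGWCC`` -> {``GGACC``, ``GGTCC``}.
    """
    motif = recognition.upper()
    bad = set(motif) - set(IUPAC_CODES)
    if bad:
        raise ValueError(f"invalid IUPAC codes: {sorted(bad)}")
    return {"".join(word) for word in itertools.product(*(IUPAC_CODES[c] for c in motif))}


def _motif_regex(recognition: str) -> re.Pattern[str]:
    # Character classes over ACGT only: ambiguity codes (e.g. N runs) in
    # the *genome* never match any motif word.
    parts = []
    for c in recognition.upper():
        bases = IUPAC_CODES[c]
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    # lookahead allows overlapping matches (irrelevant for GGWCC, matters
    # for other motifs)
    return re.compile("(?=" + "".join(parts) + ")")


def find_sites(contig_seq: str, enzyme: EnzymeSpec) -> list[int]:
    """Top-strand cut coordinates of every motif match in a contig.

    Cut position = match start + ``cut_top``; sorted ascending,
    deduplicated.  Overlapping motif matches are allowed.
    """
    pattern = _motif_regex(enzyme.recognition)
    seq = contig_seq.upper()
    sites = {m.start() + enzyme.cut_top for m in pattern.finditer(seq)}
    return sorted(sites)


def digest_genome(genome: GenomeIndex, enzyme: EnzymeSpec) -> list[Fragment]:
    """Digest every contig; k cuts on a contig yield k+1 fragments.

    Fragments tile each contig exactly.  Contig ends are not cuts, so
    terminal fragments carry ``left_is_cut``/``right_is_cut`` False at
    the contig boundary.
    """
    fragments: list[Fragment] = []
    for contig in genome.contig_ids:
        seq = genome.sequence(contig)
        cuts = find_sites(seq, enzyme)
        bounds = [0] + [c for c in cuts if 0 < c < len(seq)] + [len(seq)]
        for i, (a, b) in enumerate(zip(bounds[:-1], bounds[1:])):
            fragments.append(
                Fragment(
                    contig=contig,
                    start=a,
                    end=b,
                    left_is_cut=i > 0,
                    right_is_cut=i < len(bounds) - 2,
                )
            )
    return fragments


def select_fragments(
    fragments: list[Fragment],
    window: SizeWindow,
    require_both_cuts: bool = True,
) -> list[Fragment]:
    """Fragments inside the size window that can be ligated and sequenced.

    Terminal contig fragments lack a ligatable overhang on one end and
    cannot receive two adapters, so they are excluded by default.
    """
    return [
        f
        for f in fragments
        if f.length in window and (f.internal or not require_both_cuts)
    ]


def summarize_digest(
    fragments: list[Fragment],
    window: SizeWindow,
    genome_length: int,
    read_len: int = 100,
    genome: GenomeIndex | None = None,
    require_both_cuts: bool = True,
) -> DigestSummary:
    """Coverage and yield statistics for a digest under a size window.

    ``expected_sequenced_bases`` assumes paired-end reads of ``read_len``
    from both fragment ends: min(length, 2*read_len) per selected
    fragment.  ``unique_fragment_count`` counts coordinate-distinct
    selected fragments; pass ``genome`` to additionally report a
    sequence-deduplicated count.
    """
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    selected = select_fragments(fragments, window, require_both_cuts)
    covered = sum(f.length for f in selected)
    n_sites = sum(f.right_is_cut for f in fragments)
    seq_unique = None
    if genome is not None:
        seq_unique = len(
            {genome.fetch(f.contig, f.start, f.end) for f in selected}
        )
    return DigestSummary(
        n_sites=n_sites,
        n_fragments_total=len(fragments),
        n_fragments_selected=len(selected),
        unique_fragment_count=len({(f.contig, f.start, f.end) for f in selected}),
        covered_bases=covered,
        coverage_fraction=covered / genome_length,
        read_len=read_len,
        expected_sequenced_bases=sum(min(f.length, 2 * read_len) for f in selected),
        sequence_unique_fragment_count=seq_unique,
    )


def fragments_to_bed(fragments: list[Fragment]) -> str:
    """BED (0-based half-open) text for a fragment list."""
    lines = [
        f"{f.contig}\t{f.start}\t{f.end}\tfrag\t{f.length}\t+"
        for f in fragments
    ]
    return "\n".join(lines) + ("\n" if lines else "")
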