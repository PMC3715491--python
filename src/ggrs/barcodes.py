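"""Variable-length barcode sets and adapter construction.

Sample barcodes of mixed lengths (4-8 nt by default) stagger the
invariant cut-site remnant across sequencing cycles, so that no cycle
presents the same base on every cluster — the low-diversity condition
that causes phasing errors on Illumina instruments.  Variable lengths,
however, make demultiplexing ambiguous unless the set is chosen so that
no read prefix can parse as (barcode + remnant) under two different
barcodes.  This module designs such sets, validates arbitrary sets
against that decodability condition, and derives the adapter oligo pair
for each barcode.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass, field

from .digest import EnzymeSpec, expand_motif
from .seqio import reverse_complement

PLUS_STUB = "ACACTCTTTCCCTACACGACGCTCTTCCGATCT"
MINUS_STUB = "AGATCGGAAGAGCGGTTCAGCAGGAATGCCGAG"

DEFAULT_REMNANT = "GWC"


@dataclass(frozen=True)
class Barcode:
    sample_id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not set(seq) <= set("ACGT"):
            raise ValueError(f"barcode {seq!r}: only A/C/G/T allowed")
        if not 4 <= len(seq) <= 8:
            raise ValueError(f"barcode {seq!r}: length must be 4-8")
        object.__setattr__(self, "sequence", seq)


@dataclass(frozen=True)
class AdapterPair:
    """The two oligo strands of a barcoded Y-adapter.

    plus_strand  = PLUS_STUB + barcode
    minus_strand = overhang + rc(barcode) + MINUS_STUB

    The overhang is kept symbolic (``GWC``) unless a concrete word is
    requested; when annealed, the barcode region of the minus strand is
    the reverse complement of the barcode region of the plus strand.
    """

    plus_strand: str
    minus_strand: str


class BarcodeSet:
    """An ordered set of barcodes with unique sample ids and sequences."""

    def __init__(self, barcodes: list[Barcode]):
        if not barcodes:
            raise ValueError("empty barcode set")
        ids = [b.sample_id for b in barcodes]
        seqs = [b.sequence for b in barcodes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids in barcode set")
        if len(set(seqs)) != len(seqs):
            raise ValueError("duplicate barcode sequences in barcode set")
        self.barcodes = list(barcodes)

    def __len__(self) -> int:
        return len(self.barcodes)

    def __iter__(self):
        return iter(self.barcodes)

    @property
    def sequences(self) -> list[str]:
        return [b.sequence for b in self.barcodes]

    @property
    def max_length(self) -> int:
        return max(len(b.sequence) for b in self.barcodes)

    def by_sequence(self) -> dict[str, str]:
        return {b.sequence: b.sample_id for b in self.barcodes}

    @classmethod
    def from_rows(cls, rows: list[tuple[str, str]]) -> "BarcodeSet":
        return cls([Barcode(sid, seq) for sid, seq in rows])

    def to_rows(self) -> list[tuple[str, str]]:
        return [(b.sample_id, b.sequence) for b in self.barcodes]


def build_adapter(
    barcode: Barcode, enzyme: EnzymeSpec | None = None, concrete_overhang: str | None = None
) -> AdapterPair:
    """Construct the adapter oligo pair for one barcode.

    The minus strand starts with the enzyme's 5' overhang (symbolic
    ``GWC`` for AvaII unless ``concrete_overhang`` picks one of its
    expansions) followed by the reverse complement of the barcode.
    """
    enzyme = enzyme or EnzymeSpec()
    overhang = enzyme.overhang
    if concrete_overhang is not None:
        if concrete_overhang not in expand_motif(overhang):
            raise ValueError(
                f"{concrete_overhang!r} is not an expansion of overhang {overhang!r}"
            )
        overhang = concrete_overhang
    return AdapterPair(
        plus_strand=PLUS_STUB + barcode.sequence,
        minus_strand=overhang + reverse_complement(barcode.sequence) + MINUS_STUB,
    )


def _prefix_compatible(a: str, b: str) -> bool:
    return a.startswith(b) or b.startswith(a)


def validate_barcode_set(
    bset: BarcodeSet, remnant_words: set[str] | None = None
) -> dict:
    """Check that a barcode set is decodable given the cut-site remnant.

    Every valid read begins barcode + remnant word.  The set is invalid
    iff two different barcodes admit prefix-compatible (barcode +
    remnant) strings — i.e. some read prefix parses under both.  Returns
    ``{"valid": bool, "conflicts": [(seq1, seq2), ...]}`` with conflicts
    listed for every offending pair.
    """
    remnant_words = remnant_words or expand_motif(DEFAULT_REMNANT)
    seqs = bset.sequences
    conflicts: list[tuple[str, str]] = []
    for b1, b2 in itertools.combinations(seqs, 2):
        if any(
            _prefix_compatible(b1 + w1, b2 + w2)
            for w1 in remnant_words
            for w2 in remnant_words
        ):
            conflicts.append((b1, b2))
    return {"valid": not conflicts, "conflicts": conflicts}


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _cycle_balanced(seqs: list[str], max_len: int) -> bool:
    # no sequencing cycle <= max barcode length may present a single base
    # across the whole set (remnant bases count for shorter barcodes)
    remnant = "GWC"
    for cycle in range(max_len):
        bases = set()
        for s in seqs:
            if cycle < len(s):
                bases.add(s[cycle])
            else:
                # after the barcode the invariant remnant follows; W is diverse
                off = cycle - len(s)
                if off < len(remnant):
                    bases.add(remnant[off] if remnant[off] != "W" else "AT")
                else:
                    bases.add("*")  # genomic sequence: diverse
        if len(bases) == 1 and "*" not in bases:
            return False
    return True


class BarcodeCapacityError(RuntimeError):
    def __init__(self, requested: int, achieved: int):
        self.requested = requested
        self.achieved = achieved
        super().__init__(
            f"could not construct {requested} barcodes under the design "
            f"constraints; best achieved {achieved}"
        )


def design_barcode_set(
    n: int,
    lengths: list[int] | None = None,
    remnant_words: set[str] | None = None,
    seed: int = 0,
    sample_prefix: str = "S",
    max_tries: int = 200_000,
    alphabet: str = "ACGT",
) -> BarcodeSet:
    """Greedy randomised construction of a decodable barcode set.

    Produces ``n`` barcodes spanning the requested lengths (cycled so the
    set covers all of them), each at Hamming distance >= 2 from every
    other barcode of the same length, jointly decodable against the
    remnant, and with per-cycle base balance so no early sequencing
    cycle is monomorphic across the set.  Reproducible for a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lengths = lengths or [4, 5, 6, 7, 8]
    remnant_words = remnant_words or expand_motif(DEFAULT_REMNANT)
    rng = random.Random(seed)
    chosen: list[str] = []
    target_lengths = [lengths[i % len(lengths)] for i in range(n)]
    tries = 0
    for L in target_lengths:
        placed = False
        while tries < max_tries:
            tries += 1
            cand = "".join(rng.choice(alphabet) for _ in range(L))
            if cand in chosen:
                continue
            if any(len(c) == L and _hamming(c, cand) < 2 for c in chosen):
                continue
            trial = chosen + [cand]
            ok = all(
                not any(
                    _prefix_compatible(cand + w1, other + w2)
                    for w1 in remnant_words
                    for w2 in remnant_words
                )
                for other in chosen
            )
            if not ok:
                continue
            if n > 1 and len(trial) == n and not _cycle_balanced(trial, max(lengths)):
                continue
            chosen = trial
            placed = True
            break
        if not placed:
            raise BarcodeCapacityError(n, len(chosen))
    width = len(str(n))
    bset = BarcodeSet(
        [Barcode(f"{sample_prefix}{i+1:0{width}d}", s) for i, s in enumerate(chosen)]
    )
    report = validate_barcode_set(bset, remnant_words)
    if not report["valid"]:  # pragma: no cover - construction guarantees this
        raise BarcodeCapacityError(n, 0)
    return bset
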