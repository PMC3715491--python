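"""Multi-sample Bayesian diploid genotype calling and SNP validation.

Per site, per sample, read bases are modelled as independent draws from
the underlying diploid genotype with a Phred-derived substitution error
rate e = 10^(-Q/10):

    P(base x | hom aa)  = 1 - e      if x == a, else e/3
    P(base x | het ab)  = 1/2 P(x|aa) + 1/2 P(x|bb)

The genotype log-likelihood is the sum over reads.  The genotype prior
is Hardy-Weinberg, {(1-f)^2, 2f(1-f), f^2}, with the alternate-allele
frequency f estimated by an EM algorithm pooling the genotype
likelihoods of all samples — the "multi-individual" prior: each E-step
computes per-sample genotype posteriors under HWE(f), each M-step sets f
to the posterior-expected alternate-allele dosage over 2n chromosomes.

A genotype is reported when the sample's depth reaches ``min_depth`` and
the maximum posterior reaches ``posterior_threshold``; otherwise the
genotype is missing.  Sites then pass validation only with call rate >=
``min_call_rate`` and minor allele frequency >= ``min_maf``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

GENOTYPES = ("0/0", "0/1", "1/1")
MISSING = "./."

QUAL_FLOOR = 2
QUAL_CAP = 40


@dataclass
class FilterCriteria:
    """The three SNP-validation thresholds.

    min_depth: reads/site/individual required to call a genotype (>= 5).
    min_call_rate: minimum fraction of genotyped individuals (15%).
    min_maf: minimum minor allele frequency (5%).
    ``strict_depth`` switches the depth rule from >= to strictly >.
    """

    min_depth: int = 5
    min_call_rate: float = 0.15
    min_maf: float = 0.05
    posterior_threshold: float = 0.9
    strict_depth: bool = False
    max_third_allele_fraction: float = 0.10

    def depth_ok(self, depth: int) -> bool:
        return depth > self.min_depth if self.strict_depth else depth >= self.min_depth


@dataclass
class PileupColumn:
    """Per-site base evidence: one (bases, quals) pair per sample."""

    contig: str
    pos: int  # 0-based
    ref_base: str
    samples: list[tuple[str, list[int]]]  # (bases string, phred quals)


@dataclass
class SampleCall:
    genotype: str
    depth: int
    posterior: float


@dataclass
class VariantCall:
    contig: str
    pos: int  # 0-based
    ref: str
    alt: str
    alt_freq: float
    samples: list[SampleCall]

    @property
    def call_rate(self) -> float:
        called = sum(s.genotype != MISSING for s in self.samples)
        return called / len(self.samples) if self.samples else 0.0

    @property
    def maf(self) -> float:
        return min(self.alt_freq, 1.0 - self.alt_freq)


def base_error(phred: float) -> float:
    """Phred score to base-calling error probability: e = 10^(-Q/10)."""
    if phred < 0:
        raise ValueError("negative Phred score")
    return 10.0 ** (-phred / 10.0)


def _clamp_qual(q: int) -> int:
    return max(QUAL_FLOOR, min(QUAL_CAP, q))


def genotype_likelihoods(
    bases: str, quals: Sequence[int], allele_ref: str, allele_alt: str
) -> np.ndarray:
    """Log-likelihoods [log L(RR), log L(RA), log L(AA)] for one sample.

    An empty pileup returns zeros (uninformative).  Qualities are
    floored at 2 and capped at 40 before conversion.
    """
    ll = np.zeros(3)
    for base, q in zip(bases, quals):
        e = base_error(_clamp_qual(q))
        p_ref = (1.0 - e) if base == allele_ref else e / 3.0
        p_alt = (1.0 - e) if base == allele_alt else e / 3.0
        ll[0] += math.log(p_ref)
        ll[1] += math.log(0.5 * p_ref + 0.5 * p_alt)
        ll[2] += math.log(p_alt)
    return ll


def hwe_prior(f: float) -> np.ndarray:
    return np.array([(1.0 - f) ** 2, 2.0 * f * (1.0 - f), f * f])


def _posteriors(loglik: np.ndarray, prior: np.ndarray) -> np.ndarray:
    """Normalised genotype posteriors from log-likelihoods and a prior."""
    with np.errstate(divide="ignore"):
        logpost = loglik + np.log(prior)
    logpost -= logpost.max(axis=-1, keepdims=True)
    post = np.exp(logpost)
    return post / post.sum(axis=-1, keepdims=True)


def estimate_allele_frequency(
    logliks: np.ndarray,
    f_init: float = 0.5,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> tuple[float, list[float]]:
    """EM estimate of the alternate allele frequency under HWE.

    ``logliks`` is (n_samples, 3).  Samples with all-zero log-likelihood
    rows (no data) are ignored.  Returns (f_hat, observed-data
    log-likelihood trace); the trace is non-decreasing.
    """
    logliks = np.asarray(logliks, dtype=float)
    informative = ~np.all(logliks == 0.0, axis=1)
    ll = logliks[informative]
    n = ll.shape[0]
    if n == 0:
        raise ValueError("no informative samples at site")
    f = f_init
    trace: list[float] = []
    dosage = np.array([0.0, 1.0, 2.0])
    for _ in range(max_iter):
        prior = hwe_prior(f)
        with np.errstate(divide="ignore"):
            joint = ll + np.log(np.maximum(prior, 1e-300))
        m = joint.max(axis=1, keepdims=True)
        marg = m[:, 0] + np.log(np.exp(joint - m).sum(axis=1))
        trace.append(float(marg.sum()))
        post = np.exp(joint - m)
        post /= post.sum(axis=1, keepdims=True)
        f_new = float((post @ dosage).sum() / (2 * n))
        if abs(f_new - f) < tol:
            f = f_new
            break
        f = f_new
    return f, trace


def choose_alleles(
    column: PileupColumn, max_third_allele_fraction: float = 0.10
) -> tuple[str, str] | None:
    """The two modelled alleles: highest summed base quality, ties broken
    lexicographically; the reference base is the ref allele when it is
    among the top two.  Returns None for monomorphic columns or columns
    with a credible third allele."""
    qual_sum: dict[str, float] = {"A": 0.0, "C": 0.0, "G": 0.0, "T": 0.0}
    for bases, quals in column.samples:
        for b, q in zip(bases, quals):
            if b in qual_sum:
                qual_sum[b] += _clamp_qual(q)
    present = [b for b, s in qual_sum.items() if s > 0]
    if len(present) < 2:
        return None
    ranked = sorted(present, key=lambda b: (-qual_sum[b], b))
    top2 = ranked[:2]
    total = sum(qual_sum.values())
    third = total - qual_sum[top2[0]] - qual_sum[top2[1]]
    if third > max_third_allele_fraction * total:
        return None  # credible third allele: not a biallelic SNP
    if column.ref_base in top2:
        ref = column.ref_base
        alt = top2[0] if top2[1] == ref else top2[1]
    else:
        ref, alt = top2[0], top2[1]
    return ref, alt


def call_site(column: PileupColumn, criteria: FilterCriteria) -> VariantCall | None:
    """Bayesian genotype call at one site across all samples.

    Returns None when the column is monomorphic (or fails the biallelic
    screen).  Per sample the posterior is proportional to prior x
    likelihood; the argmax genotype is reported only at sufficient depth
    and posterior, else missing.
    """
    alleles = choose_alleles(column, criteria.max_third_allele_fraction)
    if alleles is None:
        return None
    ref, alt = alleles
    logliks = np.array(
        [genotype_likelihoods(b, q, ref, alt) for b, q in column.samples]
    )
    try:
        f, _ = estimate_allele_frequency(logliks)
    except ValueError:
        return None
    prior = hwe_prior(f)
    calls = []
    for (bases, quals), ll in zip(column.samples, logliks):
        depth = len(bases)
        post = _posteriors(ll, np.maximum(prior, 1e-300))
        best = int(post.argmax())
        if criteria.depth_ok(depth) and post[best] >= criteria.posterior_threshold:
            gt = GENOTYPES[best]
        else:
            gt = MISSING
        calls.append(SampleCall(gt, depth, float(post[best])))
    return VariantCall(column.contig, column.pos, ref, alt, f, calls)


def apply_site_filters(
    calls: Iterable[VariantCall], criteria: FilterCriteria
) -> list[VariantCall]:
    """Keep sites with call rate >= min_call_rate and MAF >= min_maf.

    Per-sample depth masking is already applied inside :func:`call_site`.
    Boundary values (call rate exactly 15%, MAF exactly 5%) are kept.
    """
    return [
        c
        for c in calls
        if c.call_rate >= criteria.min_call_rate and c.maf >= criteria.min_maf
    ]


def call_pileup(
    columns: Iterable[PileupColumn], criteria: FilterCriteria | None = None
) -> list[VariantCall]:
    """Call and filter every column; convenience wrapper."""
    criteria = criteria or FilterCriteria()
    raw = [call_site(col, criteria) for col in columns]
    return apply_site_filters([c for c in raw if c is not None], criteria)


VCF_HEADER = """\
##fileformat=VCFv4.2
##FILTER=<ID=PASS,Description="All filters passed">
##INFO=<ID=AF,Number=A,Type=Float,Description="Estimated alternate allele frequency">
##INFO=<ID=NS,Number=1,Type=Integer,Description="Number of genotyped samples">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
"""


def write_vcf(
    calls: list[VariantCall],
    sample_ids: list[str],
    path: str | Path,
    contig_lengths: dict[str, int] | None = None,
) -> None:
    """VCF 4.2 with GT and DP per sample; positions converted to 1-based."""
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        for contig, length in (contig_lengths or {}).items():
            fh.write(f"##contig=<ID={contig},length={length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_ids)
            + "\n"
        )
        for call in sorted(calls, key=lambda c: (c.contig, c.pos)):
            ns = sum(s.genotype != MISSING for s in call.samples)
            fields = [
                call.contig,
                str(call.pos + 1),
                ".",
                call.ref,
                call.alt,
                ".",
                "PASS",
                f"AF={call.alt_freq:.4f};NS={ns}",
                "GT:DP",
            ]
            fields += [f"{s.genotype}:{s.depth}" for s in call.samples]
            fh.write("\t".join(fields) + "\n")


def genotype_matrix(calls: list[VariantCall], sample_ids: list[str]):
    """Samples x sites alternate-allele dosage matrix (0/1/2, NA missing).

    The export surface for downstream imputation; rows are samples,
    columns are ``contig:pos1`` site labels, deterministic order.
    """
    import pandas as pd

    dosage = {"0/0": 0.0, "0/1": 1.0, "1/1": 2.0, MISSING: np.nan}
    ordered = sorted(calls, key=lambda c: (c.contig, c.pos))
    data = {
        f"{c.contig}:{c.pos + 1}": [dosage[s.genotype] for s in c.samples]
        for c in ordered
    }
    return pd.DataFrame(data, index=sample_ids)


def write_genotype_matrix(
    calls: list[VariantCall], sample_ids: list[str], path: str | Path
) -> None:
    df = genotype_matrix(calls, sample_ids)
    df.to_csv(path, sep="\t", na_rep="NA", index_label="sample_id")
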