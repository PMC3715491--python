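import math

import numpy as np
import pytest

from ggrs.genocall import (
    MISSING,
    FilterCriteria,
    PileupColumn,
    SampleCall,
    VariantCall,
    apply_site_filters,
    base_error,
    call_site,
    choose_alleles,
    estimate_allele_frequency,
    genotype_likelihoods,
    genotype_matrix,
    hwe_prior,
    write_vcf,
)
from ggrs.simulate import SimConfig, simulate_pileup


def _col(samples, ref="A", pos=0):
    return PileupColumn("c1", pos, ref, samples)


class TestBaseError:
    @pytest.mark.parametrize("phred,eps", [(20, 0.01), (30, 0.001), (0, 1.0)])
    def test_phred_table(self, phred, eps):
        assert base_error(phred) == pytest.approx(eps)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            base_error(-1)


class TestGenotypeLikelihoods:
    def test_single_base_q30(self):
        ll = np.exp(genotype_likelihoods("A", [30], "A", "T"))
        assert ll[0] == pytest.approx(0.999)
        assert ll[1] == pytest.approx(0.5 * 0.999 + 0.5 * 0.001 / 3)
        assert ll[2] == pytest.approx(0.001 / 3)

    def test_balanced_pileup_favors_het(self):
        ll = genotype_likelihoods("AAAAATTTTT", [20] * 10, "A", "T")
        assert ll[1] > ll[0]
        assert ll[0] == pytest.approx(ll[2])

    def test_product_over_reads(self):
        ll = genotype_likelihoods("A" * 10, [40] * 10, "A", "T")
        assert ll[0] == pytest.approx(10 * math.log(0.9999))

    def test_empty_pileup_uninformative(self):
        assert genotype_likelihoods("", [], "A", "T").tolist() == [0.0, 0.0, 0.0]

    def test_quality_floor_and_cap(self):
        # Q0 would give error 1.0; flooring at Q2 keeps likelihoods sane
        ll = genotype_likelihoods("A", [0], "A", "T")
        assert ll[0] == pytest.approx(math.log(1 - base_error(2)))
        ll_hi = genotype_likelihoods("A", [90], "A", "T")
        assert ll_hi[0] == pytest.approx(math.log(1 - base_error(40)))


class TestAlleleFrequencyEM:
    def test_all_hom_ref_drives_f_to_zero(self):
        logliks = np.array([genotype_likelihoods("A" * 10, [30] * 10, "A", "T")] * 20)
        f, trace = estimate_allele_frequency(logliks)
        assert f <= 1e-4

    def test_symmetric_likelihoods_fix_half(self):
        logliks = np.array([genotype_likelihoods("AAAAATTTTT", [20] * 10, "A", "T")] * 10)
        f, _ = estimate_allele_frequency(logliks, f_init=0.5)
        assert f == pytest.approx(0.5, abs=1e-9)

    def test_recovers_simulated_frequency(self, rng):
        # 100 samples, true f = 0.3, depth 10, eps = 0.01
        f_true, n, depth = 0.3, 100, 10
        logliks = []
        for _ in range(n):
            g = rng.binomial(2, f_true)
            bases = "".join(
                "T" if rng.random() < g / 2 else "A" for _ in range(depth)
            )
            logliks.append(genotype_likelihoods(bases, [20] * depth, "A", "T"))
        f, _ = estimate_allele_frequency(np.array(logliks))
        assert abs(f - f_true) < 0.05

    def test_loglik_trace_monotone(self, rng):
        cfg = SimConfig(seed=5, n_individuals=40, error_rate=0.01)
        cols, _, _ = simulate_pileup(cfg, 40, mean_depth=6)
        for col in cols:
            logliks = np.array(
                [genotype_likelihoods(b, q, "A", "C") for b, q in col.samples]
            )
            try:
                _, trace = estimate_allele_frequency(logliks, f_init=0.2)
            except ValueError:
                continue
            assert all(b - a > -1e-9 for a, b in zip(trace, trace[1:]))

    def test_no_informative_samples(self):
        with pytest.raises(ValueError):
            estimate_allele_frequency(np.zeros((5, 3)))


class TestCallSite:
    def test_low_depth_sample_missing(self):
        samples = [("AAAATTTTTT", [30] * 10)] * 10 + [("AATT", [30] * 4)]
        vc = call_site(_col(samples), FilterCriteria())
        assert vc.samples[-1].genotype == MISSING
        assert vc.samples[-1].depth == 4

    def test_strong_alt_homozygote(self):
        # several het samples keep f away from the boundary
        samples = [("AAAAATTTTT", [30] * 10)] * 6 + [("TTTTTTTTTT", [30] * 10)]
        vc = call_site(_col(samples), FilterCriteria())
        assert vc.samples[-1].genotype == "1/1"
        assert vc.samples[-1].posterior > 0.99

    def test_hom_alt_posterior_plug_in_value(self):
        # 10 alt reads at Q30 under an HWE(f=0.3) prior: the posterior is
        # p(AA)L(AA) / sum_g p(g)L(g) with L(AA)=0.999^10, L(RA)~0.49967^10
        from ggrs.genocall import _posteriors

        ll = genotype_likelihoods("T" * 10, [30] * 10, "A", "T")
        post = _posteriors(ll, hwe_prior(0.3))
        expected = (
            0.09 * 0.999**10
            / (0.49 * (0.001 / 3) ** 10 + 0.42 * (0.5 * 0.999 + 0.5 * 0.001 / 3) ** 10
               + 0.09 * 0.999**10)
        )
        assert post[2] == pytest.approx(expected, rel=1e-9)
        assert post[2] > 0.99

    def test_posteriors_normalized_everywhere(self):
        cfg = SimConfig(seed=9, n_individuals=30, error_rate=0.01)
        cols, _, _ = simulate_pileup(cfg, 30, mean_depth=8)
        from ggrs.genocall import _posteriors, hwe_prior

        for col in cols:
            for bases, quals in col.samples:
                ll = genotype_likelihoods(bases, quals, "A", "C")
                post = _posteriors(ll, hwe_prior(0.3))
                assert post.sum() == pytest.approx(1.0, abs=1e-12)

    def test_monomorphic_column_not_emitted(self):
        samples = [("AAAA", [30] * 4)] * 10
        assert call_site(_col(samples), FilterCriteria()) is None

    def test_third_allele_screen(self):
        samples = [("AAAA", [30] * 4), ("TTTT", [30] * 4), ("GGGG", [30] * 4)]
        assert choose_alleles(_col(samples)) is None

    def test_reference_base_becomes_ref_allele(self):
        samples = [("AAAATTTT", [30] * 8)] * 6
        vc = call_site(_col(samples, ref="T"), FilterCriteria())
        assert vc.ref == "T" and vc.alt == "A"

    def test_allele_swap_symmetry(self):
        cfg = SimConfig(seed=21, n_individuals=40, error_rate=0.001)
        cols, _, _ = simulate_pileup(cfg, 25, mean_depth=12)
        crit = FilterCriteria()
        swap = {"0/0": "1/1", "0/1": "0/1", "1/1": "0/0", MISSING: MISSING}
        for col in cols:
            a = call_site(col, crit)
            flipped = PileupColumn(col.contig, col.pos, "C", col.samples)
            b = call_site(flipped, crit)
            if a is None or b is None:
                assert a is None and b is None
                continue
            if a.ref == b.ref:
                continue  # same orientation chosen; nothing to compare
            assert b.alt_freq == pytest.approx(1 - a.alt_freq, abs=1e-6)
            assert b.maf == pytest.approx(a.maf, abs=1e-6)
            for sa, sb in zip(a.samples, b.samples):
                assert sb.genotype == swap[sa.genotype]


def brute_force_filter(calls, min_call_rate, min_maf):
    kept = []
    for c in calls:
        n = len(c.samples)
        called = [s for s in c.samples if s.genotype != MISSING]
        maf = min(c.alt_freq, 1 - c.alt_freq)
        if len(called) / n >= min_call_rate and maf >= min_maf:
            kept.append(c)
    return kept


def _vc(pos, alt_freq, genotypes):
    samples = [SampleCall(g, 10, 0.99) for g in genotypes]
    return VariantCall("c1", pos, "A", "C", alt_freq, samples)


class TestSiteFilters:
    def test_matches_brute_force_on_synthetic_panel(self, rng):
        crit = FilterCriteria()
        calls = []
        for pos in range(50):
            f = float(rng.uniform(0, 0.6))
            genotypes = [
                MISSING if rng.random() < rng.uniform(0, 1) else "0/1"
                for _ in range(20)
            ]
            calls.append(_vc(pos, f, genotypes))
        ours = apply_site_filters(calls, crit)
        oracle = brute_force_filter(calls, 0.15, 0.05)
        assert [c.pos for c in ours] == [c.pos for c in oracle]

    def test_call_rate_below_threshold_removed(self):
        # 10/72 genotyped = 13.9% < 15%
        genotypes = ["0/1"] * 10 + [MISSING] * 62
        assert apply_site_filters([_vc(0, 0.3, genotypes)], FilterCriteria()) == []

    def test_boundary_call_rate_exactly_15_percent_kept(self):
        genotypes = ["0/1"] * 3 + [MISSING] * 17  # 3/20 = 0.15
        assert len(apply_site_filters([_vc(0, 0.3, genotypes)], FilterCriteria())) == 1

    @pytest.mark.parametrize("maf,kept", [(0.04, 0), (0.05, 1)])
    def test_maf_boundary(self, maf, kept):
        genotypes = ["0/1"] * 20
        assert len(apply_site_filters([_vc(0, maf, genotypes)], FilterCriteria())) == kept

    def test_depth_criterion_inclusive_vs_strict(self):
        samples = [("AAAAATTTTT", [30] * 10)] * 10
        samples.append(("AATTT", [30] * 5))  # depth exactly 5
        vc = call_site(_col(samples), FilterCriteria())
        assert vc.samples[-1].genotype != MISSING
        vc_strict = call_site(_col(samples), FilterCriteria(strict_depth=True))
        assert vc_strict.samples[-1].genotype == MISSING


class TestExport:
    def _calls(self):
        return [
            VariantCall(
                "c1",
                4,
                "A",
                "C",
                0.25,
                [SampleCall("0/1", 9, 0.99), SampleCall(MISSING, 2, 0.5)],
            )
        ]

    def test_vcf_fields(self, tmp_path):
        path = tmp_path / "x.vcf"
        write_vcf(self._calls(), ["s1", "s2"], path, {"c1": 100})
        lines = [l for l in path.read_text().splitlines() if not l.startswith("#")]
        assert len(lines) == 1
        fields = lines[0].split("\t")
        assert fields[0] == "c1" and fields[1] == "5"  # 1-based
        assert fields[3] == "A" and fields[4] == "C"
        assert fields[9] == "0/1:9" and fields[10] == "./.:2"

    def test_vcf_parses_with_cyvcf2(self, tmp_path):
        import cyvcf2

        path = tmp_path / "x.vcf"
        write_vcf(self._calls(), ["s1", "s2"], path, {"c1": 100})
        vcf = cyvcf2.VCF(str(path))
        (var,) = list(vcf)
        assert var.POS == 5
        assert var.genotypes[0][:2] == [0, 1]
        assert var.genotypes[1][:2] == [-1, -1]

    def test_dosage_matrix_codes(self):
        df = genotype_matrix(self._calls(), ["s1", "s2"])
        col = df["c1:5"]
        assert col["s1"] == 1.0
        assert np.isnan(col["s2"])
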