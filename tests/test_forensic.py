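"""Forensic parameter formulas against brute-force enumeration oracles."""
from __future__ import annotations

import math

import numpy as np
import pytest

from strpopgen import (
    FrequencyTable,
    YHaplotypeSet,
    autosomal_locus_stats,
    combine_panel,
    gene_diversity,
    haplotype_diversity,
    match_probability,
    mec_duo,
    mec_kruger,
    mec_suite,
    mec_trio,
    pe_tpi,
    pic,
    snp_stats,
    x_discrimination,
)

from oracles import (
    frequency_grid,
    mec_enumeration,
    mp_pairwise,
    pdf_enumeration,
    pic_double_sum,
)


class TestGeneDiversity:
    def test_monomorphic_zero(self):
        assert gene_diversity([1.0], n=50) == 0.0

    def test_all_distinct_exactly_one(self):
        n = 37
        assert gene_diversity([1 / n] * n, n=n) == pytest.approx(1.0, abs=1e-12)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            gene_diversity([0.5, 0.5], n=1)

    def test_relabelling_invariance(self):
        p = [0.5, 0.3, 0.2]
        assert gene_diversity(p, 40) == pytest.approx(gene_diversity(p[::-1], 40))


class TestPic:
    def test_degenerate_and_biallelic(self):
        assert pic([1.0]) == 0.0
        assert pic([0.5, 0.5]) == pytest.approx(0.375)

    def test_bounded_by_one_minus_s2(self):
        for p in ([0.5, 0.5], [0.7, 0.2, 0.1], [0.25] * 4):
            assert pic(p) <= 1 - sum(x * x for x in p) + 1e-12

    def test_unnormalised_frequencies_rejected(self):
        with pytest.raises(ValueError):
            pic([0.5, 0.4])


class TestMatchProbability:
    def test_degenerate_cases(self):
        assert match_probability({("A", "A"): 10}) == (1.0, 0.0)
        mp, pd_ = match_probability({i: 1 for i in range(8)})
        assert mp == pytest.approx(1 / 8)
        assert pd_ == pytest.approx(1 - 1 / 8)

    def test_matches_ordered_pair_oracle(self):
        rng = np.random.default_rng(3)
        genos = [tuple(sorted(rng.choice(list("ABCD"), 2))) for _ in range(60)]
        counts: dict = {}
        for g in genos:
            counts[g] = counts.get(g, 0) + 1
        mp, _ = match_probability(counts)
        assert mp == pytest.approx(mp_pairwise(genos), abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            match_probability({})


class TestPeTpi:
    @pytest.mark.parametrize(
        "h,pe,tpi",
        [(0.0, 0.0, 0.5), (0.5, 0.1875, 1.0), (1.0, 1.0, math.inf)],
    )
    def test_boundary_and_midpoint(self, h, pe, tpi):
        got_pe, got_tpi = pe_tpi(h)
        assert got_pe == pytest.approx(pe)
        assert got_tpi == tpi if math.isinf(tpi) else got_tpi == pytest.approx(tpi)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            pe_tpi(1.2)


class TestXStats:
    def test_monomorphic_all_zero(self):
        s = mec_suite(FrequencyTable("X1", {"10": 20}, 20))
        assert (
            s.MEC_Kruger == s.MEC_Kishida == s.MEC_Desmarais == s.MEC_Desmarais_Duo == 0.0
        )
        assert s.PD_M == 0.0 and s.PD_F == 0.0

    def test_biallelic_values_fixed_by_enumeration(self):
        p = [0.5, 0.5]
        assert mec_trio(p) == pytest.approx(mec_enumeration(p, "trio"), abs=1e-12)
        assert mec_duo(p) == pytest.approx(mec_enumeration(p, "duo"), abs=1e-12)
        assert mec_kruger(p) == pytest.approx(
            mec_enumeration(p, "deficiency"), abs=1e-12
        )
        # frozen oracle values
        assert mec_trio(p) == pytest.approx(0.375)
        assert mec_duo(p) == pytest.approx(0.25)
        assert mec_kruger(p) == pytest.approx(0.1875)

    def test_trio_dominates_duo_on_equifrequent_alleles(self):
        p = [0.1] * 10
        assert mec_trio(p) >= mec_duo(p)

    def test_x_discrimination_examples(self):
        assert x_discrimination([1.0]) == (0.0, 0.0)
        pd_f, pd_m = x_discrimination([0.5, 0.5])
        assert pd_m == pytest.approx(0.5)
        assert pd_f == pytest.approx(0.625)
        for k in (2, 5, 10):
            assert x_discrimination([1 / k] * k)[1] == pytest.approx(1 - 1 / k)


class TestYHaplotypeDiversity:
    def _yh(self, counts):
        haplos = {}
        i = 0
        for j, c in enumerate(counts):
            for _ in range(c):
                haplos[f"M{i}"] = (f"h{j}",)
                i += 1
        return YHaplotypeSet(loci=["Y"], haplotypes=haplos)

    def test_all_identical(self):
        s = haplotype_diversity(self._yh([50]))
        assert s.HD == 0.0 and s.DC == pytest.approx(1 / 50)

    def test_all_distinct(self):
        s = haplotype_diversity(self._yh([1] * 50))
        assert s.HD == pytest.approx(1.0) and s.DC == pytest.approx(1.0)
        assert s.unique_fraction == 1.0

    def test_one_doubleton_formula_values(self):
        s = haplotype_diversity(self._yh([1] * 48 + [2]))
        assert s.n == 50 and s.k == 49
        assert s.HD == pytest.approx(0.999183673469, abs=1e-9)
        assert s.DC == pytest.approx(0.98)
        assert s.unique_fraction == pytest.approx(48 / 49)

    def test_relabelling_invariance(self):
        a = haplotype_diversity(self._yh([3, 2, 1]))
        b = haplotype_diversity(self._yh([1, 3, 2]))
        assert a.HD == pytest.approx(b.HD) and a.DC == b.DC

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            haplotype_diversity(self._yh([1]))


class TestSnpStats:
    def test_fixed_allele_zero_dp(self):
        ft = FrequencyTable("rs1", {"A": 40, "G": 0}, 40)
        s = snp_stats("rs1", ft, {("A", "A"): 20}, het_count=0)
        assert s.DP == 0.0

    def test_triallelic_rejected(self):
        ft = FrequencyTable("rs1", {"A": 1, "C": 1, "G": 2}, 4)
        with pytest.raises(ValueError):
            snp_stats("rs1", ft, {("A", "C"): 1, ("G", "G"): 1}, het_count=1)

    def test_dp_equals_pairwise_match_oracle(self):
        rng = np.random.default_rng(9)
        genos = [tuple(sorted(rng.choice(["A", "G"], 2, p=[0.5, 0.5]))) for _ in range(50)]
        counts: dict = {}
        het = 0
        alleles: dict = {}
        for g in genos:
            counts[g] = counts.get(g, 0) + 1
            het += g[0] != g[1]
            for a in g:
                alleles[a] = alleles.get(a, 0) + 1
        ft = FrequencyTable("rs1", alleles, 100)
        s = snp_stats("rs1", ft, counts, het)
        assert s.DP == pytest.approx(1 - mp_pairwise(genos), abs=1e-12)


class TestClosedFormsAgainstEnumerationGrid:
    def test_pic_mec_pdf_match_oracles_on_grid(self):
        """Closed-form PIC, the three MECs and PD_F agree with their
        enumeration oracles on every frequency vector of length <= 5 over a
        0.05 grid (tolerance 1e-10)."""
        worst = 0.0
        for p in frequency_grid(max_len=5, step=0.05):
            worst = max(
                worst,
                abs(pic(p) - pic_double_sum(p)),
                abs(mec_trio(p) - mec_enumeration(p, "trio")),
                abs(mec_duo(p) - mec_enumeration(p, "duo")),
                abs(mec_kruger(p) - mec_enumeration(p, "deficiency")),
                abs(x_discrimination(p)[0] - pdf_enumeration(p)),
            )
        assert worst <= 1e-10


class TestPanelCombination:
    def _locus(self, name, mp, pe, tpi):
        from strpopgen.forensic import LocusStats

        return LocusStats(
            locus=name, n_obs=200, Hobs=0.8, Hexp=0.8, PIC=0.8,
            MP=mp, PD=1 - mp, PE=pe, TPI=tpi,
        )

    def test_single_locus_equals_locus_stats(self):
        s = self._locus("L1", 0.1, 0.5, 2.0)
        panel = combine_panel([s])
        assert panel.CMP == pytest.approx(0.1)
        assert panel.CPE == pytest.approx(0.5)
        assert panel.CPI == pytest.approx(2.0)

    def test_two_loci_products(self):
        loci = [self._locus(f"L{i}", 0.1, 0.5, 2.0) for i in range(2)]
        panel = combine_panel(loci)
        assert panel.CMP == pytest.approx(0.01)
        assert panel.CPE == pytest.approx(0.75)
        assert panel.CPI == pytest.approx(4.0)

    def test_cpd_monotone_in_loci(self):
        loci = [self._locus(f"L{i}", 0.2, 0.3, 1.5) for i in range(30)]
        cpds = [combine_panel(loci[: i + 1]).CPD for i in range(30)]
        assert all(b >= a for a, b in zip(cpds, cpds[1:]))

    def test_log_space_survives_extreme_magnitudes(self):
        loci = [self._locus(f"L{i}", 0.08, 0.6, 3.0) for i in range(66)]
        panel = combine_panel(loci)
        assert panel.ln_cmp < math.log(1e-70)
        rendered = panel.render()
        assert rendered["CPD"].startswith("1-")
        assert np.isfinite(rendered["log10_CMP"])

    def test_infinite_tpi_propagates(self):
        loci = [self._locus("L1", 0.1, 1.0, math.inf)]
        panel = combine_panel(loci)
        assert panel.CPE == 1.0


class TestHWEConvergence:
    def test_hobs_tracks_hexp_on_simulated_hwe_population(self):
        """On HWE populations the observed heterozygosity stays within three
        binomial standard errors of the expected heterozygosity."""
        from strpopgen import LocusDef, SimConfig, simulate_population

        p = {"A": 0.45, "B": 0.35, "C": 0.20}
        hexp_gen = 1 - sum(x * x for x in p.values())
        within = 0
        for seed in range(10):
            cat = {"L": LocusDef("L", "autosomal", 4)}
            cfg = SimConfig(
                loci=cat, spectra={"L": p}, n_males=250, n_females=250, seed=seed
            )
            gt, _, _ = simulate_population(cfg)
            het = sum(
                1 for s in gt.samples if len(set(gt.get(s, "L"))) == 2
            ) / len(gt.samples)
            se = math.sqrt(hexp_gen * (1 - hexp_gen) / len(gt.samples))
            within += abs(het - hexp_gen) <= 3 * se
        assert within >= 9
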