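"""Frequency denominators, Y haplotypes, and the sex-homogeneity check."""
from __future__ import annotations

import numpy as np
import pytest
from scipy.stats import fisher_exact

from strpopgen import (
    FrequencyTable,
    GenotypeTable,
    LocusDef,
    ValidationError,
    assemble_y_haplotypes,
    compute_allele_frequencies,
    pool_sex_frequencies_check,
)
from strpopgen.reported_variants import reported_locus_def

from oracles import contingency_g_enumeration, haplotype_counts_pairwise


def small_cohort(n_males=3, n_females=3):
    samples = [f"M{i}" for i in range(n_males)] + [f"F{i}" for i in range(n_females)]
    sex = {s: s[0] for s in samples}
    loci = {
        "AUT": LocusDef("AUT", "autosomal", 4),
        "XL": LocusDef("XL", "X", 4),
        "YL": LocusDef("YL", "Y", 4),
        "YM": LocusDef("YM", "Y", 4, copy_count=2),
    }
    return GenotypeTable(samples=samples, sex=sex, loci=loci)


class TestDenominators:
    def test_autosomal_denominator_two_per_sample(self, injected_population):
        ft = compute_allele_frequencies(
            injected_population, injected_population.loci["D8S1132"]
        )
        assert ft.denominator == 200
        assert ft.freqs["[TCTA]13 TCTG [TCTA]1"] == pytest.approx(0.015)

    def test_x_denominator_pooled_haploid_aware(self, injected_population):
        locus = injected_population.loci["DXS10074"]
        ft = compute_allele_frequencies(injected_population, locus)
        assert ft.denominator == 2 * 50 + 50
        ft2 = compute_allele_frequencies(
            injected_population, locus, x_male_double_count=True
        )
        assert ft2.denominator == 200

    def test_y_single_copy_denominator(self, injected_population):
        ft = compute_allele_frequencies(
            injected_population, injected_population.loci["DYS710"]
        )
        assert ft.denominator == 50
        assert ft.freqs["[AAAG]16 [AG]11 [AAAG]9"] == pytest.approx(0.02)

    def test_y_multicopy_denominator(self, injected_population):
        ft = compute_allele_frequencies(
            injected_population, injected_population.loci["DYF387S1a/b"]
        )
        assert ft.denominator == 100

    def test_monomorphic_locus_freq_one(self):
        gt = small_cohort()
        for s in gt.samples:
            gt.set(s, "AUT", ("[TCTA]9", "[TCTA]9"))
        ft = compute_allele_frequencies(gt, gt.loci["AUT"])
        assert ft.freqs == {"[TCTA]9": 1.0}

    def test_null_calls_shrink_denominator_by_ploidy(self):
        gt = small_cohort()
        for s in gt.samples:
            gt.set(s, "AUT", ("A", "B"))
        full = compute_allele_frequencies(gt, gt.loci["AUT"])
        gt.set("M0", "AUT", ())
        dropped = compute_allele_frequencies(gt, gt.loci["AUT"])
        assert full.denominator - dropped.denominator == 2

    def test_ploidy_violation_names_sample_and_locus(self):
        gt = small_cohort()
        gt.set("M0", "AUT", ("A",))
        with pytest.raises(ValidationError, match="M0.*AUT"):
            compute_allele_frequencies(gt, gt.loci["AUT"])

    def test_frequency_table_invariants(self):
        with pytest.raises(ValueError):
            FrequencyTable("L", {"A": 3}, 4)  # counts must sum to denominator
        ft = FrequencyTable.from_freqs("L", {"A": 0.25, "B": 0.75}, 8)
        assert ft.counts == {"A": 2, "B": 6}
        assert sum(ft.freqs.values()) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            FrequencyTable.from_freqs("L", {"A": 0.3, "B": 0.7}, 7)


class TestYHaplotypes:
    def _male_table(self, tuples):
        samples = [f"M{i}" for i in range(len(tuples))]
        loci = {
            "Y1": LocusDef("Y1", "Y", 4),
            "Y2": LocusDef("Y2", "Y", 4),
        }
        gt = GenotypeTable(samples=samples, sex={s: "M" for s in samples}, loci=loci)
        for s, (a, b) in zip(samples, tuples):
            gt.set(s, "Y1", (a,))
            gt.set(s, "Y2", (b,))
        return gt

    def test_all_distinct_gives_all_singletons(self):
        gt = self._male_table([(f"a{i}", f"b{i}") for i in range(50)])
        yh = assemble_y_haplotypes(gt, list(gt.loci.values()))
        assert yh.n == 50 and yh.k == 50
        assert set(yh.counts().values()) == {1}

    def test_planted_duplicate_gives_one_doubleton(self):
        tuples = [(f"a{i}", f"b{i}") for i in range(49)] + [("a0", "b0")]
        gt = self._male_table(tuples)
        yh = assemble_y_haplotypes(gt, list(gt.loci.values()))
        assert yh.n == 50 and yh.k == 49
        assert sorted(yh.counts().values())[-1] == 2

    def test_counts_match_pairwise_oracle(self):
        rng = np.random.default_rng(11)
        tuples = [
            (f"a{rng.integers(4)}", f"b{rng.integers(3)}") for _ in range(40)
        ]
        gt = self._male_table(tuples)
        yh = assemble_y_haplotypes(gt, list(gt.loci.values()))
        assert sorted(yh.counts().values()) == haplotype_counts_pairwise(
            yh.haplotypes.values()
        )

    def test_multicopy_pair_is_unordered(self):
        loci = {"YM": LocusDef("YM", "Y", 4, copy_count=2)}
        gt = GenotypeTable(samples=["M0", "M1"], sex={"M0": "M", "M1": "M"}, loci=loci)
        gt.set("M0", "YM", ("38", "37.3"))
        gt.set("M1", "YM", ("37.3", "38"))
        yh = assemble_y_haplotypes(gt, [loci["YM"]])
        assert yh.k == 1

    def test_missing_male_dropped_with_warning(self):
        gt = self._male_table([("a", "b"), ("c", "d")])
        gt.set("M1", "Y2", ())
        with pytest.warns(UserWarning, match="M1"):
            yh = assemble_y_haplotypes(gt, list(gt.loci.values()))
        assert yh.n == 1

    def test_female_with_y_calls_rejected(self):
        gt = small_cohort()
        for s in gt.males():
            gt.set(s, "YL", ("10",))
        gt.set("F0", "YL", ("10",))
        with pytest.raises(ValidationError, match="F0"):
            assemble_y_haplotypes(gt, [gt.loci["YL"]])


class TestSexHomogeneity:
    def _x_table(self, male_alleles, female_pairs):
        loci = {"XL": LocusDef("XL", "X", 4)}
        samples = [f"M{i}" for i in range(len(male_alleles))] + [
            f"F{i}" for i in range(len(female_pairs))
        ]
        sex = {s: s[0] for s in samples}
        gt = GenotypeTable(samples=samples, sex=sex, loci=loci)
        for i, a in enumerate(male_alleles):
            gt.set(f"M{i}", "XL", (a,))
        for i, pair in enumerate(female_pairs):
            gt.set(f"F{i}", "XL", pair)
        return gt

    def test_identical_spectra_p_near_one(self):
        gt = self._x_table(["A"] * 5 + ["B"] * 5, [("A", "B")] * 5)
        p = pool_sex_frequencies_check(gt, gt.loci["XL"], seed=1)
        assert p > 0.9

    def test_disjoint_spectra_small_p_matches_fisher(self):
        gt = self._x_table(["A"] * 20, [("B", "B")] * 10)
        p = pool_sex_frequencies_check(gt, gt.loci["XL"], seed=1)
        table = [[20, 0], [0, 20]]
        assert p == pytest.approx(fisher_exact(table)[1])
        assert p < 0.01

    def test_permutation_p_matches_enumeration_on_2x3(self):
        gt = self._x_table(
            ["A"] * 6 + ["B"] * 3 + ["C"] * 1,
            [("A", "B"), ("B", "C"), ("C", "C"), ("B", "B"), ("A", "C")],
        )
        perms = 20000
        p_mc = pool_sex_frequencies_check(
            gt, gt.loci["XL"], permutations=perms, seed=5
        )
        table = np.zeros((2, 3), dtype=int)
        for a in ["A"] * 6 + ["B"] * 3 + ["C"]:
            table[0, "ABC".index(a)] += 1
        for pair in [("A", "B"), ("B", "C"), ("C", "C"), ("B", "B"), ("A", "C")]:
            for a in pair:
                table[1, "ABC".index(a)] += 1
        p_exact = contingency_g_enumeration(table)
        se = np.sqrt(p_exact * (1 - p_exact) / perms)
        assert abs(p_mc - p_exact) < 3 * se + 2 / perms

    def test_single_sex_rejected(self):
        gt = self._x_table(["A", "B"], [])
        with pytest.raises(ValidationError):
            pool_sex_frequencies_check(gt, gt.loci["XL"], seed=1)
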