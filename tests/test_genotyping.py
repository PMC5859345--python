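import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from warfarin_pgx.genotyping import (
    ASSAYS,
    GenotypeCounts,
    NoCall,
    RflpAssay,
    allele_frequencies,
    call_rflp_genotype,
    cyp2c9_diplotype,
    fragments_for_genotype,
    genotype_frequencies,
    genotypes_from_fragments,
    hwe_chi_square,
    vkorc1_genotype,
)

AVAII = ASSAYS["CYP2C9_star2_AvaII"]
KPNI = ASSAYS["CYP2C9_star3_KpnI"]
MSPI = ASSAYS["VKORC1_1639_MspI"]


class TestRflpCalling:
    @pytest.mark.parametrize("assay,fragments,expected", [
        # AvaII cuts the wild-type *1 allele of the 454 bp amplicon
        (AVAII, {397, 57}, "hom_ref"),
        (AVAII, {454}, "hom_var"),
        (AVAII, {454, 397, 57}, "het"),
        # KpnI cuts the variant *3 allele of the 105 bp amplicon
        (KPNI, {105}, "hom_ref"),
        (KPNI, {85, 20}, "hom_var"),
        (KPNI, {105, 85, 20}, "het"),
        # MspI cuts the wild-type G allele of the 290 bp promoter amplicon
        (MSPI, {167, 123}, "hom_ref"),
        (MSPI, {290}, "hom_var"),
        (MSPI, {290, 167, 123}, "het"),
    ])
    def test_all_legal_patterns(self, assay, fragments, expected):
        assert call_rflp_genotype(assay, fragments) == expected

    @pytest.mark.parametrize("assay,fragments,expected", [
        (AVAII, {397}, "hom_ref"),          # 57 bp runs off a 2.5% gel
        (AVAII, {454, 397}, "het"),
        (KPNI, {85}, "hom_var"),            # 20 bp unobservable
        (KPNI, {105, 85}, "het"),
    ])
    def test_sub_resolution_fragments_are_optional(self, assay, fragments, expected):
        assert call_rflp_genotype(assay, fragments) == expected

    def test_call_symmetric_under_ordering(self):
        assert (call_rflp_genotype(MSPI, [123, 290, 167])
                == call_rflp_genotype(MSPI, [290, 167, 123]))

    @pytest.mark.parametrize("fragments", [set(), {300}, {397, 58}, {290, 167}])
    def test_no_call_on_bad_patterns(self, fragments):
        assay = MSPI if 290 in fragments else AVAII
        with pytest.raises(NoCall):
            call_rflp_genotype(assay, fragments)

    def test_assay_fragments_must_sum_to_amplicon(self):
        with pytest.raises(ValueError):
            RflpAssay("bad", 454, frozenset({397, 58}), "wild_type")

    @pytest.mark.parametrize("assay", list(ASSAYS.values()), ids=lambda a: a.name)
    @pytest.mark.parametrize("cls", ["hom_ref", "het", "hom_var"])
    def test_pattern_generation_round_trips(self, assay, cls):
        assert call_rflp_genotype(assay, fragments_for_genotype(assay, cls)) == cls

    def test_diplotype_combination(self):
        assert cyp2c9_diplotype("hom_ref", "hom_ref") == "*1/*1"
        assert cyp2c9_diplotype("het", "hom_ref") == "*1/*2"
        assert cyp2c9_diplotype("het", "het") == "*2/*3"
        assert vkorc1_genotype("het") == "GA"
        with pytest.raises(ValueError):
            cyp2c9_diplotype("hom_var", "het")

    def test_missing_assay_yields_unknown(self):
        cyp, vko = genotypes_from_fragments({"VKORC1_1639_MspI": frozenset({290})})
        assert (cyp, vko) == ("unknown", "AA")


class TestFrequencies:
    def test_study_cyp2c9_percentages(self):
        freqs = genotype_frequencies(GenotypeCounts("cyp", 75, 25, 1))
        assert freqs == pytest.approx((0.743, 0.248, 0.010), abs=5e-4)

    def test_study_vkorc1_percentages(self):
        freqs = genotype_frequencies(GenotypeCounts("vko", 30, 49, 22))
        assert freqs == pytest.approx((0.297, 0.485, 0.218), abs=5e-4)

    def test_monomorphic_frequencies(self):
        assert genotype_frequencies(GenotypeCounts("x", 17, 0, 0)) == (1.0, 0.0, 0.0)
        assert allele_frequencies(GenotypeCounts("x", 0, 0, 9)) == (0.0, 1.0)

    def test_allele_frequency_by_direct_count(self):
        # variant = (het + 2*hom_var) / 2n
        _, q = allele_frequencies(GenotypeCounts("cyp", 75, 25, 1))
        assert q == pytest.approx(27 / 202)
        _, q = allele_frequencies(GenotypeCounts("vko", 30, 49, 22))
        assert q == pytest.approx(93 / 202)

    @given(st.tuples(st.integers(0, 200), st.integers(0, 200), st.integers(0, 200))
           .filter(lambda t: sum(t) > 0))
    def test_frequencies_sum_to_one(self, triple):
        counts = GenotypeCounts("x", *triple)
        assert sum(genotype_frequencies(counts)) == pytest.approx(1.0)
        assert sum(allele_frequencies(counts)) == pytest.approx(1.0)

    def test_allele_frequency_equals_mean_dosage_over_two(self):
        counts = GenotypeCounts("x", 11, 7, 3)
        dosages = [0] * 11 + [1] * 7 + [2] * 3
        _, q = allele_frequencies(counts)
        assert q == pytest.approx(sum(dosages) / len(dosages) / 2)


class TestHardyWeinberg:
    def test_exact_hwe_counts_give_zero_statistic(self):
        # p = 0.5: expected (n/4, n/2, n/4)
        res = hwe_chi_square(GenotypeCounts("x", 25, 50, 25))
        assert res.chi_square == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_study_cyp2c9_counts(self):
        res = hwe_chi_square(GenotypeCounts("cyp", 75, 25, 1))
        assert res.chi_square == pytest.approx(0.478, abs=1e-3)
        assert res.p_value == pytest.approx(0.489, abs=1e-3)
        assert res.df == 1

    def test_study_vkorc1_counts(self):
        res = hwe_chi_square(GenotypeCounts("vko", 30, 49, 22))
        assert res.p_value == pytest.approx(0.81, abs=0.01)

    def test_expected_counts_sum_to_total(self):
        res = hwe_chi_square(GenotypeCounts("x", 12, 9, 4))
        assert sum(res.expected_counts) == pytest.approx(25)

    def test_monomorphic_locus_is_flagged(self):
        res = hwe_chi_square(GenotypeCounts("x", 31, 0, 0))
        assert res.monomorphic
        assert res.chi_square == 0.0 and res.p_value == 1.0

    def test_matches_brute_force_pearson_on_small_tables(self):
        # independent oracle: explicit Pearson statistic against HWE-expected
        # multinomial proportions, all polymorphic triples with total <= 30
        def oracle(a, b, c):
            n = a + b + c
            q = (b + 2 * c) / (2 * n)
            p = 1 - q
            exp = [n * p * p, n * 2 * p * q, n * q * q]
            chi2 = sum((o - e) ** 2 / e for o, e in zip((a, b, c), exp))
            return chi2, float(stats.distributions.chi2.sf(chi2, 1))

        for a, b, c in itertools.product(range(31), repeat=3):
            n = a + b + c
            if n == 0 or n > 30:
                continue
            q = (b + 2 * c) / (2 * n)
            if q in (0.0, 1.0):
                continue
            res = hwe_chi_square(GenotypeCounts("x", a, b, c))
            chi2, p = oracle(a, b, c)
            assert res.chi_square == pytest.approx(chi2, rel=1e-12)
            assert res.p_value == pytest.approx(p, rel=1e-12)
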