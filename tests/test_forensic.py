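"""Forensic statistics: gene diversity, occurrence spectra, MP/HD/DC/FUH.

The published per-population occurrence spectra are realized exactly by
the spectrum generator, so every haplotype-level statistic is checked
against the printed values without the source genotypes.
"""

import math
from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ystrkit.errors import (
    EmptyLocusError,
    EmptyTableError,
    UndefinedDiversityError,
)
from ystrkit.forensic import (
    AlleleFrequencySet,
    OccurrenceSpectrum,
    allele_frequencies,
    discrimination_capacity,
    forensic_report,
    gene_diversity,
    haplotype_diversity,
    haplotype_spectrum,
    match_probability,
    unique_haplotype_fraction,
)
from ystrkit.haplotypes import HaplotypeTable
from ystrkit.simulate import generate_spectrum_table

HAKKA_SPECTRUM = {1: 208, 2: 18, 3: 4, 4: 1}  # n=260, k=231
SHE_SPECTRUM = {1: 65, 2: 43, 3: 6, 4: 5, 5: 1, 6: 1, 15: 1}  # n=215, k=122


def base_row(i, pop="P", dys19=14):
    return (f"S{i:02d}", pop, {"DYS19": dys19, "DYS390": 23, "DYS391": 10, "DYS385a/b": [13, 17]})


class TestAlleleFrequencies:
    def test_simple_counts(self, make_table):
        rows = [base_row(i, dys19=a) for i, a in enumerate([10, 10, 11, 12])]
        fs = allele_frequencies(make_table(rows), "DYS19")
        freqs = {str(k): v for k, v in fs.freqs.items()}
        assert freqs == {"10": Fraction(1, 2), "11": Fraction(1, 4), "12": Fraction(1, 4)}
        assert sum(fs.freqs.values()) == 1

    def test_single_sample_is_frequency_one(self, make_table):
        fs = allele_frequencies(make_table([base_row(0)]), "DYS19")
        assert list(fs.freqs.values()) == [Fraction(1)]

    def test_all_missing_raises(self, make_table):
        rows = [(f"S{i}", "P", {"DYS19": None, "DYS390": 23, "DYS391": 10, "DYS385a/b": [13, 17]}) for i in range(3)]
        with pytest.raises(EmptyLocusError):
            allele_frequencies(make_table(rows), "DYS19")

    def test_multicopy_combination_vs_values(self, make_table):
        rows = [base_row(0), base_row(1)]
        rows[1][2]["DYS385a/b"] = [13, 18]
        table = make_table(rows)
        combos = allele_frequencies(table, "DYS385a/b")
        values = allele_frequencies(table, "DYS385a/b", mode="values")
        assert combos.n_alleles == 2  # (13,17) and (13,18)
        assert values.n_alleles == 3  # 13, 17, 18

    def test_missing_excluded_per_locus_only(self, make_table):
        rows = [base_row(0, dys19=10), base_row(1, dys19=12)]
        rows[1][2]["DYS391"] = None
        table = make_table(rows)
        # sample 1 still contributes at DYS19 despite missing DYS391
        assert allele_frequencies(table, "DYS19").n == 2
        assert allele_frequencies(table, "DYS391").n == 1


class TestGeneDiversity:
    def test_monomorphic_is_zero(self, make_table):
        fs = allele_frequencies(make_table([base_row(i) for i in range(5)]), "DYS19")
        assert gene_diversity(fs) == 0.0

    def test_two_distinct_n2_is_one(self, make_table):
        fs = allele_frequencies(make_table([base_row(0, dys19=10), base_row(1, dys19=11)]), "DYS19")
        assert gene_diversity(fs) == 1.0

    def test_direct_arithmetic(self, make_table):
        # freqs {0.5, 0.25, 0.25} at n=4: (4/3)*(1-0.375)
        fs = allele_frequencies(make_table([base_row(i, dys19=a) for i, a in enumerate([10, 10, 11, 12])]), "DYS19")
        assert gene_diversity(fs) == pytest.approx(float(Fraction(4, 3) * Fraction(5, 8)), abs=1e-15)

    def test_n_below_two_raises(self, make_table):
        fs = allele_frequencies(make_table([base_row(0)]), "DYS19")
        with pytest.raises(UndefinedDiversityError):
            gene_diversity(fs)

    def test_mutating_one_modal_copy_increases_diversity(self, make_table):
        before = make_table([base_row(i, dys19=10) for i in range(4)])
        rows = [base_row(i, dys19=10) for i in range(3)] + [base_row(3, dys19=11)]
        after = make_table(rows)
        assert gene_diversity(allele_frequencies(after, "DYS19")) > gene_diversity(
            allele_frequencies(before, "DYS19")
        )


class TestSpectrum:
    def test_all_identical(self, make_table):
        s = haplotype_spectrum(make_table([base_row(i) for i in range(4)]))
        assert s.counts == {4: 1} and s.n == 4 and s.k == 1

    def test_all_distinct(self, make_table):
        s = haplotype_spectrum(make_table([base_row(i, dys19=10 + i) for i in range(3)]))
        assert s.counts == {1: 3}

    def test_no_complete_haplotypes_raises(self, make_table):
        rows = [(f"S{i}", "P", {"DYS19": None, "DYS390": 23, "DYS391": 10, "DYS385a/b": [13, 17]}) for i in range(2)]
        with pytest.raises(EmptyTableError):
            haplotype_spectrum(make_table(rows))

    def test_published_she_spectrum_realized(self):
        table = generate_spectrum_table(OccurrenceSpectrum(SHE_SPECTRUM), seed=7)
        s = haplotype_spectrum(table)
        assert s.counts == SHE_SPECTRUM and s.n == 215 and s.k == 122


class TestHaplotypeLevelStatistics:
    @pytest.mark.parametrize(
        "spectrum, mp, dc, fuh_pct, k",
        [
            (HAKKA_SPECTRUM, 4.91e-3, 0.8885, 90.04, 231),
            (SHE_SPECTRUM, 1.42e-2, 0.5674, 53.28, 122),
        ],
    )
    def test_published_forensic_parameters(self, spectrum, mp, dc, fuh_pct, k):
        s = OccurrenceSpectrum(spectrum)
        assert s.k == k
        assert float(f"{match_probability(s):.2e}") == mp
        assert round(discrimination_capacity(s), 4) == dc
        assert round(100 * unique_haplotype_fraction(s), 2) == fuh_pct

    def test_hakka_mp_exact_fraction(self):
        assert match_probability(OccurrenceSpectrum(HAKKA_SPECTRUM)) == 332 / 67600

    def test_hd_from_formula(self):
        # n/(n-1) * (1 - MP) on the published spectra; the printed table
        # values (0.9994 / 0.9939) are not consistent with these spectra
        hakka = haplotype_diversity(OccurrenceSpectrum(HAKKA_SPECTRUM))
        she = haplotype_diversity(OccurrenceSpectrum(SHE_SPECTRUM))
        assert hakka == pytest.approx(260 / 259 * (1 - 332 / 67600), abs=1e-12)
        assert she == pytest.approx(215 / 214 * (1 - 657 / 46225), abs=1e-12)
        assert round(hakka, 5) == 0.99893
        assert round(she, 5) == 0.99039

    def test_degenerate_spectra(self):
        assert haplotype_diversity(OccurrenceSpectrum({5: 1})) == 0.0
        assert haplotype_diversity(OccurrenceSpectrum({1: 2})) == 1.0
        assert match_probability(OccurrenceSpectrum({1: 7})) == pytest.approx(1 / 7)
        assert discrimination_capacity(OccurrenceSpectrum({1: 7})) == 1.0
        assert unique_haplotype_fraction(OccurrenceSpectrum({2: 3})) == 0.0
        with pytest.raises(UndefinedDiversityError):
            haplotype_diversity(OccurrenceSpectrum({1: 1}))


spectrum_st = st.dictionaries(
    st.integers(1, 12), st.integers(1, 30), min_size=1, max_size=6
)


class TestSpectrumIdentities:
    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(spectrum_st)
    def test_integer_identities(self, counts):
        """HD = n/(n-1)(1-MP); DC*n = k; FUH*k = singletons; MP in [1/n, 1]."""
        s = OccurrenceSpectrum(counts)
        mp = match_probability(s)
        assert 1 / s.n <= mp <= 1 + 1e-15
        if s.n >= 2:
            hd = haplotype_diversity(s)
            assert math.isclose(hd, s.n / (s.n - 1) * (1 - mp), rel_tol=1e-12)
            assert 0.0 <= hd <= 1.0
        assert discrimination_capacity(s) * s.n == pytest.approx(s.k, abs=1e-9)
        assert unique_haplotype_fraction(s) * s.k == pytest.approx(s.singletons, abs=1e-9)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(spectrum_st, st.integers(0, 2**31 - 1))
    def test_table_statistics_factor_through_spectrum(self, counts, seed):
        """Stats computed on a realizing table equal stats on its spectrum."""
        s = OccurrenceSpectrum(counts)
        table = generate_spectrum_table(s, seed=seed)
        assert haplotype_spectrum(table).counts == s.counts


class TestForensicReport:
    def test_monomorphic_single_population(self, make_table):
        table = make_table([base_row(i) for i in range(4)])
        rep = forensic_report(table)
        assert (rep.per_locus["gene_diversity"] == 0.0).all()
        row = rep.summary.iloc[0]
        assert row["hd"] == 0.0 and row["dc"] == pytest.approx(0.25)

    def test_row_order_invariance(self, make_table):
        rows = [base_row(i, pop="A", dys19=10 + i % 3) for i in range(6)]
        rows += [base_row(i + 6, pop="B", dys19=12 + i % 2) for i in range(4)]
        fwd = forensic_report(make_table(rows))
        rev = forensic_report(make_table(rows[::-1]))
        assert fwd.summary.equals(rev.summary)
        assert fwd.per_locus.equals(rev.per_locus)

    def test_published_summary_via_spectra(self):
        hakka = generate_spectrum_table(OccurrenceSpectrum(HAKKA_SPECTRUM), seed=1, population="Hakka")
        she = generate_spectrum_table(OccurrenceSpectrum(SHE_SPECTRUM), seed=2, population="She")
        merged = HaplotypeTable(
            hakka.panel,
            hakka.haplotypes
            + [
                type(h)(f"T{i:04d}", h.population, h.calls)
                for i, h in enumerate(she.haplotypes)
            ],
        )
        rep = forensic_report(merged)
        summary = rep.summary.set_index("population")
        assert round(summary.loc["Hakka", "dc"], 4) == 0.8885
        assert round(summary.loc["She", "dc"], 4) == 0.5674
        assert float(f"{summary.loc['Hakka', 'mp']:.2e}") == 4.91e-3
        assert float(f"{summary.loc['She', 'mp']:.2e}") == 1.42e-2
        assert summary.loc["Hakka", "k_distinct"] == 231
        assert summary.loc["She", "k_distinct"] == 122
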