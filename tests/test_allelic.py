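"""Trio phasing, winner tallies, and the exact binomial bias test."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.special import comb

from fourcstab import (AllelicCountRecord, AnalysisConfig, Pedigree,
                       Viewpoint, binomial_bias_test, phase_snps,
                       region_bias_report, select_informative, tally_winners)
from fourcstab.allelic import (SnpRecord, TrioGenotypes, read_pedigree_yaml,
                               read_trio_vcf, read_allelic_counts_tsv,
                               write_allelic_counts_tsv, write_bias_report_tsv)

PED = Pedigree(proband="kid", parents=("dad", "mom"), affected_parent="dad")


def snp(pos, kid, dad, mom, ref="A", alt="G"):
    return SnpRecord(chrom="c", pos=pos, ref=ref, alt=alt,
                     genotypes=(("kid", kid), ("dad", dad), ("mom", mom)))


class TestPhasing:
    def test_affected_parent_homozygous(self):
        trio = TrioGenotypes([snp(10, (0, 1), (0, 0), (0, 1))], PED)
        [p] = phase_snps(trio)
        assert p.expanded_base == "A" and p.normal_base == "G"
        assert "dad" in p.provenance

    def test_unaffected_parent_homozygous_elimination(self):
        # only informative parent is the unaffected one: the other allele
        # must have come from the affected parent
        trio = TrioGenotypes([snp(10, (0, 1), None, (1, 1))], PED)
        [p] = phase_snps(trio)
        assert p.expanded_base == "A" and p.normal_base == "G"
        assert "mom" in p.provenance

    def test_both_parents_heterozygous_discarded(self):
        trio = TrioGenotypes([snp(10, (0, 1), (0, 1), (0, 1))], PED)
        assert phase_snps(trio) == []

    def test_homozygous_proband_discarded(self):
        trio = TrioGenotypes([snp(10, (1, 1), (1, 1), (0, 1))], PED)
        assert phase_snps(trio) == []

    def test_mendelian_inconsistency_discarded(self, caplog):
        # het child from two identical homozygous parents is impossible
        trio = TrioGenotypes([snp(10, (0, 1), (0, 0), (0, 0))], PED)
        with caplog.at_level("WARNING"):
            assert phase_snps(trio) == []
        assert "inconsistent" in caplog.text.lower()

    def test_both_parents_missing_discarded(self):
        trio = TrioGenotypes([snp(10, (0, 1), None, None)], PED)
        assert phase_snps(trio) == []

    def test_pedigree_without_parents_rejected(self):
        with pytest.raises(ValueError, match="parent"):
            Pedigree(proband="kid", parents=(), affected_parent="dad")

    def test_pedigree_affected_not_a_parent_rejected(self):
        with pytest.raises(ValueError, match="affected"):
            Pedigree(proband="kid", parents=("mom",), affected_parent="dad")


class TestSelectInformative:
    VP = Viewpoint(name="vp", chrom="c", position=2_000_000,
                   fragment_index=0, exclusion_halfwidth=2500)

    def _phased(self, pos):
        from fourcstab import PhasedSNP
        return PhasedSNP(chrom="c", pos=pos, expanded_base="A",
                         normal_base="G", provenance="t")

    def test_window_boundary_inclusive(self, cfg):
        keep = select_informative([self._phased(2_000_000 + 999_999)],
                                  self.VP, cfg)
        assert len(keep) == 1
        kept = select_informative([self._phased(2_000_000 + 1_000_000)],
                                  self.VP, cfg)
        assert len(kept) == 1  # exactly at the boundary: |d| <= window

    def test_beyond_window_dropped(self, cfg):
        assert select_informative([self._phased(2_000_000 + 1_000_001)],
                                  self.VP, cfg) == []

    def test_exclusion_zone_dropped(self, cfg):
        assert select_informative([self._phased(2_000_000 + 100)],
                                  self.VP, cfg) == []

    def test_other_chromosome_dropped(self, cfg):
        from fourcstab import PhasedSNP
        s = PhasedSNP(chrom="other", pos=2_000_000 + 5000,
                      expanded_base="A", normal_base="G", provenance="t")
        assert select_informative([s], self.VP, cfg) == []

    def test_empty_input(self, cfg):
        assert select_informative([], self.VP, cfg) == []


class TestTally:
    def test_coverage_rule(self, cfg):
        recs = [AllelicCountRecord("c", 1, "L", 12, 3),
                AllelicCountRecord("c", 2, "L", 4, 4)]  # 8 reads: ineligible
        assert tally_winners(recs, cfg) == (1, 1, 0)

    def test_tie_excluded(self, cfg):
        recs = [AllelicCountRecord("c", 1, "L", 7, 7)]
        assert tally_winners(recs, cfg) == (0, 0, 0)

    def test_engineered_tallies(self, cfg):
        # 26 normal-majority + 15 expanded-majority samples, all covered
        recs = ([AllelicCountRecord("c", i, "L", 4, 16) for i in range(26)]
                + [AllelicCountRecord("c", 100 + i, "L", 16, 4)
                   for i in range(15)])
        n, k_exp, k_norm = tally_winners(recs, cfg)
        assert (n, k_norm, k_exp) == (41, 26, 15)


def oracle_two_sided_p(k, n, p0=0.5):
    """Exhaustive pmf summation over the minimum-likelihood rejection set."""
    probs = [comb(n, i, exact=True) * p0 ** i * (1 - p0) ** (n - i)
             for i in range(n + 1)]
    return min(1.0, sum(p for p in probs if p <= probs[k] * (1 + 1e-9)))


class TestBinomialTest:
    @pytest.mark.parametrize("k,n,printed", [
        (4, 5, 0.38), (26, 41, 0.12), (5, 12, 0.77), (20, 43, 0.76)])
    def test_published_winner_tallies(self, k, n, printed):
        # agreement at the printed 2-decimal precision (0.375 prints as 0.38)
        assert binomial_bias_test(k, n, 0.5) == pytest.approx(printed,
                                                              abs=0.0051)

    def test_matches_exhaustive_oracle_all_small_n(self):
        for n in range(1, 21):
            for k in range(n + 1):
                assert binomial_bias_test(k, n, 0.5) == pytest.approx(
                    oracle_two_sided_p(k, n), abs=1e-10)

    def test_matches_scipy_binomtest(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(1, 200))
            k = int(rng.integers(0, n + 1))
            assert binomial_bias_test(k, n, 0.5) == pytest.approx(
                stats.binomtest(k, n, 0.5).pvalue, rel=1e-9)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(min_value=1, max_value=50))
    def test_symmetry_at_half(self, n):
        for k in range(n + 1):
            assert binomial_bias_test(k, n, 0.5) == pytest.approx(
                binomial_bias_test(n - k, n, 0.5), abs=1e-12)

    def test_balanced_split_gives_one(self):
        assert binomial_bias_test(20, 40, 0.5) == pytest.approx(1.0)

    def test_zero_samples_rejected(self):
        with pytest.raises(ValueError):
            binomial_bias_test(0, 0)


class TestRegionReport:
    def test_rows_with_tallies_and_p(self, cfg):
        recs = ([AllelicCountRecord("c", i, "L", 16, 4) for i in range(4)]
                + [AllelicCountRecord("c", 50, "L", 4, 16)])
        [row] = region_bias_report({("DM1-A", "ACTA1"): recs}, cfg)
        assert (row.n_samples, row.n_normal_wins, row.n_expanded_wins) == (5, 1, 4)
        assert row.p_value == pytest.approx(0.38, abs=0.0051)

    def test_zero_eligible_gives_missing_p(self, cfg):
        recs = [AllelicCountRecord("c", 1, "L", 3, 2)]
        [row] = region_bias_report({("HD-B", "HTT"): recs}, cfg)
        assert row.n_samples == 0 and row.p_value is None

    def test_report_round_trip(self, cfg, tmp_path):
        recs = [AllelicCountRecord("c", i, "L", 16, 4) for i in range(3)]
        rows = region_bias_report({("s", "r"): recs}, cfg)
        path = tmp_path / "report.tsv"
        write_bias_report_tsv(rows, path)
        text = path.read_text()
        assert "n_expanded_wins" in text and "\ts\t" not in text.split("\n")[0]


class TestIO:
    def test_vcf_and_pedigree_round_trip(self, tmp_path):
        from fourcstab.simulate import write_trio_vcf
        trio = TrioGenotypes(
            [snp(10, (0, 1), (0, 0), (0, 1)),
             snp(20, (0, 1), None, (1, 1), ref="C", alt="T")], PED)
        vcf = tmp_path / "trio.vcf"
        write_trio_vcf(trio, vcf)
        ped_yaml = tmp_path / "ped.yaml"
        ped_yaml.write_text(
            "proband: kid\nparents: [dad, mom]\naffected_parent: dad\n")
        ped = read_pedigree_yaml(ped_yaml)
        back = read_trio_vcf(vcf, ped)
        assert back.pedigree == PED
        assert [(s.pos, s.ref, s.alt, s.genotypes) for s in back.snps] == \
            [(s.pos, s.ref, s.alt, s.genotypes) for s in trio.snps]

    def test_non_biallelic_records_skipped(self, tmp_path):
        vcf = tmp_path / "bad.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n##contig=<ID=c>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="G">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tkid\tdad\tmom\n"
            "c\t5\t.\tA\tG,T\t.\tPASS\t.\tGT\t0/1\t0/0\t0/1\n"
            "c\t9\t.\tAT\tG\t.\tPASS\t.\tGT\t0/1\t0/0\t0/1\n"
            "c\t12\t.\tA\tG\t.\tPASS\t.\tGT\t0/1\t0/0\t0/1\n")
        trio = read_trio_vcf(vcf, PED)
        assert [s.pos for s in trio.snps] == [11]  # 0-based

    def test_allelic_counts_round_trip(self, tmp_path):
        recs = [AllelicCountRecord("c", 5, "L1", 12, 3),
                AllelicCountRecord("c", 9, "L2", 0, 20)]
        path = tmp_path / "ac.tsv"
        write_allelic_counts_tsv(recs, path)
        assert read_allelic_counts_tsv(path) == recs
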