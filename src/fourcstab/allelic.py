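"""Allele-specific 4C contact analysis via trio-phased SNPs.

In dominantly inherited repeat-expansion disorders the proband is
heterozygous for the expanded allele, so any contact change on the expanded
chromosome could be masked by the normal homolog.  To resolve the two
homologs, biallelic SNPs near the viewpoint are phased with parental
genotypes: a proband-heterozygous SNP is informative when at least one
genotyped parent is homozygous, which pins down which allele was inherited
from which parent.  The chromosome inherited from the affected
(expansion-transmitting) parent carries the expansion.

4C read coverage is then compared between the two alleles: each
(SNP, library) pair with at least ``min_snp_cov`` reads is a sample, and the
allele with more reads "wins" (ties are excluded).  Under the null of no
allelic bias the expanded allele wins with probability 0.5, tested with a
two-sided exact binomial test (minimum-likelihood rule).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam
import yaml
from scipy import stats

from .config import AnalysisConfig
from .fragment_map import Viewpoint

logger = logging.getLogger(__name__)

Genotype = tuple[int, int] | None  # allele indices (0=ref, 1=alt); None=missing


@dataclass(frozen=True)
class SnpRecord:
    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str
    genotypes: tuple[tuple[str, Genotype], ...]  # (individual id, GT)

    def genotype_of(self, individual: str) -> Genotype:
        for ind, gt in self.genotypes:
            if ind == individual:
                return gt
        return None


@dataclass(frozen=True)
class Pedigree:
    proband: str
    parents: tuple[str, ...]
    affected_parent: str

    def __post_init__(self) -> None:
        if not self.parents:
            raise ValueError("pedigree lists no parents; phasing needs at "
                             "least one genotyped parent")
        if self.affected_parent not in self.parents:
            raise ValueError(
                f"affected parent {self.affected_parent!r} is not among the "
                f"pedigree parents {self.parents}")


@dataclass
class TrioGenotypes:
    snps: list[SnpRecord]
    pedigree: Pedigree


@dataclass(frozen=True)
class PhasedSNP:
    """A proband-het SNP with alleles assigned to the two homologs."""

    chrom: str
    pos: int
    expanded_base: str
    normal_base: str
    provenance: str  # which parental homozygous genotype resolved the phase

    def __post_init__(self) -> None:
        if self.expanded_base == self.normal_base:
            raise ValueError("expanded and normal base must differ")


@dataclass(frozen=True)
class AllelicCountRecord:
    snp_chrom: str
    snp_pos: int
    library_id: str
    reads_expanded: int
    reads_normal: int

    def __post_init__(self) -> None:
        if self.reads_expanded < 0 or self.reads_normal < 0:
            raise ValueError("allelic read counts must be non-negative")

    @property
    def total(self) -> int:
        return self.reads_expanded + self.reads_normal


@dataclass
class BiasTestResult:
    """One Table-1-style row: winner tallies and exact binomial P."""

    cell_line: str
    region: str
    n_samples: int
    n_normal_wins: int
    n_expanded_wins: int
    p_value: float | None
    n_ties_excluded: int = 0


def _is_hom(gt: Genotype) -> bool:
    return gt is not None and gt[0] == gt[1]


def _is_het(gt: Genotype) -> bool:
    return gt is not None and gt[0] != gt[1]


def phase_snps(trio: TrioGenotypes) -> list[PhasedSNP]:
    """Phase proband-heterozygous SNPs using parental homozygosity.

    A SNP is retained when the proband is heterozygous and at least one
    genotyped parent is homozygous.  The allele matching a homozygous
    parent is assigned to the chromosome inherited from that parent; the
    chromosome from the affected parent is the expanded one.  SNPs with
    both parents heterozygous, a homozygous proband, or Mendelian
    inconsistencies are discarded (inconsistencies logged).
    """
    ped = trio.pedigree
    affected = ped.affected_parent
    unaffected = [p for p in ped.parents if p != affected]
    phased: list[PhasedSNP] = []
    n_inconsistent = 0
    for snp in trio.snps:
        pro = snp.genotype_of(ped.proband)
        if not _is_het(pro):
            continue
        bases = {0: snp.ref, 1: snp.alt}
        gt_aff = snp.genotype_of(affected)
        gt_un = snp.genotype_of(unaffected[0]) if unaffected else None

        if _is_hom(gt_aff) and _is_hom(gt_un) and gt_aff[0] == gt_un[0]:
            # het proband cannot arise from two identical homozygous parents
            n_inconsistent += 1
            logger.info("Mendelian inconsistency at %s:%d", snp.chrom, snp.pos)
            continue
        if _is_hom(gt_aff):
            exp_allele = gt_aff[0]
            prov = f"{affected}:hom"
        elif _is_hom(gt_un):
            # the allele matching the unaffected parent came from them;
            # the other proband allele came from the affected parent
            exp_allele = 1 - gt_un[0]
            prov = f"{unaffected[0]}:hom-elimination"
        else:
            continue  # both het or both missing: ambiguous
        phased.append(PhasedSNP(chrom=snp.chrom, pos=snp.pos,
                                expanded_base=bases[exp_allele],
                                normal_base=bases[1 - exp_allele],
                                provenance=prov))
    if n_inconsistent:
        logger.warning("discarded %d Mendelian-inconsistent SNPs", n_inconsistent)
    return phased


def select_informative(phased: Sequence[PhasedSNP], viewpoint: Viewpoint,
                       cfg: AnalysisConfig | None = None) -> list[PhasedSNP]:
    """Keep SNPs within ``snp_window`` of the viewpoint (inclusive) and
    outside its exclusion zone."""
    cfg = cfg or AnalysisConfig()
    lo, hi = viewpoint.exclusion_zone
    out = []
    for s in phased:
        if s.chrom != viewpoint.chrom:
            continue
        if abs(s.pos - viewpoint.position) > cfg.snp_window:
            continue
        if lo <= s.pos <= hi:
            continue
        out.append(s)
    return out


def tally_winners(records: Iterable[AllelicCountRecord],
                  cfg: AnalysisConfig | None = None,
                  ) -> tuple[int, int, int]:
    """Count allele-winner samples: (n_samples, n_expanded_wins, n_normal_wins).

    A sample is one (SNP, library) record; it is eligible when its total
    coverage reaches ``min_snp_cov``.  Ties are excluded from both tallies
    (and from n_samples) and logged.
    """
    cfg = cfg or AnalysisConfig()
    n_exp = n_norm = n_ties = 0
    for rec in records:
        if rec.total < cfg.min_snp_cov:
            continue
        if rec.reads_expanded > rec.reads_normal:
            n_exp += 1
        elif rec.reads_normal > rec.reads_expanded:
            n_norm += 1
        else:
            n_ties += 1
    if n_ties:
        logger.info("excluded %d tied samples from the allelic tally", n_ties)
    return n_exp + n_norm, n_exp, n_norm


def binomial_bias_test(k_expanded: int, n: int, p0: float = 0.5) -> float:
    """Two-sided exact binomial P for k expanded wins out of n samples.

    Minimum-likelihood rule: the P-value sums every Binomial(n, p0) point
    probability not exceeding that of the observed k.  At p0 = 0.5 this
    equals 2 * min(P(X <= k), P(X >= k)), capped at 1.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k_expanded <= n:
        raise ValueError(f"k_expanded={k_expanded} outside [0, {n}]")
    pmf = stats.binom.pmf(np.arange(n + 1), n, p0)
    # relative tolerance absorbs float noise at the observed probability
    p = float(pmf[pmf <= pmf[k_expanded] * (1 + 1e-7)].sum())
    return min(p, 1.0)


def region_bias_report(regions: dict[tuple[str, str],
                                     Sequence[AllelicCountRecord]],
                       cfg: AnalysisConfig | None = None,
                       ) -> list[BiasTestResult]:
    """One bias-test row per (cell line, region): tallies plus exact P.

    Regions with zero eligible samples are reported with n=0 and a missing
    P-value.
    """
    cfg = cfg or AnalysisConfig()
    results = []
    for (cell_line, region), records in regions.items():
        records = list(records)
        eligible = [r for r in records if r.total >= cfg.min_snp_cov]
        n_ties = sum(1 for r in eligible if r.reads_expanded == r.reads_normal)
        n, k_exp, k_norm = tally_winners(records, cfg)
        p = binomial_bias_test(k_exp, n, cfg.null_prop) if n > 0 else None
        results.append(BiasTestResult(cell_line=cell_line, region=region,
                                      n_samples=n, n_normal_wins=k_norm,
                                      n_expanded_wins=k_exp, p_value=p,
                                      n_ties_excluded=n_ties))
    return results


def allelic_counts_from_tagged_reads(
        tagged: Iterable[tuple[str, int, str, str]],
        ) -> list[AllelicCountRecord]:
    """Aggregate haplotype-tagged reads (chrom, pos, library, tag) into
    per-(SNP, library) allelic count records; tag is 'expanded' or 'normal'."""
    acc: dict[tuple[str, int, str], list[int]] = {}
    for chrom, pos, lib, tag in tagged:
        key = (chrom, pos, lib)
        acc.setdefault(key, [0, 0])
        if tag == "expanded":
            acc[key][0] += 1
        elif tag == "normal":
            acc[key][1] += 1
        else:
            raise ValueError(f"unknown haplotype tag {tag!r}")
    return [AllelicCountRecord(c, p, lib, e, n)
            for (c, p, lib), (e, n) in sorted(acc.items())]


# ---------------------------------------------------------------------------
# I/O

def read_trio_vcf(vcf_path: str | Path, pedigree: Pedigree) -> TrioGenotypes:
    """Read biallelic SNPs (GT field) from a VCF 4.x file.

    Multi-allelic records and records with symbolic or multi-base alleles
    are skipped with a warning tally.
    """
    snps = []
    n_skipped = 0
    with pysam.VariantFile(str(vcf_path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            if (rec.alts is None or len(rec.alts) != 1
                    or len(rec.ref) != 1 or len(rec.alts[0]) != 1
                    or rec.ref not in "ACGT" or rec.alts[0] not in "ACGT"):
                n_skipped += 1
                continue
            gts = []
            for s in samples:
                gt = rec.samples[s].get("GT")
                if gt is None or None in gt:
                    gts.append((s, None))
                else:
                    gts.append((s, (int(gt[0]), int(gt[1]))))
            snps.append(SnpRecord(chrom=rec.chrom, pos=rec.pos - 1,
                                  ref=rec.ref, alt=rec.alts[0],
                                  genotypes=tuple(gts)))
    if n_skipped:
        logger.warning("skipped %d non-biallelic-SNP VCF records", n_skipped)
    return TrioGenotypes(snps=snps, pedigree=pedigree)


def read_pedigree_yaml(path: str | Path) -> Pedigree:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    return Pedigree(proband=d["proband"], parents=tuple(d["parents"]),
                    affected_parent=d["affected_parent"])


def read_allelic_counts_tsv(path: str | Path) -> list[AllelicCountRecord]:
    df = pd.read_csv(path, sep="\t")
    return [AllelicCountRecord(r.chrom, int(r.pos), str(r.library_id),
                               int(r.reads_expanded), int(r.reads_normal))
            for r in df.itertuples()]


def write_allelic_counts_tsv(records: Sequence[AllelicCountRecord],
                             path: str | Path) -> None:
    pd.DataFrame(
        {"chrom": [r.snp_chrom for r in records],
         "pos": [r.snp_pos for r in records],
         "library_id": [r.library_id for r in records],
         "reads_expanded": [r.reads_expanded for r in records],
         "reads_normal": [r.reads_normal for r in records]},
    ).to_csv(path, sep="\t", index=False)


def write_bias_report_tsv(results: Sequence[BiasTestResult],
                          path: str | Path) -> None:
    pd.DataFrame(
        {"cell_line": [r.cell_line for r in results],
         "region": [r.region for r in results],
         "n_samples": [r.n_samples for r in results],
         "n_normal_wins": [r.n_normal_wins for r in results],
         "n_expanded_wins": [r.n_expanded_wins for r in results],
         "p_value": [r.p_value for r in results]},
    ).to_csv(path, sep="\t", index=False)
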