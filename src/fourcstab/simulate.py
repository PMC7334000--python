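"""Synthetic 4C-seq data with the statistical structure the analysis assumes.

The generator emulates, at desk scale, the data regime of a patient-trio 4C
experiment: an i.i.d. random chromosome digested in silico; contact counts
decaying as a power law of distance from the viewpoint with
negative-binomial replicate noise and optional spiked high-interaction
regions; a parent-child trio in which exactly one parental chromosome
carries the expansion label; and per-SNP allelic read coverage with a
tunable bias toward the expanded homolog.  Every draw is taken from a
seeded numpy Generator, so a fixed seed reproduces outputs exactly.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .allelic import AllelicCountRecord, Pedigree, SnpRecord, TrioGenotypes
from .counts import CountMatrix, LibraryInfo, ReadRecord
from .fragment_map import (Fragment, GenomeSeq, Viewpoint,
                           excluded_fragment_indices)

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Study conditions for the synthetic 4C experiment.

    Defaults mirror a typical single-viewpoint patient-LCL 4C library:
    ~1 Mb analysis window, ~1 million usable reads per library, contact
    frequency proportional to 1/distance, mild negative-binomial
    overdispersion across replicates, three replicates per condition, and
    ~30x allelic coverage per SNP site.
    """

    seed: int = 0
    chrom: str = "chrSim"
    chrom_length: int = 1_000_000
    primary_motif: str = "GATC"
    secondary_motif: str = "CTAG"
    viewpoint_pos: int = 500_000
    decay_exponent: float = 1.0  # contact ~ distance^-alpha
    depth: int = 1_000_000  # reads per library
    nb_dispersion: float = 0.05
    n_replicates: int = 3
    spike_regions: list[tuple[int, int, float]] = field(default_factory=list)
    n_snps: int = 50
    snp_het_rate: float = 0.5
    allelic_bias: float = 0.5  # P(read comes from the expanded homolog)
    snp_coverage_mean: float = 30.0
    snp_coverage_dispersion: float = 0.1

    def __post_init__(self) -> None:
        if self.decay_exponent <= 0:
            raise ValueError("decay_exponent must be positive")
        if not 0 < self.allelic_bias < 1:
            raise ValueError("allelic_bias must lie in (0, 1)")


def _rng(cfg: SimConfig, stream: str) -> np.random.Generator:
    """Independent, named, deterministic substream of the config seed."""
    return np.random.default_rng([cfg.seed, zlib.adler32(stream.encode())])


def simulate_genome(cfg: SimConfig) -> GenomeSeq:
    """I.i.d. uniform ACGT sequence; expected GATC spacing is 4^4 = 256 bp,
    which gives realistic 4C fragment sizes."""
    if cfg.chrom_length < 10_000:
        raise ValueError("chrom_length must be at least 10 kb")
    rng = _rng(cfg, "genome")
    seq = "".join(_BASES[rng.integers(0, 4, size=cfg.chrom_length)])
    return GenomeSeq(chrom=cfg.chrom, seq=seq)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray,
             dispersion: float) -> np.ndarray:
    """NB(mean, dispersion) with Var = mean + dispersion * mean^2."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + np.maximum(mean, 1e-12))
    out = rng.negative_binomial(r, p)
    return np.where(mean > 0, out, 0)


def simulate_4c_counts(fragments: Sequence[Fragment], viewpoint: Viewpoint,
                       cfg: SimConfig, condition: str = "cond",
                       ) -> tuple[CountMatrix, pd.DataFrame]:
    """Draw a replicate count matrix for one condition, plus a truth table.

    Expected count per fragment is proportional to (1 + distance)^-alpha
    (distance of the fragment midpoint from the viewpoint), scaled so the
    expectations sum to ``depth``; fragments in spike regions have their
    expectation multiplied by the region's fold.  Each replicate is an
    independent NB draw around the expectation.  The truth table lists the
    spiked fragment indices with their folds.
    """
    rng = _rng(cfg, f"counts:{condition}")
    mids = np.array([f.midpoint for f in fragments])
    idx = np.array([f.index for f in fragments])
    dist = np.abs(mids - viewpoint.position)
    expected = (1.0 + dist) ** (-cfg.decay_exponent)
    excluded = excluded_fragment_indices(list(fragments), viewpoint)
    expected[np.isin(idx, list(excluded))] = 0.0

    fold = np.ones_like(expected)
    for start, end, f in cfg.spike_regions:
        in_region = (mids >= start) & (mids < end)
        fold[in_region] *= f
    expected = expected * fold
    expected *= cfg.depth / expected.sum()

    libs = {}
    cols = {}
    for rep in range(1, cfg.n_replicates + 1):
        lib = f"{condition}_rep{rep}"
        cols[lib] = _nb_draw(rng, expected, cfg.nb_dispersion)
        libs[lib] = LibraryInfo(condition=condition, replicate=rep)
    counts = pd.DataFrame(cols, index=pd.Index(idx, name="fragment"), dtype=int)
    truth = pd.DataFrame({"fragment": idx[fold > 1], "fold": fold[fold > 1]})
    cm = CountMatrix(counts=counts, libraries=libs, fragments=list(fragments))
    return cm, truth


def reads_from_counts(cm: CountMatrix, cfg: SimConfig,
                      library_id: str) -> list[ReadRecord]:
    """Expand one library's counts into read records at uniform positions
    within each fragment (to exercise read-to-fragment assignment)."""
    rng = _rng(cfg, f"reads:{library_id}")
    by_index = {f.index: f for f in cm.fragments}
    reads = []
    for idx, n in cm.counts[library_id].items():
        f = by_index[idx]
        for pos in rng.integers(f.start, f.end, size=int(n)):
            strand = "+" if rng.random() < 0.5 else "-"
            reads.append(ReadRecord(f.chrom, int(pos), strand, library_id))
    return reads


def simulate_trio(cfg: SimConfig, viewpoint: Viewpoint,
                  ) -> tuple[TrioGenotypes, dict[int, str]]:
    """Simulate trio genotypes around the viewpoint plus the phase truth.

    Each parent is heterozygous at a SNP with probability ``snp_het_rate``
    (otherwise homozygous ref or alt with equal odds).  The proband
    inherits one uniformly chosen haplotype from each parent; the
    chromosome inherited from the affected parent is the expanded one.
    The truth map stores, for every SNP, the base the expanded chromosome
    carries (whether or not phasing can recover it).
    """
    if cfg.n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    rng = _rng(cfg, "trio")
    lo = max(0, viewpoint.position - 1_000_000)
    hi = min(cfg.chrom_length, viewpoint.position + 1_000_000)
    positions = np.sort(rng.choice(np.arange(lo, hi), size=cfg.n_snps,
                                   replace=False))
    ped = Pedigree(proband="proband", parents=("father", "mother"),
                   affected_parent="father")
    snps = []
    truth: dict[int, str] = {}
    for pos in positions:
        ref, alt = rng.choice(4, size=2, replace=False)
        bases = {0: str(_BASES[ref]), 1: str(_BASES[alt])}
        haplos = {}
        for parent in ped.parents:
            if rng.random() < cfg.snp_het_rate:
                haplos[parent] = [0, 1]
            else:
                a = int(rng.random() < 0.5)
                haplos[parent] = [a, a]
        transmitted = {p: haplos[p][int(rng.random() < 0.5)]
                       for p in ped.parents}
        pro_gt = tuple(sorted((transmitted["father"], transmitted["mother"])))
        truth[int(pos)] = bases[transmitted[ped.affected_parent]]
        gts = (("proband", pro_gt),
               ("father", tuple(sorted(haplos["father"]))),
               ("mother", tuple(sorted(haplos["mother"]))))
        snps.append(SnpRecord(chrom=cfg.chrom, pos=int(pos),
                              ref=bases[0], alt=bases[1], genotypes=gts))
    return TrioGenotypes(snps=snps, pedigree=ped), truth


def simulate_allelic_counts(snp_positions: Sequence[int], cfg: SimConfig,
                            libraries: Sequence[str] | None = None,
                            ) -> list[AllelicCountRecord]:
    """Per-(SNP, library) allelic coverage with the configured bias.

    Total coverage is NB(snp_coverage_mean, snp_coverage_dispersion); reads
    from the expanded homolog are Binomial(total, allelic_bias).
    """
    rng = _rng(cfg, "allelic")
    if libraries is None:
        libraries = [f"lib{r}" for r in range(1, cfg.n_replicates + 1)]
    records = []
    for pos in snp_positions:
        for lib in libraries:
            total = int(_nb_draw(rng, np.array([cfg.snp_coverage_mean]),
                                 cfg.snp_coverage_dispersion)[0])
            k = int(rng.binomial(total, cfg.allelic_bias)) if total else 0
            records.append(AllelicCountRecord(cfg.chrom, int(pos), lib,
                                              k, total - k))
    return records


# ---------------------------------------------------------------------------
# File output (same formats the pipeline reads)

def write_fasta(genome: GenomeSeq, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{genome.chrom}\n")
        for i in range(0, len(genome.seq), 80):
            fh.write(genome.seq[i:i + 80] + "\n")


def write_reads_tsv(reads: Sequence[ReadRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"{r.chrom}\t{r.pos5}\t{r.library_id}\n")


def write_trio_vcf(trio: TrioGenotypes, path: str | Path) -> None:
    """Minimal VCF 4.2 with GT-only genotype columns."""
    samples = [ind for ind, _ in trio.snps[0].genotypes] if trio.snps else \
        [trio.pedigree.proband, *trio.pedigree.parents]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        chroms = sorted({s.chrom for s in trio.snps})
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for s in trio.snps:
            gt_strs = []
            for _, gt in s.genotypes:
                gt_strs.append("./." if gt is None else f"{gt[0]}/{gt[1]}")
            fh.write(f"{s.chrom}\t{s.pos + 1}\t.\t{s.ref}\t{s.alt}\t.\tPASS\t."
                     f"\tGT\t" + "\t".join(gt_strs) + "\n")


def write_truth_tsv(truth: dict[int, str], path: str | Path) -> None:
    pd.DataFrame({"pos": list(truth), "expanded_base": list(truth.values())}
                 ).to_csv(path, sep="\t", index=False)
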