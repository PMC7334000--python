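"""Read-to-fragment assignment, viewpoint exclusion, and replicate QC.

Aligned 4C reads (represented by their 5' position) are assigned to the
restriction fragment containing that position.  Reads falling in fragments
that overlap the viewpoint exclusion zone (+-2.5 kb by default) are dropped:
they are dominated by self-ligation and undigested products, not genuine
contacts.  The result is a dense fragment x library count matrix with
explicit zeros, the unit of every downstream statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig
from .fragment_map import Fragment, Viewpoint, excluded_fragment_indices

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReadRecord:
    """One aligned 4C read: chromosome, 5' position, strand, library."""

    chrom: str
    pos5: int
    strand: str = "+"
    library_id: str = "lib1"

    def __post_init__(self) -> None:
        if self.pos5 < 0:
            raise ValueError("pos5 must be >= 0")


@dataclass
class LibraryInfo:
    condition: str
    replicate: int


@dataclass
class CountMatrix:
    """Dense per-fragment read counts per library.

    ``counts`` is a DataFrame indexed by fragment index with one integer
    column per library; every fragment has an explicit row (zeros included).
    ``dropped_exclusion`` / ``dropped_unmapped`` tally reads removed by the
    viewpoint exclusion zone or aligned to chromosomes absent from the map,
    so total input reads are always reconstructible.
    """

    counts: pd.DataFrame
    libraries: dict[str, LibraryInfo]
    fragments: list[Fragment]
    dropped_exclusion: int = 0
    dropped_unmapped: int = 0

    @property
    def library_ids(self) -> list[str]:
        return list(self.counts.columns)

    def libraries_for(self, condition: str) -> list[str]:
        return [lib for lib, info in self.libraries.items()
                if info.condition == condition]

    def total(self, library_id: str) -> int:
        return int(self.counts[library_id].sum())


def count_reads(reads: Iterable[ReadRecord], fragments: Sequence[Fragment],
                viewpoint: Viewpoint,
                libraries: dict[str, LibraryInfo] | None = None) -> CountMatrix:
    """Assign each read to the fragment containing its 5' position.

    Reads in fragments overlapping the viewpoint exclusion zone are dropped
    and tallied; reads on chromosomes absent from the map are skipped with a
    warning.  Strand is ignored: the counting unit is the fragment.
    """
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {f.chrom for f in fragments}:
        frs = [f for f in fragments if f.chrom == chrom]
        starts = np.array([f.start for f in frs])
        idx = np.array([f.index for f in frs])
        by_chrom[chrom] = (starts, idx)
    chrom_end: dict[str, int] = {}
    for f in fragments:
        chrom_end[f.chrom] = max(chrom_end.get(f.chrom, 0), f.end)
    excluded = excluded_fragment_indices(list(fragments), viewpoint)

    frag_index = pd.Index([f.index for f in fragments], name="fragment")
    reads = list(reads)
    lib_ids = sorted({r.library_id for r in reads})
    if libraries is not None:
        lib_ids = sorted(set(lib_ids) | set(libraries))
    counts = pd.DataFrame(0, index=frag_index, columns=lib_ids, dtype=int)

    dropped_excl = 0
    dropped_unmapped = 0
    for r in reads:
        if r.chrom not in by_chrom:
            dropped_unmapped += 1
            continue
        starts, idx = by_chrom[r.chrom]
        if r.pos5 >= chrom_end[r.chrom]:
            dropped_unmapped += 1
            continue
        i = int(np.searchsorted(starts, r.pos5, side="right") - 1)
        frag = idx[i]
        if frag in excluded:
            dropped_excl += 1
            continue
        counts.at[frag, r.library_id] += 1
    if dropped_unmapped:
        logger.warning("skipped %d reads outside the fragment map", dropped_unmapped)
    if dropped_excl:
        logger.info("dropped %d reads in the viewpoint exclusion zone", dropped_excl)

    if libraries is None:
        libraries = {lib: LibraryInfo(condition="default", replicate=i + 1)
                     for i, lib in enumerate(lib_ids)}
    return CountMatrix(counts=counts, libraries=libraries,
                       fragments=list(fragments),
                       dropped_exclusion=dropped_excl,
                       dropped_unmapped=dropped_unmapped)


def filter_min_count(cm: CountMatrix, cfg: AnalysisConfig | None = None,
                     condition: str | None = None) -> set[int]:
    """Candidate fragments: mean count across a condition's libraries >= min_count.

    The threshold is inclusive.  Only the statistical calling stages use this
    set; display profiles keep every fragment.
    """
    cfg = cfg or AnalysisConfig()
    if condition is None:
        cols = cm.library_ids
    else:
        cols = cm.libraries_for(condition)
    if not cols:
        return set()
    means = cm.counts[cols].mean(axis=1)
    return set(means.index[means >= cfg.min_count])


def replicate_correlation(cm: CountMatrix,
                          cfg: AnalysisConfig | None = None) -> pd.DataFrame:
    """Pairwise replicate QC correlations on log-transformed counts.

    For each pair of libraries in the same condition, Pearson and Spearman
    correlations of log1p(count) over fragments with >= min_count reads in
    both members.  Pairs with fewer than two qualifying fragments are
    reported with missing correlations.
    """
    cfg = cfg or AnalysisConfig()
    rows = []
    libs = cm.library_ids
    for i, a in enumerate(libs):
        for b in libs[i + 1:]:
            if cm.libraries[a].condition != cm.libraries[b].condition:
                continue
            mask = (cm.counts[a] >= cfg.min_count) & (cm.counts[b] >= cfg.min_count)
            n = int(mask.sum())
            if n < 2:
                pear = spear = np.nan
            else:
                x = np.log1p(cm.counts.loc[mask, a].to_numpy(float))
                y = np.log1p(cm.counts.loc[mask, b].to_numpy(float))
                pear = float(stats.pearsonr(x, y).statistic)
                spear = float(stats.spearmanr(x, y).statistic)
            rows.append({"library_a": a, "library_b": b,
                         "condition": cm.libraries[a].condition,
                         "n_fragments": n, "pearson": pear, "spearman": spear})
    return pd.DataFrame(rows, columns=["library_a", "library_b", "condition",
                                       "n_fragments", "pearson", "spearman"])


# ---------------------------------------------------------------------------
# I/O

def read_reads_tsv(path: str | Path) -> list[ReadRecord]:
    """Read aligned positions from 3-column TSV (chrom, pos5, library_id)
    or BED6 (chrom, start, end, library_id, score, strand)."""
    reads = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 6:  # BED6
                chrom, start, _end, name, _score, strand = parts[:6]
                reads.append(ReadRecord(chrom, int(start), strand, name))
            else:
                chrom, pos5, lib = parts[:3]
                reads.append(ReadRecord(chrom, int(pos5), "+", lib))
    return reads


def write_counts_tsv(cm: CountMatrix, path: str | Path) -> None:
    frag_meta = pd.DataFrame(
        {"chrom": [f.chrom for f in cm.fragments],
         "start": [f.start for f in cm.fragments],
         "end": [f.end for f in cm.fragments]},
        index=pd.Index([f.index for f in cm.fragments], name="fragment"))
    out = frag_meta.join(cm.counts)
    out.to_csv(path, sep="\t")


def read_counts_tsv(path: str | Path,
                    libraries: dict[str, LibraryInfo] | None = None) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col="fragment")
    meta_cols = ["chrom", "start", "end"]
    fragments = [Fragment(row.chrom, int(row.start), int(row.end), int(i))
                 for i, row in df[meta_cols].iterrows()]
    counts = df.drop(columns=meta_cols).astype(int)
    if libraries is None:
        libraries = {lib: LibraryInfo(condition="default", replicate=i + 1)
                     for i, lib in enumerate(counts.columns)}
    return CountMatrix(counts=counts, libraries=libraries, fragments=fragments)
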