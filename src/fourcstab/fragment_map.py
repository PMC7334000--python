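"""In-silico restriction digestion and viewpoint placement.

4C-seq libraries are built by a double restriction digest: a frequent-cutter
primary enzyme (DpnII, site GATC) defines the counting units (fragments), and
a secondary enzyme (BfaI, site CTAG) trims the circularised ligation products.
Fragment ends that lack a secondary site between the primary cut and the
fragment midpoint are "blind": they are captured inefficiently.  This module
builds the ordered fragment map of a chromosome by scanning for the primary
motif, flags blind sides from the secondary motif, and locates viewpoints
(the anchor loci whose contacts a 4C experiment reports) together with their
exclusion zones.

Coordinates are 0-based, half-open (BED convention) throughout.  A cut is
placed at the start index of each motif occurrence; because every downstream
quantity is fragment-relative, any single consistent convention is
equivalent.  ``N`` bases never match a motif.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

DEFAULT_PRIMARY_MOTIF = "GATC"  # DpnII
DEFAULT_SECONDARY_MOTIF = "CTAG"  # BfaI
DEFAULT_EXCLUSION_HALFWIDTH = 2500

_VALID_SEQ = re.compile(r"^[ACGTN]+$")
_VALID_MOTIF = re.compile(r"^[ACGT]+$")


@dataclass(frozen=True)
class GenomeSeq:
    """A chromosome sequence restricted to the {A,C,G,T,N} alphabet."""

    chrom: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"empty sequence for chromosome {self.chrom!r}")
        seq = self.seq.upper()
        if not _VALID_SEQ.match(seq):
            bad = sorted(set(seq) - set("ACGTN"))
            raise ValueError(f"invalid characters in {self.chrom!r}: {bad}")
        object.__setattr__(self, "seq", seq)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class Fragment:
    """A restriction fragment: half-open interval between consecutive cuts."""

    chrom: str
    start: int
    end: int
    index: int
    blind_left: bool = False
    blind_right: bool = False

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"degenerate fragment [{self.start}, {self.end})")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class Viewpoint:
    """A 4C anchor locus: its containing fragment plus the exclusion zone.

    Fragments overlapping ``position ± exclusion_halfwidth`` are dominated by
    self-ligation and re-ligation products and are excluded from counting.
    """

    name: str
    chrom: str
    position: int
    fragment_index: int
    exclusion_halfwidth: int = DEFAULT_EXCLUSION_HALFWIDTH

    @property
    def exclusion_zone(self) -> tuple[int, int]:
        """Exclusion interval, clipped at the chromosome start."""
        return (max(0, self.position - self.exclusion_halfwidth),
                self.position + self.exclusion_halfwidth)


def _find_motif(seq: str, motif: str) -> list[int]:
    """Start indices of every (possibly overlapping) motif occurrence."""
    positions = []
    start = 0
    while True:
        i = seq.find(motif, start)
        if i == -1:
            return positions
        positions.append(i)
        start = i + 1


def digest(genome: GenomeSeq,
           primary_motif: str = DEFAULT_PRIMARY_MOTIF,
           secondary_motif: str = DEFAULT_SECONDARY_MOTIF) -> list[Fragment]:
    """Double-digest a chromosome; return ordered fragments tiling it.

    Cut positions are the start index of every primary-motif occurrence.
    Fragments are the intervals between consecutive cuts plus the two
    terminal intervals; together they tile ``[0, len(seq))`` exactly.  Each
    side of a fragment is flagged blind when no secondary-motif occurrence
    starts between that side's boundary and the fragment midpoint.
    """
    for motif in (primary_motif, secondary_motif):
        if not motif or not _VALID_MOTIF.match(motif):
            raise ValueError(f"motif must be a non-empty ACGT string, got {motif!r}")
    seq = genome.seq
    cuts = _find_motif(seq, primary_motif)
    bounds = [0] + cuts + [len(seq)]
    # A cut at position 0 or len(seq) duplicates a terminal bound.
    bounds = sorted(set(bounds))
    secondary = _find_motif(seq, secondary_motif)

    fragments: list[Fragment] = []
    sec_i = 0
    for idx, (start, end) in enumerate(zip(bounds[:-1], bounds[1:])):
        mid = (start + end) / 2
        while sec_i < len(secondary) and secondary[sec_i] < start:
            sec_i += 1
        j = sec_i
        left_ok = right_ok = False
        while j < len(secondary) and secondary[j] < end:
            if secondary[j] < mid:
                left_ok = True
            else:
                right_ok = True
            j += 1
        fragments.append(Fragment(genome.chrom, start, end, idx,
                                  blind_left=not left_ok,
                                  blind_right=not right_ok))
    return fragments


def locate_viewpoint(fragments: list[Fragment], name: str, chrom: str,
                     position: int,
                     exclusion_halfwidth: int = DEFAULT_EXCLUSION_HALFWIDTH,
                     ) -> Viewpoint:
    """Find the fragment containing ``position`` and build the viewpoint.

    Boundary positions belong to the fragment whose start equals them
    (half-open convention).  A position outside every fragment raises.
    """
    for frag in fragments:
        if frag.chrom == chrom and frag.contains(position):
            return Viewpoint(name=name, chrom=chrom, position=position,
                             fragment_index=frag.index,
                             exclusion_halfwidth=exclusion_halfwidth)
    raise ValueError(
        f"viewpoint {name!r}: position {chrom}:{position} outside all fragments")


def excluded_fragment_indices(fragments: list[Fragment],
                              viewpoint: Viewpoint) -> set[int]:
    """Indices of fragments overlapping the viewpoint exclusion zone."""
    lo, hi = viewpoint.exclusion_zone
    return {f.index for f in fragments
            if f.chrom == viewpoint.chrom and f.start < hi and f.end > lo}


# ---------------------------------------------------------------------------
# I/O

def read_fasta(path: str | Path) -> dict[str, GenomeSeq]:
    """Read a (multi-)FASTA file into per-chromosome GenomeSeq objects."""
    genomes = {}
    for record in SeqIO.parse(str(path), "fasta"):
        genomes[record.id] = GenomeSeq(chrom=record.id, seq=str(record.seq))
    if not genomes:
        raise ValueError(f"no sequences found in {path}")
    return genomes


def write_fragments_bed(fragments: Iterable[Fragment], path: str | Path) -> None:
    """Write the fragment map as 6-column BED (name=index, score=0)."""
    with open(path, "w") as fh:
        for f in fragments:
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t{f.index}\t0\t.\n")


def read_fragments_bed(path: str | Path) -> list[Fragment]:
    fragments = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end, name = line.split("\t")[:4]
            fragments.append(Fragment(chrom, int(start), int(end), int(name)))
    return fragments
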