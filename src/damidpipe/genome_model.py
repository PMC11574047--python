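"""Genomic coordinate scaffold for DamID analysis.

Builds the GATC site map, GATC fragments, fixed-size bin grids, extended
gene intervals, and the autosomal arm/center partition.  All coordinates
are 0-based half-open internally; GFF3 input is converted from 1-based
closed, BED/bedgraph output stays 0-based half-open.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

GATC = "GATC"

#: ce11 chromosome lengths (bp), including the mitochondrial genome.
CE11_CHROM_LENGTHS = {
    "chrI": 15072434,
    "chrII": 15279421,
    "chrIII": 13783801,
    "chrIV": 17493829,
    "chrV": 20924180,
    "chrX": 17718942,
    "chrM": 13794,
}

#: Total ce11 genome length in bp.
CE11_GENOME_LENGTH = sum(CE11_CHROM_LENGTHS.values())

#: Arm|center|arm border coordinates for the five autosomes.  The published
#: chrX border exceeds the chromosome length and is unusable, so chrX is
#: excluded from arm/center statistics.
CE11_ARM_CENTER_BORDERS = {
    "chrI": (3745632, 10809938),
    "chrII": (4708341, 11877168),
    "chrIII": (3508994, 9947268),
    "chrIV": (7317812, 12176625),
    "chrV": (8125434, 13849337),
}

ARM = "arm"
CENTER = "center"
NOT_APPLICABLE = "not_applicable"


def find_gatc_sites(sequence: str) -> np.ndarray:
    """Return all 0-based start positions of the exact motif GATC.

    Case-insensitive; ``N`` never matches.  An empty sequence yields an
    empty array.  Overlapping occurrences are impossible for this motif.
    """
    seq = sequence.upper()
    sites = []
    pos = seq.find(GATC)
    while pos != -1:
        sites.append(pos)
        pos = seq.find(GATC, pos + 1)
    return np.asarray(sites, dtype=np.int64)


def build_fragments(sites: Sequence[int], chrom_length: int) -> np.ndarray:
    """Fragments delimited by consecutive GATC site starts.

    Returns an (n, 2) int array of half-open intervals
    ``[0,s1), [s1,s2), ..., [sk, L)``; empty leading intervals (site at 0)
    are suppressed.  A chromosome without sites yields the single fragment
    ``[0, L)``.

    Raises
    ------
    ValueError
        If *sites* is not strictly increasing or out of bounds (corrupt
        site table).
    """
    sites = np.asarray(sites, dtype=np.int64)
    if sites.size:
        if np.any(np.diff(sites) <= 0):
            raise ValueError("GATC site table is not strictly increasing")
        if sites[0] < 0 or sites[-1] > chrom_length - len(GATC):
            raise ValueError("GATC site outside chromosome bounds")
    bounds = np.concatenate([[0], sites, [chrom_length]])
    starts, ends = bounds[:-1], bounds[1:]
    keep = ends > starts
    return np.stack([starts[keep], ends[keep]], axis=1)


def classify_arm_center(
    chrom: str,
    position: int | float,
    borders: dict[str, tuple[int, int]] | None = None,
    known_chroms: Iterable[str] | None = None,
) -> str:
    """Classify an autosomal position as ``arm`` or ``center``.

    The center interval is left-closed right-open at the borders:
    positions in ``[b1, b2)`` are center, the rest arm.  Chromosomes
    without borders (chrX, chrM, toy genomes without a border table)
    return ``not_applicable``.
    """
    borders = CE11_ARM_CENTER_BORDERS if borders is None else borders
    if chrom not in borders:
        if known_chroms is not None and chrom not in set(known_chroms):
            raise KeyError(f"unknown chromosome: {chrom!r}")
        if known_chroms is None and chrom not in CE11_CHROM_LENGTHS:
            raise KeyError(f"unknown chromosome: {chrom!r}")
        return NOT_APPLICABLE
    b1, b2 = borders[chrom]
    return CENTER if b1 <= position < b2 else ARM


@dataclass
class GeneAnnotation:
    """Gene intervals (0-based half-open) with an optional flanking extension."""

    gene_ids: list[str]
    chroms: list[str]
    starts: np.ndarray
    ends: np.ndarray
    strands: list[str]

    def __post_init__(self):
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        if np.any(self.starts >= self.ends):
            raise ValueError("gene start must be < end")

    def __len__(self) -> int:
        return len(self.gene_ids)

    def extended_intervals(
        self, chrom_lengths: dict[str, int], extension: int = 500
    ) -> np.ndarray:
        """Per-gene ``[max(0, start-ext), min(L, end+ext))`` intervals."""
        lengths = np.array([chrom_lengths[c] for c in self.chroms], dtype=np.int64)
        starts = np.maximum(self.starts - extension, 0)
        ends = np.minimum(self.ends + extension, lengths)
        return np.stack([starts, ends], axis=1)


def gene_intervals(
    annotation: GeneAnnotation,
    chrom_lengths: dict[str, int],
    extension: int = 500,
) -> np.ndarray:
    """Extended half-open gene intervals, clipped to chromosome bounds.

    Both sides are extended regardless of strand.
    """
    return annotation.extended_intervals(chrom_lengths, extension)


@dataclass
class BinGrid:
    """Fixed-size bin tiling of a genome, anchored at position 0.

    The last bin of each chromosome may be shorter; bins tile each
    chromosome disjointly.  Bin ids are global indices in chromosome
    order.
    """

    bin_size: int
    chrom_names: list[str]
    chrom_lengths: dict[str, int]
    n_bins_per_chrom: dict[str, int] = field(init=False)
    offsets: dict[str, int] = field(init=False)
    n_bins: int = field(init=False)

    def __post_init__(self):
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        self.n_bins_per_chrom = {
            c: math.ceil(self.chrom_lengths[c] / self.bin_size)
            for c in self.chrom_names
        }
        self.offsets = {}
        total = 0
        for c in self.chrom_names:
            self.offsets[c] = total
            total += self.n_bins_per_chrom[c]
        self.n_bins = total

    def bin_id(self, chrom: str, position: int) -> int:
        """Global bin id containing *position* on *chrom*."""
        return self.offsets[chrom] + int(position) // self.bin_size

    def bin_ids(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        return self.offsets[chrom] + np.asarray(positions, dtype=np.int64) // self.bin_size

    def bin_interval(self, bin_id: int) -> tuple[str, int, int]:
        """(chrom, start, end) of a global bin id."""
        for c in self.chrom_names:
            n = self.n_bins_per_chrom[c]
            off = self.offsets[c]
            if off <= bin_id < off + n:
                idx = bin_id - off
                start = idx * self.bin_size
                end = min(start + self.bin_size, self.chrom_lengths[c])
                return c, start, end
        raise IndexError(f"bin id {bin_id} out of range")

    def intervals(self) -> list[tuple[str, int, int]]:
        out = []
        for c in self.chrom_names:
            L = self.chrom_lengths[c]
            for i in range(self.n_bins_per_chrom[c]):
                out.append((c, i * self.bin_size, min((i + 1) * self.bin_size, L)))
        return out

    def midpoints(self) -> np.ndarray:
        """Bin midpoint positions (chromosome-local, float)."""
        return np.array([(s + e) / 2.0 for _, s, e in self.intervals()])

    def chrom_of_bins(self) -> list[str]:
        out = []
        for c in self.chrom_names:
            out.extend([c] * self.n_bins_per_chrom[c])
        return out


@dataclass
class GenomeModel:
    """Chromosomes, GATC-site map, derived fragments and arm/center borders."""

    chrom_names: list[str]
    chrom_lengths: dict[str, int]
    gatc_sites: dict[str, np.ndarray]
    borders: dict[str, tuple[int, int]] = field(default_factory=dict)
    fragments: dict[str, np.ndarray] = field(init=False)
    #: global fragment id offsets per chromosome
    fragment_offsets: dict[str, int] = field(init=False)
    n_fragments: int = field(init=False)

    def __post_init__(self):
        for c in self.chrom_names:
            sites = np.asarray(self.gatc_sites.get(c, []), dtype=np.int64)
            L = self.chrom_lengths[c]
            if sites.size and (sites[0] < 0 or sites[-1] > L - len(GATC)):
                raise ValueError(f"GATC site out of bounds on {c}")
            self.gatc_sites[c] = sites
        for c, (b1, b2) in self.borders.items():
            if not (0 < b1 < b2 < self.chrom_lengths[c]):
                raise ValueError(f"invalid arm/center borders on {c}")
        self.fragments = {
            c: build_fragments(self.gatc_sites[c], self.chrom_lengths[c])
            for c in self.chrom_names
        }
        self.fragment_offsets = {}
        total = 0
        for c in self.chrom_names:
            self.fragment_offsets[c] = total
            total += len(self.fragments[c])
        self.n_fragments = total

    @classmethod
    def from_sequences(
        cls,
        sequences: dict[str, str],
        borders: dict[str, tuple[int, int]] | None = None,
    ) -> "GenomeModel":
        """Build the model by scanning chromosome sequences for GATC."""
        names = list(sequences)
        lengths = {c: len(s) for c, s in sequences.items()}
        sites = {c: find_gatc_sites(s) for c, s in sequences.items()}
        return cls(names, lengths, sites, borders or {})

    def fragment_table(self) -> "np.ndarray":
        """(n_fragments, 2) start/end array in global fragment order."""
        return np.concatenate([self.fragments[c] for c in self.chrom_names])

    def fragment_chroms(self) -> list[str]:
        out = []
        for c in self.chrom_names:
            out.extend([c] * len(self.fragments[c]))
        return out

    def fragment_midpoints(self) -> np.ndarray:
        tab = self.fragment_table()
        return (tab[:, 0] + tab[:, 1]) / 2.0

    def bin_grid(self, bin_size: int) -> BinGrid:
        return BinGrid(bin_size, self.chrom_names, self.chrom_lengths)

    def genome_length(self) -> int:
        return sum(self.chrom_lengths.values())

    def classify_bins(self, grid: BinGrid) -> list[str]:
        """Arm/center label per bin, by bin midpoint."""
        return [
            classify_arm_center(
                c, (s + e) / 2.0, self.borders, known_chroms=self.chrom_names
            )
            for c, s, e in grid.intervals()
        ]
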