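"""DamID quantification: reads -> fragment counts -> normalized log2 tracks.

The normalization chain per the study design: add a pseudocount to every
bin, convert to relative reads per replicate, average relative reads
across replicates, form one log2(fusion/control) ratio per bin, and
center by subtracting the genome-wide mean log2 ratio.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .genome_model import BinGrid, GeneAnnotation, GenomeModel

logger = logging.getLogger(__name__)

#: The DamID adapter every informative read must contain.
DAMID_ADAPTER = "CGCGGCCGAG"

#: Minimum usable post-adapter length for anchoring a read to a GATC site.
#: Long enough that distinct sites share a full anchor only with
#: negligible probability, keeping read assignment unambiguous.
MIN_ANCHOR_LENGTH = 20


@dataclass
class ReadFilterParams:
    adapter: str = DAMID_ADAPTER
    require_gatc_anchor: bool = True

    def __post_init__(self):
        if not self.adapter:
            raise ValueError("adapter must be non-empty")


@dataclass
class SampleCounts:
    """Integer read counts per GATC fragment for one sample."""

    sample_id: str
    construct: str  # "fusion" or "dam_control"
    fusion_name: str  # e.g. "BAF-1", "BAF-1(G12T)", "RPB-6", "none"
    tissue: str
    genotype: str
    replicate: int
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def total_retained_reads(self) -> int:
        return int(self.counts.sum())


@dataclass
class NormalizationParams:
    pseudocount: float = 1.0
    center_genome_wide: bool = True
    #: average per-replicate log ratios instead of ratios of averaged
    #: relative reads (sensitivity-analysis mode).
    per_replicate_ratios: bool = False

    def __post_init__(self):
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")


@dataclass
class NormalizedRatioTrack:
    """Per-bin or per-gene centered log2(fusion/control) values."""

    values: np.ndarray
    unit: str  # "bin" or "gene"
    fusion_name: str = ""
    tissue: str = ""
    n_fusion_reps: int = 0
    n_control_reps: int = 0
    grid: BinGrid | None = None
    gene_ids: list[str] | None = None


class AnchorIndex:
    """Toy exact-match aligner: post-adapter sequences -> GATC fragments.

    Indexes the first ``MIN_ANCHOR_LENGTH`` bases of every GATC site and
    verifies candidate hits against the full genomic sequence, so reads
    truncated at fragment ends still map as long as they carry at least
    the minimum anchor.
    """

    def __init__(self, model: GenomeModel, sequences: dict[str, str]):
        self.model = model
        self.sequences = {c: s.upper() for c, s in sequences.items()}
        self._prefix: dict[str, list[tuple[str, int, int]]] = {}
        for chrom in model.chrom_names:
            seq = self.sequences[chrom]
            frag_starts = model.fragments[chrom][:, 0]
            offset = model.fragment_offsets[chrom]
            for site in model.gatc_sites[chrom]:
                site = int(site)
                key = seq[site : site + MIN_ANCHOR_LENGTH]
                if len(key) < MIN_ANCHOR_LENGTH:
                    continue
                # fragment beginning at this site (a site at 0 keeps id 0)
                idx = int(np.searchsorted(frag_starts, site))
                if idx == len(frag_starts) or frag_starts[idx] != site:
                    continue
                self._prefix.setdefault(key, []).append((chrom, site, offset + idx))

    def locate(self, post_adapter_seq: str) -> int | None:
        """Global fragment id for a GATC-anchored sequence, or None."""
        if len(post_adapter_seq) < MIN_ANCHOR_LENGTH:
            return None
        for chrom, site, frag_id in self._prefix.get(
            post_adapter_seq[:MIN_ANCHOR_LENGTH], ()
        ):
            ref = self.sequences[chrom][site : site + len(post_adapter_seq)]
            if ref == post_adapter_seq:
                return frag_id
        return None


@dataclass
class ReadFilterResult:
    assignments: np.ndarray  # global fragment id per retained read
    n_input: int
    discards: dict[str, int] = field(default_factory=dict)

    @property
    def n_retained(self) -> int:
        return len(self.assignments)


def filter_reads(
    reads: Iterable[tuple[str, str]],
    params: ReadFilterParams,
    index: AnchorIndex,
) -> ReadFilterResult:
    """Retain reads that contain the adapter and anchor on a GATC site.

    A read is retained iff its sequence contains the adapter and the
    sequence 3' of the first adapter occurrence begins with GATC at a
    known site start.  Retained reads are assigned to the fragment
    beginning at that site; discards are tallied by reason
    (``no_adapter``, ``no_gatc_anchor``, ``unmapped``).
    """
    assignments: list[int] = []
    discards = {"no_adapter": 0, "no_gatc_anchor": 0, "unmapped": 0}
    n_input = 0
    for _, seq in reads:
        n_input += 1
        seq = seq.upper()
        pos = seq.find(params.adapter)
        if pos == -1:
            discards["no_adapter"] += 1
            continue
        genomic = seq[pos + len(params.adapter) :]
        if params.require_gatc_anchor and not genomic.startswith("GATC"):
            discards["no_gatc_anchor"] += 1
            continue
        frag_id = index.locate(genomic)
        if frag_id is None:
            discards["unmapped"] += 1
            continue
        assignments.append(frag_id)
    if n_input == 0:
        warnings.warn("empty read input", stacklevel=2)
    return ReadFilterResult(
        np.asarray(assignments, dtype=np.int64), n_input, discards
    )


def count_fragments(
    assignments: np.ndarray,
    n_fragments: int,
    **metadata,
) -> SampleCounts:
    """Tally fragment assignments into an integer count vector.

    Conservation: the counts sum to the number of retained reads.
    """
    assignments = np.asarray(assignments, dtype=np.int64)
    if assignments.size and (
        assignments.min() < 0 or assignments.max() >= n_fragments
    ):
        raise ValueError("assignment to unknown fragment id")
    counts = np.bincount(assignments, minlength=n_fragments)
    meta = {
        "sample_id": metadata.get("sample_id", "sample"),
        "construct": metadata.get("construct", "fusion"),
        "fusion_name": metadata.get("fusion_name", "none"),
        "tissue": metadata.get("tissue", ""),
        "genotype": metadata.get("genotype", ""),
        "replicate": metadata.get("replicate", 1),
    }
    return SampleCounts(counts=counts, **meta)


def bin_counts(
    fragment_counts: np.ndarray, model: GenomeModel, grid: BinGrid
) -> np.ndarray:
    """Sum fragment counts into bins by fragment midpoint.

    Each fragment contributes all its reads to exactly one bin, so the
    sample total is conserved at every resolution.
    """
    fragment_counts = np.asarray(fragment_counts)
    out = np.zeros(grid.n_bins, dtype=fragment_counts.dtype)
    for chrom in model.chrom_names:
        frags = model.fragments[chrom]
        if len(frags) == 0:
            continue
        mids = (frags[:, 0] + frags[:, 1]) // 2
        ids = grid.bin_ids(chrom, mids)
        off = model.fragment_offsets[chrom]
        np.add.at(out, ids, fragment_counts[off : off + len(frags)])
    return out


def _relative_reads(reps: Sequence[np.ndarray], pseudocount: float) -> np.ndarray:
    """Pseudocount each replicate, scale to relative reads, average."""
    rel = []
    for rep in reps:
        rep = np.asarray(rep, dtype=float)
        if rep.sum() <= 0:
            raise ValueError("replicate has zero total reads (empty sample)")
        pc = rep + pseudocount
        rel.append(pc / pc.sum())
    return np.mean(rel, axis=0)


def normalize_ratio(
    fusion_reps: Sequence[np.ndarray],
    control_reps: Sequence[np.ndarray],
    params: NormalizationParams | None = None,
    **track_metadata,
) -> NormalizedRatioTrack:
    """Replicate-averaged, genome-mean-centered log2(fusion/control).

    Per replicate the pseudocount is added to every bin before relative
    reads are computed; relative reads are averaged across replicates on
    each side and a single ratio is log2-transformed.  If centering is
    on, the mean over all bins is subtracted (resulting mean is 0 to
    within 1e-9).
    """
    params = params or NormalizationParams()
    if len(fusion_reps) == 0 or len(control_reps) == 0:
        raise ValueError("need at least one replicate per side")
    lengths = {len(np.asarray(r)) for r in list(fusion_reps) + list(control_reps)}
    if len(lengths) != 1:
        raise ValueError("replicate count vectors have mismatched lengths")

    if params.per_replicate_ratios:
        if len(fusion_reps) != len(control_reps):
            raise ValueError("per-replicate mode needs paired replicates")
        ratios = []
        for f, c in zip(fusion_reps, control_reps):
            rf = _relative_reads([f], params.pseudocount)
            rc = _relative_reads([c], params.pseudocount)
            ratios.append(np.log2(rf / rc))
        values = np.mean(ratios, axis=0)
    else:
        fusion_avg = _relative_reads(fusion_reps, params.pseudocount)
        control_avg = _relative_reads(control_reps, params.pseudocount)
        with np.errstate(divide="ignore"):
            values = np.log2(fusion_avg / control_avg)

    if params.center_genome_wide:
        values = values - values.mean()
    return NormalizedRatioTrack(
        values=values,
        unit=track_metadata.pop("unit", "bin"),
        n_fusion_reps=len(fusion_reps),
        n_control_reps=len(control_reps),
        **track_metadata,
    )


def gene_counts(
    fragment_counts: np.ndarray,
    model: GenomeModel,
    annotation: GeneAnnotation,
    extension: int = 500,
) -> np.ndarray:
    """Sum fragment counts per gene over fragments whose midpoint falls
    in the gene's extended interval.

    Overlapping gene extensions may share fragments; a gene with no
    overlapping fragment gets 0 (the pseudocount handles it downstream).
    """
    fragment_counts = np.asarray(fragment_counts, dtype=float)
    intervals = annotation.extended_intervals(model.chrom_lengths, extension)
    out = np.zeros(len(annotation))
    # per-chromosome cumulative sums over midpoint-sorted fragments
    csums, mids_by_chrom = {}, {}
    for chrom in model.chrom_names:
        frags = model.fragments[chrom]
        off = model.fragment_offsets[chrom]
        mids = (frags[:, 0] + frags[:, 1]) / 2.0
        mids_by_chrom[chrom] = mids
        csums[chrom] = np.concatenate(
            [[0.0], np.cumsum(fragment_counts[off : off + len(frags)])]
        )
    for i, (chrom, (gs, ge)) in enumerate(zip(annotation.chroms, intervals)):
        mids = mids_by_chrom[chrom]
        lo = np.searchsorted(mids, gs, side="left")
        hi = np.searchsorted(mids, ge, side="left")
        out[i] = csums[chrom][hi] - csums[chrom][lo]
    return out


def gene_level_values(
    fusion_reps: Sequence[np.ndarray],
    control_reps: Sequence[np.ndarray],
    model: GenomeModel,
    annotation: GeneAnnotation,
    params: NormalizationParams | None = None,
    extension: int = 500,
    **track_metadata,
) -> NormalizedRatioTrack:
    """Normalization chain applied over the gene universe.

    Fragment counts are summed per extended gene interval first, then
    pseudocounting, relative reads, replicate averaging, log2 ratio and
    centering run over genes instead of bins.
    """
    fus = [gene_counts(r, model, annotation, extension) for r in fusion_reps]
    ctl = [gene_counts(r, model, annotation, extension) for r in control_reps]
    track = normalize_ratio(fus, ctl, params, unit="gene", **track_metadata)
    track.gene_ids = list(annotation.gene_ids)
    return track
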