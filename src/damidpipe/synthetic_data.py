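"""Synthetic study generator.

Emulates the experimental design end to end: a toy genome with
discovered (not planted) GATC sites, non-overlapping genes, arm-biased
fusion binding, a planted set of genotype-differential bins, planted
expressed genes and planted deregulated genes, with NB-distributed
counts and optional adapter-prefixed FASTQ emission.  Everything is
deterministic under the config seed via named substreams.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .damid_quant import DAMID_ADAPTER, MIN_ANCHOR_LENGTH, SampleCounts
from .genome_model import GeneAnnotation, GenomeModel

NUCLEOTIDES = np.array(list("ACGT"))


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent, reproducible generator for a named simulation stage."""
    return np.random.default_rng([seed, zlib.crc32(name.encode())])


@dataclass
class SimulationConfig:
    seed: int
    n_chromosomes: int = 6
    chrom_length: int = 1_000_000
    n_genes: int = 2000
    gene_length_log_mean: float = float(np.log(2000.0))
    gene_length_log_sigma: float = 0.5
    #: log2 elevation of fusion signal on chromosome arms
    arm_effect_log2: float = 1.0
    #: fraction of diff-grid bins with a genotype-specific effect
    fraction_diff_bins: float = 0.02
    diff_effect_log2: float = 1.0
    diff_bin_size: int = 10_000
    n_expressed_genes: int = 200
    expressed_overlap_fraction: float = 0.25
    occupancy_effect_log2: float = 2.0
    #: log2 depletion of fusion binding over expressed genes
    expressed_depletion_log2: float = 1.0
    n_up: int = 30
    n_down: int = 30
    dereg_effect_log2: float = 2.0
    nb_dispersion: float = 0.1
    reads_per_replicate: int = 1_000_000
    rapid_reads_per_replicate: int = 500_000
    n_damid_replicates: int = 3
    n_rapid_replicates: int = 2
    tissues: tuple[str, str] = ("hypodermis", "intestine")
    genotypes: tuple[str, str] = ("wild_type", "G12T")
    decoy_fraction: float = 0.0
    read_length: int = 50

    def __post_init__(self):
        for frac in (self.fraction_diff_bins, self.expressed_overlap_fraction,
                     self.decoy_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        for eff in (self.arm_effect_log2, self.diff_effect_log2,
                    self.occupancy_effect_log2, self.dereg_effect_log2):
            if not np.isfinite(eff):
                raise ValueError("effects must be finite")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    @property
    def borders(self) -> dict[str, tuple[int, int]]:
        b1, b2 = self.chrom_length // 3, 2 * self.chrom_length // 3
        return {c: (b1, b2) for c in self.chrom_names}


def simulate_genome(
    config: SimulationConfig,
) -> tuple[GenomeModel, GeneAnnotation, dict[str, str]]:
    """I.i.d. nucleotide chromosomes with discovered GATC sites and
    non-overlapping lognormal-length genes.

    Raises
    ------
    ValueError
        When the requested genes cannot be placed without overlap.
    """
    rng_seq = substream(config.seed, "genome_sequence")
    sequences = {
        c: "".join(NUCLEOTIDES[rng_seq.integers(0, 4, config.chrom_length)])
        for c in config.chrom_names
    }
    model = GenomeModel.from_sequences(sequences, borders=config.borders)

    rng_gene = substream(config.seed, "gene_placement")
    per_chrom = np.full(config.n_chromosomes, config.n_genes // config.n_chromosomes)
    per_chrom[: config.n_genes % config.n_chromosomes] += 1
    ids, chroms, starts, ends, strands = [], [], [], [], []
    gi = 0
    for chrom, n_c in zip(config.chrom_names, per_chrom):
        placed = False
        for _ in range(20):  # bounded retries
            lengths = np.round(
                rng_gene.lognormal(
                    config.gene_length_log_mean, config.gene_length_log_sigma, n_c
                )
            ).astype(np.int64)
            lengths = np.maximum(lengths, 200)
            slack = config.chrom_length - lengths.sum()
            if slack > n_c:  # room for at least 1 bp gaps
                placed = True
                break
        if not placed:
            raise ValueError(
                "cannot place genes without overlap; lower n_genes or "
                "gene length parameters"
            )
        gaps = rng_gene.random(n_c + 1)
        gaps = np.floor(gaps / gaps.sum() * slack).astype(np.int64)
        pos = 0
        for j in range(n_c):
            pos += gaps[j]
            ids.append(f"gene{gi:05d}")
            chroms.append(chrom)
            starts.append(pos)
            ends.append(pos + lengths[j])
            strands.append("+" if rng_gene.random() < 0.5 else "-")
            pos += lengths[j]
            gi += 1
    annotation = GeneAnnotation(
        ids, chroms, np.array(starts), np.array(ends), strands
    )
    return model, annotation, sequences


def _emittable_fragment_weights(model: GenomeModel) -> np.ndarray:
    """Base fragment weights proportional to length; fragments that do
    not start at a GATC site or are too short to anchor a read get zero
    weight so FASTQ round trips are exact."""
    weights = np.zeros(model.n_fragments)
    for chrom in model.chrom_names:
        frags = model.fragments[chrom]
        off = model.fragment_offsets[chrom]
        sites = set(model.gatc_sites[chrom].tolist())
        for i, (s, e) in enumerate(frags):
            if int(s) in sites and e - s >= MIN_ANCHOR_LENGTH:
                weights[off + i] = e - s
    return weights


def _fragment_labels(model: GenomeModel) -> np.ndarray:
    """Arm/center label per fragment by midpoint."""
    labels = np.empty(model.n_fragments, dtype=object)
    for chrom in model.chrom_names:
        frags = model.fragments[chrom]
        off = model.fragment_offsets[chrom]
        b1, b2 = model.borders.get(chrom, (None, None))
        mids = (frags[:, 0] + frags[:, 1]) / 2.0
        if b1 is None:
            labels[off : off + len(frags)] = "not_applicable"
        else:
            lab = np.where((mids >= b1) & (mids < b2), "center", "arm")
            labels[off : off + len(frags)] = lab
    return labels


def _sample_nb(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """NB(mean, variance = mu + alpha mu^2) draws; Poisson when alpha=0."""
    mean = np.maximum(mean, 0.0)
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    out = np.zeros(len(mean), dtype=np.int64)
    pos = mean > 0
    out[pos] = rng.negative_binomial(r, p[pos])
    return out


@dataclass
class SyntheticStudy:
    """All simulated data plus ground truth for one config."""

    config: SimulationConfig
    model: GenomeModel
    annotation: GeneAnnotation
    sequences: dict[str, str]
    damid_samples: list[SampleCounts] = field(default_factory=list)
    rapid_samples: list[SampleCounts] = field(default_factory=list)
    ground_truth: dict = field(default_factory=dict)

    def damid(
        self, fusion_name: str, tissue: str, genotype: str | None = None
    ) -> list[np.ndarray]:
        """Replicate count vectors for one DamID sample group."""
        return [
            s.counts
            for s in self.damid_samples
            if s.fusion_name == fusion_name
            and s.tissue == tissue
            and (genotype is None or s.genotype == genotype)
        ]

    def rapid(
        self, fusion_name: str, tissue: str, genotype: str
    ) -> list[np.ndarray]:
        return [
            s.counts
            for s in self.rapid_samples
            if s.fusion_name == fusion_name
            and s.tissue == tissue
            and s.genotype == genotype
        ]


def simulate_damid_counts(
    config: SimulationConfig, model: GenomeModel, annotation: GeneAnnotation
) -> tuple[list[SampleCounts], dict]:
    """DamID counts for {BAF-1, BAF-1(G12T), GFP::Dam} x tissues x replicates.

    Fragment rates are proportional to fragment length; fusion samples
    gain the arm effect, lose the expressed-gene depletion, and
    BAF-1(G12T) additionally gains the planted genotype effect on a
    seeded subset of center bins in the first tissue.  Counts are NB
    with one global dispersion.  Ground truth (arm labels, planted bin
    ids, fragment-to-diff-bin mask) is returned alongside.
    """
    base = _emittable_fragment_weights(model)
    labels = _fragment_labels(model)
    arm_mask = labels == "arm"

    grid = model.bin_grid(config.diff_bin_size)
    bin_labels = np.asarray(model.classify_bins(grid))
    center_bins = np.flatnonzero(bin_labels == "center")
    rng_bins = substream(config.seed, "diff_bins")
    n_diff = int(round(config.fraction_diff_bins * grid.n_bins))
    n_diff = min(n_diff, len(center_bins))
    diff_bins = np.sort(rng_bins.choice(center_bins, size=n_diff, replace=False))

    frag_bins = np.empty(model.n_fragments, dtype=np.int64)
    for chrom in model.chrom_names:
        frags = model.fragments[chrom]
        off = model.fragment_offsets[chrom]
        mids = (frags[:, 0] + frags[:, 1]) // 2
        frag_bins[off : off + len(frags)] = grid.bin_ids(chrom, mids)
    diff_frag_mask = np.isin(frag_bins, diff_bins)

    # expressed-gene depletion for fusion constructs (Fig-5-style ordering)
    rng_expr = substream(config.seed, "expressed_genes")
    expressed = _plant_expressed_genes(config, annotation, rng_expr)
    depletion_mask = _gene_set_fragment_mask(
        model, annotation, expressed["union"]
    )

    samples: list[SampleCounts] = []
    rng_counts = substream(config.seed, "damid_counts")
    for tissue_idx, tissue in enumerate(config.tissues):
        for fusion_name in ("BAF-1", "BAF-1(G12T)", "GFP::Dam"):
            for rep in range(1, config.n_damid_replicates + 1):
                log2_effect = np.zeros(model.n_fragments)
                if fusion_name != "GFP::Dam":
                    log2_effect[arm_mask] += config.arm_effect_log2
                    log2_effect[depletion_mask] -= config.expressed_depletion_log2
                if fusion_name == "BAF-1(G12T)" and tissue_idx == 0:
                    log2_effect[diff_frag_mask] += config.diff_effect_log2
                weights = base * np.exp2(log2_effect)
                mean = weights / weights.sum() * config.reads_per_replicate
                counts = _sample_nb(rng_counts, mean, config.nb_dispersion)
                construct = "dam_control" if fusion_name == "GFP::Dam" else "fusion"
                samples.append(
                    SampleCounts(
                        sample_id=f"damid_{tissue}_{fusion_name}_rep{rep}",
                        construct=construct,
                        fusion_name=fusion_name,
                        tissue=tissue,
                        genotype="wild_type" if fusion_name != "BAF-1(G12T)" else "G12T",
                        replicate=rep,
                        counts=counts,
                    )
                )
    truth = {
        "fragment_arm_mask": arm_mask,
        "fragment_labels": labels,
        "diff_bins": diff_bins,
        "diff_bin_tissue": config.tissues[0],
        "diff_fragment_mask": diff_frag_mask,
        "bin_labels": bin_labels,
        "expressed": expressed,
    }
    return samples, truth


def _plant_expressed_genes(
    config: SimulationConfig, annotation: GeneAnnotation, rng: np.random.Generator
) -> dict:
    """Choose per-tissue expressed gene sets with a shared core, and
    up/down deregulated subsets within each tissue's expressed set."""
    n = len(annotation)
    n_expr = min(config.n_expressed_genes, n // 2)
    n_shared = int(round(config.expressed_overlap_fraction * n_expr))
    order = rng.permutation(n)
    shared = order[:n_shared]
    t1_only = order[n_shared : n_expr]
    t2_only = order[n_expr : 2 * n_expr - n_shared]
    ids = np.asarray(annotation.gene_ids)
    expr1 = np.concatenate([shared, t1_only])
    expr2 = np.concatenate([shared, t2_only])
    out = {
        config.tissues[0]: set(ids[expr1].tolist()),
        config.tissues[1]: set(ids[expr2].tolist()),
    }
    out["union"] = out[config.tissues[0]] | out[config.tissues[1]]
    dereg: dict[str, dict[str, set]] = {}
    for tissue, expr_idx in zip(config.tissues, (expr1, expr2)):
        pick = rng.permutation(expr_idx)
        n_up = min(config.n_up, len(pick) // 2)
        n_down = min(config.n_down, len(pick) - n_up)
        dereg[tissue] = {
            "up": set(ids[pick[:n_up]].tolist()),
            "down": set(ids[pick[n_up : n_up + n_down]].tolist()),
        }
    out["deregulated"] = dereg
    return out


def _gene_set_fragment_mask(
    model: GenomeModel,
    annotation: GeneAnnotation,
    genes: set[str],
    extension: int = 500,
) -> np.ndarray:
    """Boolean mask over fragments whose midpoint falls in any of the
    given genes' extended intervals (matching the quantification
    windows, so planted effects cover the whole measured signal)."""
    from .rapid_expression import _gene_fragment_ranges

    lows, highs = _gene_fragment_ranges(model, annotation, extension)
    mask = np.zeros(model.n_fragments, dtype=bool)
    for gid, lo, hi in zip(annotation.gene_ids, lows, highs):
        if gid in genes:
            mask[lo:hi] = True
    return mask


def simulate_rapid_counts(
    config: SimulationConfig,
    model: GenomeModel,
    annotation: GeneAnnotation,
    expressed: dict | None = None,
) -> tuple[list[SampleCounts], dict]:
    """RAPID counts for {RPB-6, GFP::Dam} x genotypes x tissues x replicates.

    Expressed genes gain the occupancy effect on RPB-6 fragments within
    the gene; planted up/down genes shift by +/- the deregulation effect
    in the mutant genotype.  Ground truth carries the expressed and
    deregulated sets per tissue.
    """
    if expressed is None:
        rng_expr = substream(config.seed, "expressed_genes")
        expressed = _plant_expressed_genes(config, annotation, rng_expr)
    base = _emittable_fragment_weights(model)
    rng_counts = substream(config.seed, "rapid_counts")

    masks = {
        tissue: _gene_set_fragment_mask(model, annotation, expressed[tissue])
        for tissue in config.tissues
    }
    up_masks = {
        tissue: _gene_set_fragment_mask(
            model, annotation, expressed["deregulated"][tissue]["up"]
        )
        for tissue in config.tissues
    }
    down_masks = {
        tissue: _gene_set_fragment_mask(
            model, annotation, expressed["deregulated"][tissue]["down"]
        )
        for tissue in config.tissues
    }

    samples: list[SampleCounts] = []
    for tissue in config.tissues:
        for genotype in config.genotypes:
            for fusion_name in ("RPB-6", "GFP::Dam"):
                for rep in range(1, config.n_rapid_replicates + 1):
                    log2_effect = np.zeros(model.n_fragments)
                    if fusion_name == "RPB-6":
                        log2_effect[masks[tissue]] += config.occupancy_effect_log2
                        if genotype == config.genotypes[1]:
                            log2_effect[up_masks[tissue]] += config.dereg_effect_log2
                            log2_effect[down_masks[tissue]] -= config.dereg_effect_log2
                    weights = base * np.exp2(log2_effect)
                    mean = (
                        weights / weights.sum() * config.rapid_reads_per_replicate
                    )
                    counts = _sample_nb(rng_counts, mean, config.nb_dispersion)
                    samples.append(
                        SampleCounts(
                            sample_id=f"rapid_{tissue}_{genotype}_{fusion_name}_rep{rep}",
                            construct=(
                                "dam_control" if fusion_name == "GFP::Dam" else "fusion"
                            ),
                            fusion_name=fusion_name,
                            tissue=tissue,
                            genotype=genotype,
                            replicate=rep,
                            counts=counts,
                        )
                    )
    truth = {"expressed": expressed}
    return samples, truth


def simulate_study(config: SimulationConfig) -> SyntheticStudy:
    """Run the full generator: genome, DamID arm and RAPID arm."""
    model, annotation, sequences = simulate_genome(config)
    damid_samples, damid_truth = simulate_damid_counts(config, model, annotation)
    rapid_samples, rapid_truth = simulate_rapid_counts(
        config, model, annotation, expressed=damid_truth["expressed"]
    )
    truth = dict(damid_truth)
    truth.update(rapid_truth)
    return SyntheticStudy(
        config, model, annotation, sequences, damid_samples, rapid_samples, truth
    )


def emit_fastq(
    sample: SampleCounts,
    model: GenomeModel,
    sequences: dict[str, str],
    config: SimulationConfig,
) -> Iterator[tuple[str, str]]:
    """Yield adapter-prefixed reads reproducing the sample's counts.

    Each fragment with count n yields n reads of adapter + up to
    ``read_length`` genomic bases from the fragment's GATC start,
    truncated at the fragment end.  With a positive decoy fraction,
    extra uninformative reads (half without adapter, half with a
    non-GATC genomic part) are appended so that the decoys make up that
    fraction of all emitted reads.
    """
    table = model.fragment_table()
    chroms = model.fragment_chroms()
    n_signal = 0
    read_idx = 0
    for frag_id in np.flatnonzero(sample.counts):
        s, e = table[frag_id]
        chrom = chroms[frag_id]
        genomic = sequences[chrom][int(s) : int(min(e, s + config.read_length))]
        seq = DAMID_ADAPTER + genomic
        for _ in range(int(sample.counts[frag_id])):
            yield f"{sample.sample_id}_r{read_idx}", seq
            read_idx += 1
            n_signal += 1
    if config.decoy_fraction > 0:
        rng = substream(config.seed, f"decoys_{sample.sample_id}")
        n_decoy = int(round(
            n_signal * config.decoy_fraction / (1.0 - config.decoy_fraction)
        ))
        # G-free alphabet guarantees no accidental adapter or GATC motif
        act = np.array(list("ACT"))
        for d in range(n_decoy):
            rand = "".join(act[rng.integers(0, 3, config.read_length)])
            if d % 2 == 0:  # no adapter at all
                seq = rand
            else:  # adapter present but no GATC anchor
                seq = DAMID_ADAPTER + "AAAA" + rand[4:]
            yield f"{sample.sample_id}_decoy{d}", seq
            read_idx += 1
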