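"""Gene-set algebra and reporting: association calls, Venn overlaps,
multi-dataset membership and expression-category summaries."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .damid_quant import NormalizedRatioTrack
from .enrichment_stats import EnrichmentTable, GroupComparison, arm_center_compare
from .report import round_half_up


@dataclass
class GeneCallSet:
    """A labelled set of called genes, e.g. one (protein, tissue) pair."""

    label: str
    genes: frozenset[str]

    def __len__(self) -> int:
        return len(self.genes)


def call_associated_genes(
    gene_enrichment: EnrichmentTable,
    gene_ids: Sequence[str],
    fdr: float = 0.05,
    label: str = "",
) -> GeneCallSet:
    """Genes significantly enriched for the fusion over the Dam-only control."""
    if len(gene_enrichment) != len(gene_ids):
        raise ValueError("enrichment table and gene list differ in length")
    called = (gene_enrichment.q_value < fdr) & (gene_enrichment.log2_fold > 0)
    return GeneCallSet(label, frozenset(np.asarray(gene_ids)[called].tolist()))


@dataclass
class OverlapSummary:
    """Two-set overlap with integer percentages of the union."""

    n_a: int
    n_b: int
    n_shared: int
    n_a_only: int
    n_b_only: int
    n_union: int
    pct_shared: int
    pct_a_only: int
    pct_b_only: int
    pct_specific: int  # a-only + b-only combined

    @classmethod
    def from_region_counts(
        cls, shared: int, a_only: int, b_only: int
    ) -> "OverlapSummary":
        """Build the summary from the three disjoint region counts."""
        union = shared + a_only + b_only
        pct = lambda n: int(round_half_up(100.0 * n / union)) if union else 0
        return cls(
            n_a=shared + a_only,
            n_b=shared + b_only,
            n_shared=shared,
            n_a_only=a_only,
            n_b_only=b_only,
            n_union=union,
            pct_shared=pct(shared),
            pct_a_only=pct(a_only),
            pct_b_only=pct(b_only),
            pct_specific=pct(a_only + b_only),
        )

    @classmethod
    def from_set_sizes(
        cls, n_a: int, n_b: int, n_shared: int
    ) -> "OverlapSummary":
        """Build the summary from |A|, |B| and |A n B|."""
        return cls.from_region_counts(n_shared, n_a - n_shared, n_b - n_shared)


def venn2(set_a: GeneCallSet | set, set_b: GeneCallSet | set) -> OverlapSummary:
    """Two-set Venn decomposition with percentages of the union."""
    a = set_a.genes if isinstance(set_a, GeneCallSet) else set(set_a)
    b = set_b.genes if isinstance(set_b, GeneCallSet) else set(set_b)
    return OverlapSummary.from_region_counts(
        len(a & b), len(a - b), len(b - a)
    )


@dataclass
class MembershipSummary:
    """How many genes of the union appear in 1, 2, ... k datasets."""

    histogram: dict[int, int]
    n_union: int
    n_at_least_two: int
    n_unique: int
    n_all: int  # genes present in every dataset
    pct_at_least_two: int
    pct_unique: int
    pct_all: int


def multiset_membership(sets: Sequence[GeneCallSet | set]) -> MembershipSummary:
    """Membership histogram over the union of k >= 2 gene sets."""
    if len(sets) < 2:
        raise ValueError("need at least two sets")
    plain = [
        s.genes if isinstance(s, GeneCallSet) else set(s) for s in sets
    ]
    union = set().union(*plain)
    counts: dict[str, int] = {g: 0 for g in union}
    for s in plain:
        for g in s:
            counts[g] += 1
    histogram: dict[int, int] = {}
    for c in counts.values():
        histogram[c] = histogram.get(c, 0) + 1
    n_union = len(union)
    n_ge2 = sum(v for k, v in histogram.items() if k >= 2)
    n_unique = histogram.get(1, 0)
    n_all = histogram.get(len(plain), 0)
    pct = lambda n: int(round_half_up(100.0 * n / n_union)) if n_union else 0
    return MembershipSummary(
        histogram, n_union, n_ge2, n_unique, n_all, pct(n_ge2), pct(n_unique), pct(n_all)
    )


def membership_percentages(n_at_least_two: int, n_unique: int) -> tuple[int, int]:
    """Integer percentages of the union from the two membership counts."""
    union = n_at_least_two + n_unique
    return (
        int(round_half_up(100.0 * n_at_least_two / union)),
        int(round_half_up(100.0 * n_unique / union)),
    )


EXPRESSION_CATEGORIES = ("both", "hyp_only", "int_only", "neither")


def expression_categories(
    gene_ids: Sequence[str], expressed_hyp: set[str], expressed_int: set[str]
) -> np.ndarray:
    """Partition the gene universe into the four expression categories."""
    out = np.empty(len(gene_ids), dtype=object)
    for i, g in enumerate(gene_ids):
        h, t = g in expressed_hyp, g in expressed_int
        out[i] = "both" if h and t else "hyp_only" if h else "int_only" if t else "neither"
    return out


def expression_category_summary(
    track: NormalizedRatioTrack,
    expressed_hyp: set[str],
    expressed_int: set[str],
) -> tuple[np.ndarray, GroupComparison]:
    """Distribution of binding values per expression category.

    Returns the per-gene category labels and a comparison with per-group
    medians/quartiles plus BH-corrected pairwise Wilcoxon tests.
    """
    if track.gene_ids is None:
        raise ValueError("track must be gene-level (gene_ids set)")
    cats = expression_categories(track.gene_ids, expressed_hyp, expressed_int)
    return cats, arm_center_compare(track.values, cats)
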