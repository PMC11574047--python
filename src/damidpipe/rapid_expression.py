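"""RNA-polymerase DamID (RAPID) expression analysis.

Per-gene polymerase occupancy is the log2 ratio of Pol-II-subunit fusion
to Dam-only control, computed through the same pseudocount/relative-read
chain as the binding tracks but without genome-mean centering.  Expressed
genes are called at FDR 0.05 against a seeded permutation null; genes
deregulated between genotypes must exceed the |delta log2| > 1 threshold
in every replicate pair and on average.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .damid_quant import gene_counts
from .enrichment_stats import benjamini_hochberg
from .genome_model import GeneAnnotation, GenomeModel


@dataclass
class RapidGeneTable:
    """Per-gene Pol II occupancy with expressed-gene calls."""

    gene_ids: list[str]
    occupancy_reps: np.ndarray  # (n_replicates, n_genes)
    occupancy: np.ndarray  # replicate average
    p_value: np.ndarray | None = None
    q_value: np.ndarray | None = None
    expressed: np.ndarray | None = None
    fdr: float = 0.05

    def expressed_genes(self) -> set[str]:
        if self.expressed is None:
            raise ValueError("call_expressed has not been run on this table")
        return {g for g, e in zip(self.gene_ids, self.expressed) if e}


@dataclass
class DeregulationCall:
    """Replicate-consistent differential expression between genotypes."""

    gene_ids: list[str]
    delta_reps: np.ndarray  # (n_pairs, n_genes), mutant - wild type
    delta_avg: np.ndarray
    direction: np.ndarray  # "up", "down" or "none" per gene
    threshold: float = 1.0

    def genes(self, direction: str) -> set[str]:
        return {
            g for g, d in zip(self.gene_ids, self.direction) if d == direction
        }


def _occupancy_chain(
    fusion_gene_counts: np.ndarray,
    control_gene_counts: np.ndarray,
    pseudocount: float,
) -> np.ndarray:
    f = fusion_gene_counts + pseudocount
    c = control_gene_counts + pseudocount
    return np.log2((f / f.sum()) / (c / c.sum()))


def gene_occupancy(
    rpb6_reps: Sequence[np.ndarray],
    control_reps: Sequence[np.ndarray],
    model: GenomeModel,
    annotation: GeneAnnotation,
    pseudocount: float = 1.0,
    extension: int = 500,
) -> RapidGeneTable:
    """log2(Pol II fusion / Dam-only) occupancy per gene.

    Replicates are paired by index; each pair yields one occupancy
    vector over the gene universe, and the table also stores the
    replicate average.  No genome-mean centering is applied.
    """
    if len(rpb6_reps) != len(control_reps):
        raise ValueError("replicate count mismatch between fusion and control")
    occ = []
    for f_frag, c_frag in zip(rpb6_reps, control_reps):
        if np.asarray(f_frag).sum() <= 0 or np.asarray(c_frag).sum() <= 0:
            raise ValueError("replicate has zero total reads (empty sample)")
        fg = gene_counts(f_frag, model, annotation, extension)
        cg = gene_counts(c_frag, model, annotation, extension)
        occ.append(_occupancy_chain(fg, cg, pseudocount))
    occ = np.stack(occ, axis=0)
    return RapidGeneTable(
        gene_ids=list(annotation.gene_ids),
        occupancy_reps=occ,
        occupancy=occ.mean(axis=0),
    )


def _gene_fragment_ranges(
    model: GenomeModel, annotation: GeneAnnotation, extension: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene [lo, hi) index ranges into the global fragment order,
    selecting fragments whose midpoint lies in the extended interval."""
    intervals = annotation.extended_intervals(model.chrom_lengths, extension)
    lows = np.zeros(len(annotation), dtype=np.int64)
    highs = np.zeros(len(annotation), dtype=np.int64)
    mids_by_chrom = {
        c: (model.fragments[c][:, 0] + model.fragments[c][:, 1]) / 2.0
        for c in model.chrom_names
    }
    for i, (chrom, (gs, ge)) in enumerate(zip(annotation.chroms, intervals)):
        off = model.fragment_offsets[chrom]
        mids = mids_by_chrom[chrom]
        lows[i] = off + np.searchsorted(mids, gs, side="left")
        highs[i] = off + np.searchsorted(mids, ge, side="left")
    return lows, highs


def call_expressed(
    table: RapidGeneTable,
    rpb6_reps: Sequence[np.ndarray],
    control_reps: Sequence[np.ndarray],
    model: GenomeModel,
    annotation: GeneAnnotation,
    fdr: float = 0.05,
    n_permutations: int = 1000,
    rng: np.random.Generator | int | None = 0,
    pseudocount: float = 1.0,
    extension: int = 500,
) -> RapidGeneTable:
    """Call expressed genes at the given FDR.

    The per-gene one-sided p-value compares observed average occupancy
    against an empirical null built by permuting fragment-to-gene
    assignment labels (the fragment count vectors are jointly shuffled
    and the occupancy chain recomputed, *n_permutations* times with a
    seeded generator).  BH correction runs over genes; a gene is
    expressed when q < fdr and its average occupancy is positive.
    """
    if n_permutations < 100:
        warnings.warn(
            "fewer than 100 permutations gives an unstable null tail",
            stacklevel=2,
        )
    rng = np.random.default_rng(rng)
    lows, highs = _gene_fragment_ranges(model, annotation, extension)

    f_frags = [np.asarray(r, dtype=float) for r in rpb6_reps]
    c_frags = [np.asarray(r, dtype=float) for r in control_reps]
    n_frag = model.n_fragments

    null_pool = np.empty(n_permutations * len(annotation))
    for b in range(n_permutations):
        perm = rng.permutation(n_frag)
        occ_b = []
        for f, c in zip(f_frags, c_frags):
            fp = np.concatenate([[0.0], np.cumsum(f[perm])])
            cp = np.concatenate([[0.0], np.cumsum(c[perm])])
            fg = fp[highs] - fp[lows]
            cg = cp[highs] - cp[lows]
            occ_b.append(_occupancy_chain(fg, cg, pseudocount))
        null_pool[b * len(annotation) : (b + 1) * len(annotation)] = np.mean(
            occ_b, axis=0
        )
    null_pool.sort()

    # one-sided: P(null >= observed)
    n_null = len(null_pool)
    n_ge = n_null - np.searchsorted(null_pool, table.occupancy, side="left")
    p = (1.0 + n_ge) / (1.0 + n_null)
    q = benjamini_hochberg(p)
    table.p_value = p
    table.q_value = q
    table.expressed = (q < fdr) & (table.occupancy > 0)
    table.fdr = fdr
    return table


def call_deregulated(
    wt: RapidGeneTable,
    mut: RapidGeneTable,
    expressed_union: set[str],
    threshold: float = 1.0,
) -> DeregulationCall:
    """Genotype-differential genes with replicate-consistent |delta| > threshold.

    delta = mutant occupancy - wild-type occupancy, paired by replicate
    index (all pairs when replicate counts differ).  ``up`` requires every
    pair delta and the average to be strictly above the threshold;
    ``down`` is symmetric.  Genes outside *expressed_union* are ``none``.
    """
    if wt.gene_ids != mut.gene_ids:
        raise ValueError("gene universes differ between genotypes")
    r_wt, r_mut = wt.occupancy_reps.shape[0], mut.occupancy_reps.shape[0]
    if r_wt == r_mut:
        deltas = mut.occupancy_reps - wt.occupancy_reps
    else:  # all replicate pairs
        deltas = np.stack(
            [
                mut.occupancy_reps[j] - wt.occupancy_reps[i]
                for i in range(r_wt)
                for j in range(r_mut)
            ]
        )
    avg = deltas.mean(axis=0)
    in_universe = np.array([g in expressed_union for g in wt.gene_ids])
    up = in_universe & np.all(deltas > threshold, axis=0) & (avg > threshold)
    down = in_universe & np.all(deltas < -threshold, axis=0) & (avg < -threshold)
    direction = np.where(up, "up", np.where(down, "down", "none"))
    return DeregulationCall(list(wt.gene_ids), deltas, avg, direction, threshold)


def _paired_t(diffs: np.ndarray) -> tuple[float, float]:
    """Two-sided one-sample t on paired differences; degenerate zero-variance
    vectors give (0, 1) when centered on zero."""
    diffs = np.asarray(diffs, dtype=float)
    if np.allclose(diffs.std(ddof=1) if len(diffs) > 1 else 0.0, 0.0):
        return (0.0, 1.0) if np.allclose(diffs.mean(), 0.0) else (np.inf, 0.0)
    res = stats.ttest_1samp(diffs, 0.0)
    return float(res.statistic), float(res.pvalue)


def crosslink_deregulated_to_binding(
    dereg: DeregulationCall,
    wt_track_values: dict[str, float],
    mut_track_values: dict[str, float],
    exclude_outliers: bool = True,
    subsets: dict[str, set[str]] | None = None,
    min_pairs: int = 3,
) -> dict:
    """Join deregulated genes to their binding scores and run paired t-tests.

    For each direction class (and each optional annotated subset, e.g. a
    ribosomal flag) the two-sided paired t-test compares mutant-protein
    vs wild-type-protein binding values.  Outlier pairs (difference
    beyond 1.5 x IQR of the differences) are excluded when requested;
    classes with fewer than *min_pairs* pairs skip the test.
    """
    rows = []
    for g, d in zip(dereg.gene_ids, dereg.direction):
        if d == "none":
            continue
        if g in wt_track_values and g in mut_track_values:
            rows.append((g, d, wt_track_values[g], mut_track_values[g]))
    out: dict = {"genes": rows, "tests": {}}

    def run(name: str, members: list[tuple[str, str, float, float]]):
        if len(members) < min_pairs:
            out["tests"][name] = {"n": len(members), "skipped": True}
            return
        diffs = np.array([m - w for _, _, w, m in members])
        if exclude_outliers and len(diffs) >= 4:
            q1, q3 = np.percentile(diffs, [25, 75])
            iqr = q3 - q1
            keep = (diffs >= q1 - 1.5 * iqr) & (diffs <= q3 + 1.5 * iqr)
            diffs = diffs[keep]
        if len(diffs) < min_pairs:
            out["tests"][name] = {"n": len(diffs), "skipped": True}
            return
        t, p = _paired_t(diffs)
        out["tests"][name] = {
            "n": len(diffs),
            "mean_difference": float(diffs.mean()),
            "t": t,
            "p": p,
            "skipped": False,
        }

    for direction in ("up", "down"):
        run(direction, [r for r in rows if r[1] == direction])
    for name, members in (subsets or {}).items():
        run(name, [r for r in rows if r[0] in members])
    return out
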