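"""End-to-end orchestration of the two analyses.

``run_binding_analysis`` covers the DamID binding arm: accessibility,
tracks at several resolutions, enrichment, genotype-differential
association, arm/center statistics, gene-level association calls and
set overlaps.  ``run_expression_analysis`` covers the RAPID arm:
expressed-gene calling, genotype deregulation and the crosslink back to
binding.  Both return JSON-serializable report dictionaries.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import damid_quant, enrichment_stats, rapid_expression, set_analysis
from .damid_quant import NormalizationParams
from .enrichment_stats import DifferentialAssociationParams
from .report import percent_change, round_half_up
from .synthetic_data import SyntheticStudy

logger = logging.getLogger(__name__)


@dataclass
class PipelineParams:
    bin_size_accessibility: int = 2000
    bin_size_association: int = 10_000
    pseudocount: float = 1.0
    fdr: float = 0.05
    min_abs_delta_log2: float = 0.58
    dereg_threshold: float = 1.0
    n_permutations: int = 300
    seed: int = 0

    def __post_init__(self):
        if self.fdr <= 0 or self.min_abs_delta_log2 <= 0 or self.dereg_threshold <= 0:
            raise ValueError("thresholds must be positive")


def _binned(study: SyntheticStudy, reps, grid):
    return [damid_quant.bin_counts(r, study.model, grid) for r in reps]


def _require(reps, what: str):
    if not reps:
        raise ValueError(f"missing samples: {what}")
    return reps


def run_binding_analysis(
    study: SyntheticStudy, params: PipelineParams | None = None
) -> dict:
    """DamID binding arm on a (synthetic or loaded) study.

    Produces, per tissue: normalized tracks and enrichment tables for
    both fusion proteins at the association resolution, differential
    association between genotypes, arm/center comparisons, gene-level
    association calls, the per-tissue Venn and the 4-set membership
    summary, plus the between-tissue accessibility comparison.
    """
    params = params or PipelineParams()
    model = study.model
    genome_length = model.genome_length()
    norm = NormalizationParams(pseudocount=params.pseudocount)
    report: dict = {
        "parameters": asdict(params),
        "genome_length": genome_length,
        "tissues": {},
    }
    results: dict = {"report": report, "tracks": {}, "diffassoc": {}, "gene_sets": {}}

    tissues = study.config.tissues
    grid_acc = model.bin_grid(params.bin_size_accessibility)
    gfp1 = _require(
        _binned(study, study.damid("GFP::Dam", tissues[0]), grid_acc),
        f"GFP::Dam in {tissues[0]}",
    )
    gfp2 = _require(
        _binned(study, study.damid("GFP::Dam", tissues[1]), grid_acc),
        f"GFP::Dam in {tissues[1]}",
    )
    acc = enrichment_stats.differential_accessibility(
        gfp1, gfp2, params.bin_size_accessibility, genome_length, fdr=params.fdr
    )
    report["accessibility"] = {
        "bin_size": params.bin_size_accessibility,
        f"bins_up_in_{tissues[0]}": acc.n_bins_up_in_1,
        f"bins_up_in_{tissues[1]}": acc.n_bins_up_in_2,
        f"percent_genome_{tissues[0]}": acc.percent_genome_1,
        f"percent_genome_{tissues[1]}": acc.percent_genome_2,
    }

    grid = model.bin_grid(params.bin_size_association)
    bin_labels = model.classify_bins(grid)
    gene_sets = []
    for tissue in tissues:
        control = _require(
            _binned(study, study.damid("GFP::Dam", tissue), grid),
            f"GFP::Dam in {tissue}",
        )
        tissue_report: dict = {}
        tracks = {}
        enrich = {}
        for protein in ("BAF-1", "BAF-1(G12T)"):
            fusion = _require(
                _binned(study, study.damid(protein, tissue), grid),
                f"{protein} in {tissue}",
            )
            enrich[protein] = enrichment_stats.nb_enrichment_test(
                fusion, control, fdr=params.fdr
            )
            tracks[protein] = damid_quant.normalize_ratio(
                fusion, control, norm, fusion_name=protein, tissue=tissue
            )
            comp = enrichment_stats.arm_center_compare(
                tracks[protein].values, bin_labels
            )
            tissue_report[protein] = {
                "n_enriched_bins": enrich[protein].n_enriched,
                "arm_center_medians": comp.medians,
                "arm_center_p": {
                    f"{a}_vs_{b}": (None if np.isnan(p) else float(p))
                    for (a, b), p in zip(comp.pairs, comp.p_values)
                },
            }

        diff = enrichment_stats.differential_association(
            enrich["BAF-1"],
            enrich["BAF-1(G12T)"],
            tracks["BAF-1"],
            tracks["BAF-1(G12T)"],
            DifferentialAssociationParams(params.fdr, params.min_abs_delta_log2),
            bin_labels=bin_labels,
        )
        n_autosomal_bins = sum(1 for l in bin_labels if l != "not_applicable")
        tissue_report["differential_association"] = {
            "n_preferential_BAF-1": len(diff.a_preferential),
            "n_preferential_BAF-1(G12T)": len(diff.b_preferential),
            "percent_autosomal_bins_BAF-1": (
                round_half_up(100.0 * len(diff.a_preferential) / n_autosomal_bins)
                if n_autosomal_bins
                else None
            ),
            "arm_summary": {
                k: {kk: (vv if not isinstance(vv, float) or np.isfinite(vv) else None)
                    for kk, vv in v.items()}
                for k, v in diff.arm_summary.items()
            },
        }

        # gene-level association calls
        gene_enrich = {}
        for protein in ("BAF-1", "BAF-1(G12T)"):
            fusion_frag = study.damid(protein, tissue)
            control_frag = study.damid("GFP::Dam", tissue)
            fus = [
                damid_quant.gene_counts(r, model, study.annotation)
                for r in fusion_frag
            ]
            ctl = [
                damid_quant.gene_counts(r, model, study.annotation)
                for r in control_frag
            ]
            gene_enrich[protein] = enrichment_stats.nb_enrichment_test(
                fus, ctl, fdr=params.fdr
            )
        calls = {
            protein: set_analysis.call_associated_genes(
                gene_enrich[protein],
                study.annotation.gene_ids,
                fdr=params.fdr,
                label=f"{protein}/{tissue}",
            )
            for protein in ("BAF-1", "BAF-1(G12T)")
        }
        gene_sets.extend(calls.values())
        venn = set_analysis.venn2(calls["BAF-1"], calls["BAF-1(G12T)"])
        tissue_report["associated_genes"] = {
            "BAF-1": len(calls["BAF-1"]),
            "BAF-1(G12T)": len(calls["BAF-1(G12T)"]),
            "venn": asdict(venn),
        }
        report["tissues"][tissue] = tissue_report
        results["tracks"][tissue] = tracks
        results["diffassoc"][tissue] = diff
        results["gene_sets"][tissue] = calls

    membership = set_analysis.multiset_membership(gene_sets)
    report["four_set_membership"] = {
        "n_union": membership.n_union,
        "n_at_least_two": membership.n_at_least_two,
        "n_unique": membership.n_unique,
        "n_all_four": membership.n_all,
        "pct_at_least_two": membership.pct_at_least_two,
        "pct_unique": membership.pct_unique,
    }
    results["membership"] = membership
    return results


def run_expression_analysis(
    study: SyntheticStudy, params: PipelineParams | None = None
) -> dict:
    """RAPID arm: expressed sets, deregulated genes, binding crosslink."""
    params = params or PipelineParams()
    model = study.model
    annotation = study.annotation
    genotypes = study.config.genotypes
    report: dict = {"parameters": asdict(params), "tissues": {}}
    results: dict = {"report": report, "tables": {}, "dereg": {}, "expressed": {}}

    norm = NormalizationParams(pseudocount=params.pseudocount)
    for tissue in study.config.tissues:
        tables = {}
        for genotype in genotypes:
            rpb6 = _require(
                study.rapid("RPB-6", tissue, genotype),
                f"RPB-6 {genotype} in {tissue}",
            )
            control = _require(
                study.rapid("GFP::Dam", tissue, genotype),
                f"GFP::Dam {genotype} in {tissue}",
            )
            table = rapid_expression.gene_occupancy(
                rpb6, control, model, annotation, pseudocount=params.pseudocount
            )
            rapid_expression.call_expressed(
                table,
                rpb6,
                control,
                model,
                annotation,
                fdr=params.fdr,
                n_permutations=params.n_permutations,
                rng=params.seed,
            )
            tables[genotype] = table
        expressed_union = (
            tables[genotypes[0]].expressed_genes()
            | tables[genotypes[1]].expressed_genes()
        )
        dereg = rapid_expression.call_deregulated(
            tables[genotypes[0]],
            tables[genotypes[1]],
            expressed_union,
            threshold=params.dereg_threshold,
        )

        # crosslink to wild-type vs mutant binding (gene-level tracks)
        wt_track = damid_quant.gene_level_values(
            study.damid("BAF-1", tissue),
            study.damid("GFP::Dam", tissue),
            model,
            annotation,
            norm,
            fusion_name="BAF-1",
            tissue=tissue,
        )
        mut_track = damid_quant.gene_level_values(
            study.damid("BAF-1(G12T)", tissue),
            study.damid("GFP::Dam", tissue),
            model,
            annotation,
            norm,
            fusion_name="BAF-1(G12T)",
            tissue=tissue,
        )
        crosslink = rapid_expression.crosslink_deregulated_to_binding(
            dereg,
            dict(zip(wt_track.gene_ids, wt_track.values)),
            dict(zip(mut_track.gene_ids, mut_track.values)),
        )
        report["tissues"][tissue] = {
            genotype: {
                "n_expressed": int(tables[genotype].expressed.sum()),
            }
            for genotype in genotypes
        }
        report["tissues"][tissue]["n_up"] = len(dereg.genes("up"))
        report["tissues"][tissue]["n_down"] = len(dereg.genes("down"))
        report["tissues"][tissue]["crosslink_tests"] = crosslink["tests"]
        results["tables"][tissue] = tables
        results["dereg"][tissue] = dereg
        results["expressed"][tissue] = {
            g: tables[g].expressed_genes() for g in genotypes
        }
    return results


def write_report(report: dict, path: str | Path) -> None:
    """Serialize a report dict deterministically."""
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    raise TypeError(f"not JSON serializable: {type(obj)!r}")


def lifespan_percent_reduction(before_days: float, after_days: float) -> float:
    """Percent reduction helper used in report summaries."""
    return percent_change(before_days, after_days, ndigits=0)
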