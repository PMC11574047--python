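import numpy as np
import pytest

from damidpipe.rapid_expression import (
    RapidGeneTable,
    call_deregulated,
    call_expressed,
    crosslink_deregulated_to_binding,
    gene_occupancy,
)
from damidpipe.synthetic_data import simulate_genome, substream

from conftest import small_config


def _flat_counts(rng, model, depth):
    """Flat NB counts over fragments, length-weighted."""
    lens = []
    for c in model.chrom_names:
        frags = model.fragments[c]
        lens.append(frags[:, 1] - frags[:, 0])
    w = np.concatenate(lens).astype(float)
    mean = w / w.sum() * depth
    r = 1 / 0.05
    return rng.negative_binomial(r, r / (r + mean))


class TestGeneOccupancy:
    def test_equal_counts_give_zero(self, toy_model, toy_genes):
        counts = np.arange(1, 11)
        table = gene_occupancy(
            [counts, counts], [counts, counts], toy_model, toy_genes,
            extension=0,
        )
        assert np.allclose(table.occupancy, 0.0)
        assert table.occupancy_reps.shape == (2, 2)

    def test_tenfold_excess_hand_arithmetic(self, toy_model, toy_genes):
        # gene A fragments carry 10x Pol II signal; matched control
        rpb6 = np.array([100, 100, 100, 100, 100, 10, 10, 10, 10, 10])
        gfp = np.full(10, 10)
        table = gene_occupancy([rpb6], [gfp], toy_model, toy_genes, extension=0)
        # hand chain: gene sums (500, 50) + 1 -> rel (501/552, 51/552)
        #             control (50, 50) + 1 -> rel (51/102, 51/102)
        exp_a = np.log2((501 / 552) / (51 / 102))
        exp_b = np.log2((51 / 552) / (51 / 102))
        assert np.allclose(table.occupancy, [exp_a, exp_b], atol=1e-12)
        # approximately log2(10) difference between the genes
        assert np.isclose(exp_a - exp_b, np.log2(501 / 51), atol=1e-12)

    def test_depth_invariance_at_zero_pseudocount(self, toy_model, toy_genes):
        rng = np.random.default_rng(0)
        rpb6 = rng.integers(1, 100, 10)
        gfp = rng.integers(1, 100, 10)
        t1 = gene_occupancy(
            [rpb6], [gfp], toy_model, toy_genes, pseudocount=0.0, extension=0
        )
        t2 = gene_occupancy(
            [rpb6 * 3], [gfp], toy_model, toy_genes, pseudocount=0.0, extension=0
        )
        assert np.allclose(t1.occupancy, t2.occupancy, atol=1e-12)

    def test_replicate_mismatch_raises(self, toy_model, toy_genes):
        with pytest.raises(ValueError, match="mismatch"):
            gene_occupancy(
                [np.ones(10)], [np.ones(10), np.ones(10)], toy_model, toy_genes
            )

    def test_empty_replicate_raises(self, toy_model, toy_genes):
        with pytest.raises(ValueError, match="zero total"):
            gene_occupancy([np.zeros(10)], [np.ones(10)], toy_model, toy_genes)


@pytest.fixture(scope="module")
def null_setup():
    config = small_config(seed=21, n_chromosomes=2, n_genes=200,
                          n_expressed_genes=0)
    model, annotation, _ = simulate_genome(config)
    rng = substream(21, "null_counts")
    rpb6 = [_flat_counts(rng, model, 300_000) for _ in range(2)]
    gfp = [_flat_counts(rng, model, 300_000) for _ in range(2)]
    return model, annotation, rpb6, gfp


class TestCallExpressed:

    def test_null_false_positive_control(self, null_setup):
        model, annotation, rpb6, gfp = null_setup
        table = gene_occupancy(rpb6, gfp, model, annotation)
        call_expressed(
            table, rpb6, gfp, model, annotation, n_permutations=200, rng=0
        )
        assert table.expressed.mean() <= 0.05

    def test_max_occupancy_gene_called_in_signal_run(self, study):
        tissue = study.config.tissues[0]
        rpb6 = study.rapid("RPB-6", tissue, "wild_type")
        gfp = study.rapid("GFP::Dam", tissue, "wild_type")
        table = gene_occupancy(rpb6, gfp, study.model, study.annotation)
        call_expressed(
            table, rpb6, gfp, study.model, study.annotation,
            n_permutations=150, rng=0,
        )
        assert table.expressed[np.argmax(table.occupancy)]
        # and recovery of the planted set is strong
        planted = study.ground_truth["expressed"][tissue]
        called = table.expressed_genes()
        assert len(called & planted) >= 0.9 * len(planted)
        assert len(called - planted) <= 0.05 * len(planted)

    def test_few_permutations_warn(self, null_setup):
        model, annotation, rpb6, gfp = null_setup
        table = gene_occupancy(rpb6, gfp, model, annotation)
        with pytest.warns(UserWarning, match="permutations"):
            call_expressed(
                table, rpb6, gfp, model, annotation, n_permutations=50, rng=0
            )

    def test_expressed_implies_q_and_positive_occupancy(self, study):
        tissue = study.config.tissues[0]
        rpb6 = study.rapid("RPB-6", tissue, "wild_type")
        gfp = study.rapid("GFP::Dam", tissue, "wild_type")
        table = gene_occupancy(rpb6, gfp, study.model, study.annotation)
        call_expressed(
            table, rpb6, gfp, study.model, study.annotation,
            n_permutations=150, rng=0,
        )
        assert np.all(table.q_value[table.expressed] < table.fdr)
        assert np.all(table.occupancy[table.expressed] > 0)

    def test_uncalled_table_raises(self):
        table = RapidGeneTable(["g"], np.zeros((2, 1)), np.zeros(1))
        with pytest.raises(ValueError, match="call_expressed"):
            table.expressed_genes()


def _tables(wt_reps, mut_reps, genes):
    wt = RapidGeneTable(genes, np.asarray(wt_reps, float),
                        np.asarray(wt_reps, float).mean(axis=0))
    mut = RapidGeneTable(genes, np.asarray(mut_reps, float),
                         np.asarray(mut_reps, float).mean(axis=0))
    return wt, mut


class TestCallDeregulated:
    def test_reproducible_up(self):
        wt, mut = _tables([[0.0], [0.0]], [[1.2], [1.4]], ["g"])
        call = call_deregulated(wt, mut, {"g"})
        assert call.direction.tolist() == ["up"]

    def test_inconsistent_replicas_none(self):
        wt, mut = _tables([[0.0], [0.0]], [[1.2], [0.3]], ["g"])
        call = call_deregulated(wt, mut, {"g"})
        assert call.direction.tolist() == ["none"]

    def test_down(self):
        wt, mut = _tables([[0.0], [0.0]], [[-1.5], [-1.1]], ["g"])
        call = call_deregulated(wt, mut, {"g"})
        assert call.direction.tolist() == ["down"]

    def test_threshold_strict(self):
        wt, mut = _tables([[0.0], [0.0]], [[1.0], [1.0]], ["g"])
        call = call_deregulated(wt, mut, {"g"})
        assert call.direction.tolist() == ["none"]

    def test_outside_expressed_union_none(self):
        wt, mut = _tables([[0.0], [0.0]], [[2.0], [2.0]], ["g"])
        call = call_deregulated(wt, mut, set())
        assert call.direction.tolist() == ["none"]

    def test_antisymmetry(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(50)]
        wt_reps = rng.normal(0, 1.5, (2, 50))
        mut_reps = rng.normal(0, 1.5, (2, 50))
        wt, mut = _tables(wt_reps, mut_reps, genes)
        fwd = call_deregulated(wt, mut, set(genes))
        rev = call_deregulated(mut, wt, set(genes))
        assert fwd.genes("up") == rev.genes("down")
        assert fwd.genes("down") == rev.genes("up")

    def test_all_pairs_mode_for_unequal_replicates(self):
        wt = RapidGeneTable(["g"], np.array([[0.0], [0.2]]),
                            np.array([0.1]))
        mut = RapidGeneTable(["g"], np.array([[1.5], [1.6], [1.4]]),
                             np.array([1.5]))
        call = call_deregulated(wt, mut, {"g"})
        assert call.delta_reps.shape == (6, 1)
        assert call.direction.tolist() == ["up"]

    def test_gene_universe_mismatch_raises(self):
        wt, _ = _tables([[0.0]], [[0.0]], ["a"])
        _, mut = _tables([[0.0]], [[0.0]], ["b"])
        with pytest.raises(ValueError, match="universes"):
            call_deregulated(wt, mut, set())


def _dereg(genes, direction):
    n = len(genes)
    return type(
        "D",
        (),
        {
            "gene_ids": genes,
            "direction": np.array([direction] * n),
        },
    )()


class TestCrosslink:
    def test_identical_tracks_give_null_t(self):
        genes = [f"g{i}" for i in range(10)]
        vals = {g: float(i) for i, g in enumerate(genes)}
        res = crosslink_deregulated_to_binding(
            _dereg(genes, "up"), vals, vals, exclude_outliers=False
        )
        assert res["tests"]["up"]["t"] == 0.0
        assert res["tests"]["up"]["p"] == 1.0

    def test_constant_shift_significant(self):
        genes = [f"g{i}" for i in range(13)]
        wt = {g: float(i) * 0.1 for i, g in enumerate(genes)}
        mut = {g: v + 0.5 for g, v in wt.items()}
        res = crosslink_deregulated_to_binding(_dereg(genes, "down"), wt, mut)
        t = res["tests"]["down"]
        assert np.isclose(t["mean_difference"], 0.5)
        assert t["p"] < 0.01

    def test_closed_form_paired_t(self):
        genes = ["a", "b", "c", "d", "e"]
        wt = {g: 0.0 for g in genes}
        diffs = np.array([0.1, 0.3, 0.2, 0.5, 0.4])
        mut = {g: d for g, d in zip(genes, diffs)}
        res = crosslink_deregulated_to_binding(
            _dereg(genes, "up"), wt, mut, exclude_outliers=False
        )
        # textbook: t = mean / (sd / sqrt(n))
        t_expected = diffs.mean() / (diffs.std(ddof=1) / np.sqrt(5))
        assert np.isclose(res["tests"]["up"]["t"], t_expected, atol=1e-12)

    def test_disjoint_universes_skip(self):
        res = crosslink_deregulated_to_binding(
            _dereg(["a", "b", "c"], "up"), {"x": 1.0}, {"x": 2.0}
        )
        assert res["tests"]["up"]["skipped"]

    def test_too_few_pairs_skip(self):
        res = crosslink_deregulated_to_binding(
            _dereg(["a", "b"], "up"), {"a": 1.0, "b": 2.0},
            {"a": 1.5, "b": 2.5},
        )
        assert res["tests"]["up"]["skipped"]

    def test_outlier_exclusion(self):
        genes = [f"g{i}" for i in range(20)]
        wt = {g: 0.0 for g in genes}
        mut = {g: 0.5 for g in genes}
        mut["g0"] = 50.0  # wild outlier
        res = crosslink_deregulated_to_binding(_dereg(genes, "up"), wt, mut)
        assert res["tests"]["up"]["n"] == 19
        assert np.isclose(res["tests"]["up"]["mean_difference"], 0.5)

    def test_ribosomal_subset(self):
        genes = [f"g{i}" for i in range(10)]
        wt = {g: float(i) * 0.1 for i, g in enumerate(genes)}
        mut = {g: v + 1.0 for g, v in wt.items()}
        res = crosslink_deregulated_to_binding(
            _dereg(genes, "up"), wt, mut, exclude_outliers=False,
            subsets={"ribosomal": {"g1", "g2", "g3", "g4"}},
        )
        assert res["tests"]["ribosomal"]["n"] == 4
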