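import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from damidpipe.damid_quant import NormalizedRatioTrack
from damidpipe.enrichment_stats import (
    DifferentialAssociationParams,
    arm_center_compare,
    benjamini_hochberg,
    differential_accessibility,
    differential_association,
    median_of_ratios_size_factors,
    nb_enrichment_test,
    percent_of_genome,
)
from damidpipe.genome_model import CE11_GENOME_LENGTH


def bh_bruteforce(p):
    """Independent step-up oracle: q_(i) = min_{j>=i} p_(j) * n / j."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(n)
    for rank_pos, idx in enumerate(order):
        candidates = [
            p[order[j]] * n / (j + 1) for j in range(rank_pos, n)
        ]
        q[idx] = min(1.0, min(candidates))
    return q


class TestBenjaminiHochberg:
    def test_hand_example(self):
        q = benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        assert np.allclose(benjamini_hochberg([1.0, 1.0, 1.0]), 1.0)

    def test_single_p(self):
        assert benjamini_hochberg([0.3]).tolist() == [0.3]

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.5])
        with pytest.raises(ValueError):
            benjamini_hochberg([-0.1])

    def test_empty(self):
        assert benjamini_hochberg([]).size == 0

    def test_q_at_least_p_and_monotone(self):
        rng = np.random.default_rng(11)
        p = rng.random(200)
        q = benjamini_hochberg(p)
        assert np.all(q >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_matches_bruteforce_on_random_vectors(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(1, 21))
            p = rng.random(n)
            assert np.allclose(benjamini_hochberg(p), bh_bruteforce(p))

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    @settings(max_examples=100)
    def test_matches_bruteforce_property(self, p):
        assert np.allclose(benjamini_hochberg(p), bh_bruteforce(p))


class TestSizeFactors:
    def test_equal_libraries_give_unit_factors(self):
        rng = np.random.default_rng(0)
        col = rng.integers(1, 100, 50).astype(float)
        counts = np.stack([col, col, col], axis=1)
        assert np.allclose(median_of_ratios_size_factors(counts), 1.0)

    def test_scaled_library_detected(self):
        rng = np.random.default_rng(1)
        col = rng.integers(10, 100, 200).astype(float)
        counts = np.stack([col, 3 * col], axis=1)
        sf = median_of_ratios_size_factors(counts)
        assert np.isclose(sf[1] / sf[0], 3.0)


def nb_draw(rng, mean, dispersion, size=None):
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mean), size)


class TestNbEnrichmentTest:
    def test_identical_matrices_give_no_calls(self):
        rng = np.random.default_rng(2)
        reps = [nb_draw(rng, 100.0, 0.1, 300) for _ in range(3)]
        table = nb_enrichment_test(reps, reps)
        assert table.n_enriched == 0
        assert np.allclose(table.log2_fold, 0.0, atol=1e-6)

    def test_null_simulation_calibration(self):
        # under the complete null the q<0.05 fraction stays within noise
        for seed in (1, 2, 3):
            rng = np.random.default_rng(seed)
            fus = [nb_draw(rng, 100.0, 0.1, 1000) for _ in range(3)]
            ctl = [nb_draw(rng, 100.0, 0.1, 1000) for _ in range(3)]
            table = nb_enrichment_test(fus, ctl)
            assert (table.q_value < 0.05).mean() <= 0.05

    def test_planted_signal_recovery(self):
        rng = np.random.default_rng(7)
        mu_c = np.full(1000, 100.0)
        mu_f = mu_c.copy()
        mu_f[:50] *= 8
        fus = [nb_draw(rng, mu_f, 0.05) for _ in range(3)]
        ctl = [nb_draw(rng, mu_c, 0.05) for _ in range(3)]
        table = nb_enrichment_test(fus, ctl)
        assert table.enriched[:50].sum() >= 45
        # regression pin at this seed
        assert table.enriched[:50].sum() == 50
        assert table.enriched[50:].sum() <= 2

    def test_all_zero_bins_get_p_one(self):
        fus = [np.array([0, 10, 20])] * 2
        ctl = [np.array([0, 10, 20])] * 2
        table = nb_enrichment_test(fus, ctl)
        assert table.p_value[0] == 1.0
        assert not table.enriched[0]

    def test_mismatched_lengths_raise(self):
        with pytest.raises(ValueError):
            nb_enrichment_test([np.ones(5)], [np.ones(4)])

    def test_single_replicate_poisson_fallback(self):
        rng = np.random.default_rng(8)
        fus = [rng.poisson(100, 100)]
        ctl = [rng.poisson(100, 100)]
        table = nb_enrichment_test(fus, ctl)
        assert table.method == "poisson_wald"
        assert (table.q_value < 0.05).mean() <= 0.05

    def test_one_sided_flag(self):
        # depleted bins are significant but never flagged enriched
        rng = np.random.default_rng(9)
        mu_f = np.full(500, 100.0)
        mu_f[:20] /= 8
        fus = [nb_draw(rng, mu_f, 0.02) for _ in range(3)]
        ctl = [nb_draw(rng, np.full(500, 100.0), 0.02) for _ in range(3)]
        table = nb_enrichment_test(fus, ctl)
        assert not table.enriched[:20].any()
        assert (table.q_value[:20] < 0.05).sum() >= 15


class TestDifferentialAccessibility:
    def test_identical_tissues(self):
        rng = np.random.default_rng(3)
        reps = [nb_draw(rng, 50.0, 0.05, 400) for _ in range(3)]
        res = differential_accessibility(reps, reps, 2000, 800_000)
        assert res.n_bins_up_in_1 == 0
        assert res.n_bins_up_in_2 == 0

    def test_planted_recovery(self):
        rng = np.random.default_rng(4)
        n = 1000
        mu1 = np.full(n, 1000.0)  # ~1e6 reads per replicate over 1000 bins
        mu1[:20] *= 4  # 2% of bins more accessible in tissue 1
        t1 = [nb_draw(rng, mu1, 0.05) for _ in range(3)]
        t2 = [nb_draw(rng, np.full(n, 1000.0), 0.05) for _ in range(3)]
        res = differential_accessibility(t1, t2, 2000, 2_000_000)
        recovered = res.table_1_over_2.enriched[:20].sum()
        assert recovered >= 18  # >= 0.9 sensitivity
        assert res.table_1_over_2.enriched[20:].sum() <= 2

    def test_percent_arithmetic(self):
        assert percent_of_genome(1924, 2000, 100_286_401, ndigits=1) == 3.8

    def test_percent_of_genome_exact(self):
        assert percent_of_genome(10, 2000, 1_000_000) == 2.0
        assert (
            percent_of_genome(1924, 2000, CE11_GENOME_LENGTH)
            == 100.0 * 1924 * 2000 / CE11_GENOME_LENGTH
        )


def _track(values):
    return NormalizedRatioTrack(np.asarray(values, dtype=float), "bin")


def _table(enriched):
    from damidpipe.enrichment_stats import EnrichmentTable

    e = np.asarray(enriched, dtype=bool)
    n = len(e)
    return EnrichmentTable(
        base_mean=np.ones(n),
        log2_fold=np.where(e, 1.0, 0.0),
        p_value=np.full(n, 0.5),
        q_value=np.where(e, 0.01, 0.5),
        enriched=e,
        fdr=0.05,
    )


class TestDifferentialAssociation:
    def test_equal_tracks_give_empty_sets(self):
        t = _track([0.1, 0.2, 0.3])
        res = differential_association(
            _table([1, 1, 1]), _table([1, 1, 1]), t, t
        )
        assert res.a_preferential.size == 0
        assert res.b_preferential.size == 0

    def test_threshold_is_strict(self):
        ta = _track([0.58, 1.0])
        tb = _track([0.0, 0.0])
        res = differential_association(
            _table([1, 1]), _table([0, 0]), ta, tb
        )
        assert res.a_preferential.tolist() == [1]

    def test_sets_disjoint(self):
        rng = np.random.default_rng(5)
        va, vb = rng.normal(0, 1, 100), rng.normal(0, 1, 100)
        res = differential_association(
            _table(rng.random(100) < 0.5),
            _table(rng.random(100) < 0.5),
            _track(va),
            _track(vb),
        )
        assert not set(res.a_preferential) & set(res.b_preferential)

    def test_requires_enrichment(self):
        ta, tb = _track([2.0]), _track([0.0])
        res = differential_association(_table([0]), _table([0]), ta, tb)
        assert res.a_preferential.size == 0

    def test_arm_summary_binomial(self):
        labels = ["arm"] * 50 + ["center"] * 50
        ta = _track([1.0] * 50 + [0.0] * 50)
        tb = _track([0.0] * 100)
        enr = _table([1] * 50 + [0] * 50)
        res = differential_association(
            enr, _table([0] * 100), ta, tb, bin_labels=labels
        )
        s = res.arm_summary["a_preferential"]
        assert s["n_arm"] == 50 and s["arm_fraction"] == 1.0
        assert s["binom_p"] < 1e-10  # all 50 in arms vs null 0.5

    def test_grid_mismatch_raises(self):
        with pytest.raises(ValueError, match="grid"):
            differential_association(
                _table([1]), _table([1]), _track([0.0]), _track([0.0, 1.0])
            )


def rank_sum_exact_oracle(x, y):
    """Two-sided rank-sum p by full enumeration (tiny n, no ties)."""
    pooled = np.concatenate([x, y])
    nx = len(x)
    obs_u = sum(sum(u > v for v in y) for u in x)
    count = 0
    total = 0
    for comb in itertools.combinations(range(len(pooled)), nx):
        sel = set(comb)
        xs = pooled[list(comb)]
        ys = pooled[[i for i in range(len(pooled)) if i not in sel]]
        u = sum(sum(a > b for b in ys) for a in xs)
        mean_u = nx * len(y) / 2
        if abs(u - mean_u) >= abs(obs_u - mean_u) - 1e-12:
            count += 1
        total += 1
    return count / total


class TestArmCenterCompare:
    def test_shift_detected(self):
        rng = np.random.default_rng(6)
        center = rng.normal(0, 1, 150)
        arm = center + 1.0
        values = np.concatenate([arm, center])
        labels = ["arm"] * 150 + ["center"] * 150
        comp = arm_center_compare(values, labels)
        assert np.isclose(comp.medians["arm"] - comp.medians["center"], 1.0)
        assert comp.p_values[0] < 0.01

    def test_identical_distributions(self):
        rng = np.random.default_rng(7)
        vals = rng.normal(0, 1, 200)
        labels = ["arm"] * 100 + ["center"] * 100
        comp = arm_center_compare(vals, labels)
        assert comp.p_values[0] > 0.01
        assert abs(comp.medians["arm"] - comp.medians["center"]) < 0.5

    def test_single_group_has_no_pairs(self):
        comp = arm_center_compare(np.arange(10.0), ["arm"] * 10)
        assert comp.pairs == []
        assert comp.p_values.size == 0

    def test_small_group_gives_missing_p(self):
        comp = arm_center_compare(
            np.array([1.0, 2.0, 3.0]), ["arm", "center", "center"]
        )
        assert np.isnan(comp.p_values[0])

    def test_not_applicable_dropped(self):
        vals = np.array([1.0, 2.0, 100.0, 3.0, 4.0, 200.0])
        labels = ["arm", "arm", "not_applicable", "center", "center",
                  "not_applicable"]
        comp = arm_center_compare(vals, labels)
        assert comp.n == {"arm": 2, "center": 2}

    def test_exact_branch_matches_enumeration_oracle(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0, 1, 6)
        y = rng.normal(0.5, 1, 6)
        comp = arm_center_compare(
            np.concatenate([x, y]), ["arm"] * 6 + ["center"] * 6
        )
        assert np.isclose(comp.p_values[0], rank_sum_exact_oracle(x, y))
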