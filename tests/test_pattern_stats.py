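import numpy as np
import pandas as pd
import pytest

from slicepattern import pattern_stats, synthetic
from slicepattern.pattern_stats import (average_pattern, change_flags,
                                        classify_cohort, classify_pattern,
                                        cluster_genes, co_change_test,
                                        delta_d, delta_d_table, level_response,
                                        pattern_change, pattern_change_table,
                                        top_changed_genes, transition_table)
from slicepattern.synthetic import (CohortConfig, EmbryoSample, GenotypeEffect,
                                    PatternSpec, generate_cohort)


def make_embryo(values, embryo_id="e1", genotype="wt", stage=14, qc_mask=None):
    values = np.asarray(values, dtype=float)
    if qc_mask is None:
        qc_mask = np.ones(values.shape[1], dtype=bool)
    gene_ids = tuple(f"g{i}" for i in range(values.shape[0]))
    return EmbryoSample(embryo_id, genotype, stage, gene_ids, values, qc_mask)


class TestClassifyPattern:
    def test_low_expression_below_floor_in_every_replicate(self):
        embryos = [make_embryo(np.full((1, 8), 10.0), "a"),
                   make_embryo(np.full((1, 8), 14.0), "b")]
        out = classify_pattern("g0", embryos)
        assert out.label == "low_expression"
        assert out.emd_to_uniform is None

    def test_flat_expressed_profile_is_uniform(self):
        embryos = [make_embryo(np.full((1, 10), 50.0))]
        out = classify_pattern("g0", embryos)
        assert out.label == "uniform" and out.emd_to_uniform == 0.0

    def test_single_slice_spike_is_patterned(self):
        values = np.zeros((1, 27))
        values[0, 13] = 100.0
        out = classify_pattern("g0", [make_embryo(values)])
        assert out.label == "patterned"
        assert out.emd_to_uniform > 0.08

    def test_no_embryos_raises(self):
        with pytest.raises(ValueError):
            classify_pattern("g0", [])

    def test_cohort_classification_matches_per_gene(self, small_cohort):
        _, embryos, _ = small_cohort
        wt = [e for e in embryos if e.genotype == "wt" and e.stage == 14]
        table = classify_cohort(wt).set_index("gene_id")
        for gene in wt[0].gene_ids[::7]:
            single = classify_pattern(gene, wt)
            assert table.loc[gene, "label"] == single.label
            if single.emd_to_uniform is not None:
                assert table.loc[gene, "emd_to_uniform"] == pytest.approx(
                    single.emd_to_uniform, abs=1e-12)


def _classes(labels):
    return pd.DataFrame({
        "gene_id": [f"g{i}" for i in range(len(labels))],
        "genotype": "x", "label": labels,
        "emd_to_uniform": [0.0] * len(labels)})


class TestTransitionTable:
    def test_toy_counts(self):
        wt = _classes(["patterned", "uniform", "patterned"])
        mut = _classes(["uniform", "patterned", "patterned"])
        t = transition_table(wt, mut)
        assert (t.low_to_patterned, t.patterned_to_uniform,
                t.patterned_to_low, t.uniform_to_patterned) == (0, 1, 0, 1)
        assert t.remainder == 1

    def test_identical_classes_all_transition_cells_zero(self):
        wt = _classes(["patterned", "uniform", "low_expression", "patterned"])
        t = transition_table(wt, wt)
        assert (t.low_to_patterned == t.patterned_to_uniform
                == t.patterned_to_low == t.uniform_to_patterned == 0)

    def test_total_equals_expressed_universe(self):
        wt = _classes(["patterned", "low_expression", "uniform", "ambiguous",
                       "low_expression"])
        mut = _classes(["uniform", "low_expression", "patterned", "uniform",
                        "patterned"])
        t = transition_table(wt, mut)
        assert t.total == 4  # gene g1 is low in both genotypes

    def test_ambiguous_excluded_from_named_cells(self):
        wt = _classes(["patterned", "ambiguous"])
        mut = _classes(["ambiguous", "patterned"])
        t = transition_table(wt, mut)
        assert t.excluded_ambiguous == 2
        assert t.patterned_to_uniform == 0

    def test_mismatched_gene_sets(self):
        wt = _classes(["patterned"] * 3)
        mut = _classes(["uniform"] * 4)
        with pytest.raises(ValueError):
            transition_table(wt, mut)

    def test_planted_uniformize_and_loss_recovered_exactly_at_sigma0(self):
        specs = []
        effects = {}
        for i in range(30):
            g = f"g{i:04d}"
            specs.append(PatternSpec(
                g, "anterior_domain",
                {"amplitude": 150.0, "center": 0.2, "width": 0.06},
                baseline=1.0))
            if i < 8:
                effects[(g, "bcd_minus")] = GenotypeEffect(
                    g, "bcd_minus", "uniformize")
            elif i < 13:
                effects[(g, "bcd_minus")] = GenotypeEffect(
                    g, "bcd_minus", "loss_to_low")
        config = CohortConfig(n_genes=30, genotypes=("wt", "bcd_minus"),
                              noise_sigma=0.0, qc_fail_rate=0.0, seed=2)
        embryos, _ = generate_cohort(config, specs=specs, effects=effects)
        wt_cls = classify_cohort([e for e in embryos
                                  if e.genotype == "wt" and e.stage == 14])
        mut_cls = classify_cohort([e for e in embryos
                                   if e.genotype == "bcd_minus" and e.stage == 14])
        t = transition_table(wt_cls, mut_cls)
        assert t.patterned_to_uniform == 8
        assert t.patterned_to_low == 5
        assert t.low_to_patterned == 0 and t.uniform_to_patterned == 0


class TestPatternChange:
    def test_same_embryos_zero(self):
        e = make_embryo(np.random.default_rng(0).random((5, 10)) * 100)
        table = pattern_change_table([e], [e])
        assert np.allclose(table["emd"].dropna(), 0.0)

    def test_sigma0_replicates_zero(self, noiseless_cohort):
        _, embryos, _ = noiseless_cohort
        reps = [e for e in embryos if e.genotype == "wt" and e.stage == 14]
        # different slice counts -> small discretisation residue only
        table = pattern_change_table(reps[:1], reps[1:])
        assert table["emd"].dropna().max() < 0.03

    def test_translation_by_two_slices_of_twenty(self):
        n = 20
        x = (np.arange(n) + 0.5) / n
        base = 100 * np.exp(-((x - 0.3) / 0.05) ** 2 / 2)
        shifted = 100 * np.exp(-((x - 0.4) / 0.05) ** 2 / 2)
        a = make_embryo(base[None, :], "a")
        b = make_embryo(shifted[None, :], "b")
        assert pattern_change("g0", [a], [b]) == pytest.approx(0.1, abs=5e-3)

    def test_unexpressed_in_both_is_none(self):
        a = make_embryo(np.full((1, 8), 5.0), "a")
        b = make_embryo(np.full((1, 8), 6.0), "b")
        assert pattern_change("g0", [a], [b]) is None

    def test_cross_pair_mean_aggregation(self):
        rng = np.random.default_rng(1)
        groups = [[make_embryo(rng.random((3, 10)) * 50 + 20, f"a{i}")
                   for i in range(2)],
                  [make_embryo(rng.random((3, 12)) * 50 + 20, f"b{i}")
                   for i in range(2)]]
        table = pattern_change_table(*groups).set_index("gene_id")
        singles = np.stack([
            pattern_change_table([a], [b]).set_index("gene_id")["emd"]
            for a in groups[0] for b in groups[1]])
        np.testing.assert_allclose(table["emd"], singles.mean(axis=0))


class TestDeltaD:
    def test_m1_equals_m2_gives_zero(self):
        rng = np.random.default_rng(3)
        wt = make_embryo(rng.random((4, 10)) * 100 + 20, "wt")
        m = make_embryo(rng.random((4, 11)) * 100 + 20, "m")
        rec = delta_d("g0", [wt], [m], [m])
        assert rec.delta_d == pytest.approx(0.0, abs=1e-12)
        assert rec.d_m1_m2 == 0.0

    def test_m1_equals_wt_gives_zero(self):
        rng = np.random.default_rng(4)
        wt = make_embryo(rng.random((4, 10)) * 100 + 20, "wt")
        m2 = make_embryo(rng.random((4, 9)) * 100 + 20, "m2")
        rec = delta_d("g0", [wt], [wt], [m2])
        assert rec.delta_d == pytest.approx(0.0, abs=1e-12)

    def test_nonnegative_and_bounded_on_random_triples(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            wt = make_embryo(rng.random((2, int(rng.integers(5, 15)))) * 100 + 16, "wt")
            m1 = make_embryo(rng.random((2, int(rng.integers(5, 15)))) * 100 + 16, "m1")
            m2 = make_embryo(rng.random((2, int(rng.integers(5, 15)))) * 100 + 16, "m2")
            table = delta_d_table([wt], [m1], [m2])
            assert (table["delta_d"] >= -1e-12).all()
            assert (table["delta_d"] <= table["d_m1_m2"] + 1e-12).all()

    def test_missing_genotype_group(self):
        e = make_embryo(np.full((1, 8), 20.0))
        with pytest.raises(ValueError, match="m2"):
            delta_d_table([e], [e], [])


class TestChangeFlags:
    def test_top_20_percent_of_1_to_10(self):
        s = pd.Series(range(1, 11), index=[f"g{i}" for i in range(10)],
                      dtype=float)
        flags = change_flags(s, 0.8)
        assert flags.sum() == 2
        assert set(flags[flags].index) == {"g8", "g9"}

    def test_constant_vector_flags_nothing(self):
        s = pd.Series(5.0, index=[f"g{i}" for i in range(10)])
        with pytest.warns(UserWarning):
            flags = change_flags(s)
        assert not flags.any()

    def test_fraction_close_to_quantile_for_continuous_values(self):
        rng = np.random.default_rng(6)
        s = pd.Series(rng.random(1000))
        flags = change_flags(s, 0.8)
        assert flags.sum() == 200

    def test_boundary_ties_included(self):
        s = pd.Series([1, 2, 3, 4, 5, 6, 7, 9, 9, 9], dtype=float)
        assert change_flags(s, 0.8).sum() == 3

    def test_too_few_genes(self):
        with pytest.raises(ValueError):
            change_flags(pd.Series([1.0, 2.0]))


class TestCoChange:
    def test_independent_table_chi2_zero(self):
        idx = [f"g{i}" for i in range(200)]
        a = pd.Series([True] * 100 + [False] * 100, index=idx)
        b = pd.Series(([True] * 50 + [False] * 50) * 2, index=idx)
        chi2, p, ratio = co_change_test(a, b)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert ratio == pytest.approx(1.0)

    def test_hand_computed_90_10_table(self):
        idx = [f"g{i}" for i in range(200)]
        a = pd.Series([True] * 100 + [False] * 100, index=idx)
        b = pd.Series([True] * 90 + [False] * 10 + [True] * 10 + [False] * 90,
                      index=idx)
        chi2, p, ratio = co_change_test(a, b)
        assert chi2 == pytest.approx(128.0)
        assert p < 1e-28

    def test_correlated_cohort_ratio_exceeds_one(self):
        rng = np.random.default_rng(7)
        n = 1000
        latent = rng.random(n) < 0.2
        a = latent | (rng.random(n) < 0.05)
        b = latent | (rng.random(n) < 0.05)
        idx = [f"g{i}" for i in range(n)]
        _, p, ratio = co_change_test(pd.Series(a, index=idx),
                                     pd.Series(b, index=idx))
        assert ratio > 1.5 and p < 1e-10

    def test_zero_margin_rejected(self):
        idx = list("abcdef")
        a = pd.Series([True] * 6, index=idx)
        b = pd.Series([True, False] * 3, index=idx)
        with pytest.raises(ValueError, match="margin"):
            co_change_test(a, b)


class TestTopChanged:
    def test_ordering(self):
        s = pd.Series({"g_1": 1.0, "g_2": 2.0, "g_3": 3.0})
        assert top_changed_genes(s, 2) == ["g_3", "g_2"]

    def test_ties_broken_lexicographically(self):
        s = pd.Series({"b": 1.0, "a": 1.0, "c": 2.0})
        assert top_changed_genes(s, 2) == ["c", "a"]

    def test_n_larger_than_universe(self):
        with pytest.raises(ValueError):
            top_changed_genes(pd.Series({"a": 1.0}), 5)


class TestAveragePattern:
    def test_single_gene_returns_its_normalized_profile(self):
        e = make_embryo(np.array([[10.0, 50.0, 25.0, 0.0]]))
        np.testing.assert_allclose(average_pattern(["g0"], e),
                                   [0.2, 1.0, 0.5, 0.0])

    def test_mirror_gradients_average_flat(self):
        e = make_embryo(np.array([[40.0, 30.0, 20.0, 10.0],
                                  [10.0, 20.0, 30.0, 40.0]]))
        np.testing.assert_allclose(average_pattern(["g0", "g1"], e),
                                   np.full(4, 0.625))

    def test_empty_gene_list(self):
        e = make_embryo(np.ones((2, 5)))
        with pytest.raises(ValueError):
            average_pattern([], e)


class TestClusterGenes:
    def _embryos(self):
        n = 20
        x = (np.arange(n) + 0.5) / n
        ant = 100 * np.exp(-((x - 0.15) / 0.08) ** 2 / 2)
        post = 100 * np.exp(-((x - 0.85) / 0.08) ** 2 / 2)
        values = np.stack([ant, ant * 1.1, ant * 0.9, post, post * 1.2, post])
        return [make_embryo(values, "e1"), make_embryo(values, "e2")]

    def test_duplicate_genes_merge_first_at_height_zero(self):
        embryos = self._embryos()
        gene_ids, linkage, _ = cluster_genes(embryos)
        # g3 and g5 are exact duplicates (same mass distribution as g4 too)
        assert linkage[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_anterior_and_posterior_classes_separate(self):
        gene_ids, linkage, leaf_order = cluster_genes(self._embryos())
        ordered = [gene_ids[i] for i in leaf_order]
        ant = {"g0", "g1", "g2"}
        first3 = set(ordered[:3])
        assert first3 == ant or first3 == {"g3", "g4", "g5"}
        # final merge joins the two classes at a large height
        assert linkage[-1, 2] > 0.3

    def test_row_permutation_invariance(self):
        embryos = self._embryos()
        perm = [3, 0, 5, 2, 4, 1]
        permuted = [EmbryoSample(e.embryo_id, e.genotype, e.stage,
                                 tuple(e.gene_ids[i] for i in perm),
                                 e.values[perm], e.qc_mask)
                    for e in embryos]
        out1 = cluster_genes(embryos)
        out2 = cluster_genes(permuted)
        assert out1[0] == out2[0]
        np.testing.assert_allclose(out1[1], out2[1])

    def test_needs_two_expressed_genes(self):
        e = make_embryo(np.full((2, 8), 1.0))
        with pytest.raises(ValueError):
            cluster_genes([e])


class TestLevelResponse:
    def test_counting_rules(self):
        wt = [make_embryo(np.array([[10.0], [10.0], [10.0]]) * np.ones(8), "wt")]
        up = [make_embryo(np.array([[20.0], [20.0], [5.0]]) * np.ones(8), "up")]
        down = [make_embryo(np.array([[20.0], [5.0], [5.0]]) * np.ones(8), "dn")]
        n_up, n_down = level_response(wt, up, down)
        assert (n_up, n_down) == (1, 1)

    def test_boundary_fold_inclusive(self):
        wt = [make_embryo(np.full((1, 6), 10.0), "wt")]
        mut = [make_embryo(np.full((1, 6), 15.0), "m")]
        assert level_response(wt, mut, mut) == (1, 0)

    def test_fold_must_exceed_one(self):
        e = make_embryo(np.ones((1, 6)))
        with pytest.raises(ValueError):
            level_response([e], [e], [e], fold=1.0)
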