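import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import spotfactor as sf
from spotfactor import downstream as d
from spotfactor.errors import ContractError


def cm_from_counts(counts, section="s"):
    counts = np.asarray(counts)
    S, G = counts.shape
    return sf.CountMatrix(
        [f"g{i:03d}" for i in range(G)],
        [sf.SpotId(section, i % 50, i // 50) for i in range(S)],
        counts,
    )


class TestQcFilterSpots:
    def test_equal_libraries_keep_everything(self):
        cm = cm_from_counts(np.full((6, 3), 5))
        assert d.qc_filter_spots(cm).n_spots == 6

    def test_spiked_low_depth_spot_removed(self):
        # nine spots at library e^10, one at e^1: only the low one drops
        sizes = [22026] * 9 + [3]
        counts = np.array(sizes)[:, None] * np.ones((10, 1), dtype=int)
        cm = cm_from_counts(counts)
        kept = d.qc_filter_spots(cm)
        assert kept.n_spots == 9
        assert all(s.token != cm.spots[9].token for s in kept.spots)

    def test_invariant_under_global_scaling(self, rng):
        counts = rng.integers(1, 30, size=(8, 5))
        cm1 = cm_from_counts(counts)
        cm2 = cm_from_counts(counts * 10)
        kept1 = {s.token for s in d.qc_filter_spots(cm1).spots}
        kept2 = {s.token for s in d.qc_filter_spots(cm2).spots}
        assert kept1 == kept2


class TestFilterGenes:
    def test_totals_threshold(self):
        cm = cm_from_counts(np.array([[0, 1, 2], [0, 0, 3]]))
        assert d.filter_genes(cm, min_total=2).genes == ["g002"]
        assert d.filter_genes(cm, min_total=1).genes == ["g001", "g002"]
        assert d.filter_genes(cm, min_total=0).genes == cm.genes

    def test_commutes_with_spot_filter(self, rng):
        counts = rng.integers(0, 12, size=(10, 8))
        counts[3] = 0  # one empty spot
        cm = cm_from_counts(counts)
        a = d.filter_genes(d.qc_filter_spots(cm), min_total=3)
        b = d.qc_filter_spots(d.filter_genes(cm, min_total=3))
        assert a.genes == b.genes and a.spots == b.spots


class TestNormalization:
    def test_cpm_simple_row(self):
        nm = d.normalize_cpm(cm_from_counts([[1, 1]]))
        assert np.allclose(nm.values, [[5e5, 5e5]])

    def test_cpm_scale_invariance_and_row_sums(self, rng):
        counts = rng.integers(1, 40, size=(6, 7))
        nm1 = d.normalize_cpm(cm_from_counts(counts))
        nm2 = d.normalize_cpm(cm_from_counts(counts * 10))
        assert np.allclose(nm1.values, nm2.values)
        assert np.allclose(nm1.values.sum(axis=1), 1e6, atol=1e-6)

    def test_cpm_zero_library_names_spot(self):
        cm = cm_from_counts([[1, 2], [0, 0]])
        with pytest.raises(ContractError, match="1x0"):
            d.normalize_cpm(cm)

    def test_pooled_factors_identical_spots_are_one(self):
        cm = cm_from_counts(np.tile([3, 7, 2], (12, 1)))
        f = d.pooled_size_factors(cm, pool_sizes=(3, 5))
        assert np.allclose(f, 1.0)

    def test_pooled_factors_recover_proportional_depths(self, rng):
        k = rng.uniform(0.5, 2.0, 24)
        profile = rng.integers(5, 60, 40)
        counts = np.rint(np.outer(k, profile)).astype(int)
        cm = cm_from_counts(counts)
        f = d.pooled_size_factors(cm, pool_sizes=(5, 7))
        target = counts.sum(axis=1) / counts.sum(axis=1).mean()
        assert np.corrcoef(f, target)[0, 1] > 0.999

    def test_pooled_factors_mean_is_one(self, rng):
        counts = rng.integers(1, 25, size=(15, 10))
        f = d.pooled_size_factors(cm_from_counts(counts), pool_sizes=(4, 6))
        assert abs(f.mean() - 1.0) < 1e-9
        assert np.all(f > 0)


class TestVariableGenesAndPca:
    def test_hand_variances_rank(self):
        # three genes with log1p variances 0 < g2 < g1
        vals = np.array([[0.0, 10.0, 3.0], [0.0, 90.0, 9.0], [0.0, 40.0, 5.0]])
        nm = d.NormalizedMatrix(vals, ["a", "b", "c"],
                                [sf.SpotId("s", i, 0) for i in range(3)], "cpm")
        assert d.top_variable_genes(nm, 2) == ["b", "c"]
        assert d.top_variable_genes(nm, 3) == ["b", "c", "a"]

    def test_constant_gene_never_precedes_varying(self, rng):
        vals = np.column_stack([np.full(8, 4.0), rng.uniform(0, 5, 8)])
        nm = d.NormalizedMatrix(vals, ["const", "vary"],
                                [sf.SpotId("s", i, 0) for i in range(8)], "cpm")
        assert d.top_variable_genes(nm, 1) == ["vary"]

    def test_pca_separates_duplicated_groups(self):
        X = np.vstack([np.tile([5.0, 0.0, 1.0], (4, 1)), np.tile([0.0, 5.0, 1.0], (4, 1))])
        scores = d.pca_scores(X, n_components=2)
        assert np.allclose(scores.mean(axis=0), 0.0, atol=1e-9)
        pc1 = scores[:, 0]
        assert np.var(pc1[:4]) < 1e-18 and np.var(pc1[4:]) < 1e-18
        assert abs(pc1[:4].mean() - pc1[4:].mean()) > 1.0

    def test_pc_variances_are_ordered(self, rng):
        X = rng.normal(size=(20, 10))
        scores = d.pca_scores(X, n_components=3)
        v = scores.var(axis=0)
        assert v[0] >= v[1] >= v[2]

    def test_sign_convention_is_deterministic(self, rng):
        X = rng.normal(size=(12, 6))
        assert np.array_equal(d.pca_scores(X, 2), d.pca_scores(X.copy(), 2))


class TestRuzicka:
    def test_metric_endpoints(self):
        assert d.ruzicka_distance(np.array([1.0, 2.0]), np.array([1.0, 2.0])) == 0.0
        assert d.ruzicka_distance(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == 1.0

    def test_hand_value(self):
        assert d.ruzicka_distance(np.array([2.0, 1.0]), np.array([1.0, 1.0])) == pytest.approx(1 / 3)

    def test_zero_profiles_convention(self):
        z = np.zeros(3)
        with pytest.warns(UserWarning):
            assert d.ruzicka_distance(z, z) == 0.0
        assert d.ruzicka_distance(z, np.array([1.0, 0.0, 0.0])) == 1.0

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_metric_axioms_on_random_triples(self, seed):
        rng = np.random.default_rng(seed)
        x, y, z = rng.gamma(0.5, 1.0, size=(3, 6))
        dxy = d.ruzicka_distance(x, y)
        dyz = d.ruzicka_distance(y, z)
        dxz = d.ruzicka_distance(x, z)
        assert dxy == d.ruzicka_distance(y, x)
        assert 0.0 <= dxy <= 1.0
        assert dxz <= dxy + dyz + 1e-12


class TestFactorTree:
    def test_near_duplicates_merge_first(self, rng):
        base = rng.gamma(1, 1, size=50)
        phi = np.column_stack([base, base * 1.02, rng.gamma(1, 1, size=50)])
        tree = d.factor_tree(phi, labels=["a", "a2", "other"])
        assert tree.contains_clade({"a", "a2"})
        assert tree.linkage[0, 2] < tree.linkage[1, 2]

    def test_binary_variant_available(self, rng):
        phi = (rng.uniform(size=(30, 4)) > 0.5).astype(float)
        tree = d.factor_tree(phi, distance="jaccard-binary")
        assert tree.n_leaves == 4

    def test_needs_two_factors(self, rng):
        with pytest.raises(ContractError):
            d.factor_tree(rng.gamma(1, 1, size=(10, 1)))


class TestOutlierGenes:
    def test_identical_values_never_listed(self):
        phi = np.full((20, 6), 3.0)
        out = d.outlier_genes(phi)
        assert all(len(v) == 0 for v in out.values())

    def test_hand_z_score_example(self):
        others = np.array([1.0, 2, 3, 2, 2, 1, 3, 2, 1])
        mu, sd = others.mean(), others.std(ddof=1)
        z = (10.0 - mu) / sd
        assert z == pytest.approx(10.37, abs=0.01)
        # embed as factor 0 of gene g0, with a complementary filler gene so
        # every column sums to 12 and per-factor normalization is uniform
        row0 = np.concatenate([[10.0], others])
        phi = np.vstack([row0, 12.0 - row0])
        ks_p = stats.kstest(others, "norm", args=(mu, sd)).pvalue
        out = d.outlier_genes(phi, gene_ids=["g0", "g1"])
        assert ("g0" in out[0]) == (ks_p >= 0.05)

    def test_ks_gate_matches_scipy(self, rng):
        vals = rng.gamma(2.0, 1.0, size=(15, 9))
        mu = vals.mean(axis=1)
        sd = vals.std(axis=1, ddof=1)
        ours = d._ks_normal_pvalues(vals, mu, sd)
        oracle = [stats.kstest(v, "norm", args=(m, s), method="exact").pvalue
                  for v, m, s in zip(vals, mu, sd)]
        assert np.allclose(ours, oracle, atol=1e-10)

    def test_null_rate_matches_t_tail_prediction(self):
        # exchangeable normal null: the z > 2.5 rule with estimated moments
        # flags at the t_{T-2} tail rate sf(2.5 / sqrt(1 + 1/(T-1)))
        T, G = 10, 20_000
        rng = np.random.default_rng(1)
        phi = rng.normal(50.0, 1.0, size=(G, T))
        out = d.outlier_genes(phi, gene_ids=[str(g) for g in range(G)])
        rate = np.mean([len(v) / G for v in out.values()])
        predicted = stats.t.sf(2.5 / np.sqrt(1 + 1 / (T - 1)), T - 2)
        assert rate == pytest.approx(predicted, rel=0.25)

    def test_planted_markers_recovered(self):
        # 20 genes boosted 10x in one factor are nearly all flagged there
        for seed in range(1, 6):
            spec = sf.SimulationSpec(n_factors=6, n_genes=400, markers_per_factor=20,
                                     marker_boost=10.0, seed=seed)
            truth = sf.make_truth(spec)
            out = d.outlier_genes(truth.model.profiles, gene_ids=truth.genes)
            for t, markers in truth.markers.items():
                assert len(set(out[t]) & set(markers)) >= 18

    def test_requires_four_factors(self, rng):
        with pytest.raises(ContractError):
            d.outlier_genes(rng.gamma(1, 1, size=(10, 3)))


class TestTopGenes:
    def test_argmax_and_uniform_tie_rule(self):
        phi = np.array([[1.0, 5.0], [4.0, 5.0], [2.0, 5.0]])
        out = d.top_genes_per_factor(phi, gene_ids=["a", "b", "c"], n=1)
        assert out[0] == ["b"]
        assert out[1] == ["a"]  # uniform column: lexicographic tie-break

    def test_matches_sort_oracle(self, rng):
        phi = rng.gamma(1, 1, size=(25, 3))
        ids = [f"g{i:02d}" for i in range(25)]
        out = d.top_genes_per_factor(phi, gene_ids=ids, n=25)
        for t in range(3):
            oracle = [ids[i] for i in sorted(range(25), key=lambda i: (-phi[i, t], ids[i]))]
            assert out[t] == oracle


class TestDeCenterPeriphery:
    def _nm(self, values):
        values = np.asarray(values, dtype=float)
        S, G = values.shape
        spots = [sf.SpotId("s", i, 0) for i in range(S)]
        return d.NormalizedMatrix(values, [f"g{i}" for i in range(G)], spots, "cpm"), spots

    def test_identical_groups_are_null(self):
        nm, spots = self._nm([[2, 4], [3, 1], [2, 4], [3, 1]])
        sel = sf.SpotSelection({spots[0]: "center", spots[1]: "center",
                                spots[2]: "periphery", spots[3]: "periphery"})
        res = d.de_center_periphery(nm, sel)
        assert np.allclose(res["fold_change"], 1.0)
        assert np.allclose(res["p_value"], 1.0)

    def test_hand_means_and_zero_variance_flag(self):
        nm, spots = self._nm([[4], [4], [4], [2], [2], [2]])
        sel = sf.SpotSelection({spots[i]: "center" for i in range(3)}
                               | {spots[i]: "periphery" for i in range(3, 6)})
        res = d.de_center_periphery(nm, sel)
        assert res["fold_change"].iloc[0] == pytest.approx(2.0)
        assert res["zero_variance"].iloc[0]
        assert res["p_value"].iloc[0] == 0.0

    def test_group_swap_inverts_fold_change(self, rng):
        vals = rng.uniform(1, 10, size=(8, 6))
        nm, spots = self._nm(vals)
        half = {spots[i]: "center" for i in range(4)} | {spots[i]: "periphery" for i in range(4, 8)}
        swapped = {s: ("periphery" if l == "center" else "center") for s, l in half.items()}
        a = d.de_center_periphery(nm, sf.SpotSelection(half))
        b = d.de_center_periphery(nm, sf.SpotSelection(swapped))
        assert np.allclose(a["fold_change"], 1.0 / b["fold_change"])
        assert np.allclose(a["p_value"], b["p_value"])

    def test_missing_group_names_label(self):
        nm, spots = self._nm(np.ones((4, 2)))
        sel = sf.SpotSelection({spots[0]: "center", spots[1]: "center"})
        with pytest.raises(ContractError, match="periphery"):
            d.de_center_periphery(nm, sel)


class TestTsneColors:
    def test_bounds_and_determinism(self, rng):
        X = rng.normal(size=(25, 6))
        with pytest.warns(UserWarning, match="perplexity"):
            a = d.tsne_colors(X, seed=9)
            b = d.tsne_colors(X, seed=9)
        assert np.array_equal(a, b)
        assert a.shape == (25, 3)
        assert a.min() >= 0.0 and a.max() <= 1.0

    def test_duplicated_rows_get_similar_colors(self, rng):
        base = rng.normal(size=(20, 5))
        X = np.vstack([base, base[:3]])  # rows 20..22 duplicate rows 0..2
        colors = d.tsne_colors(X, seed=4, perplexity=5)
        for i in range(3):
            assert np.linalg.norm(colors[i] - colors[20 + i]) < 0.05

    def test_too_few_rows_rejected(self, rng):
        with pytest.raises(ContractError):
            d.tsne_colors(rng.normal(size=(3, 4)), seed=0)
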