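import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from tissuemark.errors import EmptyResultError, ValidationError
from tissuemark.simulate import SyntheticSpec, generate
from tissuemark.wgcna import (
    UNASSIGNED,
    CoexpressionNetwork,
    NetworkConfig,
    PreprocessConfig,
    adjacency_from_correlation,
    detect_modules,
    export_edges,
    merge_modules,
    module_eigengene,
    pick_soft_threshold,
    preprocess,
    scale_free_fit,
    tissue_fold_profile,
    tom_similarity,
)
from conftest import planted_two_module_spec


def brute_force_tom(a: np.ndarray) -> np.ndarray:
    """Triple-loop oracle for the topological overlap formula."""
    n = a.shape[0]
    k = np.array([sum(a[i, u] for u in range(n) if u != i) for i in range(n)])
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            tom[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return tom


def random_adjacency(rng, n):
    cor = rng.uniform(-1, 1, size=(n, n))
    cor = (cor + cor.T) / 2
    np.fill_diagonal(cor, 1.0)
    return adjacency_from_correlation(cor, beta=int(rng.integers(1, 13)))


class TestPreprocess:
    def test_zero_tpm_maps_to_minus_four(self):
        expr = pd.DataFrame([[0.0, 1.0]], index=["g"], columns=["a", "b"])
        out = preprocess(expr, PreprocessConfig(min_detected_samples=1))
        assert out.loc["g", "a"] == pytest.approx(-4.0)
        assert out.loc["g", "b"] == pytest.approx(np.log10(1.0001))

    def test_detection_threshold_is_inclusive(self, rng):
        n = 1305
        row_650 = np.zeros(n)
        row_650[:650] = 1.0
        row_649 = np.zeros(n)
        row_649[:649] = 1.0
        expr = pd.DataFrame([row_650, row_649], index=["keep", "drop"],
                            columns=[f"s{i}" for i in range(n)])
        out = preprocess(expr, PreprocessConfig(min_detected_samples=650))
        assert list(out.index) == ["keep"]

    def test_survivor_count_matches_bruteforce(self, rng):
        expr = pd.DataFrame(
            rng.lognormal(size=(40, 60)) * (rng.random((40, 60)) > 0.5),
            index=[f"g{i}" for i in range(40)],
            columns=[f"s{j}" for j in range(60)],
        )
        out = preprocess(expr, PreprocessConfig(min_detected_samples=30))
        expected = sum(
            1 for i in range(40) if (expr.iloc[i].to_numpy() > 0).sum() >= 30
        )
        assert out.shape[0] == expected

    def test_nothing_survives_is_empty_result(self):
        expr = pd.DataFrame(np.zeros((3, 4)), index=list("abc"),
                            columns=[f"s{j}" for j in range(4)])
        with pytest.raises(EmptyResultError):
            preprocess(expr, PreprocessConfig(min_detected_samples=1))

    def test_fractional_threshold(self):
        cfg = PreprocessConfig(min_detected_samples=0.5)
        assert cfg.threshold(100) == 50
        assert cfg.threshold(101) == 51


class TestAdjacency:
    def test_closed_forms(self):
        cor = np.array([[1.0, 1.0], [1.0, 1.0]])
        assert adjacency_from_correlation(cor, 6)[0, 1] == pytest.approx(1.0)
        cor = np.array([[1.0, -1.0], [-1.0, 1.0]])
        assert adjacency_from_correlation(cor, 6)[0, 1] == pytest.approx(0.0)
        cor = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert adjacency_from_correlation(cor, 12)[0, 1] == pytest.approx(0.5 ** 12)

    def test_signed_map_preserves_correlation_order(self, rng):
        cors = np.sort(rng.uniform(-1, 1, size=20))
        for beta in (1, 4, 9):
            adj = ((1 + cors) / 2) ** beta
            assert (np.diff(adj) >= 0).all()


class TestTOM:
    def test_two_gene_network_tom_equals_adjacency(self):
        for a12 in (0.0, 0.3, 0.9):
            a = np.array([[1.0, a12], [a12, 1.0]])
            assert tom_similarity(a)[0, 1] == pytest.approx(a12)

    def test_identity_adjacency_gives_identity(self):
        np.testing.assert_allclose(tom_similarity(np.eye(5)), np.eye(5))

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 9))
            a = random_adjacency(rng, n)
            np.testing.assert_allclose(tom_similarity(a), brute_force_tom(a), atol=1e-12)

    def test_range_and_symmetry(self, rng):
        a = random_adjacency(rng, 8)
        tom = tom_similarity(a)
        assert (tom >= 0).all() and (tom <= 1).all()
        np.testing.assert_allclose(tom, tom.T)
        np.testing.assert_allclose(np.diag(tom), 1.0)

    def test_asymmetric_input_rejected(self):
        a = np.eye(3)
        a[0, 1] = 0.5
        with pytest.raises(ValidationError):
            tom_similarity(a)


class TestSoftThreshold:
    def test_power_law_degrees_fit_well(self, rng):
        # k drawn exactly from p(k) ~ k^-2 via inverse CDF
        u = (np.arange(1, 2001) - 0.5) / 2000
        k = 1.0 / (1.0 - u)  # Pareto(1), tail exponent 2
        r2, slope = scale_free_fit(k, n_bins=10)
        assert r2 >= 0.95
        assert slope < 0

    def test_mean_connectivity_decreases_with_power(self):
        expr, _, _ = generate(planted_two_module_spec(0))
        logx = np.log10(expr + 1e-4)
        _, table = pick_soft_threshold(logx, NetworkConfig(candidate_powers=range(1, 9)))
        assert (np.diff(table["mean_connectivity"]) < 0).all()

    def test_unreachable_target_falls_back_to_argmax(self):
        expr, _, _ = generate(planted_two_module_spec(1))
        logx = np.log10(expr + 1e-4)
        beta, table = pick_soft_threshold(
            logx, NetworkConfig(scale_free_r2_target=0.999999)
        )
        assert not table["reached_target"].any()
        assert beta == int(table.loc[table["r_squared"].idxmax(), "power"])

    def test_degenerate_connectivity_rejected(self):
        with pytest.raises(ValidationError):
            scale_free_fit(np.full(100, 3.0))


class TestModuleDetection:
    def test_planted_two_modules_recovered(self):
        for seed in (0, 1, 2):
            spec = planted_two_module_spec(seed)
            expr, _, truth = generate(spec)
            logx = np.log10(expr + 1e-4)
            net = CoexpressionNetwork().fit(logx.T)
            truth_labels = [truth.modules.get(g, "none") for g in logx.index]
            assert adjusted_rand_score(truth_labels, list(net.labels_)) >= 0.9

    def test_independent_genes_yield_no_module(self):
        spec = SyntheticSpec(n_tissues=1, samples_per_tissue=200, n_genes=150,
                             noise_sd_log10=0.2, seed=5)
        expr, _, _ = generate(spec)
        net = CoexpressionNetwork().fit(np.log10(expr + 1e-4).T)
        assert set(net.labels_) == {UNASSIGNED}

    def test_gene_order_invariance(self, rng):
        expr, _, _ = generate(planted_two_module_spec(3))
        logx = np.log10(expr + 1e-4)
        net1 = CoexpressionNetwork().fit(logx.T)
        perm = rng.permutation(len(logx.index))
        shuffled = logx.iloc[perm]
        net2 = CoexpressionNetwork().fit(shuffled.T)
        lab1 = pd.Series(net1.labels_, index=logx.index)
        lab2 = pd.Series(net2.labels_, index=shuffled.index)
        assert (lab1.sort_index() == lab2.sort_index()).all()

    def test_fewer_genes_than_min_size_all_unassigned(self, rng):
        tom = np.eye(5)
        part = detect_modules(tom, list("abcde"), NetworkConfig(min_module_size=30))
        assert set(part.labels) == {UNASSIGNED}


class TestEigengene:
    @staticmethod
    def _partition(genes, label="turquoise"):
        from tissuemark.wgcna import ModulePartition
        return ModulePartition(pd.Series(label, index=genes))

    def test_identical_genes_give_common_profile(self):
        profile = np.array([1.0, 3.0, 2.0, 5.0])
        logx = pd.DataFrame([profile, profile, profile],
                            index=list("abc"), columns=[f"s{i}" for i in range(4)])
        eig = module_eigengene(logx, self._partition(list("abc"))).iloc[0].to_numpy()
        std = (profile - profile.mean()) / profile.std()
        std /= np.linalg.norm(std)
        np.testing.assert_allclose(eig, std, atol=1e-10)

    def test_pc1_variance_dominates_power_iteration_oracle(self, rng):
        logx = pd.DataFrame(rng.normal(size=(10, 30)),
                            index=[f"g{i}" for i in range(10)],
                            columns=[f"s{j}" for j in range(30)])
        eig = module_eigengene(logx, self._partition(list(logx.index))).iloc[0].to_numpy()
        x = (logx.to_numpy() - logx.to_numpy().mean(1, keepdims=True))
        x /= x.std(1, keepdims=True)
        # power iteration on X^T X
        v = rng.normal(size=30)
        for _ in range(500):
            v = x.T @ (x @ v)
            v /= np.linalg.norm(v)
        var_eig = ((x @ eig) ** 2).sum()
        var_power = ((x @ v) ** 2).sum()
        assert var_eig == pytest.approx(var_power, rel=1e-8)

    def test_global_sign_flip_unobservable(self, rng):
        logx = pd.DataFrame(rng.normal(size=(6, 20)) + rng.normal(size=(1, 20)),
                            index=[f"g{i}" for i in range(6)],
                            columns=[f"s{j}" for j in range(20)])
        part = self._partition(list(logx.index))
        e1 = module_eigengene(logx, part)
        e2 = module_eigengene(-logx, part)
        np.testing.assert_allclose(e1.to_numpy(), -e2.to_numpy(), atol=1e-10)
        # both are positively aligned with their own module mean profile
        for lx, e in ((logx, e1), (-logx, e2)):
            x = lx.to_numpy()
            mean_profile = ((x - x.mean(1, keepdims=True)) / x.std(1, keepdims=True)).mean(0)
            assert np.dot(e.iloc[0], mean_profile) > 0


class TestMerge:
    def test_identical_eigengene_modules_merge(self, rng):
        from tissuemark.wgcna import ModulePartition
        shared = rng.normal(size=40)
        logx = pd.DataFrame(
            np.vstack([shared + rng.normal(0, 0.05, size=(4, 40))]),
            index=[f"g{i}" for i in range(4)],
            columns=[f"s{j}" for j in range(40)],
        )
        part = ModulePartition(pd.Series(["m1", "m1", "m2", "m2"], index=logx.index))
        merged, _ = merge_modules(logx, part, merge_height=0.25)
        assert merged.labels.nunique() == 1

    def test_zero_merge_height_is_identity(self):
        from tissuemark.wgcna import ModulePartition
        expr, _, _ = generate(planted_two_module_spec(2))
        logx = np.log10(expr + 1e-4).iloc[:100]
        part = ModulePartition(pd.Series(["m1"] * 50 + ["m2"] * 50, index=logx.index))
        merged, _ = merge_modules(logx, part, merge_height=0.0)
        assert merged.labels.nunique() == 2

    def test_merge_independent_of_module_enumeration_order(self, rng):
        from tissuemark.wgcna import ModulePartition
        expr, _, _ = generate(planted_two_module_spec(4))
        logx = np.log10(expr + 1e-4).iloc[:100]
        labels_a = pd.Series(["m1"] * 50 + ["m2"] * 50, index=logx.index)
        labels_b = pd.Series(["m2"] * 50 + ["m1"] * 50, index=logx.index)
        ma, _ = merge_modules(logx, ModulePartition(labels_a), 0.25)
        mb, _ = merge_modules(logx, ModulePartition(labels_b), 0.25)
        assert (ma.labels == mb.labels).all()


class TestEdgeExport:
    def test_cutoff_above_max_gives_empty(self, rng):
        tom = np.full((4, 4), 0.5)
        np.fill_diagonal(tom, 1.0)
        assert len(export_edges(tom, list("abcd"), cutoff=0.999)) == 0

    def test_zero_cutoff_gives_all_pairs(self, rng):
        a = random_adjacency(rng, 6)
        tom = tom_similarity(a)
        assert len(export_edges(tom, list("abcdef"), cutoff=0.0)) == 15

    def test_edge_count_matches_bruteforce(self, rng):
        a = random_adjacency(rng, 10)
        tom = tom_similarity(a)
        cutoff = 0.025
        edges = export_edges(tom, [f"g{i}" for i in range(10)], cutoff)
        expected = sum(
            1 for i in range(10) for j in range(i + 1, 10) if tom[i, j] > cutoff
        )
        assert len(edges) == expected


class TestTissueFoldProfile:
    def test_uniform_gene_is_zero(self):
        expr = pd.DataFrame([[4.0] * 6], index=["g"], columns=[f"s{i}" for i in range(6)])
        annot = pd.DataFrame({"tissue": ["A", "A", "B", "B", "C", "C"]},
                             index=expr.columns)
        np.testing.assert_allclose(tissue_fold_profile(expr, annot).loc["g"], 0.0,
                                   atol=1e-12)

    def test_hand_computed_values(self):
        expr = pd.DataFrame([[8.0, 0, 0, 0]], index=["g"], columns=list("abcd"))
        annot = pd.DataFrame({"tissue": list("ABCD")}, index=list("abcd"))
        row = tissue_fold_profile(expr, annot).loc["g"]
        assert row["A"] == pytest.approx(np.log2(8.0001 / 2.0001))
        assert row["B"] == pytest.approx(np.log2(0.0001 / 2.0001))

    def test_scaling_invariance_up_to_pseudocount(self, rng):
        expr = pd.DataFrame(rng.lognormal(2, 1, size=(3, 8)),
                            index=list("xyz"), columns=[f"s{i}" for i in range(8)])
        annot = pd.DataFrame({"tissue": [f"T{i % 4}" for i in range(8)]},
                             index=expr.columns)
        p1 = tissue_fold_profile(expr, annot)
        p2 = tissue_fold_profile(2 * expr, annot)
        np.testing.assert_allclose(p1.to_numpy(), p2.to_numpy(), atol=1e-3)


def test_network_pipeline_is_deterministic():
    expr, _, _ = generate(planted_two_module_spec(6))
    logx = np.log10(expr + 1e-4)
    net1 = CoexpressionNetwork().fit(logx.T)
    net2 = CoexpressionNetwork().fit(logx.T)
    assert (net1.labels_ == net2.labels_).all()
    pd.testing.assert_frame_equal(net1.edges(), net2.edges())
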