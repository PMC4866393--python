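import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from coexshift import diffcoex as dc
from coexshift.io import split_samples
from coexshift.simulate import ModuleSpec, default_module_specs, simulate_expression

from conftest import make_expression


def naive_pearson_matrix(X):
    n = X.shape[0]
    C = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            xi, xj = X[i] - X[i].mean(), X[j] - X[j].mean()
            C[i, j] = C[j, i] = (xi * xj).sum() / np.sqrt(
                (xi**2).sum() * (xj**2).sum()
            )
    return C


def naive_tom(D):
    n = D.shape[0]
    k = D.sum(axis=1)
    T = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l_ij = sum(D[i, u] * D[u, j] for u in range(n) if u not in (i, j))
            T[i, j] = (l_ij + D[i, j]) / (min(k[i], k[j]) + 1 - D[i, j])
    return T


def split_windows(E):
    groups = dict(split_samples(E, "window"))
    return groups["prenatal"], groups["postnatal"]


class TestCoexpression:
    def test_self_correlation_one(self, toy_expression):
        C = dc.coexpression(toy_expression)
        np.testing.assert_allclose(np.diag(C), 1.0)

    def test_identical_and_negated_genes(self):
        E = make_expression(n_genes=3, seed=0)
        E.values[1] = E.values[0]
        E.values[2] = -E.values[0]
        C = dc.coexpression(E)
        assert C[0, 1] == pytest.approx(1.0)
        assert C[0, 2] == pytest.approx(-1.0)

    def test_matches_naive_oracle(self, rng):
        for _ in range(10):
            E = make_expression(n_genes=20, n_regions=1, n_per_stratum=5,
                                seed=int(rng.integers(1e6)))
            C = dc.coexpression(E)
            np.testing.assert_allclose(
                C, naive_pearson_matrix(E.values), atol=1e-12
            )

    def test_too_few_samples(self):
        E = make_expression(n_genes=4, n_regions=1, n_per_stratum=1)
        with pytest.raises(ValueError):
            dc.coexpression(E.subset_samples(np.array([0, 1])))


class TestAdjacencyDifference:
    def test_identical_conditions_zero(self, rng):
        C = naive_pearson_matrix(rng.normal(size=(8, 12)))
        D = dc.adjacency_difference(C, C.copy())
        np.testing.assert_allclose(D, 0.0)

    def test_maximal_rewiring(self):
        C1 = np.array([[1.0, 1.0], [1.0, 1.0]])
        C2 = np.array([[1.0, -1.0], [-1.0, 1.0]])
        D = dc.adjacency_difference(C1, C2, beta=6)
        assert D[0, 1] == pytest.approx(1.0)

    def test_formula_evaluation(self):
        # (0.5 * |0.81 - 0.01|)^3 = 0.4^3 = 0.064
        C1 = np.full((2, 2), 0.9)
        C2 = np.full((2, 2), 0.1)
        np.fill_diagonal(C1, 1.0)
        np.fill_diagonal(C2, 1.0)
        D = dc.adjacency_difference(C1, C2, beta=6)
        assert D[0, 1] == pytest.approx(0.064)

    def test_symmetric_in_conditions(self, rng):
        A = naive_pearson_matrix(rng.normal(size=(6, 10)))
        B = naive_pearson_matrix(rng.normal(size=(6, 10)))
        np.testing.assert_allclose(
            dc.adjacency_difference(A, B), dc.adjacency_difference(B, A)
        )

    def test_entries_bounded(self, rng):
        A = naive_pearson_matrix(rng.normal(size=(10, 8)))
        B = naive_pearson_matrix(rng.normal(size=(10, 8)))
        D = dc.adjacency_difference(A, B)
        assert (D >= 0).all() and (D <= 1).all()
        assert np.allclose(np.diag(D), 0.0)

    def test_odd_beta_rejected(self, rng):
        A = naive_pearson_matrix(rng.normal(size=(4, 8)))
        with pytest.raises(ValueError):
            dc.adjacency_difference(A, A, beta=5)


class TestScaleFreeFit:
    def test_power_law_connectivity(self):
        # deterministic Pareto quantiles give near-power-law row sums
        u = (np.arange(3000) + 0.5) / 3000
        w = u ** (-1.0 / 2.0)
        w = np.clip(w, None, 50.0)
        D = np.outer(w, w) / w.sum()
        np.fill_diagonal(D, 0.0)
        D = np.clip(D, 0.0, 1.0)
        assert dc.scale_free_fit(D) > 0.95

    def test_bounds(self, rng):
        D = rng.random((30, 30))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0.0)
        r2 = dc.scale_free_fit(D)
        assert 0.0 <= r2 <= 1.0

    def test_uniform_connectivity_errors(self):
        D = np.full((5, 5), 0.5)
        np.fill_diagonal(D, 0.0)
        with pytest.raises(ValueError):
            dc.scale_free_fit(D)


class TestTopologicalOverlap:
    def test_zero_adjacency(self):
        T = dc.topological_overlap(np.zeros((6, 6)))
        assert np.allclose(T, np.eye(6))

    def test_complete_graph(self):
        D = np.ones((4, 4)) - np.eye(4)
        T = dc.topological_overlap(D)
        np.testing.assert_allclose(T, 1.0)

    def test_matches_naive_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(10, 21))
            D = rng.random((n, n))
            D = (D + D.T) / 2
            np.fill_diagonal(D, 0.0)
            np.testing.assert_allclose(
                dc.topological_overlap(D), naive_tom(D), atol=1e-12
            )

    def test_entries_in_unit_interval(self, rng):
        D = rng.random((15, 15)) * 0.5
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0.0)
        T = dc.topological_overlap(D)
        assert (T >= 0).all() and (T <= 1).all()


def planted_block_adjacency(rng, blocks, n_background=0, within=0.6, noise=0.02):
    n = sum(blocks) + n_background
    D = rng.random((n, n)) * noise
    start = 0
    for b in blocks:
        D[start : start + b, start : start + b] = within + rng.random((b, b)) * 0.1
        start += b
    D = (D + D.T) / 2
    np.fill_diagonal(D, 0.0)
    return D


class TestCutModules:
    def test_two_planted_blocks(self, rng):
        D = planted_block_adjacency(rng, [150, 150])
        dend = dc.tom_dendrogram(dc.topological_overlap(D), list(range(300)))
        assign = dc.cut_modules(dend, min_module_size=100)
        assert len(assign.module_ids()) == 2
        truth = np.repeat([1, 2], 150)
        assert adjusted_rand_score(truth, assign.labels) > 0.99

    def test_size_floor(self, rng):
        D = planted_block_adjacency(rng, [80])
        dend = dc.tom_dendrogram(dc.topological_overlap(D), list(range(80)))
        assign = dc.cut_modules(dend, min_module_size=100)
        assert assign.module_ids() == []
        assert (assign.labels == 0).all()

    def test_min_size_above_gene_count_warns(self, rng):
        D = planted_block_adjacency(rng, [20])
        dend = dc.tom_dendrogram(dc.topological_overlap(D), list(range(20)))
        with pytest.warns(UserWarning):
            assign = dc.cut_modules(dend, min_module_size=50)
        assert (assign.labels == 0).all()

    def test_five_blocks_with_background(self, rng):
        blocks = [120] * 5
        D = planted_block_adjacency(rng, blocks, n_background=500)
        dend = dc.tom_dendrogram(dc.topological_overlap(D), list(range(1100)))
        assign = dc.cut_modules(dend, min_module_size=100)
        truth = np.concatenate([np.repeat(np.arange(1, 6), 120), np.zeros(500, int)])
        recovered = 0
        for m in range(1, 6):
            true_set = set(np.flatnonzero(truth == m))
            best = max(
                (
                    len(true_set & set(np.flatnonzero(assign.labels == p)))
                    / len(true_set | set(np.flatnonzero(assign.labels == p)))
                    for p in assign.module_ids()
                ),
                default=0.0,
            )
            recovered += best >= 0.8
        assert recovered >= 4

    def test_deterministic(self, rng):
        D = planted_block_adjacency(rng, [110, 130], n_background=100)
        dend = dc.tom_dendrogram(dc.topological_overlap(D), list(range(340)))
        a1 = dc.cut_modules(dend, min_module_size=100)
        a2 = dc.cut_modules(dend, min_module_size=100)
        np.testing.assert_array_equal(a1.labels, a2.labels)


class TestEigengenes:
    def make_assigned(self, E, labels):
        return dc.ModuleAssignment(E.gene_ids, labels, min_module_size=2)

    def test_identical_genes(self):
        E = make_expression(n_genes=4, seed=1)
        E.values[1] = E.values[0]
        E.values[2] = E.values[0] * 2 + 3
        E.values[3] = E.values[0]
        eig = dc.module_eigengenes(E, self.make_assigned(E, np.ones(4, int)))
        z = (E.values[0] - E.values[0].mean()) / E.values[0].std()
        corr = np.corrcoef(eig.eigengenes[1], z)[0, 1]
        assert abs(corr) == pytest.approx(1.0)
        assert eig.variance_explained[1] == pytest.approx(1.0)

    def test_duplicate_row_invariance(self):
        E = make_expression(n_genes=6, seed=2)
        labels = np.array([1, 1, 1, 0, 0, 0])
        e1 = dc.module_eigengenes(E, self.make_assigned(E, labels))
        E2 = make_expression(n_genes=6, seed=2)
        E2.values[3] = E2.values[0]  # duplicate a member into the module
        labels2 = np.array([1, 1, 1, 1, 0, 0])
        e2 = dc.module_eigengenes(E2, self.make_assigned(E2, labels2))
        corr = np.corrcoef(e1.eigengenes[1], e2.eigengenes[1])[0, 1]
        assert abs(corr) > 0.95

    def test_factor_recovery(self):
        specs = [ModuleSpec(1, 60, "stable", 1.0, 1.0, 0.3)]
        E, truth = simulate_expression(specs, n_regions=2, n_timepoints_per_window=14, seed=6)
        eig = dc.module_eigengenes(
            E, self.make_assigned(E, np.ones(E.n_genes, int))
        )
        corr = np.corrcoef(eig.eigengenes[1], truth.factor_trajectories[1])[0, 1]
        assert abs(corr) > 0.95

    def test_sign_orientation(self):
        E = make_expression(n_genes=5, seed=3)
        eig = dc.module_eigengenes(E, self.make_assigned(E, np.ones(5, int)))
        Z = (E.values - E.values.mean(1, keepdims=True)) / E.values.std(1, keepdims=True)
        assert np.corrcoef(eig.eigengenes[1], Z.mean(0))[0, 1] > 0


class TestMergeModules:
    def test_same_factor_modules_merge(self):
        specs = [
            ModuleSpec(1, 40, "stable", 1.0, 1.0, 0.2),
            ModuleSpec(2, 40, "background"),
        ]
        E, truth = simulate_expression(specs, n_regions=2, n_timepoints_per_window=14, seed=9)
        # split the factor-driven module in two: eigengenes correlate ~1
        labels = np.zeros(E.n_genes, int)
        labels[:20] = 1
        labels[20:40] = 2
        assign = dc.ModuleAssignment(E.gene_ids, labels, min_module_size=10)
        merged = dc.merge_modules(E, assign, r_threshold=0.9)
        assert len(merged.module_ids()) == 1

    def test_orthogonal_factors_not_merged(self):
        specs = [
            ModuleSpec(1, 30, "stable", 1.0, 1.0, 0.2),
            ModuleSpec(2, 30, "stable", 1.0, 1.0, 0.2),
        ]
        E, _ = simulate_expression(specs, n_regions=2, n_timepoints_per_window=14, seed=10)
        labels = np.repeat([1, 2], 30)
        assign = dc.ModuleAssignment(E.gene_ids, labels, min_module_size=10)
        merged = dc.merge_modules(E, assign, r_threshold=0.9)
        assert len(merged.module_ids()) == 2

    def test_duplicate_factor_pairs_merge_down(self):
        # 8 modules built on 4 factors -> merging leaves 4
        specs = []
        for mid in range(1, 5):
            specs.append(ModuleSpec(mid, 40, "stable", 1.0, 1.0, 0.2))
        E, truth = simulate_expression(specs, n_regions=2, n_timepoints_per_window=14, seed=11)
        labels = np.zeros(E.n_genes, int)
        for mid in range(4):
            labels[mid * 40 : mid * 40 + 20] = 2 * mid + 1
            labels[mid * 40 + 20 : (mid + 1) * 40] = 2 * mid + 2
        assign = dc.ModuleAssignment(E.gene_ids, labels, min_module_size=10)
        merged = dc.merge_modules(E, assign, r_threshold=0.9)
        assert len(merged.module_ids()) == 4


class TestRewiringStatistic:
    def test_identical_strata_zero_delta(self):
        E = make_expression(n_genes=10, n_regions=1, n_per_stratum=6, seed=4)
        pre, post = split_windows(E)
        post.values[:] = pre.values
        stat = dc.rewiring_statistic(pre, post, E.gene_ids[:5])
        assert stat.delta == pytest.approx(0.0)

    def test_gain_module_positive_delta(self):
        specs = [ModuleSpec(1, 50, "gain", 0.0, 1.0, 0.3)]
        E, _ = simulate_expression(specs, n_regions=4, n_timepoints_per_window=7, seed=5)
        pre, post = split_windows(E)
        stat = dc.rewiring_statistic(pre, post, E.gene_ids)
        assert stat.delta > 0.5

    def test_loss_module_negative_delta(self):
        specs = [ModuleSpec(1, 50, "loss", 1.0, 0.0, 0.3)]
        E, _ = simulate_expression(specs, n_regions=4, n_timepoints_per_window=7, seed=5)
        pre, post = split_windows(E)
        stat = dc.rewiring_statistic(pre, post, E.gene_ids)
        assert stat.delta < -0.5

    def test_small_module_errors(self, toy_expression):
        pre, post = split_windows(toy_expression)
        with pytest.raises(ValueError):
            dc.rewiring_statistic(pre, post, toy_expression.gene_ids[:1])


class TestRewiringPermutationTest:
    def test_strong_rewiring_hits_floor(self):
        specs = [ModuleSpec(1, 50, "gain", 0.0, 1.0, 0.3)]
        E, _ = simulate_expression(specs, n_regions=4, n_timepoints_per_window=7, seed=6)
        stat = dc.rewiring_permutation_test(E, E.gene_ids, n_perm=1000, seed=1)
        assert stat.p == pytest.approx(1 / 1001)

    def test_seed_determinism(self):
        specs = [ModuleSpec(1, 20, "gain", 0.0, 0.5, 0.5)]
        E, _ = simulate_expression(specs, n_regions=2, n_timepoints_per_window=5, seed=7)
        p1 = dc.rewiring_permutation_test(E, E.gene_ids, n_perm=99, seed=42).p
        p2 = dc.rewiring_permutation_test(E, E.gene_ids, n_perm=99, seed=42).p
        assert p1 == p2

    def test_null_calibration(self):
        hits, n_rep = 0, 40
        for rep in range(n_rep):
            specs = [ModuleSpec(1, 25, "background", noise_sd=1.0)]
            E, _ = simulate_expression(specs, n_regions=2, n_timepoints_per_window=10,
                                       seed=100 + rep)
            p = dc.rewiring_permutation_test(E, E.gene_ids, n_perm=199, seed=rep).p
            hits += p < 0.05
        assert hits / n_rep <= 0.1

    def test_shuffle_mode_runs(self):
        specs = [ModuleSpec(1, 15, "gain", 0.0, 1.0, 0.3)]
        E, _ = simulate_expression(specs, n_regions=2, n_timepoints_per_window=5, seed=8)
        stat = dc.rewiring_permutation_test(E, E.gene_ids, n_perm=99, seed=0, mode="shuffle")
        assert 0 < stat.p <= 1

    def test_bad_n_perm(self, toy_expression):
        with pytest.raises(ValueError):
            dc.rewiring_permutation_test(toy_expression, toy_expression.gene_ids, n_perm=0)
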