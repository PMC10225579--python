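import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from sklearn.metrics import adjusted_mutual_info_score

from dgcna import (
    ParameterError,
    SimulationParams,
    adjacency,
    detect_modules,
    filter_genes_invgamma,
    find_hubs,
    generate_dataset,
    module_stability,
    run_coexpression_chain,
    select_soft_threshold,
    tom_similarity,
)
from dgcna.coexpression import CoexpressionModules, adjacency_from_correlation
from dgcna.preprocess import vst


def expr_frame(values, gene_ids=None):
    values = np.asarray(values, dtype=float)
    gene_ids = gene_ids or [f"g{i}" for i in range(values.shape[0])]
    return pd.DataFrame(values, index=gene_ids)


def tom_oracle(adj):
    """Triple-loop reference implementation of topological overlap."""
    a = np.asarray(adj, dtype=float).copy()
    np.fill_diagonal(a, 0.0)
    n = a.shape[0]
    out = np.eye(n)
    for g in range(n):
        for h in range(n):
            if g == h:
                continue
            shared = sum(a[g, u] * a[u, h] for u in range(n) if u not in (g, h))
            k_g = sum(a[g, u] for u in range(n) if u != g)
            k_h = sum(a[h, u] for u in range(n) if u != h)
            out[g, h] = (shared + a[g, h]) / (min(k_g, k_h) + 1.0 - a[g, h])
    return out


def random_adjacency(rng, n):
    r = rng.uniform(0, 1, size=(n, n))
    a = (r + r.T) / 2.0
    np.fill_diagonal(a, 1.0)
    return a


class TestInverseGammaFilter:
    def test_high_variance_gene_survives_strict_threshold(self):
        rng = np.random.default_rng(0)
        values = rng.standard_normal((200, 40))
        values[0] *= 10.0  # 100x the variance of the background
        kept = filter_genes_invgamma(expr_frame(values), p_threshold=0.02)
        assert "g0" in kept

    def test_fraction_kept_matches_threshold_for_invgamma_variances(self):
        # Variances drawn i.i.d. inverse-gamma: the probability-integral
        # transform makes the kept fraction track the threshold.
        rng = np.random.default_rng(1)
        sd = np.sqrt(stats.invgamma.rvs(3.0, scale=2.0, size=5000, random_state=rng))
        values = rng.standard_normal((5000, 200)) * sd[:, None]
        kept = filter_genes_invgamma(expr_frame(values), p_threshold=0.1)
        assert len(kept) / 5000 == pytest.approx(0.1, abs=0.03)

    def test_threshold_one_keeps_everything(self):
        rng = np.random.default_rng(2)
        values = rng.standard_normal((50, 10))
        kept = filter_genes_invgamma(expr_frame(values), p_threshold=1.0)
        assert len(kept) == 50

    def test_degenerate_equal_variances_raise(self):
        values = np.tile([1.0, 2.0, 3.0, 4.0], (10, 1))
        with pytest.raises(ParameterError, match="filter"):
            filter_genes_invgamma(expr_frame(values))


class TestSoftThreshold:
    def test_modular_data_meets_criterion(self):
        params = SimulationParams(
            n_genes=200,
            n_samples_per_condition=(100, 100),
            module_sizes=[60, 30],
            within_module_cor=0.9,
            seed=3,
        )
        counts, _ = generate_dataset(params)
        result = select_soft_threshold(vst(counts))
        assert result.criterion_met
        assert 1 <= result.beta <= 20

    def test_identical_genes_are_degenerate(self):
        values = np.tile(np.arange(10.0), (5, 1))
        result = select_soft_threshold(expr_frame(values))
        assert not result.criterion_met
        assert len(result.fit_table) == 20

    def test_fit_table_invariant_to_gene_permutation(self):
        rng = np.random.default_rng(4)
        values = rng.standard_normal((30, 25))
        a = select_soft_threshold(expr_frame(values))
        perm = rng.permutation(30)
        b = select_soft_threshold(expr_frame(values[perm]))
        pd.testing.assert_frame_equal(a.fit_table, b.fit_table)
        assert a.beta == b.beta


class TestAdjacency:
    def test_power_of_absolute_correlation(self):
        corr = np.array([[1.0, -0.5], [-0.5, 1.0]])
        adj = adjacency_from_correlation(corr, beta=2)
        assert adj[0, 1] == pytest.approx(0.25)
        assert adj[0, 0] == 1.0

    def test_entries_shrink_with_beta(self):
        rng = np.random.default_rng(5)
        values = expr_frame(rng.standard_normal((10, 30)))
        a1 = adjacency(values, beta=1).to_numpy()
        a6 = adjacency(values, beta=6).to_numpy()
        off = ~np.eye(10, dtype=bool)
        assert (a6[off] < a1[off]).all()

    def test_matches_elementwise_oracle(self):
        rng = np.random.default_rng(6)
        values = expr_frame(rng.standard_normal((4, 12)))
        oracle = np.abs(np.corrcoef(values.to_numpy())) ** 3
        np.fill_diagonal(oracle, 1.0)
        np.testing.assert_allclose(
            adjacency(values, beta=3).to_numpy(), oracle, atol=1e-12
        )

    def test_zero_variance_gene_gets_zero_correlations(self):
        values = expr_frame([[1.0, 1.0, 1.0, 1.0], [0.0, 1.0, 2.0, 3.0]])
        with pytest.warns(UserWarning, match="zero-variance"):
            adj = adjacency(values, beta=2)
        assert adj.iloc[0, 1] == 0.0
        assert adj.iloc[0, 0] == 1.0


class TestTOM:
    def test_equal_adjacency_closed_form(self):
        for c in (0.2, 0.5, 0.9):
            a = np.full((3, 3), c)
            np.fill_diagonal(a, 1.0)
            tom = tom_similarity(a)
            # TOM_12 = (c^2 + c) / (2c + 1 - c) = c
            assert tom[0, 1] == pytest.approx(c, abs=1e-12)

    def test_identity_adjacency_maps_to_identity(self):
        np.testing.assert_allclose(tom_similarity(np.eye(5)), np.eye(5))

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(7)
        a = random_adjacency(rng, 6)
        np.testing.assert_allclose(tom_similarity(a), tom_oracle(a), atol=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(2, 8), st.integers(0, 10_000))
    def test_oracle_agreement_property(self, n, seed):
        rng = np.random.default_rng(seed)
        a = random_adjacency(rng, n)
        tom = tom_similarity(a)
        np.testing.assert_allclose(tom, tom_oracle(a), atol=1e-12)
        assert np.allclose(tom, tom.T, atol=1e-12)
        assert tom.min() >= 0.0 and tom.max() <= 1.0 + 1e-12

    def test_asymmetric_input_rejected(self):
        bad = np.array([[1.0, 0.2], [0.4, 1.0]])
        with pytest.raises(ParameterError, match="symmetric"):
            tom_similarity(bad)


class TestModuleDetection:
    def test_recovers_planted_modules(self, two_module_dataset):
        counts, truth = two_module_dataset
        result = run_coexpression_chain(vst(counts), var_filter_p=None)
        labels = result.assignment.module_of_gene
        true_labels = truth.module_labels(labels.index)
        in_module = true_labels > 0
        ami = adjusted_mutual_info_score(
            true_labels[in_module], labels.to_numpy()[in_module]
        )
        assert result.assignment.n_modules == 2
        assert ami >= 0.9

    def test_pure_noise_finds_no_modules(self):
        zero_module_seeds = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            values = expr_frame(rng.standard_normal((60, 60)))
            result = run_coexpression_chain(values, var_filter_p=None)
            if result.assignment.n_modules == 0:
                zero_module_seeds += 1
        assert zero_module_seeds >= 9

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(8)
        a = random_adjacency(rng, 40)
        tom = tom_similarity(a)
        ids = [f"g{i}" for i in range(40)]
        base = detect_modules(pd.DataFrame(tom, index=ids, columns=ids), min_module_size=5)
        perm = rng.permutation(40)
        pids = [ids[i] for i in perm]
        permuted = detect_modules(
            pd.DataFrame(tom[np.ix_(perm, perm)], index=pids, columns=pids),
            min_module_size=5,
        )
        # identical partition of gene ids, up to relabeling
        a_labels = base.module_of_gene.loc[ids].to_numpy()
        b_labels = permuted.module_of_gene.loc[ids].to_numpy()
        assert adjusted_mutual_info_score(a_labels, b_labels) == pytest.approx(1.0)

    def test_fewer_genes_than_min_size_gives_single_label_zero(self):
        tom = np.eye(5)
        result = detect_modules(tom, min_module_size=30)
        assert (result.module_of_gene == 0).all()


class TestHubs:
    @staticmethod
    def one_module_assignment(ids):
        from dgcna import ModuleAssignment

        return ModuleAssignment(pd.Series(1, index=pd.Index(ids), name="module"))

    def test_star_center_is_rank_one(self):
        n = 6
        a = np.full((n, n), 0.05)
        a[0, :] = a[:, 0] = 0.9  # center tied to every leaf
        np.fill_diagonal(a, 1.0)
        ids = [f"g{i}" for i in range(n)]
        adj = pd.DataFrame(a, index=ids, columns=ids)
        hubs = find_hubs(adj, self.one_module_assignment(ids), n_hubs=1)
        assert hubs[1] == ["g0"]

    def test_requesting_more_hubs_returns_whole_module_in_order(self):
        rng = np.random.default_rng(9)
        a = random_adjacency(rng, 5)
        ids = [f"g{i}" for i in range(5)]
        adj = pd.DataFrame(a, index=ids, columns=ids)
        hubs = find_hubs(adj, self.one_module_assignment(ids), n_hubs=10)
        k = a.sum(axis=1) - 1
        oracle = [ids[i] for i in np.argsort(-k, kind="stable")]
        assert hubs[1] == oracle


class TestModuleStability:
    def test_single_rep_has_accuracy_one(self, two_module_dataset):
        counts, _ = two_module_dataset
        report = module_stability(counts, n_reps=1, seed=0, var_filter_p=None)
        assert report.modal_count_accuracy == 1.0

    def test_same_seed_reproduces_report(self, two_module_dataset):
        counts, _ = two_module_dataset
        a = module_stability(counts, n_reps=5, seed=42, var_filter_p=None)
        b = module_stability(counts, n_reps=5, seed=42, var_filter_p=None)
        assert a.module_count_distribution == b.module_count_distribution
        assert a.hub_recovery.equals(b.hub_recovery)

    def test_hub_recovery_favors_module_genes(self, two_module_dataset):
        counts, truth = two_module_dataset
        report = module_stability(counts, n_reps=10, seed=1, var_filter_p=None)
        labels = truth.module_labels(report.hub_recovery.index)
        module_best = report.hub_recovery[labels > 0].max()
        background_best = report.hub_recovery[labels == 0].max()
        assert module_best > background_best


def test_estimator_round_trip(two_module_dataset):
    counts, truth = two_module_dataset
    X = vst(counts).values.T  # samples x genes
    model = CoexpressionModules(var_filter_p=None).fit(X)
    assert model.n_modules_ == 2
    assert len(model.labels_) == X.shape[1]
    assert set(model.hubs_) == {1, 2}
    params = model.get_params()
    assert params["min_module_size"] == 30
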