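import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import erfc

from dgcna import (
    ConditionedExpression,
    ParameterError,
    SimulationParams,
    call_dcgs,
    call_dcls,
    classify_dcl,
    coexpressed_pairs,
    dcg_stability,
    differential_coexpression,
    fisher_z_diff_test,
    generate_dataset,
    generate_null_correlation_pairs,
    pairwise_correlations,
)
from dgcna.diffcoexp import DifferentialCoexpression, bh_adjust
from dgcna.preprocess import vst


def random_conditioned(n_genes, n1, n2, seed):
    rng = np.random.default_rng(seed)
    ids = pd.Index([f"g{i}" for i in range(n_genes)])
    e1 = pd.DataFrame(rng.standard_normal((n_genes, n1)), index=ids)
    e2 = pd.DataFrame(rng.standard_normal((n_genes, n2)), index=ids)
    return ConditionedExpression(e1, e2)


class TestPairwiseCorrelations:
    def test_duplicated_gene_has_perfect_correlation(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(20)
        expr = pd.DataFrame([x, x, -x], index=["a", "b", "c"])
        r, p = pairwise_correlations(expr)
        assert r.loc["a", "b"] == pytest.approx(1.0)
        assert p.loc["a", "b"] == 0.0
        assert r.loc["a", "c"] == pytest.approx(-1.0)

    def test_p_values_match_t_distribution_oracle(self):
        rng = np.random.default_rng(1)
        expr = pd.DataFrame(rng.standard_normal((6, 30)))
        r, p = pairwise_correlations(expr)
        for i in range(6):
            for j in range(i + 1, 6):
                _, p_ref = stats.pearsonr(expr.iloc[i], expr.iloc[j])
                assert p.iloc[i, j] == pytest.approx(p_ref, rel=1e-9)

    def test_zero_variance_gene_warned_and_nullified(self):
        expr = pd.DataFrame(
            [[1.0, 1.0, 1.0, 1.0, 1.0], [0.0, 1.0, 2.0, 1.0, 0.0]]
        )
        with pytest.warns(UserWarning, match="zero-variance"):
            r, p = pairwise_correlations(expr)
        assert r.iloc[0, 1] == 0.0
        assert p.iloc[0, 1] == 1.0

    def test_too_few_samples_rejected(self):
        with pytest.raises(ParameterError):
            pairwise_correlations(pd.DataFrame(np.ones((3, 3))))


class TestCoexpressedPairs:
    def test_pair_strong_in_one_condition_is_retained_with_flags(self):
        rng = np.random.default_rng(2)
        n = 100
        base = rng.standard_normal(n)
        e1 = pd.DataFrame(
            [base, 0.95 * base + 0.31 * rng.standard_normal(n)], index=["a", "b"]
        )
        e2 = pd.DataFrame(rng.standard_normal((2, n)), index=["a", "b"])
        filler1 = pd.DataFrame(rng.standard_normal((4, n)), index=list("cdef"))
        filler2 = pd.DataFrame(rng.standard_normal((4, n)), index=list("cdef"))
        cond = ConditionedExpression(
            pd.concat([e1, filler1]), pd.concat([e2, filler2])
        )
        pairs = coexpressed_pairs(cond)
        row = pairs[(pairs.gene_i == "a") & (pairs.gene_j == "b")]
        assert len(row) == 1
        assert bool(row.coexp1.iloc[0]) and not bool(row.coexp2.iloc[0])

    def test_impossible_threshold_gives_empty_set(self):
        cond = random_conditioned(8, 30, 30, seed=3)
        assert len(coexpressed_pairs(cond, rth=1.01)) == 0

    def test_matches_independent_bh_oracle(self):
        cond = random_conditioned(10, 25, 25, seed=4)
        pairs = coexpressed_pairs(cond, rth=0.2, q_coexp=0.3)

        def oracle_flags(expr, rth, q):
            n = expr.shape[1]
            x = expr.to_numpy()
            m = x.shape[0]
            ps, rs, names = [], [], []
            for i in range(m):
                for j in range(i + 1, m):
                    r, p = stats.pearsonr(x[i], x[j])
                    rs.append(r)
                    ps.append(p)
                    names.append((expr.index[i], expr.index[j]))
            # independent BH: step-up on sorted p-values
            ps = np.array(ps)
            order = np.argsort(ps)
            qs = np.empty_like(ps)
            prev = 1.0
            for rank_idx in range(len(ps) - 1, -1, -1):
                idx = order[rank_idx]
                val = ps[idx] * len(ps) / (rank_idx + 1)
                prev = min(prev, val)
                qs[idx] = prev
            return {
                name: (abs(r) >= rth and q_val <= q)
                for name, r, q_val in zip(names, rs, qs)
            }

        f1 = oracle_flags(cond.expr1, 0.2, 0.3)
        f2 = oracle_flags(cond.expr2, 0.2, 0.3)
        expected = {k for k in f1 if f1[k] or f2[k]}
        got = set(zip(pairs.gene_i, pairs.gene_j))
        assert got == expected
        for _, row in pairs.iterrows():
            key = (row.gene_i, row.gene_j)
            assert row.coexp1 == f1[key]
            assert row.coexp2 == f2[key]


class TestFisherZ:
    def test_equal_correlations_give_null(self):
        z, p = fisher_z_diff_test(0.63, 50, 0.63, 80)
        assert z == 0.0
        assert p == 1.0

    def test_swapping_conditions_negates_z(self):
        z1, p1 = fisher_z_diff_test(0.8, 40, 0.2, 60)
        z2, p2 = fisher_z_diff_test(0.2, 60, 0.8, 40)
        assert z1 == pytest.approx(-z2)
        assert p1 == pytest.approx(p2)

    def test_closed_form_example(self):
        z, p = fisher_z_diff_test(0.8, 103, 0.2, 103)
        expected_z = (math.atanh(0.8) - math.atanh(0.2)) / math.sqrt(2.0 / 100.0)
        assert z == pytest.approx(expected_z, abs=1e-12)
        assert p == pytest.approx(erfc(abs(expected_z) / math.sqrt(2)), rel=1e-10)

    def test_matches_high_precision_oracle_on_grid(self):
        rng = np.random.default_rng(5)
        r1 = rng.uniform(-0.99, 0.99, 1000)
        r2 = rng.uniform(-0.99, 0.99, 1000)
        n1, n2 = 37, 91
        z, p = fisher_z_diff_test(r1, n1, r2, n2)
        se = math.sqrt(1 / (n1 - 3) + 1 / (n2 - 3))
        for k in range(1000):
            z_ref = (math.atanh(r1[k]) - math.atanh(r2[k])) / se
            p_ref = erfc(abs(z_ref) / math.sqrt(2))
            assert z[k] == pytest.approx(z_ref, abs=1e-10)
            assert p[k] == pytest.approx(p_ref, abs=1e-10)

    def test_unit_correlation_is_clamped_not_infinite(self):
        z, p = fisher_z_diff_test(1.0, 10, 0.0, 10)
        assert np.isfinite(z)

    def test_tiny_samples_rejected(self):
        with pytest.raises(ParameterError):
            fisher_z_diff_test(0.5, 3, 0.1, 10)


class TestCallDCLs:
    def test_type_one_error_is_calibrated_under_the_null(self):
        pairs = generate_null_correlation_pairs(100, 100, 0.3, 10_000, seed=6)
        r1 = np.array([a for a, _ in pairs])
        r2 = np.array([b for _, b in pairs])
        _, p = fisher_z_diff_test(r1, 100, r2, 100)
        assert 0.03 <= (p <= 0.05).mean() <= 0.07

    def test_empty_pair_set_gives_empty_output(self):
        cond = random_conditioned(5, 20, 20, seed=7)
        empty = coexpressed_pairs(cond, rth=1.01)
        out = call_dcls(empty, cond)
        assert len(out) == 0
        assert "q_diff" in out.columns

    def test_planted_difference_is_called(self):
        params = SimulationParams(
            n_genes=20,
            n_samples_per_condition=(70, 200),
            planted_pairs=[(0, 1, 0.8, 0.0)],
            seed=8,
        )
        counts, _ = generate_dataset(params)
        cond = ConditionedExpression.from_expression(vst(counts), "cond1", "cond2")
        pairs = coexpressed_pairs(cond)
        dcls = call_dcls(pairs, cond)
        assert {("G000001", "G000002")} <= set(zip(dcls.gene_i, dcls.gene_j))


class TestClassifyDCL:
    def test_three_textbook_cases(self):
        labels = classify_dcl(
            r1=[0.8, 0.7, 0.8],
            r2=[0.3, -0.6, 0.1],
            coexp1=[True, True, True],
            coexp2=[True, True, False],
        )
        assert list(labels) == ["same-signed", "switched-opposite", "diff-signed"]

    def test_uncoexpressed_pair_rejected(self):
        with pytest.raises(ParameterError):
            classify_dcl([0.5], [0.1], [False], [False])


class TestCallDCGs:
    @staticmethod
    def pair_table(links):
        return pd.DataFrame(
            [{"gene_i": a, "gene_j": b} for a, b in links]
        )

    def test_binomial_tail_matches_exact_enumeration(self):
        # hub with 10 links, 5 of them DCLs, global rate 0.1 (5 DCLs / 50 pairs)
        links = [("hub", f"x{i}") for i in range(10)]
        links += [(f"y{i}", f"z{i}") for i in range(40)]
        dcls = self.pair_table([("hub", f"x{i}") for i in range(5)])
        out = call_dcgs(dcls, self.pair_table(links))
        row = out[out.gene == "hub"].iloc[0]
        p_hat = 5 / 50
        exact = sum(
            math.comb(10, k) * p_hat**k * (1 - p_hat) ** (10 - k)
            for k in range(5, 11)
        )
        assert row.n_links == 10 and row.n_dcls == 5
        assert row.p_binom == pytest.approx(exact, abs=1e-12)

    def test_gene_without_dcls_has_p_one(self):
        links = [("a", "b"), ("a", "c"), ("b", "c")]
        dcls = self.pair_table([("b", "c")])
        out = call_dcgs(dcls, self.pair_table(links))
        # gene "a" touches no DCL
        assert out.loc[out.gene == "a", "p_binom"].iloc[0] == pytest.approx(1.0)

    def test_saturated_rate_enriches_nothing(self):
        links = [("a", "b"), ("c", "d")]
        out = call_dcgs(self.pair_table(links), self.pair_table(links))
        assert (out.p_binom == 1.0).all()
        assert not out.dcg.any()

    def test_no_pairs_rejected(self):
        with pytest.raises(ParameterError):
            call_dcgs(self.pair_table([]), self.pair_table([]))


class TestBH:
    def test_q_values_monotone_in_p_rank(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(size=200)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert q.min() >= 0.0 and q.max() <= 1.0


class TestDCGStability:
    def test_same_seed_reproduces_fractions(self):
        cond = random_conditioned(10, 30, 30, seed=10)
        a = dcg_stability(cond, n_reps=5, seed=3)
        b = dcg_stability(cond, n_reps=5, seed=3)
        assert a.equals(b)

    def test_null_data_recovery_stays_low(self):
        high = 0
        for seed in range(5):
            cond = random_conditioned(12, 40, 40, seed=100 + seed)
            rec = dcg_stability(cond, n_reps=10, seed=seed)
            if rec.max() > 0.2:
                high += 1
        assert high <= 1

    def test_joint_subsampling_mode_runs(self):
        cond = random_conditioned(8, 30, 30, seed=11)
        rec = dcg_stability(cond, n_reps=3, seed=0, joint=True)
        assert ((rec >= 0) & (rec <= 1)).all()


def test_estimator_fit_exposes_network(planted_star_dataset):
    counts, truth = planted_star_dataset
    X = vst(counts).values.T
    y = counts.conditions.to_numpy()
    model = DifferentialCoexpression().fit(X, y)
    assert set(truth.planted_hub_genes) <= set(model.dcg_genes_)
    assert model.network_.thresholds["rth"] == 0.5
    assert (model.dcls_["q_diff"] <= 0.1).all()


def test_power_grows_with_sample_size():
    sizes = [10, 30, 90]
    power = []
    for n in sizes:
        pairs = generate_null_correlation_pairs(n, n, 0.0, 400, seed=12)
        r1 = np.array([a for a, _ in pairs])
        # shift condition 2 to a true correlation of 0.5
        pairs2 = generate_null_correlation_pairs(n, n, 0.5, 400, seed=13)
        r2 = np.array([b for _, b in pairs2])
        _, p = fisher_z_diff_test(r1, n, r2, n)
        power.append((p <= 0.05).mean())
    assert power[0] < power[1] < power[2]
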