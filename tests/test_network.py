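import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import alternating_ipf
from viosna.categories import CATEGORIES
from viosna.network import (
    CooccurrenceNetwork,
    IPFError,
    IPFNormalizer,
    build_cooccurrence,
    density,
    ipf_normalize,
    robust_network,
    threshold_edges,
)


class TestCooccurrence:
    def test_single_pair(self, histories_factory):
        h = histories_factory([{"circulatory", "respiratory"}])
        M = build_cooccurrence(h)
        assert M.loc["circulatory", "respiratory"] == 1
        assert M.to_numpy().sum() == 2  # the symmetric counterpart only

    def test_three_women_brute_force(self, histories_factory):
        h = histories_factory([
            {"circulatory", "respiratory"},
            {"circulatory", "respiratory", "digestive"},
            {"digestive"},
        ])
        M = build_cooccurrence(h)
        assert M.loc["circulatory", "respiratory"] == 2
        assert M.loc["circulatory", "digestive"] == 1
        assert M.loc["respiratory", "digestive"] == 1

    def test_symmetric_zero_diagonal(self, small_cohort):
        M = build_cooccurrence(small_cohort[0]).to_numpy()
        assert (M == M.T).all()
        assert (np.diag(M) == 0).all()


class TestIPF:
    def test_two_by_two(self):
        res = ipf_normalize(np.array([[0.0, 2.0], [2.0, 0.0]]))
        assert np.allclose(res.values, [[0, 1], [1, 0]], atol=1e-12)

    def test_fixed_point_returns_immediately(self):
        X = np.array([[0.0, 0.4, 0.6], [0.4, 0.0, 0.6], [0.6, 0.6, 0.0]])
        X = alternating_ipf(X)  # make it exactly doubly stochastic first
        res = ipf_normalize(X)
        assert res.iterations == 0

    def test_three_by_three_against_alternating_oracle(self):
        X = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 3.0], [2.0, 3.0, 0.0]])
        res = ipf_normalize(X)
        assert np.abs(res.values - alternating_ipf(X)).max() < 1e-8

    def test_unit_marginals_and_cpr_on_random_positive_matrices(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            X = rng.uniform(0.1, 5.0, size=(5, 5))
            X = (X + X.T) / 2
            res = ipf_normalize(X)
            A = res.values
            assert np.abs(A.sum(axis=1) - 1).max() < 1e-10
            assert np.allclose(A, A.T)
            # cross-product ratios preserved
            r0 = (X[0, 1] * X[2, 3]) / (X[0, 3] * X[2, 1])
            r1 = (A[0, 1] * A[2, 3]) / (A[0, 3] * A[2, 1])
            assert abs(r0 - r1) < 1e-8 * max(1.0, abs(r0))

    def test_zero_row_excluded_and_reported(self):
        X = np.zeros((3, 3))
        X[0, 1] = X[1, 0] = 4.0
        res = ipf_normalize(X)
        assert res.zero_rows == [2]
        assert np.allclose(res.values[:2, :2], [[0, 1], [1, 0]])

    def test_single_partner_row_released_from_constraint(self):
        # node 3 co-occurs only with the hub 0: no unit-marginal limit exists
        X = np.array([
            [0.0, 3.0, 3.0, 1.0],
            [3.0, 0.0, 3.0, 0.0],
            [3.0, 3.0, 0.0, 0.0],
            [1.0, 0.0, 0.0, 0.0],
        ])
        res = ipf_normalize(X)
        assert res.deficient_rows == [3]
        sums = res.values.sum(axis=1)
        assert np.abs(sums[:3] - 1).max() < 1e-9

    def test_zero_support_raises(self):
        with pytest.raises(IPFError):
            ipf_normalize(np.zeros((4, 4)))

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000),
           st.floats(min_value=0.1, max_value=100.0))
    def test_scale_invariance(self, seed, scale):
        rng = np.random.default_rng(seed)
        X = rng.uniform(0.5, 2.0, size=(4, 4))
        X = X + X.T
        a = ipf_normalize(X).values
        b = ipf_normalize(scale * X).values
        assert np.abs(a - b).max() < 1e-8

    def test_normalizer_estimator_round_trip(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(0.5, 2.0, size=(6, 6))
        X = X + X.T
        norm = IPFNormalizer().fit(X)
        out = norm.transform(X)
        assert np.abs(np.asarray(out).sum(axis=1) - 1).max() < 1e-10
        assert norm.get_params()["target"] == 1.0


class TestThreshold:
    @staticmethod
    def matrix_from_values(values):
        """Symmetric 29x29 matrix with given upper-triangle values."""
        A = np.zeros((29, 29))
        iu = np.triu_indices(29, k=1)
        A[iu] = values
        A = A + A.T
        return pd.DataFrame(A, index=list(CATEGORIES), columns=list(CATEGORIES))

    def test_known_multiset_1_to_406(self):
        rng = np.random.default_rng(3)
        vals = rng.permutation(np.arange(1, 407, dtype=float))
        M = self.matrix_from_values(vals)
        edges, thr = threshold_edges(M, percentile=95)
        assert thr == pytest.approx(np.percentile(np.arange(1, 407), 95))
        kept = sorted(w for _, _, w in edges)
        assert kept == [float(v) for v in range(386, 407)]
        assert len(kept) == 21

    def test_all_equal_yields_empty_with_warning(self):
        M = self.matrix_from_values(np.ones(406))
        with pytest.warns(UserWarning):
            edges, _ = threshold_edges(M)
        assert edges == []

    def test_dominant_entry_always_kept(self):
        rng = np.random.default_rng(4)
        vals = rng.uniform(0.9, 1.1, size=406)
        vals[123] = 50.0
        edges, _ = threshold_edges(self.matrix_from_values(vals))
        assert any(w == 50.0 for _, _, w in edges)

    def test_at_most_five_percent_kept(self, small_cohort):
        res = ipf_normalize(build_cooccurrence(small_cohort[0]))
        edges, _ = threshold_edges(res)
        assert len(edges) <= int(np.ceil(0.05 * 406)) + 1


class TestRobustNetwork:
    def test_k1_equals_plain_threshold(self, small_cohort):
        h, _ = small_cohort
        net = robust_network(h, k=1)
        res = ipf_normalize(build_cooccurrence(h))
        edges, thr = threshold_edges(res)
        got = {(r.source, r.target) for r in net.edges.itertuples()}
        assert got == {(i, j) for i, j, _ in edges}
        assert net.threshold == thr

    def test_bookkeeping_every_robust_edge_passed_all_subsets(self):
        from viosna import synthetic as syn

        cfg = syn.planted_recovery_config(n_women=8000)
        h = syn.generate_histories(cfg, seed=4)
        net = robust_network(h, k=5, seed=4)
        assert len(net.edges) > 0
        assert (net.edges["passes"] == 5).all()

    def test_independent_cohort_has_no_robust_edges(self):
        """With one visit per woman, no communities and no outcome effects,
        every subset's top-5% tail is noise, so the all-subsets intersection
        is empty (expected robust edges ~ 406 x 0.05^k)."""
        from scipy.special import logit

        from viosna import synthetic as syn

        coef = {k: 0.0 for k in syn.GeneratorConfig().true_coefficients}
        cfg = syn.default_config(
            n_women=10_000, visits_mean=1.0, true_coefficients=coef,
            profile_probs=(0.0, 0.0, 0.0, 0.0), intercept=float(logit(0.02)),
            baseline_category_probs={c: 0.08 for c in syn.EMITTABLE},
        )
        h = syn.generate_histories(cfg, seed=6)
        net = robust_network(h, k=10, seed=6)
        assert len(net.edges) == 0

    def test_stratification_infeasible_raises(self, histories_factory):
        h = histories_factory([{"circulatory", "respiratory"}] * 30)
        h["wvv"] = [True] + [False] * 29
        with pytest.raises(ValueError, match="stratification"):
            robust_network(h, k=10)


class TestDensity:
    def test_complete_empty_and_partial(self, histories_factory):
        import networkx as nx

        assert density(nx.complete_graph(29)) == 1.0
        g = nx.Graph()
        g.add_nodes_from(range(29))
        assert density(g) == 0.0
        g.add_edges_from((0, i) for i in range(1, 21))
        assert density(g) == pytest.approx(20 / 406)


def test_estimator_pipeline_interface(small_cohort):
    h, _ = small_cohort
    est = CooccurrenceNetwork(percentile=95, k=2, seed=0).fit(h)
    assert est.matrix_.shape == (29, 29)
    assert est.graph_.number_of_nodes() == 29
    assert 0.0 <= est.density_() <= 1.0
    assert est.get_params()["k"] == 2
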