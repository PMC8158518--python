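"""Shrinkage partial correlations, PCLRC probabilities, and edge masking."""

import numpy as np
import pytest

import liponet as lp
from liponet.network import PclrcParams, shrinkage_intensity


class TestShrinkagePartialCorrelation:
    def test_two_variables_partial_equals_marginal(self, rng):
        x = rng.standard_normal(200)
        y = 0.6 * x + 0.8 * rng.standard_normal(200)
        X = np.column_stack([x, y])
        lam = shrinkage_intensity(X)
        marginal = np.corrcoef(X, rowvar=False)[0, 1] * (1 - lam)
        # with m=2, conditioning set is empty: shrunken marginal comes back
        R = lp.shrinkage_partial_correlation(X)
        shrunk = (1 - lam) * np.corrcoef(X, rowvar=False)[0, 1]
        assert np.sign(R[0, 1]) == np.sign(marginal)
        assert abs(R[0, 1]) <= abs(shrunk) + 1e-12

    def test_lambda_zero_matches_pseudoinverse_oracle(self, rng):
        X = rng.standard_normal((200, 10))
        R = lp.shrinkage_partial_correlation(X, lam=0.0)
        C = np.corrcoef(X, rowvar=False)
        omega = np.linalg.pinv(C)
        d = np.sqrt(np.diag(omega))
        ref = -omega / np.outer(d, d)
        np.fill_diagonal(ref, 1.0)
        assert np.abs(R - ref).max() < 1e-10

    def test_unit_diagonal_and_symmetry(self, rng):
        R = lp.shrinkage_partial_correlation(rng.standard_normal((100, 8)))
        assert np.allclose(np.diag(R), 1.0)
        assert np.allclose(R, R.T)

    def test_all_zero_correlations_warn_to_full_shrinkage(self):
        # two exactly orthogonal sign patterns: every off-diagonal r is 0
        X = np.column_stack(
            [np.tile([1.0, -1.0], 50), np.repeat([1.0, -1.0], 50)]
        )
        with pytest.warns(UserWarning, match="intensity"):
            lam = shrinkage_intensity(X)
        assert lam == 1.0


class TestPclrc:
    def test_probabilities_are_symmetric_unit_interval(self, rng):
        X = rng.standard_normal((120, 8))
        P = lp.pclrc_probabilities(X, niter=50, seed=0)
        assert np.allclose(P, P.T)
        assert P.min() >= 0 and P.max() <= 1
        assert np.allclose(np.diag(P), 0)

    def test_planted_edges_recovered_with_high_probability(self):
        """Five strong disjoint edges in a 21-node network: all recovered at
        P >= 0.95 with precision >= 0.8, across 5 seeds."""
        pn = lp.PlantedNetwork.disjoint_pairs(21, 5, 0.5)
        iu = np.triu_indices(21, k=1)
        truth = pn.adjacency[iu] == 1
        for seed in range(5):
            X = lp.generate_from_planted_network(pn, 600, seed=seed)
            P = lp.pclrc_probabilities(X, niter=200, seed=100 + seed)
            selected = P[iu] >= 0.95
            assert (P[iu][truth] >= 0.95).all()
            precision = (truth & selected).sum() / max(selected.sum(), 1)
            assert precision >= 0.8

    def test_duplicated_rows_leave_probabilities_stable(self, rng):
        pn = lp.PlantedNetwork.disjoint_pairs(10, 2, 0.6)
        X = lp.generate_from_planted_network(pn, 300, seed=4)
        P1 = lp.pclrc_probabilities(X, niter=150, seed=1)
        P2 = lp.pclrc_probabilities(np.vstack([X, X]), niter=150, seed=2)
        assert np.abs(P1 - P2).max() <= 0.2  # Monte-Carlo noise only

    def test_tiny_subsample_is_an_error(self):
        with pytest.raises(ValueError, match="too small"):
            lp.pclrc_probabilities(np.random.default_rng(0).standard_normal((4, 3)),
                                   niter=5, frac=0.5)


class TestMaskNetwork:
    def test_zero_probability_empty_network(self, rng):
        R = lp.shrinkage_partial_correlation(rng.standard_normal((50, 5)))
        net = lp.mask_network(R, np.zeros((5, 5)))
        assert net.n_edges == 0
        assert (net.weights == 0).all()

    def test_full_probability_keeps_off_diagonal(self, rng):
        R = lp.shrinkage_partial_correlation(rng.standard_normal((50, 5)))
        net = lp.mask_network(R, np.ones((5, 5)))
        off = ~np.eye(5, dtype=bool)
        assert np.allclose(net.weights[off], R[off])
        assert np.allclose(np.diag(net.weights), 0)

    def test_threshold_boundary_is_inclusive(self):
        R = np.array([[1.0, -0.4], [-0.4, 1.0]])
        P = np.array([[0.0, 0.95], [0.95, 0.0]])
        net = lp.mask_network(R, P, prob_threshold=0.95)
        assert net.weights[0, 1] == -0.4

    def test_no_numeric_dust_below_threshold(self, rng):
        R = lp.shrinkage_partial_correlation(rng.standard_normal((60, 8)))
        P = rng.uniform(size=(8, 8))
        P = (P + P.T) / 2
        net = lp.mask_network(R, P, prob_threshold=0.9)
        assert (net.weights[P < 0.9] == 0).all()

    def test_raising_threshold_never_adds_edges(self, rng):
        R = lp.shrinkage_partial_correlation(rng.standard_normal((60, 8)))
        P = rng.uniform(size=(8, 8))
        P = (P + P.T) / 2
        np.fill_diagonal(P, 0)
        edges = [
            lp.mask_network(R, P, prob_threshold=t).n_edges
            for t in (0.2, 0.5, 0.8, 0.95)
        ]
        assert edges == sorted(edges, reverse=True)


class TestInferGroupNetworks:
    def test_six_networks_with_full_panel(self, small_cohort):
        groups = lp.stratify_by_age(small_cohort)
        nets = lp.infer_group_networks(
            small_cohort, groups, PclrcParams(niter=30), seed=0
        )
        assert set(nets) == {"W", "M", "YM", "OM", "YW", "OW"}
        for net in nets.values():
            assert net.m == 21

    def test_same_seed_reproduces_probabilities(self, small_cohort):
        groups = lp.stratify_by_age(small_cohort)
        a = lp.infer_group_networks(small_cohort, groups, PclrcParams(niter=20), seed=5)
        b = lp.infer_group_networks(small_cohort, groups, PclrcParams(niter=20), seed=5)
        for label in a:
            assert np.array_equal(a[label].probability, b[label].probability)
            assert np.array_equal(a[label].weights, b[label].weights)

    def test_sample_order_does_not_matter(self, small_cohort):
        groups = lp.stratify_by_age(small_cohort)
        shuffled = small_cohort.subset(
            np.random.default_rng(9).permutation(small_cohort.concentrations.index)
        )
        groups_s = lp.stratify_by_age(shuffled)
        a = lp.infer_network(small_cohort.subset(groups.labels["M"]),
                             PclrcParams(niter=25), seed=3)
        b = lp.infer_network(shuffled.subset(groups_s.labels["M"]),
                             PclrcParams(niter=25), seed=3)
        assert np.array_equal(a.probability, b.probability)

    def test_small_group_warns_but_returns(self, small_cohort):
        tiny = small_cohort.subset(small_cohort.concentrations.index[:20])
        with pytest.warns(UserWarning, match="small"):
            net = lp.infer_network(tiny, PclrcParams(niter=10), seed=0)
        assert net.m == 21
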