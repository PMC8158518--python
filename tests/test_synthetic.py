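"""Synthetic cohort, planted networks, and COVSCA ground-truth generators."""

import numpy as np
import pytest
from scipy import stats

import liponet as lp


class TestStudyDesign:
    def test_totals_and_strata(self):
        spec = lp.default_study_design()
        assert spec.total == 844
        assert spec.group_sizes == {"M": 661, "W": 183}
        assert spec.strata_sizes["YM"] == 216
        for sex, (young, old) in (("M", ("YM", "OM")), ("W", ("YW", "OW"))):
            assert (
                spec.strata_sizes[young] + spec.strata_sizes[old]
                <= spec.group_sizes[sex]
            )

    def test_effect_table_directions_follow_medians(self):
        spec = lp.default_study_design()
        eff = spec.effect_table
        assert np.allclose(eff["M"], 1.0)
        # women's HDL fractions are elevated, VLDL fractions reduced
        assert eff.loc["Cholesterol HDL", "W"] > 1
        assert eff.loc["Triglycerides VLDL", "W"] < 1


class TestGenerateCohort:
    def test_shape_and_positivity(self, default_cohort):
        assert default_cohort.n_samples == 844
        assert default_cohort.n_fractions == 21
        assert (default_cohort.values() > 0).all()
        assert (default_cohort.sex == "M").sum() == 661
        assert (default_cohort.sex == "W").sum() == 183

    def test_sex_effect_direction_across_seeds(self):
        """Fractions elevated in women by design come out higher in the
        women's sample median, checked over 10 seeds."""
        wins = 0
        for seed in range(10):
            tab = lp.generate_cohort(seed=seed)
            med_w = tab.concentrations.loc[tab.sex == "W", "Cholesterol HDL"].median()
            med_m = tab.concentrations.loc[tab.sex == "M", "Cholesterol HDL"].median()
            wins += med_w > med_m
        assert wins == 10

    def test_identity_correlation_gives_near_zero_correlations(self):
        """With the latent correlation switched off and group median shifts
        neutralized (identical median columns, so pooling adds no structure),
        all pairwise correlations stay within the sampling-error bound for
        the max over 210 pairs at n = 844 (z for a 0.1% family bound is
        about 4.05, giving |r| < 4.05/sqrt(844) ~ 0.14)."""
        spec = lp.SyntheticCohortSpec(within_class_corr=0.0, between_class_corr=0.0)
        flat = spec.group_medians.copy()
        for col in flat.columns:
            flat[col] = spec.group_medians["M"]
        spec.group_medians = flat
        tab = lp.generate_cohort(spec, seed=5)
        corr = np.corrcoef(np.sqrt(tab.values()), rowvar=False)
        off = corr[~np.eye(21, dtype=bool)]
        assert np.abs(off).max() < 4.05 / np.sqrt(844)

    def test_sqrt_transform_stabilizes_variance_across_groups(self):
        """Levene's test on the square-root scale across the four age/sex
        strata stays non-significant at alpha=0.01 (10 seeds, all fractions)."""
        rejections = 0
        for seed in range(10):
            tab = lp.generate_cohort(seed=seed)
            st = lp.sqrt_transform(tab)
            groups = lp.stratify_by_age(tab)
            for frac in tab.fraction_names:
                samples = [
                    st.concentrations.loc[groups.labels[g], frac]
                    for g in ("YM", "OM", "YW", "OW")
                ]
                if stats.levene(*samples, center="median").pvalue < 0.01:
                    rejections += 1
        # 210 tests at the 1% level: a couple of rejections is chance level
        assert rejections <= 6

    def test_bad_block_structure_fails_before_sampling(self):
        spec = lp.SyntheticCohortSpec(within_class_corr=0.1, between_class_corr=0.9)
        with pytest.raises(ValueError, match="positive definite"):
            lp.generate_cohort(spec, seed=0)


class TestPlantedNetwork:
    def test_chain_graph_conditional_independence(self):
        """In a 1-2-3 chain the (1,3) partial correlation given 2 vanishes."""
        chain = lp.PlantedNetwork.from_edges(3, [(0, 1, 0.5), (1, 2, 0.5)])
        X = lp.generate_from_planted_network(chain, 2000, seed=3)
        R = lp.shrinkage_partial_correlation(X)
        assert abs(R[0, 2]) < 0.08

    def test_empty_graph_gives_uncorrelated_data(self):
        empty = lp.PlantedNetwork(np.zeros((6, 6)), np.zeros((6, 6), dtype=int))
        X = lp.generate_from_planted_network(empty, 2000, seed=1)
        corr = np.corrcoef(X, rowvar=False)
        assert np.abs(corr[~np.eye(6, dtype=bool)]).max() < 0.1

    def test_planted_edge_strength_recovered(self):
        pn = lp.PlantedNetwork.from_edges(5, [(0, 1, 0.6)])
        X = lp.generate_from_planted_network(pn, 2000, seed=2)
        R = lp.shrinkage_partial_correlation(X)
        assert abs(R[0, 1] - 0.6) < 0.1

    def test_estimation_error_halves_from_500_to_2000_samples(self):
        pn = lp.PlantedNetwork.disjoint_pairs(10, 3, 0.5)
        errs = {500: [], 2000: []}
        for seed in range(7):
            for n in (500, 2000):
                X = lp.generate_from_planted_network(pn, n, seed=seed)
                omega = np.linalg.inv(np.cov(X, rowvar=False))
                d = np.sqrt(np.diag(omega))
                est = -omega / np.outer(d, d)
                np.fill_diagonal(est, 0.0)
                errs[n].append(np.linalg.norm(est - pn.partial_corr))
        assert np.median(errs[2000]) < 0.65 * np.median(errs[500])

    def test_indefinite_precision_is_rejected(self):
        with pytest.raises(ValueError, match="positive definite"):
            lp.PlantedNetwork.from_edges(3, [(0, 1, 0.9), (1, 2, 0.9), (0, 2, 0.9)])


class TestCovscaInstances:
    def test_shapes_symmetry_and_psd(self):
        mats, coeff, protos = lp.generate_covsca_instances(6, 2, [2, 2], 21, seed=4)
        assert len(mats) == 6 and coeff.shape == (6, 2)
        for S in mats:
            assert S.shape == (21, 21)
            assert np.allclose(S, S.T)
            assert np.linalg.eigvalsh(S).min() > -1e-12

    def test_reconstruction_is_exact(self):
        mats, coeff, protos = lp.generate_covsca_instances(4, 2, [2, 3], 10, seed=9)
        for k, S in enumerate(mats):
            rebuilt = sum(coeff[k, l] * protos[l] @ protos[l].T for l in range(2))
            assert np.allclose(S, rebuilt, atol=1e-10)

    def test_single_prototype_equal_coefficients_repeat_matrix(self):
        mats, coeff, protos = lp.generate_covsca_instances(3, 1, [2], 8, seed=2)
        scaled = [S / c for S, c in zip(mats, coeff[:, 0])]
        for S in scaled[1:]:
            assert np.allclose(S, scaled[0], atol=1e-10)
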