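"""BLUP of SNP effects, GEBV prediction, fixed-SNP selection, two-pass fitting."""

import numpy as np
import pytest

import snpblup as sb
from snpblup.reml import VarianceComponents


def _vc(s2a, s2e, m):
    h2 = m * s2a / (m * s2a + s2e)
    return VarianceComponents(s2a, s2e, h2, 0.0, True, 0, m)


class TestSnpBlup:
    def test_zero_genetic_variance_gives_zero_effects_and_gls_beta(self):
        rng = np.random.default_rng(0)
        Z = rng.standard_normal((20, 5))
        X = np.column_stack([np.ones(20), rng.normal(size=20)])
        r = rng.uniform(0.5, 2, 20)
        y = rng.normal(size=20)
        data = sb.MixedModelData(y=y, X=X, r=r)
        eff = sb.blup_snp_effects(_vc(0.0, 1.0, 5), data, Z)
        np.testing.assert_array_equal(eff.alpha_hat, 0.0)
        Xw = X / r[:, None]
        beta_gls = np.linalg.solve(X.T @ Xw, Xw.T @ y)
        np.testing.assert_allclose(eff.beta_hat, beta_gls, atol=1e-10)

    def test_single_snp_ridge_closed_form(self):
        """m=1 toy: effect equals s2a w z' V^{-1} (y - X beta) computed by explicit inverse."""
        z = np.array([[-2.0], [-1.0], [0.0], [1.0], [2.0]])
        y = np.array([0.5, -0.2, 0.1, 0.9, 1.5])
        X = np.ones((5, 1))
        data = sb.MixedModelData(y=y, X=X, r=np.ones(5))
        s2a, s2e, w = 0.7, 1.1, np.array([1.3])
        V = s2a * w[0] * z @ z.T + s2e * np.eye(5)
        Vi = np.linalg.inv(V)
        beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        alpha = s2a * w[0] * (z.T @ Vi @ (y - X @ beta))
        eff = sb.blup_snp_effects(_vc(s2a, s2e, 1), data, z, w)
        assert eff.alpha_hat[0] == pytest.approx(alpha[0], abs=1e-3)
        assert eff.beta_hat[0] == pytest.approx(beta[0], abs=1e-3)

    def test_duplicated_snp_with_split_weight_shares_effect_and_keeps_fit(self, small_sim):
        """Duplicating a SNP column with the pair's variance share split evenly
        leaves Z W Z' — hence V and the fitted genetic values — unchanged,
        and each copy receives half of the original effect."""
        g, data, _ = small_sim
        sg = sb.standardize(g)
        Z = sg.Z[:, :50]
        vc = sb.reml_direct(data, Z)
        eff = sb.blup_snp_effects(vc, data, Z)
        Zdup = np.column_stack([Z, Z[:, 0]])
        wdup = np.ones(51)
        wdup[0] = wdup[50] = 0.5
        effd = sb.blup_snp_effects(vc, data, Zdup, wdup)
        assert effd.alpha_hat[0] == pytest.approx(effd.alpha_hat[-1], abs=1e-10)
        assert effd.alpha_hat[0] == pytest.approx(eff.alpha_hat[0] / 2, abs=1e-8)
        np.testing.assert_allclose(Zdup @ effd.alpha_hat, Z @ eff.alpha_hat, atol=1e-8)

    def test_unconverged_fit_refused_without_force(self, small_sim):
        g, data, _ = small_sim
        sg = sb.standardize(g)
        vc = sb.reml_direct(data, sg.Z)
        vc.converged = False
        with pytest.raises(RuntimeError, match="force"):
            sb.blup_snp_effects(vc, data, sg.Z)
        sb.blup_snp_effects(vc, data, sg.Z, force=True)


class TestPredict:
    def test_training_genotypes_reproduce_fitted_genetic_values(self, small_fit):
        sg, vc, data = small_fit
        eff = sb.blup_snp_effects(vc, data, sg.Z)
        pred = sb.predict_gebv(eff, sg.Z)
        np.testing.assert_allclose(pred.gebv, sg.Z @ eff.alpha_hat, atol=1e-12)
        # centered Z makes training GEBVs mean-zero
        assert abs(pred.gebv.mean()) < 1e-8

    def test_zero_effects_give_zero_gebv(self):
        eff = sb.SNPEffects(np.zeros(4), np.zeros(1))
        pred = sb.predict_gebv(eff, np.random.default_rng(0).normal(size=(7, 4)))
        np.testing.assert_array_equal(pred.gebv, 0.0)

    def test_prediction_is_linear_in_rows(self, small_fit):
        sg, vc, data = small_fit
        eff = sb.blup_snp_effects(vc, data, sg.Z)
        a = sb.predict_gebv(eff, sg.Z[:10]).gebv
        b = sb.predict_gebv(eff, sg.Z[10:25]).gebv
        both = sb.predict_gebv(eff, sg.Z[:25]).gebv
        np.testing.assert_allclose(both, np.concatenate([a, b]), atol=1e-12)

    def test_snp_mismatch_rejected(self, small_fit):
        sg, vc, data = small_fit
        eff = sb.blup_snp_effects(vc, data, sg.Z)
        with pytest.raises(ValueError, match="mismatch"):
            sb.predict_gebv(eff, sg.Z[:, :10])

    def test_snp_model_equals_grm_model_gebvs(self):
        """SNP-effect GEBVs match the equivalent GRM mixed-model predictions."""
        cfg = sb.SimulationConfig(n_individuals=200, n_snps=500, n_chromosomes=2,
                                  n_qtl=50, h2_target=0.4, seed=13)
        g, data_all, _ = sb.simulate_dataset(cfg)
        train = np.arange(160)
        new = np.arange(160, 200)
        sg = sb.standardize(g, train)
        d_train = data_all.subset(train)
        wv = sb.maf_weights(sg.maf, 2.0, 2.0)  # any valid W
        vc = sb.reml_direct(d_train, sg.Z, wv.w)
        eff = sb.blup_snp_effects(vc, d_train, sg.Z, wv.w)
        Z_new = sb.standardize_like(g.subset_samples(new), sg)
        gebv_snp = sb.predict_gebv(eff, Z_new).gebv
        # independent GRM-model oracle: u_new = s2g G_nt V^{-1} (y - X beta)
        m = sg.m
        s2g = m * vc.sigma2_alpha
        G_tt = (sg.Z * wv.w) @ sg.Z.T / m
        G_nt = (Z_new * wv.w) @ sg.Z.T / m
        V = s2g * G_tt + vc.sigma2_e * np.diag(d_train.r)
        Vi = np.linalg.inv(V)
        X = d_train.X
        beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ d_train.y)
        gebv_grm = s2g * G_nt @ Vi @ (d_train.y - X @ beta)
        np.testing.assert_allclose(gebv_snp, gebv_grm, atol=1e-6)
        np.testing.assert_allclose(eff.beta_hat, beta, atol=1e-6)


class TestSelectFixedSnps:
    def test_type_one_error_controlled_on_pure_noise(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            Z = rng.standard_normal((300, 400))
            data = sb.MixedModelData(y=rng.normal(size=300), X=np.ones((300, 1)),
                                     r=np.ones(300))
            sel = sb.select_fixed_snps(data, Z)
            hits += sel.size > 0
        assert hits <= 1  # empty in >= 9/10 seeds under Bonferroni 0.05

    def test_planted_large_qtl_detected(self):
        cfg = sb.SimulationConfig(n_individuals=800, n_snps=500, n_chromosomes=2,
                                  n_qtl=1, h2_target=0.2, seed=5)
        g, data, truth = sb.simulate_dataset(cfg)
        sg = sb.standardize(g)
        sel = sb.select_fixed_snps(data, sg.Z)
        assert any(abs(int(s) - int(truth.qtl_indices[0])) <= 5 for s in sel)

    def test_none_policy_returns_empty(self, small_fit):
        sg, _, data = small_fit
        assert sb.select_fixed_snps(data, sg.Z, "none").size == 0

    def test_overparameterized_selection_rejected(self):
        rng = np.random.default_rng(1)
        n, m = 40, 30
        base = rng.standard_normal(n)
        Z = base[:, None] + 0.05 * rng.standard_normal((n, m))  # every marker near-perfect
        y = base
        data = sb.MixedModelData(y=y, X=np.ones((n, 1)), r=np.ones(n))
        with pytest.raises(ValueError, match="overparameterized"):
            sb.select_fixed_snps(data, Z)


class TestTwoPass:
    def test_round_zero_is_identity_and_reweighting_uses_its_effects(self, small_sim):
        g, data, _ = small_sim
        sg = sb.standardize(g)
        rounds = sb.fit_two_pass(data, sg, scheme="window", S=5, rounds=1)
        assert len(rounds) == 2
        assert rounds[0].weights.scheme == "identity"
        np.testing.assert_array_equal(rounds[0].weights.w, 1.0)
        expected = sb.window_weights(rounds[0].effects.alpha_hat, 5, sg.chrom)
        np.testing.assert_allclose(rounds[1].weights.w, expected.w, atol=1e-12)

    def test_extra_round_reweights_from_previous_round(self, small_sim):
        g, data, _ = small_sim
        sg = sb.standardize(g)
        rounds = sb.fit_two_pass(data, sg, scheme="window", S=5, rounds=2)
        assert len(rounds) == 3
        expected = sb.window_weights(rounds[1].effects.alpha_hat, 5, sg.chrom)
        np.testing.assert_allclose(rounds[2].weights.w, expected.w, atol=1e-12)

    def test_combined_scheme_multiplies_in_maf_factor(self, small_sim):
        g, data, _ = small_sim
        sg = sb.standardize(g)
        rounds = sb.fit_two_pass(data, sg, scheme="combined", shape=2.0, S=5, rounds=1)
        expected = sb.combined_weights(
            sg.maf, 2.0, 2.0, rounds[0].effects.alpha_hat, 5, sg.chrom
        )
        np.testing.assert_allclose(rounds[1].weights.w, expected.w, atol=1e-12)

    def test_invalid_configuration_rejected(self, small_sim):
        g, data, _ = small_sim
        sg = sb.standardize(g)
        with pytest.raises(ValueError, match="rounds"):
            sb.fit_two_pass(data, sg, scheme="window", rounds=0)
        with pytest.raises(ValueError, match="scheme"):
            sb.fit_two_pass(data, sg, scheme="maf")

    def test_allelic_effects_rescale_by_column_scale(self, small_fit):
        sg, vc, data = small_fit
        eff = sb.blup_snp_effects(vc, data, sg.Z)
        per_allele = sb.allelic_effects(eff, sg.scales)
        np.testing.assert_allclose(per_allele * sg.scales, eff.alpha_hat, atol=1e-12)
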