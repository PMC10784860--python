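"""Generator tests: structural arithmetic, closed-form SEs, seeding, LD."""

import dataclasses

import numpy as np
import pytest

import mrmediate as mm


def _null_config(**kw):
    cfg = dict(n_variants=50, seed=1, theta_direct=0.0,
               mediators=[dict(name="m1", alpha=0.0, beta=0.0, delta_sd=0.0)],
               outcome_type="continuous")
    cfg.update(kw)
    return cfg


class TestBuildTrueModel:
    def test_null_model_has_zero_total_effect(self):
        model = mm.build_true_model(_null_config())
        assert model.theta_total == 0.0

    def test_total_effect_is_direct_plus_mediated_paths(self):
        model = mm.build_true_model(_null_config(
            theta_direct=0.5,
            mediators=[dict(name="m1", alpha=0.4, beta=0.5)],
        ))
        assert model.theta_total == pytest.approx(0.7)
        assert model.proportion_mediated == pytest.approx(1 - 0.5 / 0.7)

    def test_same_seed_reproduces_model_field_by_field(self):
        cfg = _null_config(theta_direct=0.3, pleio_mean=0.01, pleio_sd=0.02,
                           outcome_type="binary", case_fraction=0.1)
        a = mm.build_true_model(cfg)
        b = mm.build_true_model(cfg)
        for f in dataclasses.fields(mm.TrueModel):
            va, vb = getattr(a, f.name), getattr(b, f.name)
            if isinstance(va, np.ndarray):
                assert np.array_equal(va, vb), f.name
            else:
                assert va == vb, f.name

    def test_rejects_invalid_configs(self):
        with pytest.raises(ValueError, match="mediator"):
            mm.build_true_model(dict(n_variants=10, mediation=True, mediators=[]))
        with pytest.raises(ValueError, match="eaf_range"):
            mm.build_true_model(dict(n_variants=10, eaf_range=(0.0, 0.9)))
        with pytest.raises(ValueError, match="case_fraction"):
            mm.build_true_model(dict(n_variants=10, outcome_type="binary", case_fraction=1.5))

    def test_marginal_effects_follow_structural_model(self):
        model = mm.build_true_model(_null_config(
            theta_direct=0.2,
            mediators=[dict(name="m1", alpha=0.3, beta=-0.5, delta_sd=0.01)],
            pleio_mean=0.01, pleio_sd=0.0,
        ))
        expected_outcome = (model.gamma * model.theta_total
                            + model.delta @ model.beta_med + model.pleio)
        np.testing.assert_allclose(model.marginal_effects("outcome"), expected_outcome)
        np.testing.assert_allclose(
            model.marginal_effects("m1"),
            model.gamma * 0.3 + model.delta[:, 0],
        )


class TestGenerateSummaryStats:
    def test_continuous_se_matches_closed_form(self):
        # eaf = 0.5, n = 10 000, sigma = 1 -> SE = 1/sqrt(2*10000*0.25)
        model = mm.build_true_model(_null_config(n_variants=5, eaf_range=(0.4999, 0.5001)))
        design = mm.SampleDesign(n={"exposure": 10_000, "m1": 10_000, "outcome": 10_000}, seed=0)
        tabs = mm.generate_summary_stats(model, design, traits=["exposure"])
        np.testing.assert_allclose(tabs["exposure"].df["se"], 0.0141421, rtol=1e-3)

    def test_binary_se_matches_closed_form(self):
        model = mm.build_true_model(dict(n_variants=200, seed=2, outcome_type="binary",
                                         case_fraction=0.1))
        design = mm.SampleDesign(n={"exposure": 10_000, "outcome": 50_000}, seed=0)
        tab = mm.generate_summary_stats(model, design, traits=["outcome"])["outcome"]
        expected = 1.0 / np.sqrt(2 * 50_000 * 0.1 * 0.9 * model.eaf * (1 - model.eaf))
        np.testing.assert_allclose(tab.df["se"], expected, rtol=1e-12)

    def test_null_model_estimates_have_normal_tails(self):
        model = mm.build_true_model(_null_config(n_variants=2000, gamma=dict(kind="normal", sd=0.0)))
        design = mm.SampleDesign(n={"exposure": 10**6, "m1": 10**6, "outcome": 10**6}, seed=3)
        tabs = mm.generate_summary_stats(model, design)
        for tab in tabs.values():
            z = np.abs(tab.df["beta"] / tab.df["se"])
            assert np.mean(z <= 5) >= 0.99

    def test_trait_seeds_are_independent(self):
        model = mm.build_true_model(_null_config())
        base = dict(n={"exposure": 10_000, "m1": 10_000, "outcome": 10_000})
        a = mm.generate_summary_stats(model, mm.SampleDesign(**base, seed=1))
        b = mm.generate_summary_stats(model, mm.SampleDesign(**base, seed=1,
                                                             trait_seeds={"outcome": 99}))
        assert a["exposure"].df.equals(b["exposure"].df)
        assert a["m1"].df.equals(b["m1"].df)
        assert not np.allclose(a["outcome"].df["beta"], b["outcome"].df["beta"])

    def test_generation_is_bit_reproducible(self):
        model = mm.build_true_model(_null_config(theta_direct=0.4))
        design = mm.SampleDesign(n={"exposure": 10_000, "m1": 10_000, "outcome": 10_000},
                                 seed=7, swap_rate=0.3, strand_flip_rate=0.2)
        a = mm.generate_summary_stats(model, design)
        b = mm.generate_summary_stats(model, design)
        for t in a:
            assert a[t].df.equals(b[t].df)

    def test_replicate_mean_recovers_true_marginal_effects(self):
        model = mm.build_true_model(dict(
            n_variants=40, seed=11, theta_direct=0.3,
            mediators=[dict(name="m1", alpha=0.4, beta=0.5, delta_sd=0.02)],
            outcome_type="continuous",
        ))
        truth = model.marginal_effects("outcome")
        n_rep = 1000
        betas = np.empty((n_rep, model.n_variants))
        for r in range(n_rep):
            design = mm.SampleDesign(n={"exposure": 10_000, "m1": 10_000, "outcome": 10_000},
                                     seed=100_000 + r)
            tab = mm.generate_summary_stats(model, design, traits=["outcome"])["outcome"]
            betas[r] = tab.df["beta"].to_numpy()
        se = tab.df["se"].to_numpy()
        mc_se = se / np.sqrt(n_rep)
        assert np.all(np.abs(betas.mean(axis=0) - truth) <= 4 * mc_se)

    def test_f_statistics_match_noncentral_expectation(self):
        model = mm.build_true_model(dict(n_variants=8, seed=21,
                                         gamma=dict(kind="normal", sd=0.02)))
        n = 50_000
        lam = n * model.gamma**2 * 2 * model.eaf * (1 - model.eaf)
        n_rep = 800
        f_obs = np.empty((n_rep, 8))
        for r in range(n_rep):
            design = mm.SampleDesign(n={"exposure": n, "outcome": n}, seed=200_000 + r)
            df = mm.generate_summary_stats(model, design, traits=["exposure"])["exposure"].df
            f_obs[r] = (df["beta"] / df["se"]) ** 2
        mc_se = np.sqrt(2 * (1 + 2 * lam) / n_rep)
        assert np.all(np.abs(f_obs.mean(axis=0) - (lam + 1)) <= 3.5 * mc_se)

    def test_design_validation(self):
        with pytest.raises(ValueError, match=">= 100"):
            mm.SampleDesign(n={"exposure": 10})
        with pytest.raises(ValueError, match="rates"):
            mm.SampleDesign(n={"exposure": 1000}, swap_rate=1.5)


class TestReferenceLD:
    def test_zero_rho_gives_identity(self):
        model = mm.build_true_model(_null_config(ld_blocks=(4, 0.0)))
        ld = mm.generate_reference_ld(model)
        np.testing.assert_array_equal(ld.to_numpy(), np.eye(model.n_variants))

    def test_block_correlations_decay_geometrically(self):
        model = mm.build_true_model(_null_config(n_variants=3, ld_blocks=(3, 0.5)))
        ld = mm.generate_reference_ld(model).to_numpy()
        np.testing.assert_allclose(ld, [[1, 0.5, 0.25], [0.5, 1, 0.5], [0.25, 0.5, 1]])

    def test_matrix_is_positive_semidefinite(self):
        for rho in (-0.9, 0.3, 0.85):
            model = mm.build_true_model(_null_config(n_variants=30, ld_blocks=(7, rho)))
            eig = np.linalg.eigvalsh(mm.generate_reference_ld(model).to_numpy())
            assert eig.min() >= -1e-10

    def test_rejects_rho_at_or_beyond_one(self):
        with pytest.raises(ValueError, match="rho"):
            mm.build_true_model(_null_config(ld_blocks=(3, 1.0)))


class TestIndividualLevelValidation:
    def test_continuous_regression_matches_closed_form_se(self):
        model = mm.build_true_model(dict(n_variants=10, seed=5,
                                         gamma=dict(kind="normal", sd=0.05)))
        design = mm.SampleDesign(n={"exposure": 30_000, "outcome": 30_000}, seed=0)
        beta_hat, se_hat = mm.simulate_individual_level(model, design, "exposure", seed=9)
        closed = 1.0 / np.sqrt(2 * 30_000 * model.eaf[:10] * (1 - model.eaf[:10]))
        np.testing.assert_allclose(se_hat, closed, rtol=0.05)
        assert np.all(np.abs(beta_hat - model.gamma[:10]) <= 4 * se_hat)

    def test_binary_logistic_matches_closed_form_se(self):
        model = mm.build_true_model(dict(n_variants=4, seed=6, outcome_type="binary",
                                         case_fraction=0.3,
                                         gamma=dict(kind="normal", sd=0.02)))
        design = mm.SampleDesign(n={"exposure": 20_000, "outcome": 20_000}, seed=0)
        _, se_hat = mm.simulate_individual_level(model, design, "outcome", seed=3)
        closed = 1.0 / np.sqrt(2 * 20_000 * 0.3 * 0.7 * model.eaf[:4] * (1 - model.eaf[:4]))
        np.testing.assert_allclose(se_hat, closed, rtol=0.1)
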