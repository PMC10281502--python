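"""Bayesian fitting processes: likelihood correctness, oracles, recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit

import bearcomp as bc
from bearcomp.fitting import (IdentifiabilityError, beta_logpdf_mean_precision,
                              normal_logpdf, prior_sets, validate_dissection)


class TestDensityPrimitives:
    """Implementation formulas versus scipy.stats, term by term."""

    def test_normal_logpdf_matches_scipy(self, rng):
        x = rng.normal(0, 2, 50)
        mu = rng.normal(0, 1, 50)
        sd = rng.uniform(0.1, 3, 50)
        mine = normal_logpdf(x, mu, sd)
        ref = np.array([stats.norm.logpdf(a, b, c)
                        for a, b, c in zip(x, mu, sd)])
        np.testing.assert_allclose(mine, ref, atol=1e-8)

    def test_beta_mean_precision_matches_scipy(self, rng):
        x = rng.uniform(0.01, 0.99, 50)
        mu = rng.uniform(0.1, 0.9, 50)
        phi = rng.uniform(0.5, 60, 50)
        mine = beta_logpdf_mean_precision(x, mu, phi)
        ref = np.array([stats.beta.logpdf(a, m * p, (1 - m) * p)
                        for a, m, p in zip(x, mu, phi)])
        np.testing.assert_allclose(mine, ref, atol=1e-8)

    def test_beta_parameterization_moments(self, rng):
        """a = mu*phi, b = (1-mu)*phi gives mean mu, var mu(1-mu)/(1+phi)."""
        mu, phi = 0.3, 8.0
        draws = rng.beta(mu * phi, (1 - mu) * phi, 200_000)
        assert draws.mean() == pytest.approx(mu, abs=0.005)
        assert draws.var() == pytest.approx(mu * (1 - mu) / (1 + phi),
                                            rel=0.05)


class TestPriorSets:
    def test_both_sets_cover_all_model_parameters(self):
        sets = prior_sets()
        needed = ["alpha_lU0", "beta_lU1", "beta_lU2", "sd_lU", "alpha_lKnU0",
                  "beta_lKnU1", "sd_lKnU", "alpha_POu", "beta_POu", "phi1",
                  "alpha_F", "alpha_M", "beta_PAL", "phi2", "alpha_PAP",
                  "beta_PAP", "phi3"]
        for ps in sets.values():
            ps.for_params(needed)  # raises if any is missing

    def test_unknown_name_rejected(self):
        with pytest.raises(bc.InvalidInputError):
            bc.get_prior_set("vague")


class TestStructureNonmuscleFit:
    def test_grid_integration_oracle(self, fast_sampler):
        """Posterior means versus brute-force numerical integration.

        Small regression, flat priors: the posterior over (intercept,
        slope, log sd) is integrated on a dense grid, independently of the
        MCMC path.
        """
        rng = np.random.default_rng(0)
        n = 12
        L = rng.uniform(1.0, 2.5, n)
        lnK = 2.5 + 2.8 * np.log(L) + rng.normal(0, 0.1, n)
        df = pd.DataFrame({
            "id": [f"b{i}" for i in range(n)], "sex": ["F"] * n,
            "length_m": L, "mass_kg": np.exp(lnK) * 3,
            "muscle_kg": np.exp(lnK), "adipose_kg": np.exp(lnK),
            "hide_kg": np.exp(lnK) * 0.35, "viscera_kg": np.exp(lnK) * 0.30,
            "bones_kg": np.exp(lnK) * 0.35,
        })
        df["mass_kg"] = df[["muscle_kg", "adipose_kg", "hide_kg",
                            "viscera_kg", "bones_kg"]].sum(axis=1)
        fit = bc.fit_structure_nonmuscle(df, bc.get_prior_set("unrestricted"),
                                         fast_sampler)
        # independent oracle: dense-grid posterior for the same flat-prior
        # model, ln K_nU ~ N(a + b lnL, sd), density 1/sd Jacobian-free in
        # (a, b, ln sd) with flat prior on (a, b) and on sd > 0.
        lnL = np.log(L)
        y = np.log(df[["hide_kg", "viscera_kg", "bones_kg"]].sum(axis=1))
        m, s = fit.summary["mean"], fit.summary["sd"]
        a_g = np.linspace(m["alpha_lKnU0"] - 6 * s["alpha_lKnU0"],
                          m["alpha_lKnU0"] + 6 * s["alpha_lKnU0"], 160)
        b_g = np.linspace(m["beta_lKnU1"] - 6 * s["beta_lKnU1"],
                          m["beta_lKnU1"] + 6 * s["beta_lKnU1"], 160)
        s_lo, s_hi = m["sd_lKnU"] / 4, m["sd_lKnU"] * 6
        s_g = np.linspace(np.log(s_lo), np.log(s_hi), 160)
        A, B, S = np.meshgrid(a_g, b_g, s_g, indexing="ij")
        sd = np.exp(S)
        ll = sum(normal_logpdf(y[i], A + B * lnL[i], sd) for i in range(n))
        ll += S  # Jacobian: flat prior on sd, integrated over ln sd
        w = np.exp(ll - ll.max())
        w /= w.sum()
        for name, grid in (("alpha_lKnU0", A), ("beta_lKnU1", B),
                           ("sd_lKnU", sd)):
            oracle_mean = float((w * grid).sum())
            assert fit.posterior_means[name] == pytest.approx(
                oracle_mean, abs=0.15 * s[name])

    def test_noiseless_exponent_recovery(self, fast_sampler):
        rng = np.random.default_rng(1)
        L = rng.uniform(1.0, 2.5, 40)
        KnU = np.exp(1.0 + 3.0 * np.log(L) + rng.normal(0, 1e-4, 40))
        df = pd.DataFrame({
            "id": range(40), "sex": ["M"] * 40, "length_m": L,
            "mass_kg": KnU * 3, "muscle_kg": KnU, "adipose_kg": KnU,
            "hide_kg": KnU * 0.35, "viscera_kg": KnU * 0.3,
            "bones_kg": KnU * 0.35})
        df["mass_kg"] = df[["muscle_kg", "adipose_kg", "hide_kg",
                            "viscera_kg", "bones_kg"]].sum(axis=1)
        fit = bc.fit_structure_nonmuscle(
            df, bc.get_prior_set("weakly_informative"), fast_sampler)
        assert fit.posterior_means["beta_lKnU1"] == pytest.approx(3.0,
                                                                  abs=0.01)

    def test_fitted_exponent_below_three_on_realistic_data(
            self, dissection_df, fast_sampler):
        fit = bc.fit_structure_nonmuscle(
            dissection_df, bc.get_prior_set("weakly_informative"),
            fast_sampler)
        assert fit.posterior_means["beta_lKnU1"] < 3.0


class TestCombinedFit:
    def test_underdetermined_data_rejected(self, truth, fast_sampler):
        df = bc.gen_dissection(bc.GeneratorConfig(seed=1, n_dissection=5)
                               ).iloc[:2]
        with pytest.raises(IdentifiabilityError):
            bc.fit_combined(df, truth.smi, bc.get_prior_set("unrestricted"),
                            fast_sampler)

    def test_posterior_orientation_on_synthetic_data(self, dissection_df,
                                                     truth, fast_sampler):
        """Slope signs and magnitudes match the generating regime."""
        fit = bc.fit_combined(dissection_df, truth.smi,
                              bc.get_prior_set("weakly_informative"),
                              fast_sampler)
        m = fit.posterior_means
        assert m["beta_POu"] < 0  # storage muscle declines with condition
        assert 2.0 < m["beta_lU1"] < 3.5
        assert fit.diagnostics["divergences"] == 0

    def test_determinism(self, dissection_df, truth, fast_sampler):
        f1 = bc.fit_combined(dissection_df, truth.smi,
                             bc.get_prior_set("weakly_informative"),
                             fast_sampler)
        f2 = bc.fit_combined(dissection_df, truth.smi,
                             bc.get_prior_set("weakly_informative"),
                             fast_sampler)
        np.testing.assert_array_equal(f1.draws, f2.draws)

    def test_two_stage_fallback(self, dissection_df, truth, fast_sampler):
        out = bc.fit_combined_two_stage(dissection_df, truth.smi,
                                        bc.get_prior_set("weakly_informative"),
                                        fast_sampler)
        assert set(out) == {"regression", "allocation"}
        assert out["allocation"].posterior_means["beta_POu"] < 0
        assert "n_dropped_invalid_latent" in out["allocation"].flags


class TestSexVaryingVariant:
    def test_requires_both_sexes(self, truth, fast_sampler):
        df = bc.gen_dissection(bc.GeneratorConfig(seed=3, n_dissection=30))
        df = df[df.sex == "F"]
        with pytest.raises(IdentifiabilityError):
            bc.fit_combined_sex_varying(df, truth.smi,
                                        bc.get_prior_set("weakly_informative"),
                                        fast_sampler)

    def test_sex_levels_overlap_on_homogeneous_data(self, dissection_df,
                                                    truth, fast_sampler):
        """The generator has no sex effect in allocation, so the
        sex-specific posteriors should overlap."""
        fit = bc.fit_combined_sex_varying(
            dissection_df, truth.smi, bc.get_prior_set("weakly_informative"),
            fast_sampler)
        lo_f, hi_f = fit.credible_interval("alpha_POu_F")
        lo_m, hi_m = fit.credible_interval("alpha_POu_M")
        assert max(lo_f, lo_m) < min(hi_f, hi_m)  # intervals overlap


class TestAdiposeLipidFit:
    def test_emcee_cross_check(self, fast_sampler):
        """Same posterior via an independent sampler and density code."""
        emcee = pytest.importorskip("emcee")
        cfg = bc.GeneratorConfig(seed=5, n_biopsy=80)
        df = bc.gen_biopsy(cfg)
        smi = cfg.truth.smi
        fit = bc.fit_adipose_lipid(df, smi,
                                   bc.get_prior_set("weakly_informative"),
                                   fast_sampler)
        from bearcomp.smi import scaled_mass_index
        s = scaled_mass_index(df.mass_kg.to_numpy(), df.length_m.to_numpy(),
                              smi)
        P = df.lipid_proportion.to_numpy()
        isf = (df.sex == "F").to_numpy()

        def lp(theta):
            aF, aM, b, lphi = theta
            phi = np.exp(lphi)
            if not (0 < phi < 100):
                return -np.inf
            mu = expit(np.where(isf, aF, aM) + b * s)
            ll = stats.beta.logpdf(P, mu * phi, (1 - mu) * phi).sum()
            prior = stats.norm.logpdf([aF, aM, b], 0, 2).sum() - np.log(100)
            return ll + prior + lphi  # Jacobian for log-phi

        ndim, nwalk = 4, 24
        p0 = np.array([0.0, 0.0, 0.005, np.log(30.0)])
        rng = np.random.default_rng(2)
        start = p0 + 0.01 * rng.standard_normal((nwalk, ndim))
        sampler = emcee.EnsembleSampler(nwalk, ndim, lp)
        state = emcee.State(start,
                            random_state=np.random.RandomState(3).get_state())
        sampler.run_mcmc(state, 4000)
        chain = sampler.get_chain(discard=1500, flat=True)
        ref = {"alpha_F": chain[:, 0].mean(), "alpha_M": chain[:, 1].mean(),
               "beta_PAL": chain[:, 2].mean(),
               "phi2": np.exp(chain[:, 3]).mean()}
        for k, v in ref.items():
            sd = fit.summary.loc[k, "sd"]
            assert fit.posterior_means[k] == pytest.approx(v, abs=0.2 * sd + 1e-4)

    def test_boundary_proportions_rejected(self, truth, fast_sampler):
        df = bc.gen_biopsy(bc.GeneratorConfig(seed=6, n_biopsy=20))
        df.loc[df.index[0], "lipid_proportion"] = 1.0
        with pytest.raises(bc.InvalidInputError):
            bc.fit_adipose_lipid(df, truth.smi,
                                 bc.get_prior_set("weakly_informative"),
                                 fast_sampler)

    def test_single_sex_fit_flagged(self, truth, fast_sampler):
        df = bc.gen_biopsy(bc.GeneratorConfig(seed=7, n_biopsy=80))
        df = df[df.sex == "F"]
        fit = bc.fit_adipose_lipid(df, truth.smi,
                                   bc.get_prior_set("unrestricted"),
                                   fast_sampler)
        assert fit.flags.get("missing_sex") == ["M"]

    def test_fitted_relationships_match_generating_regime(
            self, truth, fast_sampler):
        df = bc.gen_biopsy(bc.GeneratorConfig(seed=8, n_biopsy=140))
        fit = bc.fit_adipose_lipid(df, truth.smi,
                                   bc.get_prior_set("weakly_informative"),
                                   fast_sampler)
        m = fit.posterior_means
        assert m["beta_PAL"] > 0  # weakly positive with condition
        assert m["alpha_F"] > m["alpha_M"]


class TestAdiposeProteinFit:
    def test_constant_proportions_give_flat_slope(self, fast_sampler):
        rng = np.random.default_rng(9)
        df = pd.DataFrame({"lipid_proportion": rng.uniform(0.45, 0.75, 40),
                           "protein_proportion": rng.beta(30, 170, 40)})
        fit = bc.fit_adipose_protein(df, bc.get_prior_set("weakly_informative"),
                                     fast_sampler)
        lo, hi = fit.credible_interval("beta_PAP")
        assert lo < 0 < hi

    def test_negative_slope_on_decay_shaped_data(self, truth, fast_sampler):
        df = bc.gen_adipose_chem(bc.GeneratorConfig(seed=10, n_chem=60))
        fit = bc.fit_adipose_protein(df, bc.get_prior_set("weakly_informative"),
                                     fast_sampler)
        assert fit.posterior_means["beta_PAP"] < 0


class TestDataValidation:
    def test_mass_closure_enforced(self, dissection_df):
        bad = dissection_df.copy()
        bad.loc[bad.index[0], "mass_kg"] *= 1.2
        with pytest.raises(bc.InvalidInputError):
            validate_dissection(bad)

    def test_recovery_within_posterior_intervals(self, truth):
        """Parameter recovery for the exactly specified beta regressions.

        A reduced-replicate version of the full recovery study: pooled
        coverage of central 95% intervals across replicates and parameters
        should be near nominal.
        """
        hits = tot = 0
        for r in range(5):
            cfg = bc.GeneratorConfig(seed=300 + r, n_biopsy=140, n_chem=25)
            s = bc.SamplerConfig(chains=2, warmup_iterations=800,
                                 sampling_iterations=1500, seed=r)
            fit = bc.fit_adipose_lipid(bc.gen_biopsy(cfg), truth.smi,
                                       bc.get_prior_set("weakly_informative"),
                                       s)
            for k, v in (("alpha_F", -0.25), ("alpha_M", -0.45),
                         ("beta_PAL", 0.0055), ("phi2", 40.0)):
                lo, hi = fit.credible_interval(k)
                hits += lo <= v <= hi
                tot += 1
            fit = bc.fit_adipose_protein(bc.gen_adipose_chem(cfg),
                                         bc.get_prior_set("weakly_informative"),
                                         s)
            for k, v in (("alpha_PAP", -0.145), ("beta_PAP", -2.5),
                         ("phi3", 35.0)):
                lo, hi = fit.credible_interval(k)
                hits += lo <= v <= hi
                tot += 1
        assert hits / tot >= 0.8
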