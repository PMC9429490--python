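"""ML covariance-structure engine: algebra, fitting, indices, effects."""

import numpy as np
import pandas as pd
import pytest

from floodrisk import sem_engine as se
from floodrisk import synthetic_data as sd
from oracle_sem import OracleModel


@pytest.fixture(scope="module")
def spec():
    return se.build_default_spec()


class TestSpec:
    def test_default_topology(self, spec):
        assert spec.n_observed == 28
        assert len(spec.latents) == 4
        assert len(spec.structural_edges) == 4
        assert spec.df == 343 >= 0

    def test_pure_cfa_remains_valid(self, spec):
        cfa = se.SemModelSpec(
            latents=spec.latents,
            indicators=spec.indicators,
            structural_edges=(),
            exogenous_covariances=spec.exogenous_covariances,
        )
        assert cfa.df >= 0 and cfa.endogenous == ()

    def test_cyclic_graph_rejected(self, spec):
        with pytest.raises(ValueError, match="acyclic"):
            se.SemModelSpec(
                latents=spec.latents,
                indicators=spec.indicators,
                structural_edges=(("help", "php"), ("php", "help")),
            )

    def test_yaml_round_trip(self, spec):
        back = se.SemModelSpec.from_yaml(spec.to_yaml())
        assert back == spec


class TestImpliedCovariance:
    def test_no_paths_identity_loadings(self):
        spec4 = se.SemModelSpec(
            latents=("severity", "preparedness", "help", "php"),
            indicators=tuple(
                (f"x{i}", lat)
                for i, lat in enumerate(("severity", "preparedness", "help", "php"))
            ),
            structural_edges=(),
        )
        psi = np.diag([1.0, 1.0, 0.8, 0.9])
        params = se.SemParams(
            loadings=np.eye(4), beta=np.zeros((4, 4)), psi=psi, theta=np.zeros((4, 4))
        )
        np.testing.assert_allclose(se.implied_covariance(spec4, params), psi, atol=1e-14)

    def test_matches_generator_analytic_covariance(self, spec, default_config):
        params = se.params_from_generator_config(default_config, spec)
        sigma = se.implied_covariance(spec, params)
        pop = sd.implied_population_covariance(default_config).to_numpy()
        np.testing.assert_allclose(sigma, pop, atol=1e-12)

    def test_symmetry(self, spec, default_config):
        params = se.params_from_generator_config(default_config, spec)
        sigma = se.implied_covariance(spec, params)
        np.testing.assert_allclose(sigma, sigma.T, atol=0)


class TestGradient:
    def test_analytic_gradient_matches_finite_differences(self, spec, default_config):
        params = se.params_from_generator_config(default_config, spec)
        s_mat = se.implied_covariance(spec, params) + 0.05 * np.eye(28)
        _, logdet_s = np.linalg.slogdet(s_mat)
        template = se._pack_template(spec)
        rng = np.random.default_rng(0)
        x = se._start_values(spec, s_mat) * rng.uniform(0.9, 1.1, 63)
        f0, grad = se._fml_and_grad(x, spec, s_mat, logdet_s, template)
        eps = 1e-6
        for j in rng.choice(63, size=15, replace=False):
            xp = x.copy()
            xp[j] += eps
            fp, _ = se._fml_and_grad(xp, spec, s_mat, logdet_s, template)
            xm = x.copy()
            xm[j] -= eps
            fm, _ = se._fml_and_grad(xm, spec, s_mat, logdet_s, template)
            assert grad[j] == pytest.approx((fp - fm) / (2 * eps), rel=1e-4, abs=1e-7)


class TestFitML:
    def test_zero_discrepancy_recovers_parameters(self, spec, default_config):
        params0 = se.params_from_generator_config(default_config, spec)
        sigma0 = se.implied_covariance(spec, params0)
        fit = se.fit_ml(spec, sigma0, 560)
        assert fit.converged
        assert fit.chi_square == pytest.approx(0.0, abs=1e-4)
        std = se.standardized_solution(fit)
        assert std.paths[("severity", "php")] == pytest.approx(0.287, abs=1e-4)
        assert std.paths[("preparedness", "help")] == pytest.approx(0.452, abs=1e-4)
        assert std.exo_correlations[("severity", "preparedness")] == pytest.approx(0.534, abs=1e-4)
        np.testing.assert_allclose(std.loadings.to_numpy(), 0.7, atol=1e-4)

    def test_fml_nonnegative_and_zero_iff_exact(self, spec, default_config):
        params0 = se.params_from_generator_config(default_config, spec)
        sigma0 = se.implied_covariance(spec, params0)
        exact = se.fit_ml(spec, sigma0, 560)
        assert 0.0 <= exact.fml < 1e-9
        perturbed = se.fit_ml(spec, sigma0 + 0.02 * np.eye(28), 560)
        assert perturbed.fml >= 0.0

    def test_large_sample_recovery_of_published_path(self, spec):
        cfg = sd.GeneratorConfig(n_respondents=100_000, seed=42)
        ds = sd.generate_survey(cfg)
        s_mat = np.cov(ds.items.to_numpy().T.astype(float), ddof=1)
        fit = se.fit_ml(spec, s_mat, cfg.n_respondents)
        std = se.standardized_solution(fit)
        assert std.paths[("severity", "php")] == pytest.approx(0.287, abs=0.02)

    def test_invalid_inputs_rejected(self, spec):
        with pytest.raises(ValueError, match="positive definite"):
            se.fit_ml(spec, np.zeros((28, 28)), 560)
        with pytest.raises(ValueError, match="sample size"):
            se.fit_ml(spec, np.eye(28), 20)

    def test_labelled_covariance_reordered_by_item(self, spec, default_config):
        pop = sd.implied_population_covariance(default_config)
        shuffled = pop.iloc[::-1, ::-1]
        fit = se.fit_ml(spec, shuffled, 560)
        assert fit.chi_square == pytest.approx(0.0, abs=1e-4)


class TestStandardizedSolution:
    def test_scaling_an_indicator_leaves_solution_unchanged(self, spec):
        cfg = sd.GeneratorConfig(n_respondents=2_000, seed=9)
        ds = sd.generate_survey(cfg, discretize=False)
        data = ds.items.to_numpy().copy()
        s1 = np.cov(data.T, ddof=1)
        data[:, 0] *= 10.0
        s2 = np.cov(data.T, ddof=1)
        f1 = se.fit_ml(spec, s1, 2_000)
        f2 = se.fit_ml(spec, s2, 2_000)
        a, b = se.standardized_solution(f1), se.standardized_solution(f2)
        for key in a.paths:
            assert a.paths[key] == pytest.approx(b.paths[key], abs=1e-5)
        np.testing.assert_allclose(a.loadings.to_numpy(), b.loadings.to_numpy(), atol=1e-5)


class TestFitIndices:
    def test_published_ratio_and_rmsea(self):
        idx = se.fit_indices_from_stats(chi_square=479.757, df=160, n=560)
        assert round(idx.chi_square_ratio, 3) == 2.998
        assert round(idx.rmsea, 3) == 0.060

    def test_chi_square_equal_df_is_saturated_fit(self):
        idx = se.fit_indices_from_stats(150.0, 150, 560, baseline_chi_square=5000.0, baseline_df=378)
        assert idx.rmsea == 0.0 and idx.cfi == 1.0

    def test_df_zero_signalled(self):
        with pytest.raises(ValueError):
            se.fit_indices_from_stats(10.0, 0, 560)

    def test_fitted_model_indices_near_perfect_on_population_cov(self, spec, default_config):
        params0 = se.params_from_generator_config(default_config, spec)
        fit = se.fit_ml(spec, se.implied_covariance(spec, params0), 560)
        idx = se.fit_indices(fit)
        assert idx.cfi == pytest.approx(1.0, abs=1e-6)
        assert idx.rmsea == pytest.approx(0.0, abs=1e-6)


class TestEffects:
    def test_published_indirect_and_total_effects(self):
        table = se.effects_from_paths(
            {
                ("severity", "php"): 0.287,
                ("preparedness", "php"): -0.008,
                ("help", "php"): -0.029,
                ("preparedness", "help"): 0.452,
            }
        )
        ie = table.indirect[("preparedness", "php")]
        assert ie == pytest.approx(0.452 * -0.029, abs=1e-12)
        assert round(ie, 3) == -0.013
        assert round(table.total("preparedness", "php"), 3) == -0.021
        assert table.total("severity", "php") == pytest.approx(0.287)
        assert ("severity", "php") not in table.indirect  # no mediated path

    def test_te_equals_de_plus_ie_for_every_pair(self, spec, default_config):
        params0 = se.params_from_generator_config(default_config, spec)
        fit = se.fit_ml(spec, se.implied_covariance(spec, params0), 560)
        df = se.effect_decomposition(fit).to_dataframe()
        np.testing.assert_allclose(df["TE"], df["DE"] + df["IE"], atol=0)


class TestSquaredMultipleCorrelations:
    def test_help_r2_from_single_predictor(self, spec, default_config):
        params0 = se.params_from_generator_config(default_config, spec)
        fit = se.fit_ml(spec, se.implied_covariance(spec, params0), 560)
        smc = se.squared_multiple_correlations(fit)
        assert smc["help"] == pytest.approx(0.452**2, abs=1e-4)  # 20.4%
        assert smc["php"] == pytest.approx(0.077, abs=5e-4)

    def test_all_paths_zero_gives_zero_r2(self, spec):
        cfg = sd.GeneratorConfig(
            structural_paths={k: 0.0 for k in sd.DEFAULT_STRUCTURAL_PATHS},
            exo_correlation_F_P=0.3,
        )
        params0 = se.params_from_generator_config(cfg, spec)
        fit = se.fit_ml(spec, se.implied_covariance(spec, params0), 560)
        for v in se.squared_multiple_correlations(fit).values():
            assert v == pytest.approx(0.0, abs=1e-5)


class TestOracleEquivalence:
    def test_agrees_with_independent_fitter_on_random_small_models(self):
        """Two independently written ML fitters (different identification and
        optimizers) must produce the same standardized solution."""
        rng = np.random.default_rng(2024)
        for trial in range(20):
            lam1 = rng.uniform(0.5, 0.9, 3)
            lam2 = rng.uniform(0.5, 0.9, 3)
            beta = rng.uniform(-0.6, 0.6)
            lam = np.zeros((6, 2))
            lam[:3, 0] = lam1
            lam[3:, 1] = lam2
            b = np.array([[0.0, 0.0], [beta, 0.0]])
            psi = np.diag([1.0, 1.0 - beta**2])
            a = np.linalg.inv(np.eye(2) - b)
            sigma_true = lam @ a @ psi @ a.T @ lam.T + np.diag(1 - (lam**2).sum(1))
            data = rng.multivariate_normal(np.zeros(6), sigma_true, size=500)
            s_mat = np.cov(data.T, ddof=1)

            spec2 = se.SemModelSpec(
                latents=("l1", "l2"),
                indicators=tuple((f"x{i}", "l1" if i < 3 else "l2") for i in range(6)),
                structural_edges=(("l1", "l2"),),
            )
            fit = se.fit_ml(spec2, s_mat, 500, seed=trial)
            std = se.standardized_solution(fit)

            oracle = OracleModel(blocks=[3, 3], edges=[(0, 1)])
            res = oracle.fit(s_mat, 500)
            o_load, o_paths = oracle.standardized(res.x)

            assert fit.fml == pytest.approx(res.fun, abs=1e-6)
            assert std.paths[("l1", "l2")] == pytest.approx(o_paths[0], abs=1e-3)
            np.testing.assert_allclose(
                std.loadings.to_numpy(), o_load, atol=1e-3
            )


class TestChiSquareCalibration:
    def test_mean_chi_square_near_df(self, recovery_200):
        """Fitting the true model to 200 synthetic samples: the empirical mean
        chi-square should sit within 10% of the model degrees of freedom."""
        assert recovery_200.converged.all()
        assert abs(recovery_200.mean_chi_square - recovery_200.df) < 0.10 * recovery_200.df
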