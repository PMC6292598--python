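import subprocess
import textwrap

import numpy as np
import pytest

import stepwedge as sw
from stepwedge.lme import _LikelihoodData

from conftest import dense_gaussian_loglik, random_tiny_instance


class TestClusterBlockCovariance:
    def test_cs_entries(self):
        vc = sw.VarianceComponents(0.9, 1.5, 2.0, 0.0)
        V = sw.cluster_block_covariance(vc, m=3, n=4, structure="CS")
        assert V.shape == (12, 12)
        assert np.allclose(np.diag(V), 0.9**2 + 1.5**2 + 2.0**2)
        # within-participant off-diagonal: cluster + participant components
        assert V[0, 1] == pytest.approx(0.9**2 + 1.5**2)
        # across participants, same cluster: cluster component only
        assert V[0, 4] == pytest.approx(0.9**2)
        assert np.all(np.linalg.eigvalsh(V) > 0)

    def test_ar1_lag_structure(self):
        vc = sw.VarianceComponents(0.5, 1.0, 2.0, 0.4)
        V = sw.cluster_block_covariance(vc, m=2, n=3, structure="AR1")
        assert V[0, 1] == pytest.approx(0.5**2 + 1.0**2 + 2.0**2 * 0.4)
        assert V[0, 2] == pytest.approx(0.5**2 + 1.0**2 + 2.0**2 * 0.4**2)

    def test_iid_limit(self):
        vc = sw.VarianceComponents(0.0, 0.0, 1.7, 0.0)
        for s in ("CS", "AR1"):
            assert np.allclose(
                sw.cluster_block_covariance(vc, 2, 3, s), 1.7**2 * np.eye(6)
            )

    def test_bad_arguments(self):
        with pytest.raises(ValueError):
            sw.cluster_block_covariance(sw.VarianceComponents(), 0, 3)
        with pytest.raises(ValueError):
            sw.cluster_block_covariance(sw.VarianceComponents(), 2, 2, "Toeplitz")


class TestProfiledLoglik:
    @pytest.mark.parametrize("structure", ["CS", "AR1"])
    @pytest.mark.parametrize("unbalanced", [False, True])
    def test_matches_dense_oracle(self, structure, unbalanced):
        rng = np.random.default_rng(20181206)
        for _ in range(10):
            rows, X, y, vc = random_tiny_instance(rng, unbalanced=unbalanced)
            ll, beta, vcov = sw.profiled_loglik(
                vc, X, y, rows[:, 0], rows[:, 1], rows[:, 2], structure
            )
            ll_dense, beta_dense = dense_gaussian_loglik(rows, X, y, vc, structure)
            assert ll == pytest.approx(ll_dense, abs=1e-8)
            assert beta == pytest.approx(beta_dense, abs=1e-8)
            assert np.allclose(vcov, vcov.T)
            assert np.all(np.linalg.eigvalsh(vcov) > -1e-12)

    def test_gls_reduces_to_ols_for_iid(self):
        rng = np.random.default_rng(3)
        rows, X, y, _ = random_tiny_instance(rng)
        vc = sw.VarianceComponents(0.0, 0.0, 1.3, 0.0)
        _, beta, _ = sw.profiled_loglik(
            vc, X, y, rows[:, 0], rows[:, 1], rows[:, 2], "CS"
        )
        beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert beta == pytest.approx(beta_ols, abs=1e-10)

    def test_rank_deficiency_names_columns(self):
        rng = np.random.default_rng(4)
        rows, X, y, vc = random_tiny_instance(rng)
        X = np.column_stack([X, X[:, 1]])  # duplicate a column
        with pytest.raises(np.linalg.LinAlgError, match="dup|x1"):
            sw.profiled_loglik(
                vc, X, y, rows[:, 0], rows[:, 1], rows[:, 2], "CS",
                names=["const", "x1", "x2", "dup"],
            )


class TestFitML:
    def test_refit_is_bit_identical(self, d17_small):
        a = sw.fit_formulation(d17_small, "M4", "CS")
        b = sw.fit_formulation(d17_small, "M4", "CS")
        assert a.loglik == b.loglik
        assert (a.beta == b.beta).all()
        assert a.varcomp == b.varcomp

    def test_bic_identity(self, m4_fit_small):
        fit = m4_fit_small
        assert fit.bic == pytest.approx(
            -2 * fit.loglik + fit.n_params * np.log(fit.n_obs)
        )
        assert fit.n_params == len(fit.beta) + 3  # CS: 3 variance parameters

    def test_ar1_counts_one_more_parameter(self, d17_small):
        fit = sw.fit_formulation(d17_small, "M1", "AR1")
        assert fit.n_params == len(fit.beta) + 4

    def test_unit_scaling_equivariance(self, d17_small):
        fit1 = sw.fit_formulation(d17_small, "M2", "CS")
        scaled = sw.TrialDataset(d17_small.df.assign(y=d17_small.df["y"] * 2.0))
        fit2 = sw.fit_formulation(scaled, "M2", "CS")
        assert fit2.beta.to_numpy() == pytest.approx(
            2.0 * fit1.beta.to_numpy(), rel=1e-4
        )
        assert np.diag(fit2.vcov_beta) == pytest.approx(
            4.0 * np.diag(fit1.vcov_beta), rel=1e-3
        )

    def test_cs_invariant_to_time_permutation_ar1_not(self, d17_small):
        rng = np.random.default_rng(8)
        perm = rng.permutation(np.arange(1, 14)) + 0
        df = d17_small.df.copy()
        # relabel the time values only in the covariance sense: shuffle each
        # subject's rows (X stays tied to the original rows)
        X, names = sw.design_matrix("M1", d17_small)
        y = df["y"].to_numpy()
        cl, su = df["cluster_id"].to_numpy(), df["subject_id"].to_numpy()
        t_orig = df["time"].to_numpy(dtype=float)
        t_perm = np.asarray([perm[int(t) - 1] for t in t_orig], dtype=float)
        vc = sw.VarianceComponents(0.9, 4.0, 5.0, 0.0)
        ll_cs_a, _, _ = sw.profiled_loglik(vc, X, y, cl, su, t_orig, "CS")
        ll_cs_b, _, _ = sw.profiled_loglik(vc, X, y, cl, su, t_perm, "CS")
        assert ll_cs_a == pytest.approx(ll_cs_b, abs=1e-6)
        vc_ar = sw.VarianceComponents(0.9, 4.0, 5.0, 0.5)
        ll_ar_a, _, _ = sw.profiled_loglik(vc_ar, X, y, cl, su, t_orig, "AR1")
        ll_ar_b, _, _ = sw.profiled_loglik(vc_ar, X, y, cl, su, t_perm, "AR1")
        assert abs(ll_ar_a - ll_ar_b) > 1.0

    def test_matches_reference_mixed_model_software(self, tmp_path, d17_small):
        """Full ML fit agrees with nlme::lme (nested intercepts, ML) in R."""
        csv = tmp_path / "trial.csv"
        d17_small.to_csv(csv)
        script = textwrap.dedent(f"""
            suppressMessages(library(nlme))
            d <- read.csv('{csv}')
            d$cluster_id <- factor(d$cluster_id)
            d$subject_id <- factor(d$subject_id)
            m <- lme(y ~ treated + time + exposure,
                     random = ~1 | cluster_id/subject_id, data = d, method = 'ML')
            ma <- lme(y ~ treated + time + exposure,
                      random = ~1 | cluster_id/subject_id,
                      correlation = corAR1(form = ~ time | cluster_id/subject_id),
                      data = d, method = 'ML')
            cat(logLik(m), BIC(m), fixef(m), logLik(ma), BIC(ma), fixef(ma),
                coef(ma$modelStruct$corStruct, unconstrained = FALSE), sep='\\n')
        """)
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        vals = [float(v) for v in out.stdout.split()]
        ll_cs, bic_cs, beta_cs = vals[0], vals[1], vals[2:6]
        ll_ar, bic_ar, beta_ar, rho = vals[6], vals[7], vals[8:12], vals[12]

        fit_cs = sw.fit_formulation(d17_small, "M4", "CS")
        assert fit_cs.loglik == pytest.approx(ll_cs, abs=1e-3)
        assert fit_cs.bic == pytest.approx(bic_cs, abs=1e-2)
        assert fit_cs.beta.to_numpy() == pytest.approx(beta_cs, abs=1e-3)

        fit_ar = sw.fit_formulation(d17_small, "M4", "AR1")
        assert fit_ar.loglik == pytest.approx(ll_ar, abs=1e-3)
        assert fit_ar.bic == pytest.approx(bic_ar, abs=1e-2)
        assert fit_ar.beta.to_numpy() == pytest.approx(beta_ar, abs=1e-3)
        assert fit_ar.varcomp.rho == pytest.approx(rho, abs=1e-3)

    def test_variance_recovery_at_moderate_size(self):
        # one large balanced dataset: estimates near the generating values
        design = sw.standard_design(12, 80)
        data = sw.simulate_trial(design, sw.get_scenario("D10"), 99)
        fit = sw.fit_formulation(data, "M1", "AR1")
        assert fit.converged
        assert fit.varcomp.sigma_h == pytest.approx(4.42, abs=0.45)
        assert fit.varcomp.sigma == pytest.approx(5.44, abs=0.35)
        assert fit.varcomp.rho == pytest.approx(0.5, abs=0.1)

    def test_cs_and_ar1_agree_on_intervention_estimate(self, d17_dataset):
        # misspecifying the residual correlation barely moves the fixed effects
        cs = sw.fit_formulation(d17_dataset, "M4", "CS")
        ar = sw.fit_formulation(d17_dataset, "M4", "AR1")
        c = sw.contrast("M4", "six_month")
        e_cs = sw.estimate_effect(cs, c).estimate
        e_ar = sw.estimate_effect(ar, c).estimate
        assert e_cs == pytest.approx(e_ar, abs=0.2)


class TestFittedValues:
    def test_conditional_beats_marginal_on_null_data(self, d1_small):
        fit = sw.fit_formulation(d1_small, "M1", "CS")
        mse_cond = sw.mse_of_fit(fit, d1_small, conditional=True)
        mse_marg = sw.mse_of_fit(fit, d1_small, conditional=False)
        assert mse_cond < mse_marg  # shrinkage removes participant variance

    def test_mse_invariant_to_row_order(self, d1_small):
        fit = sw.fit_formulation(d1_small, "M1", "CS")
        shuffled = sw.TrialDataset(
            d1_small.df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        )
        assert sw.mse_of_fit(fit, shuffled) == pytest.approx(
            sw.mse_of_fit(fit, d1_small), abs=1e-10
        )

    def test_zero_variance_randoms_give_residual_mean_square(self, d1_small):
        from stepwedge.lme import fitted_values

        df = d1_small.df
        X, names = sw.design_matrix("M1", d1_small)
        fit = sw.fit_formulation(d1_small, "M1", "CS")
        # force zero random-effect variances: conditional == marginal
        from dataclasses import replace as drep

        fit0 = drep(
            fit, varcomp=sw.VarianceComponents(0.0, 0.0, fit.varcomp.sigma, 0.0)
        )
        yhat = fitted_values(
            fit0, X, df["y"].to_numpy(), df["cluster_id"], df["subject_id"],
            df["time"].to_numpy(float), conditional=True,
        )
        assert yhat == pytest.approx(X @ fit.beta.to_numpy(), abs=1e-10)


def test_likelihood_data_groups_balanced_clusters_together(d17_small):
    df = d17_small.df
    X, _ = sw.design_matrix("M1", d17_small)
    data = _LikelihoodData(
        X, df["y"].to_numpy(), df["cluster_id"].to_numpy(),
        df["subject_id"].to_numpy(), df["time"].to_numpy(float),
    )
    assert len(data.groups) == 1  # all clusters share one balanced pattern
    assert data.groups[0][0] == "balanced"
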