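"""Per-cohort EWAS: OLS/GLS fits, variance moderation, empirical null."""

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from metamethyl.annotation_io import MethylationDataset, SampleRecord
from metamethyl.ewas import (
    apply_empirical_null,
    estimate_consensus_correlation,
    estimate_empirical_null,
    fit_age_models,
    fit_age_models_gls,
    moderate_statistics,
    run_ewas,
    write_ewas_result,
    read_ewas_result,
)
from metamethyl.synthetic_data import CohortSpec, SimulationConfig, build_toy_annotation, simulate_multicohort


def make_dataset(beta: np.ndarray, samples):
    probes = [f"cg{i}" for i in range(beta.shape[0])]
    cols = [s.sample_id for s in samples]
    return MethylationDataset("d", pd.DataFrame(beta, index=probes, columns=cols), samples)


class TestOlsFit:
    def test_exact_linear_trend(self):
        samples = [SampleRecord(f"s{i}", f"u{i}", a) for i, a in enumerate([20, 30, 40, 50])]
        ds = make_dataset(np.array([[0.50, 0.52, 0.54, 0.56]]), samples)
        fit = fit_age_models(ds, covariates=())
        assert fit["b"].iloc[0] == pytest.approx(0.002, abs=1e-12)
        assert fit["s2"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert fit["degenerate"].iloc[0]  # zero residual variance

    def test_constant_probe_flagged_degenerate(self):
        samples = [SampleRecord(f"s{i}", f"u{i}", a) for i, a in enumerate([20, 30, 40, 50])]
        ds = make_dataset(np.full((1, 4), 0.5), samples)
        fit = fit_age_models(ds, covariates=())
        assert fit["b"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert fit["degenerate"].iloc[0]

    def test_constant_age_hard_error(self):
        samples = [SampleRecord(f"s{i}", f"u{i}", 30.0) for i in range(4)]
        ds = make_dataset(np.random.default_rng(0).uniform(0.2, 0.8, (2, 4)), samples)
        with pytest.raises(ValueError, match="age"):
            fit_age_models(ds, covariates=())

    def test_matches_normal_equations_with_covariate(self):
        ages = np.array([22.0, 31.0, 45.0, 52.0, 63.0, 70.0])
        sex = np.array([0, 1, 0, 1, 0, 1])
        y = np.array([0.42, 0.47, 0.51, 0.50, 0.58, 0.61])
        samples = [
            SampleRecord(f"s{i}", f"u{i}", a, sex="M" if s else "F")
            for i, (a, s) in enumerate(zip(ages, sex))
        ]
        ds = make_dataset(y[None, :], samples)
        fit = fit_age_models(ds, covariates=("sex",))
        # independent oracle: solve the normal equations explicitly
        X = np.column_stack([np.ones(6), ages, sex])
        beta_hat = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta_hat
        s2 = resid @ resid / (6 - 3)
        assert fit["b"].iloc[0] == pytest.approx(beta_hat[1], abs=1e-12)
        assert fit["s2"].iloc[0] == pytest.approx(s2, abs=1e-12)
        assert fit["df"].iloc[0] == 3

    def test_missing_values_complete_case(self):
        ages = [20.0, 30.0, 40.0, 50.0, 60.0, 70.0]
        samples = [SampleRecord(f"s{i}", f"u{i}", a) for i, a in enumerate(ages)]
        beta = np.random.default_rng(1).uniform(0.3, 0.7, (3, 6))
        beta[0, 2] = np.nan
        ds = make_dataset(beta, samples)
        fit = fit_age_models(ds, covariates=())
        mask = np.isfinite(beta[0])
        X = np.column_stack([np.ones(mask.sum()), np.array(ages)[mask]])
        oracle = np.linalg.solve(X.T @ X, X.T @ beta[0][mask])
        assert fit["b"].iloc[0] == pytest.approx(oracle[1], abs=1e-12)


class TestRepeatedMeasures:
    def _paired(self, subject_sd, noise_sd, n_probes=200, seed=0):
        rng = np.random.default_rng(seed)
        n_subj = 40
        ages = rng.uniform(20, 80, n_subj)
        samples, cols = [], []
        for i in range(n_subj):
            for t in range(2):
                samples.append(SampleRecord(f"s{i}_{t}", f"u{i}", ages[i] + 0.1 * t))
        u = rng.normal(0, subject_sd, (n_probes, n_subj))
        beta = np.empty((n_probes, 2 * n_subj))
        for i in range(n_subj):
            for t in range(2):
                beta[:, 2 * i + t] = 0.5 + u[:, i] + rng.normal(0, noise_sd, n_probes)
        return make_dataset(np.clip(beta, 0.01, 0.99), samples)

    def test_no_repeats_reduces_to_ols(self):
        samples = [SampleRecord(f"s{i}", f"u{i}", 20.0 + 5 * i) for i in range(8)]
        beta = np.random.default_rng(2).uniform(0.3, 0.7, (30, 8))
        ds = make_dataset(beta, samples)
        assert estimate_consensus_correlation(ds, covariates=()) == 0.0
        a = fit_age_models(ds, covariates=())
        b = fit_age_models_gls(ds, rho=0.0, covariates=())
        pd.testing.assert_frame_equal(a, b)

    def test_gls_small_rho_close_to_ols(self):
        ds = self._paired(0.02, 0.05)
        a = fit_age_models(ds, covariates=())
        b = fit_age_models_gls(ds, rho=1e-12, covariates=())
        assert np.allclose(a["b"], b["b"], atol=1e-10)
        assert np.allclose(a["s2"], b["s2"], atol=1e-10)

    def test_high_subject_variance_gives_high_rho(self):
        ds = self._paired(0.10, 0.02, seed=3)
        rho = estimate_consensus_correlation(ds, covariates=())
        assert rho > 0.8

    def test_zero_subject_variance_gives_rho_near_zero(self):
        ds = self._paired(0.0, 0.05, seed=4)
        rho = estimate_consensus_correlation(ds, covariates=())
        assert abs(rho) < 0.05


class TestModeration:
    def _fit_frame(self, s2, d):
        n = len(s2)
        return pd.DataFrame(
            {
                "b": np.zeros(n),
                "c": np.ones(n),
                "s2": s2,
                "df": np.full(n, float(d)),
                "degenerate": np.zeros(n, dtype=bool),
            },
            index=[f"cg{i}" for i in range(n)],
        )

    def test_prior_recovery_and_posterior_formula(self):
        # s^2 ~ s0^2 * chi2_d / d scaled by an inverse-chi2 prior with known d0
        rng = np.random.default_rng(8)
        d0, s02, d, n = 4.0, 0.01, 10, 20_000
        true_var = s02 * d0 / rng.chisquare(d0, n)
        s2 = true_var * rng.chisquare(d, n) / d
        table, d0_hat, s02_hat = moderate_statistics(self._fit_frame(s2, d))
        assert d0_hat == pytest.approx(d0, rel=0.15)
        assert s02_hat == pytest.approx(s02, rel=0.1)
        expected = (d0_hat * s02_hat + d * s2) / (d0_hat + d)
        assert np.allclose(table["s2_post"], expected, rtol=1e-12)
        assert np.all(table["df_total"] == d0_hat + d)

    def test_posterior_between_prior_and_sample(self):
        rng = np.random.default_rng(9)
        s2 = rng.chisquare(6, 5_000) / 6 * 0.02
        table, d0_hat, s02_hat = moderate_statistics(self._fit_frame(s2, 6))
        lo = np.minimum(s2, s02_hat)
        hi = np.maximum(s2, s02_hat)
        assert np.all(table["s2_post"] >= lo - 1e-15)
        assert np.all(table["s2_post"] <= hi + 1e-15)

    def test_homogeneous_variances_shrink_completely(self):
        # no hypervariability: d0 -> inf, every posterior equals the prior
        table, d0_hat, s02_hat = moderate_statistics(
            self._fit_frame(np.full(200, 0.02), 10)
        )
        assert np.isinf(d0_hat)
        assert np.allclose(table["s2_post"].dropna(), s02_hat)

    def test_too_few_probes_rejected(self):
        with pytest.raises(ValueError, match="50"):
            moderate_statistics(self._fit_frame(np.full(10, 0.02), 10))


class TestEmpiricalNull:
    def test_standard_normal_quantiles(self):
        z = stats.norm.ppf((np.arange(1, 10_002) - 0.5) / 10_001)
        mu0, sigma0, pi0 = estimate_empirical_null(z, seed=1)
        assert abs(mu0) < 0.01
        assert abs(sigma0 - 1.0) < 0.02

    def test_biased_inflated_null(self):
        rng = np.random.default_rng(5)
        z = 0.15 + 1.4 * rng.standard_normal(50_000)
        mu0, sigma0, _ = estimate_empirical_null(z, seed=1)
        assert mu0 == pytest.approx(0.15, abs=0.02)
        assert sigma0 == pytest.approx(1.40, abs=0.03)

    def test_contaminated_null(self):
        rng = np.random.default_rng(6)
        z = np.concatenate([rng.standard_normal(45_000), 4.0 + rng.standard_normal(5_000)])
        mu0, sigma0, _ = estimate_empirical_null(z, seed=1)
        assert abs(mu0) < 0.03
        assert abs(sigma0 - 1.0) < 0.05

    def test_apply_identity_and_example(self):
        z = np.array([-1.0, 0.0, 2.6])
        zc, pc = apply_empirical_null(z, 0.0, 1.0)
        assert np.allclose(zc, z)
        zc, pc = apply_empirical_null(np.array([2.6]), 0.1, 1.25)
        assert zc[0] == pytest.approx(2.0)
        assert pc[0] == pytest.approx(2 * stats.norm.sf(2.0))

    def test_apply_sign_symmetry(self):
        z = np.linspace(-3, 3, 11)
        zc_pos, _ = apply_empirical_null(z, 0.2, 1.3)
        zc_neg, _ = apply_empirical_null(-z, -0.2, 1.3)
        assert np.allclose(zc_pos, -zc_neg)

    def test_sigma_must_be_positive(self):
        with pytest.raises(ValueError):
            apply_empirical_null(np.zeros(5), 0.0, 0.0)


class TestRunEwas:
    @pytest.fixture(scope="class")
    def cohort(self):
        cohorts = (CohortSpec("c", "EPIC", 60, 2, 18, 85, 45.0, 16.0, 0.6, 1.0),)
        cfg = SimulationConfig(cohorts=cohorts, n_probes=1_500, slope_scale=0.0, seed=17)
        ann, _, _ = build_toy_annotation(cfg)
        datasets, _ = simulate_multicohort(ann, cfg)
        return datasets[0]

    def test_null_cohort_calibrated(self, cohort):
        res = run_ewas(cohort, seed=17)
        p = res.table["p_corr"].dropna()
        assert 0.02 < (p < 0.05).mean() < 0.09
        assert res.rho > 0  # repeated measures present
        assert 0.8 < res.sigma0 < 1.25

    def test_corrected_columns_consistent(self, cohort):
        res = run_ewas(cohort, seed=17)
        t = res.table.dropna(subset=["p_raw"])
        assert np.allclose(t["z_corr"], (t["z"] - res.mu0) / res.sigma0)
        assert np.allclose(t["se_corr"], res.sigma0 * t["se"])
        assert np.allclose(t["b_corr"], t["b"] - res.mu0 * t["se"])

    def test_m_value_scale_runs(self, cohort):
        res = run_ewas(cohort, scale="m", seed=17)
        assert res.table["p_corr"].notna().sum() > 1_000

    def test_result_tsv_round_trip(self, cohort, tmp_path):
        res = run_ewas(cohort, seed=17)
        path = tmp_path / "ewas.tsv"
        write_ewas_result(res, path)
        back = read_ewas_result(path)
        assert back.dataset_id == res.dataset_id
        assert back.sigma0 == pytest.approx(res.sigma0)
        assert np.allclose(back.table["b_corr"], res.table["b_corr"], equal_nan=True)
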