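"""Clock components: intersection, calibration, age transform, training, LODO."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from metamethyl.annotation_io import MethylationDataset, SampleRecord
from metamethyl.epigenetic_clock import (
    ClockModel,
    calibrate_to_reference,
    fit_beta_mixture,
    intersect_probes,
    inverse_transform_age,
    lodo_evaluate,
    predict_age,
    train_clock,
    transform_age,
)
from metamethyl.synthetic_data import CohortSpec, SimulationConfig, build_toy_annotation, simulate_multicohort


def quick_dataset(name, beta, ages=None):
    n = beta.shape[1]
    ages = ages if ages is not None else np.linspace(25, 65, n)
    samples = [SampleRecord(f"{name}_s{i}", f"{name}_u{i}", float(a)) for i, a in enumerate(ages)]
    return MethylationDataset(
        name,
        pd.DataFrame(beta, index=[f"cg{i}" for i in range(beta.shape[0])],
                     columns=[s.sample_id for s in samples]),
        samples,
    )


class TestIntersectProbes:
    def _ds(self, name, probes):
        beta = pd.DataFrame(
            {f"{name}_s0": np.full(len(probes), 0.5), f"{name}_s1": np.full(len(probes), 0.5)},
            index=probes,
        )
        samples = [SampleRecord(f"{name}_s0", "u0", 30.0), SampleRecord(f"{name}_s1", "u1", 40.0)]
        return MethylationDataset(name, beta, samples)

    def test_identity_and_pairwise(self):
        a = self._ds("a", ["A", "B", "C"])
        b = self._ds("b", ["B", "C", "D"])
        assert list(intersect_probes([a, a])) == ["A", "B", "C"]
        assert list(intersect_probes([a, b])) == ["B", "C"]

    def test_empty_intersection_error(self):
        a = self._ds("a", ["A"])
        b = self._ds("b", ["B"])
        with pytest.raises(ValueError, match="empty"):
            intersect_probes([a, b])

    def test_single_dataset_rejected(self):
        with pytest.raises(ValueError, match="2 datasets"):
            intersect_probes([self._ds("a", ["A"])])

    def test_intersection_size_matches_binomial_expectation(self):
        # six datasets each keeping an independent 70% of 5000 probes
        rng = np.random.default_rng(12)
        n, cov, k = 5_000, 0.7, 6
        probes = np.array([f"cg{i}" for i in range(n)])
        datasets = [
            self._ds(f"d{j}", sorted(rng.choice(probes, size=int(cov * n), replace=False)))
            for j in range(k)
        ]
        shared = intersect_probes(datasets)
        expect = n * cov**k
        sd = np.sqrt(n * cov**k * (1 - cov**k))
        assert abs(len(shared) - expect) < 4 * sd


class TestBetaMixture:
    def test_component_mean_recovery(self):
        rng = np.random.default_rng(7)
        x = np.concatenate(
            [rng.beta(2, 20, 4_000), rng.beta(5, 5, 2_000), rng.beta(20, 2, 4_000)]
        )
        mix = fit_beta_mixture(x, seed=0)
        assert mix.means[0] == pytest.approx(2 / 22, abs=0.03)
        assert mix.means[1] == pytest.approx(0.5, abs=0.03)
        assert mix.means[2] == pytest.approx(20 / 22, abs=0.03)

    def test_concentrated_data_dominated_by_middle_component(self):
        rng = np.random.default_rng(8)
        x = np.clip(0.5 + 0.02 * rng.standard_normal(3_000), 0.01, 0.99)
        mix = fit_beta_mixture(x, seed=0)
        assert mix.weights[np.argmin(np.abs(mix.means - 0.5))] > 0.9

    def test_input_order_invariance(self):
        rng = np.random.default_rng(9)
        x = np.concatenate([rng.beta(2, 10, 2_000), rng.beta(10, 2, 2_000)])
        a = fit_beta_mixture(x, seed=1)
        b = fit_beta_mixture(x[::-1], seed=1)
        assert np.allclose(a.means, b.means, atol=1e-9)
        assert np.allclose(a.weights, b.weights, atol=1e-9)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match="100"):
            fit_beta_mixture(np.full(50, 0.5))


class TestCalibration:
    def test_identical_distribution_maps_near_identity(self, bimodal_betas):
        ref_mix = fit_beta_mixture(bimodal_betas(40_000), seed=0)
        beta = np.column_stack([bimodal_betas(20_000) for _ in range(3)])
        ds = quick_dataset("t", beta)
        cal = calibrate_to_reference(ds, ref_mix, seed=0)
        dev = np.abs(cal.beta.to_numpy() - ds.beta.to_numpy())
        assert dev.max() < 0.01
        assert np.median(dev) < 0.005

    def test_shift_reduces_ks_distance_to_reference(self, bimodal_betas):
        ref_vals = bimodal_betas(40_000)
        ref_mix = fit_beta_mixture(ref_vals, seed=0)
        from scipy.special import expit, logit

        shifted = expit(logit(np.clip(bimodal_betas(20_000), 1e-6, 1 - 1e-6)) + 0.5)
        ds = quick_dataset("t", shifted[:, None], ages=[40.0])
        cal = calibrate_to_reference(ds, ref_mix, seed=0)
        before = stats.ks_2samp(shifted, ref_vals).statistic
        after = stats.ks_2samp(cal.beta.to_numpy().ravel(), ref_vals).statistic
        assert after < before

    def test_monotone_within_component(self, bimodal_betas):
        ref_mix = fit_beta_mixture(bimodal_betas(40_000), seed=0)
        x = np.sort(bimodal_betas(20_000))
        ds = quick_dataset("t", x[:, None], ages=[40.0])
        cal = calibrate_to_reference(ds, ref_mix, seed=0)
        from metamethyl.epigenetic_clock import _classify

        mix = fit_beta_mixture(x, seed=0)
        comp = _classify(np.clip(x, 1e-6, 1 - 1e-6), mix)
        out = cal.beta.to_numpy().ravel()
        for k in range(3):
            vals = out[comp == k]
            assert np.all(np.diff(vals) >= -1e-12)

    def test_idempotence(self, bimodal_betas):
        ref_mix = fit_beta_mixture(bimodal_betas(40_000), seed=0)
        ds = quick_dataset("t", bimodal_betas(20_000)[:, None], ages=[40.0])
        cal = calibrate_to_reference(ds, ref_mix, seed=0)
        cal2 = calibrate_to_reference(cal, ref_mix, seed=0)
        diff = np.abs(cal2.beta.to_numpy() - cal.beta.to_numpy())
        assert np.median(diff) < 1e-3


class TestAgeTransform:
    def test_knot_is_zero_and_example(self):
        assert transform_age(20.0) == pytest.approx(0.0)
        assert transform_age(40.0) == pytest.approx(20 / 21)

    @pytest.mark.parametrize("age", [1.0, 20.0, 45.4, 89.0])
    def test_exact_round_trip(self, age):
        assert inverse_transform_age(transform_age(age)) == pytest.approx(age, abs=1e-12)

    def test_round_trip_over_lifespan(self):
        ages = np.linspace(0.01, 120.0, 500)
        back = inverse_transform_age(transform_age(ages))
        assert np.allclose(back, ages, atol=1e-10)

    def test_age_below_minus_one_rejected(self):
        with pytest.raises(ValueError):
            transform_age(-1.5)


class TestTrainPredict:
    def _signal_data(self, seed=0, n=120, p=60):
        rng = np.random.default_rng(seed)
        ages = rng.uniform(20, 80, n)
        beta = rng.uniform(0.2, 0.8, (p, n))
        # probe 0 tracks transformed age perfectly
        t = transform_age(ages)
        beta[0] = 0.5 + 0.15 * (t - t.mean()) / t.std()
        return quick_dataset("sig", np.clip(beta, 0.01, 0.99), ages), ages

    def test_single_informative_probe_found(self):
        ds, ages = self._signal_data()
        model = train_clock([ds], seed=0)
        assert "cg0" in model.probe_ids
        pred = predict_age(model, ds)
        assert np.corrcoef(pred, ages)[0, 1] > 0.99
        assert np.median(np.abs(pred - ages)) < 2.0

    def test_ridge_limit_keeps_all_probes(self):
        ds, _ = self._signal_data(n=80, p=20)
        model = train_clock([ds], alpha=0.0, seed=0)
        assert len(model.probe_ids) == 20

    def test_deterministic_probe_selection(self):
        ds, _ = self._signal_data()
        a = train_clock([ds], seed=3)
        b = train_clock([ds], seed=3)
        assert a.probe_ids == b.probe_ids
        assert np.allclose(a.coefficients, b.coefficients)

    def test_constant_sample_prediction_finite(self):
        ds, _ = self._signal_data()
        model = train_clock([ds], seed=0)
        const = quick_dataset("c", np.full((60, 1), 0.5), ages=[50.0])
        pred = predict_age(model, const)
        assert np.isfinite(pred.iloc[0])

    def test_missing_probe_imputation_and_cap(self):
        ds, _ = self._signal_data()
        model = train_clock([ds], seed=0)
        # drop one model probe: imputed from training means
        keep = [p for p in ds.beta.index if p != model.probe_ids[0]]
        partial = MethylationDataset("d", ds.beta.loc[keep], ds.samples)
        if len(model.probe_ids) > 1:
            assert np.isfinite(predict_age(model, partial)).all()
        # drop everything: error
        stub_beta = ds.beta.loc[[p for p in ds.beta.index if p not in model.probe_ids]]
        stub = MethylationDataset("d2", stub_beta, ds.samples)
        with pytest.raises(ValueError, match="missing"):
            predict_age(model, stub)


class TestLodo:
    def test_requires_three_datasets(self):
        ds1, _ = TestTrainPredict()._signal_data(1, n=60)
        ds2, _ = TestTrainPredict()._signal_data(2, n=60)
        with pytest.raises(ValueError, match="3 datasets"):
            lodo_evaluate([ds1, ds2])

    def test_small_simulated_lodo_aggregates(self):
        cohorts = tuple(
            CohortSpec(f"k{i}", "EPIC", 25, 1, 18, 85, 45.0, 18.0, 0.5, 1.0)
            for i in range(3)
        )
        cfg = SimulationConfig(
            cohorts=cohorts, n_probes=600, frac_age_cpgs=0.1,
            slope_scale=0.0025, seed=31,
        )
        ann, _, _ = build_toy_annotation(cfg)
        datasets, _ = simulate_multicohort(ann, cfg)
        ev = lodo_evaluate(datasets, seed=31)
        assert set(ev.per_dataset.index) == {"k0", "k1", "k2"}
        assert ev.mean_r == pytest.approx(ev.per_dataset["r"].mean())
        assert ev.median_error == pytest.approx(
            ev.per_dataset["median_abs_error"].median()
        )
        assert ev.mean_r > 0.5  # strong spiked signal is learnable
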