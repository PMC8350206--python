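"""Muscle epigenetic clock: calibration, age transform, penalized regression.

The clock predicts chronological age from methylation beta values.  Datasets
are first reduced to their shared probes and calibrated to a gold-standard
reference with a beta-mixture quantile approach: each sample's values are
modelled as a three-component beta mixture (unmethylated / hemimethylated /
methylated), each value is assigned to its most probable component and mapped
through that component's CDF onto the reference component's inverse CDF.
Age enters the regression through the standard non-linear transform

    F(age) = log(age + 1) - log(adult_age + 1)      if age <= adult_age
           = (age - adult_age) / (adult_age + 1)    otherwise

which is exactly invertible, and the clock is an elastic net on F(age) with
the penalty strength chosen by internal k-fold cross-validation.  Accuracy is
evaluated by leave-one-dataset-out (LODO) cross-validation: the held-out
dataset influences neither the reference choice nor the penalty selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import betaln
from sklearn.linear_model import ElasticNetCV
from sklearn.model_selection import KFold

from .annotation_io import MethylationDataset

__all__ = [
    "BetaMixture",
    "ClockModel",
    "ClockEvaluation",
    "intersect_probes",
    "fit_beta_mixture",
    "calibrate_to_reference",
    "transform_age",
    "inverse_transform_age",
    "train_clock",
    "predict_age",
    "lodo_evaluate",
    "fit_sample_mixtures",
]

logger = logging.getLogger(__name__)

ADULT_AGE_DEFAULT = 20.0


# ---------------------------------------------------------------------------
# probe intersection
# ---------------------------------------------------------------------------


def intersect_probes(datasets: list[MethylationDataset]) -> pd.Index:
    """Sorted intersection of probe sets across >= 2 datasets."""
    if len(datasets) < 2:
        raise ValueError("need at least 2 datasets")
    shared = set(datasets[0].probe_ids)
    for ds in datasets[1:]:
        shared &= set(ds.probe_ids)
    if not shared:
        raise ValueError("empty probe intersection across datasets")
    return pd.Index(sorted(shared))


# ---------------------------------------------------------------------------
# beta mixture
# ---------------------------------------------------------------------------


@dataclass
class BetaMixture:
    """Three-component beta mixture, components ordered by mean."""

    weights: np.ndarray
    alphas: np.ndarray
    betas: np.ndarray

    @property
    def means(self) -> np.ndarray:
        return self.alphas / (self.alphas + self.betas)

    def to_dict(self) -> dict:
        return {
            "weights": list(map(float, self.weights)),
            "alphas": list(map(float, self.alphas)),
            "betas": list(map(float, self.betas)),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BetaMixture":
        return cls(
            np.asarray(d["weights"], float),
            np.asarray(d["alphas"], float),
            np.asarray(d["betas"], float),
        )


def _beta_logpdf(x: np.ndarray, a: float, b: float) -> np.ndarray:
    return (a - 1) * np.log(x) + (b - 1) * np.log1p(-x) - betaln(a, b)


def _moments_to_ab(mean: float, var: float) -> tuple[float, float]:
    mean = min(max(mean, 1e-4), 1 - 1e-4)
    var = min(max(var, 1e-8), mean * (1 - mean) * 0.999)
    nu = mean * (1 - mean) / var - 1.0
    return max(mean * nu, 1e-2), max((1 - mean) * nu, 1e-2)


def _tercile_init(x: np.ndarray) -> BetaMixture:
    """Moment fits on the value terciles; also the non-convergence fallback."""
    qs = np.quantile(x, [1 / 3, 2 / 3])
    groups = [x[x <= qs[0]], x[(x > qs[0]) & (x <= qs[1])], x[x > qs[1]]]
    a, b, w = [], [], []
    for g in groups:
        if len(g) < 2:
            g = x
        ai, bi = _moments_to_ab(float(np.mean(g)), float(np.var(g)))
        a.append(ai)
        b.append(bi)
        w.append(max(len(g) / len(x), 1e-3))
    w = np.asarray(w)
    return BetaMixture(w / w.sum(), np.asarray(a), np.asarray(b))


def fit_beta_mixture(
    values: np.ndarray,
    n_restarts: int = 5,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> BetaMixture:
    """EM fit of a 3-component beta mixture (moment-matching M-step).

    Runs a deterministic tercile-based start plus jittered restarts, keeping
    the best log-likelihood; components are returned ordered by mean.  Falls
    back to the tercile moment fit if no restart converges.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    x = np.clip(x, 1e-6, 1 - 1e-6)
    if len(x) < 100:
        raise ValueError(f"need >= 100 finite values in (0,1), have {len(x)}")
    rng = np.random.default_rng(seed)
    base = _tercile_init(x)
    best_ll, best = -np.inf, None
    for restart in range(n_restarts):
        if restart == 0:
            mix = BetaMixture(base.weights.copy(), base.alphas.copy(), base.betas.copy())
        else:
            jitter = rng.uniform(0.6, 1.6, size=3)
            mix = BetaMixture(
                base.weights.copy(), base.alphas * jitter, base.betas * jitter[::-1]
            )
        ll_prev = -np.inf
        converged = False
        for _ in range(max_iter):
            logp = np.stack(
                [
                    np.log(mix.weights[k]) + _beta_logpdf(x, mix.alphas[k], mix.betas[k])
                    for k in range(3)
                ]
            )
            m = logp.max(axis=0)
            lse = m + np.log(np.exp(logp - m).sum(axis=0))
            ll = float(lse.sum())
            r = np.exp(logp - lse)
            nk = r.sum(axis=1)
            w = np.maximum(nk / len(x), 1e-4)
            mean = (r @ x) / nk
            var = (r @ x**2) / nk - mean**2
            for k in range(3):
                mix.alphas[k], mix.betas[k] = _moments_to_ab(mean[k], var[k])
            mix.weights = w / w.sum()
            if abs(ll - ll_prev) < tol * len(x):
                converged = True
                break
            ll_prev = ll
        if converged and np.isfinite(ll) and ll > best_ll:
            best_ll, best = ll, mix
    if best is None:
        logger.warning("beta-mixture EM did not converge; tercile moment fallback")
        best = base
    order = np.argsort(best.means)
    return BetaMixture(best.weights[order], best.alphas[order], best.betas[order])


def _classify(x: np.ndarray, mix: BetaMixture) -> np.ndarray:
    logp = np.stack(
        [
            np.log(mix.weights[k]) + _beta_logpdf(x, mix.alphas[k], mix.betas[k])
            for k in range(3)
        ]
    )
    return logp.argmax(axis=0)


def calibrate_to_reference(
    target: MethylationDataset,
    reference: BetaMixture,
    sample_mixtures: dict[str, BetaMixture] | None = None,
    seed: int = 0,
) -> MethylationDataset:
    """Per-sample beta-mixture quantile calibration onto the reference.

    Each sample's values are fit with their own 3-component mixture (or a
    pre-computed one from ``sample_mixtures``), assigned to the most probable
    component, and mapped through the component CDF onto the reference
    component's inverse CDF.  The map is monotone within each component and
    identity-like when target and reference distributions agree.
    """
    if len(reference.weights) != 3:
        raise ValueError("reference summary must have 3 components")
    out = target.beta.copy()
    for j, col in enumerate(target.beta.columns):
        vals = target.beta[col].to_numpy(float)
        ok = np.isfinite(vals)
        x = np.clip(vals[ok], 1e-6, 1 - 1e-6)
        mix = None
        if sample_mixtures is not None:
            mix = sample_mixtures.get(col)
        if mix is None:
            mix = fit_beta_mixture(x, seed=seed + j)
        comp = _classify(x, mix)
        calibrated = np.empty_like(x)
        for k in range(3):
            sel = comp == k
            if not sel.any():
                continue
            u = stats.beta.cdf(x[sel], mix.alphas[k], mix.betas[k])
            u = np.clip(u, 1e-12, 1 - 1e-12)
            calibrated[sel] = stats.beta.ppf(u, reference.alphas[k], reference.betas[k])
        new = np.full_like(vals, np.nan)
        new[ok] = np.clip(calibrated, 1e-6, 1 - 1e-6)
        out[col] = new
    return MethylationDataset(target.dataset_id, out, target.samples, target.array_label)


# ---------------------------------------------------------------------------
# age transform
# ---------------------------------------------------------------------------


def transform_age(age, adult_age: float = ADULT_AGE_DEFAULT):
    """F(age): log-linear below the adult knot, linear above; F(adult_age) = 0."""
    age = np.asarray(age, dtype=float)
    if np.any(age <= -1):
        raise ValueError("age must exceed -1")
    out = np.where(
        age <= adult_age,
        np.log(age + 1) - np.log(adult_age + 1),
        (age - adult_age) / (adult_age + 1),
    )
    return out if out.ndim else float(out)


def inverse_transform_age(t, adult_age: float = ADULT_AGE_DEFAULT):
    """Exact inverse of :func:`transform_age`."""
    t = np.asarray(t, dtype=float)
    out = np.where(
        t <= 0,
        np.exp(t + np.log(adult_age + 1)) - 1,
        t * (adult_age + 1) + adult_age,
    )
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# clock model
# ---------------------------------------------------------------------------


@dataclass
class ClockModel:
    """Fitted clock: calibration reference, age transform, coefficients."""

    probe_ids: list[str]  # probes with nonzero coefficients
    coefficients: np.ndarray
    intercept: float
    adult_age: float
    calibration_reference: dict  # mixture params + quantile summary
    probe_means: np.ndarray  # training means, used to impute missing probes

    def to_dict(self) -> dict:
        return {
            "probe_ids": list(self.probe_ids),
            "coefficients": list(map(float, self.coefficients)),
            "intercept": float(self.intercept),
            "adult_age": float(self.adult_age),
            "calibration_reference": self.calibration_reference,
            "probe_means": list(map(float, self.probe_means)),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClockModel":
        return cls(
            probe_ids=list(d["probe_ids"]),
            coefficients=np.asarray(d["coefficients"], float),
            intercept=float(d["intercept"]),
            adult_age=float(d["adult_age"]),
            calibration_reference=d["calibration_reference"],
            probe_means=np.asarray(d["probe_means"], float),
        )


def _pool(datasets: list[MethylationDataset], probes: pd.Index):
    X = np.column_stack([ds.beta.loc[probes].to_numpy(float) for ds in datasets]).T
    ages = np.concatenate([[s.age for s in ds.samples] for ds in datasets])
    return X, ages


def train_clock(
    datasets: list[MethylationDataset],
    alpha: float = 0.5,
    k_inner: int = 10,
    seed: int = 0,
    adult_age: float = ADULT_AGE_DEFAULT,
    calibration_reference: dict | None = None,
    n_alphas: int = 30,
) -> ClockModel:
    """Elastic net of transformed age on the shared calibrated probes.

    ``alpha`` is the L1/L2 mixing (0.5 by default); the penalty strength is
    chosen by ``k_inner``-fold cross-validation minimizing squared error.
    Features are standardized for the fit (so the penalty treats probes of
    different baseline variance evenly) and coefficients are stored back on
    the beta-value scale.  Only probes with nonzero coefficients are
    retained in the model.
    """
    probes = intersect_probes(datasets) if len(datasets) > 1 else datasets[0].probe_ids
    X, ages = _pool(datasets, probes)
    if X.shape[0] < 50:
        raise ValueError(f"need >= 50 pooled samples, have {X.shape[0]}")
    keep = np.isfinite(X).all(axis=0)
    if keep.sum() == 0 or np.allclose(np.nanstd(X, axis=0), 0):
        raise ValueError("degenerate feature matrix")
    probes = probes[keep]
    X = X[:, keep]
    y = transform_age(ages, adult_age)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd
    cv = KFold(n_splits=k_inner, shuffle=True, random_state=seed)
    enet = ElasticNetCV(
        l1_ratio=max(alpha, 1e-3),
        alphas=n_alphas,
        cv=cv,
        random_state=seed,
        max_iter=5_000,
        tol=1e-4,
    )
    enet.fit(Xs, y)
    nz = np.flatnonzero(enet.coef_)
    coef = enet.coef_[nz] / sd[nz]
    intercept = float(enet.intercept_ - np.sum(enet.coef_[nz] * mu[nz] / sd[nz]))
    return ClockModel(
        probe_ids=[str(p) for p in probes[nz]],
        coefficients=coef,
        intercept=intercept,
        adult_age=adult_age,
        calibration_reference=calibration_reference or {},
        probe_means=X[:, nz].mean(axis=0),
    )


def predict_age(model: ClockModel, dataset: MethylationDataset) -> pd.Series:
    """Predicted ages (years) for every sample of a calibrated dataset.

    Model probes absent from the dataset are imputed with their stored
    training means (logged); more than 20% missing is an error.
    """
    present = [p for p in model.probe_ids if p in dataset.beta.index]
    n_missing = len(model.probe_ids) - len(present)
    if len(model.probe_ids) and n_missing / len(model.probe_ids) > 0.2:
        raise ValueError(
            f"{n_missing}/{len(model.probe_ids)} model probes missing from "
            f"{dataset.dataset_id}"
        )
    if n_missing:
        logger.info("%s: imputing %d missing model probes", dataset.dataset_id, n_missing)
    X = np.empty((dataset.n_samples, len(model.probe_ids)))
    for i, p in enumerate(model.probe_ids):
        if p in dataset.beta.index:
            col = dataset.beta.loc[p].to_numpy(float)
            col = np.where(np.isfinite(col), col, model.probe_means[i])
        else:
            col = np.full(dataset.n_samples, model.probe_means[i])
        X[:, i] = col
    t = model.intercept + X @ model.coefficients
    return pd.Series(
        inverse_transform_age(t, model.adult_age),
        index=dataset.beta.columns,
        name="predicted_age",
    )


# ---------------------------------------------------------------------------
# leave-one-dataset-out evaluation
# ---------------------------------------------------------------------------


@dataclass
class ClockEvaluation:
    """Per-dataset and aggregate LODO accuracy."""

    per_dataset: pd.DataFrame  # r, median_abs_error, mean_error, n
    mean_r: float
    median_error: float  # median of per-dataset median absolute errors
    predictions: dict[str, pd.Series] = field(default_factory=dict)


def _reference_dataset(datasets: list[MethylationDataset]) -> MethylationDataset:
    """Gold standard: the dataset with the widest age range (ties by id)."""
    def span(ds):
        ages = [s.age for s in ds.samples]
        return (max(ages) - min(ages), ds.dataset_id)
    return max(datasets, key=span)


def fit_sample_mixtures(
    datasets: list[MethylationDataset], seed: int
) -> dict[str, BetaMixture]:
    """One mixture per sample, fit on the sample's own values only (so the
    fits are shared across LODO folds without leakage)."""
    out: dict[str, BetaMixture] = {}
    for ds in datasets:
        for j, col in enumerate(ds.beta.columns):
            vals = ds.beta[col].to_numpy(float)
            vals = vals[np.isfinite(vals)]
            out[col] = fit_beta_mixture(vals, seed=seed + j)
    return out


def lodo_evaluate(
    datasets: list[MethylationDataset],
    alpha: float = 0.5,
    k_inner: int = 10,
    seed: int = 0,
    adult_age: float = ADULT_AGE_DEFAULT,
) -> ClockEvaluation:
    """Leave-one-dataset-out accuracy of the clock.

    For each fold the reference (widest age range), calibration, and penalty
    selection use only the training datasets.  A held-out dataset with
    constant age has undefined correlation; it is reported missing and
    excluded from the mean r.
    """
    if len(datasets) < 3:
        raise ValueError("need >= 3 datasets for leave-one-dataset-out evaluation")
    sample_mixtures = fit_sample_mixtures(datasets, seed)
    rows = []
    predictions: dict[str, pd.Series] = {}
    for held in datasets:
        train = [d for d in datasets if d.dataset_id != held.dataset_id]
        ref_ds = _reference_dataset(train)
        ref_vals = ref_ds.beta.to_numpy(float)
        ref_mix = fit_beta_mixture(ref_vals[np.isfinite(ref_vals)], seed=seed)
        cal_train = [
            calibrate_to_reference(d, ref_mix, sample_mixtures, seed=seed) for d in train
        ]
        model = train_clock(
            cal_train,
            alpha=alpha,
            k_inner=k_inner,
            seed=seed,
            adult_age=adult_age,
            calibration_reference=ref_mix.to_dict(),
        )
        cal_held = calibrate_to_reference(
            held, ref_mix, sample_mixtures, seed=seed
        )
        pred = predict_age(model, cal_held)
        actual = np.array([s.age for s in held.samples])
        err = pred.to_numpy() - actual
        if np.std(actual) == 0:
            r = np.nan  # undefined: reported missing, excluded from the mean
            logger.info("%s: constant ages, correlation undefined", held.dataset_id)
        elif np.std(pred.to_numpy()) == 0:
            r = 0.0  # an intercept-only clock carries no age association
        else:
            r = float(np.corrcoef(actual, pred.to_numpy())[0, 1])
        predictions[held.dataset_id] = pred
        rows.append(
            {
                "dataset_id": held.dataset_id,
                "n": len(actual),
                "r": r,
                "median_abs_error": float(np.median(np.abs(err))),
                "mean_error": float(np.mean(err)),
                "n_clock_cpgs": len(model.probe_ids),
            }
        )
    per_dataset = pd.DataFrame(rows).set_index("dataset_id")
    finite_r = per_dataset["r"].dropna()
    return ClockEvaluation(
        per_dataset=per_dataset,
        mean_r=float(finite_r.mean()) if len(finite_r) else np.nan,
        median_error=float(per_dataset["median_abs_error"].median()),
        predictions=predictions,
    )
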