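"""Per-cohort EWAS of age.

Each CpG is regressed on age with covariate adjustment (sex, BMI, diabetes
status, batch, time point when present).  Repeated measures from the same
subject (or twin pair) are handled by a single consensus within-block
correlation and generalized least squares under an exchangeable-correlation
model.  Residual variances are moderated by empirical-Bayes shrinkage toward
a fitted scaled inverse chi-square prior, and the resulting test statistics
are corrected for bias and inflation with an empirical-null Gaussian-mixture
fit to the probit z-scores.
"""

from __future__ import annotations

import logging
import warnings
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .annotation_io import MethylationDataset

__all__ = [
    "EwasResult",
    "build_design",
    "fit_age_models",
    "estimate_consensus_correlation",
    "fit_age_models_gls",
    "moderate_statistics",
    "estimate_empirical_null",
    "apply_empirical_null",
    "run_ewas",
    "write_ewas_result",
    "read_ewas_result",
]

logger = logging.getLogger(__name__)

DEFAULT_COVARIATES = ("sex", "bmi", "t2d", "batch", "time_point")


@dataclass
class EwasResult:
    """Per-probe statistics and dataset-level parameters of one EWAS."""

    dataset_id: str
    table: pd.DataFrame  # b, se, t, df, p_raw, z, z_corr, p_corr, b_corr, se_corr, degenerate
    d0: float  # prior degrees of freedom
    s02: float  # prior variance
    rho: float  # consensus within-block correlation (0 when no repeats)
    mu0: float  # empirical-null bias
    sigma0: float  # empirical-null inflation
    pi0: float  # empirical-null weight


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------


def build_design(
    dataset: MethylationDataset, covariates: tuple[str, ...] = DEFAULT_COVARIATES
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Build the regression design (intercept, age, adjustment columns).

    Covariates that are absent, entirely missing or constant in the cohort are
    dropped with a logged warning.  Returns (X, column names, complete-case
    sample mask); samples with a missing value in a retained covariate are
    excluded via the mask, never imputed.
    """
    sheet = dataset.sample_frame()
    if sheet["age"].nunique() <= 1:
        raise ValueError(f"{dataset.dataset_id}: age is constant; EWAS of age undefined")
    cols = [np.ones(len(sheet)), sheet["age"].to_numpy(float)]
    names = ["intercept", "age"]
    keep_mask = np.ones(len(sheet), dtype=bool)
    for cov in covariates:
        if cov not in sheet.columns or sheet[cov].isna().all():
            logger.warning("%s: covariate %r unavailable, dropped", dataset.dataset_id, cov)
            continue
        col = sheet[cov]
        observed = col.dropna()
        if observed.nunique() <= 1:
            logger.warning("%s: covariate %r constant, dropped", dataset.dataset_id, cov)
            continue
        keep_mask &= col.notna().to_numpy()
        if cov in ("bmi", "t2d"):
            cols.append(pd.to_numeric(col).to_numpy(float))
            names.append(cov)
        else:  # categorical: one-hot, drop first level
            levels = sorted(observed.astype(str).unique())
            for lev in levels[1:]:
                cols.append((col.astype(str) == lev).to_numpy(float))
                names.append(f"{cov}[{lev}]")
    X = np.column_stack(cols)
    X[~keep_mask] = np.nan
    return X, names, keep_mask


def _ols_stats(Y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, ...]:
    """Vectorized OLS of every row of Y on X; returns (b, c, s2, d) for age.

    ``c`` is the unscaled coefficient standard deviation sqrt((X'X)^-1_aa),
    so the standard error is ``c * s``.
    """
    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    xtx_inv = np.linalg.pinv(X.T @ X)
    pinv = xtx_inv @ X.T
    coef = Y @ pinv.T
    resid = Y - coef @ X.T
    rss = np.einsum("ij,ij->i", resid, resid)
    d = n - rank
    s2 = rss / d if d > 0 else np.full(Y.shape[0], np.nan)
    c = np.sqrt(xtx_inv[1, 1])
    return coef[:, 1], np.full(Y.shape[0], c), s2, np.full(Y.shape[0], float(d)), resid


def fit_age_models(
    dataset: MethylationDataset,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
) -> pd.DataFrame:
    """Ordinary least squares per probe on the beta-value scale.

    Complete-case per probe; probes with fewer than p+2 usable samples or a
    rank-deficient design are flagged degenerate.  Returns a frame with
    columns b, c, s2, df, degenerate (b is the age slope in beta fraction
    per year).
    """
    X, names, keep = build_design(dataset, covariates)
    return _fit_with_design(dataset, X, keep)


def _fit_with_design(
    dataset: MethylationDataset, X: np.ndarray, keep: np.ndarray
) -> pd.DataFrame:
    Y = dataset.beta.to_numpy(float)
    n_probes = Y.shape[0]
    p = X.shape[1]
    out = {
        "b": np.full(n_probes, np.nan),
        "c": np.full(n_probes, np.nan),
        "s2": np.full(n_probes, np.nan),
        "df": np.full(n_probes, np.nan),
        "degenerate": np.zeros(n_probes, dtype=bool),
    }
    usable = keep & np.isfinite(X).all(axis=1)
    # fast path: probes fully observed on the usable samples
    full = np.isfinite(Y[:, usable]).all(axis=1)
    full_rows = np.where(full)[0]
    Xu = X[usable]
    if len(full_rows) and Xu.shape[0] >= p + 2:
        b, c, s2, d, _ = _ols_stats(Y[np.ix_(full_rows, np.where(usable)[0])], Xu)
        out["b"][full_rows] = b
        out["c"][full_rows] = c
        out["s2"][full_rows] = s2
        out["df"][full_rows] = d
    # slow path: probes with missing cells
    for i in np.where(~full)[0]:
        mask = usable & np.isfinite(Y[i])
        if mask.sum() < p + 2:
            out["degenerate"][i] = True
            continue
        Xi = X[mask]
        if np.linalg.matrix_rank(Xi) < Xi.shape[1] or np.unique(Xi[:, 1]).size <= 1:
            out["degenerate"][i] = True
            continue
        b, c, s2, d, _ = _ols_stats(Y[i][mask][None, :], Xi)
        out["b"][i], out["c"][i], out["s2"][i], out["df"][i] = b[0], c[0], s2[0], d[0]
    zero_var = np.isfinite(out["s2"]) & (out["s2"] <= 1e-16)
    out["degenerate"] |= zero_var
    return pd.DataFrame(out, index=dataset.beta.index)


# ---------------------------------------------------------------------------
# repeated measures: consensus correlation + GLS
# ---------------------------------------------------------------------------


def _block_labels(dataset: MethylationDataset) -> np.ndarray:
    """Grouping variable for the random intercept: twin pair when recorded,
    otherwise subject."""
    return np.array(
        [s.twin_pair if s.twin_pair is not None else s.subject_id for s in dataset.samples]
    )


def estimate_consensus_correlation(
    dataset: MethylationDataset,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    max_probes: int = 2_000,
    seed: int = 0,
) -> float:
    """Single consensus within-block correlation of the residuals.

    Per-probe intraclass correlations are computed from a one-way ANOVA of
    OLS residuals grouped by block, on a probe subsample (at least 500, or
    all probes), then combined by a 15%-trimmed mean on the Fisher-z scale.
    Returns 0 when no block has repeated measures.
    """
    blocks = _block_labels(dataset)
    _, counts = np.unique(blocks, return_counts=True)
    if (counts >= 2).sum() < 2:
        return 0.0
    X, _, keep = build_design(dataset, covariates)
    usable = keep & np.isfinite(X).all(axis=1)
    Y = dataset.beta.to_numpy(float)
    full = np.isfinite(Y[:, usable]).all(axis=1)
    idx = np.where(full)[0]
    n_take = max(min(len(idx), 500), min(len(idx), max_probes))
    if len(idx) > n_take:
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(idx, size=n_take, replace=False))
    Xu = X[usable]
    _, _, _, _, resid = _ols_stats(Y[np.ix_(idx, np.where(usable)[0])], Xu)
    blk = blocks[usable]
    uniq, inv = np.unique(blk, return_inverse=True)
    k = len(uniq)
    n = len(blk)
    counts = np.bincount(inv).astype(float)
    group_sum = np.zeros((resid.shape[0], k))
    np.add.at(group_sum.T, inv, resid.T)
    group_mean = group_sum / counts
    ssb = np.einsum("gk,k->g", group_mean**2, counts)
    sst = np.einsum("ij,ij->i", resid, resid)
    ssw = sst - ssb
    df_b = k - 1
    df_w = n - k
    if df_w <= 0 or df_b <= 0:
        return 0.0
    msb = ssb / df_b
    msw = ssw / df_w
    m_bar = n / k
    icc = (msb - msw) / (msb + (m_bar - 1) * msw)
    icc = np.clip(icc, -0.95, 0.95)
    fz = np.arctanh(icc)
    rho = float(np.tanh(stats.trim_mean(fz, 0.15)))
    return float(np.clip(rho, -0.2, 0.99))


def fit_age_models_gls(
    dataset: MethylationDataset,
    rho: float,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
) -> pd.DataFrame:
    """GLS per probe under an exchangeable within-block correlation ``rho``.

    The data are whitened per block with the analytic inverse square root of
    ``(1-rho) I + rho J`` and refit by OLS; with ``rho = 0`` this reduces
    exactly to :func:`fit_age_models`.
    """
    if rho == 0:
        return fit_age_models(dataset, covariates)
    X, _, keep = build_design(dataset, covariates)
    usable = keep & np.isfinite(X).all(axis=1)
    Y = dataset.beta.to_numpy(float)
    blocks = _block_labels(dataset)

    def whiten(M: np.ndarray, blk: np.ndarray) -> np.ndarray:
        out = np.array(M, dtype=float, copy=True)
        for g in np.unique(blk):
            sel = blk == g
            m = sel.sum()
            c1 = (1 + (m - 1) * rho) ** -0.5
            c2 = (1 - rho) ** -0.5
            mean = M[sel].mean(axis=0)
            out[sel] = c2 * M[sel] + (c1 - c2) * mean
        return out

    n_probes = Y.shape[0]
    out = {
        "b": np.full(n_probes, np.nan),
        "c": np.full(n_probes, np.nan),
        "s2": np.full(n_probes, np.nan),
        "df": np.full(n_probes, np.nan),
        "degenerate": np.zeros(n_probes, dtype=bool),
    }
    p = X.shape[1]
    u_idx = np.where(usable)[0]
    full = np.isfinite(Y[:, u_idx]).all(axis=1)
    Xw = whiten(X[u_idx], blocks[u_idx])
    rows = np.where(full)[0]
    if len(rows) and Xw.shape[0] >= p + 2:
        Yw = whiten(Y[np.ix_(rows, u_idx)].T, blocks[u_idx]).T
        b, c, s2, d, _ = _ols_stats(Yw, Xw)
        out["b"][rows] = b
        out["c"][rows] = c
        out["s2"][rows] = s2
        out["df"][rows] = d
    for i in np.where(~full)[0]:
        mask = usable & np.isfinite(Y[i])
        if mask.sum() < p + 2:
            out["degenerate"][i] = True
            continue
        Xi = whiten(X[mask], blocks[mask])
        if np.linalg.matrix_rank(Xi) < Xi.shape[1]:
            out["degenerate"][i] = True
            continue
        yi = whiten(Y[i][mask][:, None], blocks[mask]).T
        b, c, s2, d, _ = _ols_stats(yi, Xi)
        out["b"][i], out["c"][i], out["s2"][i], out["df"][i] = b[0], c[0], s2[0], d[0]
    zero_var = np.isfinite(out["s2"]) & (out["s2"] <= 1e-16)
    out["degenerate"] |= zero_var
    return pd.DataFrame(out, index=dataset.beta.index)


# ---------------------------------------------------------------------------
# empirical-Bayes variance moderation
# ---------------------------------------------------------------------------


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (monotone, well-behaved)."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def moderate_statistics(fit: pd.DataFrame) -> tuple[pd.DataFrame, float, float]:
    """Shrink per-probe variances toward a fitted prior; moderated t and p.

    Fits the prior (d0, s0^2) by matching the first two moments of
    log(s^2) against the scaled-F model (digamma/trigamma matching), then
    forms posterior variances ``(d0 s0^2 + d s^2) / (d0 + d)`` and t
    statistics on ``d0 + d`` degrees of freedom.  Degenerate probes keep
    missing p-values.  Falls back to complete shrinkage (d0 = inf) when the
    moment equation has no positive solution.
    """
    ok = (~fit["degenerate"]) & np.isfinite(fit["s2"]) & (fit["s2"] > 0) & (fit["df"] > 0)
    if ok.sum() < 50:
        raise ValueError(f"need >=50 non-degenerate probes, have {int(ok.sum())}")
    s2 = fit.loc[ok, "s2"].to_numpy()
    d = fit.loc[ok, "df"].to_numpy()
    e = np.log(s2) - special.digamma(d / 2) + np.log(d / 2)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(np.mean(special.polygamma(1, d / 2)))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s02 = float(np.exp(emean + special.digamma(d0 / 2) - np.log(d0 / 2)))
    else:
        logger.info("log-variance moments imply no hypervariability; using d0 = inf")
        d0 = np.inf
        s02 = float(np.exp(emean))

    table = fit.copy()
    if np.isinf(d0):
        s2_post = np.where(ok, s02, np.nan)
        df_total = np.full(len(fit), np.inf)
    else:
        s2_post = (d0 * s02 + fit["df"].to_numpy() * fit["s2"].to_numpy()) / (
            d0 + fit["df"].to_numpy()
        )
        s2_post = np.where(ok, s2_post, np.nan)
        df_total = d0 + fit["df"].to_numpy()
    table["s2_post"] = s2_post
    table["df_total"] = df_total
    with np.errstate(invalid="ignore", divide="ignore"):
        t = fit["b"].to_numpy() / (fit["c"].to_numpy() * np.sqrt(s2_post))
    table["t"] = np.where(ok, t, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = np.where(
            np.isinf(df_total),
            2 * stats.norm.sf(np.abs(t)),
            2 * stats.t.sf(np.abs(t), np.maximum(df_total, 1e-3)),
        )
    table["p_raw"] = np.where(ok, p, np.nan)
    table["se"] = fit["c"].to_numpy() * np.sqrt(s2_post)
    return table, float(d0), s02


# ---------------------------------------------------------------------------
# empirical null (bias and inflation)
# ---------------------------------------------------------------------------


def _em_fit(z: np.ndarray, rng: np.random.Generator, max_iter: int = 500):
    n = len(z)
    med = np.median(z)
    scale = stats.median_abs_deviation(z, scale="normal")
    scale = max(scale, 1e-3)
    mu = np.array(
        [
            med + rng.normal(0, 0.05),
            med - scale * (2.0 + rng.exponential(0.5)),
            med + scale * (2.0 + rng.exponential(0.5)),
        ]
    )
    sd = np.array([scale * rng.uniform(0.8, 1.1), scale * 1.5, scale * 1.5])
    w = np.array([0.9, 0.05, 0.05])
    prev_ll = -np.inf
    for _ in range(max_iter):
        logp = (
            np.log(w)[:, None]
            - 0.5 * np.log(2 * np.pi)
            - np.log(sd)[:, None]
            - 0.5 * ((z[None, :] - mu[:, None]) / sd[:, None]) ** 2
        )
        m = logp.max(axis=0)
        lse = m + np.log(np.exp(logp - m).sum(axis=0))
        ll = float(lse.sum())
        r = np.exp(logp - lse)
        nk = r.sum(axis=1)
        w = np.maximum(nk / n, 1e-6)
        w = w / w.sum()
        mu_hat = (r @ z) / nk
        var_hat = (r @ z**2) / nk - mu_hat**2
        sd_hat = np.sqrt(np.maximum(var_hat, 1e-6))
        # null component free; alternative means kept >= 2 null sds away so
        # the null component retains the central mass it owns under H0
        mu[0], sd[0] = mu_hat[0], max(sd_hat[0], 1e-3)
        mu[1] = min(mu_hat[1], mu[0] - 2 * sd[0])
        mu[2] = max(mu_hat[2], mu[0] + 2 * sd[0])
        sd[1] = max(sd_hat[1], sd[0])
        sd[2] = max(sd_hat[2], sd[0])
        if abs(ll - prev_ll) < 1e-8 * n:
            prev_ll = ll
            break
        prev_ll = ll
    return prev_ll, (float(mu[0]), float(sd[0]), float(w[0]))


def estimate_empirical_null(
    z: np.ndarray, n_restarts: int = 10, seed: int = 0
) -> tuple[float, float, float]:
    """Bias, inflation and null weight of a z-score vector.

    Fits a three-component Gaussian mixture by EM — a central null component
    plus one negative-mean and one positive-mean alternative, each with sd at
    least the null sd — over ``n_restarts`` random initializations, keeping
    the best log-likelihood.  Returns (mu0, sigma0, pi0).  Falls back to the
    robust median/MAD null if every restart fails.
    """
    z = np.asarray(z, dtype=float)
    z = z[np.isfinite(z)]
    if len(z) < 1_000:
        logger.warning("only %d finite z-scores; using robust median/MAD null", len(z))
        return _robust_null(z)
    rng = np.random.default_rng(seed)
    best = (-np.inf, None)
    for _ in range(n_restarts):
        try:
            ll, params = _em_fit(z, rng)
        except FloatingPointError:
            continue
        if np.isfinite(ll) and ll > best[0]:
            best = (ll, params)
    if best[1] is None:
        logger.warning("empirical-null EM failed in all restarts; robust fallback")
        return _robust_null(z)
    return best[1]


def _robust_null(z: np.ndarray) -> tuple[float, float, float]:
    mu0 = float(np.median(z))
    sigma0 = float(stats.median_abs_deviation(z, scale="normal"))
    return mu0, max(sigma0, 1e-6), 1.0


def apply_empirical_null(
    z: np.ndarray, mu0: float, sigma0: float
) -> tuple[np.ndarray, np.ndarray]:
    """Recenter and rescale z-scores by the empirical null; two-sided p."""
    if sigma0 <= 0:
        raise ValueError("sigma0 must be positive")
    z_corr = (np.asarray(z, dtype=float) - mu0) / sigma0
    p_corr = 2 * stats.norm.sf(np.abs(z_corr))
    return z_corr, p_corr


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def run_ewas(
    dataset: MethylationDataset,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    scale: str = "beta",
    seed: int = 0,
) -> EwasResult:
    """Full EWAS of one cohort: fit, moderate, probit z, empirical-null correct.

    The corrected effect and standard error (``b_corr = b - mu0 * se``,
    ``se_corr = sigma0 * se``) are what downstream meta-analysis consumes, so
    both effects and uncertainties carry the bias/inflation adjustment.
    ``scale`` may be "beta" (default; effects in methylation fraction per
    year) or "m" for logit2 M-values.
    """
    if scale not in ("beta", "m"):
        raise ValueError("scale must be 'beta' or 'm'")
    rho = estimate_consensus_correlation(dataset, covariates, seed=seed)
    if scale == "m":
        vals = np.clip(dataset.beta.to_numpy(float), 1e-6, 1 - 1e-6)
        m = np.log2(vals / (1 - vals))
        m_df = pd.DataFrame(m, index=dataset.beta.index, columns=dataset.beta.columns)
        fit = _fit_scaled(dataset, m_df, rho, covariates)
    else:
        fit = fit_age_models_gls(dataset, rho, covariates) if rho != 0 else fit_age_models(
            dataset, covariates
        )
    table, d0, s02 = moderate_statistics(fit)
    # probit z: sign of t with the magnitude of the two-sided p quantile
    with np.errstate(invalid="ignore"):
        z = np.sign(table["t"].to_numpy()) * stats.norm.isf(
            np.clip(table["p_raw"].to_numpy() / 2, 1e-320, 1.0)
        )
    table["z"] = z
    em_seed = zlib.crc32(dataset.dataset_id.encode("utf8")) ^ (seed & 0x7FFFFFFF)
    mu0, sigma0, pi0 = estimate_empirical_null(z, seed=em_seed)
    z_corr, p_corr = apply_empirical_null(z, mu0, sigma0)
    table["z_corr"] = z_corr
    table["p_corr"] = p_corr
    table["b_corr"] = table["b"] - mu0 * table["se"]
    table["se_corr"] = sigma0 * table["se"]
    return EwasResult(
        dataset_id=dataset.dataset_id,
        table=table,
        d0=d0,
        s02=s02,
        rho=rho,
        mu0=mu0,
        sigma0=sigma0,
        pi0=pi0,
    )


def _fit_scaled(dataset, values_df, rho, covariates):
    shadow = MethylationDataset.__new__(MethylationDataset)
    shadow.dataset_id = dataset.dataset_id
    shadow.beta = values_df
    shadow.samples = dataset.samples
    shadow.array_label = dataset.array_label
    if rho != 0:
        return fit_age_models_gls(shadow, rho, covariates)
    return fit_age_models(shadow, covariates)


_HEADER_KEYS = ("d0", "s02", "rho", "mu0", "sigma0", "pi0")


def write_ewas_result(result: EwasResult, path) -> None:
    """TSV with '#key=value' header comment lines for dataset-level parameters."""
    with open(path, "w") as fh:
        fh.write(f"#dataset_id={result.dataset_id}\n")
        for key in _HEADER_KEYS:
            fh.write(f"#{key}={getattr(result, key)!r}\n")
        cols = ["b", "se", "t", "df_total", "p_raw", "z_corr", "p_corr", "b_corr", "se_corr"]
        result.table[cols].to_csv(fh, sep="\t", index_label="probe_id")


def read_ewas_result(path) -> EwasResult:
    meta = {}
    with open(path) as fh:
        pos = 0
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].strip().partition("=")
            meta[key] = val
            pos += len(line)
    table = pd.read_csv(path, sep="\t", comment="#", index_col="probe_id")
    table["degenerate"] = ~np.isfinite(table["p_raw"])
    return EwasResult(
        dataset_id=meta["dataset_id"],
        table=table,
        **{key: float(meta[key]) for key in _HEADER_KEYS},
    )
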