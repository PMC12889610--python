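"""Median normalization, empirical-Bayes batch correction, and imputation.

Batch correction follows the parametric location/scale empirical-Bayes model
("ComBat"): per feature the log2 data are standardized, per-batch additive
(γ) and multiplicative (δ²) effects are estimated, shrunk toward batch-level
priors — normal on γ, inverse-gamma on δ², with hyperparameters fitted by
method of moments across features — and removed, after which the pooled
feature mean and variance are restored. The implementation is missing-value
aware: only observed cells enter the estimates and missing cells stay
missing. Features observed in fewer than two batches, and batches
contributing fewer than two observations of a feature, are passed through
unadjusted and flagged in the returned :class:`BatchModel`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer

from .quant_io import QuantMatrix

__all__ = ["BatchModel", "median_normalize", "combat_adjust", "impute"]


def median_normalize(qm: QuantMatrix) -> QuantMatrix:
    """Shift each sample so its observed median equals the global median.

    The target is the median of the per-sample medians before normalization;
    missing cells are untouched. Idempotent. Requires log2 scale (shifts are
    additive).
    """
    if qm.scale != "log2":
        raise ValueError("median_normalize expects a log2-scale matrix")
    medians = qm.values.median(axis=0, skipna=True)
    if medians.isna().any():
        bad = list(medians.index[medians.isna()])[:5]
        raise ValueError(f"samples without any observation: {bad}")
    target = float(medians.median())
    return replace(qm, values=qm.values + (target - medians))


# ---------------------------------------------------------------------------
# ComBat
# ---------------------------------------------------------------------------


@dataclass
class BatchModel:
    """Fitted batch-effect model (log2 scale).

    ``gamma_hat``/``delta_hat_sq`` are the per-(feature, batch) location and
    scale estimates on standardized data; ``gamma_star``/``delta_star_sq``
    their empirical-Bayes shrunken versions; ``priors`` the per-batch
    hyperparameters. ``skipped_features`` were observed in fewer than two
    batches and passed through; ``skipped_batches`` contributed fewer than
    two samples overall.
    """

    batches: list[str]
    grand_mean: pd.Series
    pooled_var: pd.Series
    gamma_hat: pd.DataFrame
    delta_hat_sq: pd.DataFrame
    gamma_star: pd.DataFrame
    delta_star_sq: pd.DataFrame
    priors: pd.DataFrame
    skipped_features: list[str]
    skipped_batches: list[str]


def _aprior(delta_hat_sq: np.ndarray) -> float:
    m, s2 = float(np.mean(delta_hat_sq)), float(np.var(delta_hat_sq, ddof=1))
    if s2 <= 0:
        return np.inf
    return (2.0 * s2 + m**2) / s2


def _bprior(delta_hat_sq: np.ndarray) -> float:
    m, s2 = float(np.mean(delta_hat_sq)), float(np.var(delta_hat_sq, ddof=1))
    if s2 <= 0:
        return np.inf
    return (m * s2 + m**3) / s2


def _postmean(g_hat, g_bar, n, d_star, t2):
    return (t2 * n * g_hat + d_star * g_bar) / (t2 * n + d_star)


def _postvar(sum_sq, n, a, b):
    return (0.5 * sum_sq + b) / (n / 2.0 + a - 1.0)


def _it_sol(z, g_hat, d_hat, g_bar, t2, a, b, conv=1e-4, max_iter=500):
    """Iterative EB solution for one batch (rows = features, NaN-aware)."""
    n = np.sum(~np.isnan(z), axis=1).astype(float)
    g_old, d_old = g_hat.copy(), d_hat.copy()
    for _ in range(max_iter):
        g_new = _postmean(g_hat, g_bar, n, d_old, t2)
        sum_sq = np.nansum((z - g_new[:, None]) ** 2, axis=1)
        d_new = _postvar(sum_sq, n, a, b)
        change = max(
            np.max(np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-12)),
            np.max(np.abs(d_new - d_old) / np.maximum(np.abs(d_old), 1e-12)),
        )
        g_old, d_old = g_new, d_new
        if change < conv:
            break
    return g_old, d_old


def combat_adjust(
    qm: QuantMatrix, batches: pd.Series, parametric: bool = True
) -> tuple[QuantMatrix, BatchModel]:
    """Remove per-batch location/scale effects with empirical-Bayes shrinkage.

    ``batches`` maps sample id to batch id. Only parametric priors are
    implemented. Missing cells remain missing; a single batch is a no-op.
    """
    if qm.scale != "log2":
        raise ValueError("combat_adjust expects a log2-scale matrix")
    if not parametric:
        raise NotImplementedError("only parametric priors are implemented")
    batches = pd.Series(batches).reindex(qm.sample_ids)
    if batches.isna().any():
        bad = list(qm.sample_ids[batches.isna()])[:5]
        raise ValueError(f"samples without batch assignment: {bad}")

    X = qm.values.to_numpy(dtype=float).copy()
    n_feat, n_samp = X.shape
    batch_ids = list(pd.unique(batches))
    masks = {b: (batches == b).to_numpy() for b in batch_ids}

    skipped_batches = [b for b in batch_ids if masks[b].sum() < 2]
    if skipped_batches:
        warnings.warn(
            f"batches with a single sample passed through unadjusted: {skipped_batches}"
        )
    active = [b for b in batch_ids if b not in skipped_batches]
    if len(active) < 2:
        model = BatchModel(
            batches=batch_ids,
            grand_mean=pd.Series(np.nanmean(X, axis=1), index=qm.feature_ids),
            pooled_var=pd.Series(np.nanvar(X, axis=1, ddof=1), index=qm.feature_ids),
            gamma_hat=pd.DataFrame(index=qm.feature_ids),
            delta_hat_sq=pd.DataFrame(index=qm.feature_ids),
            gamma_star=pd.DataFrame(index=qm.feature_ids),
            delta_star_sq=pd.DataFrame(index=qm.feature_ids),
            priors=pd.DataFrame(),
            skipped_features=[],
            skipped_batches=skipped_batches,
        )
        return qm, model

    obs = ~np.isnan(X)
    # per-feature, per-batch observation counts; features must be seen in ≥2
    # samples of ≥2 active batches to be adjustable
    counts = np.column_stack([obs[:, masks[b]].sum(axis=1) for b in active])
    adjustable = (counts >= 2).sum(axis=1) >= 2
    skipped_features = list(qm.feature_ids[~adjustable])

    idx = np.flatnonzero(adjustable)
    Xa = X[idx]
    cnt = counts[idx]
    estimable = cnt >= 2  # features × active batches

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        batch_means = np.column_stack(
            [np.nanmean(Xa[:, masks[b]], axis=1) for b in active]
        )
    batch_means = np.where(estimable, batch_means, np.nan)
    weights = np.where(estimable, cnt, 0).astype(float)
    grand = np.nansum(np.nan_to_num(batch_means) * weights, axis=1) / weights.sum(axis=1)

    # pooled variance of residuals around batch means, over estimable cells
    resid_sq = np.zeros(Xa.shape[0])
    n_obs = np.zeros(Xa.shape[0])
    for j, b in enumerate(active):
        sub = Xa[:, masks[b]]
        r = sub - batch_means[:, j][:, None]
        r = np.where(estimable[:, j][:, None], r, np.nan)
        resid_sq += np.nansum(r**2, axis=1)
        n_obs += np.sum(~np.isnan(r), axis=1)
    pooled_var = resid_sq / np.maximum(n_obs, 1)
    pooled_var = np.maximum(pooled_var, 1e-12)
    sd = np.sqrt(pooled_var)

    Z = (Xa - grand[:, None]) / sd[:, None]

    gamma_hat = np.full((Xa.shape[0], len(active)), np.nan)
    delta_hat = np.full_like(gamma_hat, np.nan)
    gamma_star = np.full_like(gamma_hat, np.nan)
    delta_star = np.full_like(gamma_hat, np.nan)
    priors = []
    for j, b in enumerate(active):
        zb = Z[:, masks[b]]
        est = estimable[:, j]
        if not est.any():
            priors.append(
                {"batch": b, "gamma_bar": np.nan, "tau_sq": np.nan, "a_prior": np.nan, "b_prior": np.nan}
            )
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            g = np.nanmean(zb, axis=1)
            d = np.nanvar(zb, axis=1, ddof=1)
        d = np.maximum(d, 1e-12)
        gamma_hat[est, j] = g[est]
        delta_hat[est, j] = d[est]
        g_e, d_e = g[est], d[est]
        g_bar, t2 = float(np.mean(g_e)), float(np.var(g_e, ddof=1)) if g_e.size > 1 else 0.0
        a, b_pr = _aprior(d_e), _bprior(d_e)
        priors.append({"batch": b, "gamma_bar": g_bar, "tau_sq": t2, "a_prior": a, "b_prior": b_pr})
        if t2 <= 0 or not np.isfinite(a) or not np.isfinite(b_pr):
            # degenerate prior (e.g. identical effects across features): no
            # shrinkage is needed or possible — keep the direct estimates
            g_s, d_s = g_e, d_e
        else:
            g_s, d_s = _it_sol(zb[est], g_e, d_e, g_bar, t2, a, b_pr)
        gamma_star[est, j] = g_s
        delta_star[est, j] = d_s

    Z_adj = Z.copy()
    for j, b in enumerate(active):
        est = estimable[:, j]
        rows = np.flatnonzero(est)
        cols = masks[b]
        block = Z[np.ix_(rows, cols)]
        block = (block - gamma_star[rows, j][:, None]) / np.sqrt(delta_star[rows, j])[:, None]
        Z_adj[np.ix_(rows, cols)] = block

    X_adj = X.copy()
    X_adj[idx] = Z_adj * sd[:, None] + grand[:, None]
    # non-estimable (feature, batch) cells and skipped features keep raw values
    values = pd.DataFrame(X_adj, index=qm.feature_ids, columns=qm.sample_ids)

    def _frame(arr):
        out = pd.DataFrame(np.nan, index=qm.feature_ids, columns=active)
        out.iloc[idx] = arr
        return out

    model = BatchModel(
        batches=batch_ids,
        grand_mean=pd.Series(np.nan, index=qm.feature_ids).combine_first(
            pd.Series(grand, index=qm.feature_ids[idx])
        ),
        pooled_var=pd.Series(np.nan, index=qm.feature_ids).combine_first(
            pd.Series(pooled_var, index=qm.feature_ids[idx])
        ),
        gamma_hat=_frame(gamma_hat),
        delta_hat_sq=_frame(delta_hat),
        gamma_star=_frame(gamma_star),
        delta_star_sq=_frame(delta_star),
        priors=pd.DataFrame(priors),
        skipped_features=skipped_features,
        skipped_batches=skipped_batches,
    )
    return replace(qm, values=values), model


# ---------------------------------------------------------------------------
# Imputation
# ---------------------------------------------------------------------------


def impute(
    qm: QuantMatrix,
    method: str = "knn",
    k: int = 5,
    min_observation_rate: float = 0.3,
    seed: int = 0,
) -> tuple[QuantMatrix, pd.DataFrame]:
    """Fill missing values for analyses requiring complete data.

    Features observed in fewer than ``min_observation_rate`` of the samples
    are dropped first. ``knn`` (default) averages each missing cell over the
    ``k`` nearest samples by NaN-aware Euclidean distance; ``minprob`` draws
    from a down-shifted Gaussian per sample (left-censored missingness),
    using ``seed``. Observed values are never altered. Returns the complete
    matrix and a boolean mask marking imputed cells.
    """
    if qm.scale != "log2":
        raise ValueError("impute expects a log2-scale matrix")
    rate = qm.mask.mean(axis=1)
    keep = rate >= min_observation_rate
    values = qm.values.loc[keep]
    if values.shape[0] == 0:
        raise ValueError("no feature passes the observation-rate floor")
    if (values.notna().sum(axis=1) == 0).any():
        raise ValueError("a feature with zero observations reached the imputer")
    missing = values.isna()

    if method == "knn":
        imputer = KNNImputer(n_neighbors=k, weights="uniform")
        # samples are the units of similarity: impute across sample rows
        filled = imputer.fit_transform(values.to_numpy().T).T
    elif method == "minprob":
        rng = np.random.default_rng(seed)
        filled = values.to_numpy().copy()
        for j in range(filled.shape[1]):
            col = filled[:, j]
            obs = col[~np.isnan(col)]
            mu = np.mean(obs) - 1.8 * np.std(obs)
            sdv = 0.3 * np.std(obs)
            n_miss = int(np.isnan(col).sum())
            col[np.isnan(col)] = rng.normal(mu, sdv, size=n_miss)
    else:
        raise ValueError(f"unknown imputation method {method!r}")

    out = pd.DataFrame(filled, index=values.index, columns=values.columns)
    out[~missing] = values[~missing]  # guarantee observed values untouched
    return replace(qm, values=out), missing
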