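"""One-vs-rest differential protein abundance with a moderated t-statistic.

For each cell type, every protein is compared between cells of that type and
all other cells with a two-sample model on observed log2 intensities only
(no imputed values). Per-protein residual variances s² with d degrees of
freedom are shrunk toward a common prior by empirical Bayes: assuming a
scaled inverse-χ² prior with d₀ degrees of freedom and scale s₀²,

    s̃² = (d₀ s₀² + d s²) / (d₀ + d)

and the moderated statistic t = Δ / sqrt(s̃² (1/n₁ + 1/n₂)) follows a t
distribution with d₀ + d degrees of freedom under the null. The prior
(d₀, s₀²) is estimated by method of moments on log s², matching the standard
empirical-Bayes linear-model machinery: with z = log s²,
E[z] = log s₀² + ψ(d/2) − log(d/2) − ψ(d₀/2) + log(d₀/2) and
Var[z] = ψ′(d/2) + ψ′(d₀/2), solved for d₀ by inverting the trigamma
function. p-values are two-sided and Bonferroni-adjusted within each
contrast.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "fit_one_vs_rest",
    "moderate_variances",
    "adjust_pvalues",
    "differential_abundance",
    "marker_top_decile_rate",
]


def fit_one_vs_rest(
    values: pd.DataFrame,
    labels: pd.Series,
    min_obs_per_group: int = 10,
) -> pd.DataFrame:
    """Group statistics per protein × target type (observed values only).

    ``values`` is a proteins × cells log2 matrix (missing allowed); ``labels``
    maps cell to final type. Returns one row per (protein, type) with group
    sizes, the mean difference (type minus rest), pooled residual variance
    and residual degrees of freedom. Proteins with fewer than
    ``min_obs_per_group`` observations in either group are kept but flagged
    ``skipped`` and excluded from testing downstream.
    """
    labels = labels.reindex(values.columns)
    if labels.isna().any():
        raise ValueError("labels missing for some samples")
    types = sorted(labels.unique())
    if len(types) < 2:
        raise ValueError("need at least two labels for one-vs-rest contrasts")

    X = values.to_numpy(dtype=float)
    obs = ~np.isnan(X)
    rows = []
    for t in types:
        g1 = (labels == t).to_numpy()
        g0 = ~g1
        n1 = obs[:, g1].sum(axis=1)
        n0 = obs[:, g0].sum(axis=1)
        with np.errstate(invalid="ignore"):
            m1 = np.nansum(np.where(obs, X, 0)[:, g1], axis=1) / np.maximum(n1, 1)
            m0 = np.nansum(np.where(obs, X, 0)[:, g0], axis=1) / np.maximum(n0, 1)
            ss1 = np.nansum((X[:, g1] - m1[:, None]) ** 2, axis=1)
            ss0 = np.nansum((X[:, g0] - m0[:, None]) ** 2, axis=1)
        df = n1 + n0 - 2
        s2 = np.where(df > 0, (ss1 + ss0) / np.maximum(df, 1), np.nan)
        skipped = (n1 < min_obs_per_group) | (n0 < min_obs_per_group)
        rows.append(
            pd.DataFrame(
                {
                    "protein": values.index,
                    "type": t,
                    "n1": n1,
                    "n0": n0,
                    "log2fc": m1 - m0,
                    "s2": s2,
                    "df": df,
                    "skipped": skipped,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def trigamma_inverse(x: float, max_iter: int = 50) -> float:
    """Solve ψ′(y) = x for y > 0 (Newton iteration on 1/y asymptotics)."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif / y) < 1e-8:
            break
    return float(y)


def moderate_variances(
    s2: np.ndarray | pd.Series,
    df: np.ndarray | pd.Series,
    d0: float | None = None,
    s0_sq: float | None = None,
) -> tuple[float, float, np.ndarray]:
    """Empirical-Bayes shrinkage of per-protein variances.

    Estimates the prior degrees of freedom d₀ and prior variance s₀² by
    method of moments on log s² unless both are forced, then returns
    (d₀, s₀², s̃²). ``d0=0`` reproduces ordinary per-protein variances;
    ``d0=np.inf`` collapses every s̃² to s₀².
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.asarray(df, dtype=float)
    ok = np.isfinite(s2) & (df > 0) & (s2 > 0)
    if d0 is None or s0_sq is None:
        if ok.sum() < 2:
            raise ValueError("need at least two proteins with positive finite s2")
        z = np.log(s2[ok])
        d = df[ok]
        e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
        emean = float(np.mean(e))
        evar = float(np.var(e, ddof=1)) - float(np.mean(special.polygamma(1, d / 2.0)))
        if evar > 0:
            est_d0 = 2.0 * trigamma_inverse(evar)
            est_s0 = float(
                np.exp(emean + special.digamma(est_d0 / 2.0) - np.log(est_d0 / 2.0))
            )
        else:
            est_d0 = np.inf
            est_s0 = float(np.exp(emean))
        d0 = est_d0 if d0 is None else d0
        s0_sq = est_s0 if s0_sq is None else s0_sq

    if np.isinf(d0):
        s2_tilde = np.full_like(s2, s0_sq)
    elif d0 == 0:
        s2_tilde = s2.copy()
    else:
        s2_tilde = (d0 * s0_sq + df * s2) / (d0 + df)
    return float(d0), float(s0_sq), s2_tilde


def adjust_pvalues(p: np.ndarray | list[float], method: str = "bonferroni") -> np.ndarray:
    """Multiple-testing adjustment; Bonferroni: min(1, m·p) with m = len(p)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if method != "bonferroni":
        raise ValueError(f"unknown method {method!r}")
    return np.minimum(1.0, p * p.size)


def marker_top_decile_rate(de: pd.DataFrame, marker_type: pd.Series) -> float:
    """Fraction of planted marker proteins ranking in the top decile of the
    moderated t for their own one-vs-rest contrast.

    ``marker_type`` maps protein id to the cell type whose marker it is
    (empty string = not a marker). Only contrasts whose type carries planted
    markers, and only markers actually tested in that contrast, contribute.
    """
    hits = total = 0
    for t, sub in de.groupby("type"):
        markers = set(marker_type.index[marker_type == t])
        if not markers:
            continue
        tested = sub[~sub["skipped"] & np.isfinite(sub["t_mod"])]
        if tested.empty:
            continue
        n_top = max(1, int(np.ceil(0.1 * len(tested))))
        top = set(tested.nlargest(n_top, "t_mod")["protein"])
        present = markers & set(tested["protein"])
        hits += len(present & top)
        total += len(present)
    return hits / total if total else float("nan")


def differential_abundance(
    values: pd.DataFrame,
    labels: pd.Series,
    min_obs_per_group: int = 10,
    d0: float | None = None,
    s0_sq: float | None = None,
) -> pd.DataFrame:
    """Full one-vs-rest moderated-t analysis with Bonferroni correction.

    Returns one row per protein × type with log2 fold change, moderated t,
    total degrees of freedom, raw and Bonferroni-adjusted two-sided p-values
    (m = number of proteins tested within each contrast). Skipped proteins
    carry NaN statistics.
    """
    fit = fit_one_vs_rest(values, labels, min_obs_per_group=min_obs_per_group)
    tested = fit[~fit["skipped"] & np.isfinite(fit["s2"]) & (fit["s2"] > 0)]
    if tested.empty:
        raise ValueError("no protein passes the observation floor in any contrast")
    d0_est, s0_est, _ = moderate_variances(
        tested["s2"].to_numpy(), tested["df"].to_numpy(), d0=d0, s0_sq=s0_sq
    )

    fit["d0"] = d0_est
    fit["s0_sq"] = s0_est
    out = []
    for t, sub in fit.groupby("type", sort=True):
        sub = sub.copy()
        usable = ~sub["skipped"] & np.isfinite(sub["s2"])
        _, _, s2_tilde = moderate_variances(
            sub["s2"].to_numpy(), sub["df"].to_numpy(), d0=d0_est, s0_sq=s0_est
        )
        se = np.sqrt(s2_tilde * (1.0 / sub["n1"].clip(lower=1) + 1.0 / sub["n0"].clip(lower=1)))
        # scipy's t distribution does not accept infinite df; a huge finite
        # value is numerically the normal limit
        df_total = np.minimum(d0_est + sub["df"].to_numpy(), 1e9)
        t_mod = sub["log2fc"].to_numpy() / se
        with np.errstate(invalid="ignore"):
            p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
        sub["s2_tilde"] = s2_tilde
        sub["t_mod"] = np.where(usable, t_mod, np.nan)
        sub["df_total"] = df_total
        sub["p"] = np.where(usable, p, np.nan)
        mask = usable.to_numpy()
        p_adj = np.full(len(sub), np.nan)
        p_adj[mask] = adjust_pvalues(sub.loc[usable, "p"].to_numpy())
        sub["p_bonf"] = p_adj
        out.append(sub)
    return pd.concat(out, ignore_index=True)
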