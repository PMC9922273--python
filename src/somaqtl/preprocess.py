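"""Proteome normalization and shared statistical utilities.

Implements the preprocessing chain applied to an aptamer proteome before
genetic analysis: log2 median normalization within dilution groups,
parametric empirical-Bayes location/scale batch correction across plates
(the canonical ComBat model: per-batch analyte means shrunk toward a normal
prior, per-batch variances toward a moment-matched inverse-gamma prior,
iterated to their joint conditional posterior means), principal components
for use as covariates, the rank-based inverse normal transform, and
Benjamini-Hochberg FDR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import ProteinMatrix
from .exceptions import DesignError

__all__ = [
    "log2_median_normalize", "combat_adjust", "BatchModel",
    "compute_pcs", "inverse_normal_transform", "bh_fdr",
]


def log2_median_normalize(raw: ProteinMatrix, already_log2: bool = True) -> ProteinMatrix:
    """Equalize per-sample medians within each dilution group.

    For every dilution group the per-sample median over the group's analytes
    is shifted to the group's global median.  If ``already_log2`` is False
    the values are log2-transformed first (raising on non-positive entries,
    naming the offending analyte and sample).
    """
    values = raw.values.copy()
    if not already_log2:
        arr = values.to_numpy()
        bad = np.argwhere(arr <= 0)
        if bad.size:
            i, j = bad[0]
            raise ValueError(
                f"non-positive raw value for analyte {values.columns[j]!r}, "
                f"sample {values.index[i]!r}")
        values = np.log2(values)
    dil = raw.analytes.loc[values.columns, "dilution"]
    for _group, cols in values.columns.groupby(dil.to_numpy()).items():
        sub = values.loc[:, cols]
        sample_med = sub.median(axis=1)
        values.loc[:, cols] = sub.sub(sample_med, axis=0) + sample_med.median()
    return ProteinMatrix(values, raw.analytes)


@dataclass
class BatchModel:
    """Fitted empirical-Bayes batch parameters.

    ``gamma_star``/``delta2_star`` are batches x analytes shrunken location
    and squared-scale estimates; ``gamma_bar``/``tau2`` the normal prior
    moments of the locations and ``a_prior``/``b_prior`` the inverse-gamma
    moments of the variances, one per batch.
    """

    batches: list
    gamma_star: np.ndarray
    delta2_star: np.ndarray
    gamma_bar: np.ndarray
    tau2: np.ndarray
    a_prior: np.ndarray
    b_prior: np.ndarray
    n_iter: int


def _it_sol(z: np.ndarray, g_hat: np.ndarray, d_hat: np.ndarray,
            g_bar: float, t2: float, a: float, b: float,
            tol: float = 1e-6, max_iter: int = 200) -> tuple[np.ndarray, np.ndarray, int]:
    """Iterate the conditional posterior means of (gamma, delta2) for one batch."""
    n = z.shape[0]
    g_new, d_new = g_hat.copy(), d_hat.copy()
    it = 0
    for it in range(1, max_iter + 1):
        g_old, d_old = g_new, d_new
        g_new = (n * t2 * g_hat + d_old * g_bar) / (n * t2 + d_old)
        ssq = ((z - g_new) ** 2).sum(axis=0)
        d_new = (0.5 * ssq + b) / (n / 2 + a - 1)
        change = max(np.abs(g_new - g_old).max() / np.abs(g_old).max(),
                     np.abs(d_new - d_old).max() / d_old.max())
        if change < tol:
            break
    return g_new, d_new, it


def combat_adjust(
    data: ProteinMatrix,
    batch: pd.Series,
    covariates: pd.DataFrame | None = None,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> tuple[ProteinMatrix, BatchModel]:
    """Parametric empirical-Bayes location/scale batch adjustment.

    Standardizes each analyte against the grand mean and covariate fit,
    estimates per-batch location/scale, shrinks them via conjugate priors
    (normal for location, moment-matched inverse gamma for scale), and
    back-transforms.  Biological covariate effects are preserved; with a
    single batch the adjustment is the identity.
    """
    batch = batch.loc[data.sample_ids]
    levels = sorted(pd.unique(batch))
    counts = batch.value_counts()
    if (counts < 2).any():
        raise DesignError(f"singleton batches: {list(counts.index[counts < 2])}")
    Y = data.values.to_numpy(dtype=float)
    n, k = Y.shape
    B = np.stack([(batch == lv).to_numpy(dtype=float) for lv in levels], axis=1)

    if covariates is not None:
        C = np.asarray(covariates.loc[data.sample_ids], dtype=float)
        X = np.hstack([B, C])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise DesignError("covariates are confounded with batch (design not full rank)")
    else:
        C = np.zeros((n, 0))
        X = B

    if len(levels) == 1:
        model = BatchModel(levels, np.zeros((1, k)), np.ones((1, k)),
                           np.zeros(1), np.ones(1), np.ones(1), np.ones(1), 0)
        return ProteinMatrix(data.values.copy(), data.analytes), model

    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    nb = len(levels)
    frac = counts.reindex(levels).to_numpy() / n
    grand = frac @ coef[:nb]                       # weighted grand mean
    resid = Y - X @ coef
    var_pooled = (resid ** 2).mean(axis=0)
    var_pooled = np.maximum(var_pooled, 1e-12)
    stand_mean = grand + C @ coef[nb:]
    Z = (Y - stand_mean) / np.sqrt(var_pooled)

    gamma_hat = np.stack([Z[(batch == lv).to_numpy()].mean(axis=0) for lv in levels])
    delta2_hat = np.stack([Z[(batch == lv).to_numpy()].var(axis=0, ddof=1)
                           for lv in levels])
    gamma_bar = gamma_hat.mean(axis=1)
    tau2 = gamma_hat.var(axis=1, ddof=1)
    m_d = delta2_hat.mean(axis=1)
    s2_d = delta2_hat.var(axis=1, ddof=1)
    a_prior = (2 * s2_d + m_d ** 2) / s2_d
    b_prior = (m_d * s2_d + m_d ** 3) / s2_d

    gamma_star = np.empty_like(gamma_hat)
    delta2_star = np.empty_like(delta2_hat)
    iters = 0
    for i, lv in enumerate(levels):
        mask = (batch == lv).to_numpy()
        g, d, it = _it_sol(Z[mask], gamma_hat[i], delta2_hat[i],
                           gamma_bar[i], tau2[i], a_prior[i], b_prior[i],
                           tol=tol, max_iter=max_iter)
        gamma_star[i], delta2_star[i] = g, d
        iters = max(iters, it)

    Z_adj = Z.copy()
    for i, lv in enumerate(levels):
        mask = (batch == lv).to_numpy()
        Z_adj[mask] = (Z[mask] - gamma_star[i]) / np.sqrt(delta2_star[i])
    Y_adj = Z_adj * np.sqrt(var_pooled) + stand_mean

    adjusted = pd.DataFrame(Y_adj, index=data.sample_ids, columns=data.analyte_ids)
    model = BatchModel(levels, gamma_star, delta2_star, gamma_bar, tau2,
                       a_prior, b_prior, iters)
    return ProteinMatrix(adjusted, data.analytes), model


def compute_pcs(data: pd.DataFrame | np.ndarray, k: int) -> pd.DataFrame:
    """Column-centered SVD scores ordered by decreasing variance explained.

    Deterministic sign convention: within each component the loading with
    the largest magnitude is made positive.
    """
    X = np.asarray(data, dtype=float)
    if k >= min(X.shape):
        raise ValueError(f"k={k} must be < min(n_samples, n_features)={min(X.shape)}")
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    signs = np.sign(Vt[np.arange(Vt.shape[0]), np.abs(Vt).argmax(axis=1)])
    signs[signs == 0] = 1.0
    scores = (U[:, :k] * s[:k]) * signs[:k]
    index = data.index if isinstance(data, pd.DataFrame) else pd.RangeIndex(X.shape[0])
    return pd.DataFrame(scores, index=index,
                        columns=[f"PC{i + 1}" for i in range(k)])


def inverse_normal_transform(x, offset: float = 3.0 / 8.0) -> np.ndarray:
    """Blom rank-based inverse normal transform, average rank for ties.

    Maps value of rank r (1-based) to ``Phi^-1((r - c) / (n - 2c + 1))``
    with c the Blom offset 3/8 by default.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two observations")
    if np.nanmax(x) == np.nanmin(x):
        raise ValueError("constant vector: all ranks tied")
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - offset) / (x.size - 2 * offset + 1))


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
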