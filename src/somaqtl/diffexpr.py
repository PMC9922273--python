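"""Differential protein expression with empirical-Bayes moderated t.

Per-analyte covariate-adjusted linear models are fitted through one shared
decomposition of the design matrix; residual variances are then shrunk
toward a common prior by moment-matching the marginal scaled-inverse-chi^2
model of per-analyte variances (digamma/trigamma inversion of the log-s^2
moments), giving moderated t-statistics on d0 + d_g degrees of freedom.
The comparison battery mirrors a three-subcohort case/control study:
each genetic subcohort against its own controls (treatment flag as an
extra covariate), idiopathic patients against healthy controls
(drug-naive, so no treatment column), all patients against all controls,
and a disease x mutation-status interaction model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .datatypes import ProteinMatrix
from .exceptions import DesignError
from .preprocess import bh_fdr, compute_pcs

__all__ = [
    "fit_linear_models", "ebayes_moderate", "run_comparisons",
    "DifferentialExpressionModel", "DEResults",
]


def fit_linear_models(
    Y: np.ndarray | pd.DataFrame,
    X: np.ndarray | pd.DataFrame,
    contrast_idx: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Per-analyte OLS through one shared decomposition of the design.

    Returns (coef, se_unmoderated_scale, s2, df): the contrast coefficient
    per analyte, the unscaled coefficient variance factor v = (X'X)^-1_cc,
    the residual variance s_g^2 and the residual df.
    """
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        u, s, vt = np.linalg.svd(X)
        aliased = np.where(np.abs(vt[rank:]).max(axis=0) > 1e-8)[0]
        raise DesignError(f"design is rank deficient; aliased columns: {list(aliased)}")
    df = n - p
    if df <= 0:
        raise DesignError("not enough residual degrees of freedom")
    xtx_inv = np.linalg.inv(X.T @ X)
    beta_all = xtx_inv @ (X.T @ Y)
    resid = Y - X @ beta_all
    s2 = (resid ** 2).sum(axis=0) / df
    v = xtx_inv[contrast_idx, contrast_idx]
    return beta_all[contrast_idx], v, s2, df


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1 - tri / x) / special.polygamma(2, y)
        y += dif
        if -dif / y < 1e-8:
            break
    return float(y)


def ebayes_moderate(
    coef: np.ndarray,
    v: float | np.ndarray,
    s2: np.ndarray,
    df: int | np.ndarray,
) -> pd.DataFrame:
    """Empirical-Bayes variance moderation and moderated t-statistics.

    Hyperparameters (d0, s0^2) are estimated by moment-matching the log
    residual variances: with z_g = log s_g^2, E[z] = log s0^2 +
    digamma(d0/2) - log(d0/2) - (digamma(d_g/2) - log(d_g/2)) and
    Var[z] approx trigamma(d_g/2) + trigamma(d0/2), solved for d0 by Newton
    inversion of the trigamma function.  Posterior variances
    s~^2 = (d0 s0^2 + d_g s_g^2)/(d0 + d_g) give t~ = beta/(s~ sqrt(v)) on
    d0 + d_g df.  Non-finite moment estimates fall back to complete pooling
    (d0 = inf) with a warning.
    """
    s2 = np.asarray(s2, dtype=float)
    if s2.size < 10:
        warnings.warn("fewer than 10 analytes: hyperparameters are unstable",
                      stacklevel=2)
    dg = np.broadcast_to(np.asarray(df, dtype=float), s2.shape)
    z = np.log(np.maximum(s2, 1e-300))
    e = z - special.digamma(dg / 2) + np.log(dg / 2)
    e_mean = e.mean()
    e_var = np.var(e, ddof=1) - special.polygamma(1, dg / 2).mean()

    if e_var > 0:
        d0 = 2.0 * _trigamma_inverse(e_var)
        s0_2 = float(np.exp(e_mean + special.digamma(d0 / 2) - np.log(d0 / 2)))
        if not (np.isfinite(d0) and np.isfinite(s0_2) and d0 > 0 and s0_2 > 0):
            warnings.warn("hyperparameter estimation failed; pooling completely",
                          stacklevel=2)
            d0, s0_2 = np.inf, float(np.exp(e_mean))
    else:
        d0, s0_2 = np.inf, float(np.exp(e_mean))

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_total = np.full_like(s2, np.inf)
    else:
        s2_post = (d0 * s0_2 + dg * s2) / (d0 + dg)
        df_total = d0 + dg
    t = coef / np.sqrt(s2_post * v)
    if np.isinf(d0):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return pd.DataFrame({
        "coef": coef, "s2": s2, "s2_post": s2_post, "t": t,
        "df_total": df_total, "p": p, "d0": d0, "s0_2": s0_2,
    })


def _build_design(meta: pd.DataFrame, pcs: pd.DataFrame | None,
                  case_mask: np.ndarray, include_treatment: bool,
                  extra: pd.DataFrame | None = None) -> pd.DataFrame:
    cols = {"intercept": 1.0, "disease": case_mask.astype(float),
            "age": meta["age"].to_numpy(dtype=float),
            "sex": meta["sex"].to_numpy(dtype=float)}
    X = pd.DataFrame(cols, index=meta.index)
    centers = pd.get_dummies(meta["center"], prefix="center", drop_first=True)
    X = pd.concat([X, centers.astype(float)], axis=1)
    if pcs is not None:
        X = pd.concat([X, pcs.loc[meta.index]], axis=1)
    if include_treatment:
        X["treatment"] = meta["medication"].to_numpy(dtype=float)
    if extra is not None:
        X = pd.concat([X, extra], axis=1)
    return X


def run_comparisons(
    proteins: ProteinMatrix,
    meta: pd.DataFrame,
    pcs: pd.DataFrame | None = None,
    min_group: int = 3,
) -> dict[str, pd.DataFrame]:
    """The full differential-expression battery, FDR within each comparison.

    Returns a dict of record tables keyed by comparison label:
    ``GBA``, ``LRRK2``, ``idiopathic``, ``all``, and interaction terms
    ``interaction:GBA`` / ``interaction:LRRK2``.  Each table carries
    log2 fold change (case - control, positive = higher in patients),
    moderated t, total df, p and BH FDR within the comparison.
    """
    results: dict[str, pd.DataFrame] = {}
    is_case = (meta["status"] == "patient").to_numpy()

    def one(label: str, mask: np.ndarray, include_treatment: bool,
            extra: pd.DataFrame | None = None, contrast: str = "disease"):
        sub = meta.loc[mask]
        case = (sub["status"] == "patient").to_numpy()
        if case.sum() < min_group or (~case).sum() < min_group:
            warnings.warn(f"comparison {label!r} skipped: too few samples",
                          stacklevel=2)
            return
        X = _build_design(sub, pcs, case, include_treatment,
                          None if extra is None else extra.loc[sub.index])
        # drop constant columns (e.g. a center absent from the subcohort)
        keep = [c for c in X.columns
                if c == "intercept" or X[c].nunique() > 1]
        X = X.loc[:, keep]
        if contrast not in X.columns:
            warnings.warn(f"comparison {label!r} skipped: contrast column "
                          f"{contrast!r} is empty", stacklevel=2)
            return
        Y = proteins.values.loc[sub.index]
        cidx = list(X.columns).index(contrast)
        coef, vfac, s2, dfree = fit_linear_models(Y, X, cidx)
        mod = ebayes_moderate(coef, vfac, s2, dfree)
        tab = pd.DataFrame({
            "analyte_id": proteins.analyte_ids,
            "log2fc": coef, "t": mod["t"].to_numpy(),
            "df": mod["df_total"].to_numpy(), "p": mod["p"].to_numpy(),
        })
        tab["fdr"] = bh_fdr(tab["p"])
        tab["comparison"] = label
        results[label] = tab.sort_values("p", kind="mergesort").reset_index(drop=True)

    sub_col = meta["subcohort"]
    one("GBA", (sub_col == "GBA").to_numpy(), include_treatment=True)
    one("LRRK2", (sub_col == "LRRK2").to_numpy(), include_treatment=True)
    one("idiopathic", (sub_col == "idiopathic").to_numpy(), include_treatment=False)

    mut = pd.get_dummies(sub_col, prefix="mut").astype(float)
    mut = mut.drop(columns="mut_idiopathic", errors="ignore")
    one("all", np.ones(len(meta), dtype=bool), include_treatment=True, extra=mut)

    # interaction model: disease x mutation status, same covariates
    inter = mut.mul(is_case.astype(float), axis=0)
    inter.columns = [c.replace("mut_", "ix_") for c in inter.columns]
    both = pd.concat([mut, inter], axis=1)
    for term in inter.columns:
        one(f"interaction:{term[3:]}", np.ones(len(meta), dtype=bool),
            include_treatment=True, extra=both, contrast=term)
    return results


@dataclass
class DEResults:
    """Differential-expression tables for every comparison."""

    tables: dict[str, pd.DataFrame]
    fdr_threshold: float = 0.05
    pcs: pd.DataFrame | None = field(default=None, repr=False)

    def significant(self, comparison: str) -> pd.DataFrame:
        tab = self.tables[comparison]
        return tab.loc[tab["fdr"] <= self.fdr_threshold]

    def summary(self) -> pd.DataFrame:
        rows = []
        for label, tab in self.tables.items():
            sig = tab["fdr"] <= self.fdr_threshold
            rows.append({
                "comparison": label, "n_analytes": len(tab),
                "n_significant": int(sig.sum()),
                "top_analyte": tab["analyte_id"].iloc[0] if len(tab) else None,
                "top_fdr": tab["fdr"].min() if len(tab) else np.nan,
            })
        return pd.DataFrame(rows)


class DifferentialExpressionModel:
    """Subcohort-stratified differential expression on a protein matrix.

    Covariates are age, sex, study center and the first ``n_pcs`` protein
    principal components (computed on the supplied matrix), with the
    treatment flag added for the genetic subcohorts and the combined model.
    """

    def __init__(self, proteins: ProteinMatrix, meta: pd.DataFrame,
                 n_pcs: int = 4, fdr_threshold: float = 0.05):
        self.proteins = proteins
        self.meta = meta.loc[proteins.sample_ids]
        self.n_pcs = n_pcs
        self.fdr_threshold = fdr_threshold

    def fit(self) -> DEResults:
        pcs = compute_pcs(self.proteins.values, self.n_pcs) if self.n_pcs else None
        tables = run_comparisons(self.proteins, self.meta, pcs)
        return DEResults(tables, self.fdr_threshold, pcs)
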