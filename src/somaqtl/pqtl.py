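"""Cis-pQTL mapping: covariate-adjusted association scan per analyte.

Every analyte (inverse-normal transformed upstream) is regressed on the
dosage of every variant inside the +-1 Mb window flanking its encoding
gene, adjusting for covariates.  The scan residualizes both the analyte
matrix and the dosage matrix on the covariate design once (Frisch-Waugh)
and computes per-pair slope, SE, t and two-sided p with degrees of freedom
n - rank(design) - 1, exactly matching per-pair OLS.

A genome-wide threshold of p < 5e-8 (strict) defines a significant
cis-pQTL; variants are pre-filtered to MAF > 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GenotypeMatrix, ProteinMatrix
from .exceptions import DesignError

__all__ = [
    "map_cis_windows", "scan_pqtl", "significant_cis_pqtls",
    "CisPQTLModel", "CisPQTLResults", "CIS_WINDOW", "GENOME_WIDE_ALPHA",
]

CIS_WINDOW = 1_000_000
GENOME_WIDE_ALPHA = 5e-8

RECORD_COLUMNS = ["analyte_id", "variant_id", "beta", "se", "t", "p", "n"]


def map_cis_windows(
    analytes: pd.DataFrame,
    variants: pd.DataFrame,
    window: int = CIS_WINDOW,
) -> dict[str, list[str]]:
    """Map each analyte to the variants inside its cis window.

    A variant is included iff it lies on the gene's chromosome with position
    in ``[gene_start - window, gene_end + window]`` (1-based, inclusive on
    both boundaries; the lower bound is clamped at position 1).  Analytes
    appearing on several metadata rows (multi-gene aptamers) take the union
    of their windows.  Analytes with missing coordinates are excluded with
    a warning.
    """
    out: dict[str, list[str]] = {}
    pos = variants["pos"].to_numpy()
    chrom = variants["chrom"].to_numpy()
    vids = variants.index.to_numpy()
    skipped = []
    for aid, rows in analytes.groupby(level=0, sort=False):
        hit = np.zeros(len(variants), dtype=bool)
        ok = False
        for _, row in rows.iterrows():
            if pd.isna(row.get("chrom")) or pd.isna(row.get("gene_start")) \
                    or pd.isna(row.get("gene_end")):
                continue
            ok = True
            start = max(int(row["gene_start"]) - window, 1)
            end = int(row["gene_end"]) + window
            hit |= (chrom == row["chrom"]) & (pos >= start) & (pos <= end)
        if not ok:
            skipped.append(aid)
            continue
        out[aid] = list(vids[hit])
    if skipped:
        warnings.warn(f"analytes without gene coordinates excluded: {skipped}",
                      stacklevel=2)
    return out


def _residualize(M: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Project out the orthonormal column space Q from the columns of M."""
    return M - Q @ (Q.T @ M)


def scan_pqtl(
    proteins: ProteinMatrix,
    genotypes: GenotypeMatrix,
    covariates: pd.DataFrame | None,
    windows: dict[str, list[str]] | None = None,
    maf_min: float = 0.05,
) -> pd.DataFrame:
    """Per-(analyte, cis variant) covariate-adjusted OLS association scan.

    Returns one row per tested pair with ``beta, se, t, p, n`` where beta is
    the per-dosage effect.  Monomorphic variants (after the MAF filter) are
    skipped.
    """
    Y = proteins.values
    G = genotypes.dosages.loc[Y.index]
    n = len(Y)
    if covariates is not None:
        X = np.column_stack([np.ones(n), np.asarray(covariates.loc[Y.index], dtype=float)])
    else:
        X = np.ones((n, 1))
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise DesignError("covariate design is rank deficient")
    df = n - rank - 1
    if df <= 0:
        raise DesignError("not enough samples for the covariate-adjusted scan")
    Q, _ = np.linalg.qr(X)

    keep = genotypes.maf() > maf_min
    poly = G.std(axis=0) > 0
    usable = set(G.columns[keep.reindex(G.columns).to_numpy() & poly.to_numpy()])

    if windows is None:
        windows = {aid: list(G.columns) for aid in Y.columns}

    Yr = _residualize(Y.to_numpy(dtype=float), Q)
    Gr = _residualize(G.to_numpy(dtype=float), Q)
    gss = (Gr ** 2).sum(axis=0)
    yss = (Yr ** 2).sum(axis=0)
    vloc = {v: i for i, v in enumerate(G.columns)}
    aloc = {a: i for i, a in enumerate(Y.columns)}

    rows_a, rows_v, betas, ses, ts = [], [], [], [], []
    for aid, vlist in windows.items():
        if aid not in aloc:
            continue
        vuse = [v for v in vlist if v in usable]
        if not vuse:
            continue
        vi = np.array([vloc[v] for v in vuse])
        ji = aloc[aid]
        g = Gr[:, vi]
        xy = g.T @ Yr[:, ji]
        beta = xy / gss[vi]
        rss = yss[ji] - beta * xy          # residual SS after adding dosage
        sigma2 = np.maximum(rss, 0.0) / df
        se = np.sqrt(sigma2 / gss[vi])
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, beta / se, np.inf * np.sign(beta))
        rows_a.extend([aid] * len(vuse))
        rows_v.extend(vuse)
        betas.append(beta)
        ses.append(se)
        ts.append(t)

    if not rows_a:
        return pd.DataFrame(columns=RECORD_COLUMNS)
    beta = np.concatenate(betas)
    se = np.concatenate(ses)
    t = np.concatenate(ts)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return pd.DataFrame({
        "analyte_id": rows_a, "variant_id": rows_v,
        "beta": beta, "se": se, "t": t, "p": p, "n": n,
    })


def significant_cis_pqtls(
    records: pd.DataFrame,
    alpha: float = GENOME_WIDE_ALPHA,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Filter to p < alpha (strict) and report each analyte's best record."""
    if records.empty:
        return records.copy(), records.copy()
    sig = records.loc[records["p"] < alpha].copy()
    best = records.loc[records.groupby("analyte_id")["p"].idxmin()].copy()
    return sig, best


@dataclass
class CisPQTLResults:
    """Result of a cis-pQTL scan: the full pair table plus helpers."""

    records: pd.DataFrame
    alpha: float = GENOME_WIDE_ALPHA
    windows: dict = field(default_factory=dict, repr=False)

    def significant(self, alpha: float | None = None) -> pd.DataFrame:
        sig, _ = significant_cis_pqtls(self.records, alpha or self.alpha)
        return sig

    def best_per_analyte(self) -> pd.DataFrame:
        _, best = significant_cis_pqtls(self.records, self.alpha)
        return best

    def summary(self) -> pd.DataFrame:
        sig = self.significant()
        return pd.DataFrame({
            "n_pairs_tested": [len(self.records)],
            "n_significant_pairs": [len(sig)],
            "n_significant_analytes": [sig["analyte_id"].nunique() if len(sig) else 0],
            "alpha": [self.alpha],
        })


class CisPQTLModel:
    """Cis association scan of a proteome against a genotype panel.

    Parameters mirror the mapping procedure: an inverse-normal-transformed
    :class:`ProteinMatrix`, a :class:`GenotypeMatrix`, a covariate design
    (age, sex, subcohort, protein PCs 1-4, genetic PCs 1-10 in the full
    pipeline) and the cis window half-width.
    """

    def __init__(self, proteins: ProteinMatrix, genotypes: GenotypeMatrix,
                 covariates: pd.DataFrame | None = None,
                 window: int = CIS_WINDOW, maf_min: float = 0.05,
                 alpha: float = GENOME_WIDE_ALPHA):
        self.proteins = proteins
        self.genotypes = genotypes
        self.covariates = covariates
        self.window = window
        self.maf_min = maf_min
        self.alpha = alpha

    def fit(self) -> CisPQTLResults:
        windows = map_cis_windows(self.proteins.analytes, self.genotypes.variants,
                                  self.window)
        records = scan_pqtl(self.proteins, self.genotypes, self.covariates,
                            windows, self.maf_min)
        return CisPQTLResults(records, self.alpha, windows)
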