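"""Bayesian colocalization with Wakefield approximate Bayes factors.

Under a single-causal-variant assumption per trait, each region is scored
against five hypotheses: H0 no association, H1 pQTL only, H2 GWAS only,
H3 two distinct causal variants, H4 one shared causal variant.  Per-variant
log ABFs (``0.5 log(V/(V+W)) + W z^2 / (2(V+W))`` with V the squared SE and
W the squared prior effect sd) are combined with prior probabilities
p1, p2, p12 into posterior hypothesis probabilities PPH0..PPH4; all sums
run in log space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

__all__ = ["ColocConfig", "ColocResult", "wakefield_abf", "coloc_posteriors",
           "coloc_scan"]


@dataclass(frozen=True)
class ColocConfig:
    """Priors of the five-hypothesis colocalization model.

    ``p1``/``p2`` are per-variant prior probabilities of association with
    the pQTL / the outcome trait, ``p12`` with both.  Prior effect scales:
    0.15 for the quantitative (pQTL) side, 0.2 for the case-control (GWAS)
    side, following the defaults of the standard implementation.
    """

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5
    prior_sd_quant: float = 0.15
    prior_sd_cc: float = 0.2
    pph4_strong: float = 0.75

    def __post_init__(self) -> None:
        if not (self.p1 + self.p2 + self.p12 < 1):
            raise ValueError("p1 + p2 + p12 must be < 1")
        if self.prior_sd_quant <= 0 or self.prior_sd_cc <= 0:
            raise ValueError("prior effect sds must be positive")


@dataclass
class ColocResult:
    """Posterior hypothesis probabilities for one region."""

    region: str
    pph: np.ndarray            # PPH0..PPH4
    n_snps: int

    def __post_init__(self) -> None:
        assert abs(self.pph.sum() - 1.0) < 1e-9

    @property
    def pph4(self) -> float:
        return float(self.pph[4])

    def strong(self, threshold: float = 0.75) -> bool:
        return self.pph4 > threshold

    def as_dict(self) -> dict:
        d = {f"PPH{i}": float(self.pph[i]) for i in range(5)}
        d.update(region=self.region, n_snps=self.n_snps)
        return d


def wakefield_abf(beta, se, prior_sd: float) -> np.ndarray:
    """Log approximate Bayes factor for association at one variant.

    With V = se^2, W = prior_sd^2 and z = beta/se:
    ``log ABF = 0.5 log(V/(V+W)) + W z^2 / (2 (V+W))``.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    v = se**2
    w = prior_sd**2
    z2 = (beta / se) ** 2
    return 0.5 * np.log(v / (v + w)) + (w * z2) / (2 * (v + w))


def coloc_posteriors(
    pqtl_region: pd.DataFrame,
    gwas_region: pd.DataFrame,
    config: ColocConfig = ColocConfig(),
    region: str = "",
) -> ColocResult:
    """Five-hypothesis posteriors for one region.

    Both inputs need columns ``variant_id, beta, se``; only the shared
    variants enter.  Unnormalized weights (log space, via log-sum-exp):
    L0 = 1, L1 = p1 sum BF1, L2 = p2 sum BF2,
    L3 = p1 p2 (sum BF1 sum BF2 - sum BF1 BF2), L4 = p12 sum BF1 BF2.
    """
    a = pqtl_region.set_index("variant_id")
    b = gwas_region.set_index("variant_id")
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        raise ValueError("no shared variants between the two regions")
    l1 = wakefield_abf(a.loc[shared, "beta"], a.loc[shared, "se"],
                       config.prior_sd_quant)
    l2 = wakefield_abf(b.loc[shared, "beta"], b.loc[shared, "se"],
                       config.prior_sd_cc)

    ls1 = logsumexp(l1)
    ls2 = logsumexp(l2)
    ls12 = logsumexp(l1 + l2)
    # log(sum_i sum_{j != i} BF1_i BF2_j) = log(exp(ls1+ls2) - exp(ls12))
    if ls1 + ls2 > ls12:
        ls3 = ls1 + ls2 + np.log1p(-np.exp(ls12 - ls1 - ls2))
    else:
        # negative weight can only arise from round-off (one variant
        # dominating both sums); clamp, and warn if beyond float noise
        if len(shared) > 1 and ls12 - (ls1 + ls2) > 1e-9:
            warnings.warn("negative distinct-variant weight clamped at 0",
                          stacklevel=2)
        ls3 = -np.inf

    logw = np.array([
        0.0,
        np.log(config.p1) + ls1,
        np.log(config.p2) + ls2,
        np.log(config.p1) + np.log(config.p2) + ls3,
        np.log(config.p12) + ls12,
    ])
    pph = np.exp(logw - logsumexp(logw))
    pph /= pph.sum()
    return ColocResult(region, pph, len(shared))


def coloc_scan(
    pqtl_records: pd.DataFrame,
    gwas: pd.DataFrame,
    windows: dict[str, list[str]],
    config: ColocConfig = ColocConfig(),
    proteins: list[str] | None = None,
) -> pd.DataFrame:
    """Colocalize each protein's cis region against the outcome GWAS.

    ``pqtl_records`` is the full per-pair scan table; ``windows`` maps each
    analyte to its cis variants.  Returns one row per protein with
    PPH0..PPH4, n_snps and the strong-evidence flag.
    """
    gtab = gwas.loc[:, ["variant_id", "beta", "se"]]
    rows = []
    for protein, grp in pqtl_records.groupby("analyte_id", sort=True):
        if proteins is not None and protein not in proteins:
            continue
        vids = windows.get(protein)
        sub = grp if vids is None else grp[grp["variant_id"].isin(vids)]
        if sub.empty:
            continue
        res = coloc_posteriors(sub.loc[:, ["variant_id", "beta", "se"]],
                               gtab, config, region=protein)
        d = res.as_dict()
        d["protein"] = protein
        d["strong"] = res.strong(config.pph4_strong)
        rows.append(d)
    cols = ["protein", "PPH0", "PPH1", "PPH2", "PPH3", "PPH4", "n_snps", "strong"]
    return pd.DataFrame(rows, columns=cols + ["region"]).loc[:, cols]
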