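"""Two-sample Mendelian randomization of proteins on an outcome GWAS.

For each protein the cis-pQTL records supply the exposure side and the
outcome GWAS the other.  The chain is: instrument selection (MAF > 0.05,
F > 10, p < 5e-8), allele harmonization (sign flips for swapped alleles,
EAF-based resolution of palindromic variants), greedy LD clumping at
r^2 < 0.3 using in-sample dosage correlations, causal estimation by the
Wald ratio (single instrument) or multiplicative random-effects IVW
(several), a simulation-based global horizontal-pleiotropy test in the
style of MR-PRESSO, and BH FDR across proteins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import PALINDROMIC_PAIRS, GenotypeMatrix, GwasSummary
from .preprocess import bh_fdr
from .pqtl import GENOME_WIDE_ALPHA

__all__ = [
    "select_instruments", "harmonize", "ld_clump",
    "mr_wald", "mr_ivw", "presso_global_test", "causal_table",
    "MrEstimate", "MRModel", "MRResults",
]

F_MIN = 10.0
EAF_AMBIGUOUS = (0.42, 0.58)


@dataclass
class MrEstimate:
    """Causal estimate for one protein."""

    protein: str
    n_instruments: int
    method: str               # "Wald ratio" or "IVW"
    beta: float
    se: float
    p: float
    q: float = np.nan         # Cochran's Q heterogeneity
    pleiotropy_p: float = np.nan


def select_instruments(
    pqtls: pd.DataFrame,
    variants: pd.DataFrame,
    maf_min: float = 0.05,
    f_min: float = F_MIN,
    alpha: float = GENOME_WIDE_ALPHA,
) -> pd.DataFrame:
    """Keep cis-pQTL records with MAF > maf_min, F > f_min and p < alpha.

    F is the squared t of the pQTL regression (single-variant instrument
    strength).  Returns the surviving records with an ``F`` column.
    """
    rec = pqtls.copy()
    eaf = variants["eaf"].reindex(rec["variant_id"]).to_numpy()
    maf = np.minimum(eaf, 1 - eaf)
    rec["F"] = (rec["beta"] / rec["se"]) ** 2
    keep = (maf > maf_min) & (rec["F"] > f_min) & (rec["p"] < alpha)
    return rec.loc[keep.to_numpy()].reset_index(drop=True)


def harmonize(
    exposure: pd.DataFrame,
    outcome: GwasSummary | pd.DataFrame,
    exposure_variants: pd.DataFrame | None = None,
    eaf_band: tuple[float, float] = EAF_AMBIGUOUS,
) -> pd.DataFrame:
    """Align outcome effect alleles with the exposure orientation.

    Exposure records must carry ``variant_id``; the exposure effect allele
    and EAF come from ``exposure_variants`` (columns ``ref, alt, eaf``; the
    counted dosage allele is ``alt``).  Outcome rows whose alleles are
    swapped get their beta sign flipped and EAF complemented.  Palindromic
    variants are kept only when both EAFs are decisive (< lower band or
    > upper band) and concordant; otherwise they are dropped, as are
    variants with irreconcilable alleles or absent from the outcome.
    Output columns: exposure beta/se/p, outcome beta/se, eaf both sides,
    and a ``drop_reason`` diagnostic on removed rows is not retained --
    only harmonized instruments are returned.
    """
    out = outcome.table if isinstance(outcome, GwasSummary) else outcome
    out = out.set_index("variant_id")
    lo, hi = eaf_band
    rows = []
    for _, rec in exposure.iterrows():
        vid = rec["variant_id"]
        if vid not in out.index:
            continue
        o = out.loc[vid]
        if exposure_variants is not None and vid in exposure_variants.index:
            ev = exposure_variants.loc[vid]
            e_eff, e_oth, e_eaf = ev["alt"], ev["ref"], float(ev["eaf"])
        else:  # orientation unknown: trust the outcome labels
            e_eff, e_oth, e_eaf = o["effect_allele"], o["other_allele"], float(o["eaf"])
        beta_o, se_o, eaf_o = float(o["beta"]), float(o["se"]), float(o["eaf"])
        palindromic = (e_eff, e_oth) in PALINDROMIC_PAIRS
        if (o["effect_allele"], o["other_allele"]) == (e_eff, e_oth):
            pass
        elif (o["effect_allele"], o["other_allele"]) == (e_oth, e_eff):
            beta_o, eaf_o = -beta_o, 1.0 - eaf_o
        else:
            continue  # allele pair mismatch in both orientations
        if palindromic:
            decisive = ((e_eaf < lo and eaf_o < lo)
                        or (e_eaf > hi and eaf_o > hi))
            if not decisive:
                continue
        rows.append({
            "variant_id": vid, "protein": rec.get("analyte_id", ""),
            "beta_exp": rec["beta"], "se_exp": rec["se"], "p_exp": rec["p"],
            "F": rec.get("F", (rec["beta"] / rec["se"]) ** 2),
            "beta_out": beta_o, "se_out": se_o,
            "eaf_exp": e_eaf, "eaf_out": eaf_o,
        })
    return pd.DataFrame(rows, columns=[
        "variant_id", "protein", "beta_exp", "se_exp", "p_exp", "F",
        "beta_out", "se_out", "eaf_exp", "eaf_out"])


def ld_clump(
    instruments: pd.DataFrame,
    genotypes: GenotypeMatrix,
    r2_max: float = 0.3,
) -> pd.DataFrame:
    """Greedy clumping on exposure p: keep the best, drop r^2 > r2_max allies.

    LD is the squared Pearson correlation between dosage columns of the
    genotype panel.  Instruments absent from the panel are dropped.
    """
    inst = instruments.loc[instruments["variant_id"].isin(genotypes.variant_ids)]
    inst = inst.sort_values("p_exp", kind="mergesort").reset_index(drop=True)
    if inst.empty:
        return inst
    G = genotypes.dosages.loc[:, inst["variant_id"]].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        r2 = np.corrcoef(G, rowvar=False) ** 2
    r2 = np.atleast_2d(r2)
    alive = np.ones(len(inst), dtype=bool)
    kept = []
    for i in range(len(inst)):
        if not alive[i]:
            continue
        kept.append(i)
        alive &= ~(r2[i] > r2_max)
        alive[i] = False
    return inst.iloc[kept].reset_index(drop=True)


def mr_wald(inst: pd.Series | pd.DataFrame, protein: str = "",
            second_order: bool = False) -> MrEstimate:
    """Single-instrument Wald ratio with the delta-method SE.

    First order by default, SE = SE_out/|beta_exp|; ``second_order`` adds
    the exposure-side variance term of the ratio expansion.
    """
    if isinstance(inst, pd.DataFrame):
        if len(inst) != 1:
            raise ValueError("mr_wald requires exactly one instrument")
        inst = inst.iloc[0]
    b_exp = float(inst["beta_exp"])
    if b_exp == 0:
        raise ZeroDivisionError("exposure beta is zero: Wald ratio undefined")
    beta = float(inst["beta_out"]) / b_exp
    se = float(inst["se_out"]) / abs(b_exp)
    if second_order:
        se = np.sqrt(se**2 + (float(inst["beta_out"])**2
                              * float(inst["se_exp"])**2) / b_exp**4)
    p = 2.0 * stats.norm.sf(abs(beta) / se) if se > 0 else 0.0
    return MrEstimate(protein or str(inst.get("protein", "")), 1, "Wald ratio",
                      beta, se, p)


def mr_ivw(insts: pd.DataFrame, protein: str = "",
           random_effects: bool = True) -> MrEstimate:
    """Inverse-variance-weighted meta-analysis of per-instrument Wald ratios.

    Fixed-effect weights 1/se_j^2 on the ratio scale; the SE is inflated by
    max(1, sqrt(Q/(k-1))) when ``random_effects`` (multiplicative
    random-effects model).  With a single instrument the call routes to
    :func:`mr_wald`.
    """
    if len(insts) < 2:
        return mr_wald(insts, protein)
    b_exp = insts["beta_exp"].to_numpy(dtype=float)
    ratio = insts["beta_out"].to_numpy(dtype=float) / b_exp
    se_r = insts["se_out"].to_numpy(dtype=float) / np.abs(b_exp)
    w = 1.0 / se_r**2
    beta = float(np.sum(w * ratio) / np.sum(w))
    se_fixed = float(np.sum(w) ** -0.5)
    k = len(insts)
    q = float(np.sum(w * (ratio - beta) ** 2))
    infl = max(1.0, np.sqrt(q / (k - 1))) if random_effects else 1.0
    se = se_fixed * infl
    p = 2.0 * stats.norm.sf(abs(beta) / se)
    return MrEstimate(protein or str(insts["protein"].iloc[0]), k, "IVW",
                      beta, se, p, q=q)


def _loo_ivw(b_exp, se_exp, b_out, se_out):
    """Leave-one-out IVW estimates on the ratio scale, vectorized.

    Accepts 1-D arrays (k,) or 2-D arrays (n_sim, k); returns the matching
    shape of per-instrument leave-one-out causal estimates.
    """
    ratio = b_out / b_exp
    w = (b_exp / se_out) ** 2
    sw = (w * ratio).sum(axis=-1, keepdims=True)
    tw = w.sum(axis=-1, keepdims=True)
    return (sw - w * ratio) / (tw - w)


def presso_global_test(
    insts: pd.DataFrame,
    n_sim: int = 1000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Global horizontal-pleiotropy p via a simulated RSS null distribution.

    The observed statistic is ``sum_j w_j (beta_out_j - bhat_loo(-j) *
    beta_exp_j)^2`` with ``w_j = 1/se_out_j^2`` and leave-one-out IVW
    predictions.  The null distribution regenerates both sides from their
    SEs under the fitted (no-pleiotropy) model; the p-value uses the
    add-one rule.  Returns NaN for fewer than three instruments.
    """
    if len(insts) < 3:
        return np.nan
    if n_sim < 100:
        import warnings
        warnings.warn("n_sim < 100 yields an unstable pleiotropy p", stacklevel=2)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    b_exp = insts["beta_exp"].to_numpy(dtype=float)
    se_exp = insts["se_exp"].to_numpy(dtype=float)
    b_out = insts["beta_out"].to_numpy(dtype=float)
    se_out = insts["se_out"].to_numpy(dtype=float)
    w = 1.0 / se_out**2

    loo = _loo_ivw(b_exp, se_exp, b_out, se_out)
    rss_obs = float(np.sum(w * (b_out - loo * b_exp) ** 2))

    k = len(insts)
    b_exp_s = b_exp + rng.standard_normal((n_sim, k)) * se_exp
    b_out_s = loo * b_exp + rng.standard_normal((n_sim, k)) * se_out
    loo_s = _loo_ivw(b_exp_s, se_exp, b_out_s, se_out)
    rss_s = np.sum(w * (b_out_s - loo_s * b_exp_s) ** 2, axis=1)
    return float((1 + np.sum(rss_s >= rss_obs)) / (1 + n_sim))


def leave_worst_out(insts: pd.DataFrame, protein: str = "") -> MrEstimate:
    """Re-estimate after dropping the instrument with the largest weighted
    residual from the leave-one-out fit (outlier-corrected estimate)."""
    if len(insts) < 3:
        raise ValueError("need at least 3 instruments to drop an outlier")
    b_exp = insts["beta_exp"].to_numpy(dtype=float)
    b_out = insts["beta_out"].to_numpy(dtype=float)
    se_out = insts["se_out"].to_numpy(dtype=float)
    loo = _loo_ivw(b_exp, insts["se_exp"].to_numpy(dtype=float), b_out, se_out)
    resid = (b_out - loo * b_exp) ** 2 / se_out**2
    worst = int(np.argmax(resid))
    est = mr_ivw(insts.drop(index=insts.index[worst]), protein)
    est.method += " (outlier-corrected)"
    return est


def causal_table(estimates: list[MrEstimate] | pd.DataFrame,
                 coloc: pd.DataFrame | None = None,
                 fdr_threshold: float = 0.05) -> pd.DataFrame:
    """Per-protein MR table with BH FDR and the causal-candidate flag.

    Joined with colocalization posteriors (on ``protein``) when supplied.
    """
    if isinstance(estimates, pd.DataFrame):
        tab = estimates.copy()
    else:
        tab = pd.DataFrame([vars(e) for e in estimates])
    if tab.empty:
        tab["fdr"] = []
        tab["causal_candidate"] = []
        return tab
    tab["fdr"] = bh_fdr(tab["p"])
    tab["causal_candidate"] = tab["fdr"] <= fdr_threshold
    if coloc is not None:
        tab = tab.merge(coloc, on="protein", how="left")
    return tab.sort_values("fdr", kind="mergesort").reset_index(drop=True)


@dataclass
class MRResults:
    """Fitted MR results: the per-protein causal table plus instruments."""

    table: pd.DataFrame
    instruments: dict[str, pd.DataFrame]

    def summary(self) -> pd.DataFrame:
        """Table shaped like a published causal-protein listing."""
        cols = ["protein", "n_instruments", "method", "beta", "se", "fdr",
                "pleiotropy_p", "causal_candidate"]
        have = [c for c in cols if c in self.table.columns]
        return self.table.loc[:, have]


class MRModel:
    """Two-sample MR of every protein against one outcome GWAS.

    Parameters
    ----------
    exposure : per-pair cis-pQTL records (significant ones are selected
        internally with the MAF/F/p rules).
    outcome : outcome GWAS summary statistics.
    ld_panel : genotype panel supplying in-sample LD for clumping.
    variants : variant metadata (ref/alt/eaf) for harmonization.
    """

    def __init__(self, exposure: pd.DataFrame, outcome: GwasSummary,
                 ld_panel: GenotypeMatrix, variants: pd.DataFrame | None = None,
                 r2_max: float = 0.3, n_presso_sim: int = 1000,
                 fdr_threshold: float = 0.05):
        self.exposure = exposure
        self.outcome = outcome
        self.ld_panel = ld_panel
        self.variants = variants if variants is not None else ld_panel.variants
        self.r2_max = r2_max
        self.n_presso_sim = n_presso_sim
        self.fdr_threshold = fdr_threshold

    def fit(self, seed: int = 0) -> MRResults:
        rng = np.random.default_rng(seed)
        selected = select_instruments(self.exposure, self.variants)
        estimates: list[MrEstimate] = []
        kept: dict[str, pd.DataFrame] = {}
        for protein, grp in selected.groupby("analyte_id", sort=True):
            harm = harmonize(grp, self.outcome, self.variants)
            if harm.empty:
                continue
            clumped = ld_clump(harm, self.ld_panel, self.r2_max)
            if clumped.empty:
                continue
            kept[protein] = clumped
            est = mr_ivw(clumped, protein)
            est.pleiotropy_p = presso_global_test(
                clumped, self.n_presso_sim, rng)
            estimates.append(est)
        if not estimates:
            return MRResults(causal_table([]), kept)
        return MRResults(causal_table(estimates, fdr_threshold=self.fdr_threshold),
                         kept)
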