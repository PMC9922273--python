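"""Synthetic proteogenomic cohort generator with known ground truth.

The generator emulates the statistical structure of a CSF aptamer-proteomics
cohort with matched genotypes:

* LD-blocked biallelic genotypes on a single synthetic chromosome, generated
  through a Gaussian copula (block-autoregressive latent correlation
  thresholded to Hardy-Weinberg dosage frequencies).
* A log2-scale proteome with per-analyte baselines, age/sex/center effects,
  cis genetic effects for a configurable fraction of analytes, plate
  location/scale batch effects, latent co-expression modules carrying a
  two-endotype structure, optional disease effects, and Gaussian noise.
* Outcome-GWAS summary statistics computed analytically from the virtual
  cohort's generative model plus sampling noise (so external cohort sizes up
  to millions cost nothing), with shared vs. distinct causal-variant
  scenarios and optional swapped-allele / palindromic records.
* Clinical variables (CSF p-tau, amyloid-beta, total tau, alpha-synuclein,
  UPDRS I, MoCA) whose distributions differ between the two latent
  endotypes of idiopathic patients; by default p-tau straddles 11 pg/mL.

Every operation is a pure function of a :class:`SimConfig` (whose ``seed``
fully determines all outputs) plus upstream artifacts, and every injected
effect is recorded in a :class:`~somaqtl.datatypes.GroundTruth`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GenotypeMatrix, GroundTruth, GwasSummary, ProteinMatrix
from .exceptions import ConfigError, StateError

__all__ = [
    "SimConfig", "simulate_genotypes", "simulate_sample_meta",
    "simulate_proteome", "simulate_gwas_summary", "simulate_clinical_cohort",
    "simulate_cohort",
]

_SUBCOHORTS = ("idiopathic", "GBA", "LRRK2")

# endotype-2 minus endotype-1 location shifts of the clinical variables, at
# clinical_shift=1.  p-tau means straddle the 11 pg/mL decision point.
_CLINICAL_VARS = {
    # name: (endotype-1 mean, endotype-2 delta, sd, lower clip)
    "abeta": (900.0, -250.0, 200.0, 50.0),
    "total_tau": (170.0, -60.0, 45.0, 10.0),
    "asyn": (1500.0, -400.0, 350.0, 50.0),
    "updrs1": (5.5, 1.2, 3.0, 0.0),
    "moca": (27.0, 0.0, 2.0, 0.0),
}


@dataclass(frozen=True)
class SimConfig:
    """Scenario parameters of the synthetic cohort.

    Defaults are a desk-scale rendering of a three-subcohort CSF proteomics
    study: several hundred samples, LD-blocked genotypes, a proteome in
    which ~30% of analytes carry a cis genetic effect, plate batch effects,
    a large external outcome GWAS, and a latent two-endotype split of the
    idiopathic patients (fraction 0.47 in endotype 2, mirroring a 185/165
    split).
    """

    n_samples: int = 600
    n_variants: int = 300
    n_analytes: int = 100
    ld_block_size: int = 10
    ld_rho: float = 0.8
    maf_range: tuple[float, float] = (0.05, 0.5)
    variant_spacing: int = 50_000
    cis_effect_sd: float = 0.4
    prop_cis_regulated: float = 0.3
    noise_sd: float = 0.25
    n_plates: int = 8
    plate_shift_sd: float = 0.3
    plate_scale_sd: float = 0.1
    n_centers: int = 5
    center_sd: float = 0.05
    age_effect_sd: float = 0.005
    sex_effect_sd: float = 0.1
    # outcome GWAS (virtual external cohort)
    gwas_n: int = 500_000
    theta_causal: float = 0.15
    prop_causal: float = 0.2
    pleiotropy_frac: float = 0.0
    pleiotropy_sd: float = 0.05
    shared_causal_variant: bool = True
    allele_swap_frac: float = 0.0
    palindromic_frac: float = 0.1
    # disease effects on the proteome
    n_de_analytes: int = 0
    de_effect: float = 0.3
    de_subcohort: str = "all"
    # endotype structure
    endotype_frac: float = 0.47
    module_frac: float = 0.25
    module_loading: tuple[float, float] = (0.4, 0.8)
    module_nuisance: float = 0.3
    endotype_shift: float = 4.0
    clinical_shift: float = 1.0
    ptau_mu: tuple[float, float] = (14.0, 8.5)
    ptau_sd: float = 2.2
    # cohort composition (patients; controls mirror with their own split)
    frac_patients: float = 0.52
    patient_split: tuple[float, float, float] = (0.615, 0.114, 0.271)
    control_split: tuple[float, float, float] = (0.45, 0.15, 0.40)
    medication_rate: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.05 <= lo <= hi <= 0.5):
            raise ConfigError(f"maf_range must lie within [0.05, 0.5], got {self.maf_range}")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ConfigError("ld_rho must be in [0, 1)")
        for name in ("prop_cis_regulated", "prop_causal", "pleiotropy_frac",
                     "endotype_frac", "module_frac", "frac_patients",
                     "allele_swap_frac", "palindromic_frac", "clinical_shift"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.n_variants % self.ld_block_size:
            raise ConfigError("n_variants must be divisible by ld_block_size")
        if self.gwas_n <= 0:
            raise ConfigError("gwas_n must be positive")

    def rng(self, stream: str) -> np.random.Generator:
        """Independent, reproducible generator for a named stream."""
        return np.random.default_rng(
            np.random.SeedSequence([self.seed % 2**31, _STREAMS[stream]]))


_STREAMS = {"genotypes": 0, "meta": 1, "proteome": 2, "gwas": 3, "clinical": 4}


# ---------------------------------------------------------------------------
# genotypes

def simulate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """LD-blocked biallelic dosages via a Gaussian copula.

    Within each block of ``ld_block_size`` variants the latent haplotype
    field is AR(1) with parameter ``ld_rho``; blocks are independent.  Two
    independent haplotypes are thresholded at the allele frequency and
    summed, so dosages are in {0, 1, 2} and Hardy-Weinberg holds marginally.
    """
    rng = config.rng("genotypes")
    n, m, bs = config.n_samples, config.n_variants, config.ld_block_size
    n_blocks = m // bs
    lo, hi = config.maf_range
    mafs = rng.uniform(lo, hi, size=m)

    dosage = np.zeros((n, m), dtype=np.int8)
    for _hap in range(2):
        z = rng.standard_normal((n, n_blocks, bs))
        rho = config.ld_rho
        for j in range(1, bs):
            z[:, :, j] = rho * z[:, :, j - 1] + np.sqrt(1 - rho**2) * z[:, :, j]
        u = stats.norm.cdf(z.reshape(n, m))
        dosage += (u < mafs).astype(np.int8)

    pos = config.variant_spacing * np.arange(1, m + 1)
    bases = np.array(list("ACGT"))
    ref = rng.choice(bases, size=m)
    complement = {"A": "T", "T": "A", "C": "G", "G": "C"}
    alt = np.empty(m, dtype="<U1")
    pal = rng.random(m) < config.palindromic_frac
    for j in range(m):
        if pal[j]:
            alt[j] = complement[ref[j]]
        else:
            alt[j] = rng.choice([b for b in "ACGT" if b not in (ref[j], complement[ref[j]])])

    vids = pd.Index([f"var{j:05d}" for j in range(m)], name="variant_id")
    sids = pd.Index([f"S{i:04d}" for i in range(n)], name="sample_id")
    variants = pd.DataFrame({
        "chrom": "1", "pos": pos, "ref": ref, "alt": alt,
        "eaf": dosage.mean(axis=0) / 2.0,
        "block": np.repeat(np.arange(n_blocks), bs),
    }, index=vids)
    return GenotypeMatrix(pd.DataFrame(dosage, index=sids, columns=vids), variants)


# ---------------------------------------------------------------------------
# sample metadata (demographics, subcohorts, plates, latent endotypes)

def simulate_sample_meta(config: SimConfig) -> pd.DataFrame:
    """Demographics, subcohort membership, plate assignment, endotype truth.

    Columns: age, sex (0/1), center, plate, subcohort, status
    (``patient``/``control``), medication (bool), endotype (1/2 for
    idiopathic patients, 0 otherwise).
    """
    rng = config.rng("meta")
    n = config.n_samples
    sids = pd.Index([f"S{i:04d}" for i in range(n)], name="sample_id")

    age = np.clip(rng.normal(62, 10, n), 35, 88).round(1)
    sex = (rng.random(n) < 0.6).astype(int)
    center = rng.integers(0, config.n_centers, n)
    plate = rng.permuted(np.arange(n) % config.n_plates)

    status = np.where(rng.random(n) < config.frac_patients, "patient", "control")
    sub = np.empty(n, dtype=object)
    pat = status == "patient"
    sub[pat] = rng.choice(_SUBCOHORTS, size=pat.sum(), p=config.patient_split)
    sub[~pat] = rng.choice(_SUBCOHORTS, size=(~pat).sum(), p=config.control_split)

    medication = pat & (sub != "idiopathic") & (rng.random(n) < config.medication_rate)

    endotype = np.zeros(n, dtype=int)
    idio_pat = pat & (sub == "idiopathic")
    endotype[idio_pat] = np.where(
        rng.random(idio_pat.sum()) < config.endotype_frac, 2, 1)

    return pd.DataFrame({
        "age": age, "sex": sex, "center": center, "plate": plate,
        "subcohort": sub, "status": status, "medication": medication,
        "endotype": endotype,
    }, index=sids)


# ---------------------------------------------------------------------------
# proteome

def _assign_genes(config: SimConfig, variants: pd.DataFrame,
                  rng: np.random.Generator) -> pd.DataFrame:
    """Lay analyte target genes along the synthetic chromosome."""
    k = config.n_analytes
    span = int(variants["pos"].max())
    gene_len = 20_000
    centers = rng.integers(1_100_000, max(span - 1_100_000, 1_200_000), k)
    start = np.maximum(centers - gene_len // 2, 1)
    dilution = rng.choice(["20%", "1%", "0.005%"], size=k, p=[0.6, 0.3, 0.1])
    aids = pd.Index([f"seq{j:04d}" for j in range(k)], name="analyte_id")
    return pd.DataFrame({
        "gene_symbol": [f"GENE{j}" for j in range(k)],
        "chrom": "1", "gene_start": start, "gene_end": start + gene_len - 1,
        "dilution": dilution,
    }, index=aids)


def simulate_proteome(
    config: SimConfig,
    genotypes: GenotypeMatrix,
    meta: pd.DataFrame,
) -> tuple[ProteinMatrix, GroundTruth]:
    """Log2 proteome with cis, covariate, module/endotype and plate effects.

    Each analyte value is baseline + age/sex/center effects + cis dosage
    effect (for the regulated fraction) + module loading x latent endotype
    factor + disease effect (configured subcohorts) + plate location/scale
    batch effect + Gaussian noise.
    """
    if not genotypes.sample_ids.equals(meta.index):
        from .exceptions import AlignmentError
        raise AlignmentError("genotypes and sample meta have different samples")
    rng = config.rng("proteome")
    n, k = config.n_samples, config.n_analytes
    analytes = _assign_genes(config, genotypes.variants, rng)
    variants = genotypes.variants

    # choose cis-regulated analytes and their causal variant inside +-1 Mb
    n_reg = int(round(config.prop_cis_regulated * k))
    reg_idx = rng.choice(k, size=n_reg, replace=False)
    cis_variant = np.full(k, None, dtype=object)
    cis_beta = np.zeros(k)
    maf_ok = genotypes.maf().to_numpy() > 0.05
    pos = variants["pos"].to_numpy()
    for j in reg_idx:
        gs, ge = analytes["gene_start"].iloc[j], analytes["gene_end"].iloc[j]
        in_win = (pos >= gs - 1_000_000) & (pos <= ge + 1_000_000) & maf_ok
        cand = np.flatnonzero(in_win)
        if cand.size == 0:
            continue
        v = rng.choice(cand)
        cis_variant[j] = variants.index[v]
        b = rng.normal(0.0, config.cis_effect_sd)
        cis_beta[j] = b if abs(b) > 0.05 * config.cis_effect_sd else np.sign(b or 1.0) * 0.05 * config.cis_effect_sd

    # causal subset of the regulated analytes (protein -> trait effect)
    causal = np.zeros(k, dtype=bool)
    regulated = np.flatnonzero(cis_variant != None)  # noqa: E711
    n_causal = int(round(config.prop_causal * regulated.size))
    if n_causal and config.theta_causal != 0.0:
        causal[rng.choice(regulated, size=n_causal, replace=False)] = True
    theta = np.where(causal, config.theta_causal, 0.0)

    # distinct-variant scenario: trait-side causal variant in another block
    trait_variant = cis_variant.copy()
    if not config.shared_causal_variant:
        block = variants["block"]
        for j in np.flatnonzero(causal):
            own = block.loc[cis_variant[j]]
            gs, ge = analytes["gene_start"].iloc[j], analytes["gene_end"].iloc[j]
            in_win = (pos >= gs - 1_000_000) & (pos <= ge + 1_000_000) & maf_ok
            cand = np.flatnonzero(in_win & (block.to_numpy() != own))
            if cand.size:
                trait_variant[j] = variants.index[rng.choice(cand)]

    # module membership for the endotype structure
    module = np.zeros(k, dtype=int)
    m_size = int(round(config.module_frac * k))
    free = rng.permutation(k)
    module[free[:m_size]] = 1
    module[free[m_size:2 * m_size]] = 2

    # disease-effect analytes
    de_mask = np.zeros(k, dtype=bool)
    if config.n_de_analytes:
        de_mask[rng.choice(k, size=min(config.n_de_analytes, k), replace=False)] = True

    # assemble the matrix
    baseline = rng.normal(10.0, 1.5, k)
    b_age = rng.normal(0.0, config.age_effect_sd, k)
    b_sex = rng.normal(0.0, config.sex_effect_sd, k)
    b_center = rng.normal(0.0, config.center_sd, (config.n_centers, k))
    lo_l, hi_l = config.module_loading
    loading = rng.uniform(lo_l, hi_l, k) * (module > 0)

    age_c = meta["age"].to_numpy() - meta["age"].mean()
    Y = baseline + np.outer(age_c, b_age) + np.outer(meta["sex"].to_numpy(), b_sex)
    Y += b_center[meta["center"].to_numpy(), :]

    G = genotypes.dosages.to_numpy(dtype=float)
    vloc = {v: i for i, v in enumerate(variants.index)}
    for j in regulated:
        Y[:, j] += cis_beta[j] * G[:, vloc[cis_variant[j]]]

    # latent endotype factors: module 1 up / module 2 down in endotype 2,
    # plus a module-specific nuisance factor carrying endotype-independent
    # covariation (decorrelates the two modules)
    endo2 = (meta["endotype"].to_numpy() == 2).astype(float)
    f1 = config.endotype_shift * endo2 + rng.standard_normal(n)
    f2 = -config.endotype_shift * endo2 + rng.standard_normal(n)
    g1 = rng.standard_normal(n)
    g2 = rng.standard_normal(n)
    Y += np.outer(f1, loading * (module == 1))
    Y += np.outer(f2, loading * (module == 2))
    Y += config.module_nuisance * np.outer(g1, module == 1)
    Y += config.module_nuisance * np.outer(g2, module == 2)

    if de_mask.any():
        is_case = (meta["status"] == "patient").to_numpy(dtype=float)
        if config.de_subcohort != "all":
            is_case *= (meta["subcohort"] == config.de_subcohort).to_numpy(dtype=float)
        Y += np.outer(is_case, config.de_effect * de_mask)

    # plate location/scale batch effects, then noise
    gamma = rng.normal(0.0, config.plate_shift_sd, (config.n_plates, k))
    delta = np.exp(rng.normal(0.0, config.plate_scale_sd, (config.n_plates, k)))
    plate = meta["plate"].to_numpy()
    eps = rng.standard_normal((n, k)) * config.noise_sd
    Y += gamma[plate, :] + delta[plate, :] * eps

    values = pd.DataFrame(Y, index=meta.index, columns=analytes.index)
    truth_analytes = pd.DataFrame({
        "cis_variant": cis_variant, "cis_beta": cis_beta,
        "causal": causal, "theta": theta, "trait_variant": trait_variant,
        "module": module, "de_effect": np.where(de_mask, config.de_effect, 0.0),
        "de_subcohort": np.where(de_mask, config.de_subcohort, ""),
    }, index=analytes.index)
    truth_samples = meta[["endotype"]].copy()
    truth_variants = pd.DataFrame(
        {"pleio_effect": 0.0}, index=variants.index)
    truth = GroundTruth(truth_analytes, truth_samples, truth_variants)
    return ProteinMatrix(values, analytes), truth


# ---------------------------------------------------------------------------
# outcome GWAS summary statistics

def simulate_gwas_summary(
    config: SimConfig,
    truth: GroundTruth,
    genotypes: GenotypeMatrix,
) -> GwasSummary:
    """Analytic marginal summary statistics of the virtual outcome cohort.

    The virtual trait is ``sum_k theta_k * beta_k * dosage(v_k)`` over causal
    proteins (``v_k`` the shared or distinct trait variant), plus direct
    pleiotropic variant effects, plus unit-variance environmental noise.
    Marginal per-variant betas are computed from the genotype panel's
    empirical dosage covariance with the genetic score; sampling noise at
    the configured ``gwas_n`` is then added, so no outcome individuals are
    ever simulated.
    """
    rng = config.rng("gwas")
    variants = genotypes.variants
    m = len(variants)
    G = genotypes.dosages.to_numpy(dtype=float)
    Gc = G - G.mean(axis=0)

    w = pd.Series(0.0, index=variants.index)
    ta = truth.analytes
    for aid, row in ta[ta["causal"]].iterrows():
        w.loc[row["trait_variant"]] += row["theta"] * row["cis_beta"]

    # direct (pleiotropic) effects on instruments
    pleio = pd.Series(0.0, index=variants.index)
    if config.pleiotropy_frac > 0:
        instruments = ta.loc[ta["cis_variant"].notna(), "cis_variant"].unique()
        n_p = int(round(config.pleiotropy_frac * len(instruments)))
        if n_p:
            chosen = rng.choice(instruments, size=n_p, replace=False)
            pleio.loc[chosen] = rng.normal(0.0, config.pleiotropy_sd, n_p)
    w_total = w + pleio

    n_panel = G.shape[0]
    score = Gc @ w_total.to_numpy()
    var_d = Gc.var(axis=0)
    var_d = np.where(var_d < 1e-12, np.nan, var_d)
    cov = (Gc * score[:, None]).mean(axis=0)
    beta_true = cov / var_d
    var_y = score.var() + 1.0

    se = np.sqrt(var_y / (config.gwas_n * var_d))
    beta_hat = beta_true + rng.normal(0.0, 1.0, m) * se
    z = beta_hat / se
    pval = 2.0 * stats.norm.sf(np.abs(z))

    eaf = variants["eaf"].to_numpy().copy()
    effect = variants["alt"].to_numpy().copy()
    other = variants["ref"].to_numpy().copy()
    swapped = rng.random(m) < config.allele_swap_frac
    effect[swapped], other[swapped] = other[swapped], effect[swapped]
    beta_hat = np.where(swapped, -beta_hat, beta_hat)
    eaf = np.where(swapped, 1.0 - eaf, eaf)

    table = pd.DataFrame({
        "variant_id": variants.index,
        "chrom": variants["chrom"].to_numpy(),
        "pos": variants["pos"].to_numpy(),
        "effect_allele": effect, "other_allele": other,
        "eaf": eaf, "beta": beta_hat, "se": se, "pval": pval,
        "n": config.gwas_n, "swapped": swapped,
    })
    ok = np.isfinite(table["beta"]) & np.isfinite(table["se"])
    truth.variants["pleio_effect"] = pleio
    return GwasSummary(table.loc[ok].reset_index(drop=True))


# ---------------------------------------------------------------------------
# clinical variables

def simulate_clinical_cohort(
    config: SimConfig,
    truth: GroundTruth,
    meta: pd.DataFrame,
) -> pd.DataFrame:
    """Fill endotype-conditional clinical columns on the sample metadata.

    p-tau is drawn from endotype-conditional normals whose means straddle
    11 pg/mL by default; the other variables get endotype-2 location shifts
    scaled by ``clinical_shift`` (0 gives a pure null).  Samples outside the
    idiopathic-patient subset draw from the endotype-1 distributions.
    """
    if (meta["endotype"].to_numpy() == 0).all() and (meta["subcohort"] == "idiopathic").any() \
            and (meta["status"] == "patient").any():
        raise StateError("endotype labels must be assigned before clinical simulation")
    rng = config.rng("clinical")
    out = meta.copy()
    n = len(meta)
    endo2 = (meta["endotype"].to_numpy() == 2)

    mu1, mu2 = config.ptau_mu
    shift = config.clinical_shift
    mu = np.where(endo2, mu1 + shift * (mu2 - mu1), mu1)
    out["ptau"] = np.clip(rng.normal(mu, config.ptau_sd), 0.5, None).round(2)

    for name, (base, delta, sd, lo) in _CLINICAL_VARS.items():
        mu = base + shift * delta * endo2
        out[name] = np.clip(rng.normal(mu, sd, n), lo, None).round(2)
    return out


# ---------------------------------------------------------------------------
# one-call cohort

@dataclass
class SyntheticCohort:
    """All artifacts of one synthetic study, plus the ground truth."""

    config: SimConfig
    genotypes: GenotypeMatrix
    meta: pd.DataFrame
    proteins: ProteinMatrix
    truth: GroundTruth
    gwas: GwasSummary

    sample_meta: pd.DataFrame = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.sample_meta = self.meta


def simulate_cohort(config: SimConfig | None = None, **overrides) -> SyntheticCohort:
    """Generate genotypes, metadata, proteome, clinical table and GWAS."""
    if config is None:
        config = SimConfig(**overrides)
    elif overrides:
        config = replace(config, **overrides)
    genotypes = simulate_genotypes(config)
    meta = simulate_sample_meta(config)
    proteins, truth = simulate_proteome(config, genotypes, meta)
    meta = simulate_clinical_cohort(config, truth, meta)
    gwas = simulate_gwas_summary(config, truth, genotypes)
    return SyntheticCohort(config, genotypes, meta, proteins, truth, gwas)
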