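"""Convenience chains wiring the analysis stages together.

These helpers reproduce the canonical ordering of the study design:
median normalization -> empirical-Bayes plate correction -> protein PCs ->
inverse normal transform -> cis-pQTL scan with age/sex/subcohort/protein
PCs 1-4/genetic PCs 1-10 -> MR + colocalization; and, on the idiopathic
patients, residualization -> network modules -> consensus endotypes ->
clinical tree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coloc import ColocConfig, coloc_scan
from .datatypes import GenotypeMatrix, GwasSummary, ProteinMatrix
from .diffexpr import DEResults, DifferentialExpressionModel
from .endotype import EndotypeModel, EndotypeResults, NetworkConfig
from .mr import MRModel, MRResults
from .pqtl import CisPQTLModel, CisPQTLResults
from .preprocess import (combat_adjust, compute_pcs,
                         inverse_normal_transform, log2_median_normalize)

__all__ = ["preprocess_proteome", "pqtl_covariates", "run_genetic_arm",
           "run_endotype_arm", "GeneticArmResults"]


def preprocess_proteome(
    proteins: ProteinMatrix,
    meta: pd.DataFrame,
    batch_col: str = "plate",
    n_protein_pcs: int = 4,
    int_transform: bool = True,
) -> tuple[ProteinMatrix, pd.DataFrame]:
    """Normalize, batch-correct, compute protein PCs and optionally INT.

    Returns the analysis-ready matrix (INT scale if requested) and the
    protein principal-component scores computed on the batch-corrected,
    normalized matrix.
    """
    norm = log2_median_normalize(proteins)
    adjusted, _ = combat_adjust(norm, meta[batch_col],
                                meta[["age", "sex"]].astype(float))
    pcs = compute_pcs(adjusted.values, n_protein_pcs)
    if int_transform:
        arr = np.column_stack([inverse_normal_transform(adjusted.values[c])
                               for c in adjusted.values.columns])
        out = ProteinMatrix(pd.DataFrame(arr, index=adjusted.values.index,
                                         columns=adjusted.values.columns),
                            adjusted.analytes)
    else:
        out = adjusted
    return out, pcs


def pqtl_covariates(meta: pd.DataFrame, protein_pcs: pd.DataFrame,
                    genotypes: GenotypeMatrix,
                    n_genetic_pcs: int = 10) -> pd.DataFrame:
    """Age, sex, subcohort dummies, protein PCs 1-4, genetic PCs 1-10."""
    gpcs = compute_pcs(genotypes.dosages, n_genetic_pcs)
    gpcs.columns = [f"g{c}" for c in gpcs.columns]
    return pd.concat([
        meta[["age", "sex"]].astype(float),
        pd.get_dummies(meta["subcohort"], prefix="sub", drop_first=True).astype(float),
        protein_pcs.loc[meta.index],
        gpcs.loc[meta.index],
    ], axis=1)


@dataclass
class GeneticArmResults:
    """pQTL scan + MR + colocalization, joined per protein."""

    pqtl: CisPQTLResults
    mr: MRResults
    coloc: pd.DataFrame
    table: pd.DataFrame        # MR table joined with PPH0-4


def run_genetic_arm(
    proteins: ProteinMatrix,
    genotypes: GenotypeMatrix,
    meta: pd.DataFrame,
    gwas: GwasSummary,
    r2_max: float = 0.3,
    n_presso_sim: int = 1000,
    coloc_config: ColocConfig = ColocConfig(),
    seed: int = 0,
) -> GeneticArmResults:
    """Full proteogenomic causal chain on preprocessed inputs."""
    ready, pcs = preprocess_proteome(proteins, meta)
    cov = pqtl_covariates(meta, pcs, genotypes)
    pq = CisPQTLModel(ready, genotypes, cov).fit()
    mr_res = MRModel(pq.significant(), gwas, genotypes,
                     r2_max=r2_max, n_presso_sim=n_presso_sim).fit(seed=seed)
    tested = list(mr_res.table["protein"]) if len(mr_res.table) else []
    col = coloc_scan(pq.records, gwas.table, pq.windows, coloc_config,
                     proteins=tested or None)
    table = mr_res.table.merge(
        col.loc[:, ["protein", "PPH3", "PPH4", "strong"]], on="protein",
        how="left") if len(mr_res.table) else mr_res.table
    return GeneticArmResults(pq, mr_res, col, table)


def run_endotype_arm(
    proteins: ProteinMatrix,
    meta: pd.DataFrame,
    network: NetworkConfig = NetworkConfig(),
    n_reps: int = 100,
    seed: int = 0,
) -> EndotypeResults:
    """Normalize + batch-correct, then stratify the idiopathic patients."""
    norm = log2_median_normalize(proteins)
    adjusted, _ = combat_adjust(norm, meta["plate"],
                                meta[["age", "sex"]].astype(float))
    idio = meta.index[(meta["subcohort"] == "idiopathic")
                      & (meta["status"] == "patient")]
    sub = ProteinMatrix(adjusted.values.loc[idio], adjusted.analytes)
    model = EndotypeModel(sub, meta.loc[idio], network, n_reps=n_reps)
    return model.fit(seed=seed)


def run_differential_expression(
    proteins: ProteinMatrix,
    meta: pd.DataFrame,
    n_pcs: int = 4,
) -> DEResults:
    """Normalize + batch-correct, then the comparison battery."""
    norm = log2_median_normalize(proteins)
    adjusted, _ = combat_adjust(norm, meta["plate"],
                                meta[["age", "sex"]].astype(float))
    return DifferentialExpressionModel(adjusted, meta, n_pcs=n_pcs).fit()
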