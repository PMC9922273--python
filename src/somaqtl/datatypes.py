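"""In-memory containers for the proteogenomic data model.

All containers are thin dataclasses around :class:`pandas.DataFrame` objects,
aligned on shared sample identifiers.  Genotypes are dosage-coded (count of
the alternate allele), protein abundances live on the log2 scale, and GWAS
summary statistics follow the conventional per-variant marginal layout
(effect allele, other allele, EAF, beta, SE, p, N).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import AlignmentError

GWAS_COLUMNS = [
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "n",
]

#: allele pairs that are strand-ambiguous
PALINDROMIC_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage matrix plus per-variant metadata.

    ``dosages`` is indexed by sample id with one column per variant id;
    ``variants`` is indexed by variant id with columns
    ``chrom, pos, ref, alt, eaf`` (1-based positions; ``eaf`` is the
    frequency of the alternate/counted allele).
    """

    dosages: pd.DataFrame
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.dosages.columns.equals(self.variants.index):
            raise AlignmentError("dosage columns and variant metadata differ")

    @property
    def sample_ids(self) -> pd.Index:
        return self.dosages.index

    @property
    def variant_ids(self) -> pd.Index:
        return self.variants.index

    def maf(self) -> pd.Series:
        """Minor allele frequency per variant (folded EAF)."""
        eaf = self.variants["eaf"]
        return np.minimum(eaf, 1.0 - eaf)

    def write_tsv(self, path: str | Path) -> None:
        self.dosages.to_csv(path, sep="\t", index_label="sample_id")

    def write_vcf(self, path: str | Path) -> None:
        """Write a minimal VCF with a DS (dosage) FORMAT field and no GT."""
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,'
                     'Description="Alternate allele dosage">\n')
            chroms = self.variants["chrom"].unique()
            for c in chroms:
                fh.write(f"##contig=<ID={c}>\n")
            samples = "\t".join(map(str, self.sample_ids))
            fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
            dos = self.dosages.to_numpy()
            for j, (vid, row) in enumerate(self.variants.iterrows()):
                ds = "\t".join(f"{x:g}" for x in dos[:, j])
                fh.write(f"{row['chrom']}\t{row['pos']}\t{vid}\t{row['ref']}"
                         f"\t{row['alt']}\t.\tPASS\t.\tDS\t{ds}\n")


@dataclass
class ProteinMatrix:
    """Samples x analytes log2 abundance matrix plus analyte metadata.

    ``analytes`` is indexed by analyte id with columns
    ``gene_symbol, chrom, gene_start, gene_end, dilution`` (coordinates
    1-based inclusive).  An analyte targeting several genes may appear on
    several metadata rows; downstream cis logic takes the union of windows.
    """

    values: pd.DataFrame
    analytes: pd.DataFrame

    def __post_init__(self) -> None:
        missing = self.values.columns.difference(self.analytes.index.unique())
        if len(missing):
            raise AlignmentError(f"analytes missing metadata: {list(missing)[:5]}")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("protein matrix contains non-finite values")
        bad = self.analytes["gene_end"] < self.analytes["gene_start"]
        if bad.any():
            raise ValueError("gene_end < gene_start for some analytes")

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def analyte_ids(self) -> pd.Index:
        return self.values.columns

    def write_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="sample_id")


@dataclass
class GwasSummary:
    """Per-variant marginal summary statistics for the outcome trait."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in GWAS_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"GWAS summary missing columns: {missing}")

    def write_tsv(self, path: str | Path) -> None:
        self.table.loc[:, GWAS_COLUMNS].to_csv(path, sep="\t", index=False)


@dataclass
class GroundTruth:
    """Record of every effect injected by the synthetic cohort generator.

    ``analytes``: per-analyte cis variant id (or NaN), true cis beta, causal
    flag, causal effect theta, co-expression module label, disease-effect
    size and the subcohort it applies to, plus (distinct-variant scenario)
    the trait-side causal variant.
    ``samples``: true endotype label for idiopathic patients.
    ``variants``: per-variant direct (pleiotropic) effect on the trait.
    """

    analytes: pd.DataFrame
    samples: pd.DataFrame
    variants: pd.DataFrame

    def write_tsv(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        self.analytes.to_csv(f"{prefix}_analytes.tsv", sep="\t", index_label="analyte_id")
        self.samples.to_csv(f"{prefix}_samples.tsv", sep="\t", index_label="sample_id")
        self.variants.to_csv(f"{prefix}_variants.tsv", sep="\t", index_label="variant_id")


def check_sample_alignment(*frames: pd.DataFrame | pd.Series) -> None:
    """Raise :class:`AlignmentError` unless all frames share an identical index."""
    first = frames[0].index
    for f in frames[1:]:
        if not first.equals(f.index):
            raise AlignmentError("sample identifiers do not match across inputs")
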