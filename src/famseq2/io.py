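"""Readers for the genotype and phenotype interchange formats.

Genotypes can come from a VCF (GT field; parsed with cyvcf2) or from a
plain TSV of minor-allele counts with ``NA`` for missing cells; phenotype
tables are long-format TSV as written by
:func:`famseq2.simulate.write_phenotypes_tsv`.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .simulate import MISSING, GenotypeMatrix, PhenotypeRecord


def read_genotypes_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a (plain or bgzipped) VCF, counting ALT alleles as the minor
    allele.  Multi-allelic records are rejected."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    individual_ids = tuple(vcf.samples)
    variant_ids: list[str] = []
    rows: list[np.ndarray] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValueError(f"multi-allelic record at {rec.CHROM}:{rec.POS}")
        variant_ids.append(rec.ID or f"{rec.CHROM}:{rec.POS}")
        gt = np.asarray(rec.gt_types, dtype=np.int8)  # 0,1,2; 3 = unknown
        gt[gt == 3] = MISSING
        rows.append(gt)
    vcf.close()
    return GenotypeMatrix(tuple(variant_ids), individual_ids, np.vstack(rows))


def read_genotypes_tsv(path: str | Path) -> GenotypeMatrix:
    """TSV with a ``variant_id`` column followed by one column per
    individual; cells are counts in {0,1,2} or NA."""
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str})
    variant_ids = tuple(df["variant_id"])
    individual_ids = tuple(df.columns[1:])
    counts = df.iloc[:, 1:].to_numpy(dtype=float)
    counts = np.where(np.isnan(counts), MISSING, counts).astype(np.int8)
    return GenotypeMatrix(variant_ids, individual_ids, counts)


def write_genotypes_tsv(genotypes: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(
        genotypes.counts.astype(float), columns=list(genotypes.individual_ids)
    )
    df[df == MISSING] = np.nan
    df.insert(0, "variant_id", list(genotypes.variant_ids))
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_phenotypes_tsv(path: str | Path) -> list[PhenotypeRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        PhenotypeRecord(
            individual_id=str(r.individual_id),
            visit_index=int(r.visit_index),
            age=float(r.age),
            sex=str(r.sex),
            treated=bool(r.treated),
            value=float(r.value),
        )
        for r in df.itertuples()
    ]
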