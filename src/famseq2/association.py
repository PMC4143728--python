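"""Hypothesis tests for the two study designs.

One-stage: the quantitative transmission disequilibrium test with
mating-type means (QTDT_M).  For each offspring o with both parents
genotyped, the Mendelian expectation of its minor-allele count is
e_o = (G_father + G_mother) / 2 and the within-family deviation is
w_o = G_o - e_o.  The offspring phenotype is regressed on w_o with
fixed-effect indicators for the parental mating type (the unordered pair
of parental genotypes) absorbing all between-family allele-frequency
differences, which is what makes the test robust to population
stratification.  The reported effect is the coefficient on w_o.

Two-stage, stage 2: ordinary least squares of the phenotype on the
minor-allele count in an independent cohort of unrelated individuals,
restricted to the stage-1-prioritized variants, with Bonferroni
adjustment over only those variants.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .pedigree import Pedigree
from .phenotypes import DerivedPhenotype, phenotype_vector
from .simulate import MISSING, GenotypeMatrix


@dataclass
class AssociationResult:
    variant_id: str
    test: str  # "qtdt_m" or "stage2_lm"
    estimate: float  # trait units per minor allele
    se: float
    p_value: float
    n_used: int
    significant: bool = False
    untestable: bool = False


# -- QTDT with mating-type means -------------------------------------------


@dataclass
class _OffspringIndex:
    """Precomputed offspring/parent genotype columns and phenotypes,
    reusable across variants."""

    child_cols: np.ndarray
    father_cols: np.ndarray
    mother_cols: np.ndarray
    y: np.ndarray
    family: np.ndarray


def _offspring_index(
    pedigree: Pedigree,
    phenotypes: Mapping[str, float],
    genotypes: GenotypeMatrix,
) -> _OffspringIndex:
    child, father, mother, y, fam = [], [], [], [], []
    for fid in pedigree.family_ids:
        for ind in pedigree.members(fid):
            if ind.founder or ind.individual_id not in phenotypes:
                continue
            try:
                cc = genotypes.col(ind.individual_id)
                fc = genotypes.col(ind.father_id)
                mc = genotypes.col(ind.mother_id)
            except KeyError:
                continue
            child.append(cc)
            father.append(fc)
            mother.append(mc)
            y.append(phenotypes[ind.individual_id])
            fam.append(fid)
    return _OffspringIndex(
        np.array(child, dtype=int),
        np.array(father, dtype=int),
        np.array(mother, dtype=int),
        np.array(y, dtype=float),
        np.array(fam),
    )


def _qtdt_one(
    counts_row: np.ndarray,
    idx: _OffspringIndex,
    variant_id: str,
    cluster_robust: bool = False,
) -> AssociationResult:
    gc = counts_row[idx.child_cols].astype(float)
    gf = counts_row[idx.father_cols].astype(float)
    gm = counts_row[idx.mother_cols].astype(float)
    ok = (gc != MISSING) & (gf != MISSING) & (gm != MISSING)
    if not ok.any():
        return AssociationResult(variant_id, "qtdt_m", 0.0, np.nan, 1.0, 0,
                                 untestable=True)
    gc, gf, gm, y = gc[ok], gf[ok], gm[ok], idx.y[ok]
    fam = idx.family[ok]
    w = gc - (gf + gm) / 2.0
    if np.ptp(w) == 0.0:
        # no informative offspring: no heterozygous parents anywhere
        return AssociationResult(variant_id, "qtdt_m", 0.0, np.nan, 1.0, len(y),
                                 untestable=True)
    # mating type = unordered parental genotype pair; indicator per observed type
    mt = np.minimum(gf, gm) * 3 + np.maximum(gf, gm)
    types, mt_idx = np.unique(mt, return_inverse=True)
    X = np.zeros((len(y), len(types) + 1))
    X[np.arange(len(y)), mt_idx] = 1.0
    X[:, -1] = w
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = len(y) - rank
    if dof <= 0:
        return AssociationResult(variant_id, "qtdt_m", float(beta[-1]), np.nan, 1.0,
                                 len(y), untestable=True)
    s2 = float(resid @ resid) / dof
    xtx_inv = np.linalg.pinv(X.T @ X)
    if cluster_robust:
        # CR0 sandwich clustered on family
        meat = np.zeros((X.shape[1], X.shape[1]))
        for f in np.unique(fam):
            rows = fam == f
            sf = X[rows].T @ resid[rows]
            meat += np.outer(sf, sf)
        cov = xtx_inv @ meat @ xtx_inv
        se = float(np.sqrt(cov[-1, -1]))
    else:
        se = float(np.sqrt(s2 * xtx_inv[-1, -1]))
    if se == 0.0 or not np.isfinite(se):
        return AssociationResult(variant_id, "qtdt_m", float(beta[-1]), np.nan, 1.0,
                                 len(y), untestable=True)
    tstat = beta[-1] / se
    p = float(2.0 * stats.t.sf(abs(tstat), dof))
    return AssociationResult(variant_id, "qtdt_m", float(beta[-1]), se, p, len(y))


def qtdt_m(
    pedigree: Pedigree,
    phenotypes: Sequence[DerivedPhenotype] | Mapping[str, float],
    genotypes: GenotypeMatrix,
    variant_id: str,
    kind: str = "intercept",
    cluster_robust: bool = False,
) -> AssociationResult:
    """QTDT_M for a single variant over all informative offspring."""
    values = (
        dict(phenotypes)
        if isinstance(phenotypes, Mapping)
        else phenotype_vector(phenotypes, kind)  # type: ignore[arg-type]
    )
    idx = _offspring_index(pedigree, values, genotypes)
    row = genotypes.counts[genotypes.row(variant_id)]
    return _qtdt_one(row, idx, variant_id, cluster_robust)


def one_stage_analysis(
    pedigree: Pedigree,
    phenotypes: Sequence[DerivedPhenotype] | Mapping[str, float],
    genotypes: GenotypeMatrix,
    alpha: float = 0.05,
    kind: str = "intercept",
    cluster_robust: bool = False,
) -> list[AssociationResult]:
    """QTDT_M over every variant with Bonferroni correction over the total
    number of variants tested (the single-stage design: all members
    sequenced, all variants tested)."""
    values = (
        dict(phenotypes)
        if isinstance(phenotypes, Mapping)
        else phenotype_vector(phenotypes, kind)  # type: ignore[arg-type]
    )
    idx = _offspring_index(pedigree, values, genotypes)
    m = genotypes.n_variants
    results = []
    for i, vid in enumerate(genotypes.variant_ids):
        res = _qtdt_one(genotypes.counts[i], idx, vid, cluster_robust)
        res.significant = res.p_value <= alpha / m
        results.append(res)
    return results


# -- stage-2 replication ---------------------------------------------------


def stage2_test(
    unrelated_phenotypes: Sequence[DerivedPhenotype] | Mapping[str, float],
    unrelated_genotypes: GenotypeMatrix,
    prioritized: Sequence[str],
    alpha: float = 0.05,
    kind: str = "intercept",
) -> list[AssociationResult]:
    """Simple linear regression Y ~ G per prioritized variant in the
    unrelated replication cohort; a variant is significant when
    p <= alpha / n_prioritized (Bonferroni over the prioritized set only).
    Variants monomorphic in the cohort are untestable (p = 1)."""
    if not prioritized:
        raise ValueError("prioritized variant list is empty")
    values = (
        dict(unrelated_phenotypes)
        if isinstance(unrelated_phenotypes, Mapping)
        else phenotype_vector(unrelated_phenotypes, kind)  # type: ignore[arg-type]
    )
    ids = [i for i in unrelated_genotypes.individual_ids if i in values]
    cols = np.array([unrelated_genotypes.col(i) for i in ids], dtype=int)
    y_all = np.array([values[i] for i in ids])
    threshold = alpha / len(prioritized)
    results = []
    for vid in prioritized:
        g_all = unrelated_genotypes.counts[unrelated_genotypes.row(vid), cols].astype(
            float
        )
        ok = g_all != MISSING
        g, y = g_all[ok], y_all[ok]
        n = len(y)
        if n < 3 or np.ptp(g) == 0.0:
            results.append(
                AssociationResult(vid, "stage2_lm", 0.0, np.nan, 1.0, n,
                                  untestable=True)
            )
            continue
        fit = stats.linregress(g, y)
        p = float(fit.pvalue)
        results.append(
            AssociationResult(
                vid,
                "stage2_lm",
                float(fit.slope),
                float(fit.stderr),
                p,
                n,
                significant=p <= threshold,
            )
        )
    return results


def association_to_frame(results: Sequence[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "variant_id": [r.variant_id for r in results],
            "test": [r.test for r in results],
            "estimate": [r.estimate for r in results],
            "se": [r.se for r in results],
            "p_value": [r.p_value for r in results],
            "n_used": [r.n_used for r in results],
            "significant": [r.significant for r in results],
            "untestable": [r.untestable for r in results],
        }
    )
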