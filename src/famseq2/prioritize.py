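"""Stage-1 machinery: extreme-phenotype member sampling, subset MAF
estimation, the kinship-weighted score statistic, and variant ranking.

The score statistic for variant v accumulates, over families f,

    t_fv = (Y_f - mu_f 1)' Phi_f^{-1} (G_fv - 2 q_v 1)

where Y_f holds the derived phenotypes of all family members, mu_f is the
family mean phenotype, Phi_f is the family kinship matrix, G_fv the
minor-allele counts in {0, 1, 2}, and q_v the minor allele frequency —
genotypes are centred at their Hardy-Weinberg expectation 2*q_v, which is
what gives the statistic mean zero under the null.  Genotype deviations
of untyped (unsequenced or missing) individuals are set to zero, but
their phenotypes still contribute through the kinship cross terms.  T_v = sum_f t_fv has mean zero under the null hypothesis of no
association, with asymptotic variance var(T_v) = sum_f t_fv^2; variants
are ranked by the score test T_v^2 / var(T_v), asymptotically chi-square
with one degree of freedom under the null.

Ranking is invariant to replacing Phi by the additive relationship matrix
2*Phi and to affine transformations of the phenotype, since both rescale
T_v and sqrt(var(T_v)) identically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import rankdata

from .pedigree import KinshipMatrix, Pedigree, solve_kinship
from .phenotypes import DerivedPhenotype, phenotype_vector
from .simulate import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


# -- member sampling -------------------------------------------------------


@dataclass
class SequencedSubset:
    """Which members of each family were sequenced in stage 1."""

    members: dict[str, tuple[str, ...]]  # family_id -> sequenced ids
    k_per_family: int
    selection_seed: int

    def all_ids(self) -> list[str]:
        out: list[str] = []
        for fid in self.members:
            out.extend(self.members[fid])
        return out


def _logistic_weights(n: int, ranks: np.ndarray, steepness: float) -> np.ndarray:
    """Selection weights: logistic(alpha + steepness * d^2), d the scaled
    rank deviation from the family median, alpha calibrated so the weights
    average 0.5 (hence steepness = 0 gives uniform sampling)."""
    d = (ranks - (n + 1) / 2.0) / n
    z = steepness * d**2
    if steepness == 0.0 or n == 1:
        return np.full(n, 0.5)

    def mean_minus_half(alpha: float) -> float:
        return expit(alpha + z).mean() - 0.5

    alpha = brentq(mean_minus_half, -steepness - 50.0, 50.0, xtol=1e-12)
    return expit(alpha + z)


def sample_members(
    pedigree: Pedigree,
    phenotypes: Sequence[DerivedPhenotype] | Mapping[str, float],
    k: int,
    steepness: float = 8.0,
    exclusions: set[str] | frozenset[str] = frozenset(),
    seed: int = 0,
    kind: str = "intercept",
) -> SequencedSubset:
    """Select ``k`` members per family for sequencing, preferentially those
    with extreme phenotypes.

    Within each family the eligible members (phenotyped, not excluded) are
    ranked by phenotype; selection weight is a logistic function of the
    squared rank deviation from the family median, and ``k`` members are
    drawn without replacement with probability proportional to weight
    (sequential draws).  If fewer than ``k`` members are eligible, all are
    taken and a warning logged.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if steepness < 0:
        raise ValueError("steepness must be non-negative")
    values = (
        dict(phenotypes)
        if isinstance(phenotypes, Mapping)
        else phenotype_vector(phenotypes, kind)  # type: ignore[arg-type]
    )
    rng = np.random.default_rng(seed)
    chosen: dict[str, tuple[str, ...]] = {}
    short_families = 0
    for fid in pedigree.family_ids:
        eligible = [
            ind.individual_id
            for ind in pedigree.members(fid)
            if ind.individual_id in values and ind.individual_id not in exclusions
        ]
        if not eligible:
            chosen[fid] = ()
            continue
        n = len(eligible)
        if k >= n:
            if k > n:
                short_families += 1
            chosen[fid] = tuple(eligible)
            continue
        y = np.array([values[i] for i in eligible])
        ranks = rankdata(y)  # average ranks on ties
        w = _logistic_weights(n, ranks, steepness).copy()
        picked: list[int] = []
        remaining = list(range(n))
        for _ in range(k):
            p = w[remaining] / w[remaining].sum()
            sel = rng.choice(len(remaining), p=p)
            picked.append(remaining.pop(sel))
        chosen[fid] = tuple(eligible[i] for i in sorted(picked))
    if short_families:
        logger.warning(
            "%d family(ies) had fewer than k=%d eligible members; all taken",
            short_families,
            k,
        )
    return SequencedSubset(chosen, k, seed)


# -- MAF estimation --------------------------------------------------------


def estimate_maf(
    genotypes: GenotypeMatrix, subset: SequencedSubset
) -> tuple[np.ndarray, np.ndarray]:
    """Per-variant minor allele frequency among sequenced, non-missing
    individuals, pooled across families.

    Returns ``(q_hat, unusable)`` where ``unusable`` flags variants that
    are monomorphic in the sequenced sample (q_hat == 0) or genotyped in
    no sequenced individual (q_hat = NaN); both are excluded from scoring.
    """
    cols = [genotypes.col(i) for i in subset.all_ids()]
    if not cols:
        raise ValueError("sequenced subset is empty")
    sub = genotypes.counts[:, cols].astype(float)
    observed = sub != MISSING
    n_obs = observed.sum(axis=1)
    allele_count = np.where(observed, sub, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        q_hat = np.where(n_obs > 0, allele_count / (2.0 * n_obs), np.nan)
    unusable = (n_obs == 0) | (q_hat == 0.0) | (q_hat == 1.0)
    return q_hat, unusable


# -- score test ------------------------------------------------------------


@dataclass
class ScoreResult:
    """Per-variant score statistic and ranking inputs."""

    variant_id: str
    T: float
    var_T: float
    stat: float  # T^2 / var_T, 0 when var_T == 0
    z: float  # signed standardized score T / sqrt(var_T)
    q_hat: float
    rank: int = 0
    n_families_contributing: int = 0
    monomorphic: bool = False
    per_family_t: dict[str, float] | None = None


class AlignmentError(ValueError):
    """Phenotype/kinship individual-id mismatch."""


def score_matrix(
    phenotypes: Mapping[str, float],
    genotypes: GenotypeMatrix,
    kinships: Mapping[str, KinshipMatrix],
    subset: SequencedSubset,
    q: np.ndarray,
    center: str = "family",
) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict[str, np.ndarray]]:
    """Vectorised core: arrays (T, var_T, n_contributing) over all variants
    plus the per-family contribution vectors.

    Per family, the kinship solve a_f = Phi_f^{-1} (Y_f - mu_f 1) is done
    once; each variant's contribution is then an inner product of a_f,
    restricted to sequenced members, with the centred genotypes.

    ``center`` chooses mu_f: ``"family"`` (default) centres phenotypes by
    the family mean, which is the statistic's intended use on pedigrees;
    ``"grand"`` centres by the overall mean of all phenotyped individuals,
    the appropriate limit for cohorts of singleton families, where family
    centring would annihilate every contribution.
    """
    if center not in ("family", "grand"):
        raise ValueError("center must be 'family' or 'grand'")
    nv = genotypes.n_variants
    T = np.zeros(nv)
    var_T = np.zeros(nv)
    n_contrib = np.zeros(nv, dtype=int)
    per_family: dict[str, np.ndarray] = {}
    pheno_fams = set()
    grand_mu = 0.0
    if center == "grand":
        pooled = [
            phenotypes[iid]
            for kin in kinships.values()
            for iid in kin.ids
            if iid in phenotypes
        ]
        grand_mu = float(np.mean(pooled)) if pooled else 0.0
    for fid, kin in kinships.items():
        ids = kin.ids
        known = set(ids)
        y_dev = np.zeros(kin.n)
        phenotyped = [j for j, iid in enumerate(ids) if iid in phenotypes]
        fam_pheno_ids = {ids[j] for j in phenotyped}
        pheno_fams |= fam_pheno_ids
        if not phenotyped:
            continue
        yvals = np.array([phenotypes[ids[j]] for j in phenotyped])
        mu_f = yvals.mean() if center == "family" else grand_mu
        y_dev[phenotyped] = yvals - mu_f
        a = solve_kinship(kin, y_dev)
        seq = [i for i in subset.members.get(fid, ()) if i in known]
        missing_ids = set(subset.members.get(fid, ())) - known
        if missing_ids:
            raise AlignmentError(
                f"sequenced ids absent from kinship matrix of family {fid}: "
                f"{sorted(missing_ids)}"
            )
        if not seq:
            per_family[fid] = np.zeros(nv)
            continue
        cols = [genotypes.col(i) for i in seq]
        a_seq = a[[kin.index(i) for i in seq]]
        G = genotypes.counts[:, cols].astype(float)  # (nv, |S_f|)
        typed = G != MISSING
        g_dev = np.where(typed, G - 2.0 * q[:, None], 0.0)
        t_f = g_dev @ a_seq
        per_family[fid] = t_f
        T += t_f
        var_T += t_f**2
        n_contrib += (t_f != 0.0).astype(int)
    stray = set(phenotypes) - pheno_fams - {
        iid for kin in kinships.values() for iid in kin.ids
    }
    if stray:
        raise AlignmentError(
            f"phenotyped individuals absent from every kinship matrix: "
            f"{sorted(stray)[:5]}"
        )
    return T, var_T, n_contrib, per_family


def score_test(
    phenotypes: Sequence[DerivedPhenotype] | Mapping[str, float],
    genotypes: GenotypeMatrix,
    kinships: Mapping[str, KinshipMatrix],
    subset: SequencedSubset,
    q: np.ndarray | None = None,
    kind: str = "intercept",
    keep_family_terms: bool = False,
    center: str = "family",
) -> list[ScoreResult]:
    """Score every variant; ``q`` defaults to the subset-estimated MAF.

    Variants monomorphic (or entirely missing) in the sequenced sample get
    ``stat = 0`` and are flagged.  Ranks are 1-based, by ``stat``
    descending with ties broken by |T| descending then variant id.
    """
    values = (
        dict(phenotypes)
        if isinstance(phenotypes, Mapping)
        else phenotype_vector(phenotypes, kind)  # type: ignore[arg-type]
    )
    kin_ids = {iid for kin in kinships.values() for iid in kin.ids}
    stray_subset = [
        i
        for i in subset.all_ids()
        if i not in kin_ids or i not in genotypes._col
    ]
    if stray_subset:
        raise AlignmentError(
            "sequenced ids absent from the kinship matrices or genotype "
            f"matrix: {sorted(stray_subset)[:5]}"
        )
    q_est, unusable = estimate_maf(genotypes, subset)
    if q is None:
        q_use = np.where(np.isnan(q_est), 0.0, q_est)
    else:
        q_use = np.asarray(q, dtype=float)
        unusable = np.isnan(q_est) | (q_use == 0.0)
    T, var_T, n_contrib, per_family = score_matrix(
        values, genotypes, kinships, subset, q_use, center=center
    )
    T = np.where(unusable, 0.0, T)
    var_T = np.where(unusable, 0.0, var_T)
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = np.where(var_T > 0, T**2 / np.where(var_T > 0, var_T, 1.0), 0.0)
        z = np.where(var_T > 0, T / np.sqrt(np.where(var_T > 0, var_T, 1.0)), 0.0)
    results = [
        ScoreResult(
            variant_id=vid,
            T=float(T[i]),
            var_T=float(var_T[i]),
            stat=float(stat[i]),
            z=float(z[i]),
            q_hat=float(q_use[i]),
            n_families_contributing=int(n_contrib[i]),
            monomorphic=bool(unusable[i]),
            per_family_t=(
                {fid: float(per_family[fid][i]) for fid in per_family}
                if keep_family_terms
                else None
            ),
        )
        for i, vid in enumerate(genotypes.variant_ids)
    ]
    order = _ranking_order(results)
    for r, res_idx in enumerate(order):
        results[res_idx].rank = r + 1
    return results


def _ranking_order(results: Sequence[ScoreResult]) -> list[int]:
    return sorted(
        range(len(results)),
        key=lambda i: (-results[i].stat, -abs(results[i].T), results[i].variant_id),
    )


def prioritize(
    scores: Sequence[ScoreResult],
    top_n: int | None = None,
    top_fraction: float | None = None,
) -> list[str]:
    """The prioritized variant ids, best first.

    Exactly one of ``top_n``/``top_fraction`` may be given; the default is
    the study's top-100 rule.  ``top_fraction`` keeps
    ceil(fraction * n_variants) variants.
    """
    if not scores:
        raise ValueError("no scores to prioritize")
    if top_n is not None and top_fraction is not None:
        raise ValueError("give top_n or top_fraction, not both")
    if top_fraction is not None:
        n = int(np.ceil(top_fraction * len(scores)))
    else:
        n = 100 if top_n is None else top_n
    order = _ranking_order(scores)
    return [scores[i].variant_id for i in order[:n]]


def scores_to_frame(scores: Sequence[ScoreResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "variant_id": [s.variant_id for s in scores],
            "T": [s.T for s in scores],
            "var_T": [s.var_T for s in scores],
            "stat": [s.stat for s in scores],
            "z": [s.z for s in scores],
            "rank": [s.rank for s in scores],
            "q_hat": [s.q_hat for s in scores],
            "n_families_contributing": [s.n_families_contributing for s in scores],
            "monomorphic": [s.monomorphic for s in scores],
        }
    )
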