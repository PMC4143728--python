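"""Pedigree representation, PED parsing, and kinship-matrix computation.

The kinship coefficient phi(i, j) is the probability that an allele drawn
at random from individual i is identical by descent to an allele drawn at
random from j.  Founders are assumed non-inbred and mutually unrelated, so
phi(i, i) = 1/2 for a founder and phi = 0 between founders.  Within each
family the coefficients are assembled recursively in topological order
(parents before offspring), which is the standard tabular method:

    phi(i, i) = 1/2 * (1 + phi(father(i), mother(i)))
    phi(i, j) = 1/2 * (phi(father(i), j) + phi(mother(i), j))   for j != i

with phi of an absent parent taken as 0.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve


class PedigreeError(ValueError):
    """Base class for pedigree problems."""


class PedigreeFormatError(PedigreeError):
    """Malformed PED content (duplicates, single parents, bad references)."""


class PedigreeStructureError(PedigreeError):
    """Structurally invalid pedigree (cycles)."""


class KinshipSolveError(np.linalg.LinAlgError):
    """Kinship matrix numerically singular / not positive definite."""


_SEX_FROM_CODE = {"1": "male", "2": "female"}
_CODE_FROM_SEX = {"male": "1", "female": "2", "unknown": "0"}


@dataclass(frozen=True)
class Individual:
    """One pedigree member.  ``father_id``/``mother_id`` are ``None`` for
    founders; records with exactly one parent are rejected at pedigree
    construction."""

    individual_id: str
    family_id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: str = "unknown"

    @property
    def founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


class Pedigree:
    """A collection of families, each an ordered list of individuals.

    Members of every family are kept in a fixed, reproducible order:
    topological (parents strictly before offspring) with ties broken by
    individual id.  All kinship matrices and genotype drops use this order.
    """

    def __init__(
        self,
        individuals: Iterable[Individual],
        phenotype_table: pd.DataFrame | None = None,
    ) -> None:
        by_family: dict[str, dict[str, Individual]] = {}
        for ind in individuals:
            fam = by_family.setdefault(ind.family_id, {})
            if ind.individual_id in fam:
                raise PedigreeFormatError(
                    f"duplicate individual ({ind.family_id}, {ind.individual_id})"
                )
            if (ind.father_id is None) != (ind.mother_id is None):
                raise PedigreeFormatError(
                    f"individual {ind.individual_id} in family {ind.family_id} "
                    "lists exactly one parent; both or neither required"
                )
            fam[ind.individual_id] = ind

        self.families: dict[str, list[Individual]] = {}
        for fid in sorted(by_family):
            self.families[fid] = _topological_order(fid, by_family[fid])
        self.phenotype_table = phenotype_table

    # -- accessors ---------------------------------------------------------

    @property
    def family_ids(self) -> list[str]:
        return list(self.families)

    def members(self, family_id: str) -> list[Individual]:
        try:
            return self.families[family_id]
        except KeyError:
            raise KeyError(f"unknown family id {family_id!r}") from None

    def individuals(self) -> Iterable[Individual]:
        for fid in self.families:
            yield from self.families[fid]

    def get(self, family_id: str, individual_id: str) -> Individual:
        for ind in self.members(family_id):
            if ind.individual_id == individual_id:
                return ind
        raise KeyError(f"no individual {individual_id!r} in family {family_id!r}")

    def family_of(self, individual_id: str) -> str:
        for fid, members in self.families.items():
            for ind in members:
                if ind.individual_id == individual_id:
                    return fid
        raise KeyError(f"no individual {individual_id!r} in pedigree")

    @property
    def n_individuals(self) -> int:
        return sum(len(m) for m in self.families.values())

    def founders(self, family_id: str) -> list[Individual]:
        return [i for i in self.members(family_id) if i.founder]

    def nonfounders(self, family_id: str) -> list[Individual]:
        return [i for i in self.members(family_id) if not i.founder]

    def generation_depth(self, family_id: str) -> dict[str, int]:
        """0 for founders whose spouse is also a founder-couple root; in
        general, 1 + max(parental depths), with founders at depth 0."""
        depth: dict[str, int] = {}
        for ind in self.members(family_id):
            if ind.founder:
                depth[ind.individual_id] = 0
            else:
                depth[ind.individual_id] = 1 + max(
                    depth[ind.father_id], depth[ind.mother_id]
                )
        return depth


def _topological_order(
    family_id: str, members: Mapping[str, Individual]
) -> list[Individual]:
    """Kahn's algorithm with a min-heap on id: parents before offspring,
    ties lexicographic.  Raises on cycles and dangling parent references."""
    children: dict[str, list[str]] = {iid: [] for iid in members}
    indeg: dict[str, int] = {iid: 0 for iid in members}
    for ind in members.values():
        for pid in (ind.father_id, ind.mother_id):
            if pid is None:
                continue
            if pid not in members:
                raise PedigreeFormatError(
                    f"individual {ind.individual_id} in family {family_id} "
                    f"references unknown parent {pid!r}"
                )
            children[pid].append(ind.individual_id)
            indeg[ind.individual_id] += 1
    ready = [iid for iid, d in indeg.items() if d == 0]
    heapq.heapify(ready)
    order: list[Individual] = []
    while ready:
        iid = heapq.heappop(ready)
        order.append(members[iid])
        for cid in children[iid]:
            indeg[cid] -= 1
            if indeg[cid] == 0:
                heapq.heappush(ready, cid)
    if len(order) != len(members):
        raise PedigreeStructureError(f"family {family_id} contains a cycle")
    return order


# -- PED format ------------------------------------------------------------


def read_ped(path: str | Path) -> Pedigree:
    """Read a whitespace-delimited PED file.

    Expected columns: FID IID PAT MAT SEX [PHENO...]; ``0`` marks a missing
    parent.  Extra columns are preserved on ``pedigree.phenotype_table``.
    """
    individuals: list[Individual] = []
    extra_rows: list[list[str]] = []
    n_extra = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 5:
                raise PedigreeFormatError(
                    f"{path}:{lineno}: expected at least 5 columns, got {len(fields)}"
                )
            fid, iid, pat, mat, sex = fields[:5]
            individuals.append(
                Individual(
                    individual_id=iid,
                    family_id=fid,
                    father_id=None if pat == "0" else pat,
                    mother_id=None if mat == "0" else mat,
                    sex=_SEX_FROM_CODE.get(sex, "unknown"),
                )
            )
            if len(fields) > 5:
                n_extra = max(n_extra, len(fields) - 5)
                extra_rows.append([fid, iid, *fields[5:]])
    table = None
    if extra_rows:
        cols = ["family_id", "individual_id"] + [f"pheno_{i+1}" for i in range(n_extra)]
        table = pd.DataFrame(
            [row + [None] * (len(cols) - len(row)) for row in extra_rows],
            columns=cols,
        )
    return Pedigree(individuals, phenotype_table=table)


def write_ped(pedigree: Pedigree, path: str | Path) -> None:
    """Write FID IID PAT MAT SEX, tab-delimited, in the pedigree's fixed order."""
    with open(path, "w") as fh:
        for ind in pedigree.individuals():
            fh.write(
                "\t".join(
                    [
                        ind.family_id,
                        ind.individual_id,
                        ind.father_id or "0",
                        ind.mother_id or "0",
                        _CODE_FROM_SEX[ind.sex],
                    ]
                )
                + "\n"
            )


# -- kinship ---------------------------------------------------------------


@dataclass
class KinshipMatrix:
    """Symmetric matrix of kinship coefficients for one family, with the
    individual ordering it was built on."""

    family_id: str
    ids: tuple[str, ...]
    phi: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        self._index = {iid: k for k, iid in enumerate(self.ids)}

    def index(self, individual_id: str) -> int:
        return self._index[individual_id]

    @property
    def n(self) -> int:
        return len(self.ids)

    def scaled(self, factor: float) -> "KinshipMatrix":
        """Same relationships, globally rescaled (e.g. 2*phi gives the
        additive relationship matrix)."""
        return KinshipMatrix(self.family_id, self.ids, factor * self.phi)


def kinship(pedigree: Pedigree, family_id: str) -> KinshipMatrix:
    """Exact kinship matrix for one family by the recursive tabular method."""
    members = pedigree.members(family_id)
    ids = tuple(ind.individual_id for ind in members)
    idx = {iid: k for k, iid in enumerate(ids)}
    n = len(ids)
    phi = np.zeros((n, n))
    for i, ind in enumerate(members):
        if ind.founder:
            phi[i, i] = 0.5
            continue
        fa, mo = idx[ind.father_id], idx[ind.mother_id]
        phi[i, i] = 0.5 * (1.0 + phi[fa, mo])
        for j in range(i):
            phi[i, j] = phi[j, i] = 0.5 * (phi[fa, j] + phi[mo, j])
    return KinshipMatrix(family_id, ids, phi)


def solve_kinship(kin: KinshipMatrix, rhs: np.ndarray) -> np.ndarray:
    """Solve phi @ x = rhs via a symmetric positive-definite (Cholesky)
    factorization; never forms an explicit inverse."""
    rhs = np.asarray(rhs, dtype=float)
    if rhs.shape[0] != kin.n:
        raise ValueError(
            f"rhs length {rhs.shape[0]} != kinship dimension {kin.n} "
            f"(family {kin.family_id})"
        )
    try:
        factor = cho_factor(kin.phi, lower=True)
    except np.linalg.LinAlgError as exc:
        raise KinshipSolveError(
            f"kinship matrix for family {kin.family_id} is not positive "
            f"definite: {exc}"
        ) from exc
    # outbred pedigrees keep Cholesky pivots >= ~0.5 (Mendelian segregation
    # residual); a tiny pivot means a numerically singular matrix that
    # LAPACK let through on a zero leading minor
    pivots = np.abs(np.diag(factor[0]))
    if pivots.min() <= 1e-6 * max(1.0, pivots.max()):
        raise KinshipSolveError(
            f"kinship matrix for family {kin.family_id} is numerically singular"
        )
    return cho_solve(factor, rhs)


def write_kinship_tsv(
    kinships: Sequence[KinshipMatrix] | Mapping[str, KinshipMatrix],
    path: str | Path,
) -> None:
    """Long-format export: family_id, id1, id2, phi (upper triangle incl. diagonal)."""
    if isinstance(kinships, Mapping):
        kinships = [kinships[k] for k in kinships]
    with open(path, "w") as fh:
        fh.write("family_id\tid1\tid2\tphi\n")
        for kin in kinships:
            for i in range(kin.n):
                for j in range(i, kin.n):
                    fh.write(
                        f"{kin.family_id}\t{kin.ids[i]}\t{kin.ids[j]}\t"
                        f"{kin.phi[i, j]:.10g}\n"
                    )
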