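"""Synthetic cohort generation: pedigrees, gene-dropped genotypes, and
longitudinal quantitative phenotypes.

The generator emulates the structure of an extended-pedigree blood-pressure
cohort: multi-generation families; rare and common variants transmitted by
Mendelian gene dropping from founder allele frequencies (Hardy-Weinberg in
founders, no linkage disequilibrium between variants); a quantitative trait
with a family random intercept, individual random intercept and age slope,
additive per-variant genetic effects, and visit-level noise; age and sex as
fixed covariates; and an antihypertensive-style treatment that is switched
on once the underlying untreated trait crosses a threshold and then lowers
the observed value — making treatment both a confounder and an intermediate
on the genotype-phenotype pathway.

Randomness is organised as one master seed split into independent
substreams (pedigree / genotype / phenotype) via ``numpy``'s
``SeedSequence.spawn``, so regenerating one stage leaves the others fixed.
All draws use ``numpy.random.Generator`` (PCG64).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .pedigree import Individual, Pedigree

MISSING = -1  # genotype missing / unsequenced marker


# -- variant specifications ------------------------------------------------


@dataclass(frozen=True)
class VariantSpec:
    """A simulated variant: founder minor-allele frequency and additive
    phenotypic effect per minor allele (0 for non-causal variants)."""

    variant_id: str
    founder_maf: float
    causal: bool = False
    beta: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.founder_maf <= 0.5):
            raise ValueError(
                f"founder_maf must be in (0, 0.5], got {self.founder_maf} "
                f"for {self.variant_id}"
            )
        if not self.causal and self.beta != 0.0:
            raise ValueError(f"non-causal variant {self.variant_id} has beta != 0")

    def variance_explained(self, total_variance: float) -> float:
        """Share of phenotypic variance, beta^2 * 2q(1-q) / total."""
        q = self.founder_maf
        return self.beta**2 * 2.0 * q * (1.0 - q) / total_variance


# -- pedigree simulation ---------------------------------------------------


def poisson_plus_one(lam: float) -> Callable[[np.random.Generator], int]:
    """Sibship-size sampler: 1 + Poisson(lam)."""

    def draw(rng: np.random.Generator) -> int:
        return 1 + int(rng.poisson(lam))

    return draw


def make_pedigrees(
    n_families: int,
    generations: int,
    sibship_size: int | Callable[[np.random.Generator], int] = 2,
    seed: int = 0,
    marriage_prob: float = 0.6,
) -> Pedigree:
    """Simulate ``n_families`` independent extended families.

    Each family starts from a founder couple; every child in a
    non-terminal generation marries an unrelated founder spouse with
    probability ``marriage_prob`` (always, in a two-member sibship family
    with no other couple, at least one child marries so the requested
    generation count is realised) and produces a sibship of the configured
    size.  ``sibship_size`` is either a constant or a callable drawing from
    a distribution, e.g. :func:`poisson_plus_one`.
    """
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    if generations not in (2, 3, 4):
        raise ValueError("generations must be 2, 3, or 4")
    if callable(sibship_size):
        draw_sibs = sibship_size
    else:
        draw_sibs = lambda rng, k=int(sibship_size): k  # noqa: E731
    rng = np.random.default_rng(seed)
    individuals: list[Individual] = []
    for f in range(1, n_families + 1):
        fid = f"F{f:04d}"
        counter = 0

        def new_id() -> str:
            nonlocal counter
            counter += 1
            return f"{fid}_{counter:03d}"

        father, mother = new_id(), new_id()
        individuals.append(Individual(father, fid, sex="male"))
        individuals.append(Individual(mother, fid, sex="female"))
        couples = [(father, mother)]
        for gen in range(2, generations + 1):
            next_couples: list[tuple[str, str]] = []
            for fa, mo in couples:
                n_kids = max(1, draw_sibs(rng))
                kids: list[tuple[str, str]] = []
                for _ in range(n_kids):
                    kid = new_id()
                    sex = "male" if rng.random() < 0.5 else "female"
                    individuals.append(Individual(kid, fid, fa, mo, sex))
                    kids.append((kid, sex))
                if gen < generations:
                    marrying = [k for k in kids if rng.random() < marriage_prob]
                    if not marrying and not next_couples:
                        marrying = [kids[0]]
                    for kid, sex in marrying:
                        spouse = new_id()
                        spouse_sex = "female" if sex == "male" else "male"
                        individuals.append(Individual(spouse, fid, sex=spouse_sex))
                        if sex == "male":
                            next_couples.append((kid, spouse))
                        else:
                            next_couples.append((spouse, kid))
            couples = next_couples
    return Pedigree(individuals)


def make_unrelated_cohort(n: int, prefix: str = "U") -> Pedigree:
    """A cohort of ``n`` mutually unrelated individuals, each its own
    single-member family (used for the stage-2 replication sample)."""
    individuals = [
        Individual(f"{prefix}{i:05d}", f"{prefix}F{i:05d}", sex="unknown")
        for i in range(1, n + 1)
    ]
    return Pedigree(individuals)


# -- genotypes -------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Variants x individuals minor-allele counts in {0, 1, 2}, with
    ``MISSING`` (-1) marking unsequenced cells.  When produced by
    :func:`gene_drop`, the parental-origin gametes of every nonfounder are
    recorded in ``paternal``/``maternal`` (-1 for founders), which QTDT and
    transmission checks rely on."""

    variant_ids: tuple[str, ...]
    individual_ids: tuple[str, ...]
    counts: np.ndarray  # (n_variants, n_individuals), int8
    paternal: np.ndarray | None = None  # transmitted allele from father
    maternal: np.ndarray | None = None
    _col: dict[str, int] = field(init=False, repr=False)
    _row: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int8)
        self._col = {iid: j for j, iid in enumerate(self.individual_ids)}
        self._row = {vid: i for i, vid in enumerate(self.variant_ids)}
        valid = (self.counts >= 0) & (self.counts <= 2)
        if not (valid | (self.counts == MISSING)).all():
            raise ValueError("genotype counts must be in {0,1,2} or MISSING")

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    def col(self, individual_id: str) -> int:
        return self._col[individual_id]

    def row(self, variant_id: str) -> int:
        return self._row[variant_id]

    def genotype(self, variant_id: str, individual_id: str) -> int:
        return int(self.counts[self.row(variant_id), self.col(individual_id)])

    def mask_to_subset(self, keep_ids: Sequence[str]) -> "GenotypeMatrix":
        """Copy with every individual outside ``keep_ids`` set to MISSING
        (emulating that only the subset was sequenced)."""
        keep = {self._col[i] for i in keep_ids}
        counts = self.counts.copy()
        drop = [j for j in range(self.n_individuals) if j not in keep]
        counts[:, drop] = MISSING
        return GenotypeMatrix(
            self.variant_ids, self.individual_ids, counts, self.paternal, self.maternal
        )


def gene_drop(
    pedigree: Pedigree, variants: Sequence[VariantSpec], seed: int = 0
) -> GenotypeMatrix:
    """Drop alleles through the pedigree independently per variant.

    Founders receive two i.i.d. Bernoulli(q) alleles (Hardy-Weinberg);
    every nonfounder inherits one uniformly chosen allele from each parent,
    independently across variants.  Transmitted parental-origin alleles are
    recorded for nonfounders.
    """
    rng = np.random.default_rng(seed)
    q = np.array([v.founder_maf for v in variants])
    nv = len(variants)
    all_ids = tuple(ind.individual_id for ind in pedigree.individuals())
    col = {iid: j for j, iid in enumerate(all_ids)}
    n = len(all_ids)
    # allele pairs per individual, uint8, indexed [variant, individual]
    a1 = np.zeros((nv, n), dtype=np.int8)  # from father (or founder allele 1)
    a2 = np.zeros((nv, n), dtype=np.int8)
    pat = np.full((nv, n), MISSING, dtype=np.int8)
    mat = np.full((nv, n), MISSING, dtype=np.int8)
    for fid in pedigree.family_ids:
        for ind in pedigree.members(fid):
            j = col[ind.individual_id]
            if ind.founder:
                a1[:, j] = rng.random(nv) < q
                a2[:, j] = rng.random(nv) < q
            else:
                jf, jm = col[ind.father_id], col[ind.mother_id]
                pick_f = rng.integers(0, 2, size=nv)
                pick_m = rng.integers(0, 2, size=nv)
                a1[:, j] = np.where(pick_f == 0, a1[:, jf], a2[:, jf])
                a2[:, j] = np.where(pick_m == 0, a1[:, jm], a2[:, jm])
                pat[:, j] = a1[:, j]
                mat[:, j] = a2[:, j]
    counts = (a1 + a2).astype(np.int8)
    return GenotypeMatrix(
        tuple(v.variant_id for v in variants), all_ids, counts, pat, mat
    )


# -- phenotypes ------------------------------------------------------------


@dataclass
class PhenoModelConfig:
    """Parameters of the longitudinal trait model (systolic-blood-pressure
    scale by default, mmHg and years).

    value = grand_mean + beta_age*age + beta_male*I(male) + sum_v beta_v*G_v
            + b_family + u0_individual + u1_individual*age + eps_visit,
    observed value reduced by ``treatment_effect`` from the first visit at
    which the underlying untreated value exceeds ``treatment_threshold``
    (treatment persists once started).
    """

    grand_mean: float = 118.0
    beta_age: float = 0.45  # mmHg per year
    beta_male: float = 4.0
    family_sd: float = 4.5
    ind_intercept_sd: float = 6.0
    ind_slope_sd: float = 0.12  # mmHg per year
    resid_sd: float = 5.5
    n_visits: int = 3
    visit_spacing: float = 5.0  # years
    treatment_threshold: float = 165.0
    treatment_effect: float = 8.0
    age_base: float = 68.0  # mean age of top-generation founders at visit 1
    age_step: float = 26.0  # mean parent-offspring age gap
    age_jitter: float = 4.0

    def environmental_variance(self) -> float:
        """Non-genetic, non-age variance reference used to size variant
        effects (family + individual intercept + visit noise; the small
        random-slope contribution is ignored)."""
        return self.family_sd**2 + self.ind_intercept_sd**2 + self.resid_sd**2


def betas_for_variance_shares(
    shares: Sequence[float], mafs: Sequence[float], config: PhenoModelConfig
) -> np.ndarray:
    """Effect sizes such that variant i explains ``shares[i]`` of the total
    phenotypic variance (environmental + all genetic), solving the joint
    constraint beta_i^2 * 2 q_i (1-q_i) = share_i * V_total with
    V_total = V_env / (1 - sum(shares))."""
    shares = np.asarray(shares, dtype=float)
    mafs = np.asarray(mafs, dtype=float)
    if shares.sum() >= 1.0:
        raise ValueError("variance shares must sum to < 1")
    v_total = config.environmental_variance() / (1.0 - shares.sum())
    return np.sqrt(shares * v_total / (2.0 * mafs * (1.0 - mafs)))


@dataclass(frozen=True)
class PhenotypeRecord:
    """One longitudinal observation."""

    individual_id: str
    visit_index: int  # 1-based
    age: float
    sex: str
    treated: bool
    value: float


def records_to_frame(records: Sequence[PhenotypeRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "individual_id": [r.individual_id for r in records],
            "visit_index": [r.visit_index for r in records],
            "age": [r.age for r in records],
            "sex": [r.sex for r in records],
            "treated": [r.treated for r in records],
            "value": [r.value for r in records],
        }
    )


def simulate_phenotypes(
    pedigree: Pedigree,
    genotypes: GenotypeMatrix,
    variants: Sequence[VariantSpec],
    model: PhenoModelConfig | None = None,
    seed: int = 0,
) -> list[PhenotypeRecord]:
    """Simulate the longitudinal trait for every pedigree member.

    Ages at first visit decrease with generation depth (children younger
    than parents); visits are equally spaced.  Treatment is assigned from
    the underlying untreated trajectory, then subtracted from the observed
    values.
    """
    cfg = model or PhenoModelConfig()
    rng = np.random.default_rng(seed)
    betas = np.array([v.beta for v in variants])
    causal_rows = np.nonzero(betas != 0.0)[0]
    records: list[PhenotypeRecord] = []
    visit_offsets = np.arange(cfg.n_visits) * cfg.visit_spacing
    for fid in pedigree.family_ids:
        b_fam = rng.normal(0.0, cfg.family_sd)
        depth = pedigree.generation_depth(fid)
        for ind in pedigree.members(fid):
            j = genotypes.col(ind.individual_id)
            g = genotypes.counts[causal_rows, j].astype(float)
            if (g < 0).any():  # simulation always produces complete genotypes
                raise ValueError("cannot simulate phenotypes from missing genotypes")
            genetic = float(betas[causal_rows] @ g)
            u0 = rng.normal(0.0, cfg.ind_intercept_sd)
            u1 = rng.normal(0.0, cfg.ind_slope_sd) if cfg.ind_slope_sd > 0 else 0.0
            age0 = max(
                18.0,
                cfg.age_base
                - depth[ind.individual_id] * cfg.age_step
                + rng.uniform(-cfg.age_jitter, cfg.age_jitter),
            )
            ages = age0 + visit_offsets
            eps = rng.normal(0.0, cfg.resid_sd, size=cfg.n_visits)
            untreated = (
                cfg.grand_mean
                + cfg.beta_age * ages
                + (cfg.beta_male if ind.sex == "male" else 0.0)
                + genetic
                + b_fam
                + u0
                + u1 * ages
                + eps
            )
            treated = np.maximum.accumulate(untreated > cfg.treatment_threshold)
            observed = untreated - cfg.treatment_effect * treated
            for k in range(cfg.n_visits):
                records.append(
                    PhenotypeRecord(
                        individual_id=ind.individual_id,
                        visit_index=k + 1,
                        age=float(ages[k]),
                        sex=ind.sex,
                        treated=bool(treated[k]),
                        value=float(observed[k]),
                    )
                )
    return records


# -- default variant panel -------------------------------------------------


def default_variant_panel(
    n_causal: int = 15,
    n_null: int = 985,
    max_share: float = 0.028,
    min_share: float = 0.0005,
    config: PhenoModelConfig | None = None,
    seed: int = 12345,
) -> list[VariantSpec]:
    """The default study panel: ``n_causal`` causal variants with variance
    shares log-spaced from ``max_share`` down to ``min_share`` (signs
    alternating - / +, so both protective and deleterious effects occur)
    plus ``n_null`` null variants.  Minor allele frequencies are drawn
    log-uniformly (causal: 0.01-0.25, null: 0.005-0.5) from a dedicated
    stream so the panel is reproducible."""
    cfg = config or PhenoModelConfig()
    rng = np.random.default_rng(seed)
    shares = np.geomspace(max_share, min_share, n_causal)
    causal_mafs = np.exp(rng.uniform(np.log(0.01), np.log(0.25), size=n_causal))
    betas = betas_for_variance_shares(shares, causal_mafs, cfg)
    signs = np.where(np.arange(n_causal) % 2 == 0, -1.0, 1.0)
    variants = [
        VariantSpec(
            variant_id=f"causal{(i + 1):02d}",
            founder_maf=float(causal_mafs[i]),
            causal=True,
            beta=float(signs[i] * betas[i]),
        )
        for i in range(n_causal)
    ]
    null_mafs = np.exp(rng.uniform(np.log(0.005), np.log(0.5), size=n_null))
    variants += [
        VariantSpec(variant_id=f"null{(i + 1):04d}", founder_maf=float(null_mafs[i]))
        for i in range(n_null)
    ]
    return variants


def split_seed(master_seed: int, n: int) -> list[int]:
    """Derive ``n`` independent 31-bit substream seeds from a master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


# -- writers ---------------------------------------------------------------


def write_vcf(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Minimal VCF 4.2 with GT-only genotype fields; missing cells as ./.
    Variants are placed on a dummy chromosome at consecutive positions."""
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=1>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.individual_ids)
            + "\n"
        )
        for i, vid in enumerate(genotypes.variant_ids):
            row = genotypes.counts[i]
            fh.write(
                f"1\t{i + 1}\t{vid}\tA\tB\t.\t.\t.\tGT\t"
                + "\t".join(gt_map[int(c)] for c in row)
                + "\n"
            )


def write_phenotypes_tsv(records: Sequence[PhenotypeRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False)


def write_truth_json(
    variants: Sequence[VariantSpec], config: PhenoModelConfig, path: str | Path
) -> None:
    """Simulation truth: per-variant causal flag, beta, founder MAF and the
    implied variance share, plus the phenotype model parameters."""
    v_env = config.environmental_variance()
    genetic = sum(
        v.beta**2 * 2 * v.founder_maf * (1 - v.founder_maf) for v in variants
    )
    v_total = v_env + genetic
    payload = {
        "phenotype_model": asdict(config),
        "total_variance": v_total,
        "variants": [
            {
                "variant_id": v.variant_id,
                "founder_maf": v.founder_maf,
                "causal": v.causal,
                "beta": v.beta,
                "pct_variance": v.variance_explained(v_total),
            }
            for v in variants
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_truth_json(path: str | Path) -> tuple[list[VariantSpec], PhenoModelConfig]:
    with open(path) as fh:
        payload = json.load(fh)
    cfg = PhenoModelConfig(**payload["phenotype_model"])
    variants = [
        VariantSpec(
            variant_id=v["variant_id"],
            founder_maf=v["founder_maf"],
            causal=v["causal"],
            beta=v["beta"],
        )
        for v in payload["variants"]
    ]
    return variants, cfg
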