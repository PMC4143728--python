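"""Shared fixtures: canonical small pedigrees, an independent Monte-Carlo
gene-drop IBD oracle for kinship, and a reusable simulated cohort."""

from __future__ import annotations

import numpy as np
import pytest

from famseq2 import (
    Individual,
    Pedigree,
    default_variant_panel,
    derive_phenotypes,
    gene_drop,
    kinship,
    make_pedigrees,
    phenotype_vector,
    simulate_phenotypes,
)
from famseq2.simulate import PhenoModelConfig


def ind(iid, fid, fa=None, mo=None, sex="unknown"):
    return Individual(iid, fid, fa, mo, sex)


@pytest.fixture(scope="session")
def trio():
    """dad, mom, one child."""
    return Pedigree(
        [
            ind("dad", "F1", sex="male"),
            ind("mom", "F1", sex="female"),
            ind("kid", "F1", "dad", "mom"),
        ]
    )


@pytest.fixture(scope="session")
def sib_pedigree():
    """Two full sibs."""
    return Pedigree(
        [
            ind("dad", "F1", sex="male"),
            ind("mom", "F1", sex="female"),
            ind("s1", "F1", "dad", "mom"),
            ind("s2", "F1", "dad", "mom"),
        ]
    )


@pytest.fixture(scope="session")
def half_sib_pedigree():
    """One father, two mothers, one child by each."""
    return Pedigree(
        [
            ind("dad", "F1", sex="male"),
            ind("mom1", "F1", sex="female"),
            ind("mom2", "F1", sex="female"),
            ind("h1", "F1", "dad", "mom1"),
            ind("h2", "F1", "dad", "mom2"),
        ]
    )


@pytest.fixture(scope="session")
def three_gen_pedigree():
    """Grandparents, two children (one married-in spouse), one grandchild."""
    return Pedigree(
        [
            ind("gpa", "F1", sex="male"),
            ind("gma", "F1", sex="female"),
            ind("p1", "F1", "gpa", "gma", "female"),
            ind("p2", "F1", "gpa", "gma", "male"),
            ind("sp1", "F1", sex="male"),
            ind("gc", "F1", "sp1", "p1"),
        ]
    )


@pytest.fixture(scope="session")
def cousin_pedigree():
    """Two sibs each with a married-in spouse and one child: first cousins."""
    return Pedigree(
        [
            ind("gpa", "F1", sex="male"),
            ind("gma", "F1", sex="female"),
            ind("a1", "F1", "gpa", "gma", "male"),
            ind("a2", "F1", "gpa", "gma", "female"),
            ind("w1", "F1", sex="female"),
            ind("h2", "F1", sex="male"),
            ind("c1", "F1", "a1", "w1"),
            ind("c2", "F1", "h2", "a2"),
        ]
    )


def mc_ibd_kinship(pedigree, family_id, id1, id2, n_drops=100_000, seed=0):
    """Monte-Carlo gene-drop estimate of the kinship coefficient and its
    standard error: drop uniquely labelled founder alleles through the
    pedigree, then compute the probability that an allele drawn at random
    from each individual is identical by descent.

    Written independently of famseq2's kinship recursion and of
    famseq2.simulate.gene_drop (its own transmission code) so it can serve
    as an oracle for both.
    """
    rng = np.random.default_rng(seed)
    members = pedigree.members(family_id)
    idx = {m.individual_id: j for j, m in enumerate(members)}
    n = len(members)
    a = np.zeros((2, n_drops, n), dtype=np.int32)
    label = 0
    for m in members:
        j = idx[m.individual_id]
        if m.founder:
            a[0, :, j] = label
            a[1, :, j] = label + 1
            label += 2
        else:
            jf, jm = idx[m.father_id], idx[m.mother_id]
            pf = rng.integers(0, 2, size=n_drops)
            pm = rng.integers(0, 2, size=n_drops)
            a[0, :, j] = np.where(pf == 0, a[0, :, jf], a[1, :, jf])
            a[1, :, j] = np.where(pm == 0, a[0, :, jm], a[1, :, jm])
    j1, j2 = idx[id1], idx[id2]
    # exact per-drop probability that random picks are IBD
    match = np.zeros(n_drops)
    for s in range(2):
        for t in range(2):
            match += a[s, :, j1] == a[t, :, j2]
    p = match / 4.0
    return p.mean(), p.std(ddof=1) / np.sqrt(n_drops)


@pytest.fixture(scope="session")
def small_cohort():
    """A reusable simulated cohort: 40 three-generation families, 5 causal
    + 60 null variants, derived intercept phenotypes, kinship matrices."""
    cfg = PhenoModelConfig()
    variants = default_variant_panel(n_causal=5, n_null=60, config=cfg, seed=99)
    ped = make_pedigrees(40, 3, 2, seed=11)
    geno = gene_drop(ped, variants, seed=12)
    records = simulate_phenotypes(ped, geno, variants, cfg, seed=13)
    derived = derive_phenotypes(records, ped)
    phen = phenotype_vector(derived, "intercept")
    kins = {fid: kinship(ped, fid) for fid in ped.family_ids}
    return {
        "config": cfg,
        "variants": variants,
        "pedigree": ped,
        "genotypes": geno,
        "records": records,
        "derived": derived,
        "phenotypes": phen,
        "kinships": kins,
    }
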