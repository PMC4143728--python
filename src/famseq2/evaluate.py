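"""End-to-end design comparison: replicate simulations, random sequencing
subsets, threshold sweeps, and the aggregation of prioritization /
significance frequencies into a report.

Definitions used throughout:

* power — the proportion of (replicate x subset) runs in which a causal
  variant is declared significant (averaged over the causal variants of a
  class when reported per class);
* empirical FDR — null significants / max(1, total significants), counted
  over all runs of a cell;
* mean score — the signed standardized score z = T / sqrt(var(T)),
  averaged per truth class (negative-effect, null, positive-effect).

All randomness derives from one master seed via ``SeedSequence`` spawning,
so a report is byte-for-byte reproducible.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .association import one_stage_analysis, stage2_test
from .pedigree import KinshipMatrix, Pedigree, kinship
from .phenotypes import derive_phenotypes, phenotype_vector
from .prioritize import (
    SequencedSubset,
    prioritize,
    sample_members,
    score_test,
)
from .simulate import (
    PhenoModelConfig,
    VariantSpec,
    default_variant_panel,
    gene_drop,
    make_pedigrees,
    make_unrelated_cohort,
    poisson_plus_one,
    simulate_phenotypes,
)

logger = logging.getLogger(__name__)

CLASSES = ("negative", "null", "positive")


def variant_class(v: VariantSpec) -> str:
    if not v.causal:
        return "null"
    return "negative" if v.beta < 0 else "positive"


@dataclass
class StudyConfig:
    """All knobs of the simulated two-stage study.

    The defaults are the package's standard desk-scale fixture: 200
    three-generation families, a panel of 15 causal variants (variance
    shares log-spaced 2.8% to 0.05%) plus 985 null variants, a replication
    cohort of 157 unrelated individuals, 5 phenotype replicates each
    analysed with 20 random sequencing subsets, subset sizes k in
    {2, 4, 6}, and a top-100 prioritization rule.
    """

    n_families: int = 200
    generations: int = 3
    sibship_mean: float = 2.0  # sibship ~ 1 + Poisson(mean - 1)
    n_causal: int = 15
    n_null: int = 985
    max_share: float = 0.028
    min_share: float = 0.0005
    n_unrelated: int = 157
    n_replicates: int = 5
    n_subsets: int = 20
    k_list: tuple[int, ...] = (2, 4, 6)
    top_n: int = 100
    thresholds: tuple[float, ...] = ()  # top fractions; empty = use top_n
    steepness: float = 8.0
    phenotype_kind: str = "intercept"
    alpha: float = 0.05
    panel_seed: int = 12345
    pheno: PhenoModelConfig = field(default_factory=PhenoModelConfig)

    def sibship(self):
        if self.sibship_mean <= 1.0:
            return 1
        return poisson_plus_one(self.sibship_mean - 1.0)


@dataclass
class DesignCell:
    """Aggregated results for one (design, phenotype kind, k, rule) cell."""

    design: str  # "one_stage" | "two_stage"
    phenotype_kind: str
    k: int | None  # members sequenced per family (None = all)
    rule: str  # "top100", "frac0.02", or "all"
    n_runs: int
    mean_score: dict[str, float]
    prop_prioritized: dict[str, float]
    prop_significant: dict[str, float]
    per_variant_prioritized: dict[str, float]
    per_variant_significant: dict[str, float]
    fdr: float
    n_significant_total: int
    n_significant_null: int
    # causal-significance events and run counts per phenotype replicate,
    # for paired across-threshold comparisons (stage-2 hits are clustered
    # by replicate because the replication cohort is shared by its runs)
    causal_sig_by_replicate: list[int] = field(default_factory=list)
    runs_by_replicate: list[int] = field(default_factory=list)


@dataclass
class DesignReport:
    master_seed: int
    config: dict
    cells: list[DesignCell]

    def to_json(self, indent: int = 1) -> str:
        return json.dumps(
            {
                "master_seed": self.master_seed,
                "config": self.config,
                "cells": [asdict(c) for c in self.cells],
            },
            indent=indent,
            sort_keys=True,
        )

    def cell(self, design: str, k: int | None = None, rule: str | None = None
             ) -> DesignCell:
        for c in self.cells:
            if c.design == design and (k is None or c.k == k) and (
                rule is None or c.rule == rule
            ):
                return c
        raise KeyError(f"no cell ({design}, k={k}, rule={rule})")

    def summary_table(self) -> pd.DataFrame:
        """Per-cell class summary: mean score and proportions prioritized /
        significant for the negative, null and positive variant classes."""
        rows = []
        for c in self.cells:
            row = {
                "design": c.design,
                "kind": c.phenotype_kind,
                "k": c.k,
                "rule": c.rule,
                "fdr": c.fdr,
            }
            for cls in CLASSES:
                row[f"mean_score_{cls}"] = c.mean_score.get(cls, float("nan"))
                row[f"prioritized_{cls}"] = c.prop_prioritized.get(cls, float("nan"))
                row[f"significant_{cls}"] = c.prop_significant.get(cls, float("nan"))
            rows.append(row)
        return pd.DataFrame(rows)

    def per_variant_table(self) -> pd.DataFrame:
        """Per causal variant frequencies of prioritization / significance
        per cell (the per-variant design-comparison layout)."""
        rows = []
        for c in self.cells:
            for vid, freq in c.per_variant_prioritized.items():
                rows.append(
                    {
                        "design": c.design,
                        "k": c.k,
                        "rule": c.rule,
                        "variant_id": vid,
                        "prioritized": freq,
                        "significant": c.per_variant_significant.get(vid, 0.0),
                    }
                )
        return pd.DataFrame(rows)


# -- replicate simulation ---------------------------------------------------


@dataclass
class ReplicateData:
    pedigree: Pedigree
    kinships: dict[str, KinshipMatrix]
    genotypes: "object"
    phenotypes: dict[str, float]
    unrelated_genotypes: "object"
    unrelated_phenotypes: dict[str, float]
    variants: list[VariantSpec]


def simulate_replicate(
    config: StudyConfig, variants: list[VariantSpec], seed_seq: np.random.SeedSequence
) -> ReplicateData:
    """One phenotype replicate: family cohort + unrelated replication cohort."""
    s_ped, s_geno, s_pheno, s_ugeno, s_upheno = (
        int(s.generate_state(1)[0] % (2**31)) for s in seed_seq.spawn(5)
    )
    ped = make_pedigrees(
        config.n_families, config.generations, config.sibship(), seed=s_ped
    )
    geno = gene_drop(ped, variants, seed=s_geno)
    records = simulate_phenotypes(ped, geno, variants, config.pheno, seed=s_pheno)
    derived = derive_phenotypes(records, ped)
    phen = phenotype_vector(derived, config.phenotype_kind)
    kinships = {fid: kinship(ped, fid) for fid in ped.family_ids}

    uped = make_unrelated_cohort(config.n_unrelated)
    ugeno = gene_drop(uped, variants, seed=s_ugeno)
    urecords = simulate_phenotypes(uped, ugeno, variants, config.pheno, seed=s_upheno)
    uderived = derive_phenotypes(urecords, uped)
    uphen = phenotype_vector(uderived, config.phenotype_kind)
    return ReplicateData(ped, kinships, geno, phen, ugeno, uphen, variants)


# -- aggregation helpers ----------------------------------------------------


class _CellAccumulator:
    def __init__(self, variants: Sequence[VariantSpec]):
        self.cls_of = {v.variant_id: variant_class(v) for v in variants}
        self.causal_ids = [v.variant_id for v in variants if v.causal]
        self.n_runs = 0
        self.z_sums: dict[str, float] = {c: 0.0 for c in CLASSES}
        self.z_counts: dict[str, int] = {c: 0 for c in CLASSES}
        self.prio_counts: dict[str, int] = {c: 0 for c in CLASSES}
        self.sig_counts: dict[str, int] = {c: 0 for c in CLASSES}
        self.n_by_class = {
            c: sum(1 for v in variants if variant_class(v) == c) for c in CLASSES
        }
        self.pv_prio: dict[str, int] = {vid: 0 for vid in self.causal_ids}
        self.pv_sig: dict[str, int] = {vid: 0 for vid in self.causal_ids}
        self.n_sig_total = 0
        self.n_sig_null = 0
        self.causal_sig_by_rep: dict[int, int] = {}
        self.runs_by_rep: dict[int, int] = {}

    def add_run(
        self,
        z_by_variant: Mapping[str, float] | None,
        prioritized: Sequence[str] | None,
        significant: Sequence[str],
        replicate: int = 0,
    ) -> None:
        self.n_runs += 1
        self.runs_by_rep[replicate] = self.runs_by_rep.get(replicate, 0) + 1
        self.causal_sig_by_rep.setdefault(replicate, 0)
        if z_by_variant is not None:
            for vid, z in z_by_variant.items():
                c = self.cls_of[vid]
                self.z_sums[c] += z
                self.z_counts[c] += 1
        if prioritized is not None:
            for vid in prioritized:
                self.prio_counts[self.cls_of[vid]] += 1
                if vid in self.pv_prio:
                    self.pv_prio[vid] += 1
        for vid in significant:
            c = self.cls_of[vid]
            self.sig_counts[c] += 1
            if vid in self.pv_sig:
                self.pv_sig[vid] += 1
                self.causal_sig_by_rep[replicate] += 1
            self.n_sig_total += 1
            if c == "null":
                self.n_sig_null += 1

    def finish(
        self, design: str, kind: str, k: int | None, rule: str
    ) -> DesignCell:
        n = max(self.n_runs, 1)
        return DesignCell(
            design=design,
            phenotype_kind=kind,
            k=k,
            rule=rule,
            n_runs=self.n_runs,
            mean_score={
                c: (self.z_sums[c] / self.z_counts[c]) if self.z_counts[c] else 0.0
                for c in CLASSES
            },
            prop_prioritized={
                c: self.prio_counts[c] / (n * self.n_by_class[c])
                if self.n_by_class[c]
                else 0.0
                for c in CLASSES
            },
            prop_significant={
                c: self.sig_counts[c] / (n * self.n_by_class[c])
                if self.n_by_class[c]
                else 0.0
                for c in CLASSES
            },
            per_variant_prioritized={
                vid: self.pv_prio[vid] / n for vid in self.pv_prio
            },
            per_variant_significant={vid: self.pv_sig[vid] / n for vid in self.pv_sig},
            fdr=self.n_sig_null / max(1, self.n_sig_total),
            n_significant_total=self.n_sig_total,
            n_significant_null=self.n_sig_null,
            causal_sig_by_replicate=[
                self.causal_sig_by_rep[r] for r in sorted(self.causal_sig_by_rep)
            ],
            runs_by_replicate=[
                self.runs_by_rep[r] for r in sorted(self.runs_by_rep)
            ],
        )


def _rule_label(top_n: int | None, fraction: float | None) -> str:
    return f"top{top_n}" if fraction is None else f"frac{fraction:g}"


# -- design runners ---------------------------------------------------------


def run_two_stage(
    config: StudyConfig,
    seed: int,
    variants: list[VariantSpec] | None = None,
    thresholds: Sequence[float] | None = None,
) -> DesignReport:
    """The two-stage design over replicates x random subsets x k values.

    Per run: sample k members per family by extreme-phenotype weighting,
    estimate subset MAFs, compute the score test from the subset's
    sequence plus all phenotypes, prioritize (top-n rule, or each top
    fraction in ``thresholds``), then test prioritized variants in the
    unrelated cohort with Bonferroni over the prioritized set.
    """
    t0 = time.time()
    variants = variants or default_variant_panel(
        config.n_causal, config.n_null, config.max_share, config.min_share,
        config.pheno, config.panel_seed,
    )
    fractions: list[float | None]
    if thresholds is not None:
        fractions = list(thresholds)
    elif config.thresholds:
        fractions = list(config.thresholds)
    else:
        fractions = [None]  # top_n rule
    ss = np.random.SeedSequence(seed)
    rep_seqs = ss.spawn(config.n_replicates)
    accs = {
        (k, _rule_label(config.top_n, f)): _CellAccumulator(variants)
        for k in config.k_list
        for f in fractions
    }
    for r, rep_seq in enumerate(rep_seqs):
        data_seq, subset_seq = rep_seq.spawn(2)
        data = simulate_replicate(config, variants, data_seq)
        subset_seeds = [
            int(s.generate_state(1)[0] % (2**31))
            for s in subset_seq.spawn(config.n_subsets * len(config.k_list))
        ]
        si = 0
        for s in range(config.n_subsets):
            for k in config.k_list:
                subset = sample_members(
                    data.pedigree,
                    data.phenotypes,
                    k,
                    steepness=config.steepness,
                    seed=subset_seeds[si],
                )
                si += 1
                scores = score_test(
                    data.phenotypes, data.genotypes, data.kinships, subset
                )
                z_by_variant = {sc.variant_id: sc.z for sc in scores}
                for f in fractions:
                    if f is None:
                        prioritized = prioritize(scores, top_n=config.top_n)
                    else:
                        prioritized = prioritize(scores, top_fraction=f)
                    stage2 = stage2_test(
                        data.unrelated_phenotypes,
                        data.unrelated_genotypes,
                        prioritized,
                        alpha=config.alpha,
                    )
                    sig = [x.variant_id for x in stage2 if x.significant]
                    accs[(k, _rule_label(config.top_n, f))].add_run(
                        z_by_variant, prioritized, sig, replicate=r
                    )
        logger.info("two-stage replicate %d/%d done (%.1fs elapsed)",
                    r + 1, config.n_replicates, time.time() - t0)
    cells = [
        accs[(k, rule)].finish("two_stage", config.phenotype_kind, k, rule)
        for (k, rule) in accs
    ]
    return DesignReport(seed, _config_dict(config), cells)


def run_one_stage(
    config: StudyConfig, seed: int, variants: list[VariantSpec] | None = None
) -> DesignReport:
    """The single-stage design: per replicate, everyone is sequenced and
    every variant is QTDT_M-tested with Bonferroni over all variants.  The
    mean-score columns are computed from the score statistic with all
    members sequenced (the complete-pedigree score)."""
    t0 = time.time()
    variants = variants or default_variant_panel(
        config.n_causal, config.n_null, config.max_share, config.min_share,
        config.pheno, config.panel_seed,
    )
    ss = np.random.SeedSequence(seed)
    acc = _CellAccumulator(variants)
    for r, rep_seq in enumerate(ss.spawn(config.n_replicates)):
        data_seq, _ = rep_seq.spawn(2)
        data = simulate_replicate(config, variants, data_seq)
        everyone = SequencedSubset(
            {
                fid: tuple(i.individual_id for i in data.pedigree.members(fid))
                for fid in data.pedigree.family_ids
            },
            k_per_family=0,
            selection_seed=0,
        )
        scores = score_test(data.phenotypes, data.genotypes, data.kinships, everyone)
        z_by_variant = {sc.variant_id: sc.z for sc in scores}
        results = one_stage_analysis(
            data.pedigree, data.phenotypes, data.genotypes, alpha=config.alpha
        )
        sig = [x.variant_id for x in results if x.significant]
        acc.add_run(z_by_variant, None, sig, replicate=r)
        logger.info("one-stage replicate %d/%d done (%.1fs elapsed)",
                    r + 1, config.n_replicates, time.time() - t0)
    cell = acc.finish("one_stage", config.phenotype_kind, None, "all")
    return DesignReport(seed, _config_dict(config), [cell])


def threshold_sweep(
    config: StudyConfig,
    thresholds: Sequence[float],
    seed: int,
    variants: list[VariantSpec] | None = None,
) -> DesignReport:
    """Two-stage design at each prioritization threshold (top fraction of
    variants), exposing the power and FDR curves."""
    if list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    return run_two_stage(config, seed, variants=variants, thresholds=thresholds)


def _config_dict(config: StudyConfig) -> dict:
    d = asdict(config)
    d["pheno"] = asdict(config.pheno)
    d["k_list"] = list(config.k_list)
    d["thresholds"] = list(config.thresholds)
    return d
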