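"""Reduce longitudinal phenotype records to per-individual derived
phenotypes: baseline (adjusted first-visit value), intercept (trait level
at the sample-mean age) and age slope, adjusted for sex and current
treatment.

Two estimators are provided.  The default ``two_stage`` method first fits
a pooled ordinary-least-squares model ``value ~ sex + treated + age``
across all visits, subtracts the estimated sex and treatment contributions
only (the age trend is deliberately retained, so per-individual slopes
estimate the population age slope plus the individual deviation), then
regresses each individual's adjusted values on age centred at the sample
mean.  The optional ``reml`` method fits a random-coefficients linear
mixed model (individual-level random intercept and age slope, restricted
maximum likelihood via statsmodels ``MixedLM``) and returns the predicted
individual coefficients (fixed effect + BLUP).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .pedigree import Pedigree
from .simulate import PhenotypeRecord, records_to_frame

logger = logging.getLogger(__name__)

Kind = Literal["baseline", "intercept", "slope"]
KINDS: tuple[Kind, ...] = ("baseline", "intercept", "slope")


@dataclass(frozen=True)
class DerivedPhenotype:
    """One per-individual derived phenotype value (slope in trait units
    per year).  ``se`` is NaN where a standard error is undefined (e.g. a
    two-point slope has zero residual degrees of freedom)."""

    individual_id: str
    family_id: str
    kind: Kind
    value: float
    se: float = float("nan")


def derive_phenotypes(
    records: Sequence[PhenotypeRecord] | pd.DataFrame,
    pedigree: Pedigree,
    method: Literal["two_stage", "reml"] = "two_stage",
    adjusted_baseline: bool = True,
) -> list[DerivedPhenotype]:
    """Derive baseline / intercept / slope phenotypes for every individual
    with at least one visit.

    Individuals with a single visit (or all visits at one age) receive a
    baseline only; their slope and intercept are omitted with a logged
    warning.  With ``adjusted_baseline=False`` the baseline is the raw
    first-visit value.
    """
    if method not in ("two_stage", "reml"):
        raise ValueError(f"unknown method {method!r}")
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if df.empty:
        return []
    df = df.sort_values(["individual_id", "visit_index"]).reset_index(drop=True)
    fam_of = {
        ind.individual_id: fid
        for fid in pedigree.family_ids
        for ind in pedigree.members(fid)
    }
    unknown = set(df["individual_id"]) - set(fam_of)
    if unknown:
        raise KeyError(f"phenotype records for individuals absent from pedigree: "
                       f"{sorted(unknown)[:5]}")

    male = (df["sex"] == "male").to_numpy(float)
    treated = df["treated"].to_numpy(float)
    age = df["age"].to_numpy(float)
    y = df["value"].to_numpy(float)
    mean_age = age.mean()

    if method == "two_stage":
        X = np.column_stack([np.ones_like(y), male, treated, age])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        b_male, b_treat = coef[1], coef[2]
        adjusted = y - b_male * male - b_treat * treated
        return _per_individual_fits(
            df, adjusted, y, age, mean_age, fam_of, adjusted_baseline
        )
    return _reml_fit(df, male, treated, age, y, mean_age, fam_of, adjusted_baseline)


def _per_individual_fits(
    df: pd.DataFrame,
    adjusted: np.ndarray,
    raw: np.ndarray,
    age: np.ndarray,
    mean_age: float,
    fam_of: dict[str, str],
    adjusted_baseline: bool,
) -> list[DerivedPhenotype]:
    out: list[DerivedPhenotype] = []
    age_c = age - mean_age
    ids = df["individual_id"].to_numpy()
    # first row per individual is the first visit (frame sorted above)
    start = np.flatnonzero(np.r_[True, ids[1:] != ids[:-1]])
    stop = np.r_[start[1:], len(ids)]
    n_degenerate = 0
    for s, e in zip(start, stop):
        iid = ids[s]
        fid = fam_of[iid]
        base = adjusted[s] if adjusted_baseline else raw[s]
        out.append(DerivedPhenotype(iid, fid, "baseline", float(base)))
        a, r = age_c[s:e], adjusted[s:e]
        n = e - s
        if n < 2 or np.ptp(a) == 0.0:
            n_degenerate += 1
            continue
        # least squares of adjusted value on centred age
        abar, rbar = a.mean(), r.mean()
        sxx = float(((a - abar) ** 2).sum())
        slope = float(((a - abar) * (r - rbar)).sum() / sxx)
        intercept_at_mean = float(rbar - slope * abar)  # value at age_c = 0
        resid = r - (rbar + slope * (a - abar))
        dof = n - 2
        if dof > 0:
            s2 = float((resid**2).sum() / dof)
            se_slope = np.sqrt(s2 / sxx)
            se_int = np.sqrt(s2 * (1.0 / n + abar**2 / sxx))
        else:
            se_slope = se_int = float("nan")
        out.append(DerivedPhenotype(iid, fid, "intercept", intercept_at_mean, se_int))
        out.append(DerivedPhenotype(iid, fid, "slope", slope, se_slope))
    if n_degenerate:
        logger.warning(
            "%d individual(s) lack two distinct visit ages; slope/intercept omitted",
            n_degenerate,
        )
    return out


def _reml_fit(
    df: pd.DataFrame,
    male: np.ndarray,
    treated: np.ndarray,
    age: np.ndarray,
    y: np.ndarray,
    mean_age: float,
    fam_of: dict[str, str],
    adjusted_baseline: bool,
) -> list[DerivedPhenotype]:
    data = pd.DataFrame(
        {
            "y": y,
            "male": male,
            "treated": treated,
            "age_c": age - mean_age,
            "iid": df["individual_id"].to_numpy(),
        }
    )
    counts = data.groupby("iid")["y"].transform("size")
    multi = data[counts >= 2]
    # constant covariate columns (e.g. all-unknown sex, nobody treated)
    # would make the fixed-effect design singular
    covars = [c for c in ("male", "treated") if multi[c].nunique() > 1]
    formula = "y ~ " + " + ".join(covars + ["age_c"])
    model = smf.mixedlm(
        formula, multi, groups=multi["iid"], re_formula="~age_c"
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(reml=True)
    fe = fit.fe_params.copy()
    for c in ("male", "treated"):
        if c not in fe:
            fe[c] = 0.0
    re = fit.random_effects
    out: list[DerivedPhenotype] = []
    ids = df["individual_id"].to_numpy()
    start = np.flatnonzero(np.r_[True, ids[1:] != ids[:-1]])
    for s in start:
        iid = ids[s]
        fid = fam_of[iid]
        base = (
            y[s] - fe["male"] * male[s] - fe["treated"] * treated[s]
            if adjusted_baseline
            else y[s]
        )
        out.append(DerivedPhenotype(iid, fid, "baseline", float(base)))
        if iid in re:
            blup = re[iid]
            out.append(
                DerivedPhenotype(
                    iid, fid, "intercept", float(fe["Intercept"] + blup.iloc[0])
                )
            )
            out.append(
                DerivedPhenotype(iid, fid, "slope", float(fe["age_c"] + blup.iloc[1]))
            )
    return out


# -- helpers / IO ----------------------------------------------------------


def phenotype_vector(
    derived: Sequence[DerivedPhenotype], kind: Kind
) -> dict[str, float]:
    """Map individual_id -> value for one derived-phenotype kind."""
    return {d.individual_id: d.value for d in derived if d.kind == kind}


def derived_to_frame(derived: Sequence[DerivedPhenotype]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "individual_id": [d.individual_id for d in derived],
            "family_id": [d.family_id for d in derived],
            "kind": [d.kind for d in derived],
            "value": [d.value for d in derived],
            "se": [d.se for d in derived],
        }
    )


def write_derived_tsv(derived: Sequence[DerivedPhenotype], path: str | Path) -> None:
    derived_to_frame(derived).to_csv(path, sep="\t", index=False)


def read_derived_tsv(path: str | Path) -> list[DerivedPhenotype]:
    df = pd.read_csv(path, sep="\t")
    return [
        DerivedPhenotype(
            str(r.individual_id), str(r.family_id), r.kind, float(r.value), float(r.se)
        )
        for r in df.itertuples()
    ]
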