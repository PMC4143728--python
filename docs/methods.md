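# Methods

`famseq2` implements and evaluates a two-stage family-based sequencing
study design for quantitative traits: stage 1 sequences a few
extreme-phenotype members per pedigree and ranks all discovered variants
by a kinship-weighted score test; stage 2 genotypes only the top-ranked
variants in an independent cohort of unrelated individuals and tests them
by linear regression with a Bonferroni correction restricted to the
prioritized set. The comparator is a single-stage design in which every
family member is sequenced and every variant is tested with the
quantitative transmission disequilibrium test with mating-type means
(QTDT_M). All components run on simulated cohorts produced by the
package's own generator, so the designs can be compared end to end
without access-restricted data.

## The score statistic

For variant v, family f contributes

    t_fv = (Y_f − μ_f 1)ᵀ Φ_f⁻¹ (G_fv − 2 q_v 1)

where Y_f is the vector of derived phenotypes of the family's members,
μ_f the family mean phenotype, Φ_f the family's kinship matrix, G_fv the
vector of minor-allele counts in {0, 1, 2}, and q_v the minor allele
frequency. The statistic is T_v = Σ_f t_fv with asymptotic variance
var(T_v) = Σ_f t_fv², and variants are ranked by T_v²/var(T_v), which is
asymptotically χ²(1) under the null hypothesis of no association.

Design notes:

* **Genotype centering.** Counts are centred at their Hardy–Weinberg
  expectation 2q_v, not at q_v. Centering at the allele frequency leaves
  every deviation with mean q_v and destroys the statistic's mean-zero
  null property (we measured a bias of ≈ 25 null standard errors on the
  calibration fixture); centering at the genotype mean restores it
  exactly. q_v itself is always reported on the allele-frequency scale.
* **Untyped individuals.** The genotype deviation of unsequenced or
  missing-genotype individuals is set to zero, but their phenotypes still
  contribute through the Φ_f⁻¹ cross-terms — this is what lets two
  sequenced members plus a fully phenotyped pedigree carry information.
  Conversely, members with genotype but no phenotype enter with a zero
  phenotype deviation.
* **Family centering.** μ_f is the unweighted mean of the chosen derived
  phenotype over the family's phenotyped members. For a cohort of
  single-member families this centering annihilates every contribution
  (each member is its own family mean), so `score_test` offers
  `center="grand"` — overall-mean centering — which reduces the statistic
  exactly to the classical covariance score test
  Σ 2(Y_i − μ)(G_i − 2q) with its empirical variance. The default,
  `center="family"`, is the intended use on pedigrees.
* **Kinship scale.** Φ stores kinship coefficients (founder diagonal
  0.5), not the additive relationship matrix 2Φ. The ranking is invariant
  to the global factor (it rescales T and √var identically), which the
  test suite asserts; only the raw t_fv values change.
* **MAF source.** q_v is estimated from the sequenced subset pooled
  across families (count of minor alleles over twice the number of
  sequenced, non-missing genotypes); external or truth frequencies can be
  supplied instead. Variants monomorphic in the sequenced sample
  (q̂ ∈ {0, 1}) or sequenced in nobody are flagged and given statistic 0.
* **Numerics.** Φ_f⁻¹ is never formed; each family is solved once per
  phenotype vector via a Cholesky factorization, and all variants then
  reduce to one matrix–vector product per family. A near-zero Cholesky
  pivot (possible when LAPACK accepts an exactly singular matrix) raises
  a linear-algebra error naming the family. Outbred pedigrees keep pivots
  ≥ ~0.5, so the 1e-6 relative threshold cannot misfire on valid input.
* **Var(T) = 0.** The statistic is defined as 0 when no family
  contributes (monomorphic or unsequenced variants).

Ties in the ranking are broken by |T| descending, then variant id, so
reports are reproducible byte for byte.

## Kinship

Kinship matrices are built per family by the recursive tabular method in
a fixed order (topological, parents before offspring, ties lexicographic):
φ_ii = ½(1 + φ_father,mother), φ_ij = ½(φ_father(i),j + φ_mother(i),j),
founders non-inbred and mutually unrelated. There is no support for
inbreeding loops beyond what the recursion naturally handles, no X-linked
kinship, and no inbreeding-coefficient reporting. The test suite checks
the recursion against an independent Monte-Carlo gene-drop
identity-by-descent estimator (100,000 drops) on trio, half-sib,
three-generation and first-cousin pedigrees, plus the textbook constants
(0.5, 0.25, 0.25, 0.125, 0.0625).

## Member sampling

Within each family the phenotyped, non-excluded members are ranked by
phenotype; with d_i the rank deviation from the family median scaled by
family size, the selection weight is logistic(α + s·d_i²), with the
intercept α calibrated per family so the weights average 0.5 (hence
steepness s = 0 is uniform sampling). k members are drawn without
replacement by sequential weighted draws. s defaults to 8; at large s the
family's extremes dominate the draw. Families with fewer than k eligible
members contribute everyone (with a logged warning). The exclusion set is
a plain id set supplied by the caller, e.g. to keep the replication
cohort disjoint from stage 1.

## Derived phenotypes

Longitudinal records (value, age, sex, current treatment per visit) are
reduced to three per-individual phenotypes: **baseline** (first-visit
value, by default adjusted for sex and treatment), **intercept** (trait
level at the sample-mean age) and **slope** (trait units per year). The
default `two_stage` estimator fits one pooled least-squares model
value ~ sex + treated + age, removes only the estimated sex and treatment
contributions (the age trend is retained so per-individual slopes centre
on the population age effect), then regresses each individual's adjusted
values on centred age. Individuals without two distinct visit ages get a
baseline only; their slope and intercept are omitted with a warning. The
optional `reml` estimator fits a random-coefficients model (individual
random intercept and slope, REML via statsmodels MixedLM) and returns the
predicted individual coefficients; a family random intercept is not fit
as a separate level — it is absorbed into the individual intercepts,
which is immaterial when the coefficients are used as derived phenotypes.
Constant covariate columns (e.g. all-unknown sex in the unrelated cohort)
are dropped from the REML design to keep it full rank. The two estimators'
intercepts correlate > 0.9 on simulated data; `two_stage` is the default
because it is deterministic and has no convergence failure modes.

Treatment is adjusted as a plain fixed effect. This is knowingly
imperfect — treatment assigned by crossing a trait threshold is both a
confounder and an intermediate on the causal path — and causal-pathway
corrections (G-estimation and relatives) are out of scope.

## Association tests

**QTDT_M.** For each offspring with both parents genotyped, the Mendelian
expectation of its count is e = (G_fa + G_mo)/2 and the within-family
deviation is w = G − e. The offspring phenotype is regressed on w with
fixed-effect indicators for the unordered parental genotype pair (the
mating type), which absorbs all between-family allele-frequency
differences and makes the test robust to population stratification; the
reported effect, standard error and two-sided t-test concern the w
coefficient. Offspring with an ungenotyped parent are dropped for that
variant; variants with no informative offspring (no heterozygous parent
anywhere) are untestable, p = 1. The regression is plain offspring-level
OLS — valid here because the simulator puts no residual dependency within
families beyond what the mating-type means capture — with an optional
family-clustered (CR0) variance for data where that assumption fails.
The least-squares path is numpy-based for speed inside replicate loops
and is verified against statsmodels OLS in the tests.

**Stage 2.** Ordinary least squares of the derived phenotype on the
minor-allele count in the unrelated cohort, one variant at a time;
a variant is declared significant when p ≤ α/m with m the number of
prioritized variants (α defaults to 0.05). The one-stage comparator
Bonferroni-corrects over all variants tested.

## The synthetic cohort generator

The generator emulates the structure of an extended-pedigree longitudinal
blood-pressure study:

* **Pedigrees.** Each family grows from a founder couple over 2–4
  generations; children in non-terminal generations marry in unrelated
  founder spouses (probability 0.6 each) and have sibships of
  configurable size (default 1 + Poisson draws). The default evaluation
  cohort is 200 three-generation families, median size ≈ 10.
* **Genotypes.** Gene dropping: founder alleles i.i.d. Bernoulli(q)
  (Hardy–Weinberg), each nonfounder inheriting one uniformly chosen
  allele per parent, independently across variants (no linkage
  disequilibrium — the score test and the design comparison are
  per-variant, and haplotype structure is deliberately out of scope).
  Parental-origin gametes are recorded, so Mendelian consistency is
  checkable cell by cell.
* **Variant panel.** 15 causal variants with variance shares log-spaced
  from 2.8% down to 0.05% (signs alternating, so both trait-lowering and
  trait-raising variants occur; MAFs log-uniform on 0.01–0.25) plus 985
  null variants (MAFs log-uniform on 0.005–0.5). Effect sizes are solved
  from the requested shares jointly: β_i = √(s_i·V_total/2q_i(1−q_i))
  with V_total = V_env/(1 − Σs), so the configured shares are exact
  shares of the total variance.
* **Phenotypes.** value = mean + β_age·age + β_male·I(male) + Σ β_v G_v
  + family intercept + individual intercept + individual slope·age +
  visit noise, on a systolic-blood-pressure scale (mmHg; defaults:
  mean 118, β_age 0.45/yr, β_male 4, SDs 4.5/6/0.12/5.5, 3 visits 5
  years apart, first-visit ages by generation ≈ 68/42/16). Treatment
  switches on at the first visit where the *untreated* trajectory
  exceeds 165 mmHg, persists, and subtracts 8 mmHg from the observed
  value — reproducing the confounder-plus-intermediate character of
  antihypertensive treatment.
* **Replication cohort.** 157 unrelated individuals by default, simulated
  with the same phenotype model (each individual its own family) and
  fresh gene drops.
* **Randomness.** One master seed is split into pedigree / genotype /
  phenotype / sampling substreams with numpy `SeedSequence.spawn`
  (PCG64), so varying one stage's seed leaves the others fixed and every
  report is byte-for-byte reproducible.

What the generator does **not** emulate: linkage disequilibrium and
haplotypes, sequencing error, depth or multi-allelic sites, ascertainment
of multiplex families, and secular trends in treatment. Passing tests
therefore demonstrate the statistical machinery under the stated model,
not robustness to real sequencing artefacts.

## Design evaluation and its scale

`run_two_stage` / `run_one_stage` / `threshold_sweep` replicate the whole
study: per phenotype replicate (default 5), per random sequencing subset
(default 20) and per subset size k ∈ {2, 4, 6}, stage 1 is run and the
prioritized set (top-100 rule, or each requested top fraction between
0.5% and 16%) is tested in the replication cohort. Reports aggregate, per
cell: mean standardized score by truth class (negative-effect / null /
positive-effect), proportions prioritized and significant by class,
per-causal-variant frequencies, and the empirical false discovery rate
(null significants over all significants). Power is the proportion of
runs in which a causal variant is declared significant. Because all runs
of a replicate share one replication cohort, stage-2 hits are clustered
by replicate; the report therefore also exposes per-replicate
causal-significance counts so across-threshold comparisons can be paired.

At this package's default scale (200 families, 1,000 variants, 157
unrelateds, 5×20 runs — a desk-scale setting chosen so the full
comparison completes in about a minute) the absolute stage-2 power is of
order 10⁻³: with variance shares ≤ 2.8% and 157 replication samples, the
per-variant noncentrality is ≈ 4.5, far below the Bonferroni threshold.
The informative outputs at this scale are the *orderings* — causal
prioritization rising with k, the sign gradient of mean scores, null
prioritization matching the rule size — not absolute power, which is also
why the monotonicity checks in the test suite treat sub-Monte-Carlo
differences as ties.

## Known limitations

* The score test's χ²(1) calibration needs adequate minor-allele counts
  in the sequenced subset; for very rare variants (a handful of carrier
  families) the statistic is bounded by the number of contributing
  families and the asymptotic reference is poor. The calibration fixture
  uses common variants for this reason; rare-variant ranking still works,
  but nominal tail probabilities should not be read off χ²(1).
* Bayes-factor prioritization, FBAT-style rare-variant tests,
  burden/collapsing tests, mixed-model (GRM) association in the
  replication cohort, Mendelian imputation of untyped members, and
  cost-efficiency optimization of the two stages are out of scope.
* Inbred pedigrees are not supported (founders are assumed unrelated);
  the kinship recursion would run but the generator never produces loops
  and no loop-specific validation exists.
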