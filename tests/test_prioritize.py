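"""Stage-1 prioritization: extreme-phenotype sampling, subset MAF,
the kinship-weighted score statistic and its invariances."""

import numpy as np
import pytest
from scipy import stats

from famseq2 import (
    MISSING,
    GenotypeMatrix,
    SequencedSubset,
    VariantSpec,
    estimate_maf,
    gene_drop,
    kinship,
    make_pedigrees,
    make_unrelated_cohort,
    prioritize,
    sample_members,
    score_test,
)
from famseq2.pedigree import KinshipMatrix, Pedigree
from famseq2.prioritize import AlignmentError, _logistic_weights, score_matrix

from conftest import ind


def _everyone(pedigree):
    return SequencedSubset(
        {
            fid: tuple(i.individual_id for i in pedigree.members(fid))
            for fid in pedigree.family_ids
        },
        k_per_family=0,
        selection_seed=0,
    )


class TestSampleMembers:
    @pytest.fixture(scope="class")
    def family10(self):
        members = [ind(f"i{j}", "F1") for j in range(10)]
        ped = Pedigree(members)
        phen = {f"i{j}": float(j) for j in range(10)}
        return ped, phen

    def test_weights_average_half(self):
        for steep in (0.0, 2.0, 8.0, 50.0):
            w = _logistic_weights(10, np.arange(1, 11, dtype=float), steep)
            assert w.mean() == pytest.approx(0.5, abs=1e-8)
            assert ((w > 0) & (w < 1)).all()

    def test_zero_steepness_is_uniform(self, family10):
        """With a flat logistic every member is picked equally often."""
        ped, phen = family10
        counts = {f"i{j}": 0 for j in range(10)}
        n_draws = 3000
        for s in range(n_draws):
            sub = sample_members(ped, phen, k=2, steepness=0.0, seed=s)
            for iid in sub.members["F1"]:
                counts[iid] += 1
        freqs = np.array(list(counts.values())) / (2 * n_draws)
        # each of 10 members should appear with frequency ~0.1
        assert np.abs(freqs - 0.1).max() < 0.03

    def test_k_equal_family_size_takes_everyone(self, family10):
        ped, phen = family10
        sub = sample_members(ped, phen, k=10, steepness=50.0, seed=0)
        assert len(sub.members["F1"]) == 10

    def test_k_exceeding_eligible_warns_and_takes_all(self, family10, caplog):
        ped, phen = family10
        with caplog.at_level("WARNING"):
            sub = sample_members(ped, phen, k=15, seed=0)
        assert len(sub.members["F1"]) == 10
        assert "fewer than k" in caplog.text

    def test_steep_logistic_prefers_extremes(self, family10):
        """At steepness 50 in a family of 10, the extreme-ranked members
        dominate the k=2 draws: each extreme is drawn far more often than
        any mid-ranked member, and the exact top+bottom pair occurs at the
        frequency an independent sequential-draw calculation predicts."""
        from scipy.optimize import brentq
        from scipy.special import expit

        ped, phen = family10
        n_draws = 2000
        pair_hits = 0
        counts = {f"i{j}": 0 for j in range(10)}
        for s in range(n_draws):
            sub = sample_members(ped, phen, k=2, steepness=50.0, seed=s)
            for iid in sub.members["F1"]:
                counts[iid] += 1
            if set(sub.members["F1"]) == {"i0", "i9"}:
                pair_hits += 1
        # independent computation of the selection weights and the exact
        # probability that the two sequential draws are {top, bottom}
        d = (np.arange(1, 11) - 5.5) / 10.0
        z = 50.0 * d**2
        alpha = brentq(lambda a: expit(a + z).mean() - 0.5, -100, 100)
        w = expit(alpha + z)
        p = w / w.sum()
        p_pair = p[0] * w[9] / (w.sum() - w[0]) + p[9] * w[0] / (w.sum() - w[9])
        se = np.sqrt(p_pair * (1 - p_pair) / n_draws)
        assert abs(pair_hits / n_draws - p_pair) < 4 * se
        for mid in ("i4", "i5"):
            assert counts["i0"] > 4 * counts[mid]
            assert counts["i9"] > 4 * counts[mid]

    def test_exclusions_respected(self, family10):
        ped, phen = family10
        sub = sample_members(ped, phen, k=3, exclusions={"i0", "i9"}, seed=1)
        assert not {"i0", "i9"} & set(sub.members["F1"])

    def test_deterministic_under_seed(self, small_cohort):
        a = sample_members(small_cohort["pedigree"], small_cohort["phenotypes"],
                           k=4, seed=77)
        b = sample_members(small_cohort["pedigree"], small_cohort["phenotypes"],
                           k=4, seed=77)
        assert a.members == b.members

    def test_invalid_parameters(self, family10):
        ped, phen = family10
        with pytest.raises(ValueError):
            sample_members(ped, phen, k=0)
        with pytest.raises(ValueError):
            sample_members(ped, phen, k=2, steepness=-1.0)


class TestEstimateMaf:
    def _geno(self, counts_row):
        counts = np.array([counts_row], dtype=np.int8)
        ids = tuple(f"i{j}" for j in range(len(counts_row)))
        return GenotypeMatrix(("v",), ids, counts)

    def _subset(self, ids):
        return SequencedSubset({"F1": tuple(ids)}, len(ids), 0)

    def test_plain_arithmetic(self):
        geno = self._geno([0, 1, 1, 2])
        q, bad = estimate_maf(geno, self._subset(["i0", "i1", "i2", "i3"]))
        assert q[0] == pytest.approx(0.5)
        assert not bad[0]

    def test_all_zeros_monomorphic(self):
        geno = self._geno([0, 0, 0])
        q, bad = estimate_maf(geno, self._subset(["i0", "i1", "i2"]))
        assert q[0] == 0.0 and bad[0]

    def test_missing_excluded_from_denominator(self):
        geno = self._geno([0, 1, MISSING, 2])
        q, bad = estimate_maf(geno, self._subset(["i0", "i1", "i2", "i3"]))
        assert q[0] == pytest.approx(3 / 6)

    def test_all_missing_flagged(self):
        geno = self._geno([MISSING, MISSING])
        q, bad = estimate_maf(geno, self._subset(["i0", "i1"]))
        assert np.isnan(q[0]) and bad[0]

    def test_empty_subset_rejected(self):
        geno = self._geno([0, 1])
        with pytest.raises(ValueError, match="empty"):
            estimate_maf(geno, SequencedSubset({}, 0, 0))


class TestScoreTest:
    def test_singleton_families_closed_form(self):
        """With singleton families fully sequenced and grand-mean
        centering, T = sum_i 2(Y_i - mu)(G_i - 2q) exactly (genotypes
        centred at their expected count), and the standardized statistic
        equals the covariance score test against its empirical variance
        (direct-summation oracle)."""
        rng = np.random.default_rng(8)
        n = 60
        ped = make_unrelated_cohort(n)
        variants = [VariantSpec("v1", 0.3), VariantSpec("v2", 0.1)]
        geno = gene_drop(ped, variants, seed=9)
        ids = [i.individual_id for i in ped.individuals()]
        phen = {iid: float(rng.normal()) for iid in ids}
        kins = {fid: kinship(ped, fid) for fid in ped.family_ids}
        sub = _everyone(ped)
        q, _ = estimate_maf(geno, sub)
        scores = score_test(phen, geno, kins, sub, q=q, center="grand")
        y = np.array([phen[i] for i in ids])
        mu = y.mean()
        for r, vid in zip(scores, geno.variant_ids):
            g = np.array([geno.genotype(vid, i) for i in ids], dtype=float)
            qv = q[geno.row(vid)]
            t_oracle = (2.0 * (y - mu) * (g - 2 * qv)).sum()
            var_oracle = (4.0 * (y - mu) ** 2 * (g - 2 * qv) ** 2).sum()
            assert abs(r.T - t_oracle) < 1e-10 * max(1.0, abs(t_oracle))
            assert r.stat == pytest.approx(t_oracle**2 / var_oracle, abs=1e-10)

    def test_family_with_no_sequenced_members_contributes_zero(self, small_cohort):
        ped = small_cohort["pedigree"]
        kins = small_cohort["kinships"]
        sub = _everyone(ped)
        # drop one family from the subset entirely
        dropped = ped.family_ids[0]
        members = dict(sub.members)
        members[dropped] = ()
        sub2 = SequencedSubset(members, 0, 0)
        scores = score_test(
            small_cohort["phenotypes"], small_cohort["genotypes"], kins, sub2,
            keep_family_terms=True,
        )
        for r in scores:
            assert r.per_family_t[dropped] == 0.0
            assert r.T == pytest.approx(sum(r.per_family_t.values()), abs=1e-9)

    def test_permutation_null_mean_zero(self, small_cohort):
        """Permuting phenotypes across individuals destroys association:
        the mean of T over permutations is within 3 SEs of 0."""
        ped = small_cohort["pedigree"]
        geno = small_cohort["genotypes"]
        kins = small_cohort["kinships"]
        sub = sample_members(ped, small_cohort["phenotypes"], k=4, seed=3)
        ids = list(small_cohort["phenotypes"])
        vals = np.array([small_cohort["phenotypes"][i] for i in ids])
        rng = np.random.default_rng(17)
        vid = "causal01"
        row = geno.row(vid)
        q, _ = estimate_maf(geno, sub)
        ts = []
        for _ in range(400):
            perm = dict(zip(ids, rng.permutation(vals)))
            T, _, _, _ = score_matrix(perm, geno, kins, sub, q)
            ts.append(T[row])
        ts = np.array(ts)
        se = ts.std(ddof=1) / np.sqrt(len(ts))
        assert abs(ts.mean()) < 3 * se

    def test_ranking_invariant_to_kinship_scaling(self, small_cohort):
        """Phi -> 2*Phi rescales T and sqrt(var) identically: the
        standardized statistic and hence the ranking are unchanged."""
        sub = sample_members(small_cohort["pedigree"], small_cohort["phenotypes"],
                             k=4, seed=5)
        kins = small_cohort["kinships"]
        kins2 = {fid: kins[fid].scaled(2.0) for fid in kins}
        s1 = score_test(small_cohort["phenotypes"], small_cohort["genotypes"],
                        kins, sub)
        s2 = score_test(small_cohort["phenotypes"], small_cohort["genotypes"],
                        kins2, sub)
        for a, b in zip(s1, s2):
            assert a.stat == pytest.approx(b.stat, rel=1e-9)
            assert a.T == pytest.approx(2 * b.T, rel=1e-9)
        assert prioritize(s1, top_n=20) == prioritize(s2, top_n=20)

    def test_ranking_invariant_to_affine_phenotype_transform(self, small_cohort):
        sub = sample_members(small_cohort["pedigree"], small_cohort["phenotypes"],
                             k=4, seed=5)
        phen = small_cohort["phenotypes"]
        phen2 = {i: -3.0 * v + 11.0 for i, v in phen.items()}
        s1 = score_test(phen, small_cohort["genotypes"],
                        small_cohort["kinships"], sub)
        s2 = score_test(phen2, small_cohort["genotypes"],
                        small_cohort["kinships"], sub)
        for a, b in zip(s1, s2):
            assert a.stat == pytest.approx(b.stat, rel=1e-9, abs=1e-12)
        assert prioritize(s1, top_n=20) == prioritize(s2, top_n=20)

    def test_invariant_to_family_processing_order(self, small_cohort):
        sub = sample_members(small_cohort["pedigree"], small_cohort["phenotypes"],
                             k=4, seed=5)
        kins = small_cohort["kinships"]
        reversed_kins = dict(reversed(list(kins.items())))
        s1 = score_test(small_cohort["phenotypes"], small_cohort["genotypes"],
                        kins, sub)
        s2 = score_test(small_cohort["phenotypes"], small_cohort["genotypes"],
                        reversed_kins, sub)
        for a, b in zip(s1, s2):
            assert a.T == pytest.approx(b.T, abs=1e-10)
            assert a.rank == b.rank

    def test_monomorphic_variant_gets_zero_stat(self, small_cohort):
        ped = small_cohort["pedigree"]
        geno = small_cohort["genotypes"]
        counts = geno.counts.copy()
        counts[0] = 0  # force first variant monomorphic
        geno2 = GenotypeMatrix(geno.variant_ids, geno.individual_ids, counts)
        sub = _everyone(ped)
        scores = score_test(small_cohort["phenotypes"], geno2,
                            small_cohort["kinships"], sub)
        assert scores[0].monomorphic and scores[0].stat == 0.0

    def test_alignment_error_lists_offending_ids(self, small_cohort):
        sub = _everyone(small_cohort["pedigree"])
        members = dict(sub.members)
        fid = small_cohort["pedigree"].family_ids[0]
        members[fid] = members[fid] + ("phantom",)
        with pytest.raises(AlignmentError, match="phantom"):
            score_test(small_cohort["phenotypes"], small_cohort["genotypes"],
                       small_cohort["kinships"],
                       SequencedSubset(members, 0, 0))

    def test_strongest_causal_scores_above_null_median(self, small_cohort):
        """Full-information sanity: the largest-effect causal variant's
        statistic exceeds the median null statistic."""
        sub = _everyone(small_cohort["pedigree"])
        scores = score_test(small_cohort["phenotypes"], small_cohort["genotypes"],
                            small_cohort["kinships"], sub)
        by_id = {s.variant_id: s.stat for s in scores}
        null_stats = [s.stat for s in scores if s.variant_id.startswith("null")]
        assert by_id["causal01"] > np.median(null_stats)

    def test_null_tail_calibration(self):
        """Under the null the fraction of standardized statistics above
        the chi-square(1) 95% quantile is ~5% (binomial 99% band)."""
        ped = make_pedigrees(150, 3, 2, seed=71)
        rng = np.random.default_rng(72)
        variants = [
            VariantSpec(f"n{i}", float(q))
            for i, q in enumerate(
                np.exp(rng.uniform(np.log(0.02), np.log(0.5), size=3000))
            )
        ]
        geno = gene_drop(ped, variants, seed=73)
        ids = [i.individual_id for i in ped.individuals()]
        # family-structured null phenotype, independent of genotypes
        phen = {}
        for fid in ped.family_ids:
            fam_eff = rng.normal(0, 1)
            for i in ped.members(fid):
                phen[i.individual_id] = fam_eff + rng.normal(0, 2)
        kins = {fid: kinship(ped, fid) for fid in ped.family_ids}
        sub = sample_members(ped, phen, k=4, seed=74)
        scores = score_test(phen, geno, kins, sub)
        stats_arr = np.array([s.stat for s in scores if not s.monomorphic])
        crit = stats.chi2.ppf(0.95, df=1)
        frac = (stats_arr > crit).mean()
        lo, hi = stats.binom.interval(0.99, len(stats_arr), 0.05)
        assert lo / len(stats_arr) <= frac <= hi / len(stats_arr)


class TestPrioritize:
    def _fake_scores(self, stats_list):
        from famseq2.prioritize import ScoreResult

        return [
            ScoreResult(f"v{i}", T=t, var_T=1.0, stat=s, z=t, q_hat=0.1)
            for i, (s, t) in enumerate(stats_list)
        ]

    def test_top_n_larger_than_count_returns_all(self):
        scores = self._fake_scores([(3.0, 1.0), (1.0, 1.0)])
        assert prioritize(scores, top_n=10) == ["v0", "v1"]

    def test_top_fraction_uses_ceiling(self):
        scores = self._fake_scores([(float(i), 1.0) for i in range(1000)])
        assert len(prioritize(scores, top_fraction=0.005)) == 5
        assert len(prioritize(scores, top_fraction=0.0051)) == 6

    def test_tie_break_by_abs_T_then_id(self):
        scores = self._fake_scores(
            [(2.0, 1.0), (2.0, -5.0), (2.0, 1.0), (9.0, 0.5)]
        )
        assert prioritize(scores, top_n=4) == ["v3", "v1", "v0", "v2"]

    def test_default_is_top_100(self):
        scores = self._fake_scores([(float(i), 1.0) for i in range(300)])
        assert len(prioritize(scores)) == 100

    def test_mutually_exclusive_rules(self):
        scores = self._fake_scores([(1.0, 1.0)])
        with pytest.raises(ValueError):
            prioritize(scores, top_n=5, top_fraction=0.1)
        with pytest.raises(ValueError):
            prioritize([])
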