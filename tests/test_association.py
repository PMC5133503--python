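import numpy as np
import pandas as pd
import pytest

from longvc import (AssociationRunner, LongitudinalPhenotypes, SimConfig,
                    lrt_pvalue, screen_covariates, simulate_replicate,
                    tally_replicates)


class TestLrtPvalue:
    @pytest.mark.parametrize("stat,df,expected", [
        (3.841, 1, 0.0500),
        (0.0, 1, 1.0),
        (7.815, 3, 0.0500),
    ])
    def test_chi_square_quantiles(self, stat, df, expected):
        assert lrt_pvalue(stat, df) == pytest.approx(expected, abs=1e-4)

    def test_small_negative_clipped(self):
        assert lrt_pvalue(-1e-8, 1) == 1.0

    def test_large_negative_raises(self):
        with pytest.raises(ValueError, match="negative"):
            lrt_pvalue(-0.01, 1)


class TestCovariateScreen:
    def test_strong_sex_effect_retained_null_smoking_dropped(self):
        """Sex explaining ~5 % of variance is detected; a smoking
        indicator with zero true effect is not carried forward."""
        cfg = SimConfig(beta_sex=np.sqrt(0.05 / 0.25), beta_smoke=0.0,
                        beta_age=0.0, causal_variants=(), n_null_variants=1)
        rep = simulate_replicate(cfg, seed=31)
        sel = screen_covariates(rep.kinship, rep.phenotypes,
                                candidates=("sex", "smoke"))
        assert "sex" in sel
        assert "smoke" not in sel

    def test_candidate_equal_to_trait_retained(self, small_replicate):
        rep = small_replicate
        phen = rep.phenotypes
        cov = phen.covariates.assign(selfy=phen.visit_mean())
        phen2 = LongitudinalPhenotypes(phen.ids, phen.trait, phen.values, cov)
        sel = screen_covariates(rep.kinship, phen2, candidates=("selfy",))
        assert sel == ["selfy"]

    def test_constant_candidate_skipped_with_warning(self, small_replicate):
        rep = small_replicate
        phen = rep.phenotypes
        cov = phen.covariates.assign(flat=1.0)
        phen2 = LongitudinalPhenotypes(phen.ids, phen.trait, phen.values, cov)
        with pytest.warns(UserWarning, match="constant"):
            sel = screen_covariates(rep.kinship, phen2, candidates=("flat",))
        assert sel == []


@pytest.fixture(scope="module")
def runner(small_replicate):
    return AssociationRunner(small_replicate.kinship,
                             small_replicate.phenotypes,
                             covariates=["age", "sex"])


class TestMeasuredGenotypeTests:
    def test_causal_variant_detected(self, small_replicate, runner):
        g = small_replicate.genotypes.dosage("snv_c1")
        res = {r.test: r for r in runner.test_variant(g, "snv_c1")}
        assert res["constrained"].df == 1
        assert res["unconstrained"].df == 3
        assert res["average"].df == 1
        # 5 % of variance in 120 individuals: clearly sub-0.05 signal
        assert res["constrained"].p < 0.05

    def test_nesting_of_logliks(self, small_replicate, runner):
        """logL_unconstrained >= logL_constrained >= logL_null on every
        variant (1e-6 optimizer slack)."""
        for vid in small_replicate.genotypes.variants["id"]:
            g = small_replicate.genotypes.dosage(vid)
            res = {r.test: r for r in runner.test_variant(
                g, vid, tests=("constrained", "unconstrained"))}
            con, unc = res["constrained"], res["unconstrained"]
            assert con.loglik_alt >= con.loglik_null - 1e-6
            assert unc.loglik_alt >= con.loglik_alt - 1e-6

    def test_allele_flip_leaves_p_flips_beta(self, small_replicate, runner):
        g = small_replicate.genotypes.dosage("snv_c1")
        res1 = {r.test: r for r in runner.test_variant(g, "v")}
        res2 = {r.test: r for r in runner.test_variant(2.0 - g, "v")}
        for test in ("average", "constrained"):
            assert res2[test].p == pytest.approx(res1[test].p, rel=1e-3)
            assert res2[test].beta == pytest.approx(-res1[test].beta,
                                                    rel=1e-3)
        assert res2["unconstrained"].p == pytest.approx(
            res1["unconstrained"].p, rel=1e-3)

    def test_monomorphic_variant_flagged_not_raised(self, small_replicate,
                                                    runner):
        g = np.zeros(small_replicate.phenotypes.n)
        res = runner.test_variant(g, "mono")
        for r in res:
            assert r.p == 1.0
            assert r.note == "monomorphic"

    def test_average_of_identical_visits_equals_single_visit(self):
        """If every visit records the same value, the averaged-trait test
        is exactly the single-time-point test."""
        cfg = SimConfig(n_pedigrees=4, total_size=120, n_null_variants=2,
                        causal_variants=((0.3, 0.05),), k=1)
        rep = simulate_replicate(cfg, seed=7)
        g = rep.genotypes.dosage("snv_c1")
        phen1 = rep.phenotypes
        phen3 = LongitudinalPhenotypes(
            phen1.ids, "SBP", np.tile(phen1.values[:, :1], (1, 3)),
            phen1.covariates)
        r1 = AssociationRunner(rep.kinship, phen1, covariates=["age", "sex"])
        r3 = AssociationRunner(rep.kinship, phen3, covariates=["age", "sex"])
        a1 = r1.test_variant(g, "v", tests=("average",))[0]
        a3 = r3.test_variant(g, "v", tests=("average",))[0]
        assert a3.stat == pytest.approx(a1.stat, abs=1e-6)
        assert a3.beta == pytest.approx(a1.beta, abs=1e-8)

    def test_duplicated_visits_reduce_to_univariate(self):
        """k = 2 with the second visit an exact copy: the constrained
        test reduces to the univariate measured-genotype test (the
        duplicated visit is perfectly predicted, a degenerate boundary
        fit, so agreement is approximate)."""
        cfg = SimConfig(n_pedigrees=4, total_size=120, n_null_variants=2,
                        causal_variants=((0.3, 0.05),), k=1)
        rep = simulate_replicate(cfg, seed=7)
        g = rep.genotypes.dosage("snv_c1")
        phen1 = rep.phenotypes
        phen2 = LongitudinalPhenotypes(
            phen1.ids, "SBP", np.tile(phen1.values[:, :1], (1, 2)),
            phen1.covariates)
        r1 = AssociationRunner(rep.kinship, phen1, covariates=["age", "sex"])
        r2 = AssociationRunner(rep.kinship, phen2, covariates=["age", "sex"])
        uni = r1.test_variant(g, "v", tests=("average",))[0]
        dup = r2.test_variant(g, "v", tests=("constrained",))[0]
        assert dup.beta == pytest.approx(uni.beta, abs=1e-3)
        assert dup.p == pytest.approx(uni.p, rel=0.05)

    def test_missing_dosages_mean_imputed(self, small_replicate, runner):
        g = small_replicate.genotypes.dosage("snv_c1").copy()
        full = runner.test_variant(g, "v", tests=("constrained",))[0]
        g[:4] = np.nan
        partial = runner.test_variant(g, "v", tests=("constrained",))[0]
        assert partial.n == full.n  # imputation keeps everyone in
        assert partial.stat == pytest.approx(full.stat, abs=3.0)


class TestTally:
    def frame(self, ps, variant="v", test="constrained"):
        return pd.DataFrame({
            "variant": variant, "test": test, "p": ps,
            "replicate": np.arange(len(ps)),
        })

    def test_all_significant(self):
        t = tally_replicates(self.frame([1e-10] * 200))
        row = t.iloc[0]
        assert (row["n_p_lt_0.001"], row["n_p_lt_5e-05"],
                row["n_p_lt_5e-09"]) == (200, 200, 200)

    def test_tie_not_counted(self):
        t = tally_replicates(self.frame([1e-3, 5e-5, 5e-9]),
                             thresholds=(1e-3, 5e-5, 5e-9))
        row = t.iloc[0]
        assert row["n_p_lt_0.001"] == 2   # 5e-5 and 5e-9 only
        assert row["n_p_lt_5e-05"] == 1
        assert row["n_p_lt_5e-09"] == 0

    def test_missing_cells_warn(self):
        f1 = self.frame([1e-10] * 3)
        f2 = self.frame([1e-10] * 2, variant="w")
        with pytest.warns(UserWarning, match="non-significant"):
            t = tally_replicates(pd.concat([f1, f2], ignore_index=True))
        w = t[t["variant"] == "w"].iloc[0]
        assert w["n_p_lt_0.001"] == 2
        assert w["n_replicates"] == 3
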