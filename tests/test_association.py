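"""Likelihood-ratio association machinery and q-value FDR control."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from srnavar.association import (arm_analysis, cis_eqtl_scan,
                                 encode_covariates, group_contrast,
                                 lrt_linear, phenotype_assoc, qvalues)


class TestLrtLinear:
    def test_orthogonal_predictor_null_stat(self, rng):
        y = rng.normal(size=50)
        x = rng.normal(size=50)
        x -= x @ y / (y @ y) * y            # orthogonalise
        stat, p, _ = lrt_linear(y, x)
        assert stat < 3.0 and p > 0.05

    def test_perfect_fit_caps_p(self):
        x = np.arange(30, dtype=float)
        stat, p, sign = lrt_linear(x.copy(), x)
        assert stat > 1e3 and p <= 1e-300 and sign == 1.0

    def test_matches_statsmodels_loglikelihood(self, rng):
        import statsmodels.api as sm
        n = 80
        cov = np.column_stack([np.ones(n), rng.normal(size=n)])
        x = rng.normal(size=n)
        y = 0.4 * x + 0.3 * cov[:, 1] + rng.normal(size=n)
        stat, _, _ = lrt_linear(y, x, cov)
        null = sm.OLS(y, cov).fit()
        full = sm.OLS(y, np.column_stack([cov, x])).fit()
        assert stat == pytest.approx(2 * (full.llf - null.llf), abs=1e-9)

    def test_asymptotic_agreement_with_f_test(self, rng):
        """For n >= 50 the chi-squared LRT p and the exact F-test p agree
        within 10% relative."""
        import statsmodels.api as sm
        n = 200
        for _ in range(5):
            x = rng.normal(size=n)
            y = 0.25 * x + rng.normal(size=n)
            stat, p, _ = lrt_linear(y, x)
            full = sm.OLS(y, np.column_stack([np.ones(n), x])).fit()
            p_f = float(full.f_pvalue)
            if p_f < 1e-12:
                continue
            assert abs(np.log(p) - np.log(p_f)) < 0.1 * abs(np.log(p_f)) + 0.05

    def test_orthogonal_covariate_invariance(self, rng):
        n = 60
        y = rng.normal(size=n)
        x = rng.normal(size=n)
        base = np.ones((n, 1))
        stat0, _, _ = lrt_linear(y, x, base)
        extra = rng.normal(size=n)
        # orthogonalise the extra covariate against intercept, x and y
        M = np.column_stack([np.ones(n), x, y])
        extra -= M @ np.linalg.lstsq(M, extra, rcond=None)[0]
        stat1, _, _ = lrt_linear(y, x, np.column_stack([base, extra]))
        assert abs(stat1 - stat0) < 1e-8

    def test_collinear_predictor_rejected(self, rng):
        n = 40
        cov = np.column_stack([np.ones(n), rng.normal(size=n)])
        with pytest.raises(ValueError):
            lrt_linear(rng.normal(size=n), cov[:, 1].copy(), cov)

    def test_null_pvalues_uniform(self, rng):
        ps = []
        n = 60
        for _ in range(2000):
            y = rng.normal(size=n)
            x = rng.normal(size=n)
            _, p, _ = lrt_linear(y, x)
            ps.append(p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestQvalues:
    def test_all_ones(self):
        assert np.allclose(qvalues(np.ones(50)), 1.0)

    def test_bh_equivalence_with_pi0_one(self, rng):
        p = np.concatenate([np.full(10, 1e-3), rng.uniform(size=990)])
        q = qvalues(p, pi0=1.0)
        bh = stats.false_discovery_control(p, method="bh")
        assert np.allclose(q, bh, atol=1e-12)

    def test_textbook_oracle_equivalence(self, rng):
        """Storey q-values match an independent loop-based implementation."""
        p = rng.uniform(size=1000)

        def oracle(pvals, pi0):
            m = len(pvals)
            order = np.argsort(pvals)
            q = np.empty(m)
            prev = 1.0
            for rank_from_top in range(m, 0, -1):
                i = order[rank_from_top - 1]
                val = min(pi0 * m * pvals[i] / rank_from_top, prev)
                q[i] = val
                prev = val
            return q

        for pi0 in (1.0, 0.7):
            assert np.allclose(qvalues(p, pi0=pi0), oracle(p, pi0),
                               atol=1e-10)

    def test_monotone_in_p(self, rng):
        p = rng.uniform(size=500)
        q = qvalues(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_pi0_estimate_reasonable_under_null(self, rng):
        q = qvalues(rng.uniform(size=5000))
        assert q.min() > 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            qvalues([])


def _cohort(rng, n=60, maf=0.3, beta=0.0):
    samples = [f"s{i}" for i in range(n)]
    g = rng.binomial(2, maf, size=n).astype(float)
    geno = pd.DataFrame({"snp1": g, "far": rng.binomial(2, 0.4, n).astype(float)},
                        index=samples).T
    info = pd.DataFrame({"chrom": ["c", "c"], "pos": [1000, 500_000],
                         "maf": [maf, 0.4], "info": [0.99, 0.99]},
                        index=["snp1", "far"])
    expr = pd.DataFrame(
        {"rna1": beta * g + rng.normal(size=n)}, index=samples).T
    ann = pd.DataFrame({"chrom": ["c"], "start": [2000], "end": [2100]},
                       index=["rna1"])
    return expr, geno, info, ann


class TestCisEqtlScan:
    def test_window_boundary(self, rng):
        expr, geno, info, ann = _cohort(rng)
        info.loc["far", "pos"] = 2100 + 100_001
        res = cis_eqtl_scan(expr, geno, info, ann)
        assert set(res["predictor"]) == {"snp1"}
        info.loc["far", "pos"] = 2100 + 100_000
        res = cis_eqtl_scan(expr, geno, info, ann)
        assert set(res["predictor"]) == {"snp1", "far"}

    def test_maf_and_info_filters(self, rng):
        expr, geno, info, ann = _cohort(rng)
        info.loc["snp1", "maf"] = 0.04
        res = cis_eqtl_scan(expr, geno, info, ann)
        assert "snp1" not in set(res["predictor"])
        info.loc["snp1", "maf"] = 0.3
        info.loc["snp1", "info"] = 0.79
        res = cis_eqtl_scan(expr, geno, info, ann)
        assert "snp1" not in set(res["predictor"])

    def test_planted_effect_recovered(self, rng):
        expr, geno, info, ann = _cohort(rng, n=100, beta=1.0)
        res = cis_eqtl_scan(expr, geno, info, ann)
        top = res.iloc[0]
        assert top["predictor"] == "snp1" and top["q"] < 0.05
        assert top["sign"] == 1.0

    def test_unannotated_rna_skipped_with_warning(self, rng):
        expr, geno, info, ann = _cohort(rng)
        expr.loc["mystery"] = rng.normal(size=expr.shape[1])
        with pytest.warns(UserWarning):
            res = cis_eqtl_scan(expr, geno, info, ann)
        assert "mystery" not in set(res["feature"])


class TestPhenotypeAssoc:
    def make(self, rng, n=80, beta=2.0):
        samples = [f"s{i}" for i in range(n)]
        expr = pd.DataFrame(rng.normal(size=(5, n)),
                            index=[f"r{i}" for i in range(5)], columns=samples)
        pheno = pd.DataFrame({
            "bmi": 27 + beta * expr.loc["r0"] + rng.normal(0, 1, n),
            "insulin": rng.uniform(5, 60, size=n),
        }, index=samples)
        return expr, pheno

    def test_planted_link_detected(self, rng):
        expr, pheno = self.make(rng)
        out = phenotype_assoc(expr, pheno)
        bmi = out["bmi"].set_index("feature")
        assert bmi.loc["r0", "q"] < 0.05

    def test_insulin_floor_applied(self, rng):
        expr, pheno = self.make(rng)
        pheno.loc[pheno.index[:5], "insulin"] = 1.0
        out = phenotype_assoc(expr, pheno)
        assert "insulin" in out      # floored values enter the test unchanged

    def test_constant_trait_rejected(self, rng):
        expr, pheno = self.make(rng)
        pheno["glucose"] = 5.0
        with pytest.raises(ValueError):
            phenotype_assoc(expr, pheno)

    def test_permuted_phenotype_calibrated(self, rng):
        n = 60
        samples = [f"s{i}" for i in range(n)]
        expr = pd.DataFrame(rng.normal(size=(200, n)), columns=samples)
        pheno = pd.DataFrame({"bmi": rng.normal(27, 4, n)}, index=samples)
        out = phenotype_assoc(expr, pheno)["bmi"]
        frac = (out["p"] < 0.05).mean()
        assert frac == pytest.approx(0.05, abs=0.05)


class TestGroupContrast:
    def make(self, rng, n=80, shift=0.0):
        samples = [f"s{i}" for i in range(n)]
        bmi = pd.Series(rng.uniform(18, 40, size=n), index=samples)
        expr = pd.DataFrame(rng.normal(size=(4, n)), columns=samples)
        expr.iloc[0] += shift * (bmi > 30).to_numpy()
        return expr, bmi

    def test_boundary_bmi_excluded(self, rng):
        expr, bmi = self.make(rng)
        bmi.iloc[0] = 25.0
        bmi.iloc[1] = 30.0
        table = group_contrast(expr, bmi)
        n_used = (bmi < 25).sum() + (bmi > 30).sum()
        assert table.attrs.get("n_samples", n_used) == n_used

    def test_large_shift_significant(self, rng):
        expr, bmi = self.make(rng, shift=3.0)
        table = group_contrast(expr, bmi).set_index("feature")
        assert table.loc[0, "q"] < 0.05

    def test_identical_groups_null(self, rng):
        expr, bmi = self.make(rng)
        table = group_contrast(expr, bmi)
        assert (table["p"] > 0.01).all()

    def test_empty_group_rejected(self, rng):
        expr, bmi = self.make(rng)
        with pytest.raises(ValueError):
            group_contrast(expr, bmi + 50)


class TestArmAnalysis:
    def test_shifted_arm_perfect_rho(self, rng):
        samples = [f"s{i}" for i in range(30)]
        mature = pd.DataFrame(rng.normal(size=(3, 30)),
                              index=["m1", "m2", "m3"], columns=samples)
        star = mature + 2.0
        corr, _ = arm_analysis(mature, star)
        assert np.allclose(corr["rho"], 1.0)
        assert corr["significant"].all()

    def test_independent_arms_null_tail(self, rng):
        n = 131
        samples = [f"s{i}" for i in range(n)]
        mature = pd.DataFrame(rng.normal(size=(300, n)), columns=samples)
        star = pd.DataFrame(rng.normal(size=(300, n)),
                            index=mature.index, columns=samples)
        corr, _ = arm_analysis(mature, star)
        # analytic Spearman null tail for |rho| > 0.4 at n=131 is ~0
        assert corr["significant"].mean() < 0.02

    def test_planted_arm_choice_snp(self, rng):
        n = 100
        samples = [f"s{i}" for i in range(n)]
        g = rng.binomial(2, 0.3, size=n).astype(float)
        base = rng.normal(size=n)
        mature = pd.DataFrame({"mir": base + 0.6 * g}, index=samples).T
        star = pd.DataFrame({"mir": base - 0.6 * g + rng.normal(0, 0.5, n)},
                            index=samples).T
        geno = pd.DataFrame({"snp": g}, index=samples).T
        info = pd.DataFrame({"chrom": ["c"], "pos": [1500], "maf": [0.3],
                             "info": [0.99]}, index=["snp"])
        ann = pd.DataFrame({"chrom": ["c"], "start": [1000], "end": [1100]},
                           index=["mir"])
        corr, qtl = arm_analysis(mature, star, geno, info, ann)
        assert qtl.iloc[0]["predictor"] == "snp"
        assert qtl.iloc[0]["q"] < 0.05

    def test_zero_arm_skipped(self):
        samples = ["s1", "s2", "s3"]
        mature = pd.DataFrame({"m": [1.0, 2.0, 3.0]}, index=samples).T
        star = pd.DataFrame({"m": [0.0, 0.0, 0.0]}, index=samples).T
        corr, _ = arm_analysis(mature, star)
        assert corr.empty


def test_encode_covariates_one_hot():
    cov = pd.DataFrame({"age": [40.0, 50.0, 60.0],
                        "batch": ["B1", "B2", "B1"]},
                       index=["s1", "s2", "s3"])
    X = encode_covariates(cov, index=["s1", "s2", "s3"])
    assert X.shape == (3, 3)           # intercept + age + one batch dummy
    assert np.allclose(X[:, 0], 1.0)
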