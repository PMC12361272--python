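"""QC filters, the Hardy-Weinberg exact test against brute-force
enumeration, logistic association against closed forms, covariate
screening, genomic inflation and fixed-effect meta-analysis."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import comb

import grskit as gk
from grskit.assoc import QCThresholds
from grskit.genotypes import GenotypeMatrix, Variant


def hwe_enumeration_oracle(n_aa, n_ab, n_bb):
    """Brute-force conditional HWE p: enumerate every heterozygote count
    consistent with the allele counts using exact binomial coefficients."""
    n = n_aa + n_ab + n_bb
    na = 2 * n_aa + n_ab
    probs = {}
    for het in range(min(na, 2 * n - na) + 1):
        if (na - het) % 2:
            continue
        aa = (na - het) // 2
        bb = n - aa - het
        if bb < 0:
            continue
        probs[het] = comb(n, aa, exact=True) * comb(n - aa, het, exact=True) * 2**het
    tot = sum(probs.values())
    p_obs = probs[n_ab]
    return sum(v for v in probs.values() if v <= p_obs) / tot


def _geno(cols: dict[str, np.ndarray]) -> GenotypeMatrix:
    ids = list(cols)
    mat = np.column_stack([cols[i] for i in ids])
    return GenotypeMatrix(
        [Variant(i, pos=k + 1) for k, i in enumerate(ids)],
        [f"i{j}" for j in range(mat.shape[0])],
        mat,
    )


class TestHWE:
    def test_monomorphic_p_is_one(self):
        assert gk.hwe_exact_test(0, 0, 50) == 1.0
        assert gk.hwe_exact_test(50, 0, 0) == 1.0

    @pytest.mark.parametrize("counts", [(3, 4, 3), (5, 0, 5), (10, 20, 10), (1, 8, 1)])
    def test_matches_enumeration(self, counts):
        assert gk.hwe_exact_test(*counts) == pytest.approx(
            hwe_enumeration_oracle(*counts), rel=1e-10
        )

    def test_label_symmetry(self, rng):
        for _ in range(20):
            a, b, c = rng.integers(0, 40, 3)
            if a + b + c == 0:
                continue
            assert gk.hwe_exact_test(a, b, c) == pytest.approx(
                gk.hwe_exact_test(c, b, a), rel=1e-12
            )

    def test_extreme_het_deficit_fails_threshold(self):
        # AA=50, Aa=0, aa=50: maximal departure, p far below 1e-4
        p = gk.hwe_exact_test(50, 0, 50)
        assert p == pytest.approx(hwe_enumeration_oracle(50, 0, 50), rel=1e-10)
        assert p < 1e-4

    def test_bad_input_rejected(self):
        with pytest.raises(ValueError):
            gk.hwe_exact_test(0, 0, 0)
        with pytest.raises(ValueError):
            gk.hwe_exact_test(-1, 2, 3)


class TestSnpQC:
    def test_reasons_assigned(self, rng):
        n = 200
        good = rng.binomial(2, 0.3, n).astype(float)
        mono = np.zeros(n)
        rare = rng.binomial(2, 0.01, n).astype(float)
        rare[0] = 1  # not monomorphic
        missing = good.copy()
        missing[: int(0.06 * n)] = np.nan
        hwe_bad = np.r_[np.zeros(n // 2), np.full(n // 2, 2.0)]
        geno = _geno({"good": good, "mono": mono, "rare": rare,
                      "miss": missing, "hwe": hwe_bad})
        rep = gk.snp_qc(geno)
        t = rep.table
        assert t.loc["good", "kept"]
        assert t.loc["mono", "reasons"] == "monomorphic"
        assert "low_maf" in t.loc["rare", "reasons"]
        assert "high_missing" in t.loc["miss", "reasons"]
        assert "hwe_fail" in t.loc["hwe", "reasons"]
        # a variant is kept iff it has no failure reasons
        assert (t["kept"] == (t["reasons"] == "")).all()

    def test_hwe_in_controls_only(self, rng):
        n = 400
        y = np.r_[np.ones(200), np.zeros(200)]
        col = np.empty(n)
        col[:200] = np.r_[np.zeros(100), np.full(100, 2.0)]  # cases wildly out of HWE
        col[200:] = rng.binomial(2, 0.5, 200)                # controls in HWE
        geno = _geno({"snp": col})
        rep = gk.snp_qc(geno, phenotype=y)
        assert "hwe_fail" not in rep.table.loc["snp", "reasons"]

    def test_disabled_thresholds_identity_on_polymorphic_data(self, rng):
        geno = _geno({f"s{i}": rng.binomial(2, 0.3, 100).astype(float) for i in range(5)})
        rep = gk.snp_qc(geno, thresholds=QCThresholds(maf=0.0, hwe_p=0.0, missing=1.0))
        assert rep.table["kept"].all()

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            gk.snp_qc(GenotypeMatrix([], [], np.empty((0, 0))))


class TestFitLogistic:
    def test_binary_predictor_matches_contingency_table(self, rng):
        """For a 0/2-coded predictor, beta equals ln(2x2 odds ratio)/2."""
        n = 2000
        x = rng.choice([0.0, 2.0], n)
        y = (rng.random(n) < np.where(x > 0, 0.6, 0.4)).astype(int)
        a = ((y == 1) & (x == 2)).sum()
        b = ((y == 0) & (x == 2)).sum()
        c = ((y == 1) & (x == 0)).sum()
        d = ((y == 0) & (x == 0)).sum()
        oracle = np.log(a * d / (b * c)) / 2
        fit = gk.fit_logistic(y, pd.DataFrame({"x": x}))
        assert fit.ok
        assert fit.table.loc["x", "beta"] == pytest.approx(oracle, abs=1e-6)

    def test_perfect_separation_flagged(self):
        y = np.r_[np.ones(20), np.zeros(20)]
        x = np.r_[np.full(20, 2.0), np.zeros(20)]
        fit = gk.fit_logistic(y, pd.DataFrame({"x": x}))
        assert not fit.ok
        assert fit.table is None

    def test_constant_predictor_rejected(self):
        y = np.r_[np.ones(5), np.zeros(5)]
        with pytest.raises(ValueError, match="constant"):
            gk.fit_logistic(y, pd.DataFrame({"x": np.ones(10)}))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            gk.fit_logistic(np.ones(10), pd.DataFrame({"x": np.arange(10.0)}))


class TestScreenCovariates:
    def test_constant_never_selected(self, rng):
        y = rng.integers(0, 2, 100)
        y[:2] = [0, 1]
        cov = pd.DataFrame({"const": np.ones(100), "noise": rng.standard_normal(100)})
        assert "const" not in gk.screen_covariates(y, cov)

    def test_covariate_equal_to_outcome_excluded_with_warning(self, rng):
        y = np.r_[np.ones(50), np.zeros(50)].astype(int)
        cov = pd.DataFrame({"leak": y.astype(float)})
        with pytest.warns(UserWarning, match="leak"):
            sel = gk.screen_covariates(y, cov)
        assert sel == []

    def test_planted_group_shift_selected(self, rng):
        """A PC shifted by 1 SD between groups at n=2000 is detected in
        every tried seed (power is essentially 1)."""
        for seed in range(10):
            r = np.random.default_rng(seed)
            y = np.r_[np.ones(1000), np.zeros(1000)].astype(int)
            pc = r.standard_normal(2000) + y  # Delta = 1 SD
            cov = pd.DataFrame({"PC1": pc, "noise": r.standard_normal(2000)})
            assert "PC1" in gk.screen_covariates(y, cov)


class TestRunGwas:
    def test_duplicate_variant_identical_result(self, rng):
        n = 500
        x = rng.binomial(2, 0.3, n).astype(float)
        y = rng.integers(0, 2, n)
        y[:2] = [0, 1]
        geno = _geno({"a": x, "b": x.copy()})
        res = {r.id: r for r in gk.run_gwas(geno, y)}
        assert res["a"].beta == pytest.approx(res["b"].beta, rel=1e-12)
        assert res["a"].p == pytest.approx(res["b"].p, rel=1e-12)

    def test_null_snps_within_three_se(self, rng):
        """Null betas fall within 3 SE in ~99.7% of variants."""
        n, m = 1500, 100
        y = np.r_[np.ones(n // 2), np.zeros(n // 2)].astype(int)
        geno = _geno({f"s{i}": rng.binomial(2, 0.3, n).astype(float) for i in range(m)})
        res = [r for r in gk.run_gwas(geno, y) if r.ok]
        within = sum(abs(r.beta) < 3 * r.se for r in res)
        assert within >= 95

    def test_or_and_ci_consistent(self, small_cohort):
        res = gk.run_gwas(small_cohort.genotypes, small_cohort.phenotype)
        for r in res:
            if not r.ok:
                continue
            assert r.odds_ratio == pytest.approx(np.exp(r.beta), rel=1e-12)
            lo, hi = r.ci95
            assert lo < r.odds_ratio < hi
            np.testing.assert_allclose(
                [lo, hi], np.exp([r.beta - 1.96 * r.se, r.beta + 1.96 * r.se]), rtol=1e-3
            )

    def test_mean_imputation_keeps_sample_size(self, rng):
        n = 300
        col = rng.binomial(2, 0.4, n).astype(float)
        col[:30] = np.nan
        y = rng.integers(0, 2, n)
        y[:2] = [0, 1]
        (res,) = gk.run_gwas(_geno({"s": col}), y)
        assert res.n_used == n


class TestGenomicInflation:
    def test_all_half_gives_unity(self):
        assert gk.genomic_inflation([0.5] * 101) == pytest.approx(1.0, abs=1e-12)

    def test_null_uniform_near_one(self, rng):
        lam = gk.genomic_inflation(rng.uniform(size=100_000))
        assert 0.95 < lam < 1.05

    def test_linearity_in_chi2(self, rng):
        chi2 = stats.chi2.rvs(1, size=1001, random_state=7)
        lam1 = gk.genomic_inflation(stats.chi2.sf(chi2, 1))
        lam2 = gk.genomic_inflation(stats.chi2.sf(chi2 / 2, 1))
        assert lam2 == pytest.approx(lam1 / 2, rel=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            gk.genomic_inflation([])


def _assoc(id="rs1", beta=0.2, se=0.1, a1="A", a2="G"):
    return gk.AssociationResult(id, beta, se, 0.05, 0.3, 1000, a1, a2)


class TestMetaFixed:
    def test_identical_cohorts_halve_variance(self):
        m = gk.meta_fixed([_assoc(), _assoc()])
        assert m.beta == pytest.approx(0.2)
        assert m.se == pytest.approx(0.1 / np.sqrt(2), rel=1e-12)

    def test_infinite_variance_cohort_ignored_in_limit(self):
        m = gk.meta_fixed([_assoc(beta=0.3, se=0.05), _assoc(beta=-5.0, se=1e6)])
        assert m.beta == pytest.approx(0.3, abs=1e-6)
        assert m.se == pytest.approx(0.05, rel=1e-6)

    def test_three_cohort_hand_arithmetic(self):
        # weights 1/se^2: 100, 25, 4  -> beta = (100*.1+25*.4+4*(-.2))/129
        rs = [_assoc(beta=0.1, se=0.1), _assoc(beta=0.4, se=0.2), _assoc(beta=-0.2, se=0.5)]
        m = gk.meta_fixed(rs)
        assert m.beta == pytest.approx((100 * 0.1 + 25 * 0.4 + 4 * -0.2) / 129, rel=1e-12)
        assert m.se == pytest.approx(1 / np.sqrt(129), rel=1e-12)
        assert m.se <= min(r.se for r in rs)

    def test_allele_swap_flips_sign(self):
        m = gk.meta_fixed([_assoc(beta=0.2), _assoc(beta=-0.2, a1="G", a2="A")])
        assert m.beta == pytest.approx(0.2)

    def test_allele_mismatch_rejected(self):
        with pytest.raises(ValueError, match="incompatible"):
            gk.meta_fixed([_assoc(), _assoc(a1="T", a2="C")])

    def test_single_cohort_rejected(self):
        with pytest.raises(ValueError):
            gk.meta_fixed([_assoc()])
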