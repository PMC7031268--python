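"""Mixed-model association scan: null model, class tests, FDR and the
additive/dominance decomposition."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import domvar
from domvar.scan import (
    EigenRelMatrix,
    ad_decompose,
    dominance_ratio,
    fdr_qvalues,
    fit_null,
    run_scan,
    scan_snp,
    snp_variance_explained,
)


@pytest.fixture(scope="module")
def related_design():
    """Pedigree cohort with genotypes and a polygenic phenotype."""
    ped = domvar.simulate_pedigree(120, 2, 8, 3, seed=61)
    rng = np.random.default_rng(62)
    g = domvar.gene_drop_genotypes(ped, founder_freqs=rng.uniform(0.15, 0.5, 300), seed=63)
    A = domvar.pedigree_a(ped)
    return ped, g, A


def _null_phenotype(ped, A, sg2, se2, seed):
    rng = np.random.default_rng(seed)
    u = domvar.simulate_polygenic(ped, sg2, seed=seed + 1).values
    return u + rng.normal(0, np.sqrt(se2), ped.n)


class TestFitNull:
    def test_recovers_polygenic_fraction(self, related_design):
        ped, g, A = related_design
        sg_hat, se_hat = [], []
        for r in range(10):
            y = _null_phenotype(ped, A, 1.0, 3.0, 100 + 10 * r)
            fit = fit_null(y, A)
            sg_hat.append(fit.sigma_g2)
            se_hat.append(fit.sigma_e2)
        assert np.mean(sg_hat) == pytest.approx(1.0, abs=0.35)
        assert np.mean(se_hat) == pytest.approx(3.0, abs=0.45)

    def test_identity_relationship_reduces_to_ols(self, related_design):
        ped, g, A = related_design
        rng = np.random.default_rng(7)
        y = rng.normal(0, 2.0, ped.n)
        fit = fit_null(y, np.eye(ped.n))
        assert fit.sigma_g2 + fit.sigma_e2 == pytest.approx(np.var(y, ddof=1), rel=0.01)

    def test_cached_gls_matches_dense_solver(self, related_design):
        """Rotated-basis per-SNP GLS against a direct dense V^-1 solve."""
        ped, g, A = related_design
        y = _null_phenotype(ped, A, 1.0, 3.0, 200)
        fit = fit_null(y, A)
        V = fit.sigma_g2 * A.values + fit.sigma_e2 * np.eye(ped.n)
        Vinv = np.linalg.inv(V)
        rng = np.random.default_rng(8)
        for j in rng.choice(g.n_snps, 50, replace=False):
            codes = g.codes[:, j]
            counts = np.array([(codes == k).sum() for k in (0, 1, 2)])
            if (counts > 0).sum() < 2:
                continue
            t = scan_snp(fit, codes)
            M = np.stack([(codes == k).astype(float) for k in (0, 1, 2)], axis=1)
            M = M[:, counts > 0]
            cov_dense = np.linalg.inv(M.T @ Vinv @ M)
            mu_dense = cov_dense @ (M.T @ Vinv @ y)
            np.testing.assert_allclose(t.means[t.observed], mu_dense, rtol=1e-6)
            np.testing.assert_allclose(t.cov, cov_dense, rtol=1e-6)


class TestStepOne:
    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(9)
        n, m = 400, 1000
        codes = rng.binomial(2, 0.3, size=(n, m)).astype(np.int8)
        snp_map = pd.DataFrame(
            {"snp": [f"s{j}" for j in range(m)], "chrom": "1", "cm": 0.0,
             "bp": np.arange(1, m + 1), "allele1": "A", "allele2": "B"}
        )
        g = domvar.GenotypeMatrix(codes, np.arange(n).astype(str), snp_map)
        y = rng.normal(0, 1, n)
        tab = run_scan(y, np.eye(n), g)
        ks = stats.kstest(tab["p"].to_numpy(), "uniform")
        assert ks.pvalue > 0.01

    def test_large_additive_effect_detected(self, related_design):
        ped, g, A = related_design
        rng = np.random.default_rng(10)
        y = _null_phenotype(ped, A, 1.0, 3.0, 300) + 1.5 * g.codes[:, 5]
        tab = run_scan(y, A, g)
        row = tab[tab["snp"] == g.snp_map.loc[5, "snp"]].iloc[0]
        assert row["p"] < 1e-6
        assert row["significant"]

    def test_permutation_breaks_association(self, related_design):
        ped, g, A = related_design
        rng = np.random.default_rng(11)
        y = _null_phenotype(ped, A, 1.0, 3.0, 400) + 1.0 * g.codes[:, 5]
        yp = rng.permutation(y)
        tab = run_scan(yp, np.eye(ped.n), g)
        # median of a central 2-df chi-square is 2 ln 2 = 1.386
        med = tab.loc[tab["df"] == 2, "chi2"].median()
        assert med == pytest.approx(1.386, abs=0.35)

    def test_type_one_error_with_relatedness(self, related_design):
        """2-df test calibration at alpha = 0.01 under polygenic structure."""
        ped, g, A = related_design
        eig = EigenRelMatrix(A)
        ps = []
        for r in range(4):
            y = _null_phenotype(ped, A, 1.0, 3.0, 500 + r)
            fit = fit_null(y, eig)
            tab = run_scan(y, eig, g, null_fit=fit)
            ps.append(tab.loc[tab["df"] == 2, "p"].to_numpy())
        ps = np.concatenate(ps)
        alpha_hat = (ps < 0.01).mean()
        se = np.sqrt(0.01 * 0.99 / len(ps))
        assert abs(alpha_hat - 0.01) < 3.5 * se

    def test_shift_and_relabel_invariance(self, related_design):
        ped, g, A = related_design
        y = _null_phenotype(ped, A, 1.0, 3.0, 600)
        fit = fit_null(y, A)
        fit2 = fit_null(y + 100.0, A)
        codes = g.codes[:, 3]
        t1 = scan_snp(fit, codes)
        t2 = scan_snp(fit2, codes)
        assert t1.chi2 == pytest.approx(t2.chi2, rel=1e-6)
        t3 = scan_snp(fit, 2 - codes)  # relabel alleles
        assert t3.chi2 == pytest.approx(t1.chi2, rel=1e-8)
        d1 = ad_decompose(t1.means, _full_cov(t1), ped.n - 3)
        d3 = ad_decompose(t3.means, _full_cov(t3), ped.n - 3)
        assert d3.a == pytest.approx(-d1.a)
        assert d3.d == pytest.approx(d1.d)


def _full_cov(t):
    cov = np.zeros((3, 3))
    cov[np.ix_(t.observed, t.observed)] = t.cov
    return cov


class TestFDR:
    def test_all_ones(self):
        np.testing.assert_allclose(fdr_qvalues(np.ones(10)), np.ones(10))

    def test_bh_hand_example(self):
        q = fdr_qvalues(np.array([0.01, 0.02, 0.03, 0.04]), method="bh")
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_storey_no_larger_than_bh_when_pi0_below_one(self):
        rng = np.random.default_rng(12)
        p = np.concatenate([rng.uniform(0, 1e-4, 60), rng.uniform(0, 1, 300)])
        qs = fdr_qvalues(p, method="storey")
        qb = fdr_qvalues(p, method="bh")
        assert (qs <= qb + 1e-12).all()
        assert (qs < qb).any()

    def test_qvalues_monotone_in_p(self):
        rng = np.random.default_rng(13)
        p = rng.uniform(0, 1, 500)
        q = fdr_qvalues(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_empty_input(self):
        assert fdr_qvalues(np.array([])).size == 0


class TestADDecomposition:
    @pytest.mark.parametrize(
        "means,a_exp,d_exp",
        [((10.0, 15.0, 20.0), 5.0, 0.0), ((0.0, 1.0, 0.0), 0.0, 1.0)],
    )
    def test_worked_examples(self, means, a_exp, d_exp):
        dec = ad_decompose(np.array(means), np.eye(3) * 0.01, df=100)
        assert dec.a == pytest.approx(a_exp)
        assert dec.d == pytest.approx(d_exp)

    def test_reported_dominance_ratio_range(self):
        # printed effect pairs reproduce the printed h = d/a range endpoints
        assert round(dominance_ratio(7.31, -9.15), 2) == -1.25
        assert round(dominance_ratio(-25.81, -25.15), 2) == 0.97

    def test_two_class_rejected(self):
        with pytest.raises(ValueError, match="three genotype classes"):
            ad_decompose(np.array([1.0, 2.0, np.nan]), np.eye(3), df=10)

    def test_reconstruction_identity(self, related_design):
        ped, g, A = related_design
        y = _null_phenotype(ped, A, 1.0, 3.0, 700) + 1.2 * (g.codes[:, 8] == 1)
        tab = run_scan(y, A, g, fdr=0.5)
        sig = tab[tab["d"].notna()]
        assert len(sig) > 0
        recon = sig["mu_Aa"] - 0.5 * (sig["mu_AA"] + sig["mu_aa"])
        np.testing.assert_allclose(recon, sig["d"], atol=1e-10)


class TestVarianceExplained:
    def test_pure_additive(self):
        va, vd = snp_variance_explained(0.3, 2.0, 0.0, Vp=1.0)
        assert va == pytest.approx(2 * 0.3 * 0.7 * 4.0)
        assert vd == 0.0

    def test_hand_arithmetic(self):
        va, vd = snp_variance_explained(0.5, 1.0, 1.0, Vp=1.0)
        assert va == pytest.approx(0.5)
        assert vd == pytest.approx(0.25)

    def test_reported_effect_pair(self):
        # a = 7.31, d = -9.15 at p = 0.11: raw V_A = 2 0.11 0.89 (7.31 + 0.78 (-9.15))^2
        va, _ = snp_variance_explained(0.11, 7.31, -9.15, Vp=1.0)
        assert va == pytest.approx(2 * 0.11 * 0.89 * (7.31 + 0.78 * -9.15) ** 2, rel=1e-10)
        assert va == pytest.approx(0.0059, abs=0.002)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            snp_variance_explained(0.3, 1.0, 0.0, Vp=0.0)
        with pytest.raises(ValueError):
            snp_variance_explained(0.0, 1.0, 0.0, Vp=1.0)


class TestRunScan:
    def test_null_simulation_fdr_control(self, related_design):
        ped, g, A = related_design
        hits = 0
        for r in range(3):
            y = _null_phenotype(ped, A, 1.0, 3.0, 800 + r)
            tab = run_scan(y, A, g)
            hits += int(tab["significant"].sum())
        assert hits <= 2

    def test_qtn_flagged_in_both_steps(self, related_design):
        ped, g, A = related_design
        codes = g.codes[:, 20]
        vals = np.array([-1.2, 1.2, 1.2])  # additive + dominant
        y = _null_phenotype(ped, A, 1.0, 3.0, 900) + vals[codes]
        tab = run_scan(y, A, g)
        row = tab[tab["snp"] == g.snp_map.loc[20, "snp"]].iloc[0]
        assert row["significant"]
        assert row["sig_additive"] and row["sig_dominance"]

    def test_row_count_equals_polymorphic_snps(self, related_design):
        ped, g, A = related_design
        codes = g.codes.copy()
        codes[:, 0] = 2  # monomorphic
        gm = domvar.GenotypeMatrix(codes, g.ids, g.snp_map)
        y = _null_phenotype(ped, A, 1.0, 3.0, 950)
        tab = run_scan(y, A, gm)
        n_poly = sum(len(np.unique(codes[:, j])) >= 2 for j in range(gm.n_snps))
        assert len(tab) == n_poly

    def test_two_class_snp_gets_1df_and_no_effects(self, related_design):
        ped, g, A = related_design
        codes = g.codes.copy()
        codes[:, 1] = np.where(codes[:, 1] == 2, 1, codes[:, 1])  # only 2 classes
        gm = domvar.GenotypeMatrix(codes, g.ids, g.snp_map)
        y = _null_phenotype(ped, A, 1.0, 3.0, 960) + 2.0 * codes[:, 1]
        tab = run_scan(y, A, gm)
        row = tab[tab["snp"] == gm.snp_map.loc[1, "snp"]].iloc[0]
        assert row["two_class"] and row["df"] == 1
        assert np.isnan(row["d"])

    def test_exact_mode_close_to_cached(self, related_design):
        ped, g, A = related_design
        y = _null_phenotype(ped, A, 1.0, 3.0, 970) + 0.8 * g.codes[:, 4]
        sub = g.take_snps(np.arange(30))
        fast = run_scan(y, A, sub)
        exact = run_scan(y, A, sub, exact=True)
        causal = fast["snp"] == sub.snp_map.loc[4, "snp"]
        np.testing.assert_allclose(
            fast.loc[~causal, "chi2"], exact.loc[~causal, "chi2"], rtol=0.05, atol=0.05
        )
        # with the causal SNP in the model the exact refit shrinks the
        # residual, so the fixed-null approximation is conservative there
        assert exact.loc[causal, "chi2"].iloc[0] >= fast.loc[causal, "chi2"].iloc[0]


class TestWeightedScan:
    def test_unit_weights_match_unweighted(self, related_design):
        ped, g, A = related_design
        y = _null_phenotype(ped, A, 1.0, 3.0, 980)
        t1 = run_scan(y, A, g.take_snps(np.arange(25)))
        t2 = run_scan(y, A, g.take_snps(np.arange(25)), weights=np.ones(ped.n))
        np.testing.assert_allclose(t1["chi2"], t2["chi2"], rtol=1e-6)

    def test_heteroscedastic_weights_accepted(self, related_design):
        ped, g, A = related_design
        rng = np.random.default_rng(99)
        w = rng.choice([0.5, 1.0, 1.5], ped.n)
        w = w / w.mean()
        u = domvar.simulate_polygenic(ped, 1.0, seed=981).values
        y = u + rng.normal(0, np.sqrt(3.0 / w))
        tab = run_scan(y, A, g.take_snps(np.arange(25)), weights=w)
        assert len(tab) > 0
        assert tab["p"].between(0, 1).all()
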