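"""Mixed-model association scan with genotype-class effects and a two-step
additive/dominance decomposition.

Model per SNP: ``y_c = M g + Z u + e`` with ``u ~ N(0, sigma_g^2 A)`` and
``e ~ N(0, sigma_e^2 W)``; ``M`` codes the three genotype classes (AA, Aa,
aa) as fixed effects.  Variance components are estimated once under the
no-SNP null model and held fixed across SNPs (EMMAX-style), which a single
eigendecomposition of ``A`` turns into O(n) generalized least squares per
SNP; an exact mode re-profiles the variance ratio per SNP for spot checks.

Step 1 tests the 2-df null ``mu_AA = mu_Aa = mu_aa`` (Wald chi-square) and
controls the FDR with Storey q-values (Benjamini-Hochberg optional); step 2
decomposes significant SNPs into the additive effect
``a = (mu_aa - mu_AA)/2`` and dominance effect
``d = mu_Aa - (mu_aa + mu_AA)/2`` with t-tests, and reports the variance
explained ``2p(1-p)[a + (1-2p)d]^2`` (additive) and ``[2p(1-p)d]^2``
(dominance) as fractions of the phenotypic variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats
from statsmodels.stats.multitest import multipletests

from .grm import RelMatrix
from .io import MISSING, GenotypeMatrix

__all__ = [
    "EigenRelMatrix",
    "RotatedGenotypes",
    "NullModelFit",
    "fit_null",
    "scan_snp",
    "ad_decompose",
    "snp_variance_explained",
    "dominance_ratio",
    "fdr_qvalues",
    "run_scan",
]


# ------------------------------------------------------------- factorizations
class EigenRelMatrix:
    """Eigendecomposition cache of a relationship matrix.

    Computing ``A = U diag(lam) U'`` once lets every subsequent REML profile
    and per-SNP GLS run in the rotated (independent-errors) basis.  Small
    negative eigenvalues from finite precision are clipped at zero.
    """

    def __init__(self, K):
        if isinstance(K, RelMatrix):
            self.ids = K.ids
            K = K.values
        else:
            self.ids = None
        K = np.asarray(K, dtype=np.float64)
        lam, U = linalg.eigh(K)
        self.lam = np.clip(lam, 0.0, None)
        self.U = U
        self.n = K.shape[0]
        self._Ut1 = U.T @ np.ones(self.n)

    def rotate(self, v: np.ndarray) -> np.ndarray:
        return self.U.T @ v


class RotatedGenotypes:
    """Genotype-class indicators pre-rotated by ``U'`` for a fixed panel.

    For each SNP the three class-indicator columns are rotated once; the
    per-replicate scan then only needs 3x3 weighted Gram matrices.  Missing
    calls are dropped from all classes (the SNP's sample size shrinks).
    """

    def __init__(self, eig: EigenRelMatrix, g: GenotypeMatrix):
        codes = g.codes
        if codes.shape[0] != eig.n:
            raise ValueError("genotype rows do not match relationship matrix")
        self.g = g
        self.eig = eig
        n, m = codes.shape
        C = np.empty((n, 3 * m))
        for k in (0, 1, 2):
            C[:, k::3] = codes == k
        R = eig.U.T @ C
        self.M = np.ascontiguousarray(R.reshape(eig.n, m, 3).transpose(1, 0, 2))
        self.counts = np.stack([(codes == k).sum(axis=0) for k in (0, 1, 2)], axis=1)
        self.n_classes = (self.counts > 0).sum(axis=1)
        self.n_obs = self.counts.sum(axis=1)


# ------------------------------------------------------------------ null fit
@dataclass
class NullModelFit:
    """Variance components of ``y = 1 mu + u + e`` plus the reusable rotation."""

    eig: EigenRelMatrix
    sigma_g2: float
    sigma_e2: float
    loglik: float
    y: np.ndarray
    ry: np.ndarray  # U'y
    weights_: np.ndarray = field(repr=False)  # 1/(sigma_g2 lam + sigma_e2)
    mu: float = 0.0

    @property
    def n(self) -> int:
        return self.eig.n


def _profile_reml_1d(ry, rx, lam, n):
    """Restricted log-likelihood profiled over the total scale.

    For ``V = sigma^2 (lam + delta)`` with delta = sigma_e^2/sigma_g^2 the
    scale has a closed form; the returned function evaluates the profiled
    criterion at log10(delta).
    """
    p = rx.shape[1]

    def crit(log_delta):
        delta = 10.0**log_delta
        v = lam + delta
        w = 1.0 / v
        xtwx = (rx * w[:, None]).T @ rx
        xtwy = (rx * w[:, None]).T @ ry
        try:
            beta = np.linalg.solve(xtwx, xtwy)
        except np.linalg.LinAlgError:
            return np.inf
        r = ry - rx @ beta
        rss = float(r * w @ r)
        sign, logdet_x = np.linalg.slogdet(xtwx)
        if sign <= 0 or rss <= 0:
            return np.inf
        ll = -0.5 * (
            (n - p) * np.log(rss / (n - p))
            + np.sum(np.log(v))
            + logdet_x
            + (n - p)
        )
        return -ll

    return crit


def fit_null(y_c, A, weights=None) -> NullModelFit:
    """REML fit of the polygenic null model, caching the eigenrotation.

    ``A`` may be a dense matrix, a :class:`~domvar.grm.RelMatrix` or an
    already-built :class:`EigenRelMatrix` (reused across replicates).
    ``weights`` are the standardized residual weights ``w*`` (heifer traits:
    None = identity); with weights the model is pre-whitened by
    ``sqrt(w*)``, so ``A`` must then be raw (not pre-factorized).
    """
    y = np.asarray(y_c, dtype=np.float64).ravel()
    if weights is not None:
        if isinstance(A, EigenRelMatrix):
            raise ValueError("pass the raw relationship matrix when using weights")
        s = np.sqrt(np.asarray(weights, dtype=np.float64))
        Av = A.values if isinstance(A, RelMatrix) else np.asarray(A)
        A = EigenRelMatrix(s[:, None] * Av * s[None, :])
        y = s * y
        ones = s.copy()
    else:
        if not isinstance(A, EigenRelMatrix):
            A = EigenRelMatrix(A)
        ones = np.ones(A.n)
    eig = A
    if y.size != eig.n:
        raise ValueError("phenotype length does not match relationship matrix")
    ry = eig.rotate(y)
    rx = eig.rotate(ones)[:, None]
    n = eig.n

    crit = _profile_reml_1d(ry, rx, eig.lam, n)
    grid = np.linspace(-4, 6, 26)
    vals = [crit(g) for g in grid]
    g0 = grid[int(np.argmin(vals))]
    res = optimize.minimize_scalar(
        crit, bounds=(g0 - 1.0, g0 + 1.0), method="bounded",
        options={"xatol": 1e-6},
    )
    if not np.isfinite(res.fun):
        raise RuntimeError("null-model REML failed to converge")
    delta = 10.0**res.x
    v = eig.lam + delta
    w = 1.0 / v
    xtwx = (rx * w[:, None]).T @ rx
    beta = np.linalg.solve(xtwx, (rx * w[:, None]).T @ ry)
    r = ry - rx @ beta
    sigma_g2 = float(r * w @ r) / (n - rx.shape[1])
    sigma_e2 = sigma_g2 * delta
    return NullModelFit(
        eig=eig,
        sigma_g2=sigma_g2,
        sigma_e2=sigma_e2,
        loglik=-float(res.fun),
        y=y,
        ry=ry,
        weights_=w / sigma_g2,
        mu=float(beta[0]),
    )


# ----------------------------------------------------------------- snp tests
@dataclass
class SnpTest:
    """Genotype-class GLS estimates and the step-1 test for one SNP."""

    counts: np.ndarray
    means: np.ndarray  # NaN for unobserved classes
    cov: np.ndarray  # covariance of observed class means (k x k)
    observed: np.ndarray  # bool mask of observed classes
    chi2: float
    df: int
    p: float


_L_FULL = np.array([[1.0, -1.0, 0.0], [0.0, 1.0, -1.0]])


def _class_test(G3, b3, counts, w=None):
    """GLS class means + Wald homogeneity test from 3x3 normal equations."""
    obs = counts > 0
    k = int(obs.sum())
    means = np.full(3, np.nan)
    if k < 2:
        return None
    Gs = G3[np.ix_(obs, obs)]
    bs = b3[obs]
    try:
        cov = np.linalg.inv(Gs)
    except np.linalg.LinAlgError:
        return None
    mu = cov @ bs
    means[obs] = mu
    # contrasts between successive observed classes
    L = np.eye(k)[: k - 1] - np.eye(k)[1:k]
    delta = L @ mu
    try:
        chi2 = float(delta @ np.linalg.solve(L @ cov @ L.T, delta))
    except np.linalg.LinAlgError:
        return None
    df = k - 1
    return means, cov, obs, chi2, df


def scan_snp(fit: NullModelFit, codes, exact: bool = False):
    """Genotype-class association test for one SNP (reference path).

    Builds the rotated class indicators directly; with ``exact=True`` the
    variance ratio is re-profiled with the class design as fixed effects
    (per-SNP REML) instead of using the null-model weights.
    """
    codes = np.asarray(codes)
    obs_rows = codes != MISSING
    counts = np.array([(codes == k).sum() for k in (0, 1, 2)])
    if (counts > 0).sum() < 2:
        raise ValueError("monomorphic SNP")
    C = np.stack([(codes == k).astype(float) for k in (0, 1, 2)], axis=1)
    R = fit.eig.U.T @ C

    if exact:
        keep = counts > 0
        crit = _profile_reml_1d(fit.ry, R[:, keep], fit.eig.lam, fit.n)
        res = optimize.minimize_scalar(
            crit, bounds=(-6, 8), method="bounded", options={"xatol": 1e-6}
        )
        delta = 10.0**res.x
        v = fit.eig.lam + delta
        Rk = R[:, keep]
        xtwx = (Rk / v[:, None]).T @ Rk
        mu = np.linalg.solve(xtwx, (Rk / v[:, None]).T @ fit.ry)
        rr = fit.ry - Rk @ mu
        s2 = float(rr / v @ rr) / (fit.n - Rk.shape[1])
        G3 = np.zeros((3, 3))
        G3[np.ix_(keep, keep)] = xtwx / s2
        b3 = np.zeros(3)
        b3[keep] = (Rk / v[:, None]).T @ fit.ry / s2
    else:
        w = fit.weights_
        G3 = (R * w[:, None]).T @ R
        b3 = (R * w[:, None]).T @ fit.ry
    out = _class_test(G3, b3, counts)
    if out is None:
        raise ValueError("degenerate genotype-class design")
    means, cov, obs, chi2, df = out
    return SnpTest(
        counts=counts,
        means=means,
        cov=cov,
        observed=obs,
        chi2=chi2,
        df=df,
        p=float(stats.chi2.sf(chi2, df)),
    )


# --------------------------------------------------------------- effect sizes
@dataclass
class ADDecomposition:
    a: float
    d: float
    se_a: float
    se_d: float
    t_a: float
    t_d: float
    p_a: float
    p_d: float


def ad_decompose(means, cov, df: int) -> ADDecomposition:
    """Additive/dominance effects from the three genotype-class means.

    ``a = (mu_aa - mu_AA)/2``, ``d = mu_Aa - (mu_AA + mu_aa)/2``; t statistics
    use the GLS covariance of the means with ``df`` residual degrees of
    freedom.
    """
    means = np.asarray(means, dtype=np.float64)
    cov = np.asarray(cov, dtype=np.float64)
    if means.shape != (3,) or np.isnan(means).any():
        raise ValueError("ad_decompose requires all three genotype classes")
    la = np.array([-0.5, 0.0, 0.5])
    ld = np.array([-0.5, 1.0, -0.5])
    a = float(la @ means)
    d = float(ld @ means)
    se_a = float(np.sqrt(la @ cov @ la))
    se_d = float(np.sqrt(ld @ cov @ ld))
    t_a = a / se_a if se_a > 0 else np.inf * np.sign(a)
    t_d = d / se_d if se_d > 0 else np.inf * np.sign(d)
    return ADDecomposition(
        a=a,
        d=d,
        se_a=se_a,
        se_d=se_d,
        t_a=t_a,
        t_d=t_d,
        p_a=float(2 * stats.t.sf(abs(t_a), df)),
        p_d=float(2 * stats.t.sf(abs(t_d), df)),
    )


def dominance_ratio(a: float, d: float) -> float:
    """Degree of dominance ``h = d/a``."""
    return d / a


def snp_variance_explained(p: float, a: float, d: float, Vp: float) -> tuple[float, float]:
    """Additive and dominance variance of a SNP as fractions of ``Vp``.

    Under Hardy-Weinberg proportions ``V_A = 2p(1-p)[a + (1-2p)d]^2`` and
    ``V_D = [2p(1-p)d]^2`` with ``p`` the frequency of the allele whose
    homozygote mean is ``+a``.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("allele frequency must be in (0, 1)")
    if Vp <= 0:
        raise ValueError("phenotypic variance must be positive")
    tpq = 2.0 * p * (1.0 - p)
    va = tpq * (a + (1.0 - 2.0 * p) * d) ** 2
    vd = (tpq * d) ** 2
    return va / Vp, vd / Vp


# ----------------------------------------------------------------------- FDR
def fdr_qvalues(pvals, method: str = "storey") -> np.ndarray:
    """q-values for FDR control.

    ``storey`` estimates the null proportion pi0 by the cubic-smoother method
    of the qvalue package (falling back to pi0 = 1 when the estimate is
    unstable or the input is small); ``bh`` gives Benjamini-Hochberg adjusted
    p-values (pi0 = 1).
    """
    p = np.asarray(pvals, dtype=np.float64)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    if method == "bh":
        return multipletests(p, method="fdr_bh")[1]
    if method != "storey":
        raise ValueError("method must be 'storey' or 'bh'")
    pi0 = 1.0
    if p.size >= 100:
        lam = np.arange(0.05, 0.96, 0.05)
        pi0_lam = np.array([(p > l).mean() / (1.0 - l) for l in lam])
        coef = np.polyfit(lam, pi0_lam, 3)
        pi0 = float(np.polyval(coef, lam.max()))
        if not 0.0 < pi0 <= 1.0:
            pi0 = 1.0
    order = np.argsort(p, kind="stable")
    ranked = p[order] * pi0 * p.size / np.arange(1, p.size + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(q, 1.0)
    return out


# ------------------------------------------------------------------ full scan
def _batch_class_stats(rot: RotatedGenotypes, fit: NullModelFit):
    """Weighted 3x3 normal equations for every SNP at once."""
    w = fit.weights_
    M = rot.M  # (m, n, 3)
    G = np.einsum("sna,n,snb->sab", M, w, M, optimize=True)
    b = np.einsum("sna,n->sa", M, w * fit.ry, optimize=True)
    return G, b


def run_scan(
    y_c,
    A,
    g,
    weights=None,
    fdr: float = 0.10,
    fdr_method: str = "storey",
    alpha_effects: float = 0.01,
    exact: bool = False,
    null_fit: NullModelFit | None = None,
    vp: float | None = None,
) -> pd.DataFrame:
    """Two-step genome scan: 2-df class test with FDR, then a/d decomposition.

    Step 1 tests every polymorphic SNP; SNPs observed in only two genotype
    classes get a 1-df test and are excluded from step 2.  Step 2 estimates
    additive and dominance effects (with t-tests at ``alpha_effects``) for
    SNPs with q <= ``fdr``, plus the variance explained relative to ``vp``
    (default: sample variance of the phenotype).

    ``g`` may be a :class:`~domvar.io.GenotypeMatrix` or a pre-built
    :class:`RotatedGenotypes`; ``A`` a matrix/:class:`EigenRelMatrix`.
    Returns one row per scanned SNP.
    """
    if null_fit is None:
        fit = fit_null(y_c, A, weights=weights)
    else:
        fit = null_fit
    if isinstance(g, RotatedGenotypes):
        rot = g
        gm = rot.g
    else:
        gm = g
        rot = RotatedGenotypes(fit.eig, gm)
    vp = float(np.var(fit.y, ddof=1)) if vp is None else vp

    counts = rot.counts
    poly = rot.n_classes >= 2
    if exact:
        rows_idx = np.flatnonzero(poly)
        stats_out = {}
        for j in rows_idx:
            stats_out[j] = scan_snp(fit, gm.codes[:, j], exact=True)
        means = np.full((gm.n_snps, 3), np.nan)
        chi2 = np.full(gm.n_snps, np.nan)
        dfv = np.zeros(gm.n_snps, dtype=int)
        pstep = np.full(gm.n_snps, np.nan)
        covs = {}
        for j, t in stats_out.items():
            means[j] = t.means
            chi2[j] = t.chi2
            dfv[j] = t.df
            pstep[j] = t.p
            covs[j] = (t.cov, t.observed)
    else:
        G, b = _batch_class_stats(rot, fit)
        means = np.full((gm.n_snps, 3), np.nan)
        chi2 = np.full(gm.n_snps, np.nan)
        dfv = np.zeros(gm.n_snps, dtype=int)
        pstep = np.full(gm.n_snps, np.nan)
        covs = {}
        for j in np.flatnonzero(poly):
            out = _class_test(G[j], b[j], counts[j])
            if out is None:
                poly[j] = False
                continue
            mu, cov, obs, c2, df = out
            means[j] = mu
            chi2[j] = c2
            dfv[j] = df
            pstep[j] = stats.chi2.sf(c2, df)
            covs[j] = (cov, obs)

    scanned = np.flatnonzero(poly)
    q = np.full(gm.n_snps, np.nan)
    q[scanned] = fdr_qvalues(pstep[scanned], method=fdr_method)

    p2 = gm.allele2_frequency()
    maf = np.minimum(p2, 1 - p2)
    res = {
        "snp": gm.snp_map["snp"].to_numpy(),
        "chrom": gm.snp_map["chrom"].to_numpy(),
        "bp": gm.snp_map["bp"].to_numpy(),
        "maf": maf,
        "n_AA": counts[:, 0],
        "n_Aa": counts[:, 1],
        "n_aa": counts[:, 2],
        "mu_AA": means[:, 0],
        "mu_Aa": means[:, 1],
        "mu_aa": means[:, 2],
        "chi2": chi2,
        "df": dfv,
        "p": pstep,
        "q": q,
        "significant": q <= fdr,
        "two_class": (rot.n_classes == 2) & poly,
    }
    for col in ("a", "d", "se_a", "se_d", "t_a", "t_d", "p_a", "p_d",
                "h_ratio", "var_a_prop", "var_d_prop"):
        res[col] = np.full(gm.n_snps, np.nan)
    res["sig_additive"] = np.zeros(gm.n_snps, dtype=bool)
    res["sig_dominance"] = np.zeros(gm.n_snps, dtype=bool)

    df_resid = fit.n - 3
    for j in scanned:
        if not res["significant"][j] or rot.n_classes[j] < 3:
            continue
        cov, obs = covs[j]
        full_cov = np.zeros((3, 3))
        full_cov[np.ix_(obs, obs)] = cov
        dec = ad_decompose(means[j], full_cov, df_resid)
        res["a"][j] = dec.a
        res["d"][j] = dec.d
        res["se_a"][j] = dec.se_a
        res["se_d"][j] = dec.se_d
        res["t_a"][j] = dec.t_a
        res["t_d"][j] = dec.t_d
        res["p_a"][j] = dec.p_a
        res["p_d"][j] = dec.p_d
        res["h_ratio"][j] = dominance_ratio(dec.a, dec.d) if dec.a != 0 else np.nan
        va, vd = snp_variance_explained(
            float(np.clip(p2[j], 1e-12, 1 - 1e-12)), dec.a, dec.d, vp
        )
        res["var_a_prop"][j] = va
        res["var_d_prop"][j] = vd
        res["sig_additive"][j] = dec.p_a < alpha_effects
        res["sig_dominance"][j] = dec.p_d < alpha_effects

    table = pd.DataFrame(res)
    return table[poly].reset_index(drop=True)
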