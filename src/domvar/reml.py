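"""Average-information REML for dense multi-component mixed models.

The model is ``y = X b + sum_i u_i + e`` with ``u_i ~ N(0, sigma_i^2 K_i)``
and ``e ~ N(0, sigma_e^2 W^-1)`` where ``W = diag(w*)`` holds per-record
residual weights (heavier weight = smaller residual variance).  All
covariance structures are dense n x n matrices, which is the right tool at
the few-thousand-record scale this package targets; no sparse mixed-model
equations are used.

Updates are average-information steps with EM-REML fallbacks whenever an AI
step would leave the parameter space or decrease the restricted likelihood;
estimates are clamped at a small positive floor, which turns hard
non-convergence into a reported ``converged_ = False`` rather than an
exception.  Asymptotic standard errors come from the inverse AI matrix at
the optimum, and standard errors of variance proportions from a first-order
Taylor (delta-method) expansion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from sklearn.base import BaseEstimator

__all__ = ["AIREML", "VarianceComponents", "ai_reml", "heritability_se"]

_FLOOR_FRAC = 1e-8  # boundary clamp, as a fraction of phenotypic variance


@dataclass
class VarianceComponents:
    """REML estimates with asymptotic uncertainty and convergence state."""

    names: list[str]
    estimates: np.ndarray
    se: np.ndarray
    cov: np.ndarray  # inverse AI matrix
    proportions: np.ndarray
    proportion_se: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    gradient_norm: float
    trace: list[dict] = field(default_factory=list, repr=False)

    def as_dict(self) -> dict:
        return {
            "estimates": dict(zip(self.names, self.estimates.tolist())),
            "se": dict(zip(self.names, self.se.tolist())),
            "proportions": dict(zip(self.names, self.proportions.tolist())),
            "proportion_se": dict(zip(self.names, self.proportion_se.tolist())),
            "loglik": self.loglik,
            "converged": self.converged,
            "n_iter": self.n_iter,
        }


def _check_design(X: np.ndarray, names) -> None:
    q, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    aliased = np.flatnonzero(diag <= tol)
    if aliased.size:
        labels = [names[k] if names is not None else str(k) for k in aliased]
        raise ValueError(f"singular fixed-effect design; aliased columns: {labels}")


class AIREML(BaseEstimator):
    """Variance-component estimation by average-information REML.

    Parameters
    ----------
    components
        Mapping name -> dense PSD covariance structure (n x n array,
        :class:`~domvar.grm.RelMatrix`, or the string ``"identity"``).  A
        residual component (structure ``diag(1/weights)``, identity when no
        weights are given) is always appended under the name ``"residual"``.
    weights
        Optional per-record residual weights ``w*`` (mean ~ 1); the residual
        covariance is ``sigma_e^2 diag(1/w*)``.
    max_iter, tol
        Iteration cap and relative restricted log-likelihood change declaring
        convergence.
    n_em
        Number of initial EM iterations before switching to AI updates.

    Attributes (after ``fit``)
    --------------------------
    variances_ : dict name -> estimate
    se_ : dict name -> asymptotic SE
    cov_ : inverse AI matrix over components (order of ``names_``)
    proportions_, proportion_se_ : variance fractions with delta-method SEs
    beta_, beta_se_ : GLS fixed effects at the optimum
    loglik_, converged_, n_iter_, result_
    """

    def __init__(
        self,
        components=None,
        weights=None,
        max_iter: int = 200,
        tol: float = 1e-8,
        n_em: int = 3,
        verbose: bool = False,
    ):
        self.components = components
        self.weights = weights
        self.max_iter = max_iter
        self.tol = tol
        self.n_em = n_em
        self.verbose = verbose

    # ------------------------------------------------------------------ fit
    def fit(self, y, X=None, feature_names=None):
        y = np.asarray(y, dtype=np.float64).ravel()
        n = y.size
        if X is None:
            X = np.ones((n, 1))
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 1:
            X = X[:, None]
        _check_design(X, feature_names)
        p = X.shape[1]
        if n <= p:
            raise ValueError("more fixed effects than observations")

        names, mats = [], []
        for name, K in (self.components or {}).items():
            if isinstance(K, str) and K == "identity":
                K = np.eye(n)
            elif hasattr(K, "values") and hasattr(K, "kind"):
                K = K.values
            K = np.asarray(K, dtype=np.float64)
            if K.shape != (n, n):
                raise ValueError(f"component {name!r} has shape {K.shape}, want ({n},{n})")
            names.append(name)
            mats.append(K)
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=np.float64)
            if (w <= 0).any():
                raise ValueError("weights must be positive")
            R = np.diag(1.0 / w)
        else:
            R = np.eye(n)
        names.append("residual")
        mats.append(R)
        k = len(mats)

        vp = float(np.var(y, ddof=1))
        if vp == 0:
            vp = 1.0
        floor = _FLOOR_FRAC * vp
        theta = np.full(k, np.var(y, ddof=1) / k)
        theta = np.maximum(theta, floor)

        def _build(theta):
            V = np.zeros((n, n))
            for t, K in zip(theta, mats):
                V += t * K
            return V

        def _common(theta):
            V = _build(theta)
            jitter = 0.0
            for _ in range(4):
                try:
                    cf = linalg.cho_factor(
                        V + (jitter * np.eye(n) if jitter else 0.0), lower=True
                    )
                    break
                except linalg.LinAlgError:
                    jitter = max(jitter * 10, 1e-10 * vp)
            else:
                raise linalg.LinAlgError("phenotypic covariance not positive definite")
            logdetV = 2.0 * np.sum(np.log(np.diag(cf[0])))
            Vinv = linalg.cho_solve(cf, np.eye(n))
            B = Vinv @ X
            XtViX = X.T @ B
            cfx = linalg.cho_factor(XtViX, lower=True)
            logdetX = 2.0 * np.sum(np.log(np.diag(cfx[0])))
            beta = linalg.cho_solve(cfx, B.T @ y)
            Py = Vinv @ y - B @ beta
            ll = -0.5 * (logdetV + logdetX + float(y @ Py))
            return Vinv, B, cfx, Py, ll, beta

        ll_prev = -np.inf
        converged = False
        n_stalled = 0
        trace = []
        Vinv = B = cfx = Py = beta = None
        ll = -np.inf
        AI = np.eye(k)
        score = np.zeros(k)

        for it in range(1, self.max_iter + 1):
            Vinv, B, cfx, Py, ll, beta = _common(theta)
            # score_i = -0.5 (tr(P K_i) - y' P K_i P y)
            u = [K @ Py for K in mats]
            yPKPy = np.array([float(Py @ ui) for ui in u])
            trPK = np.empty(k)
            for i, K in enumerate(mats):
                KB = K @ B
                trPK[i] = float(np.sum(Vinv * K)) - float(
                    np.trace(linalg.cho_solve(cfx, B.T @ KB))
                )
            score = -0.5 * (trPK - yPKPy)
            Pu = [Vinv @ ui - B @ linalg.cho_solve(cfx, B.T @ ui) for ui in u]
            AI = 0.5 * np.array(
                [[float(u[i] @ Pu[j]) for j in range(k)] for i in range(k)]
            )
            AI = 0.5 * (AI + AI.T)

            grad_norm = float(np.max(np.abs(score)))
            rel = abs(ll - ll_prev) / max(1.0, abs(ll))
            trace.append(
                {"iter": it, "loglik": ll, "theta": theta.copy(), "step": None}
            )
            if self.verbose:
                print(f"iter {it}: logL={ll:.6f} theta={theta}")
            if it > 1 and rel < self.tol:
                converged = True
                trace[-1]["step"] = "converged"
                break
            # estimates pinned at the boundary can only crawl; three
            # consecutive near-zero likelihood moves end the iteration
            n_stalled = n_stalled + 1 if (it > 1 and abs(ll - ll_prev) < 1e-6) else 0
            if n_stalled >= 3:
                converged = True
                trace[-1]["step"] = "converged-boundary"
                break

            def em_step(theta):
                new = theta + theta**2 * (yPKPy - trPK) / n
                return np.maximum(new, floor)

            if it <= self.n_em:
                theta_new, step = em_step(theta), "em"
            else:
                try:
                    delta = np.linalg.solve(AI, score)
                    # components pushed out of the space stick to the floor
                    cand = np.maximum(theta + delta, floor)
                    ll_cand = _common(cand)[4]
                    if ll_cand >= ll - 1e-10:
                        theta_new, step = cand, "ai"
                    else:
                        theta_new, step = em_step(theta), "em-fallback"
                except np.linalg.LinAlgError:
                    theta_new, step = em_step(theta), "em-fallback"
            trace[-1]["step"] = step
            ll_prev = ll
            if np.max(np.abs(theta_new - theta) / np.maximum(theta, floor)) < 1e-12:
                theta = theta_new
                converged = True
                break
            theta = theta_new

        # uncertainty at the optimum
        try:
            cov = np.linalg.inv(AI)
        except np.linalg.LinAlgError:
            cov = np.full((k, k), np.nan)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
        total = theta.sum()
        props = theta / total
        grad = (np.eye(k) * total - theta[:, None]) / total**2
        prop_se = np.sqrt(np.clip(np.diag(grad @ cov @ grad.T), 0, None))

        self.names_ = names
        self.theta_ = theta
        self.variances_ = dict(zip(names, theta))
        self.se_ = dict(zip(names, se))
        self.cov_ = cov
        self.proportions_ = dict(zip(names, props))
        self.proportion_se_ = dict(zip(names, prop_se))
        self.loglik_ = ll
        self.converged_ = bool(converged)
        self.n_iter_ = it
        self.gradient_norm_ = float(np.max(np.abs(score)))
        self.beta_ = beta
        self.beta_cov_ = linalg.cho_solve(cfx, np.eye(X.shape[1]))
        self.beta_se_ = np.sqrt(np.diag(self.beta_cov_))
        self._Vinv = Vinv
        self._Py = Py
        self._X = X
        self._y = y
        self._mats = dict(zip(names, mats))
        self.result_ = VarianceComponents(
            names=names,
            estimates=theta.copy(),
            se=se,
            cov=cov,
            proportions=props,
            proportion_se=prop_se,
            loglik=ll,
            converged=bool(converged),
            n_iter=it,
            gradient_norm=self.gradient_norm_,
            trace=trace,
        )
        return self

    # ------------------------------------------------------------- utilities
    def blup(self, name: str) -> np.ndarray:
        """Empirical BLUP of the random effect ``name``: sigma^2 K P y."""
        if name not in self._mats or name == "residual":
            raise KeyError(f"no random component {name!r}")
        return self.variances_[name] * (self._mats[name] @ self._Py)


def ai_reml(
    y, components, X=None, weights=None, max_iter: int = 200, tol: float = 1e-8
) -> VarianceComponents:
    """Functional wrapper around :class:`AIREML`; returns the result record."""
    est = AIREML(components=components, weights=weights, max_iter=max_iter, tol=tol)
    est.fit(y, X=X)
    return est.result_


def heritability_se(vc: VarianceComponents, component: str) -> tuple[float, float]:
    """Variance fraction of one component with its delta-method SE.

    The fraction is ``sigma_c^2 / sum_i sigma_i^2`` and the SE propagates the
    full AI-based covariance of all estimates through the first-order Taylor
    expansion of the ratio.
    """
    if component not in vc.names:
        raise KeyError(component)
    total = float(vc.estimates.sum())
    if total <= 0:
        raise ValueError("zero total variance")
    i = vc.names.index(component)
    prop = vc.estimates[i] / total
    grad = -vc.estimates[i] / total**2 * np.ones(len(vc.names))
    grad[i] += 1.0 / total
    var = float(grad @ vc.cov @ grad)
    return float(prop), float(np.sqrt(max(var, 0.0)))
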