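"""Cumulative-link (proportional-odds) mixed model for ordinal ratings.

Model: for subject i, observation j with ordinal outcome y_ij in {1..K},

    P(y_ij <= k | b_i) = logistic(theta_k - x_ij' beta - b_i),
    b_i ~ N(0, sigma_b^2),

with K-1 strictly increasing thresholds theta.  The marginal likelihood
integrates b_i out by adaptive Gauss-Hermite quadrature (default 15 nodes;
1 node is the Laplace approximation): per likelihood evaluation each
subject's integrand mode is located by Newton steps (the integrand is
log-concave), the quadrature grid is centered and scaled there, and the node
contributions are combined in log space.

Estimation maximizes the marginal likelihood with L-BFGS-B over the
unconstrained parameterization (theta_1, log-increments, beta, log sigma_b);
starting values are beta = 0, thresholds from the marginal cumulative
frequencies, sigma_b = 1, so fits are deterministic.  Wald z tests use the
observed-information covariance with a delta-method back-transform.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.tools.numdiff import approx_hess1

from .lmm import FitResult

__all__ = ["CumulativeLinkMixedModel"]

_SIGMOID = special.expit


def _logistic_pdf(a):
    f = _SIGMOID(a)
    return f * (1.0 - f)


class CumulativeLinkMixedModel:
    """Proportional-odds logit model with a Gaussian subject intercept.

    Parameters
    ----------
    n_quad : int
        Adaptive Gauss-Hermite nodes (1 = Laplace).
    fit_sigma : bool
        If False, ``sigma_b`` is held fixed at ``sigma_b0`` (0 gives an
        ordinary proportional-odds model; used by the oracle tests).
    """

    def __init__(self, n_quad: int = 15, fit_sigma: bool = True,
                 sigma_b0: float = 1.0, maxiter: int = 500):
        if n_quad < 1:
            raise ValueError("n_quad must be >= 1")
        self.n_quad = n_quad
        self.fit_sigma = fit_sigma
        self.sigma_b0 = sigma_b0
        self.maxiter = maxiter
        self._nodes, self._weights = np.polynomial.hermite.hermgauss(n_quad)

    # -- parameter packing ---------------------------------------------------

    def _unpack(self, params, K, p):
        th = np.empty(K - 1)
        th[0] = params[0]
        if K > 2:
            th[1:] = params[0] + np.cumsum(np.exp(params[1:K - 1]))
        beta = params[K - 1:K - 1 + p]
        if self.fit_sigma:
            sigma = float(np.exp(params[-1]))
        else:
            sigma = self.sigma_b0
        return th, beta, sigma

    # -- likelihood ----------------------------------------------------------

    def _bounds(self, th, y):
        hi = np.where(y < th.size, th[np.minimum(y, th.size - 1)], np.inf)
        lo = np.where(y > 0, th[np.maximum(y - 1, 0)], -np.inf)
        return lo, hi

    def _obs_loglik_terms(self, b_per_obs, eta, lo, hi):
        """log p, dlogp/db, d2logp/db2 for every observation at intercept b."""
        a_hi = hi - eta - b_per_obs
        a_lo = lo - eta - b_per_obs
        F_hi = np.where(np.isinf(a_hi), 1.0, _SIGMOID(a_hi))
        F_lo = np.where(np.isinf(a_lo), 0.0, _SIGMOID(a_lo))
        f_hi = np.where(np.isinf(a_hi), 0.0, _logistic_pdf(a_hi))
        f_lo = np.where(np.isinf(a_lo), 0.0, _logistic_pdf(a_lo))
        fp_hi = np.where(np.isinf(a_hi), 0.0, f_hi * (1.0 - 2.0 * F_hi))
        fp_lo = np.where(np.isinf(a_lo), 0.0, f_lo * (1.0 - 2.0 * F_lo))
        prob = np.clip(F_hi - F_lo, 1e-300, None)
        u = f_hi - f_lo
        d1 = -u / prob
        d2 = ((fp_hi - fp_lo) * prob - u * u) / (prob * prob)
        return np.log(prob), d1, d2

    def _marginal_loglik(self, params, y, X, codes, G):
        K, p = self._K, X.shape[1]
        th, beta, sigma = self._unpack(params, K, p)
        eta = X @ beta
        lo, hi = self._bounds(th, y)

        if sigma <= 1e-8:
            lp, _, _ = self._obs_loglik_terms(np.zeros_like(eta), eta, lo, hi)
            return float(np.sum(lp))

        # Newton mode search for each subject's log-integrand (log-concave)
        b = np.zeros(G)
        for _ in range(30):
            lp, d1, d2 = self._obs_loglik_terms(b[codes], eta, lo, hi)
            g = np.bincount(codes, weights=d1, minlength=G) - b / sigma ** 2
            h = np.bincount(codes, weights=d2, minlength=G) - 1.0 / sigma ** 2
            step = g / h
            b_new = b - np.clip(step, -4.0, 4.0)
            if np.max(np.abs(b_new - b)) < 1e-9:
                b = b_new
                break
            b = b_new
        lp, d1, d2 = self._obs_loglik_terms(b[codes], eta, lo, hi)
        h = np.bincount(codes, weights=d2, minlength=G) - 1.0 / sigma ** 2
        s_hat = 1.0 / np.sqrt(-h)

        # adaptive grid b = b_hat + sqrt(2) s_hat x_k
        xk, wk = self._nodes, self._weights
        contrib = np.empty((G, xk.size))
        for k, (x, w) in enumerate(zip(xk, wk)):
            bk = b + np.sqrt(2.0) * s_hat * x
            lpk, _, _ = self._obs_loglik_terms(bk[codes], eta, lo, hi)
            per_subj = np.bincount(codes, weights=lpk, minlength=G)
            log_prior = -0.5 * (bk / sigma) ** 2 - np.log(sigma) - 0.5 * np.log(2 * np.pi)
            contrib[:, k] = np.log(w) + x * x + per_subj + log_prior
        log_Li = np.log(np.sqrt(2.0) * s_hat) + special.logsumexp(contrib, axis=1)
        return float(np.sum(log_Li))

    # -- fitting -------------------------------------------------------------

    def fit(self, y: np.ndarray, X: np.ndarray, groups: np.ndarray,
            term_names: Optional[list[str]] = None,
            n_categories: Optional[int] = None) -> FitResult:
        """Fit the model.  ``y`` holds ordinal categories (1..K)."""
        y = np.asarray(y)
        X = np.asarray(X, dtype=float)
        codes, uniq = pd.factorize(np.asarray(groups))
        G = len(uniq)
        cats = np.unique(y)
        K = int(n_categories if n_categories is not None else cats.max())
        if cats.size < 2:
            raise ValueError("outcome is constant; ordinal model is degenerate")
        if cats.min() < 1 or cats.max() > K:
            raise ValueError(f"ratings must lie in 1..{K}")
        y0 = np.asarray(y, dtype=int) - 1
        p = X.shape[1]
        self._K = K
        if term_names is None:
            term_names = [f"x{j}" for j in range(p)]

        # starting values: marginal cumulative logits, beta = 0, sigma = 1
        cum = np.cumsum(np.bincount(y0, minlength=K)[:-1]) / y0.size
        cum = np.clip(cum, 0.01, 0.99)
        th0 = np.log(cum / (1 - cum))
        th0 = np.maximum.accumulate(th0)
        start = [th0[0]]
        if K > 2:
            start += list(np.log(np.maximum(np.diff(th0), 0.1)))
        start += [0.0] * p
        if self.fit_sigma:
            start += [0.0]
        start = np.array(start)

        def nll(params):
            return -self._marginal_loglik(params, y0, X, codes, G)

        res = optimize.minimize(nll, start, method="L-BFGS-B",
                                options={"maxiter": self.maxiter, "ftol": 1e-12,
                                         "gtol": 1e-8})
        th, beta, sigma = self._unpack(res.x, K, p)

        # Wald covariance on the unconstrained scale, delta method back
        H = approx_hess1(res.x, nll)
        notes = []
        try:
            cov = np.linalg.inv(H)
            ok = np.all(np.isfinite(cov)) and np.all(np.diag(cov) > 0)
        except np.linalg.LinAlgError:
            ok = False
        if not ok:
            cov = np.full((res.x.size, res.x.size), np.nan)
            notes.append("observed information not positive definite")

        # Jacobian of (theta_1..theta_{K-1}, beta, sigma) wrt packed params
        n_par = res.x.size
        J = np.zeros((K - 1 + p + (1 if self.fit_sigma else 0), n_par))
        for k in range(K - 1):
            J[k, 0] = 1.0
            for j in range(1, k + 1):
                J[k, j] = np.exp(res.x[j])
        for j in range(p):
            J[K - 1 + j, K - 1 + j] = 1.0
        if self.fit_sigma:
            J[-1, -1] = sigma
        cov_nat = J @ cov @ J.T
        est = np.concatenate([th, beta, [sigma] if self.fit_sigma else []])
        se = np.sqrt(np.diag(cov_nat))
        names = [f"threshold_{k + 1}|{k + 2}" for k in range(K - 1)] + list(term_names)
        if self.fit_sigma:
            names.append("sigma_subject")
        z = est / se
        pvals = 2 * stats.norm.sf(np.abs(z))
        # no test on the boundary-constrained variance parameter
        if self.fit_sigma:
            z[-1] = np.nan
            pvals[-1] = np.nan
        table = pd.DataFrame({
            "term": names, "estimate": est, "se": se,
            "stat": z, "df": np.inf, "p": pvals,
        })
        return FitResult(
            table=table,
            variance_components={"subject_intercept_var": sigma ** 2},
            converged=bool(res.success), n_obs=int(y0.size), n_subjects=G,
            loglik=float(-res.fun), method=f"AGQ{self.n_quad}" if self.fit_sigma else "ML",
            model="clmm", notes=notes,
        )

    def loglik(self, params: np.ndarray, y: np.ndarray, X: np.ndarray,
               groups: np.ndarray, n_categories: int) -> float:
        """Marginal log-likelihood at packed ``params`` (testing hook)."""
        codes, uniq = pd.factorize(np.asarray(groups))
        self._K = n_categories
        return self._marginal_loglik(np.asarray(params, dtype=float),
                                     np.asarray(y, dtype=int) - 1,
                                     np.asarray(X, dtype=float), codes, len(uniq))
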