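"""Gaussian linear mixed model with a single random intercept.

This is the workhorse behind all trial-level SCR analyses: REML estimation of

    y_ij = x_ij' beta + b_i + e_ij,   b_i ~ N(0, tau2),  e_ij ~ N(0, sigma2)

grouped by subject.  The variance ratio lambda = tau2/sigma2 is profiled out
analytically (block algebra on V_i = sigma2 (I + lambda J)), so a fit is a
one-dimensional deterministic optimization; p-values use Satterthwaite
degrees of freedom computed from the REML information of (tau2, sigma2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = ["FitResult", "RandomInterceptLMM", "reml_criterion"]


@dataclass
class FitResult:
    """Coefficient table plus variance components for one fitted model."""

    table: pd.DataFrame            # term, estimate, se, stat, df, p
    variance_components: dict      # subject_intercept_var, residual_var (LMM)
    converged: bool
    n_obs: int
    n_subjects: int
    loglik: float
    method: str
    model: str = "lmm"
    notes: list = field(default_factory=list)

    def coef(self, term: str) -> pd.Series:
        rows = self.table[self.table["term"] == term]
        if rows.empty:
            raise KeyError(f"no term {term!r}; have {list(self.table['term'])}")
        return rows.iloc[0]

    def __repr__(self) -> str:  # pragma: no cover - display only
        head = (f"<FitResult {self.model} {self.method}: n_obs={self.n_obs}, "
                f"n_subjects={self.n_subjects}, converged={self.converged}>")
        return head + "\n" + self.table.to_string(index=False)


def _group_stats(X: np.ndarray, y: np.ndarray, codes: np.ndarray, n_groups: int):
    """Per-group sufficient statistics for the block algebra."""
    p = X.shape[1]
    S = np.zeros((n_groups, p))          # per-group column sums of X
    np.add.at(S, codes, X)
    t = np.bincount(codes, weights=y, minlength=n_groups)   # per-group sums of y
    n_i = np.bincount(codes, minlength=n_groups).astype(float)
    return S, t, n_i


def _profiled_pieces(lam: float, XtX, Xty, yty, S, t, n_i):
    """GLS quantities under H = I + lam * ZZ' (per-block J)."""
    c = lam / (1.0 + lam * n_i)                    # shrinkage per group
    A = XtX - (S * c[:, None]).T @ S               # X' H^-1 X
    u = Xty - S.T @ (c * t)                        # X' H^-1 y
    beta = np.linalg.solve(A, u)
    tb = S @ beta                                  # per-group sums of fitted values
    rss = yty - 2 * beta @ Xty + beta @ XtX @ beta  # r'r
    rWr = rss - c @ (t - tb) ** 2                  # r' H^-1 r
    return A, beta, max(rWr, 1e-300)


def reml_criterion(lam: float, XtX, Xty, yty, S, t, n_i, n: int, p: int):
    """-2 * profiled REML log-likelihood (up to no constant) and pieces."""
    A, beta, rWr = _profiled_pieces(lam, XtX, Xty, yty, S, t, n_i)
    sigma2 = rWr / (n - p)
    logdetH = float(np.sum(np.log1p(lam * n_i)))
    sign, logdetA = np.linalg.slogdet(A)
    crit = ((n - p) * np.log(sigma2) + logdetH + logdetA
            + (n - p) * (1.0 + np.log(2 * np.pi)))
    return crit, beta, sigma2, A


def _reml_loglik_theta(tau2: float, sigma2: float, XtX, Xty, yty, S, t, n_i,
                       n: int, p: int) -> float:
    """Unprofiled REML log-likelihood at (tau2, sigma2); used for the
    Satterthwaite information matrix and as a test oracle hook."""
    lam = tau2 / sigma2
    A, beta, rWr = _profiled_pieces(lam, XtX, Xty, yty, S, t, n_i)
    logdetH = float(np.sum(np.log1p(lam * n_i)))
    sign, logdetA = np.linalg.slogdet(A / sigma2)
    m2ll = ((n - p) * np.log(2 * np.pi * sigma2) + logdetH + logdetA
            + p * np.log(sigma2) + rWr / sigma2)
    return -0.5 * m2ll


class RandomInterceptLMM:
    """REML fit of a Gaussian random-intercept model.

    Parameters
    ----------
    reml : bool
        REML (default) or ML estimation.
    df_method : {"satterthwaite", "residual"}
        Degrees of freedom for t tests.  At a boundary fit (tau2 ~ 0) the
        Satterthwaite computation degenerates and residual df are used, with
        a note on the result.
    """

    def __init__(self, reml: bool = True, df_method: str = "satterthwaite"):
        self.reml = reml
        self.df_method = df_method

    def fit(self, y: np.ndarray, X: np.ndarray, groups: np.ndarray,
            term_names: Optional[list[str]] = None) -> FitResult:
        y = np.asarray(y, dtype=float)
        X = np.asarray(X, dtype=float)
        codes, uniq = pd.factorize(np.asarray(groups))
        n, p = X.shape
        G = len(uniq)
        if n != y.size or codes.size != n:
            raise ValueError("y, X and groups must have matching length")
        if n <= p:
            raise ValueError("more parameters than observations")
        if G < 2:
            raise ValueError("need at least 2 subjects")
        if term_names is None:
            term_names = [f"x{j}" for j in range(p)]

        XtX, Xty, yty = X.T @ X, X.T @ y, float(y @ y)
        S, t, n_i = _group_stats(X, y, codes, G)

        if self.reml:
            def crit(loglam):
                return reml_criterion(np.exp(loglam), XtX, Xty, yty, S, t, n_i, n, p)[0]
        else:
            def crit(loglam):
                lam = np.exp(loglam)
                A, beta, rWr = _profiled_pieces(lam, XtX, Xty, yty, S, t, n_i)
                sigma2 = rWr / n
                logdetH = float(np.sum(np.log1p(lam * n_i)))
                return n * np.log(sigma2) + logdetH + n * (1 + np.log(2 * np.pi))

        res = optimize.minimize_scalar(crit, bounds=(-14.0, 14.0), method="bounded",
                                       options={"xatol": 1e-10})
        lam = float(np.exp(res.x))
        boundary = crit(-14.0) <= res.fun + 1e-10
        if boundary:
            lam = 0.0

        A, beta, rWr = _profiled_pieces(lam, XtX, Xty, yty, S, t, n_i)
        dof = n - p if self.reml else n
        sigma2 = rWr / dof
        tau2 = lam * sigma2
        cov_beta = sigma2 * np.linalg.inv(A)
        se = np.sqrt(np.diag(cov_beta))
        loglik = _reml_loglik_theta(max(tau2, 1e-12 * sigma2), sigma2,
                                    XtX, Xty, yty, S, t, n_i, n, p)

        notes = []
        if boundary:
            notes.append("boundary: subject-intercept variance estimated at 0")

        if self.df_method == "satterthwaite" and not boundary:
            df = self._satterthwaite_df(tau2, sigma2, XtX, Xty, yty, S, t, n_i, n, p)
            if df is None:
                df = np.full(p, float(n - p))
                notes.append("satterthwaite information degenerate; residual df used")
        else:
            df = np.full(p, float(n - p))
            if self.df_method == "satterthwaite":
                notes.append("residual df used at boundary")

        tstat = beta / se
        pvals = 2 * stats.t.sf(np.abs(tstat), df)
        table = pd.DataFrame({
            "term": term_names, "estimate": beta, "se": se,
            "stat": tstat, "df": df, "p": pvals,
        })
        return FitResult(
            table=table,
            variance_components={"subject_intercept_var": tau2, "residual_var": sigma2},
            converged=bool(res.success if hasattr(res, "success") else True),
            n_obs=n, n_subjects=G, loglik=float(loglik),
            method="REML" if self.reml else "ML", notes=notes,
        )

    @staticmethod
    def _satterthwaite_df(tau2, sigma2, XtX, Xty, yty, S, t, n_i, n, p):
        """Satterthwaite df per coefficient: 2 f^2 / (g' A g) with
        f(theta) = [ (X'V^-1 X)^-1 ]_jj, A = Cov(theta_hat) from the REML
        observed information, g the gradient of f, theta = (tau2, sigma2)."""
        theta = np.array([tau2, sigma2])

        def covdiag(th):
            lam = th[0] / th[1]
            c = lam / (1.0 + lam * n_i)
            A = (XtX - (S * c[:, None]).T @ S) / th[1]     # X' V^-1 X
            return np.diag(np.linalg.inv(A))

        def ll(th):
            return _reml_loglik_theta(th[0], th[1], XtX, Xty, yty, S, t, n_i, n, p)

        # step sizes near the optima for central differences: ~eps^(1/3)
        # relative for first derivatives, ~eps^(1/4) for second derivatives
        hg = 6e-6 * np.maximum(np.abs(theta), 1e-3 * theta[1])
        hh = 1.2e-4 * np.maximum(np.abs(theta), 1e-3 * theta[1])
        # gradient of each covariance diagonal element (central differences)
        grads = np.empty((p, 2))
        for k in range(2):
            e = np.zeros(2); e[k] = hg[k]
            grads[:, k] = (covdiag(theta + e) - covdiag(theta - e)) / (2 * hg[k])
        # observed information of (tau2, sigma2)
        H = np.empty((2, 2))
        for a in range(2):
            for b in range(a, 2):
                ea = np.zeros(2); ea[a] = hh[a]
                eb = np.zeros(2); eb[b] = hh[b]
                H[a, b] = H[b, a] = (
                    ll(theta + ea + eb) - ll(theta + ea - eb)
                    - ll(theta - ea + eb) + ll(theta - ea - eb)
                ) / (4 * hh[a] * hh[b])
        info = -H
        try:
            Acov = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            return None
        if not np.all(np.isfinite(Acov)) or Acov[0, 0] <= 0 or Acov[1, 1] <= 0:
            return None
        f = covdiag(theta)
        denom = np.einsum("jk,kl,jl->j", grads, Acov, grads)
        with np.errstate(divide="ignore", invalid="ignore"):
            df = 2 * f ** 2 / denom
        df = np.where((denom <= 0) | ~np.isfinite(df), float(n - p), df)
        return np.clip(df, 1.0, 1e7)
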