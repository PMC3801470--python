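"""Poisson regression with generalized estimating equations (GEE).

Marginal log-linear model for clustered counts: E[y_ij] = mu_ij =
exp(offset_ij + x_ij' beta), with a working exchangeable correlation within
clusters (all pairs of observations in a cluster share one correlation alpha)
and robust (sandwich) standard errors over clusters. alpha and the dispersion
phi are re-estimated from Pearson residuals at each iteration by their moment
estimators; beta solves

    sum_i D_i' V_i^{-1} (y_i - mu_i) = 0,   V_i = phi A_i^1/2 R(alpha) A_i^1/2

by Fisher scoring from the independence (Poisson ML) start. The exchangeable
R(alpha) = (1-alpha) I + alpha J admits a closed-form inverse, so each update
needs only per-cluster column sums.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

__all__ = ["PoissonGEE"]


def _cluster_segments(clusters: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sort order, segment start indices and sizes for a cluster label array."""
    labels, inverse = np.unique(clusters, return_inverse=True)
    order = np.argsort(inverse, kind="stable")
    sizes = np.bincount(inverse, minlength=labels.size)
    starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    return order, starts, sizes


class PoissonGEE(BaseEstimator):
    """Poisson GEE with an exchangeable (or independence) working correlation.

    Parameters
    ----------
    correlation : {"exchangeable", "independence"}
        Working within-cluster correlation structure. Independence fixes
        alpha = 0 and reproduces the Poisson ML point estimates.
    fit_intercept : bool
        Prepend an intercept column to the design.
    max_iter : int
        Maximum Fisher-scoring iterations.
    tol : float
        Convergence threshold on max |change in beta|.
    cov_type : {"robust", "bias_reduced"}
        Sandwich covariance, optionally with the Mancl-DeRouen small-sample
        residual correction.

    Attributes
    ----------
    coef_ : ndarray of shape (n_features,)
        Slope coefficients on the log-rate scale.
    intercept_ : float
        Intercept (0.0 when fit_intercept=False).
    params_ : pandas Series
        All coefficients, indexed by term name.
    cov_robust_ : pandas DataFrame
        Sandwich covariance of params_.
    cov_naive_ : pandas DataFrame
        Model-based covariance phi * (sum D'V^-1 D)^-1.
    satterthwaite_df_ : pandas Series
        Effective degrees of freedom per coefficient, estimated from the
        spread of per-cluster influence contributions (Satterthwaite-style);
        small values flag that a few clusters carry most of the information.
    alpha_ : float
        Estimated exchangeable correlation (0 under independence).
    scale_ : float
        Estimated dispersion phi.
    n_clusters_, n_obs_, n_iter_ : int
    converged_ : bool
    """

    def __init__(self, correlation: str = "exchangeable", fit_intercept: bool = True,
                 max_iter: int = 100, tol: float = 1e-8,
                 cov_type: str = "robust"):
        self.correlation = correlation
        self.fit_intercept = fit_intercept
        self.max_iter = max_iter
        self.tol = tol
        self.cov_type = cov_type

    # ------------------------------------------------------------------ fit
    def fit(self, X, y, clusters, offset=None) -> "PoissonGEE":
        """Fit the marginal model.

        Parameters
        ----------
        X : array-like or DataFrame of shape (n_obs, n_features)
        y : array-like of non-negative counts
        clusters : array-like of cluster labels (required; >= 2 clusters)
        offset : array-like on the log scale (e.g. log population), optional
        """
        if self.correlation not in ("exchangeable", "independence"):
            raise ValueError(f"unknown correlation {self.correlation!r}")
        if self.cov_type not in ("robust", "bias_reduced"):
            raise ValueError(f"unknown cov_type {self.cov_type!r}")

        if isinstance(X, pd.DataFrame):
            names = list(X.columns)
            self.feature_names_in_ = np.asarray(names, dtype=object)
            Xv = X.to_numpy(dtype=float)
        else:
            Xv = np.asarray(X, dtype=float)
            if Xv.ndim == 1:
                Xv = Xv[:, None]
            names = [f"x{i}" for i in range(Xv.shape[1])]
        yv = np.asarray(y, dtype=float)
        cl = np.asarray(clusters)
        n = yv.size
        if Xv.shape[0] != n or cl.shape[0] != n:
            raise ValueError("X, y and clusters must have equal length")
        if np.any(yv < 0) or not np.all(np.isfinite(yv)):
            raise ValueError("y must be finite non-negative counts")
        if not np.all(np.isfinite(Xv)):
            raise ValueError("X must be finite (drop incomplete cases first)")
        off = np.zeros(n) if offset is None else np.asarray(offset, dtype=float)
        if off.shape[0] != n:
            raise ValueError("offset must match y in length")

        if self.fit_intercept:
            Xv = np.column_stack([np.ones(n), Xv])
            names = ["intercept"] + names
        p = Xv.shape[1]
        if np.linalg.matrix_rank(Xv) < p:
            raise ValueError("singular design matrix")

        order, starts, sizes = _cluster_segments(cl)
        if sizes.size < 2:
            raise ValueError("GEE requires at least 2 clusters")
        Xs, ys, offs = Xv[order], yv[order], off[order]
        n_max = int(sizes.max())

        beta = self._independence_start(Xs, ys, offs)
        alpha = 0.0
        phi = 1.0
        converged = False
        exch = self.correlation == "exchangeable" and n_max > 1
        alpha_lb = -1.0 / (n_max - 1) + 1e-6 if n_max > 1 else 0.0

        for it in range(1, self.max_iter + 1):
            eta = offs + Xs @ beta
            mu = np.exp(np.clip(eta, -700, 700))
            e = (ys - mu) / np.sqrt(mu)
            phi = float(np.sum(e * e) / max(n - p, 1))
            if exch:
                t = np.add.reduceat(e, starts)         # per-cluster sum of e
                ss = np.add.reduceat(e * e, starts)    # per-cluster sum of e^2
                n_pairs = float(np.sum(sizes * (sizes - 1) / 2))
                denom = max(n_pairs - p, 1.0) * phi
                alpha = float(np.sum((t * t - ss) / 2.0) / denom)
                alpha = float(np.clip(alpha, alpha_lb, 0.9999))
            H, g = self._assemble(Xs, mu, ys, starts, sizes, alpha)
            try:
                delta = np.linalg.solve(H, g)
            except np.linalg.LinAlgError as exc:
                raise ValueError("singular working information matrix") from exc
            # step-halving on divergence (non-finite linear predictor)
            step = 1.0
            for _ in range(30):
                cand = beta + step * delta
                if np.all(np.abs(offs + Xs @ cand) < 700):
                    break
                step /= 2.0
            beta = beta + step * delta
            if np.max(np.abs(step * delta)) < self.tol:
                converged = True
                break
        if not converged:
            warnings.warn("PoissonGEE did not converge within max_iter",
                          RuntimeWarning, stacklevel=2)

        eta = offs + Xs @ beta
        mu = np.exp(eta)
        H, _ = self._assemble(Xs, mu, ys, starts, sizes, alpha)
        Hinv = np.linalg.inv(H)
        meat, contribs = self._meat(Xs, ys, mu, starts, sizes, alpha, phi, Hinv)
        cov_robust = Hinv @ meat @ Hinv
        cov_naive = phi * Hinv
        # Satterthwaite-style effective df per coefficient from the spread of
        # per-cluster influence contributions: when a few clusters dominate
        # (heavily skewed exposures), the t reference must have few df.
        sq2 = contribs ** 2
        num = sq2.sum(axis=0) ** 2
        den = (sq2 ** 2).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            df = np.where(den > 0, num / den, float(sizes.size - 1))
        df = np.clip(df, 1.0, float(sizes.size - 1))

        self.params_ = pd.Series(beta, index=names)
        self.cov_robust_ = pd.DataFrame(cov_robust, index=names, columns=names)
        self.cov_naive_ = pd.DataFrame(cov_naive, index=names, columns=names)
        self.satterthwaite_df_ = pd.Series(df, index=names)
        if self.fit_intercept:
            self.intercept_ = float(beta[0])
            self.coef_ = beta[1:].copy()
        else:
            self.intercept_ = 0.0
            self.coef_ = beta.copy()
        self.alpha_ = float(alpha)
        self.scale_ = float(phi)
        self.n_obs_ = int(n)
        self.n_clusters_ = int(sizes.size)
        self.n_iter_ = int(it)
        self.converged_ = bool(converged)
        self.n_features_in_ = p - (1 if self.fit_intercept else 0)
        return self

    # ------------------------------------------------------------- internals
    @staticmethod
    def _independence_start(X: np.ndarray, y: np.ndarray,
                            off: np.ndarray) -> np.ndarray:
        """Poisson ML via iteratively reweighted least squares."""
        n, p = X.shape
        mu = y + 0.5
        eta = np.log(mu)
        beta = np.zeros(p)
        for _ in range(50):
            z = eta - off + (y - mu) / mu
            WX = X * mu[:, None]
            try:
                new = np.linalg.solve(X.T @ WX, WX.T @ z)
            except np.linalg.LinAlgError as exc:
                raise ValueError("singular design in Poisson start") from exc
            if np.max(np.abs(new - beta)) < 1e-10:
                beta = new
                break
            beta = new
            eta = np.clip(off + X @ beta, -700, 700)
            mu = np.exp(eta)
        return beta

    @staticmethod
    def _assemble(X, mu, y, starts, sizes, alpha):
        """Working information H = sum Z'R^-1 Z and score g = sum Z'R^-1 e.

        Z = A^1/2 X, e = A^-1/2 (y - mu). With exchangeable R,
        R^-1 = [I - c J] / (1 - alpha), c = alpha / (1 + (n_i - 1) alpha).
        """
        sq = np.sqrt(mu)
        Z = X * sq[:, None]
        e = (y - mu) / sq
        H = Z.T @ Z
        g = Z.T @ e
        if alpha != 0.0:
            c = alpha / (1.0 + (sizes - 1.0) * alpha)  # per cluster
            S = np.add.reduceat(Z, starts, axis=0)     # cluster column sums
            t = np.add.reduceat(e, starts)
            H = (H - (S * c[:, None]).T @ S) / (1.0 - alpha)
            g = (g - S.T @ (c * t)) / (1.0 - alpha)
        return H, g

    def _meat(self, X, y, mu, starts, sizes, alpha, phi, Hinv):
        """Sandwich middle term sum_i u_i u_i', u_i = Z_i' R^-1 e_i.

        With cov_type="bias_reduced", residuals are premultiplied by
        (I - H_i)^{-1} (Mancl-DeRouen) before projection. Also returns the
        per-cluster influence contributions H^{-1} u_i (one row per cluster)
        used for the Satterthwaite effective-df estimate.
        """
        sq = np.sqrt(mu)
        Z = X * sq[:, None]
        ends = np.concatenate([starts[1:], [X.shape[0]]])
        p = X.shape[1]
        meat = np.zeros((p, p))
        contribs = np.zeros((sizes.size, p))
        for k, (s, t_, m) in enumerate(zip(starts, ends, sizes)):
            Zi = Z[s:t_]
            ei = (y[s:t_] - mu[s:t_]) / sq[s:t_]
            if self.cov_type == "bias_reduced":
                # H_i = D_i (sum D'V^-1 D)^-1 D_i' V_i^-1 on the response scale
                Rinv = self._rinv(int(m), alpha)
                Di = Zi * sq[s:t_, None]  # A_i X_i
                ViD = (Rinv @ Zi) / sq[s:t_, None] / phi  # V_i^-1 D_i rowspace
                Hi = Di @ (phi * Hinv) @ ViD.T
                ri = np.linalg.solve(np.eye(int(m)) - Hi, y[s:t_] - mu[s:t_])
                ei = ri / sq[s:t_]
            if alpha != 0.0:
                c = alpha / (1.0 + (m - 1.0) * alpha)
                ui = (Zi.T @ ei - c * Zi.sum(axis=0) * ei.sum()) / (1.0 - alpha)
            else:
                ui = Zi.T @ ei
            meat += np.outer(ui, ui)
            contribs[k] = Hinv @ ui
        return meat, contribs

    @staticmethod
    def _rinv(m: int, alpha: float) -> np.ndarray:
        if alpha == 0.0 or m == 1:
            return np.eye(m)
        c = alpha / (1.0 + (m - 1.0) * alpha)
        return (np.eye(m) - c * np.ones((m, m))) / (1.0 - alpha)

    # -------------------------------------------------------------- predict
    def predict(self, X, offset=None) -> np.ndarray:
        """Expected counts exp(offset + X beta)."""
        if not hasattr(self, "params_"):
            raise ValueError("estimator is not fitted")
        Xv = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else \
            np.asarray(X, dtype=float)
        if Xv.ndim == 1:
            Xv = Xv[:, None]
        eta = self.intercept_ + Xv @ self.coef_
        if offset is not None:
            eta = eta + np.asarray(offset, dtype=float)
        return np.exp(eta)

    def robust_se(self) -> pd.Series:
        """Sandwich standard errors by term name."""
        if not hasattr(self, "cov_robust_"):
            raise ValueError("estimator is not fitted")
        return pd.Series(np.sqrt(np.diag(self.cov_robust_.to_numpy())),
                         index=self.params_.index)

    def naive_se(self) -> pd.Series:
        """Model-based standard errors by term name."""
        if not hasattr(self, "cov_naive_"):
            raise ValueError("estimator is not fitted")
        return pd.Series(np.sqrt(np.diag(self.cov_naive_.to_numpy())),
                         index=self.params_.index)
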