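"""Marker-only semi-supervised Gaussian mixture baseline.

A standalone EM implementation that uses only the marker block: component
means are ``alpha_j + rho[j, k] * beta[j, k]`` with ``beta >= 0`` and a
diagonal covariance shared across components, and the label prior is uniform
(no spatial coupling, no factor model).  It serves as the non-spatial
contrast method in benchmarks and is deliberately written as its own code
path, independent of the full model's kernels and M-steps.
"""
from __future__ import annotations

import numpy as np
from scipy.special import logsumexp
from scipy.stats import norm


class MarkerOnlyGMM:
    """Semi-supervised diagonal GMM over marker genes.

    Parameters
    ----------
    rho
        Binary ``(m, K_eff)`` marker indicator (a trailing all-zero column
        realizes an "unknown" component).
    max_iter, tol
        EM iteration cap and relative log-likelihood convergence tolerance.
    """

    def __init__(self, rho: np.ndarray, max_iter: int = 200,
                 tol: float = 1e-10, var_floor: float = 1e-6):
        self.rho = np.asarray(rho, dtype=float)
        self.max_iter = max_iter
        self.tol = tol
        self.var_floor = var_floor
        self.alpha_: np.ndarray | None = None
        self.beta_: np.ndarray | None = None
        self.sigma2_: np.ndarray | None = None

    # --- model pieces -----------------------------------------------------
    def _component_loglik(self, x1: np.ndarray, alpha: np.ndarray,
                          beta: np.ndarray, sigma2: np.ndarray) -> np.ndarray:
        n = x1.shape[0]
        K = self.rho.shape[1]
        out = np.empty((n, K))
        sd = np.sqrt(sigma2)
        for k in range(K):
            mu_k = alpha + self.rho[:, k] * beta[:, k]
            out[:, k] = norm.logpdf(x1, loc=mu_k[None, :],
                                    scale=sd[None, :]).sum(axis=1)
        return out

    def _m_step(self, x1: np.ndarray, R: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        n, m = x1.shape
        K = self.rho.shape[1]
        Nk = R.sum(axis=0)
        alpha = np.zeros(m)
        beta = np.zeros((m, K))
        for j in range(m):
            xj = x1[:, j]
            a, b = 0.0, np.zeros(K)
            for _ in range(500):
                b_new = np.zeros(K)
                for k in range(K):
                    if self.rho[j, k] == 1 and Nk[k] > 0:
                        b_new[k] = max(0.0, R[:, k] @ xj / Nk[k] - a)
                a_new = (xj.sum() - float((self.rho[j] * b_new) @ Nk)) / n
                if max(abs(a_new - a), np.abs(b_new - b).max()) < 1e-8:
                    a, b = a_new, b_new
                    break
                a, b = a_new, b_new
            alpha[j], beta[j] = a, b
        sigma2 = np.empty(m)
        for j in range(m):
            mu_j = alpha[j] + self.rho[j] * beta[j]          # (K,)
            resid = (x1[:, j][:, None] - mu_j[None, :]) ** 2
            sigma2[j] = max((R * resid).sum() / n, self.var_floor)
        return alpha, beta, sigma2

    # --- public API -------------------------------------------------------
    def fit(self, x1: np.ndarray, alpha0: np.ndarray, beta0: np.ndarray,
            sigma2_0: np.ndarray) -> "MarkerOnlyGMM":
        """Run EM from the supplied initial parameters."""
        x1 = np.asarray(x1, dtype=float)
        alpha, beta, sigma2 = (np.asarray(alpha0, dtype=float).copy(),
                               np.asarray(beta0, dtype=float).copy(),
                               np.asarray(sigma2_0, dtype=float).copy())
        prev = -np.inf
        for _ in range(self.max_iter):
            ll = self._component_loglik(x1, alpha, beta, sigma2)
            norm_i = logsumexp(ll, axis=1)
            R = np.exp(ll - norm_i[:, None])
            obj = float(norm_i.sum())
            alpha, beta, sigma2 = self._m_step(x1, R)
            if abs(obj - prev) / max(1.0, abs(prev)) < self.tol:
                break
            prev = obj
        self.alpha_, self.beta_, self.sigma2_ = alpha, beta, sigma2
        return self

    def predict_proba(self, x1: np.ndarray) -> np.ndarray:
        """Responsibilities under the fitted parameters."""
        if self.alpha_ is None:
            raise RuntimeError("fit() must run first")
        ll = self._component_loglik(np.asarray(x1, dtype=float),
                                    self.alpha_, self.beta_, self.sigma2_)
        return np.exp(ll - logsumexp(ll, axis=1)[:, None])
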