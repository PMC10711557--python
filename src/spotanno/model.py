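"""Per-spot, per-type log-likelihood kernels and Potts prior terms.

Three ingredients combine into the posterior over labels:

* a semi-supervised Gaussian mixture on the marker block, whose component
  means are a shared baseline ``alpha`` plus a non-negative elevation
  ``beta[j, k]`` wherever gene ``j`` marks type ``k``;
* the marginal of a shared-loading factor model on the non-marker block,
  ``x2_i ~ N(L m_k, L V L^T + diag(Lambda))``, evaluated in the
  q-dimensional Woodbury form so the p x p covariance is never built;
* a Potts prior over labels on the spatial neighbor graph, used through its
  local (pseudo-likelihood) conditionals during inference.

A brute-force partition-function evaluator is provided purely as a test
oracle for tiny graphs.
"""
from __future__ import annotations

import itertools

import numpy as np
from scipy.special import logsumexp

from .types import ModelParams, NeighborGraph

LOG2PI = float(np.log(2.0 * np.pi))

#: variance floor applied to sigma2 and Lambda during fitting
VAR_FLOOR = 1e-6


def marker_loglik(x1: np.ndarray, params: ModelParams) -> np.ndarray:
    """Log N(x1_i; alpha + rho_k * beta_k, diag(sigma2)) for every spot/type.

    Returns an ``(n, K_eff)`` matrix.  The diagonal covariance factorizes the
    density over genes; the "unknown" component (rho column of zeros) reduces
    to the baseline mean ``alpha``.
    """
    x1 = np.asarray(x1, dtype=float)
    if not np.all(np.isfinite(x1)):
        raise ValueError("non-finite values in marker expression")
    mu = params.mu()                      # (m, K_eff)
    inv = 1.0 / params.sigma2             # (m,)
    const = -0.5 * np.sum(LOG2PI + np.log(params.sigma2))
    # (x_ij - mu_jk)^2 expanded to avoid an (n, m, K) intermediate
    x2s = (x1 ** 2) @ inv                 # (n,)
    cross = x1 @ (mu * inv[:, None])      # (n, K_eff)
    mu2 = np.sum(mu ** 2 * inv[:, None], axis=0)   # (K_eff,)
    return const - 0.5 * (x2s[:, None] - 2.0 * cross + mu2[None, :])


class FactorModelKernel:
    """Woodbury factorization of the non-marker covariance, reused across
    marginal likelihood and posterior-moment computations.

    With ``Sigma = L V L^T + diag(Lambda)``:
      ``Sigma^-1 = Lam^-1 - Lam^-1 L M^-1 L^T Lam^-1``,
      ``log|Sigma| = log|Lambda| + log|V| + log|M|``,
    where ``M = V^-1 + L^T Lam^-1 L`` is q x q.  The label-conditional
    posterior of the factor is ``N(m_k + M^-1 L^T Lam^-1 (x - L m_k), M^-1)``.
    """

    def __init__(self, params: ModelParams):
        L, Lam, V = params.L, params.Lambda, params.V
        self.params = params
        self.q = L.shape[1]
        w, _ = np.linalg.eigh(V)
        if w.min() <= 0:
            raise ValueError(
                f"V is not positive definite (smallest eigenvalue {w.min():.3e})")
        self.Vinv = np.linalg.inv(V)
        self.Linv_lam = L / Lam[:, None]              # Lam^-1 L, (p, q)
        self.H = L.T @ self.Linv_lam                  # L^T Lam^-1 L, (q, q)
        self.M = self.Vinv + self.H
        self.Minv = np.linalg.inv(self.M)
        self.Minv = 0.5 * (self.Minv + self.Minv.T)
        sign, logdet_M = np.linalg.slogdet(self.M)
        if sign <= 0:
            raise ValueError("Woodbury core matrix is not positive definite")
        self.logdet_sigma = (np.sum(np.log(Lam))
                             + np.linalg.slogdet(V)[1] + logdet_M)

    def marginal_loglik(self, x2: np.ndarray) -> np.ndarray:
        """``(n, K_eff)`` matrix of log N(x2_i; L m_k, L V L^T + Lambda)."""
        x2 = np.asarray(x2, dtype=float)
        if not np.all(np.isfinite(x2)):
            raise ValueError("non-finite values in non-marker expression")
        p = x2.shape[1]
        mk = self.params.mk                            # (K, q)
        G = x2 @ self.Linv_lam                         # L^T Lam^-1 x_i rows, (n, q)
        a = np.einsum("ij,ij->i", x2, x2 / self.params.Lambda[None, :])
        Hm = mk @ self.H                               # (K, q)
        b = np.einsum("kq,kq->k", mk, Hm)
        c = G @ mk.T                                   # (n, K)
        # quadratic form through Lam^-1 of the residual
        quad_lam = a[:, None] + b[None, :] - 2.0 * c
        # correction term  w^T M^-1 w  with  w = G_i - H m_k
        GM = G @ self.Minv                             # (n, q)
        t1 = np.einsum("iq,iq->i", GM, G)              # (n,)
        t2 = GM @ Hm.T                                 # (n, K)
        HMH = Hm @ self.Minv
        t3 = np.einsum("kq,kq->k", HMH, Hm)            # (K,)
        corr = t1[:, None] - 2.0 * t2 + t3[None, :]
        quad = quad_lam - corr
        return -0.5 * (p * LOG2PI + self.logdet_sigma + quad)

    def posterior_z(self, x2: np.ndarray, k: int | None = None
                    ) -> tuple[np.ndarray, np.ndarray]:
        """Posterior mean(s) of z given x2 and label, and shared covariance.

        With ``k`` given, returns ``(means (n, q), cov (q, q))`` for that
        component; with ``k=None``, means for all components stacked as an
        ``(n, K_eff, q)`` array.  The posterior covariance ``M^-1`` does not
        depend on the data or the component.
        """
        x2 = np.atleast_2d(np.asarray(x2, dtype=float))
        G = x2 @ self.Linv_lam                        # (n, q)
        mk = self.params.mk
        if k is not None:
            innov = G - (self.H @ mk[k])[None, :]
            return mk[k][None, :] + innov @ self.Minv, self.Minv
        innov = G[:, None, :] - (mk @ self.H)[None, :, :]     # (n, K, q)
        return mk[None, :, :] + innov @ self.Minv, self.Minv


def factor_marginal_loglik(x2: np.ndarray, params: ModelParams) -> np.ndarray:
    """Convenience wrapper building the kernel once per call."""
    return FactorModelKernel(params).marginal_loglik(x2)


def factor_posterior_z(x2_i: np.ndarray, k: int,
                       params: ModelParams) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mean and covariance of the factor for one spot and type."""
    mean, cov = FactorModelKernel(params).posterior_z(
        np.atleast_2d(x2_i), k=k)
    return mean[0], cov


def potts_neighbor_logterm(labels: np.ndarray, i: int, k: int,
                           graph: NeighborGraph, xi: float) -> float:
    """Local Potts prior term ``-xi * #{neighbors of i with label != k}``."""
    labels = np.asarray(labels)
    nb = graph.neighbors(i)
    if nb.size == 0 or xi == 0:
        return 0.0
    return float(-xi * np.count_nonzero(labels[nb] != k))


def potts_local_terms(labels: np.ndarray, graph: NeighborGraph, xi: float,
                      K_eff: int) -> np.ndarray:
    """Vectorized ``(n, K_eff)`` matrix of local Potts terms.

    Entry ``(i, k)`` is ``-xi * (deg(i) - #{neighbors of i labeled k})``.
    """
    labels = np.asarray(labels, dtype=int)
    n = graph.n_spots
    agree = np.zeros((n, K_eff))
    deg = graph.degree().astype(float)
    if graph.n_edges:
        e = graph.edges
        np.add.at(agree, (e[:, 0], labels[e[:, 1]]), 1.0)
        np.add.at(agree, (e[:, 1], labels[e[:, 0]]), 1.0)
    return -xi * (deg[:, None] - agree)


def potts_log_unnorm(labels: np.ndarray, graph: NeighborGraph,
                     xi: float) -> float:
    """Log of the unnormalized Potts mass ``-xi * #disagreeing edges``."""
    labels = np.asarray(labels)
    if graph.n_edges == 0:
        return 0.0
    e = graph.edges
    return float(-xi * np.count_nonzero(labels[e[:, 0]] != labels[e[:, 1]]))


def potts_partition_bruteforce(graph: NeighborGraph, K_eff: int,
                               xi: float) -> float:
    """Exact ``log C(xi)`` by enumerating all ``K_eff**n`` label fields.

    Test oracle only; refuses instances beyond 10**6 configurations.
    """
    n = graph.n_spots
    total = K_eff ** n
    if total > 10 ** 6:
        raise ValueError(
            f"brute force refused: {K_eff}^{n} = {total} configurations")
    terms = np.empty(total)
    for idx, cfg in enumerate(itertools.product(range(K_eff), repeat=n)):
        terms[idx] = potts_log_unnorm(np.asarray(cfg), graph, xi)
    return float(logsumexp(terms))


def potts_exact_conditional(labels: np.ndarray, i: int, graph: NeighborGraph,
                            K_eff: int, xi: float) -> np.ndarray:
    """Exact ``p(y_i = k | y_{-i})`` from the joint Potts mass (test oracle).

    Computed by evaluating the unnormalized joint at each candidate label of
    site ``i`` with all other labels held fixed.
    """
    labels = np.asarray(labels).copy()
    logw = np.empty(K_eff)
    for k in range(K_eff):
        labels[i] = k
        logw[k] = potts_log_unnorm(labels, graph, xi)
    return np.exp(logw - logsumexp(logw))
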