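"""Independent brute-force oracles used only by the tests.

Everything here is deliberately naive (dense covariances, explicit pair
counting, exhaustive enumeration) and shares no code with the package paths
it checks.
"""
from __future__ import annotations

import itertools
import math

import numpy as np


# --- dense Gaussian oracles ---------------------------------------------

def dense_gaussian_logpdf(x: np.ndarray, mean: np.ndarray,
                          cov: np.ndarray) -> float:
    """Log N(x; mean, cov) via explicit p x p determinant and solve."""
    p = x.shape[0]
    diff = x - mean
    sign, logdet = np.linalg.slogdet(cov)
    assert sign > 0
    quad = diff @ np.linalg.solve(cov, diff)
    return -0.5 * (p * math.log(2 * math.pi) + logdet + quad)


def dense_factor_marginal(x2: np.ndarray, L: np.ndarray, Lambda: np.ndarray,
                          mk: np.ndarray, V: np.ndarray) -> np.ndarray:
    """(n, K) marginal log-density forming the full p x p covariance."""
    cov = L @ V @ L.T + np.diag(Lambda)
    out = np.empty((x2.shape[0], mk.shape[0]))
    for i in range(x2.shape[0]):
        for k in range(mk.shape[0]):
            out[i, k] = dense_gaussian_logpdf(x2[i], L @ mk[k], cov)
    return out


def joint_conditioning_posterior(x2_i: np.ndarray, L: np.ndarray,
                                 Lambda: np.ndarray, m_k: np.ndarray,
                                 V: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Posterior of z given x via conditioning the dense (p+q) joint Gaussian."""
    p, q = L.shape
    mean_joint = np.concatenate([L @ m_k, m_k])
    Sxx = L @ V @ L.T + np.diag(Lambda)
    Sxz = L @ V
    joint = np.block([[Sxx, Sxz], [Sxz.T, V]])
    mu_x, mu_z = mean_joint[:p], mean_joint[p:]
    Sinv_diff = np.linalg.solve(Sxx, x2_i - mu_x)
    mean = mu_z + Sxz.T @ Sinv_diff
    cov = V - Sxz.T @ np.linalg.solve(Sxx, Sxz)
    return mean, cov


# --- metric oracles ------------------------------------------------------

def oracle_accuracy(pred: list[str], true: list[str]) -> float:
    return sum(p == t for p, t in zip(pred, true)) / len(true)


def oracle_kappa(pred: list[str], true: list[str]) -> float:
    labels = sorted(set(pred) | set(true))
    n = len(true)
    po = oracle_accuracy(pred, true)
    pe = sum((sum(t == c for t in true) / n) * (sum(p == c for p in pred) / n)
             for c in labels)
    if pe == 1.0:
        return 0.0
    return (po - pe) / (1 - pe)


def oracle_mean_f1(pred: list[str], true: list[str]) -> float:
    f1s = []
    for c in sorted(set(true)):
        tp = sum(p == c and t == c for p, t in zip(pred, true))
        fp = sum(p == c and t != c for p, t in zip(pred, true))
        fn = sum(p != c and t == c for p, t in zip(pred, true))
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1s.append(2 * prec * rec / (prec + rec) if prec + rec else 0.0)
    return sum(f1s) / len(f1s)


def oracle_ari(pred: list[str], true: list[str]) -> float:
    """ARI by enumerating all unordered pairs of items."""
    n = len(true)
    both = same_p = same_t = 0
    n_pairs = 0
    for i, j in itertools.combinations(range(n), 2):
        n_pairs += 1
        sp = pred[i] == pred[j]
        st = true[i] == true[j]
        both += sp and st
        same_p += sp
        same_t += st
    expected = same_p * same_t / n_pairs if n_pairs else 0.0
    max_index = 0.5 * (same_p + same_t)
    if max_index == expected:
        return 1.0 if both == expected else 0.0
    return (both - expected) / (max_index - expected)


# --- small-problem EM oracle ---------------------------------------------

def semisupervised_gmm_responsibilities(x1, rho, alpha, beta, sigma2):
    """One E-step of the marker GMM, computed gene-by-gene in plain loops."""
    n, m = x1.shape
    K = rho.shape[1]
    ll = np.zeros((n, K))
    for k in range(K):
        for j in range(m):
            mu = alpha[j] + rho[j, k] * beta[j, k]
            ll[:, k] += (-0.5 * math.log(2 * math.pi * sigma2[j])
                         - (x1[:, j] - mu) ** 2 / (2 * sigma2[j]))
    mx = ll.max(axis=1, keepdims=True)
    w = np.exp(ll - mx)
    return w / w.sum(axis=1, keepdims=True)
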