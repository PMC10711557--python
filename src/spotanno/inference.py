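"""ICM-EM fitting of the spatial annotation model.

The fit alternates: (i) iterated-conditional-modes (ICM) sweeps that update
hard labels under the Potts-coupled objective, (ii) a responsibility update
combining marker, factor and local Potts terms, (iii) M-steps for the marker
mixture and the shared-loading factor model, and (iv) a pseudo-likelihood
grid search for the Potts interaction ``xi``.  The Potts partition function
is never evaluated during fitting.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.special import logsumexp
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .model import (VAR_FLOOR, FactorModelKernel, marker_loglik,
                    potts_local_terms, potts_log_unnorm)
from .types import (UNKNOWN_LABEL, AnnotationResult, ExpressionBundle,
                    MarkerMap, ModelParams, NeighborGraph)

logger = logging.getLogger(__name__)

DEFAULT_XI_GRID = np.round(np.arange(0.0, 2.0 + 1e-9, 0.1), 10)


@dataclass
class FitConfig:
    """Tunable knobs of the fit.

    ``q`` is the embedding dimension (default 15), ``unknown`` toggles the
    extra null-elevation component that absorbs spots matching no marker
    profile, and ``unknown_threshold`` additionally relabels low-confidence
    spots (0 disables).  ``fix_xi`` pins the Potts interaction instead of
    grid-searching it; ``use_factor=False`` pins ``L = 0`` so only marker
    genes inform the labels.
    """

    q: int = 15
    max_iter: int = 30
    tol: float = 1e-6
    seed: int = 0
    unknown: bool = True
    unknown_threshold: float = 0.0
    use_factor: bool = True
    fix_xi: float | None = None
    xi_grid: np.ndarray = field(default_factory=lambda: DEFAULT_XI_GRID.copy())
    icm_sweeps: int = 10
    kmeans_n_init: int = 10
    unknown_init_clusters: int = 2


def effective_rho(markers: MarkerMap, unknown: bool) -> np.ndarray:
    """rho with the all-zero "unknown" column appended when enabled."""
    rho = markers.rho.astype(np.int8)
    if unknown:
        rho = np.hstack([rho, np.zeros((rho.shape[0], 1), dtype=np.int8)])
    return rho


def initialize_params(bundle: ExpressionBundle, markers: MarkerMap,
                      q: int, seed: int, unknown: bool = True,
                      kmeans_n_init: int = 10,
                      unknown_init_clusters: int = 2,
                      ) -> tuple[ModelParams, np.ndarray]:
    """PCA + k-means initialization with Hungarian cluster-to-type matching.

    Clusters are matched to types by maximizing the mean expression of each
    type's marker set within the cluster.  With the unknown component
    enabled, k-means is run with ``unknown_init_clusters`` surplus clusters
    and every unmatched cluster seeds the unknown component — over-clustering
    lets it start on multiple novel populations at once instead of locking
    onto a single one.  Returns initial parameters and labels.
    """
    x1, x2 = bundle.x1, bundle.x2
    n, p = x2.shape
    K = markers.n_types
    K_eff = K + (1 if unknown else 0)
    n_clusters = K + (unknown_init_clusters if unknown else 0)
    if q < 1:
        raise ValueError("q must be >= 1")
    if q > p:
        raise ValueError(f"q={q} exceeds the number of non-marker genes {p}")
    if n_clusters >= n:
        raise ValueError(f"need more spots ({n}) than clusters ({n_clusters})")

    svd = "full" if min(n, p) <= 500 else "randomized"
    pca = PCA(n_components=q, svd_solver=svd, random_state=seed)
    scores = pca.fit_transform(x2)                       # (n, q)
    L = pca.components_.T                                # (p, q), orthonormal

    clusters = None
    for attempt in range(2):
        km = KMeans(n_clusters=n_clusters, n_init=kmeans_n_init,
                    random_state=seed + attempt)
        cand = km.fit_predict(scores)
        if np.all(np.bincount(cand, minlength=n_clusters) > 0):
            clusters = cand
            break
        logger.warning("empty k-means cluster; re-seeding once")
    if clusters is None:
        raise RuntimeError("k-means produced an empty cluster twice")

    # cluster-to-type matching on mean marker-set expression
    score_ck = np.zeros((n_clusters, K))
    for c in range(n_clusters):
        in_c = clusters == c
        for k in range(K):
            genes = np.flatnonzero(markers.rho[:, k])
            if genes.size:
                score_ck[c, k] = x1[np.ix_(in_c, genes)].mean()
    rows, cols = linear_sum_assignment(-score_ck)
    # unmatched clusters (only possible with the unknown component) -> K
    comp_of_cluster = np.full(n_clusters, K if unknown else -1, dtype=int)
    for c, k in zip(rows.tolist(), cols.tolist()):
        comp_of_cluster[c] = k
    labels = comp_of_cluster[clusters]

    rho = effective_rho(markers, unknown)
    m = x1.shape[1]
    alpha = np.zeros(m)                                  # data are centered
    beta = np.zeros((m, K_eff))
    for k in range(K_eff):
        in_k = labels == k
        if not np.any(in_k):
            continue
        elev = x1[in_k].mean(axis=0) - x1.mean(axis=0)
        beta[:, k] = np.maximum(0.0, elev) * rho[:, k]
    mu = alpha[:, None] + rho * beta
    resid1 = x1 - mu[:, labels].T
    sigma2 = np.maximum(resid1.var(axis=0), VAR_FLOOR)

    mk = np.zeros((K_eff, q))
    for k in range(K_eff):
        in_k = labels == k
        if np.any(in_k):
            mk[k] = scores[in_k].mean(axis=0)
    within = scores - mk[labels]
    V = (within.T @ within) / n + 1e-6 * np.eye(q)
    resid2 = x2 - scores @ L.T
    Lambda = np.maximum(resid2.var(axis=0), VAR_FLOOR)

    params = ModelParams(alpha=alpha, beta=beta, sigma2=sigma2, L=L,
                         Lambda=Lambda, mk=mk, V=V, xi=0.5, rho=rho)
    return params, labels


def _kernels(bundle: ExpressionBundle, params: ModelParams,
             use_factor: bool = True) -> np.ndarray:
    """Marker + factor log-likelihood kernel, shape ``(n, K_eff)``."""
    ker = marker_loglik(bundle.x1, params)
    if use_factor:
        ker = ker + FactorModelKernel(params).marginal_loglik(bundle.x2)
    return ker


def update_responsibilities(bundle: ExpressionBundle, params: ModelParams,
                            labels: np.ndarray, graph: NeighborGraph,
                            use_factor: bool = True,
                            kernels: np.ndarray | None = None,
                            ) -> tuple[np.ndarray, float]:
    """Posterior responsibilities under the local (pseudo) Potts prior.

    ``R[i, k] ~ exp(marker + factor + potts_local)``, rows normalized by
    log-sum-exp.  Returns ``(R, objective)`` where the objective is the summed
    pseudo marginal log-likelihood ``sum_i logsumexp_k(...)``.
    """
    if kernels is None:
        kernels = _kernels(bundle, params, use_factor)
    logpost = kernels + potts_local_terms(labels, graph, params.xi,
                                         params.n_components)
    if not np.all(np.isfinite(logpost)):
        bad = int(np.flatnonzero(~np.isfinite(logpost).all(axis=1))[0])
        raise FloatingPointError(f"non-finite kernel at spot index {bad}")
    norm = logsumexp(logpost, axis=1)
    R = np.exp(logpost - norm[:, None])
    assert np.abs(R.sum(axis=1) - 1.0).max() < 1e-8
    return R, float(norm.sum())


def icm_labels(bundle: ExpressionBundle, params: ModelParams,
               labels: np.ndarray, graph: NeighborGraph,
               max_sweeps: int = 10, use_factor: bool = True,
               kernels: np.ndarray | None = None) -> np.ndarray:
    """Sequential ICM sweeps on the Potts-coupled hard-label objective.

    Each site moves to the label maximizing its likelihood kernel plus the
    local Potts term; the joint pseudo-objective
    ``sum_i kernel_i(y_i) - xi * #disagreeing edges`` is non-decreasing
    across sweeps (asserted) and sweeps stop at the first fixed point.
    """
    if max_sweeps < 1:
        raise ValueError("max_sweeps must be >= 1")
    if kernels is None:
        kernels = _kernels(bundle, params, use_factor)
    labels = np.asarray(labels, dtype=int).copy()
    xi = params.xi
    adj = graph.adjacency
    K_eff = params.n_components
    prev_obj = -np.inf
    for _ in range(max_sweeps):
        changed = 0
        for i in range(labels.shape[0]):
            nb = adj[i]
            score = kernels[i].copy()
            if nb.size and xi > 0:
                agree = np.bincount(labels[nb], minlength=K_eff)
                score += xi * agree.astype(float)   # -xi*(deg-agree) + const
            new = int(np.argmax(score))             # ties -> lowest index
            if new != labels[i]:
                labels[i] = new
                changed += 1
        obj = (kernels[np.arange(labels.shape[0]), labels].sum()
               + potts_log_unnorm(labels, graph, xi))
        assert obj >= prev_obj - 1e-9 * max(1.0, abs(prev_obj)), \
            "ICM objective decreased"
        prev_obj = obj
        if changed == 0:
            break
    return labels


def m_step_marker(bundle: ExpressionBundle, R: np.ndarray,
                  rho: np.ndarray, tol: float = 1e-8,
                  max_iter: int = 500) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weighted least-squares update of (alpha, beta, sigma2) with beta >= 0.

    Per gene the responsibility-weighted squared error is minimized by
    coordinate descent alternating the shared baseline ``alpha_j`` with the
    non-negatively projected elevations ``beta_jk``; iterated to ``tol``.
    """
    x1 = bundle.x1
    n, m = x1.shape
    K_eff = R.shape[1]
    Nk = R.sum(axis=0)                       # (K_eff,)
    T = x1.T @ R                             # (m, K_eff)
    colsum = x1.sum(axis=0)                  # (m,)
    rho_f = rho.astype(float)
    safe_Nk = np.where(Nk > 0, Nk, 1.0)

    alpha = np.zeros(m)
    beta = np.zeros((m, K_eff))
    for _ in range(max_iter):
        beta_new = np.maximum(0.0, T / safe_Nk[None, :] - alpha[:, None]) * rho_f
        beta_new[:, Nk == 0] = beta[:, Nk == 0]
        alpha_new = (colsum - (beta_new * rho_f * Nk[None, :]).sum(axis=1)) / n
        delta = max(np.abs(alpha_new - alpha).max(initial=0.0),
                    np.abs(beta_new - beta).max(initial=0.0))
        alpha, beta = alpha_new, beta_new
        if delta < tol:
            break
    mu = alpha[:, None] + rho_f * beta       # (m, K_eff)
    sq = ((x1 ** 2).T @ R).sum(axis=1)       # sum_ik R_ik x_ij^2
    cross = (mu * T).sum(axis=1)
    mu2 = (mu ** 2 * Nk[None, :]).sum(axis=1)
    sigma2 = np.maximum((sq - 2.0 * cross + mu2) / n, VAR_FLOOR)
    return alpha, beta, sigma2


def m_step_factor(bundle: ExpressionBundle, R: np.ndarray,
                  params: ModelParams,
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Closed-form factor-model update (L, Lambda, m_k, V).

    Posterior factor moments are mixed over responsibilities; the loading is
    re-orthonormalized by SVD with the scale absorbed into the factor space
    (``L^T L = I_q``) and type means are recentered so the responsibility-
    weighted mean embedding is zero.
    """
    x2 = bundle.x2
    n, p = x2.shape
    q = params.q
    K_eff = params.n_components
    kern = FactorModelKernel(params)
    mu, Minv = kern.posterior_z(x2)          # (n, K_eff, q), (q, q)
    Nk = R.sum(axis=0)

    Ez = np.einsum("ik,ikq->iq", R, mu)      # (n, q) mixed posterior mean
    Cxz = x2.T @ Ez                          # (p, q)
    S = n * Minv + np.einsum("ik,ikq,ikr->qr", R, mu, mu)
    S = 0.5 * (S + S.T)
    try:
        L = np.linalg.solve(S, Cxz.T).T
    except np.linalg.LinAlgError:
        logger.warning("rank-deficient second-moment matrix; adding ridge")
        L = np.linalg.solve(S + 1e-8 * np.eye(q), Cxz.T).T
    if np.linalg.cond(S) > 1e12:
        logger.warning("ill-conditioned second-moment matrix; adding ridge")
        L = np.linalg.solve(S + 1e-8 * np.eye(q), Cxz.T).T

    xx = (x2 ** 2).sum(axis=0)               # (p,)
    LS = L @ S
    Lambda = np.maximum(
        (xx - 2.0 * (L * Cxz).sum(axis=1) + (LS * L).sum(axis=1)) / n,
        VAR_FLOOR)

    mk = params.mk.copy()
    for k in range(K_eff):
        if Nk[k] <= 1e-12:
            logger.warning("component %d has zero responsibility; "
                           "its factor mean is left unchanged", k)
            continue
        mk[k] = (R[:, k] @ mu[:, k, :]) / Nk[k]
    mk = mk - (Nk @ mk)[None, :] / n         # sum_k N_k m_k = 0

    dev = mu - mk[None, :, :]
    V = Minv + np.einsum("ik,ikq,ikr->qr", R, dev, dev) / n
    V = 0.5 * (V + V.T)

    # identifiability: thin SVD L = U D W^T; keep U, push D W^T into z-space
    U, D, Wt = np.linalg.svd(L, full_matrices=False)
    T = D[:, None] * Wt                      # (q, q)
    L = U
    mk = mk @ T.T
    V = T @ V @ T.T
    V = 0.5 * (V + V.T) + 1e-10 * np.eye(q)
    return L, Lambda, mk, V


def estimate_xi(labels: np.ndarray, graph: NeighborGraph,
                grid: np.ndarray | None = None,
                K_eff: int | None = None) -> float:
    """Maximum pseudo-likelihood estimate of the Potts interaction.

    Maximizes ``sum_i log p(y_i | y_neighbors, xi)`` over the grid (default
    0 to 2, step 0.1); ties keep the smallest grid value.  ``K_eff`` is the
    number of label states the prior ranges over (at least 2 even if the
    observed field is constant).
    """
    if grid is None:
        grid = DEFAULT_XI_GRID
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0 or np.any(grid < 0):
        raise ValueError("xi grid must be nonempty and non-negative")
    labels = np.asarray(labels, dtype=int)
    if K_eff is None:
        K_eff = max(2, int(labels.max()) + 1)
    n = graph.n_spots
    # d[i, k] = number of neighbors of i with label != k
    agree = np.zeros((n, K_eff))
    if graph.n_edges:
        e = graph.edges
        np.add.at(agree, (e[:, 0], labels[e[:, 1]]), 1.0)
        np.add.at(agree, (e[:, 1], labels[e[:, 0]]), 1.0)
    deg = graph.degree().astype(float)
    d = deg[:, None] - agree                 # (n, K_eff)
    d_obs = d[np.arange(n), labels]
    pll = np.array([
        (-xi * d_obs - logsumexp(-xi * d, axis=1)).sum() for xi in grid
    ])
    return float(grid[int(np.argmax(pll))])


def extract_embeddings(bundle: ExpressionBundle, params: ModelParams,
                       R: np.ndarray) -> np.ndarray:
    """Responsibility-mixed posterior factor means, shape ``(n, q)``."""
    mu, _ = FactorModelKernel(params).posterior_z(bundle.x2)
    return np.einsum("ik,ikq->iq", R, mu)


def finalize_labels(R: np.ndarray, type_names: list[str],
                    unknown: bool = True, threshold: float = 0.0,
                    ) -> list[str]:
    """Hard labels from responsibilities, with "unknown" assignment.

    Spots whose argmax is the unknown component, or whose max posterior does
    not exceed ``threshold`` (a uniform row at threshold 0.5 is "unknown";
    the default 0 disables the rule), are labeled :data:`UNKNOWN_LABEL`.
    Argmax ties break toward the lowest type index (logged).
    """
    R = np.asarray(R, dtype=float)
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [0, 1]")
    K = len(type_names)
    names = list(type_names) + ([UNKNOWN_LABEL] if unknown else [])
    if R.shape[1] != len(names):
        raise ValueError("responsibility columns disagree with type names")
    hard = np.argmax(R, axis=1)
    maxima = R[np.arange(R.shape[0]), hard]
    n_ties = int(np.sum(np.sum(R == maxima[:, None], axis=1) > 1))
    if n_ties:
        logger.info("%d argmax ties broken toward the lowest type index",
                    n_ties)
    out = []
    for i, k in enumerate(hard):
        if (unknown and k == K) or (threshold > 0 and maxima[i] <= threshold):
            out.append(UNKNOWN_LABEL)
        else:
            out.append(names[k])
    return out


def fit(bundle: ExpressionBundle, markers: MarkerMap, graph: NeighborGraph,
        config: FitConfig | None = None) -> AnnotationResult:
    """Fit the full model by ICM-EM and return the annotation result.

    Each iteration runs ICM label sweeps, the responsibility update, the
    marker and factor M-steps, and the pseudo-likelihood update of ``xi``;
    the loop stops when the relative change of the pseudo marginal
    log-likelihood drops below ``config.tol`` or after ``config.max_iter``
    iterations.
    """
    config = config or FitConfig()
    params, labels = initialize_params(
        bundle, markers, q=config.q, seed=config.seed, unknown=config.unknown,
        kmeans_n_init=config.kmeans_n_init,
        unknown_init_clusters=config.unknown_init_clusters)
    if not config.use_factor:
        params.L = np.zeros_like(params.L)
    if config.fix_xi is not None:
        params.xi = float(config.fix_xi)

    trace: list[float] = []
    R = None
    for it in range(config.max_iter):
        kernels = _kernels(bundle, params, config.use_factor)
        labels = icm_labels(bundle, params, labels, graph,
                            max_sweeps=config.icm_sweeps,
                            use_factor=config.use_factor, kernels=kernels)
        R, obj = update_responsibilities(bundle, params, labels, graph,
                                         use_factor=config.use_factor,
                                         kernels=kernels)
        if not np.isfinite(obj):
            raise FloatingPointError(
                f"objective diverged at iteration {it}")
        alpha, beta, sigma2 = m_step_marker(bundle, R, params.rho)
        params.alpha, params.beta, params.sigma2 = alpha, beta, sigma2
        if config.use_factor:
            L, Lam, mk, V = m_step_factor(bundle, R, params)
            params.L, params.Lambda, params.mk, params.V = L, Lam, mk, V
        if config.fix_xi is None:
            params.xi = estimate_xi(labels, graph, config.xi_grid,
                                    K_eff=params.n_components)
        trace.append(obj)
        if it > 0:
            prev = trace[-2]
            rel = abs(obj - prev) / max(1.0, abs(prev))
            if rel < config.tol:
                break

    kernels = _kernels(bundle, params, config.use_factor)
    labels = icm_labels(bundle, params, labels, graph,
                        max_sweeps=config.icm_sweeps,
                        use_factor=config.use_factor, kernels=kernels)
    R, _ = update_responsibilities(bundle, params, labels, graph,
                                   use_factor=config.use_factor,
                                   kernels=kernels)
    emb = extract_embeddings(bundle, params, R)
    hard = finalize_labels(R, markers.type_names, unknown=config.unknown,
                           threshold=config.unknown_threshold)
    return AnnotationResult(
        responsibilities=R, labels=hard, embeddings=emb,
        xi_hat=float(params.xi), loglik_trace=trace,
        type_names=list(markers.type_names), params=params,
        spot_ids=bundle.spot_ids,
    )


def write_result(result: AnnotationResult, outdir: str | Path) -> None:
    """Write labels.csv, responsibilities.csv, embeddings.csv, params.json
    and fit_log.jsonl into ``outdir``."""
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    n = result.responsibilities.shape[0]
    spot_ids = result.spot_ids or [f"spot_{i + 1}" for i in range(n)]
    maxp = result.responsibilities.max(axis=1)
    pd.DataFrame({
        "spot_id": spot_ids, "label": result.labels, "max_posterior": maxp,
    }).to_csv(outdir / "labels.csv", index=False)
    cols = list(result.type_names)
    if result.responsibilities.shape[1] == len(cols) + 1:
        cols = cols + [UNKNOWN_LABEL]
    pd.DataFrame(result.responsibilities, index=spot_ids, columns=cols
                 ).to_csv(outdir / "responsibilities.csv",
                          index_label="spot_id")
    emb_cols = [f"z{j + 1}" for j in range(result.embeddings.shape[1])]
    pd.DataFrame(result.embeddings, index=spot_ids, columns=emb_cols
                 ).to_csv(outdir / "embeddings.csv", index_label="spot_id")
    if result.params is not None:
        (outdir / "params.json").write_text(
            json.dumps(result.params.to_dict()) + "\n")
    with open(outdir / "fit_log.jsonl", "w") as fh:
        for it, obj in enumerate(result.loglik_trace):
            fh.write(json.dumps({"iteration": it + 1, "objective": obj,
                                 "xi": result.xi_hat}) + "\n")
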