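"""Synthetic spatial-transcriptomics benchmarks.

The generator emulates a laminar tissue section: labels with Potts-type
spatial autocorrelation on a lattice (or any user-supplied layout), K types
each owning a small set of marker genes elevated in their own type, and a
large block of non-marker genes whose covariance is driven by type-separable
low-dimensional factors.  Scenario builders reproduce structural stress
tests: under-/over-specified marker lists, randomly corrupted marker
matrices, and varying non-marker counts.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .preprocess import build_neighbor_graph, normalize_and_center
from .types import (ExpressionBundle, MarkerMap, ModelParams, NeighborGraph,
                    RawExpression, SpotCoordinates)


@dataclass
class SimulationTruth:
    """Ground truth recorded for recovery tests."""

    labels: np.ndarray                 # (n,) integer type codes
    type_names: list[str]
    coords: SpotCoordinates
    rho_true: MarkerMap
    params_true: ModelParams | dict


@dataclass
class ScenarioData:
    """One simulated input set: expression, layout, provided markers, truth."""

    expression: np.ndarray | RawExpression   # centered matrix or raw counts
    gene_ids: list[str]
    coords: SpotCoordinates
    graph: NeighborGraph
    markers: MarkerMap                       # the (possibly wrong) list given
    truth: SimulationTruth


@dataclass
class ScenarioConfig:
    """Study conditions of the simulation benchmarks.

    Defaults mirror a cortical-layer-style design: seven domain types with
    five markers each (35 marker genes), 2000 non-marker genes, and roughly
    3600 spots on a square lattice standing in for a tissue layout; real
    layouts can be supplied via ``coords``.
    """

    nx: int = 60
    ny: int = 60
    K: int = 7
    m_per_type: int = 5
    p: int = 2000
    q_true: int = 15
    effect: float = 1.0
    xi_true: float = 1.0
    potts_sweeps: int = 100
    mode: str = "gaussian_model"
    coords: SpotCoordinates | None = None
    neighbor_mode: str = "st_square"
    neighbor_param: float | None = None
    flip_proportions: tuple[float, ...] = (0.1, 0.2, 0.3)
    nonmarker_counts: tuple[int, ...] = (60, 100, 500, 1000, 2000)

    def layout(self) -> tuple[SpotCoordinates, NeighborGraph]:
        coords = self.coords or lattice_coords(self.nx, self.ny)
        graph = build_neighbor_graph(coords, mode=self.neighbor_mode,
                                     param=self.neighbor_param)
        return coords, graph


def lattice_coords(nx: int, ny: int) -> SpotCoordinates:
    """Integer square lattice of ``nx * ny`` spots."""
    gx, gy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    xy = np.column_stack([gx.ravel(), gy.ravel()]).astype(float)
    ids = [f"spot_{i + 1}" for i in range(xy.shape[0])]
    return SpotCoordinates(spot_ids=ids, xy=xy)


def default_marker_map(K: int, m_per_type: int,
                       type_names: list[str] | None = None) -> MarkerMap:
    """Block-diagonal marker matrix: each type owns ``m_per_type`` genes."""
    types = type_names or [f"Type{k + 1}" for k in range(K)]
    genes = [f"marker_{types[k]}_{j + 1}"
             for k in range(K) for j in range(m_per_type)]
    rho = np.zeros((K * m_per_type, K), dtype=np.int8)
    for k in range(K):
        rho[k * m_per_type:(k + 1) * m_per_type, k] = 1
    return MarkerMap(rho=rho, marker_gene_ids=genes, type_names=types)


def sample_potts_labels(graph: NeighborGraph, K: int, xi: float,
                        sweeps: int = 100, seed: int = 0) -> np.ndarray:
    """Gibbs-sample a label field from the Potts distribution.

    Uses a chromatic (graph-colored) block Gibbs sampler: spots in an
    independent set are conditionally independent given the rest and are
    updated simultaneously.  Returns the final state.
    """
    if K < 2:
        raise ValueError("need K >= 2 labels")
    rng = np.random.default_rng(seed)
    n = graph.n_spots
    labels = rng.integers(0, K, size=n)
    if xi == 0 or graph.n_edges == 0:
        return labels
    colors = _greedy_coloring(graph)
    blocks = [np.flatnonzero(colors == c) for c in range(colors.max() + 1)]
    e = graph.edges
    for _ in range(sweeps):
        for block in blocks:
            agree = np.zeros((n, K))
            np.add.at(agree, (e[:, 0], labels[e[:, 1]]), 1.0)
            np.add.at(agree, (e[:, 1], labels[e[:, 0]]), 1.0)
            logits = xi * agree[block]                 # (n_b, K)
            logits -= logits.max(axis=1, keepdims=True)
            probs = np.exp(logits)
            probs /= probs.sum(axis=1, keepdims=True)
            u = rng.random(block.size)
            labels[block] = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
    return labels


def neighbor_agreement(labels: np.ndarray, graph: NeighborGraph) -> float:
    """Fraction of edges whose endpoints share a label."""
    if graph.n_edges == 0:
        return float("nan")
    e = graph.edges
    labels = np.asarray(labels)
    return float(np.mean(labels[e[:, 0]] == labels[e[:, 1]]))


def _greedy_coloring(graph: NeighborGraph) -> np.ndarray:
    colors = np.full(graph.n_spots, -1, dtype=int)
    for i in range(graph.n_spots):
        used = {colors[j] for j in graph.adjacency[i] if colors[j] >= 0}
        c = 0
        while c in used:
            c += 1
        colors[i] = c
    return colors


def simplex_means(K: int, q: int, scale: float) -> np.ndarray:
    """K factor means in q dimensions with equal pairwise distance ``scale``.

    Vertices of a centered regular simplex (requires ``q >= K - 1``),
    zero-padded to q dimensions.
    """
    if q < K - 1:
        raise ValueError(f"q={q} too small for a {K}-vertex simplex")
    E = np.eye(K) - np.full((K, K), 1.0 / K)
    U, s, _ = np.linalg.svd(E)
    verts = U[:, :K - 1] * s[:K - 1]          # pairwise distance sqrt(2)
    out = np.zeros((K, q))
    out[:, :K - 1] = verts * (scale / np.sqrt(2.0))
    return out


def random_orthonormal(p: int, q: int, rng: np.random.Generator) -> np.ndarray:
    A = rng.standard_normal((p, q))
    Q, _ = np.linalg.qr(A)
    return Q[:, :q]


def simulate_expression(labels: np.ndarray, coords: SpotCoordinates,
                        K: int, m_per_type: int = 5, p: int = 2000,
                        q: int = 15, effect: float = 1.0,
                        mode: str = "gaussian_model", seed: int = 0,
                        type_names: list[str] | None = None,
                        factor_scale: float | None = None,
                        ) -> tuple[np.ndarray | RawExpression, list[str], SimulationTruth]:
    """Simulate a full spot-by-gene matrix given a label field.

    ``gaussian_model`` draws exactly from the annotation model: marker genes
    at baseline 0 with own-type elevations drawn uniformly from
    ``[0.5, 1.5] * effect`` (marker strength varies across genes, as
    log-fold changes do) and unit noise, and
    non-marker genes from a shared-loading factor model whose type means sit
    on a regular simplex (pairwise distance ``factor_scale``, default
    ``3 * effect``).  ``nb_counts`` draws negative-binomial counts with the
    same mean structure on the log scale, as a count-data stand-in.

    Returns ``(expression, gene_ids, truth)`` where expression is a centered
    matrix (gaussian mode) or a :class:`RawExpression` of counts (nb mode).
    """
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels, dtype=int)
    n = labels.shape[0]
    markers = default_marker_map(K, m_per_type, type_names)
    m = markers.n_markers
    nonmarker_ids = [f"gene_{j + 1}" for j in range(p)]
    gene_ids = list(markers.marker_gene_ids) + nonmarker_ids
    fscale = 3.0 * effect if factor_scale is None else factor_scale

    beta = markers.rho.astype(float) * effect \
        * rng.uniform(0.5, 1.5, size=markers.rho.shape)
    alpha = np.zeros(m)
    sigma2 = np.ones(m)
    L = random_orthonormal(p, q, rng)
    mk = simplex_means(K, q, fscale)
    V = np.eye(q)
    Lambda = np.ones(p)
    params_true = ModelParams(alpha=alpha, beta=beta, sigma2=sigma2, L=L,
                              Lambda=Lambda, mk=mk, V=V, xi=0.0,
                              rho=markers.rho)
    z = mk[labels] + rng.standard_normal((n, q)) @ np.linalg.cholesky(V).T
    truth = SimulationTruth(labels=labels, type_names=list(markers.type_names),
                            coords=coords, rho_true=markers,
                            params_true=params_true)

    if mode == "gaussian_model":
        x1 = (alpha[:, None] + markers.rho * beta)[:, labels].T \
            + rng.standard_normal((n, m)) * np.sqrt(sigma2)[None, :]
        x2 = z @ L.T + rng.standard_normal((n, p)) * np.sqrt(Lambda)[None, :]
        X = np.hstack([x1, x2])
        X = X - X.mean(axis=0, keepdims=True)
        return X, gene_ids, truth
    if mode == "nb_counts":
        # log-mean structure mirrors the Gaussian design; moderate
        # overdispersion and log-normal library-size variation
        base = rng.normal(1.0, 0.25, size=m + p)
        logmu = np.tile(base, (n, 1))
        logmu[:, :m] += (markers.rho * beta)[:, labels].T
        logmu[:, m:] += 0.35 * (z @ L.T)
        size_factor = rng.lognormal(0.0, 0.2, size=n)
        mu = np.exp(logmu) * size_factor[:, None]
        r = 10.0                                   # NB size (1/dispersion)
        counts = rng.negative_binomial(r, r / (r + mu))
        raw = RawExpression(counts=counts.astype(float), gene_ids=gene_ids,
                            spot_ids=list(coords.spot_ids))
        truth.params_true = {"model": "nb_counts", "effect": effect,
                             "nb_size": r, "base_logmean": base.tolist()}
        return raw, gene_ids, truth
    raise ValueError(f"unknown simulation mode: {mode!r}")


def perturb_markers(markers: MarkerMap, proportion: float,
                    seed: int = 0) -> MarkerMap:
    """Two-step random corruption of the marker matrix.

    First a ``proportion`` of the one-entries of rho are flipped to zero;
    then the same number of original zero-entries are flipped to one.  The
    total count of ones is preserved exactly.
    """
    if not (0.0 <= proportion < 1.0):
        raise ValueError("proportion must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    rho = markers.rho.astype(np.int8).copy()
    ones = np.flatnonzero(rho.ravel() == 1)
    zeros = np.flatnonzero(rho.ravel() == 0)
    n_flip = int(round(proportion * ones.size))
    if n_flip == 0:
        return MarkerMap(rho=rho, marker_gene_ids=list(markers.marker_gene_ids),
                         type_names=list(markers.type_names))
    if n_flip > zeros.size:
        raise ValueError(
            f"{n_flip} flips requested but only {zeros.size} zeros available")
    flat = rho.ravel()
    flat[rng.choice(ones, size=n_flip, replace=False)] = 0
    flat[rng.choice(zeros, size=n_flip, replace=False)] = 1
    rho = flat.reshape(rho.shape)
    return MarkerMap(rho=rho, marker_gene_ids=list(markers.marker_gene_ids),
                     type_names=list(markers.type_names), strict=False)


def make_scenario(scenario: str, config: ScenarioConfig | None = None,
                  seed: int = 0) -> dict[str, ScenarioData]:
    """Build the structural simulation variants.

    Returns a mapping of variant name to :class:`ScenarioData`:

    - ``full_types``: the marker list matches the data exactly.
    - ``fewer_types``: markers for 2 types are removed from the provided
      list while the truth keeps all types (their spots should go "unknown").
    - ``extra_types``: the provided list specifies 2 additional marker-bearing
      types that never occur in the data.
    - ``flip_10_20_30``: one dataset with the clean list plus a corrupted
      marker list per flip proportion.
    - ``vary_nonmarkers``: one dataset per non-marker count.
    """
    cfg = config or ScenarioConfig()
    coords, graph = cfg.layout()
    labels = sample_potts_labels(graph, cfg.K, cfg.xi_true,
                                 sweeps=cfg.potts_sweeps, seed=seed)

    def build(K_gen: int, p: int, lab: np.ndarray, sub_seed: int,
              type_names: list[str] | None = None) -> ScenarioData:
        q = max(cfg.q_true, K_gen - 1)   # simplex means need q >= K_gen - 1
        X, gene_ids, truth = simulate_expression(
            lab, coords, K=K_gen, m_per_type=cfg.m_per_type, p=p,
            q=q, effect=cfg.effect, mode=cfg.mode, seed=sub_seed,
            type_names=type_names)
        return ScenarioData(expression=X, gene_ids=gene_ids, coords=coords,
                            graph=graph, markers=truth.rho_true, truth=truth)

    if scenario == "full_types":
        return {"full_types": build(cfg.K, cfg.p, labels, seed + 1)}
    if scenario == "fewer_types":
        sd = build(cfg.K, cfg.p, labels, seed + 1)
        keep = list(range(cfg.K - 2))
        rows = np.flatnonzero(sd.markers.rho[:, keep].sum(axis=1) > 0)
        provided = MarkerMap(
            rho=sd.markers.rho[np.ix_(rows, keep)],
            marker_gene_ids=[sd.markers.marker_gene_ids[j] for j in rows],
            type_names=[sd.markers.type_names[k] for k in keep])
        return {"fewer_types": replace(sd, markers=provided)}
    if scenario == "extra_types":
        # generate marker blocks for K+2 types but only K appear in truth
        names = [f"Type{k + 1}" for k in range(cfg.K + 2)]
        sd = build(cfg.K + 2, cfg.p, labels, seed + 1, type_names=names)
        sd.truth.type_names = names[:cfg.K]
        return {"extra_types": sd}
    if scenario == "flip_10_20_30":
        sd = build(cfg.K, cfg.p, labels, seed + 1)
        out = {"flip00": sd}
        for i, prop in enumerate(cfg.flip_proportions):
            corrupted = perturb_markers(sd.markers, prop, seed=seed + 100 + i)
            out[f"flip{int(round(prop * 100)):02d}"] = replace(
                sd, markers=corrupted)
        return out
    if scenario == "vary_nonmarkers":
        return {f"p{p}": build(cfg.K, p, labels, seed + 1 + i)
                for i, p in enumerate(cfg.nonmarker_counts)}
    raise ValueError(f"unknown scenario: {scenario!r}")


def scenario_bundle(sd: ScenarioData) -> tuple[ExpressionBundle, MarkerMap]:
    """Normalize (if counts) and split a scenario dataset on its provided
    marker list, returning the model-ready bundle and the effective map."""
    from .preprocess import split_genes

    if isinstance(sd.expression, RawExpression):
        x = normalize_and_center(sd.expression)
        gene_ids = sd.expression.gene_ids
        spot_ids = sd.expression.spot_ids
    else:
        x = sd.expression
        gene_ids = sd.gene_ids
        spot_ids = list(sd.coords.spot_ids)
    return split_genes(x, gene_ids, sd.markers, spot_ids=spot_ids)
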