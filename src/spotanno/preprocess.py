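"""Normalization, gene selection, marker/non-marker split, neighbor graphs.

The default normalization is library-size scaling to the median library size
followed by ``log1p``, then per-gene centering; pre-normalized input can be
passed through with centering only.
"""
from __future__ import annotations

import logging

import numpy as np
from scipy.spatial import cKDTree

from .types import ExpressionBundle, MarkerMap, NeighborGraph, RawExpression, SpotCoordinates

logger = logging.getLogger(__name__)


def normalize_and_center(raw: RawExpression,
                         method: str = "log1p_median_scale") -> np.ndarray:
    """Normalize counts and center every gene column to zero mean.

    ``log1p_median_scale`` computes
    ``log(1 + count_ij * median(libsize) / libsize_i)`` before centering;
    ``center_only`` assumes the input is already variance-stabilized and only
    removes per-gene means.
    """
    counts = raw.counts
    if method == "log1p_median_scale":
        lib = counts.sum(axis=1)
        zero = np.flatnonzero(lib == 0)
        if zero.size:
            bad = [raw.spot_ids[i] for i in zero[:10]]
            raise ValueError(f"spots with zero total count: {bad}")
        scaled = counts * (np.median(lib) / lib)[:, None]
        x = np.log1p(scaled)
    elif method == "center_only":
        x = counts.astype(float)
    else:
        raise ValueError(f"unknown normalization method: {method!r}")
    return x - x.mean(axis=0, keepdims=True)


def select_top_variable_genes(x: np.ndarray, n_keep: int,
                              always_keep: list[int] | None = None) -> np.ndarray:
    """Indices of the ``n_keep`` genes with largest sample variance.

    Genes listed in ``always_keep`` (e.g. markers) are retained regardless of
    rank; they count toward ``n_keep`` when they rank inside the top set and
    are appended otherwise.  Returned indices are sorted ascending.
    """
    G = x.shape[1]
    if n_keep <= 0:
        raise ValueError("n_keep must be positive")
    if n_keep > G:
        raise ValueError(f"n_keep={n_keep} exceeds gene count {G}")
    var = x.var(axis=0)
    order = np.argsort(-var, kind="stable")
    keep = set(order[:n_keep].tolist())
    if always_keep is not None:
        keep.update(int(i) for i in always_keep)
    return np.asarray(sorted(keep), dtype=int)


def split_genes(x: np.ndarray, gene_ids: list[str], markers: MarkerMap,
                spot_ids: list[str] | None = None) -> tuple[ExpressionBundle, MarkerMap]:
    """Split a centered matrix into marker block ``x1`` and non-marker ``x2``.

    Marker genes absent from ``gene_ids`` are dropped from rho with a logged
    warning; x1 columns follow the (surviving) MarkerMap row order.  Returns
    the bundle together with the possibly-reduced MarkerMap.
    """
    index = {g: i for i, g in enumerate(gene_ids)}
    present = [j for j, g in enumerate(markers.marker_gene_ids) if g in index]
    missing = [g for g in markers.marker_gene_ids if g not in index]
    if not present:
        raise ValueError("no marker gene overlaps the expression data")
    if missing:
        logger.warning("dropping %d marker genes absent from data: %s",
                       len(missing), missing[:10])
        rho = markers.rho[present, :]
        keep_types = np.flatnonzero(rho.sum(axis=0) > 0)
        if keep_types.size < markers.n_types:
            dropped = [markers.type_names[k] for k in range(markers.n_types)
                       if k not in set(keep_types.tolist())]
            logger.warning("types left without markers dropped: %s", dropped)
        markers = MarkerMap(
            rho=rho[:, keep_types],
            marker_gene_ids=[markers.marker_gene_ids[j] for j in present],
            type_names=[markers.type_names[k] for k in keep_types],
        )
    marker_cols = [index[g] for g in markers.marker_gene_ids]
    marker_set = set(marker_cols)
    nonmarker_cols = [i for i in range(len(gene_ids)) if i not in marker_set]
    bundle = ExpressionBundle(
        x1=x[:, marker_cols],
        x2=x[:, nonmarker_cols],
        marker_gene_ids=list(markers.marker_gene_ids),
        nonmarker_gene_ids=[gene_ids[i] for i in nonmarker_cols],
        spot_ids=spot_ids,
    )
    return bundle, markers


def build_neighbor_graph(coords: SpotCoordinates, mode: str = "visium_hex",
                         param: float | None = None) -> NeighborGraph:
    """Construct the spatial neighbor graph realizing ``i ~ i'``.

    Modes
    -----
    visium_hex : up to 6 nearest spots within 1.2x the minimal positive
        inter-spot distance (hexagonal packing).
    st_square : 4-neighborhood on the integer grid (coordinates rounded).
    knn : ``param``-nearest neighbors, symmetrized by union.
    radius : all pairs within Euclidean distance ``param``.
    """
    xy = coords.xy
    n = xy.shape[0]
    if n <= 1:
        return NeighborGraph(n, np.empty((0, 2), dtype=int))
    if mode == "visium_hex":
        tree = cKDTree(xy)
        d, _ = tree.query(xy, k=2)
        dmin = d[:, 1][d[:, 1] > 0]
        if dmin.size == 0:
            raise ValueError("all spots coincident; cannot infer hex spacing")
        radius = 1.2 * dmin.min()
        k = min(7, n)
        dists, idx = tree.query(xy, k=k)
        edges = [(i, int(j)) for i in range(n)
                 for dij, j in zip(dists[i, 1:], idx[i, 1:])
                 if 0 < dij <= radius]
        return NeighborGraph(n, np.asarray(edges, dtype=int).reshape(-1, 2))
    if mode == "st_square":
        grid = np.round(xy).astype(int)
        index = {tuple(g): i for i, g in enumerate(grid)}
        edges = []
        for i, (gx, gy) in enumerate(grid):
            for dx, dy in ((1, 0), (0, 1)):
                j = index.get((gx + dx, gy + dy))
                if j is not None and j != i:
                    edges.append((i, j))
        return NeighborGraph(n, np.asarray(edges, dtype=int).reshape(-1, 2))
    if mode == "knn":
        if param is None or param <= 0:
            raise ValueError("knn mode requires param = k > 0")
        k = int(param)
        if k >= n:
            raise ValueError(f"k={k} must be below the number of spots {n}")
        tree = cKDTree(xy)
        _, idx = tree.query(xy, k=k + 1)
        edges = [(i, int(j)) for i in range(n) for j in idx[i, 1:] if j != i]
        return NeighborGraph(n, np.asarray(edges, dtype=int).reshape(-1, 2))
    if mode == "radius":
        if param is None or param <= 0:
            raise ValueError("radius mode requires param > 0")
        tree = cKDTree(xy)
        pairs = tree.query_pairs(float(param), output_type="ndarray")
        return NeighborGraph(n, pairs)
    raise ValueError(f"unknown neighbor mode: {mode!r}")
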