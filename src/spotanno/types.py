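"""Core data containers shared across the package.

All matrices are dense :class:`numpy.ndarray`; spots index rows, genes index
columns.  Indices are 0-based internally and 1-based only in user-facing
reports.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

UNKNOWN_LABEL = "unknown"


@dataclass
class RawExpression:
    """A spot-by-gene matrix of non-negative expression values.

    Parameters
    ----------
    counts
        ``(n, G)`` array of raw counts (or non-negative normalized values).
    gene_ids
        Length-``G`` list of unique gene identifiers.
    spot_ids
        Length-``n`` list of spot identifiers.
    """

    counts: np.ndarray
    gene_ids: list[str]
    spot_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D spot-by-gene matrix")
        n, G = self.counts.shape
        if n < 1 or G < 1:
            raise ValueError("need at least one spot and one gene")
        if len(self.gene_ids) != G:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {G} columns")
        if len(self.spot_ids) != n:
            raise ValueError(f"{len(self.spot_ids)} spot ids for {n} rows")
        if len(set(self.gene_ids)) != G:
            dup = _first_duplicate(self.gene_ids)
            raise ValueError(f"duplicate gene id: {dup!r}")
        if np.any(self.counts < 0):
            raise ValueError("expression values must be non-negative")

    @property
    def n_spots(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]


@dataclass
class SpotCoordinates:
    """Spatial coordinates, one row per spot, in platform units."""

    spot_ids: list[str]
    xy: np.ndarray
    allow_duplicates: bool = False

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float)
        if self.xy.ndim != 2 or self.xy.shape[1] != 2:
            raise ValueError("xy must be an (n, 2) array")
        if len(self.spot_ids) != self.xy.shape[0]:
            raise ValueError("spot_ids and xy disagree in length")
        if not np.all(np.isfinite(self.xy)):
            raise ValueError("coordinates must be finite")
        if not self.allow_duplicates:
            uniq = {tuple(row) for row in np.round(self.xy, 12)}
            if len(uniq) < self.xy.shape[0]:
                raise ValueError(
                    "two spots share identical coordinates; "
                    "pass allow_duplicates=True to accept"
                )

    @property
    def n_spots(self) -> int:
        return self.xy.shape[0]


@dataclass
class MarkerMap:
    """Binary marker-gene indicator rho of shape ``(m, K)``.

    ``rho[j, k] == 1`` declares gene ``j`` a marker for type ``k``.  Every
    marker gene must mark at least one type and every type must own at least
    one marker.
    """

    rho: np.ndarray
    marker_gene_ids: list[str]
    type_names: list[str]
    #: corrupted marker matrices may orphan genes or types; strict=False
    #: skips the non-empty row/column checks for them
    strict: bool = True

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho)
        if self.rho.ndim != 2:
            raise ValueError("rho must be 2-D (markers x types)")
        if not np.isin(self.rho, (0, 1)).all():
            raise ValueError("rho must be binary")
        self.rho = self.rho.astype(np.int8)
        m, K = self.rho.shape
        if len(self.marker_gene_ids) != m:
            raise ValueError("marker_gene_ids and rho rows disagree")
        if len(self.type_names) != K:
            raise ValueError("type_names and rho columns disagree")
        if len(set(self.marker_gene_ids)) != m:
            dup = _first_duplicate(self.marker_gene_ids)
            raise ValueError(f"duplicate marker gene: {dup!r}")
        if len(set(self.type_names)) != K:
            dup = _first_duplicate(self.type_names)
            raise ValueError(f"duplicate type name: {dup!r}")
        if UNKNOWN_LABEL in self.type_names:
            raise ValueError(f"{UNKNOWN_LABEL!r} is a reserved type name")
        if self.strict:
            if np.any(self.rho.sum(axis=1) == 0):
                j = int(np.flatnonzero(self.rho.sum(axis=1) == 0)[0])
                raise ValueError(
                    f"marker gene {self.marker_gene_ids[j]!r} marks no type"
                )
            if np.any(self.rho.sum(axis=0) == 0):
                k = int(np.flatnonzero(self.rho.sum(axis=0) == 0)[0])
                raise ValueError(
                    f"type {self.type_names[k]!r} has no marker gene")

    @property
    def n_markers(self) -> int:
        return self.rho.shape[0]

    @property
    def n_types(self) -> int:
        return self.rho.shape[1]


@dataclass
class ExpressionBundle:
    """Centered, normalized expression split into marker / non-marker blocks."""

    x1: np.ndarray  # (n, m) marker block
    x2: np.ndarray  # (n, p) non-marker block
    marker_gene_ids: list[str]
    nonmarker_gene_ids: list[str]
    spot_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.x1 = np.asarray(self.x1, dtype=float)
        self.x2 = np.asarray(self.x2, dtype=float)
        if self.x1.shape[0] != self.x2.shape[0]:
            raise ValueError("x1 and x2 disagree in spot count")
        if self.x1.shape[1] != len(self.marker_gene_ids):
            raise ValueError("marker_gene_ids and x1 columns disagree")
        if self.x2.shape[1] != len(self.nonmarker_gene_ids):
            raise ValueError("nonmarker_gene_ids and x2 columns disagree")
        if set(self.marker_gene_ids) & set(self.nonmarker_gene_ids):
            raise ValueError("marker and non-marker gene sets overlap")
        n = self.x1.shape[0]
        if n > 1:
            for name, block in (("x1", self.x1), ("x2", self.x2)):
                if block.size and np.abs(block.mean(axis=0)).max() > 1e-8:
                    raise ValueError(f"{name} columns are not centered")

    @property
    def n_spots(self) -> int:
        return self.x1.shape[0]

    @property
    def n_markers(self) -> int:
        return self.x1.shape[1]

    @property
    def n_nonmarkers(self) -> int:
        return self.x2.shape[1]


class NeighborGraph:
    """Undirected neighbor graph over spots, stored as an edge list plus
    per-spot adjacency arrays.  No self-loops; edges are unordered pairs."""

    def __init__(self, n_spots: int, edges: np.ndarray | list):
        edges = np.asarray(edges, dtype=int).reshape(-1, 2)
        if edges.size:
            if edges.min() < 0 or edges.max() >= n_spots:
                raise ValueError("edge index out of range")
            if np.any(edges[:, 0] == edges[:, 1]):
                raise ValueError("self-loop in edge list")
        # canonical order, deduplicated
        lo = edges.min(axis=1) if edges.size else np.empty(0, int)
        hi = edges.max(axis=1) if edges.size else np.empty(0, int)
        canon = np.unique(np.column_stack([lo, hi]), axis=0) if edges.size else edges
        self.n_spots = int(n_spots)
        self.edges = canon
        adj: list[list[int]] = [[] for _ in range(n_spots)]
        for i, j in self.edges:
            adj[i].append(j)
            adj[j].append(i)
        self.adjacency = [np.asarray(sorted(a), dtype=int) for a in adj]

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    def degree(self) -> np.ndarray:
        return np.asarray([len(a) for a in self.adjacency], dtype=int)

    def neighbors(self, i: int) -> np.ndarray:
        return self.adjacency[i]


@dataclass
class ModelParams:
    """All free parameters of the annotation model.

    Marker block: ``x1_i | y_i=k ~ N(alpha + rho[:,k]*beta[:,k], diag(sigma2))``.
    Non-marker block: ``x2_i = L z_i + e_i`` with ``z_i | y_i=k ~ N(m_k, V)``
    and ``e_i ~ N(0, diag(Lambda))``.  Labels follow a Potts prior with
    interaction ``xi`` on the neighbor graph.  When an "unknown" component is
    enabled it is the last column of ``rho`` (all zeros) with its own factor
    mean.
    """

    alpha: np.ndarray       # (m,)
    beta: np.ndarray        # (m, K_eff), >= 0, zero where rho is zero
    sigma2: np.ndarray      # (m,) > 0
    L: np.ndarray           # (p, q)
    Lambda: np.ndarray      # (p,) > 0
    mk: np.ndarray          # (K_eff, q)
    V: np.ndarray           # (q, q) symmetric PD
    xi: float
    rho: np.ndarray         # (m, K_eff) binary, unknown column all zero

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        self.sigma2 = np.asarray(self.sigma2, dtype=float)
        self.L = np.asarray(self.L, dtype=float)
        self.Lambda = np.asarray(self.Lambda, dtype=float)
        self.mk = np.asarray(self.mk, dtype=float)
        self.V = np.asarray(self.V, dtype=float)
        self.rho = np.asarray(self.rho).astype(np.int8)
        self.validate()

    def validate(self) -> None:
        m = self.alpha.shape[0]
        K_eff = self.beta.shape[1]
        if self.beta.shape != (m, K_eff) or self.rho.shape != (m, K_eff):
            raise ValueError("beta/rho shape mismatch")
        if self.sigma2.shape != (m,):
            raise ValueError("sigma2 shape mismatch")
        if np.any(self.sigma2 <= 0) or np.any(self.Lambda <= 0):
            raise ValueError("variances must be strictly positive")
        if np.any(self.beta < 0):
            raise ValueError("beta must be non-negative")
        if np.any(self.beta[self.rho == 0] != 0):
            raise ValueError("beta must vanish where rho is zero")
        p, q = self.L.shape
        if self.Lambda.shape != (p,):
            raise ValueError("Lambda shape mismatch")
        if self.mk.shape != (K_eff, q):
            raise ValueError("mk shape mismatch")
        if self.V.shape != (q, q):
            raise ValueError("V shape mismatch")
        if not np.allclose(self.V, self.V.T, atol=1e-10):
            raise ValueError("V must be symmetric")
        if self.xi < 0:
            raise ValueError("xi must be non-negative")

    @property
    def n_markers(self) -> int:
        return self.alpha.shape[0]

    @property
    def n_components(self) -> int:
        return self.beta.shape[1]

    @property
    def q(self) -> int:
        return self.L.shape[1]

    def mu(self) -> np.ndarray:
        """Component means of the marker block, shape ``(m, K_eff)``."""
        return self.alpha[:, None] + self.rho * self.beta

    def copy(self) -> "ModelParams":
        return ModelParams(
            alpha=self.alpha.copy(), beta=self.beta.copy(),
            sigma2=self.sigma2.copy(), L=self.L.copy(),
            Lambda=self.Lambda.copy(), mk=self.mk.copy(), V=self.V.copy(),
            xi=float(self.xi), rho=self.rho.copy(),
        )

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("alpha", "beta", "sigma2", "L", "Lambda", "mk", "V", "rho")}
        out = {k: np.asarray(v).tolist() for k, v in d.items()}
        out["xi"] = float(self.xi)
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(
            alpha=np.asarray(d["alpha"]), beta=np.asarray(d["beta"]),
            sigma2=np.asarray(d["sigma2"]), L=np.asarray(d["L"]),
            Lambda=np.asarray(d["Lambda"]), mk=np.asarray(d["mk"]),
            V=np.asarray(d["V"]), xi=float(d["xi"]), rho=np.asarray(d["rho"]),
        )


@dataclass
class AnnotationResult:
    """Output of a fit: responsibilities, hard labels, embeddings, trace."""

    responsibilities: np.ndarray   # (n, K_eff) row-stochastic
    labels: list[str]              # length n, may contain "unknown"
    embeddings: np.ndarray         # (n, q)
    xi_hat: float
    loglik_trace: list[float] = field(default_factory=list)
    type_names: list[str] = field(default_factory=list)
    params: ModelParams | None = None
    spot_ids: list[str] | None = None

    def __post_init__(self) -> None:
        R = np.asarray(self.responsibilities, dtype=float)
        if R.ndim != 2:
            raise ValueError("responsibilities must be 2-D")
        rowsum = R.sum(axis=1)
        if np.abs(rowsum - 1.0).max() > 1e-8:
            raise ValueError("responsibility rows must sum to 1")
        if not np.all(np.isfinite(self.embeddings)):
            raise ValueError("embeddings must be finite")
        self.responsibilities = R


def _first_duplicate(items: list[str]) -> str:
    seen: set[str] = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return ""
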