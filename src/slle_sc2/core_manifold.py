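"""Locally linear embedding and its supervised variant.

The chain is: pairwise distances -> (optional class-aware inflation) ->
k-nearest-neighbor graph -> per-sample reconstruction weights solved from a
local Gram system -> quadratic cost matrix -> bottom eigenvectors as the
embedding.  The supervised variant inflates between-class distances by
``lambda_s * max(distance)`` before neighbor selection; reconstruction
weights are always solved from the original coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import eigh
from scipy.spatial.distance import pdist, squareform

from .errors import DataValidationError, NumericalError, ParameterError

__all__ = [
    "LabeledExpressionMatrix",
    "DistanceMatrix",
    "NeighborGraph",
    "WeightMatrix",
    "CostMatrix",
    "Embedding",
    "euclidean_distance_matrix",
    "supervised_distance_matrix",
    "knn_neighbors",
    "reconstruction_weights",
    "embedding_cost_matrix",
    "embed",
    "lle",
    "slle",
]

DEFAULT_K = 5
DEFAULT_LAMBDA_S = 1.0
DEFAULT_REG_TOL = 1e-3


@dataclass
class LabeledExpressionMatrix:
    """Samples x genes expression matrix with identifiers and binary labels.

    ``values[i, j]`` is the expression of gene ``gene_ids[j]`` in sample
    ``sample_ids[i]``.  Labels may take one or two distinct values; two are
    required for any supervised operation.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.values.ndim != 2:
            raise DataValidationError("expression values must be a 2-D matrix")
        n, d = self.values.shape
        if len(self.sample_ids) != n:
            raise DataValidationError(
                f"{len(self.sample_ids)} sample ids for {n} rows"
            )
        if len(self.gene_ids) != d:
            raise DataValidationError(f"{len(self.gene_ids)} gene ids for {d} columns")
        if len(set(self.gene_ids)) != d:
            dupes = sorted({g for g in self.gene_ids if self.gene_ids.count(g) > 1})
            raise DataValidationError(f"duplicate gene ids: {dupes[:5]}")
        if len(set(self.sample_ids)) != n:
            raise DataValidationError("duplicate sample ids")
        if self.labels.shape != (n,):
            raise DataValidationError("labels must align with samples")
        if not np.all(np.isfinite(self.values)):
            raise DataValidationError("expression matrix contains non-finite values")
        n_classes = len(np.unique(self.labels))
        if n_classes not in (1, 2):
            raise DataValidationError(
                f"labels must take 1 or 2 distinct values, got {n_classes}"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def gene_column(self, gene_id: str) -> np.ndarray:
        return self.values[:, self.gene_ids.index(gene_id)]


@dataclass
class DistanceMatrix:
    """Symmetric zero-diagonal pairwise sample distances."""

    d: np.ndarray
    kind: str = "euclidean"  # or "supervised"
    lambda_s: float | None = None

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if self.d.ndim != 2 or self.d.shape[0] != self.d.shape[1]:
            raise DataValidationError("distance matrix must be square")
        if self.kind not in ("euclidean", "supervised"):
            raise ParameterError(f"unknown distance kind {self.kind!r}")

    @property
    def n(self) -> int:
        return self.d.shape[0]


@dataclass
class NeighborGraph:
    """Per-sample ordered lists of the k nearest neighbor indices."""

    k: int
    neighbors: np.ndarray  # (N, k) int array, nearest first
    distances: DistanceMatrix

    @property
    def n(self) -> int:
        return self.neighbors.shape[0]


@dataclass
class WeightMatrix:
    """Row-stochastic reconstruction weights supported on the neighbor graph."""

    w: np.ndarray
    support: NeighborGraph
    reg_tol: float
    recon_error: np.ndarray = field(default=None)  # type: ignore[assignment]


@dataclass
class CostMatrix:
    """The symmetric PSD embedding cost matrix (I - W)^T (I - W)."""

    m: np.ndarray


@dataclass
class Embedding:
    """Low-dimensional sample coordinates with the retained eigenvalues."""

    y: np.ndarray  # (N, d)
    d: int
    eigenvalues: np.ndarray  # ascending, length d


def euclidean_distance_matrix(x: LabeledExpressionMatrix) -> DistanceMatrix:
    """Pairwise Euclidean distances between sample expression vectors."""
    if x.n_samples < 2:
        raise DataValidationError("need at least 2 samples for distances")
    d = squareform(pdist(x.values, metric="euclidean"))
    return DistanceMatrix(d=d, kind="euclidean")


def supervised_distance_matrix(
    d_euc: DistanceMatrix,
    labels: Sequence | np.ndarray,
    lambda_s: float = DEFAULT_LAMBDA_S,
) -> DistanceMatrix:
    """Inflate between-class distances by ``lambda_s * max(distance)``.

    With ``lambda_s == 0`` the output equals the input (plain unsupervised
    neighborhoods); with ``lambda_s == 1`` neighborhoods are maximally
    class-pure.
    """
    if d_euc.kind != "euclidean":
        raise ParameterError("supervised inflation expects euclidean input distances")
    if not (0.0 <= lambda_s <= 1.0):
        raise ParameterError(f"lambda_s must lie in [0, 1], got {lambda_s}")
    labels = np.asarray(labels)
    if labels.shape != (d_euc.n,):
        raise DataValidationError("labels must align with the distance matrix")
    if len(np.unique(labels)) != 2:
        raise DataValidationError("supervised distances require exactly 2 classes")
    differ = (labels[:, None] != labels[None, :]).astype(float)
    d = d_euc.d + lambda_s * d_euc.d.max() * differ
    return DistanceMatrix(d=d, kind="supervised", lambda_s=lambda_s)


def knn_neighbors(d: DistanceMatrix, k: int) -> NeighborGraph:
    """k nearest neighbors per sample, self excluded.

    Ties are broken by ascending sample index so the graph is deterministic
    across platforms.
    """
    n = d.n
    if not 1 <= k <= n - 1:
        raise ParameterError(f"k must satisfy 1 <= k <= N-1 = {n - 1}, got {k}")
    neighbors = np.empty((n, k), dtype=np.intp)
    idx = np.arange(n)
    for i in range(n):
        row = d.d[i].copy()
        row[i] = np.inf  # exclude self
        order = np.lexsort((idx, row))
        neighbors[i] = order[:k]
    return NeighborGraph(k=k, neighbors=neighbors, distances=d)


def reconstruction_weights(
    x: LabeledExpressionMatrix,
    g: NeighborGraph,
    reg_tol: float = DEFAULT_REG_TOL,
    from_distances: bool = False,
) -> WeightMatrix:
    """Solve each sample's local Gram system for reconstruction weights.

    For sample i with neighbor coordinates ``X_j`` the local Gram matrix is
    ``G_jk = (X_i - X_j) . (X_i - X_k)``.  G is regularized by adding
    ``reg_tol * trace(G) * I`` before solving (G is singular whenever the
    neighbor count exceeds the local rank); ``reg_tol = 0`` is allowed for
    exactly solvable cases.  Weights are normalized to sum to 1 per row, and
    the per-sample squared reconstruction error is recorded.

    With ``from_distances=True`` the Gram matrix is built from the graph's
    own (possibly class-inflated) distances via the law of cosines,
    ``G_jk = (d_ij^2 + d_ik^2 - d_jk^2) / 2``, so supervised distances enter
    the weight solve as well as the neighbor choice.
    """
    if reg_tol < 0:
        raise ParameterError("reg_tol must be non-negative")
    if g.n != x.n_samples:
        raise DataValidationError("neighbor graph does not match the data")
    n, k = g.n, g.k
    w = np.zeros((n, n))
    recon_error = np.zeros(n)
    for i in range(n):
        nbrs = g.neighbors[i]
        z = x.values[i] - x.values[nbrs]  # (k, D) differences
        if from_distances:
            dij = g.distances.d[i, nbrs]
            djk = g.distances.d[np.ix_(nbrs, nbrs)]
            gram = (dij[:, None] ** 2 + dij[None, :] ** 2 - djk**2) / 2.0
        else:
            gram = z @ z.T
        trace = np.trace(gram)
        if reg_tol > 0:
            gram = gram + reg_tol * (trace if trace > 0 else 1.0) * np.eye(k)
        try:
            wi = np.linalg.solve(gram, np.ones(k))
        except np.linalg.LinAlgError as exc:
            raise NumericalError(
                f"singular local Gram matrix at sample index {i} "
                f"({x.sample_ids[i]!r}); increase reg_tol"
            ) from exc
        s = wi.sum()
        if s == 0 or not np.isfinite(s):
            raise NumericalError(
                f"degenerate weight solution at sample index {i} "
                f"({x.sample_ids[i]!r}); increase reg_tol"
            )
        wi = wi / s
        w[i, nbrs] = wi
        resid = x.values[i] - wi @ x.values[nbrs]
        recon_error[i] = float(resid @ resid)
    return WeightMatrix(w=w, support=g, reg_tol=reg_tol, recon_error=recon_error)


def embedding_cost_matrix(w: WeightMatrix) -> CostMatrix:
    """M = (I - W)^T (I - W); symmetric PSD with the all-ones null vector."""
    n = w.w.shape[0]
    iw = np.eye(n) - w.w
    m = iw.T @ iw
    m = (m + m.T) / 2.0  # enforce exact symmetry against fp drift
    return CostMatrix(m=m)


def embed(m: CostMatrix, d: int) -> Embedding:
    """Bottom nontrivial eigenvectors of the cost matrix, scaled to unit covariance.

    Computes the d+1 algebraically smallest eigenpairs, drops the translation
    mode (the near-zero-eigenvalue eigenvector maximally correlated with the
    constant vector), flips each retained eigenvector so its largest-magnitude
    entry is positive, and scales by sqrt(N) so that (1/N) Y^T Y = I.
    """
    n = m.m.shape[0]
    if d < 1:
        raise ParameterError("embedding dimension d must be >= 1")
    if d > n - 2:
        raise ParameterError(f"d must be <= N-2 = {n - 2}, got {d}")
    try:
        vals, vecs = eigh(m.m, subset_by_index=[0, d])
    except Exception as exc:  # pragma: no cover - solver failure is environmental
        raise NumericalError(f"eigen-solver failed: {exc}") from exc

    # translation mode: among near-zero eigenvalues pick the most constant one.
    # With a degenerate null space (disconnected neighbor graph) the solver's
    # basis mixes the constant vector into several columns; rotate the
    # near-zero eigenspace so one basis vector carries the whole constant
    # component, then drop exactly that one.
    ones = np.ones(n) / np.sqrt(n)
    scale = max(1.0, float(abs(vals).max()))
    near_zero = np.nonzero(vals < 1e-8 * scale)[0]
    if near_zero.size > 1:
        z = vecs[:, near_zero]
        p = z @ (z.T @ ones)
        if np.linalg.norm(p) > 1e-8:
            u1 = p / np.linalg.norm(p)
            resid = z - np.outer(u1, u1 @ z)  # deflate the constant direction
            u, s, _ = np.linalg.svd(resid, full_matrices=False)
            vecs[:, near_zero] = np.column_stack([u1, u[:, : near_zero.size - 1]])
    candidates = near_zero if near_zero.size else np.arange(d + 1)
    corr = np.abs(vecs[:, candidates].T @ ones)
    drop = int(candidates[np.argmax(corr)])

    keep = [j for j in range(d + 1) if j != drop]
    y = vecs[:, keep]
    eigenvalues = vals[keep]
    # sign-deterministic: largest-magnitude entry of each column positive
    for c in range(y.shape[1]):
        j = int(np.argmax(np.abs(y[:, c])))
        if y[j, c] < 0:
            y[:, c] = -y[:, c]
    y = y * np.sqrt(n)
    return Embedding(y=y, d=d, eigenvalues=eigenvalues)


def lle(
    x: LabeledExpressionMatrix,
    k: int = DEFAULT_K,
    d: int = 2,
    reg_tol: float = DEFAULT_REG_TOL,
) -> Embedding:
    """Plain (unsupervised) locally linear embedding."""
    dist = euclidean_distance_matrix(x)
    graph = knn_neighbors(dist, k)
    weights = reconstruction_weights(x, graph, reg_tol)
    return embed(embedding_cost_matrix(weights), d)


def slle(
    x: LabeledExpressionMatrix,
    k: int = DEFAULT_K,
    lambda_s: float = DEFAULT_LAMBDA_S,
    d: int = 2,
    reg_tol: float = DEFAULT_REG_TOL,
    supervised_weights: bool = False,
) -> Embedding:
    """Supervised locally linear embedding.

    Class-aware distance inflation is applied before neighbor selection;
    reconstruction weights are solved from the original coordinates.  With
    ``supervised_weights=True`` the inflated distances also enter the local
    Gram matrices (law-of-cosines form), so supervision affects the weight
    solve too.
    """
    dist = euclidean_distance_matrix(x)
    if lambda_s == 0.0:
        sup = dist
    else:
        sup = supervised_distance_matrix(dist, x.labels, lambda_s)
    graph = knn_neighbors(sup, k)
    weights = reconstruction_weights(x, graph, reg_tol, from_distances=supervised_weights)
    return embed(embedding_cost_matrix(weights), d)
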