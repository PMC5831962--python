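"""The full feature-gene selection pipeline.

Steps: supervised locally linear embedding of the samples -> PCA
explained-variance contributions of the embedding components -> relevance of
each original gene as the contribution-weighted |Spearman| association with
the embedding coordinates -> greedy redundancy filter in relevance order ->
top-n surviving genes.

Ablation modes mirror the method's components: ``lle`` (unsupervised
embedding, no filter), ``slle`` (supervised embedding, no filter), ``sc2``
(relevance from PCA on the raw data, filter on), ``full`` (everything).
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .core_manifold import (
    DEFAULT_K,
    DEFAULT_LAMBDA_S,
    DEFAULT_REG_TOL,
    Embedding,
    LabeledExpressionMatrix,
    slle,
)
from .correlation import DEFAULT_THRESHOLD, RedundancyLog, _rank_columns, redundancy_filter
from .errors import DataValidationError, ParameterError

__all__ = [
    "ContributionProfile",
    "GeneRanking",
    "SelectionResult",
    "pca_contribution",
    "gene_relevance",
    "slle_sc2_select",
]

Mode = Literal["full", "lle", "slle", "sc2"]
DEFAULT_N_SELECT = 5


@dataclass
class ContributionProfile:
    """Per-component explained-variance fractions of a PCA decomposition."""

    fractions: np.ndarray  # non-negative, non-increasing, sums to 1
    cumulative: np.ndarray
    loadings: np.ndarray  # (components, attributes)

    @property
    def n_components(self) -> int:
        return self.fractions.size


@dataclass
class GeneRanking:
    """Genes ordered by non-increasing relevance, ties broken by gene index."""

    gene_ids: list[str]
    relevance: np.ndarray  # aligned with gene_ids, non-increasing


@dataclass
class SelectionResult:
    selected: list[str]
    relevance: dict
    log: RedundancyLog
    params: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)


def pca_contribution(x: np.ndarray) -> ContributionProfile:
    """Explained-variance fractions of the centered data's principal axes.

    Computed from the singular values of the centered matrix; the component
    loadings are the right singular vectors.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise DataValidationError("PCA needs at least 2 samples")
    xc = x - x.mean(axis=0)
    # rank-limited SVD: at most min(N-1, D) informative components
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    var = s**2
    total = var.sum()
    if total == 0.0:
        # all-constant data: a single degenerate component carrying everything
        fractions = np.zeros(var.size)
        fractions[0] = 1.0
    else:
        fractions = var / total
    cumulative = np.cumsum(fractions)
    return ContributionProfile(fractions=fractions, cumulative=cumulative, loadings=vt)


def gene_relevance(
    x: LabeledExpressionMatrix,
    emb: Embedding | np.ndarray,
    contrib: ContributionProfile,
) -> GeneRanking:
    """Contribution-weighted |Spearman| relevance of each gene.

    relevance(g) = sum_c fractions[c] * |spearman(expression of g, column c)|
    where the columns are the embedding coordinates (or, for the raw-data
    ablation, PCA scores).  Constant genes get relevance 0 with a warning.
    """
    y = emb.y if isinstance(emb, Embedding) else np.asarray(emb, dtype=float)
    if y.shape[0] != x.n_samples:
        raise DataValidationError("embedding does not match the data")
    n_c = min(contrib.n_components, y.shape[1])
    w = contrib.fractions[:n_c]

    gr = _rank_columns(x.values)
    gr = gr - gr.mean(axis=0)
    gnorm = np.linalg.norm(gr, axis=0)
    constant = gnorm == 0.0
    if np.any(constant):
        warnings.warn(
            f"{int(constant.sum())} constant gene(s) assigned relevance 0",
            stacklevel=2,
        )
    gnorm[constant] = 1.0
    gr = gr / gnorm

    yr = _rank_columns(y[:, :n_c])
    yr = yr - yr.mean(axis=0)
    ynorm = np.linalg.norm(yr, axis=0)
    ynorm[ynorm == 0.0] = 1.0
    yr = yr / ynorm

    rho = gr.T @ yr  # (genes, components)
    relevance = np.abs(rho) @ w
    relevance[constant] = 0.0

    order = np.lexsort((np.arange(x.n_genes), -relevance))
    return GeneRanking(
        gene_ids=[x.gene_ids[j] for j in order], relevance=relevance[order]
    )


def slle_sc2_select(
    x: LabeledExpressionMatrix,
    k: int = DEFAULT_K,
    lambda_s: float = DEFAULT_LAMBDA_S,
    d: int | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    n_select: int | None = DEFAULT_N_SELECT,
    reg_tol: float = DEFAULT_REG_TOL,
    mode: Mode = "full",
    absolute: bool = True,
    seed: int | None = None,
) -> SelectionResult:
    """Run the selection pipeline and return the chosen genes with provenance.

    ``d`` defaults to 2 x number of classes.  ``n_select=None`` keeps every
    filter survivor.  In modes without a filter the threshold is forced to 1
    so nothing is removed as redundant.
    """
    if mode not in ("full", "lle", "slle", "sc2"):
        raise ParameterError(f"unknown mode {mode!r}")
    if n_select is not None and n_select < 1:
        raise ParameterError("n_select must be >= 1 or None")
    n_classes = len(np.unique(x.labels))
    if d is None:
        d = 2 * n_classes
    d = min(d, x.n_samples - 2)

    if mode == "sc2":
        contrib = pca_contribution(x.values)
        xc = x.values - x.values.mean(axis=0)
        scores = xc @ contrib.loadings.T  # PCA scores of the raw data
        ranking = gene_relevance(x, scores, contrib)
        eff_lambda = None
    else:
        eff_lambda = 0.0 if mode == "lle" else lambda_s
        emb = slle(x, k=k, lambda_s=eff_lambda, d=d, reg_tol=reg_tol)
        contrib = pca_contribution(emb.y)
        ranking = gene_relevance(x, emb, contrib)

    filtered = mode in ("full", "sc2")
    if filtered:
        eff_threshold = threshold
        log = redundancy_filter(ranking.gene_ids, x, eff_threshold, absolute=absolute)
    else:
        # ablation without the redundancy filter: every gene survives
        eff_threshold = None
        log = RedundancyLog(
            kept=list(ranking.gene_ids), removed=[], threshold=1.0
        )

    survivors = log.kept
    if n_select is not None and n_select > len(survivors):
        warnings.warn(
            f"n_select={n_select} exceeds the {len(survivors)} filter "
            "survivors; returning all survivors",
            stacklevel=2,
        )
    selected = survivors if n_select is None else survivors[:n_select]

    digest = hashlib.sha256(
        np.ascontiguousarray(x.values).tobytes()
        + "|".join(x.gene_ids).encode()
        + "|".join(map(str, x.labels)).encode()
    ).hexdigest()
    params = {
        "k": k,
        "lambda_s": eff_lambda,
        "d": d,
        "threshold": eff_threshold,
        "n_select": n_select,
        "reg_tol": reg_tol,
        "mode": mode,
        "absolute": absolute,
    }
    rel = dict(zip(ranking.gene_ids, ranking.relevance.tolist()))
    return SelectionResult(
        selected=list(selected),
        relevance={g: rel[g] for g in selected},
        log=log,
        params=params,
        provenance={"seed": seed, "input_sha256": digest},
    )
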