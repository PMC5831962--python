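"""Spearman's rank correlation with tie-averaged ranks and the greedy
coexpression-redundancy filter.

Ranking convention: the smallest value gets rank 1, the largest rank N, ties
share the average of the ranks they span, and ranks are reported in original
sample order.  The correlation is the Pearson correlation of the two rank
vectors.  The redundancy filter walks attributes in relevance order, keeps
the current best survivor, and removes every lower-ranked survivor whose
rank correlation with it reaches the threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from .errors import DataValidationError, NumericalError

__all__ = [
    "RankVector",
    "CorrelationValue",
    "RedundancyLog",
    "rank_with_ties",
    "spearman_rho",
    "correlation_matrix",
    "redundancy_filter",
]

DEFAULT_THRESHOLD = 0.3


@dataclass
class RankVector:
    """Tie-averaged ranks in original sample order."""

    ranks: np.ndarray
    source_ids: list[str] | None = None


@dataclass
class CorrelationValue:
    rho: float
    pair: tuple[str, str] | None = None


@dataclass
class RedundancyLog:
    """Outcome of the greedy redundancy filter.

    ``removed`` holds ``(removed_id, anchor_id, rho)`` triples where
    ``anchor_id`` is the higher-relevance survivor the attribute correlated
    with.  Constant attributes carry no rank information and are listed
    separately in ``dropped_constant``.
    """

    kept: list[str]
    removed: list[tuple[str, str, float]]
    threshold: float
    dropped_constant: list[str] = field(default_factory=list)


def rank_with_ties(values: Sequence[float] | np.ndarray) -> RankVector:
    """Tie-averaged ranks, smallest value -> rank 1, original order kept."""
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise DataValidationError("rank input must be a vector of length >= 2")
    if not np.all(np.isfinite(v)):
        raise DataValidationError("rank input contains non-finite values")
    return RankVector(ranks=rankdata(v, method="average"))


def spearman_rho(
    a: Sequence[float] | np.ndarray,
    b: Sequence[float] | np.ndarray,
    pair: tuple[str, str] | None = None,
) -> CorrelationValue:
    """Pearson correlation of the two tie-averaged rank vectors."""
    ra = rank_with_ties(a).ranks
    rb = rank_with_ties(b).ranks
    if ra.size != rb.size:
        raise DataValidationError("vectors must have equal length")
    da = ra - ra.mean()
    db = rb - rb.mean()
    denom = np.sqrt((da @ da) * (db @ db))
    if denom == 0.0:
        raise NumericalError(
            "Spearman correlation undefined: at least one vector is constant"
        )
    rho = float((da @ db) / denom)
    return CorrelationValue(rho=rho, pair=pair)


def _rank_columns(x: np.ndarray) -> np.ndarray:
    """Tie-averaged ranks of each column; constant columns rank as all-mid ties."""
    return rankdata(x, method="average", axis=0)


def correlation_matrix(x: np.ndarray) -> np.ndarray:
    """Symmetric matrix of pairwise Spearman correlations of the columns of x."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise DataValidationError("need an N x (>=2) attribute matrix")
    if not np.all(np.isfinite(x)):
        raise DataValidationError("correlation input contains non-finite values")
    r = _rank_columns(x)
    r = r - r.mean(axis=0)
    norms = np.linalg.norm(r, axis=0)
    if np.any(norms == 0.0):
        raise NumericalError("constant attribute: Spearman correlation undefined")
    r = r / norms
    c = r.T @ r
    np.fill_diagonal(c, 1.0)
    return np.clip(c, -1.0, 1.0)


def redundancy_filter(
    ordered_attrs: Sequence[str],
    x,
    threshold: float = DEFAULT_THRESHOLD,
    absolute: bool = True,
) -> RedundancyLog:
    """Greedy removal of coexpressed attributes in relevance order.

    Walk ``ordered_attrs`` from most to least relevant; each surviving
    attribute becomes an anchor and every lower-ranked survivor whose
    (absolute, by default) Spearman correlation with it is ``>= threshold``
    is removed and logged against that anchor.

    ``x`` is a :class:`~slle_sc2.core_manifold.LabeledExpressionMatrix` (or
    anything with ``values`` and ``gene_ids``).
    """
    if not 0.0 <= threshold <= 1.0:
        raise DataValidationError(f"threshold must lie in [0, 1], got {threshold}")
    attrs = list(ordered_attrs)
    if not attrs:
        raise DataValidationError("empty attribute list")
    unknown = set(attrs) - set(x.gene_ids)
    if unknown:
        raise DataValidationError(f"unknown attribute ids: {sorted(unknown)[:5]}")

    col_of = {g: j for j, g in enumerate(x.gene_ids)}
    ranks = _rank_columns(x.values[:, [col_of[g] for g in attrs]])
    centered = ranks - ranks.mean(axis=0)
    norms = np.linalg.norm(centered, axis=0)

    constant = norms == 0.0
    dropped_constant = [g for g, c in zip(attrs, constant) if c]
    if dropped_constant:
        warnings.warn(
            f"dropping {len(dropped_constant)} constant attribute(s) before "
            "redundancy filtering",
            stacklevel=2,
        )
    live = [i for i in range(len(attrs)) if not constant[i]]
    unit = np.zeros_like(centered)
    unit[:, live] = centered[:, live] / norms[live]

    kept: list[str] = []
    removed: list[tuple[str, str, float]] = []
    survivors = list(live)
    while survivors:
        anchor = survivors[0]
        kept.append(attrs[anchor])
        rest = survivors[1:]
        if not rest:
            break
        rho = unit[:, rest].T @ unit[:, anchor]
        score = np.abs(rho) if absolute else rho
        next_survivors = []
        for idx, r, s in zip(rest, rho, score):
            if s >= threshold:
                removed.append((attrs[idx], attrs[anchor], float(r)))
            else:
                next_survivors.append(idx)
        survivors = next_survivors
    return RedundancyLog(
        kept=kept,
        removed=removed,
        threshold=threshold,
        dropped_constant=dropped_constant,
    )
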