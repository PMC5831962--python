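"""Synthetic two-class expression data with planted structure.

Generates informative genes (class-shifted Gaussians), blocks of coexpressed
copies of each informative gene, and a majority of pure-noise genes — the
statistical structure that motivates redundancy-aware feature-gene selection.
Also provides the 5-sample, 2-attribute worked example used by the rank
correlation tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .core_manifold import LabeledExpressionMatrix
from .errors import DataValidationError

__all__ = ["SyntheticSpec", "GeneAnnotation", "generate", "worked_example"]


@dataclass
class SyntheticSpec:
    """Parameters of the planted-structure generator.

    ``effect`` is the between-class mean shift in units of ``noise_sd``;
    ``within_block_rho`` controls how strongly each redundant copy tracks its
    block's informative gene (1.0 gives exact affine duplicates).
    """

    n_samples_per_class: int = 30
    n_informative: int = 5
    copies_per_block: int = 3
    n_noise: int = 200
    effect: float = 2.0
    within_block_rho: float = 0.9
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples_per_class < 2:
            raise DataValidationError("need at least 2 samples per class")
        if self.n_informative < 1:
            raise DataValidationError("need at least 1 informative gene")
        if self.copies_per_block < 0 or self.n_noise < 0:
            raise DataValidationError("gene counts must be non-negative")
        if not 0.0 < self.within_block_rho <= 1.0:
            raise DataValidationError("within_block_rho must lie in (0, 1]")
        if self.noise_sd <= 0:
            raise DataValidationError("noise_sd must be positive")

    @property
    def n_genes(self) -> int:
        return self.n_informative * (1 + self.copies_per_block) + self.n_noise


@dataclass
class GeneAnnotation:
    """Ground truth: gene id -> role and (for block members) block index."""

    role: dict = field(default_factory=dict)  # gene_id -> "informative"|"copy"|"noise"
    block: dict = field(default_factory=dict)  # gene_id -> block index or None

    def block_of(self, gene_id: str) -> int | None:
        return self.block.get(gene_id)


def generate(spec: SyntheticSpec) -> tuple[LabeledExpressionMatrix, GeneAnnotation]:
    """Draw a labeled expression matrix with planted blocks and noise genes.

    Informative gene for block b: Normal(+effect*sd/2) in the positive class,
    Normal(-effect*sd/2) in the negative class.  Each copy is
    ``rho * g + sqrt(1 - rho^2) * eps`` with independent Gaussian ``eps``, so
    its correlation with the block gene rises with ``within_block_rho``.
    Deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n_pos = n_neg = spec.n_samples_per_class
    n = n_pos + n_neg
    sd = spec.noise_sd
    class_sign = np.concatenate([np.ones(n_pos), -np.ones(n_neg)])
    labels = np.where(class_sign > 0, "positive", "negative")

    cols: list[np.ndarray] = []
    gene_ids: list[str] = []
    ann = GeneAnnotation()
    shift = spec.effect * sd / 2.0
    for b in range(spec.n_informative):
        g = class_sign * shift + rng.normal(0.0, sd, size=n)
        gid = f"inf_{b}"
        cols.append(g)
        gene_ids.append(gid)
        ann.role[gid] = "informative"
        ann.block[gid] = b
        rho = spec.within_block_rho
        for c in range(spec.copies_per_block):
            eps = rng.normal(0.0, sd, size=n)
            copy = rho * g + np.sqrt(1.0 - rho**2) * eps
            cid = f"copy_{b}_{c}"
            cols.append(copy)
            gene_ids.append(cid)
            ann.role[cid] = "copy"
            ann.block[cid] = b
    for j in range(spec.n_noise):
        gid = f"noise_{j}"
        cols.append(rng.normal(0.0, sd, size=n))
        gene_ids.append(gid)
        ann.role[gid] = "noise"
        ann.block[gid] = None

    values = np.column_stack(cols)
    sample_ids = [f"s{i:03d}" for i in range(n)]
    x = LabeledExpressionMatrix(
        values=values, gene_ids=gene_ids, sample_ids=sample_ids, labels=labels
    )
    return x, ann


def worked_example() -> LabeledExpressionMatrix:
    """The 5-sample, 2-attribute example matrix (a1, a2) used in the docs/tests."""
    a1 = np.array([0.7, 0.3, 0.5, 0.2, 0.8])
    a2 = np.array([0.9, 0.3, 0.4, 0.1, 0.7])
    return LabeledExpressionMatrix(
        values=np.column_stack([a1, a2]),
        gene_ids=["a1", "a2"],
        sample_ids=["x1", "x2", "x3", "x4", "x5"],
        labels=np.array(["u"] * 5),
    )


PRESETS: dict[str, SyntheticSpec] = {
    "small": SyntheticSpec(
        n_samples_per_class=15,
        n_informative=3,
        copies_per_block=2,
        n_noise=40,
    ),
    "paper-like": SyntheticSpec(),
}


def preset(name: Literal["small", "paper-like"], seed: int = 0) -> SyntheticSpec:
    if name not in PRESETS:
        raise DataValidationError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    base = PRESETS[name]
    return SyntheticSpec(**{**base.__dict__, "seed": seed})
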