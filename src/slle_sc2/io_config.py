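"""Delimited-text readers/writers and the run manifest.

File layout written by the CLI: ``expr.tsv`` (genes x samples, first column
gene id, header row of sample ids), ``labels.tsv`` (sample_id, label),
``selection.tsv``, ``redundancy_log.tsv``, ``cv_report.tsv``,
``sweep.tsv`` and ``manifest.json``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core_manifold import LabeledExpressionMatrix
from .correlation import RedundancyLog
from .errors import DataValidationError
from .evaluation import CVReport
from .selection_pipeline import SelectionResult

__all__ = [
    "RunManifest",
    "read_expression",
    "write_expression",
    "write_results",
    "read_selection",
    "file_digest",
]


@dataclass
class RunManifest:
    """Everything needed to reproduce a run, serialized as JSON."""

    tool_version: str = __version__
    command: str = ""
    parameters: dict = field(default_factory=dict)
    seed: int | None = None
    input_digests: dict = field(default_factory=dict)
    timestamp: str = ""
    mode: str = ""

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunManifest":
        return cls(**json.loads(text))


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _read_table(path: str | Path, sep: str | None) -> pd.DataFrame:
    if sep is None:
        sep = "," if Path(path).suffix.lower() == ".csv" else "\t"
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except Exception as exc:
        raise DataValidationError(f"cannot parse {path}: {exc}") from exc
    return df


def read_expression(
    expr_path: str | Path,
    labels_path: str | Path | None = None,
    transpose: bool = False,
    sep: str | None = None,
    impute: bool = False,
) -> LabeledExpressionMatrix:
    """Load a genes-x-samples table (and a sample_id/label table) from disk.

    ``transpose=True`` accepts samples-as-rows input.  Missing values are
    rejected unless ``impute=True``, which substitutes per-gene means.
    """
    df = _read_table(expr_path, sep)
    if transpose:
        df = df.T
    # now genes are rows, samples are columns
    gene_ids = [str(g) for g in df.index]
    sample_ids = [str(s) for s in df.columns]
    if len(set(gene_ids)) != len(gene_ids):
        seen: set[str] = set()
        dupes = sorted({g for g in gene_ids if g in seen or seen.add(g)})
        raise DataValidationError(f"duplicate gene id(s): {dupes[:5]}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise DataValidationError(f"non-numeric cell in {expr_path}: {exc}") from exc
    if np.isnan(values).any():
        if not impute:
            raise DataValidationError(
                f"{expr_path} contains missing values (pass impute to use gene means)"
            )
        means = np.nanmean(values, axis=1, keepdims=True)
        values = np.where(np.isnan(values), means, values)

    if labels_path is not None:
        lab = pd.read_csv(
            labels_path,
            sep="," if Path(labels_path).suffix.lower() == ".csv" else "\t",
            header=0,
            dtype=str,
        )
        if lab.shape[1] < 2:
            raise DataValidationError(
                f"{labels_path} must have (sample_id, label) columns"
            )
        mapping = dict(zip(lab.iloc[:, 0], lab.iloc[:, 1]))
        missing = [s for s in sample_ids if s not in mapping]
        if missing:
            raise DataValidationError(
                f"labels missing for sample(s): {missing[:5]}"
            )
        labels = np.array([mapping[s] for s in sample_ids])
    else:
        labels = np.array(["unlabeled"] * len(sample_ids))

    return LabeledExpressionMatrix(
        values=values.T,  # internal orientation: samples x genes
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        labels=labels,
    )


def write_expression(x: LabeledExpressionMatrix, out_dir: str | Path) -> dict:
    """Write expr.tsv (genes x samples) and labels.tsv; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    expr = out / "expr.tsv"
    labels = out / "labels.tsv"
    df = pd.DataFrame(x.values.T, index=x.gene_ids, columns=x.sample_ids)
    df.index.name = "gene_id"
    df.to_csv(expr, sep="\t", float_format="%.10g")
    pd.DataFrame({"sample_id": x.sample_ids, "label": list(map(str, x.labels))}).to_csv(
        labels, sep="\t", index=False
    )
    return {"expr": expr, "labels": labels}


def _write_selection(result: SelectionResult, out: Path) -> None:
    sel = pd.DataFrame(
        {
            "gene_id": result.selected,
            "relevance": [result.relevance[g] for g in result.selected],
        }
    )
    sel.to_csv(out / "selection.tsv", sep="\t", index=False, float_format="%.10g")
    log = result.log
    rows = [
        {"removed_id": r, "anchor_id": a, "rho": rho} for r, a, rho in log.removed
    ] + [
        {"removed_id": g, "anchor_id": "", "rho": ""} for g in log.dropped_constant
    ]
    pd.DataFrame(rows, columns=["removed_id", "anchor_id", "rho"]).to_csv(
        out / "redundancy_log.tsv", sep="\t", index=False, float_format="%.10g"
    )


def read_selection(out_dir: str | Path) -> tuple[list[str], list[tuple[str, str, float]]]:
    """Parse back selection.tsv / redundancy_log.tsv written by write_results."""
    out = Path(out_dir)
    sel = pd.read_csv(out / "selection.tsv", sep="\t", dtype={"gene_id": str})
    log = pd.read_csv(out / "redundancy_log.tsv", sep="\t", dtype=str)
    removed = [
        (r.removed_id, r.anchor_id, float(r.rho))
        for r in log.itertuples()
        if isinstance(r.anchor_id, str) and r.anchor_id != ""
    ]
    return sel["gene_id"].tolist(), removed


def write_results(
    result,
    out_dir: str | Path,
    manifest: RunManifest | None = None,
) -> Path:
    """Serialize a SelectionResult, CVReport or sweep table; always writes a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if isinstance(result, SelectionResult):
        _write_selection(result, out)
        params = result.params
    elif isinstance(result, CVReport):
        frame = result.to_frame()
        frame.insert(0, "fold", range(len(frame)))
        summary = pd.DataFrame([result.mean, result.std], index=["mean", "std"])
        with open(out / "cv_report.tsv", "w") as fh:
            frame.to_csv(fh, sep="\t", index=False, float_format="%.10g")
            fh.write("#\n")
            summary.to_csv(fh, sep="\t", float_format="%.10g")
        params = result.params
    elif isinstance(result, pd.DataFrame):
        result.to_csv(out / "sweep.tsv", sep="\t", index=False, float_format="%.10g")
        params = {}
    else:
        raise DataValidationError(f"cannot serialize result of type {type(result)!r}")

    if manifest is None:
        manifest = RunManifest(parameters=dict(params))
    (out / "manifest.json").write_text(manifest.to_json() + "\n")
    return out
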