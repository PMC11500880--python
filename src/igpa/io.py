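"""CSV / JSON / YAML serialization for predictions, labels, manifests, trees.

Conventions: prediction CSVs carry a header row of class names with an
optional leading ``sample_id`` column; class order is fixed by the header
everywhere; samples align by row order (when sample ids are present in two
files they must match).  Probabilities are written with 9 significant
digits.  Row sums are validated to 1e-6; a renormalise-with-warning mode is
available for files produced with lower precision.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .core import IGPAWarning, LabelVector, PredictionMatrix, ROW_SUM_TOL
from .multilevel import EnsembleNode, build_tree
from .synthetic import SampleManifest

__all__ = [
    "load_predictions",
    "save_predictions",
    "load_labels",
    "save_labels",
    "load_manifest",
    "save_manifest",
    "load_tree_config",
    "save_report",
]

ID_COLUMN = "sample_id"
FLOAT_FMT = "%.9g"


def load_predictions(
    path: str | Path,
    source_id: str | None = None,
    renormalize: bool = False,
) -> PredictionMatrix:
    """Read a class-probability CSV into a validated prediction matrix."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - surface parse context
        raise ValueError(f"{path}: cannot parse CSV ({exc})") from exc
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need at least two probability columns")
    if df.columns[0] == ID_COLUMN:
        df = df.drop(columns=[ID_COLUMN])
    class_names = tuple(df.columns)
    try:
        probs = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric cell ({exc})") from exc
    if not np.isfinite(probs).all():
        bad = int(np.where(~np.isfinite(probs).all(axis=1))[0][0])
        raise ValueError(f"{path}: non-finite value at data row {bad + 1}")
    sums = probs.sum(axis=1)
    off = np.abs(sums - 1.0) > ROW_SUM_TOL
    if off.any():
        row = int(np.where(off)[0][0])
        if not renormalize:
            raise ValueError(
                f"{path}: data row {row + 1} sums to {sums[row]:.9f} "
                f"(tolerance {ROW_SUM_TOL}); pass renormalize=True to rescale"
            )
        warnings.warn(
            f"{path}: renormalizing {int(off.sum())} row(s) with off-unit sums",
            IGPAWarning,
            stacklevel=2,
        )
        probs = probs / sums[:, None]
    return PredictionMatrix(probs, class_names, source_id=source_id or path.stem)


def save_predictions(pred: PredictionMatrix, path: str | Path) -> None:
    df = pd.DataFrame(pred.probs, columns=list(pred.class_names))
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def load_labels(path: str | Path, n_classes: int | None = None) -> LabelVector:
    """Read a one-column (``label``) CSV of integer class indices."""
    path = Path(path)
    df = pd.read_csv(path)
    col = "label" if "label" in df.columns else df.columns[-1]
    try:
        labels = df[col].to_numpy(dtype=int)
    except ValueError as exc:
        raise ValueError(f"{path}: non-integer label ({exc})") from exc
    return LabelVector(labels, n_classes=n_classes)


def save_labels(labels: LabelVector, path: str | Path) -> None:
    pd.DataFrame({"label": labels.labels}).to_csv(path, index=False)


def load_manifest(path: str | Path) -> SampleManifest:
    return SampleManifest(pd.read_csv(path, dtype=str))


def save_manifest(m: SampleManifest, path: str | Path) -> None:
    m.records.to_csv(path, index=False)


def load_tree_config(
    path: str | Path, known_sources: set[str] | None = None
) -> EnsembleNode:
    """Read a JSON or YAML tree description and validate it into a tree.

    Nodes are mappings {id, children, selection, k, alpha}; children are
    nested nodes or leaf-reference strings.  ``{"topology":
    "reference_all" | "reference_best3"}`` resolves the built-in stack.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        config = yaml.safe_load(text)
    else:
        config = json.loads(text)
    if not isinstance(config, Mapping):
        raise ValueError(f"{path}: tree config must be a mapping")
    return build_tree(config, known_sources=known_sources)


def save_report(report: Mapping, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=False) + "\n")
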