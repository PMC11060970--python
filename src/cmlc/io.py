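"""Readers and writers for networks, dependency matrices and results.

Supported on-disk formats:

- matrix CSV: a ``p x p`` numeric grid per layer, with an optional header
  row and first label column of node names;
- edge-list TSV: columns ``layer``, ``source``, ``target``, ``weight``;
  absent pairs are weight 0;
- dependency CSV: a ``k x k`` numeric grid, optional layer-label header;
- results: a CSV of centralities (rows = nodes, columns = layers) plus a
  JSON sidecar with the (pseudo-)eigenvalues, iteration count, convergence
  flag and solver options.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .network import DependencyMatrix, MultilayerNetwork, validate_dependency_matrix
from .solver import SolveResult, SolverOptions

__all__ = [
    "read_matrix_csv",
    "read_multilayer",
    "read_edge_list",
    "read_dependency",
    "write_multilayer",
    "write_result",
]


def _looks_like_header(first_row: Sequence[str]) -> bool:
    def _numeric(tok: str) -> bool:
        try:
            float(tok)
            return True
        except ValueError:
            return False

    return any(not _numeric(tok) for tok in first_row)


def read_matrix_csv(path: str | Path) -> tuple[np.ndarray, list[str] | None]:
    """Read one square matrix CSV; returns (matrix, node labels or None)."""
    path = Path(path)
    raw = pd.read_csv(path, header=None, dtype=str)
    if raw.empty:
        raise ValueError(f"{path}: empty file")
    labels: list[str] | None = None
    first = [str(v) for v in raw.iloc[0].tolist()]
    if _looks_like_header(first):
        # header row; the first cell may be a corner placeholder
        has_corner = raw.shape[1] == raw.shape[0]
        labels = first[1:] if has_corner else first
        raw = raw.iloc[1:]
        if has_corner or _looks_like_header([str(v) for v in raw.iloc[:, 0].tolist()]):
            raw = raw.iloc[:, 1:]
    try:
        mat = raw.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric cell in matrix body ({exc})") from exc
    if mat.shape[0] != mat.shape[1]:
        raise ValueError(f"{path}: matrix is {mat.shape[0]}x{mat.shape[1]}, expected square")
    if labels is not None and len(labels) != mat.shape[0]:
        raise ValueError(f"{path}: {len(labels)} labels for {mat.shape[0]} rows")
    return mat, labels


def read_multilayer(paths: Sequence[str | Path]) -> MultilayerNetwork:
    """Read one matrix CSV per layer into a multilayer network.

    Layer labels default to the file stems; node labels are taken from the
    first file with a header and must agree across files when present.
    """
    mats, labels = [], None
    layer_labels = []
    for path in paths:
        mat, lab = read_matrix_csv(path)
        if lab is not None:
            if labels is not None and lab != labels:
                raise ValueError(f"{path}: node labels disagree with earlier layers")
            labels = lab
        mats.append(mat)
        layer_labels.append(Path(path).stem)
    return MultilayerNetwork(mats, node_labels=labels, layer_labels=layer_labels)


def read_edge_list(path: str | Path) -> MultilayerNetwork:
    """Read a long-form TSV with columns layer, source, target, weight.

    Node order is the sorted union of all source/target labels; missing
    pairs get weight 0.  An absent weight column defaults to 1.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str, 2: str})
    cols = [c.lower() for c in df.columns]
    required = {"layer", "source", "target"}
    if not required.issubset(cols):
        raise ValueError(f"{path}: edge list needs columns layer, source, target (+ optional weight)")
    df.columns = cols
    if "weight" not in cols:
        df["weight"] = 1.0
    df["weight"] = pd.to_numeric(df["weight"], errors="raise")
    nodes = sorted(set(df["source"].astype(str)) | set(df["target"].astype(str)))
    idx = {n: i for i, n in enumerate(nodes)}
    layer_names = list(dict.fromkeys(df["layer"].astype(str)))
    p = len(nodes)
    mats = {name: np.zeros((p, p)) for name in layer_names}
    for row in df.itertuples(index=False):
        mats[str(row.layer)][idx[str(row.source)], idx[str(row.target)]] = float(row.weight)
    return MultilayerNetwork(
        [mats[name] for name in layer_names], node_labels=nodes, layer_labels=layer_names
    )


def read_dependency(path: str | Path, tol: float = 1e-9) -> DependencyMatrix:
    """Read and validate a k x k dependency CSV (optional label header)."""
    mat, _ = read_matrix_csv(path)
    return validate_dependency_matrix(mat, tol=tol)


def write_multilayer(net: MultilayerNetwork, directory: str | Path) -> list[Path]:
    """Write one full-precision matrix CSV per layer; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for label, mat in zip(net.layer_labels, net.layers):
        df = pd.DataFrame(mat, index=list(net.node_labels), columns=list(net.node_labels))
        out = directory / f"{label}.csv"
        df.to_csv(out, float_format="%.17g")
        paths.append(out)
    return paths


def write_result(
    result: SolveResult,
    prefix: str | Path,
    opts: SolverOptions | None = None,
    round_to: int | None = None,
) -> tuple[Path, Path]:
    """Write centralities to ``<prefix>.csv`` and metadata to ``<prefix>.json``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    node_labels = result.node_labels or tuple(f"n{i + 1}" for i in range(len(result.X[0])))
    layer_labels = result.layer_labels or tuple(f"layer{j + 1}" for j in range(len(result.X)))
    df = pd.DataFrame(
        {lab: x for lab, x in zip(layer_labels, result.X)}, index=list(node_labels)
    )
    if round_to is not None:
        df = df.round(round_to)
    csv_path = prefix.with_suffix(".csv")
    df.to_csv(csv_path, index_label="node", float_format=None)
    meta = {
        "method": result.method,
        "lambdas": [float(v) for v in result.lambdas],
        "iterations": int(result.iterations),
        "converged": bool(result.converged),
        "residuals": [float(v) for v in result.residuals],
        "options": asdict(opts) if opts is not None else None,
    }
    json_path = prefix.with_suffix(".json")
    json_path.write_text(json.dumps(meta, indent=2) + "\n")
    return csv_path, json_path
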