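"""Readers and writers: delimited-text matrices, binary containers, manifests.

Delimited text uses full double precision scientific notation so that
write-then-read round trips are lossless; ``.npy`` serves as the equivalent
binary container.  Every result writer drops a JSON manifest (parameters,
seed, versions) sufficient to reproduce the run.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .trajectory import Trajectory

__all__ = [
    "read_trajectory",
    "write_trajectory",
    "read_matrix",
    "write_matrix",
    "write_manifest",
    "write_tica_result",
    "write_critical_lags",
    "write_curves",
]

_FLOAT_FMT = "%.17e"


def read_matrix(path, fmt: str = "auto") -> np.ndarray:
    """Read a numeric matrix from delimited text or a .npy binary container.

    Text may be whitespace- or comma-separated, one row per line.  Ragged or
    non-numeric rows raise a parse error naming the offending row.
    """
    path = Path(path)
    if fmt == "auto":
        fmt = "binary" if path.suffix == ".npy" else "delimited"
    if fmt == "binary":
        return np.load(path)
    rows = []
    width = None
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            try:
                row = [float(p) for p in parts]
            except ValueError as exc:
                raise ValueError(f"non-numeric cell in row {i} of {path}") from exc
            if width is None:
                width = len(row)
            elif len(row) != width:
                raise ValueError(
                    f"ragged row {i} of {path}: expected {width} columns, got {len(row)}"
                )
            rows.append(row)
    if not rows:
        raise ValueError(f"empty matrix file: {path}")
    return np.asarray(rows, dtype=float)


def write_matrix(matrix: np.ndarray, path, fmt: str = "auto") -> Path:
    path = Path(path)
    if fmt == "auto":
        fmt = "binary" if path.suffix == ".npy" else "delimited"
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "binary":
        np.save(path, np.asarray(matrix))
    else:
        np.savetxt(path, np.atleast_2d(matrix), fmt=_FLOAT_FMT)
    return path


def read_trajectory(path, fmt: str = "auto") -> Trajectory:
    """Load an uncentered trajectory (one frame per row); caller centers."""
    return Trajectory(read_matrix(path, fmt))


def write_trajectory(traj: Trajectory, path, fmt: str = "auto") -> Path:
    return write_matrix(traj.coords, path, fmt)


def _versions() -> dict:
    import scipy

    from . import __version__

    return {"ticawalk": __version__, "numpy": np.__version__, "scipy": scipy.__version__}


def write_manifest(path, params: dict) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"parameters": params, "versions": _versions()}
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")
    return path


def write_tica_result(result, prefix) -> list[Path]:
    """Eigenvalue table + projection matrix + manifest for a TicaResult or
    MDecomposition / ExpectedProjections."""
    prefix = Path(prefix)
    eigenvalues = np.asarray(result.eigenvalues)
    projections = np.asarray(result.projections)
    table = np.column_stack([np.arange(1, eigenvalues.size + 1), eigenvalues])
    paths = [
        write_matrix(table, prefix.with_name(prefix.name + "_eigenvalues.tsv")),
        write_matrix(projections, prefix.with_name(prefix.name + "_projections.tsv")),
    ]
    params = {
        k: getattr(result, k)
        for k in ("method", "tau", "n", "d", "n_samples", "seed", "norm")
        if hasattr(result, k)
    }
    paths.append(write_manifest(prefix.with_name(prefix.name + "_manifest.json"), params))
    return paths


def write_critical_lags(lags, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "first": lags.first,
        "second": lags.second,
        "n": lags.n,
        "d": lags.d,
        "method": lags.method,
        "metadata": lags.metadata,
        "versions": _versions(),
    }
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")
    return path


def write_curves(curves, prefix) -> list[Path]:
    """Columnar eigenvalue-curve table (tau, then one column per rank)."""
    prefix = Path(prefix)
    table = np.column_stack([curves.tau_grid, curves.eigenvalues])
    paths = [write_matrix(table, prefix.with_name(prefix.name + "_eigenvalue_curves.tsv"))]
    params = {
        "n": curves.n, "d": curves.d, "method": curves.method,
        "n_samples": curves.n_samples, "seed": curves.seed,
        "tau_grid": curves.tau_grid.tolist(), "tracked": curves.tracked,
        "labels": curves.labels,
    }
    paths.append(write_manifest(prefix.with_name(prefix.name + "_manifest.json"), params))
    return paths
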