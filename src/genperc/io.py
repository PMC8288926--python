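"""Readers, writers and run manifests.

Edge lists are TSV ("u<TAB>v", 0-based integer node ids, '#' comments);
weight matrices are square numeric CSV; traces, sweeps and fits are written
as TSV so theory and simulation output overlay directly.  Every CLI run
writes a YAML manifest (command, parameters, seed, input checksums) so each
result file is traceable and reruns are reproducible.
"""

from __future__ import annotations

import hashlib
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import GenerationTrace

__all__ = [
    "read_edge_list",
    "write_edge_list",
    "read_weight_matrix",
    "write_weight_matrix",
    "write_trace",
    "read_trace",
    "RunManifest",
]

_ASYMMETRY_TOL = 1e-6


class EdgeListParseError(ValueError):
    pass


def read_edge_list(path, one_based: bool = False):
    """Read a TSV edge list into a canonical undirected edge array.

    Returns (edges, report) where report counts dropped self-loops and
    collapsed duplicates.  Malformed lines raise with the line number.
    """
    rows = []
    self_loops = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise EdgeListParseError(f"{path}:{lineno}: expected 'u<TAB>v', got {line!r}")
            try:
                u, v = int(parts[0]), int(parts[1])
            except ValueError as exc:
                raise EdgeListParseError(f"{path}:{lineno}: non-integer node id") from exc
            if one_based:
                u, v = u - 1, v - 1
            if u < 0 or v < 0:
                raise EdgeListParseError(f"{path}:{lineno}: negative node id")
            if u == v:
                self_loops += 1
                continue
            rows.append((min(u, v), max(u, v)))
    if rows:
        arr = np.unique(np.asarray(rows, dtype=np.int64), axis=0)
    else:
        arr = np.empty((0, 2), dtype=np.int64)
    report = {"self_loops_dropped": self_loops, "duplicates_collapsed": len(rows) - len(arr)}
    return arr, report


def write_edge_list(path, edges: np.ndarray) -> None:
    edges = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
    with open(path, "w") as fh:
        for u, v in edges:
            fh.write(f"{u}\t{v}\n")


def read_weight_matrix(path) -> np.ndarray:
    """Read a square numeric CSV weight matrix, symmetrizing tiny asymmetry.

    Asymmetry below 1e-6 (e.g. float formatting) is silently averaged away
    as (W + W^T)/2; larger asymmetry is an error, as are NaNs and
    non-square shapes.  The diagonal is ignored by downstream thresholding.
    """
    df = pd.read_csv(path, header=None)
    try:
        w = df.to_numpy(dtype=float)
    except ValueError:
        # header row present
        df = pd.read_csv(path)
        w = df.to_numpy(dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError(f"weight matrix must be square, got {w.shape}")
    if np.isnan(w).any():
        raise ValueError("weight matrix contains NaN entries")
    asym = np.max(np.abs(w - w.T)) if w.size else 0.0
    if asym > _ASYMMETRY_TOL:
        raise ValueError(f"weight matrix asymmetry {asym:.3g} exceeds tolerance {_ASYMMETRY_TOL}")
    return (w + w.T) / 2.0


def write_weight_matrix(path, weights: np.ndarray) -> None:
    np.savetxt(path, np.asarray(weights, dtype=float), delimiter=",", fmt="%.12g")


def write_trace(path, trace: GenerationTrace) -> None:
    """Serialize a trace as TSV rows (generation, psi, second_largest, n_clusters)."""
    df = pd.DataFrame({
        "generation": np.arange(1, trace.n_generations + 1),
        "psi": trace.psi,
        "second_largest": trace.second_largest,
        "n_clusters": trace.n_clusters,
    })
    df.to_csv(path, sep="\t", index=False)


def read_trace(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def _checksum(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


@dataclass
class RunManifest:
    """Reproducibility record written next to every CLI result file."""

    command: str
    parameters: dict
    seed: int | None = None
    inputs: dict = field(default_factory=dict)
    version: str = "0.1.0"
    timestamp: str = field(default_factory=lambda: time.strftime("%Y-%m-%dT%H:%M:%S"))

    def add_input(self, path) -> None:
        self.inputs[str(path)] = _checksum(path)

    def write(self, path) -> None:
        payload = {
            "command": self.command,
            "parameters": self.parameters,
            "seed": self.seed,
            "inputs": self.inputs,
            "version": self.version,
            "timestamp": self.timestamp,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def read(cls, path) -> "RunManifest":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(command=payload["command"], parameters=payload["parameters"],
                   seed=payload.get("seed"), inputs=payload.get("inputs", {}),
                   version=payload.get("version", "?"),
                   timestamp=payload.get("timestamp", "?"))
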