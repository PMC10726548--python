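"""Plain-text I/O: coordinates, dense/sparse matrices, graphs, priors.

Conventions: dense matrices are TSV with a header row of spot/column ids and
the first column holding row ids; sparse matrices are Matrix Market triplets
(1-based on disk, 0-based in memory) with companion ``*_rows.tsv`` /
``*_cols.tsv`` name files; graphs are edge lists storing each undirected edge
once (spot_i < spot_j lexicographically); priors are MTX triplets of Q with a
JSON sidecar recording {process, rho, jitter, n_spots}. write ∘ read is the
identity (bitwise for integers, to 1e-12 for reals).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp

from .graph import SpatialGraph, SpotCoordinates
from .prior import SpatialPrior

__all__ = [
    "read_coordinates",
    "write_coordinates",
    "read_dense",
    "write_dense",
    "read_mtx",
    "write_mtx",
    "read_graph",
    "write_graph",
    "read_prior",
    "write_prior",
]


def read_coordinates(path: str | Path, grid_hint: str = "irregular") -> SpotCoordinates:
    df = pd.read_csv(path, sep="\t", dtype={"spot_id": str})
    for col in ("spot_id", "x", "y"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    return SpotCoordinates.from_frame(df, grid_hint)


def write_coordinates(coords: SpotCoordinates, path: str | Path) -> None:
    coords.to_frame().to_csv(path, sep="\t", index=False)


def read_dense(path: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    """Dense TSV -> (values, row_ids, col_ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(float), [str(i) for i in df.index], [str(c) for c in df.columns]


def write_dense(
    values: np.ndarray, row_ids: list[str], col_ids: list[str], path: str | Path
) -> None:
    pd.DataFrame(values, index=row_ids, columns=col_ids).to_csv(path, sep="\t")


def write_mtx(
    values: np.ndarray | sp.spmatrix,
    row_ids: list[str],
    col_ids: list[str],
    prefix: str | Path,
) -> None:
    """Matrix Market triplet plus row/column name files (``<prefix>.mtx`` etc.)."""
    prefix = Path(prefix)
    M = sp.coo_matrix(values)
    sio.mmwrite(str(prefix.with_suffix(".mtx")), M)
    pd.Series(row_ids).to_csv(prefix.parent / f"{prefix.name}_rows.tsv", sep="\t",
                              index=False, header=False)
    pd.Series(col_ids).to_csv(prefix.parent / f"{prefix.name}_cols.tsv", sep="\t",
                              index=False, header=False)


def read_mtx(prefix: str | Path) -> tuple[sp.csr_matrix, list[str], list[str]]:
    prefix = Path(prefix)
    M = sp.csr_matrix(sio.mmread(str(prefix.with_suffix(".mtx"))))
    rows = pd.read_csv(prefix.parent / f"{prefix.name}_rows.tsv", sep="\t",
                       header=None)[0].astype(str).tolist()
    cols = pd.read_csv(prefix.parent / f"{prefix.name}_cols.tsv", sep="\t",
                       header=None)[0].astype(str).tolist()
    if M.shape != (len(rows), len(cols)):
        raise ValueError(
            f"{prefix}: matrix is {M.shape} but name files give "
            f"({len(rows)}, {len(cols)})"
        )
    return M, rows, cols


def write_graph(graph: SpatialGraph, path: str | Path) -> None:
    graph.edge_list().to_csv(path, sep="\t", index=False)


def read_graph(path: str | Path, spot_ids: list[str] | None = None, k: int = 0) -> SpatialGraph:
    """Edge-list TSV -> SpatialGraph. ``spot_ids`` fixes spot order (and
    includes isolated spots); otherwise ids are collected from the edges."""
    df = pd.read_csv(path, sep="\t", dtype={"spot_i": str, "spot_j": str})
    for col in ("spot_i", "spot_j", "weight"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if spot_ids is None:
        spot_ids = sorted(set(df["spot_i"]) | set(df["spot_j"]))
    index = {s: i for i, s in enumerate(spot_ids)}
    try:
        rows = [index[s] for s in df["spot_i"]]
        cols = [index[s] for s in df["spot_j"]]
    except KeyError as e:  # pragma: no cover - defensive
        raise ValueError(f"{path}: edge references unknown spot {e}") from None
    n = len(spot_ids)
    W = sp.coo_matrix((df["weight"], (rows, cols)), shape=(n, n))
    W = W + W.T
    return SpatialGraph(list(spot_ids), W.tocsr(), k=k)


def write_prior(prior: SpatialPrior, prefix: str | Path) -> None:
    prefix = Path(prefix)
    Q = prior.precision if prior.process != "SMA" else prior.sma_factor
    sio.mmwrite(str(prefix.with_suffix(".mtx")), sp.coo_matrix(Q))
    meta = {
        "process": prior.process,
        "rho": prior.rho,
        "jitter": prior.jitter,
        "n_spots": prior.n_spots,
        "spot_ids": prior.spot_ids,
        "matrix_is": "sma_factor" if prior.process == "SMA" else "precision",
    }
    (prefix.parent / f"{prefix.name}.json").write_text(json.dumps(meta))


def read_prior(prefix: str | Path) -> SpatialPrior:
    prefix = Path(prefix)
    meta = json.loads((prefix.parent / f"{prefix.name}.json").read_text())
    M = sp.csr_matrix(sio.mmread(str(prefix.with_suffix(".mtx"))))
    if meta["process"] == "SMA":
        return SpatialPrior(
            process="SMA",
            rho=meta["rho"],
            precision=None,
            n_spots=meta["n_spots"],
            jitter=meta["jitter"],
            spot_ids=meta.get("spot_ids"),
            sma_factor=M.tocsc(),
        )
    return SpatialPrior(
        process=meta["process"],
        rho=meta["rho"],
        precision=M,
        n_spots=meta["n_spots"],
        jitter=meta["jitter"],
        spot_ids=meta.get("spot_ids"),
    )
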