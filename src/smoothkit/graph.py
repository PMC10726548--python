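"""Spatial neighborhood graphs with boundary-aware edge scaling.

Spots (capture locations) are connected by a mutual k-nearest-neighbor rule on
their planar coordinates, producing a symmetric spatial weights matrix W with
binary edges. Boundary information — transcriptomic or histological similarity,
or categorical domain labels — is then encoded by scaling edge weights down
(never up), so that the downstream prior does not smooth across region borders.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "SpotCoordinates",
    "SpatialGraph",
    "BoundaryFeatures",
    "build_knn_graph",
    "scale_edges",
    "default_k",
]

#: default neighborhood size per grid layout (6 for hexagonal chips such as
#: 10x Visium, 4 for square grids, 6 for irregular bead arrays)
_DEFAULT_K = {"hex": 6, "square": 4, "irregular": 6}


@dataclass
class SpotCoordinates:
    """Planar positions of spots, both axes on the same scale.

    Parameters
    ----------
    spot_ids
        Unique string identifiers, one per spot.
    xy
        ``(n_spots, 2)`` array of finite coordinates.
    grid_hint
        One of ``{"hex", "square", "irregular"}``; only used to pick a
        default ``k`` when none is given.
    """

    spot_ids: list[str]
    xy: np.ndarray
    grid_hint: str = "irregular"

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float)
        self.spot_ids = [str(s) for s in self.spot_ids]
        if self.xy.ndim != 2 or self.xy.shape[1] != 2:
            raise ValueError("xy must be an (n_spots, 2) array")
        if len(self.spot_ids) != self.xy.shape[0]:
            raise ValueError("spot_ids and xy length mismatch")
        if len(set(self.spot_ids)) != len(self.spot_ids):
            raise ValueError("spot_ids must be unique")
        if not np.all(np.isfinite(self.xy)):
            raise ValueError("coordinates must be finite")
        if self.n_spots < 1:
            raise ValueError("need at least one spot")
        if self.grid_hint not in _DEFAULT_K:
            raise ValueError(f"grid_hint must be one of {sorted(_DEFAULT_K)}")

    @property
    def n_spots(self) -> int:
        return self.xy.shape[0]

    @classmethod
    def from_frame(cls, df: pd.DataFrame, grid_hint: str = "irregular") -> "SpotCoordinates":
        return cls(df["spot_id"].tolist(), df[["x", "y"]].to_numpy(float), grid_hint)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"spot_id": self.spot_ids, "x": self.xy[:, 0], "y": self.xy[:, 1]})


@dataclass
class SpatialGraph:
    """Symmetric weighted adjacency over spots (the spatial weights matrix W)."""

    spot_ids: list[str]
    W: sp.csr_matrix
    k: int
    coords: SpotCoordinates | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.W = sp.csr_matrix(self.W)
        n = len(self.spot_ids)
        if self.W.shape != (n, n):
            raise ValueError("W shape does not match number of spots")
        if (self.W != self.W.T).nnz != 0:
            raise ValueError("W must be symmetric")
        if self.W.diagonal().any():
            raise ValueError("W must have no self-edges")
        if self.W.nnz and self.W.data.min() < 0:
            raise ValueError("edge weights must be non-negative")

    @property
    def n_spots(self) -> int:
        return len(self.spot_ids)

    @property
    def n_edges(self) -> int:
        return self.W.nnz // 2

    def degrees(self) -> np.ndarray:
        """Number of incident edges (nonzero weights) per spot."""
        return np.diff(sp.csr_matrix((self.W != 0).astype(int)).indptr)

    def edge_list(self) -> pd.DataFrame:
        """Each undirected edge once, (i < j by spot-id lexicographic order)."""
        coo = sp.triu(self._lex_permuted(), k=1).tocoo()
        order = sorted(range(len(self.spot_ids)), key=lambda i: self.spot_ids[i])
        ids = [self.spot_ids[i] for i in order]
        df = pd.DataFrame(
            {
                "spot_i": [ids[i] for i in coo.row],
                "spot_j": [ids[j] for j in coo.col],
                "weight": coo.data,
            }
        )
        return df.sort_values(["spot_i", "spot_j"], ignore_index=True)

    def _lex_permuted(self) -> sp.csr_matrix:
        order = np.array(sorted(range(len(self.spot_ids)), key=lambda i: self.spot_ids[i]))
        return self.W[order][:, order]


@dataclass
class BoundaryFeatures:
    """Per-spot features used to scale edges across putative boundaries.

    ``mode`` selects the scaling rule:

    - ``soft_expression``: cosine similarity of feature vectors (e.g. the
      first 10 expression PCs), negatives clamped to zero;
    - ``soft_histology``: Gaussian kernel (bandwidth 0.1) on the Euclidean
      distance between per-dimension z-scored feature vectors;
    - ``hard_labels``: 1 within a domain, ``leak`` across domains.
    """

    values: np.ndarray | list
    mode: str

    def __post_init__(self) -> None:
        if self.mode not in ("soft_expression", "soft_histology", "hard_labels"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "hard_labels":
            self.values = np.asarray(self.values)
            if self.values.ndim != 1:
                raise ValueError("hard_labels expects one label per spot")
        else:
            self.values = np.asarray(self.values, dtype=float)
            if self.values.ndim != 2:
                raise ValueError("soft modes expect an (n_spots, n_features) matrix")

    @property
    def n_spots(self) -> int:
        return self.values.shape[0]


def default_k(grid_hint: str) -> int:
    return _DEFAULT_K[grid_hint]


def build_knn_graph(coords: SpotCoordinates, k: int | None = None) -> SpatialGraph:
    """Mutual k-nearest-neighbor graph on Euclidean spot distances.

    An edge (i, j) with weight 1 exists iff i is among j's k nearest spots AND
    j is among i's k nearest. ``k`` defaults to 6 on hexagonal grids (the 10x
    Visium convention), 4 on square grids and 6 otherwise. Distance ties are
    broken by (distance, spot index) so results are platform-deterministic.
    """
    if k is None:
        k = default_k(coords.grid_hint)
    k = int(k)
    n = coords.n_spots
    if k <= 0:
        raise ValueError("k must be positive")
    if n == 1:
        warnings.warn("single spot: graph has no edges", stacklevel=2)
        return SpatialGraph([*coords.spot_ids], sp.csr_matrix((1, 1)), k, coords)
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of spots ({n})")

    # dense pairwise distances; fine at the slide sizes this package targets
    d2 = ((coords.xy[:, None, :] - coords.xy[None, :, :]) ** 2).sum(-1)
    np.fill_diagonal(d2, np.inf)
    idx = np.arange(n)
    # stable tie-break: sort by (distance, index)
    nn = np.empty((n, k), dtype=int)
    for i in range(n):
        order = np.lexsort((idx, d2[i]))
        nn[i] = order[:k]
    inset = np.zeros((n, n), dtype=bool)
    inset[np.repeat(idx, k), nn.ravel()] = True
    mutual = inset & inset.T
    W = sp.csr_matrix(mutual.astype(float))
    return SpatialGraph([*coords.spot_ids], W, k, coords)


def scale_edges(
    graph: SpatialGraph, features: BoundaryFeatures, leak: float = 0.0
) -> SpatialGraph:
    """Scale edge weights by pairwise feature similarity (W' = W ∘ D).

    Weights can only shrink; edges whose weight falls to zero are pruned.
    ``leak`` (hard mode only, default 0) keeps a nominal connection across
    domain boundaries; leak=0.01 reproduces the soft-pruning variant.
    """
    if features.n_spots != graph.n_spots:
        raise ValueError("features not aligned to graph spots")
    if not 0.0 <= leak <= 1.0:
        raise ValueError("leak must be in [0, 1]")

    coo = graph.W.tocoo()
    if features.mode == "soft_expression":
        V = features.values
        norms = np.linalg.norm(V, axis=1)
        if np.any(norms[np.unique(np.r_[coo.row, coo.col])] == 0):
            warnings.warn("zero-norm feature vector: cosine similarity treated as 0", stacklevel=2)
        safe = np.where(norms == 0, 1.0, norms)
        U = V / safe[:, None]
        U[norms == 0] = 0.0
        sim = np.einsum("ij,ij->i", U[coo.row], U[coo.col])
        mult = np.clip(sim, 0.0, None)
    elif features.mode == "soft_histology":
        V = features.values
        mu, sd = V.mean(0), V.std(0)
        sd = np.where(sd == 0, 1.0, sd)
        Z = (V - mu) / sd
        d = np.linalg.norm(Z[coo.row] - Z[coo.col], axis=1)
        mult = np.exp(-(d**2) / (2 * 0.1**2))
    else:  # hard_labels
        same = features.values[coo.row] == features.values[coo.col]
        mult = np.where(same, 1.0, leak)

    data = coo.data * mult
    W = sp.csr_matrix((data, (coo.row, coo.col)), shape=graph.W.shape)
    W.eliminate_zeros()
    return SpatialGraph([*graph.spot_ids], W, graph.k, graph.coords)
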