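"""Sparse multivariate-normal spatial priors and the detachable spatial loss.

A spatial graph with weights matrix W is translated into the precision matrix
Q = Σ⁻¹ of a zero-centered MVN prior under one of five stationary spatial
processes:

- ``CAR``   (conditional autoregressive):    Q = I − ρW
- ``SAR``   (simultaneous autoregressive):   Q = (I − ρW)ᵀ(I − ρW)
- ``ICAR``  (weights-scaled CAR):            Q = D − ρW,  D = diag(row sums)
- ``ISAR``  (weights-scaled SAR):            Q = (I − ρW̃)ᵀ(I − ρW̃), W̃ row-normalized
- ``SMA``   (spatial moving average):        Σ = (I + ρW̃)(I + ρW̃)ᵀ, precision
  applied implicitly through sparse solves (its explicit inverse is dense-ish).

The autocorrelation ρ lies in [0, 1] for ICAR/ISAR and strictly inside the
reciprocal spectral range of W for CAR/SAR. The quadratic spatial loss
``L_sp(x) = xᵀQx`` is the negative log-density of the prior up to constants and
can be appended to any model's objective; its contrastive extension subtracts
the same quadratic form evaluated under spot-permuted ("corrupted") graphs,
which penalizes collapsing all spots onto one value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .graph import SpatialGraph

__all__ = [
    "SpatialPrior",
    "build_prior",
    "spatial_loss",
    "contrastive_spatial_loss",
    "implied_correlation",
]

PROCESSES = ("CAR", "SAR", "ICAR", "ISAR", "SMA")

#: toolkit-wide defaults: ICAR with rho = 0.99
DEFAULT_PROCESS = "ICAR"
DEFAULT_RHO = 0.99


@dataclass
class SpatialPrior:
    """Precision representation of the MVN spatial prior.

    ``precision`` holds Q for CAR/SAR/ICAR/ISAR. For SMA only the sparse
    factor B = I + ρW̃ is stored (``sma_factor``) and Q is applied via solves.
    """

    process: str
    rho: float
    precision: sp.csr_matrix | None
    n_spots: int
    jitter: float = 0.0
    spot_ids: list[str] | None = None
    sma_factor: sp.csc_matrix | None = field(default=None, repr=False)
    _sma_lu: object = field(default=None, repr=False, compare=False)

    def apply_Q(self, X: np.ndarray) -> np.ndarray:
        """Q @ X.T for row-matrix X of shape (..., n_spots)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[-1] != self.n_spots:
            raise ValueError(
                f"variable has {X.shape[-1]} entries but prior covers {self.n_spots} spots"
            )
        if self.process == "SMA":
            if self._sma_lu is None:
                self._sma_lu = spla.splu(self.sma_factor.tocsc())
            # Q = (B Bᵀ)⁻¹  =>  Qx = B⁻ᵀ B⁻¹ x
            U = self._sma_lu.solve(X.T)
            QX = self._sma_lu.solve(U, trans="T")
            if self.jitter:
                QX = QX + self.jitter * X.T
            return QX
        return self.precision @ X.T

    def dense_Q(self) -> np.ndarray:
        """Explicit dense Q (tests/small graphs only)."""
        if self.process == "SMA":
            B = self.sma_factor.toarray()
            Q = np.linalg.inv(B @ B.T)
            if self.jitter:
                Q = Q + self.jitter * np.eye(self.n_spots)
            return Q
        return self.precision.toarray()


def _rho_bounds_car(W: sp.spmatrix) -> tuple[float, float]:
    """Admissible open interval for ρ in CAR/SAR: (1/λ_min, 1/λ_max) of W."""
    n = W.shape[0]
    if W.nnz == 0:
        return (-np.inf, np.inf)
    if n <= 200:
        lams = np.linalg.eigvalsh(W.toarray())
        lam_min, lam_max = lams[0], lams[-1]
    else:
        lam_max = float(spla.eigsh(W, k=1, which="LA", return_eigenvectors=False)[0])
        lam_min = float(spla.eigsh(W, k=1, which="SA", return_eigenvectors=False)[0])
    lo = 1.0 / lam_min if lam_min < 0 else -np.inf
    hi = 1.0 / lam_max if lam_max > 0 else np.inf
    return (lo, hi)


def _row_normalize(W: sp.spmatrix) -> sp.csr_matrix:
    d = np.asarray(W.sum(axis=1)).ravel()
    inv = np.where(d > 0, 1.0 / np.where(d > 0, d, 1.0), 0.0)
    return sp.diags(inv) @ sp.csr_matrix(W)


def build_prior(
    graph: SpatialGraph,
    process: str = DEFAULT_PROCESS,
    rho: float = DEFAULT_RHO,
    jitter: float = 1e-5,
) -> SpatialPrior:
    """Translate the spatial weights matrix into a sparse precision matrix.

    ``jitter`` (default 1e-5) is added to the diagonal only when Q would be
    singular: ICAR/ISAR at ρ=1, or graphs with isolated spots. Pass
    ``jitter=0`` to disable (e.g. to expose the exact intrinsic null space).
    """
    process = process.upper()
    if process not in PROCESSES:
        raise ValueError(f"process must be one of {PROCESSES}")
    W = sp.csr_matrix(graph.W, dtype=float)
    n = graph.n_spots
    I = sp.identity(n, format="csr")

    if process in ("ICAR", "ISAR", "SMA"):
        if not 0.0 <= rho <= 1.0:
            raise ValueError(f"{process}: rho must lie in [0, 1], got {rho}")
    else:
        lo, hi = _rho_bounds_car(W)
        if not lo < rho < hi:
            raise ValueError(
                f"{process}: rho={rho} outside the admissible interval "
                f"({lo:.6g}, {hi:.6g}) set by the spectrum of W"
            )

    d = np.asarray(W.sum(axis=1)).ravel()
    isolated = bool(np.any(d == 0)) and n > 1
    singular = process in ("ICAR", "ISAR") and (rho >= 1.0 - 1e-12 or isolated)

    if process == "CAR":
        Q = (I - rho * W).tocsr()
    elif process == "SAR":
        A = (I - rho * W).tocsr()
        Q = (A.T @ A).tocsr()
    elif process == "ICAR":
        Q = (sp.diags(d) - rho * W).tocsr()
    elif process == "ISAR":
        A = (I - rho * _row_normalize(W)).tocsr()
        Q = (A.T @ A).tocsr()
    else:  # SMA
        B = (I + rho * _row_normalize(W)).tocsc()
        return SpatialPrior(
            process="SMA",
            rho=rho,
            precision=None,
            n_spots=n,
            jitter=0.0,
            spot_ids=[*graph.spot_ids],
            sma_factor=B,
        )

    applied = jitter if singular and jitter > 0 else 0.0
    if applied:
        Q = (Q + applied * I).tocsr()
    return SpatialPrior(
        process=process,
        rho=rho,
        precision=Q,
        n_spots=n,
        jitter=applied,
        spot_ids=[*graph.spot_ids],
    )


def spatial_loss(X: np.ndarray, prior: SpatialPrior) -> float:
    """Quadratic spatial loss Σ_rows x Q xᵀ (≥ 0 up to jitter tolerance).

    ``X`` is one spatial variable (length n_spots) or a stack of them
    (rows × n_spots); rows are penalized independently and summed. Cost is
    O(nnz(Q)) per row — the prior is never densified.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    QX = prior.apply_Q(X)  # (n_spots, rows)
    return float(np.einsum("rs,sr->", X, QX))


def contrastive_spatial_loss(
    X: np.ndarray,
    prior: SpatialPrior,
    n_negatives: int = 20,
    neg_weight: float = 0.05,
    seed: int = 0,
) -> float:
    """Contrastive spatial loss L_sp(Σ₀) − (α/T)·Σ_t L_sp(Σ_t).

    Negative samples Σ_t come from corrupting the graph by a uniformly random
    permutation of spot identities (one independent permutation per negative,
    all derived from ``seed``). Since permuting the graph conjugates Q by the
    permutation, each negative term equals the positive quadratic form
    evaluated on the inversely permuted variable — no re-factorization needed.
    """
    if n_negatives < 1:
        raise ValueError("n_negatives must be >= 1")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    pos = spatial_loss(X, prior)
    if neg_weight == 0.0:
        return pos
    rng = np.random.default_rng(seed)
    neg = 0.0
    for _ in range(n_negatives):
        perm = rng.permutation(prior.n_spots)
        # xᵀ(PQPᵀ)x = (Pᵀx)ᵀQ(Pᵀx): evaluate Q on the permuted variable
        neg += spatial_loss(X[:, perm], prior)
    return pos - neg_weight * neg / n_negatives


def implied_correlation(
    prior: SpatialPrior,
    graph: SpatialGraph,
    max_degree: int = 5,
    cap: int = 2000,
) -> dict[int, float]:
    """Median implied pairwise correlation by neighbor degree (dense oracle).

    Densifies Σ = Q⁻¹, converts to correlation, and summarizes the median
    correlation between k-th-degree graph neighbors (degree 0 = self = 1).
    Refuses graphs larger than ``cap`` spots: this is a diagnostic for
    test-sized graphs, not a production path.
    """
    n = prior.n_spots
    if n > cap:
        raise ValueError(f"graph too large to densify ({n} > cap={cap})")
    Q = prior.dense_Q()
    if prior.jitter == 0.0 and prior.process in ("ICAR", "ISAR") and prior.rho >= 1 - 1e-12:
        Q = Q + 1e-8 * np.eye(n)
    Sigma = np.linalg.inv(Q)
    sd = np.sqrt(np.diag(Sigma))
    corr = Sigma / np.outer(sd, sd)

    adj = sp.csr_matrix((graph.W != 0).astype(float))
    dist = sp.csgraph.shortest_path(adj, method="D", unweighted=True)
    out: dict[int, float] = {}
    for deg in range(0, max_degree + 1):
        mask = dist == deg
        if deg == 0:
            out[0] = 1.0
            continue
        if mask.any():
            out[deg] = float(np.median(corr[mask]))
    return out
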