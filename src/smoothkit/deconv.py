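"""Spatially regularized reference-based cell-type deconvolution.

Observed mixtures Y (genes × spots) are modeled as Y ≈ R·X where R is a
reference signature (genes × cell types) and X ≥ 0 the cell-type abundances
(cell types × spots). Four interchangeable data-fit losses are provided —
NNLS, DWLS (modified dampened weighted least squares), ε-insensitive SVR, and
log-normal regression — each extendable with the quadratic spatial loss
λ_sp Σ_c X_c Q X_cᵀ that places the MVN spatial prior on the abundance of each
cell type. The joint objective is minimized over all spots at once (the
spatial penalty couples spots) by projected Adam with a per-spot active-set
NNLS warm start; abundances are clamped non-negative at every step and finally
renormalized per spot into proportions.

Scale conventions follow common practice for skewed sequencing counts:
log1p-scale data for NNLS/DWLS/SVR, raw-scale for LNR (which applies log1p
internally to both sides of the fit).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls as _scipy_nnls

from .prior import SpatialPrior, spatial_loss

__all__ = [
    "OmicsMatrix",
    "ReferenceSignature",
    "AbundanceMatrix",
    "DeconvOptions",
    "deconvolve",
    "deconv_loss",
    "select_marker_genes",
    "default_lambda",
]

MODELS = ("NNLS", "DWLS", "SVR", "LNR")

#: default prior strengths used when the spatial mode is on
_DEFAULT_LAMBDA = {"NNLS": 1.0, "SVR": 1.0, "LNR": 1.0, "DWLS": 3.0}


def default_lambda(model: str) -> float:
    """λ_sp defaults: 1 for spatially aware NNLS/SVR/LNR, 3 for DWLS."""
    return _DEFAULT_LAMBDA[model.upper()]


@dataclass
class OmicsMatrix:
    """Feature-by-spot activity matrix with an explicit scale tag."""

    values: np.ndarray
    gene_ids: list[str]
    spot_ids: list[str]
    scale_tag: str = "raw"  # one of {raw, log1p, sqrt}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.spot_ids)):
            raise ValueError("values shape must be (n_genes, n_spots)")
        if self.scale_tag not in ("raw", "log1p", "sqrt"):
            raise ValueError(f"unknown scale_tag {self.scale_tag!r}")
        if self.scale_tag == "raw" and self.values.size and self.values.min() < 0:
            raise ValueError("raw-scale values must be non-negative")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene ids must be unique")
        if len(set(self.spot_ids)) != len(self.spot_ids):
            raise ValueError("spot ids must be unique")

    def to_scale(self, tag: str) -> "OmicsMatrix":
        """Convert between raw/log1p/sqrt representations."""
        if tag == self.scale_tag:
            return self
        if self.scale_tag == "raw":
            v = np.log1p(self.values) if tag == "log1p" else np.sqrt(self.values)
        elif tag == "raw":
            v = np.expm1(self.values) if self.scale_tag == "log1p" else self.values**2
        else:
            raise ValueError(f"cannot convert {self.scale_tag} -> {tag} directly")
        return OmicsMatrix(v, [*self.gene_ids], [*self.spot_ids], tag)


@dataclass
class ReferenceSignature:
    """Expected per-cell-type activity of each gene (genes × cell types)."""

    values: np.ndarray
    gene_ids: list[str]
    cell_types: list[str]
    scale_tag: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.cell_types)):
            raise ValueError("values shape must be (n_genes, n_cell_types)")
        if self.scale_tag == "raw" and self.values.size and self.values.min() < 0:
            raise ValueError("raw-scale reference must be non-negative")

    def to_scale(self, tag: str) -> "ReferenceSignature":
        if tag == self.scale_tag:
            return self
        if self.scale_tag == "raw" and tag == "log1p":
            v = np.log1p(self.values)
        elif self.scale_tag == "log1p" and tag == "raw":
            v = np.expm1(self.values)
        else:
            raise ValueError(f"cannot convert {self.scale_tag} -> {tag}")
        return ReferenceSignature(v, [*self.gene_ids], [*self.cell_types], tag)


@dataclass
class AbundanceMatrix:
    """Non-negative cell-type × spot abundances with a proportion view."""

    values: np.ndarray
    cell_types: list[str]
    spot_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size and self.values.min() < -1e-12:
            raise ValueError("abundances must be non-negative")
        self.values = np.clip(self.values, 0.0, None)

    def proportions(self) -> np.ndarray:
        """Columns renormalized to sum to 1; all-zero columns become uniform."""
        tot = self.values.sum(axis=0)
        zero = tot <= 0
        if zero.any():
            warnings.warn(
                f"{int(zero.sum())} spot(s) have zero total abundance; "
                "assigning uniform proportions",
                stacklevel=2,
            )
        P = np.empty_like(self.values)
        P[:, ~zero] = self.values[:, ~zero] / tot[~zero]
        P[:, zero] = 1.0 / self.values.shape[0]
        return P


@dataclass
class DeconvOptions:
    """Optimizer and loss hyperparameters (defaults are the documented ones)."""

    lr: float = 1e-3
    max_iter: int = 10000
    rtol: float = 1e-5  # relative loss change threshold ...
    patience: int = 10  # ... sustained over this many iterations
    seed: int = 0
    # DWLS
    dwls_delta: float = 1e-3
    dwls_cap_ratio: float = 100.0
    # SVR
    svr_epsilon: float = 0.1
    svr_ridge: float = 1e-4


def _intersect(Y: OmicsMatrix, R: ReferenceSignature) -> tuple[np.ndarray, np.ndarray]:
    common = [g for g in Y.gene_ids if g in set(R.gene_ids)]
    if not common:
        raise ValueError("empty gene intersection between data and reference")
    yi = {g: i for i, g in enumerate(Y.gene_ids)}
    ri = {g: i for i, g in enumerate(R.gene_ids)}
    rows_y = [yi[g] for g in common]
    rows_r = [ri[g] for g in common]
    return Y.values[rows_y], R.values[rows_r]


def _per_spot_nnls(R: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Active-set NNLS per spot (warm start and λ_sp=0 reference path)."""
    C, S = R.shape[1], Y.shape[1]
    X = np.empty((C, S))
    for s in range(S):
        X[:, s] = _scipy_nnls(R, Y[:, s])[0]
    return X


def _dwls_weights(R: np.ndarray, X_warm: np.ndarray, opts: DeconvOptions) -> np.ndarray:
    """Per-gene weights w_g = 1/max(ŷ_g, δ)², mean-normalized and capped."""
    yhat = (R @ X_warm).mean(axis=1)
    w = 1.0 / np.maximum(yhat, opts.dwls_delta) ** 2
    w = w / w.mean()
    return np.minimum(w, opts.dwls_cap_ratio)


def deconv_loss(
    Y: np.ndarray,
    R: np.ndarray,
    X: np.ndarray,
    model: str,
    opts: DeconvOptions | None = None,
    gene_weights: np.ndarray | None = None,
) -> float:
    """Data-fit loss L_model(Y, RX) on plain arrays (genes × …).

    NNLS: ‖Y−RX‖²_F.  DWLS: Σ w_g (Y−RX)²_{gs} with fixed per-gene weights.
    SVR: Σ max(0, |Y−RX|−ε) + c‖X‖².  LNR: ‖log1p(Y) − log1p(RX)‖²_F on the
    raw scale.
    """
    opts = opts or DeconvOptions()
    model = model.upper()
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}")
    E = R @ X - Y
    if model == "NNLS":
        return float((E**2).sum())
    if model == "DWLS":
        if gene_weights is None:
            gene_weights = _dwls_weights(R, _per_spot_nnls(R, Y), opts)
        return float((gene_weights[:, None] * E**2).sum())
    if model == "SVR":
        hinge = np.clip(np.abs(E) - opts.svr_epsilon, 0.0, None)
        return float(hinge.sum() + opts.svr_ridge * (X**2).sum())
    # LNR
    Elog = np.log1p(np.clip(R @ X, 0.0, None)) - np.log1p(Y)
    return float((Elog**2).sum())


def _loss_and_grad(
    Y: np.ndarray,
    R: np.ndarray,
    X: np.ndarray,
    model: str,
    opts: DeconvOptions,
    gene_weights: np.ndarray | None,
) -> tuple[float, np.ndarray]:
    RX = R @ X
    if model == "NNLS":
        E = RX - Y
        return float((E**2).sum()), 2.0 * R.T @ E
    if model == "DWLS":
        E = RX - Y
        WE = gene_weights[:, None] * E
        return float((E * WE).sum()), 2.0 * R.T @ WE
    if model == "SVR":
        E = RX - Y
        hinge = np.abs(E) - opts.svr_epsilon
        active = hinge > 0
        loss = float(hinge[active].sum() + opts.svr_ridge * (X**2).sum())
        G = R.T @ (np.sign(E) * active) + 2.0 * opts.svr_ridge * X
        return loss, G
    # LNR (raw scale; RX clipped at 0 keeps log defined under roundoff)
    RXc = np.clip(RX, 0.0, None)
    E = np.log1p(RXc) - np.log1p(Y)
    loss = float((E**2).sum())
    G = 2.0 * R.T @ (E / (1.0 + RXc))
    return loss, G


def deconvolve(
    Y: OmicsMatrix,
    R: ReferenceSignature,
    model: str = "NNLS",
    prior: SpatialPrior | None = None,
    lambda_sp: float | None = None,
    opts: DeconvOptions | None = None,
) -> AbundanceMatrix:
    """Estimate non-negative cell-type abundances, optionally spatially aware.

    Minimizes ``L_model(Y, RX) + λ_sp Σ_c X_c Q X_cᵀ`` over X ≥ 0 by projected
    Adam (clamp at 0 each step) from a per-spot NNLS warm start, keeping the
    best iterate seen. ``lambda_sp=None`` uses the documented default for the
    model when a prior is given, else 0.

    Data and reference are intersected on shared genes; the caller supplies
    them on the model's expected scale (log1p for NNLS/DWLS/SVR, raw for LNR —
    a mismatch for LNR raises).
    """
    model = model.upper()
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}")
    opts = opts or DeconvOptions()
    if lambda_sp is None:
        lambda_sp = default_lambda(model) if prior is not None else 0.0
    if lambda_sp < 0:
        raise ValueError("lambda_sp must be >= 0")
    if lambda_sp > 0 and prior is None:
        raise ValueError("lambda_sp > 0 requires a spatial prior")
    if model == "LNR" and Y.scale_tag != "raw":
        raise ValueError("LNR expects raw-scale data (scale_tag='raw')")
    if Y.scale_tag != R.scale_tag:
        raise ValueError(
            f"data scale {Y.scale_tag!r} does not match reference scale {R.scale_tag!r}"
        )
    if prior is not None and prior.n_spots != len(Y.spot_ids):
        raise ValueError("prior does not cover the data's spots")

    Yv, Rv = _intersect(Y, R)
    C = len(R.cell_types)
    if C == 1:
        # single cell type: proportions are forced to 1 regardless of model
        X = np.clip(_per_spot_nnls(Rv, Yv), 0.0, None)
        return AbundanceMatrix(X, [*R.cell_types], [*Y.spot_ids])

    X = _per_spot_nnls(Rv, Yv)
    gene_weights = _dwls_weights(Rv, X, opts) if model == "DWLS" else None

    def objective(Xc: np.ndarray) -> tuple[float, np.ndarray]:
        loss, G = _loss_and_grad(Yv, Rv, Xc, model, opts, gene_weights)
        if lambda_sp > 0:
            QXt = prior.apply_Q(Xc)  # (S, C)
            loss += lambda_sp * float(np.einsum("cs,sc->", Xc, QXt))
            G = G + 2.0 * lambda_sp * QXt.T
        return loss, G

    # projected Adam, best-iterate tracking
    m = np.zeros_like(X)
    v = np.zeros_like(X)
    b1, b2, eps = 0.9, 0.999, 1e-8
    loss, G = objective(X)
    best_loss, best_X = loss, X.copy()
    prev, stall = loss, 0
    for t in range(1, opts.max_iter + 1):
        m = b1 * m + (1 - b1) * G
        v = b2 * v + (1 - b2) * G**2
        mhat = m / (1 - b1**t)
        vhat = v / (1 - b2**t)
        X = np.clip(X - opts.lr * mhat / (np.sqrt(vhat) + eps), 0.0, None)
        loss, G = objective(X)
        if loss < best_loss:
            best_loss, best_X = loss, X.copy()
        denom = max(abs(prev), 1e-30)
        stall = stall + 1 if abs(prev - loss) / denom < opts.rtol else 0
        prev = loss
        if stall >= opts.patience:
            break

    return AbundanceMatrix(best_X, [*R.cell_types], [*Y.spot_ids])


def select_marker_genes(
    profiles: np.ndarray,
    gene_ids: list[str],
    labels: np.ndarray | list,
    top_n: int = 20,
    log_scale_reference: bool = True,
) -> tuple[list[str], ReferenceSignature]:
    """Rank one-vs-rest markers and build the reference signature.

    ``profiles`` is a genes × cells raw count matrix with one cell-type label
    per cell. Cells are library-size normalized to the median total; genes are
    ranked per type by one-vs-rest log2 fold change of the mean normalized
    expression; the union of the top ``top_n`` per type defines the marker
    set. The signature is the per-type mean normalized expression restricted
    to that union, log1p-transformed when the downstream model expects
    log-scale inputs.
    """
    profiles = np.asarray(profiles, dtype=float)
    labels = np.asarray(labels)
    types = sorted(set(labels.tolist()))
    if len(types) < 2:
        raise ValueError("need at least 2 cell types to rank markers")
    if top_n <= 0:
        raise ValueError("top_n must be positive")
    G = profiles.shape[0]
    if top_n > G:
        warnings.warn(f"top_n={top_n} exceeds gene count {G}; using all genes", stacklevel=2)
        top_n = G

    tot = profiles.sum(axis=0)
    target = np.median(tot[tot > 0]) if np.any(tot > 0) else 1.0
    norm = profiles / np.where(tot > 0, tot, 1.0)[None, :] * target

    means = np.stack([norm[:, labels == t].mean(axis=1) for t in types], axis=1)  # G × T
    pseudo = 1e-9
    union: set[int] = set()
    per_type_rank: dict[str, np.ndarray] = {}
    for j, t in enumerate(types):
        rest = (means.sum(axis=1) - means[:, j]) / (len(types) - 1)
        lfc = np.log2(means[:, j] + pseudo) - np.log2(rest + pseudo)
        order = np.lexsort((np.arange(G), -lfc))
        per_type_rank[t] = order
        union.update(order[:top_n].tolist())

    rows = sorted(union)
    genes = [gene_ids[i] for i in rows]
    sig = means[rows]
    tag = "raw"
    if log_scale_reference:
        sig = np.log1p(sig)
        tag = "log1p"
    return genes, ReferenceSignature(sig, genes, [str(t) for t in types], tag)
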