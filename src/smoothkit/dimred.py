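"""Spatially regularized dimensionality reduction.

Two concrete models plus a generic loss-attachment contract:

- ``spatial_pca``: a linear autoencoder with symmetric (tied) encoder/decoder
  W, soft orthogonality on WWᵀ, and the spatial loss on every latent
  dimension of Z = WY. With λ_sp=0 this reduces to classical PCA.
- ``regularized_autoencoder``: a small fully connected autoencoder
  (G → 128 → H → 128 → G) with batch normalization and ELU activations,
  trained with reconstruction + spatial (or contrastive) loss on the latent
  rows + an orthogonality penalty on the latent Gram matrix that discourages
  embedding collapse.
- ``attach_spatial_loss``: wraps any objective that exposes the embedding it
  induces on spatial spots, returning the joint objective
  L_m + λ_sp·L_sp(embedding). Non-spatial samples contribute nothing to the
  spatial term, so the same model can train jointly on spatial and
  non-spatial data.

All optimizers are plain numpy gradient methods; runs are deterministic given
the seed (single-threaded).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.utils.extmath import randomized_svd

from .prior import SpatialPrior, contrastive_spatial_loss, spatial_loss

__all__ = [
    "LatentEmbedding",
    "spatial_pca",
    "attach_spatial_loss",
    "regularized_autoencoder",
]


@dataclass
class LatentEmbedding:
    """Hidden-dims × spots embedding Z plus a description of the map."""

    Z: np.ndarray
    loadings: np.ndarray | None = None  # encoder weights where applicable
    history: list = field(default_factory=list, repr=False)
    collapsed: bool = False

    @property
    def n_components(self) -> int:
        return self.Z.shape[0]


# --------------------------------------------------------------------------
# spatial PCA
# --------------------------------------------------------------------------

def _pca_objective(
    W: np.ndarray,
    Y: np.ndarray,
    prior: SpatialPrior | None,
    lambda_sp: float,
    lambda_orth: float,
) -> tuple[float, np.ndarray]:
    """Loss and gradient for ‖Y−WᵀWY‖² + λ_sp Σ_h L_sp(Z_h) + λ_orth‖WWᵀ−I‖²."""
    Z = W @ Y
    E = W.T @ Z - Y  # reconstruction residual, G × S
    loss = float((E**2).sum())
    G = 2.0 * W @ (Y @ E.T + E @ Y.T)
    if lambda_sp > 0 and prior is not None:
        QZt = prior.apply_Q(Z)  # S × H
        loss += lambda_sp * float(np.einsum("hs,sh->", Z, QZt))
        G += 2.0 * lambda_sp * (QZt.T @ Y.T)
    if lambda_orth > 0:
        D = W @ W.T - np.eye(W.shape[0])
        loss += lambda_orth * float((D**2).sum())
        G += 4.0 * lambda_orth * (D @ W)
    return loss, G


def spatial_pca(
    Y: np.ndarray,
    n_components: int,
    prior: SpatialPrior | None = None,
    lambda_sp: float = 0.0,
    lambda_orth: float = 10.0,
    seed: int = 0,
    max_iter: int = 1000,
    lr: float = 1e-3,
    optimizer: str = "adam",
) -> LatentEmbedding:
    """PCA with the spatial loss on every latent dimension.

    ``Y`` is genes × spots; rows are centered internally. The encoder W
    (H × G) is initialized from a seeded randomized SVD of the centered data
    and refined by gradient descent on the joint objective, so at λ_sp=0 the
    solution coincides with the top-H PCA subspace. ``lambda_orth`` keeps
    WWᵀ ≈ I (soft orthogonality).
    """
    Y = np.asarray(Y, dtype=float)
    Gn, S = Y.shape
    H = int(n_components)
    if H < 1 or H > min(Gn, S):
        raise ValueError(f"n_components must be in [1, {min(Gn, S)}]")
    if lambda_sp > 0 and prior is None:
        raise ValueError("lambda_sp > 0 requires a spatial prior")
    if prior is not None and prior.n_spots != S:
        raise ValueError("prior does not cover the data's spots")

    Yc = Y - Y.mean(axis=1, keepdims=True)
    if min(Gn, S) <= 512:
        U = np.linalg.svd(Yc, full_matrices=False)[0][:, :H]
    else:
        U, _, _ = randomized_svd(Yc, n_components=H, n_iter=25, random_state=seed)
    W = U.T  # H × G, orthonormal rows

    m = np.zeros_like(W)
    v = np.zeros_like(W)
    b1, b2, eps = 0.9, 0.999, 1e-8
    history = []
    loss, Grad = _pca_objective(W, Yc, prior, lambda_sp, lambda_orth)
    best_loss, best_W = loss, W.copy()
    # accept a new best only on a real improvement, so roundoff-level drift
    # along the flat optimum manifold cannot rotate an already-optimal start
    improve_tol = 1e-9 * max(abs(loss), 1e-30)
    prev, stall = loss, 0
    for t in range(1, max_iter + 1):
        if optimizer == "adam":
            m = b1 * m + (1 - b1) * Grad
            v = b2 * v + (1 - b2) * Grad**2
            step = lr * (m / (1 - b1**t)) / (np.sqrt(v / (1 - b2**t)) + eps)
        else:  # plain (full-batch) sgd
            step = lr * Grad
        W = W - step
        loss, Grad = _pca_objective(W, Yc, prior, lambda_sp, lambda_orth)
        history.append(loss)
        if loss < best_loss - improve_tol:
            best_loss, best_W = loss, W.copy()
        denom = max(abs(prev), 1e-30)
        stall = stall + 1 if abs(prev - loss) / denom < 1e-7 else 0
        prev = loss
        if stall >= 20:
            break

    W = best_W
    return LatentEmbedding(Z=W @ Yc, loadings=W, history=history)


# --------------------------------------------------------------------------
# loss attachment contract
# --------------------------------------------------------------------------

def attach_spatial_loss(
    model_loss: Callable[..., float],
    embedding_fn: Callable[..., np.ndarray],
    prior: SpatialPrior,
    lambda_sp: float,
    spatial_index: np.ndarray | None = None,
    contrastive: bool = False,
    n_negatives: int = 20,
    neg_weight: float = 0.05,
    seed: int = 0,
) -> Callable[..., float]:
    """Convert any objective into a spatially aware one.

    ``embedding_fn(*params)`` must return the hidden-dims × samples embedding
    induced by the parameters. ``spatial_index`` selects the columns that
    correspond to spots with coordinates (default: all columns); non-spatial
    samples contribute zero spatial loss, so mixed batches are supported.

    Returns a callable ``joint(*params) = model_loss(*params) +
    λ_sp·L_sp(Z[:, spatial_index])`` (contrastive variant optional). At
    λ_sp=0 the joint objective equals the wrapped one exactly.
    """
    if spatial_index is not None:
        spatial_index = np.asarray(spatial_index, dtype=int)
        if spatial_index.size != prior.n_spots:
            raise ValueError(
                f"spatial_index selects {spatial_index.size} columns "
                f"but the prior covers {prior.n_spots} spots"
            )

    def joint(*params) -> float:
        base = model_loss(*params)
        if lambda_sp == 0.0:
            return base
        Z = np.atleast_2d(np.asarray(embedding_fn(*params), dtype=float))
        Zs = Z if spatial_index is None else Z[:, spatial_index]
        if Zs.shape[1] != prior.n_spots:
            raise ValueError(
                f"embedding has {Zs.shape[1]} spatial columns "
                f"but the prior covers {prior.n_spots} spots"
            )
        if contrastive:
            sp_term = contrastive_spatial_loss(
                Zs, prior, n_negatives=n_negatives, neg_weight=neg_weight, seed=seed
            )
        else:
            sp_term = spatial_loss(Zs, prior)
        return base + lambda_sp * sp_term

    return joint


# --------------------------------------------------------------------------
# deep autoencoder (numpy, manual backprop)
# --------------------------------------------------------------------------

def _elu(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, x, np.expm1(np.clip(x, None, 30.0)))


def _elu_grad(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.where(x > 0, 1.0, y + 1.0)


class _Linear:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        lim = np.sqrt(6.0 / (d_in + d_out))
        self.W = rng.uniform(-lim, lim, size=(d_out, d_in))
        self.b = np.zeros((d_out, 1))
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self.x = x
        return self.W @ x + self.b

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.gW = g @ self.x.T
        self.gb = g.sum(axis=1, keepdims=True)
        return self.W.T @ g

    def params(self):
        return [(self.W, self.gW), (self.b, self.gb)]


class _BatchNorm:
    """Full-batch normalization over samples (columns), with learnable γ, β."""

    def __init__(self, d: int, eps: float = 1e-5):
        self.g = np.ones((d, 1))
        self.b = np.zeros((d, 1))
        self.gg = np.zeros_like(self.g)
        self.gb = np.zeros_like(self.b)
        self.eps = eps

    def forward(self, x: np.ndarray) -> np.ndarray:
        self.mu = x.mean(axis=1, keepdims=True)
        self.var = x.var(axis=1, keepdims=True)
        self.istd = 1.0 / np.sqrt(self.var + self.eps)
        self.xhat = (x - self.mu) * self.istd
        return self.g * self.xhat + self.b

    def backward(self, gout: np.ndarray) -> np.ndarray:
        N = gout.shape[1]
        self.gg = (gout * self.xhat).sum(axis=1, keepdims=True)
        self.gb = gout.sum(axis=1, keepdims=True)
        gxhat = gout * self.g
        return (
            self.istd
            / N
            * (
                N * gxhat
                - gxhat.sum(axis=1, keepdims=True)
                - self.xhat * (gxhat * self.xhat).sum(axis=1, keepdims=True)
            )
        )

    def params(self):
        return [(self.g, self.gg), (self.b, self.gb)]


class _ELU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self.x = x
        self.y = _elu(x)
        return self.y

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g * _elu_grad(self.x, self.y)

    def params(self):
        return []


class _MLPAutoencoder:
    """Encoder G→…→H and mirrored decoder, batchnorm + ELU between layers."""

    def __init__(self, d_in: int, hidden: Sequence[int], rng: np.random.Generator):
        dims = [d_in, *hidden]
        self.encoder, self.decoder = [], []
        for i in range(len(dims) - 1):
            self.encoder.append(_Linear(dims[i], dims[i + 1], rng))
            if i < len(dims) - 2:
                self.encoder.append(_BatchNorm(dims[i + 1]))
                self.encoder.append(_ELU())
        rdims = dims[::-1]
        for i in range(len(rdims) - 1):
            self.decoder.append(_Linear(rdims[i], rdims[i + 1], rng))
            if i < len(rdims) - 2:
                self.decoder.append(_BatchNorm(rdims[i + 1]))
                self.decoder.append(_ELU())

    def encode(self, Y: np.ndarray) -> np.ndarray:
        h = Y
        for layer in self.encoder:
            h = layer.forward(h)
        return h

    def decode(self, Z: np.ndarray) -> np.ndarray:
        h = Z
        for layer in self.decoder:
            h = layer.forward(h)
        return h

    def backward(self, g_recon: np.ndarray, g_latent: np.ndarray) -> None:
        g = g_recon
        for layer in reversed(self.decoder):
            g = layer.backward(g)
        g = g + g_latent
        for layer in reversed(self.encoder):
            g = layer.backward(g)

    def params(self):
        out = []
        for layer in [*self.encoder, *self.decoder]:
            out.extend(layer.params())
        return out


def regularized_autoencoder(
    Y: np.ndarray,
    hidden: Sequence[int] = (128, 30),
    prior: SpatialPrior | None = None,
    lambda_sp: float = 0.0,
    lambda_orth: float = 1.0,
    contrastive: bool = False,
    n_negatives: int = 20,
    neg_weight: float = 0.05,
    seed: int = 0,
    epochs: int = 100,
    lr: float = 1e-3,
    collapse_ratio: float = 0.01,
) -> LatentEmbedding:
    """Train the fully connected autoencoder with spatial regularization.

    Loss = mean squared reconstruction + λ_sp · (spatial or contrastive loss
    over latent rows, normalized per spot) + λ_orth · ‖Z̄Z̄ᵀ/S − I‖²_F where Z̄
    is the latent matrix. The collapse monitor flags runs whose mean latent
    row standard deviation falls below ``collapse_ratio`` times its value at
    initialization — the failure mode the contrastive loss is designed to
    avert.

    Deterministic given ``seed`` under single-threaded numpy.
    """
    Y = np.asarray(Y, dtype=float)
    Gn, S = Y.shape
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    if lambda_sp > 0 and prior is None:
        raise ValueError("lambda_sp > 0 requires a spatial prior")
    if prior is not None and prior.n_spots != S:
        raise ValueError("prior does not cover the data's spots")

    rng = np.random.default_rng(seed)
    net = _MLPAutoencoder(Gn, hidden, rng)
    H = hidden[-1]

    # fixed permutations for the contrastive negatives (seeded once)
    perms = [rng.permutation(S) for _ in range(n_negatives)] if contrastive else []

    # Adam state
    params = net.params()
    mstate = [np.zeros_like(p) for p, _ in params]
    vstate = [np.zeros_like(p) for p, _ in params]
    b1, b2, eps = 0.9, 0.999, 1e-8

    Z0 = net.encode(Y)
    init_scale = float(Z0.std(axis=1).mean())
    history = []

    for t in range(1, epochs + 1):
        Z = net.encode(Y)
        Yhat = net.decode(Z)
        E = Yhat - Y
        recon = float((E**2).sum()) / S
        g_recon = 2.0 * E / S

        loss = recon
        g_latent = np.zeros_like(Z)
        if lambda_sp > 0:
            if contrastive:
                sp_val = spatial_loss(Z, prior)
                gq = prior.apply_Q(Z).T  # H × S
                for perm in perms:
                    Zp = Z[:, perm]
                    sp_val -= neg_weight / n_negatives * spatial_loss(Zp, prior)
                    gp = prior.apply_Q(Zp).T
                    inv = np.empty_like(perm)
                    inv[perm] = np.arange(S)
                    gq -= neg_weight / n_negatives * gp[:, inv]
            else:
                sp_val = spatial_loss(Z, prior)
                gq = prior.apply_Q(Z).T
            loss += lambda_sp * sp_val / S
            g_latent += 2.0 * lambda_sp * gq / S
        if lambda_orth > 0:
            Gram = Z @ Z.T / S - np.eye(H)
            loss += lambda_orth * float((Gram**2).sum())
            g_latent += lambda_orth * 4.0 / S * (Gram @ Z)

        if not np.isfinite(loss):
            raise FloatingPointError(
                f"non-finite loss at epoch {t} (recon={recon:.3g}); "
                "reduce lr or rescale the input"
            )
        history.append(loss)

        net.backward(g_recon, g_latent)
        params = net.params()
        for i, (p, g) in enumerate(params):
            mstate[i] = b1 * mstate[i] + (1 - b1) * g
            vstate[i] = b2 * vstate[i] + (1 - b2) * g**2
            p -= lr * (mstate[i] / (1 - b1**t)) / (np.sqrt(vstate[i] / (1 - b2**t)) + eps)

    Z = net.encode(Y)
    scale = float(Z.std(axis=1).mean())
    collapsed = bool(init_scale > 0 and scale < collapse_ratio * init_scale)
    return LatentEmbedding(Z=Z, loadings=None, history=history, collapsed=collapsed)
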