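"""Benchmark metrics for deconvolution and embeddings, plus a PC helper.

Deconvolution accuracy is scored per cell type across spots on proportions:
mean squared error, Pearson correlation, and average precision of the binary
presence call (truth proportion ≥ 0.05). Embeddings are scored by silhouette
against known labels and by adjusted Rand index after clustering into the
true number of groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import adjusted_rand_score, average_precision_score, silhouette_score

from .deconv import AbundanceMatrix, OmicsMatrix
from .graph import BoundaryFeatures

__all__ = ["DeconvEvalReport", "eval_deconv", "eval_embedding", "reduce_features"]

PRESENCE_THRESHOLD = 0.05


@dataclass
class DeconvEvalReport:
    """Per-cell-type scores with aggregation helpers."""

    per_type: pd.DataFrame  # index: cell type; columns: mse, pearson, ap
    n_pearson_excluded: int = 0

    def mean(self) -> pd.Series:
        return self.per_type.mean(skipna=True)

    def sem(self) -> pd.Series:
        return self.per_type.sem(skipna=True)


def eval_deconv(
    X_hat: AbundanceMatrix,
    X_true: AbundanceMatrix,
    presence_threshold: float = PRESENCE_THRESHOLD,
) -> DeconvEvalReport:
    """Score estimated against true proportions, one row per cell type.

    Average precision uses the predicted proportion as the score against the
    binary truth (proportion ≥ threshold); cell types never present in the
    truth get AP = NaN and are excluded from aggregation. Constant
    predictions make Pearson undefined — flagged NaN and counted.
    """
    if X_hat.cell_types != X_true.cell_types:
        raise ValueError("cell types not aligned")
    if X_hat.spot_ids != X_true.spot_ids:
        raise ValueError("spots not aligned")
    P_hat = X_hat.proportions()
    P_true = X_true.proportions()

    rows = []
    excluded = 0
    for i, ct in enumerate(X_hat.cell_types):
        p, t = P_hat[i], P_true[i]
        mse = float(((p - t) ** 2).mean())
        if p.std() == 0 or t.std() == 0:
            pearson = np.nan
            excluded += 1
        else:
            pearson = float(np.corrcoef(p, t)[0, 1])
        present = t >= presence_threshold
        ap = float(average_precision_score(present, p)) if present.any() else np.nan
        rows.append({"cell_type": ct, "mse": mse, "pearson": pearson, "ap": ap})
    df = pd.DataFrame(rows).set_index("cell_type")
    return DeconvEvalReport(df, n_pearson_excluded=excluded)


def eval_embedding(
    Z: np.ndarray, labels: np.ndarray | list, seed: int = 0
) -> tuple[float, float]:
    """(silhouette, ARI) of an embedding against known group labels.

    ``Z`` is hidden-dims × spots. ARI compares the labels with a seeded
    k-means clustering (10 restarts) into the true number of groups.
    """
    Z = np.asarray(Z, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("need at least 2 label classes")
    X = Z.T  # samples × features
    sil = float(silhouette_score(X, labels))
    km = KMeans(n_clusters=classes.size, n_init=10, random_state=seed).fit(X)
    ari = float(adjusted_rand_score(labels, km.labels_))
    return sil, ari


def reduce_features(
    Y: OmicsMatrix, n_pcs: int = 10, normalize: bool = True, mode: str = "soft_expression"
) -> BoundaryFeatures:
    """Top principal-component scores per spot, for boundary-aware scaling.

    With ``normalize`` the counts are library-size normalized to the median
    total and log1p-transformed first; genes are then centered and the top
    ``n_pcs`` PC scores of the spots returned (default 10, the convention for
    transcriptomic soft scaling).
    """
    V = np.asarray(Y.values, dtype=float)
    G, S = V.shape
    if n_pcs > min(G, S):
        raise ValueError(f"n_pcs must be <= min(n_genes, n_spots) = {min(G, S)}")
    if not V.any():
        raise ValueError("all-zero matrix has no principal components")
    if normalize:
        tot = V.sum(axis=0)
        target = np.median(tot[tot > 0])
        V = V / np.where(tot > 0, tot, 1.0)[None, :] * target
        V = np.log1p(V)
    V = V - V.mean(axis=1, keepdims=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sklearn chatter on tiny inputs
        scores = PCA(n_components=n_pcs, svd_solver="full").fit_transform(V.T)
    return BoundaryFeatures(scores, mode)
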