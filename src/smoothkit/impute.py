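"""MAP smoothing, imputation at masked spots, and resolution enhancement.

The observation model is a hidden Markov random field: y_s ~ N(x_s, σ₀²) at
observed spots, with the latent field x drawn from the zero-centered MVN
spatial prior. The MAP estimate solves the Tikhonov problem

    min_x  ‖M(y − x)‖² + λ_sp xᵀQx,

a sparse symmetric linear system (M + λ_sp Q)x = My where M = diag(mask).
Because Q is defined independently of the observations, the same solve imputes
x at arbitrary unobserved locations; resolution enhancement inserts new spots
at graph-edge midpoints and imputes them with the original spots held fixed.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .graph import SpatialGraph, SpotCoordinates, build_knn_graph
from .prior import DEFAULT_PROCESS, DEFAULT_RHO, SpatialPrior, build_prior

__all__ = ["smooth", "enhance_resolution"]

#: default regularization strength for smoothing/imputation
DEFAULT_LAMBDA_SP = 1.0


def _explicit_Q(prior: SpatialPrior) -> sp.csr_matrix:
    if prior.process != "SMA":
        return prior.precision
    # SMA precision is applied via solves elsewhere; the smoothing system
    # needs Q explicitly, so form it densely (SMA is only sensible at small n)
    return sp.csr_matrix(prior.dense_Q())


def smooth(
    y: np.ndarray,
    prior: SpatialPrior,
    lambda_sp: float = DEFAULT_LAMBDA_SP,
    mask: np.ndarray | None = None,
    fix_observed: bool = False,
) -> np.ndarray:
    """Tikhonov-regularized MAP estimate of a spatial variable.

    Parameters
    ----------
    y
        Observed values, shape ``(n_spots,)`` or ``(n_vars, n_spots)``.
        Entries at unobserved spots are ignored.
    prior
        Spatial prior supplying the sparse precision Q.
    lambda_sp
        Strength of the prior, ∝ σ₀²/σ₁². 0 returns y at observed spots.
    mask
        Boolean, True where observed. Default: all observed.
    fix_observed
        If True, observed entries are clamped to y and only the unobserved
        block is solved: Q_uu x_u = −Q_uo y_o (used for resolution
        enhancement).

    Returns
    -------
    The smoothed/imputed field, same shape as ``y``.
    """
    y = np.asarray(y, dtype=float)
    single = y.ndim == 1
    Y = np.atleast_2d(y)
    n = prior.n_spots
    if Y.shape[1] != n:
        raise ValueError(f"y has {Y.shape[1]} spots but prior covers {n}")
    if lambda_sp < 0 or not np.isfinite(lambda_sp):
        raise ValueError("lambda_sp must be finite and >= 0")
    if mask is None:
        mask = np.ones(n, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (n,):
        raise ValueError("mask must be boolean of length n_spots")
    if not np.all(np.isfinite(Y[:, mask])):
        raise ValueError("y must be finite at observed spots")

    Q = _explicit_Q(prior)

    if fix_observed:
        obs = np.flatnonzero(mask)
        unobs = np.flatnonzero(~mask)
        X = Y.copy()
        X[:, unobs] = 0.0
        if unobs.size:
            Quu = Q[unobs][:, unobs].tocsc()
            Quo = Q[unobs][:, obs]
            rhs = -(Quo @ Y[:, obs].T)
            # jitter guards components with no observed anchor
            lu = spla.splu(Quu + 1e-10 * sp.identity(unobs.size, format="csc"))
            X[:, unobs] = lu.solve(np.asarray(rhs)).T
        return X[0] if single else X

    if lambda_sp == 0:
        if not mask.all():
            raise ValueError(
                "lambda_sp=0 leaves unobserved spots undefined; "
                "use lambda_sp > 0 (or fix_observed=True) to impute them"
            )
        return y.copy()

    M = sp.diags(mask.astype(float))
    A = (M + lambda_sp * Q).tocsc()
    rhs = (M @ Y.T)
    lu = spla.splu(A + 1e-12 * sp.identity(n, format="csc"))
    X = lu.solve(np.asarray(rhs)).T
    # guard: solution should satisfy the normal equations tightly
    resid = np.linalg.norm(A @ X.T - rhs) / max(np.linalg.norm(rhs), 1e-30)
    if resid > 1e-8:
        raise RuntimeError(f"sparse solve did not converge (relative residual {resid:.2e})")
    return X[0] if single else X


def enhance_resolution(
    coords: SpotCoordinates,
    y: np.ndarray,
    factor: int = 2,
    k: int | None = None,
    process: str = DEFAULT_PROCESS,
    rho: float = 1.0,
    lambda_sp: float = DEFAULT_LAMBDA_SP,
    tol: float = 1e-9,
) -> tuple[SpotCoordinates, np.ndarray]:
    """Increase spatial resolution by midpoint interpolation.

    New spots are inserted at the midpoints of existing graph edges (repeated
    ``factor − 1`` times, coincident points merged within ``tol``); the graph
    and prior are rebuilt on the enlarged slide and the variable is imputed
    with all original values held fixed.

    ``rho`` defaults to 1 (the intrinsic prior) for interpolation: with
    ρ < 1 the zero-centered prior shrinks inserted values toward zero, while
    the intrinsic prior reproduces neighborhood averages and leaves constant
    fields constant.

    Returns the enlarged coordinates and the field on them; ``factor=1``
    returns the inputs unchanged.
    """
    if factor <= 0:
        raise ValueError("factor must be a positive integer")
    y = np.asarray(y, dtype=float)
    if factor == 1:
        return coords, y.copy()

    single = y.ndim == 1
    Y = np.atleast_2d(y)
    cur = coords
    observed = np.ones(cur.n_spots, dtype=bool)
    vals = Y

    for round_ in range(factor - 1):
        g = build_knn_graph(cur, k)
        coo = sp.triu(g.W, k=1).tocoo()
        mids = (cur.xy[coo.row] + cur.xy[coo.col]) / 2.0
        # deduplicate midpoints against themselves and existing spots
        key_exist = {tuple(np.round(p / tol).astype(np.int64)) for p in cur.xy}
        new_pts, seen = [], set()
        for p in mids:
            kk = tuple(np.round(p / tol).astype(np.int64))
            if kk in key_exist or kk in seen:
                continue
            seen.add(kk)
            new_pts.append(p)
        if not new_pts:
            break
        new_pts = np.asarray(new_pts)
        ids = [*cur.spot_ids] + [f"mid{round_}_{i}" for i in range(len(new_pts))]
        cur = SpotCoordinates(ids, np.vstack([cur.xy, new_pts]), cur.grid_hint)
        observed = np.r_[observed, np.zeros(len(new_pts), dtype=bool)]
        vals = np.hstack([vals, np.zeros((vals.shape[0], len(new_pts)))])

    g = build_knn_graph(cur, k)
    # jitter-free prior: the clamped solve only needs the unobserved block,
    # which observed anchors keep nonsingular even at rho=1
    pr = build_prior(g, process=process, rho=rho, jitter=0.0)
    out = smooth(vals, pr, lambda_sp=lambda_sp, mask=observed, fix_observed=True)
    out = np.atleast_2d(out)
    return cur, (out[0] if single else out)
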