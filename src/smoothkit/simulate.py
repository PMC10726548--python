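"""Ground-truthed synthetic spatial transcriptomics data.

The generator emulates a barcode-grid ST experiment: designated zone patterns
(doughnut-shaped compartments or uniform background) are overlaid with a 2-D
Gaussian process to produce per-type expected abundance fields; integer cell
counts are drawn Poisson from the fields; gene expression at each spot is the
sum of count vectors resampled from a (synthetic) single-cell reference
according to the drawn composition. Structured noise comes in two flavors:
lateral diffusion (spot bleeding — each spot shares a fraction p of its
counts equally among its first-degree rook neighbors, mass conserved) and
multiplicative per-gene gamma noise (default shape 0.4586, scale 1/0.6992).

A second pipeline mimics pooled single-cell ("sci-Space"-style) data: per-spot
cell counts follow a gamma-Poisson with mean 10, cells are resampled with
replacement from the spot's own pool or an adjacent pool with half
probability each, and deep spots are thinned to at most 5,000 UMI by
multivariate-hypergeometric downsampling.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .deconv import OmicsMatrix, ReferenceSignature

__all__ = [
    "SimConfig",
    "SimTruth",
    "doughnut_mask",
    "default_zone_masks",
    "simulate_abundance",
    "sample_expression",
    "apply_diffusion",
    "apply_gene_noise",
    "simulate_scispace",
    "synth_reference",
    "simulate_doughnut_dataset",
]

#: per-gene gamma noise defaults (multiplicative sampling error)
GAMMA_SHAPE = 0.4586
GAMMA_SCALE = 1.0 / 0.6992

#: density classes: mean cells per occupied spot
HIGH_DENSITY = 4.0
LOW_DENSITY = 0.4


@dataclass
class SimConfig:
    """Simulation settings; defaults are the benchmark conditions."""

    rows: int = 50
    cols: int = 50
    n_high: int = 5  # high-density cell types (4 cells/occupied spot)
    n_low: int = 10  # low-density cell types (0.4 cells/occupied spot)
    gp_lengthscale: float = 10.0  # grid units
    diffusion_rate: float = 0.0  # p in [0, 1): share of counts bled to neighbors
    gamma_shape: float = GAMMA_SHAPE
    gamma_scale: float = GAMMA_SCALE
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.diffusion_rate < 1):
            raise ValueError("diffusion_rate must be in [0, 1)")
        if self.gamma_shape <= 0 or self.gamma_scale <= 0:
            raise ValueError("gamma shape/scale must be > 0")
        if self.rows < 1 or self.cols < 1:
            raise ValueError("grid must be at least 1x1")

    @property
    def n_types(self) -> int:
        return self.n_high + self.n_low

    @property
    def n_spots(self) -> int:
        return self.rows * self.cols

    def grid_xy(self) -> np.ndarray:
        r, c = np.meshgrid(np.arange(self.rows), np.arange(self.cols), indexing="ij")
        return np.column_stack([c.ravel(), r.ravel()]).astype(float)

    def densities(self) -> np.ndarray:
        return np.r_[np.full(self.n_high, HIGH_DENSITY), np.full(self.n_low, LOW_DENSITY)]


@dataclass
class SimTruth:
    """Ground truth paired with the simulated count matrices."""

    cell_counts: np.ndarray  # types × spots, integer
    fields: np.ndarray | None = None  # types × spots expected abundance
    clean: np.ndarray | None = None  # genes × spots before noise
    noisy: np.ndarray | None = None  # genes × spots after diffusion/noise
    meta: dict = field(default_factory=dict)

    def proportions(self) -> np.ndarray:
        """Per-spot proportions of the realized cell draw (uniform at empty
        spots)."""
        tot = self.cell_counts.sum(axis=0)
        P = np.empty(self.cell_counts.shape, dtype=float)
        nz = tot > 0
        P[:, nz] = self.cell_counts[:, nz] / tot[nz]
        P[:, ~nz] = 1.0 / self.cell_counts.shape[0]
        return P

    def field_proportions(self) -> np.ndarray:
        """Per-spot proportions of the generative expected-abundance fields.

        This is the benchmark ground truth: the discrete per-spot cell draw
        on top of the fields is treated as sampling noise of the observation
        process, not as signal.
        """
        if self.fields is None:
            raise ValueError("no expected-abundance fields recorded")
        tot = self.fields.sum(axis=0)
        P = np.empty(self.fields.shape, dtype=float)
        nz = tot > 0
        P[:, nz] = self.fields[:, nz] / tot[nz]
        P[:, ~nz] = 1.0 / self.fields.shape[0]
        return P


def doughnut_mask(
    rows: int, cols: int, center: tuple[float, float], r_inner: float, r_outer: float
) -> np.ndarray:
    """Boolean ring mask (flattened row-major): r_inner ≤ dist < r_outer."""
    r, c = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    d = np.hypot(c - center[0], r - center[1])
    return ((d >= r_inner) & (d < r_outer)).ravel()


def default_zone_masks(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """One overlapping doughnut per cell type, randomly centered and sized.

    The exact geometry is parametrized rather than fixed: centers are drawn
    uniformly over the interior of the grid and radii scale with grid size,
    so rings of different types overlap. The union of the high-density
    types' patterns is patched to cover the whole grid (each uncovered spot
    joins the nearest high-density ring): the emulated benchmark slide is
    fully tissue-covered, and spots with no cells at all would be removed by
    quality control in any real pipeline.
    """
    n = config.n_types
    rows, cols = config.rows, config.cols
    scale = min(rows, cols)
    masks = np.zeros((n, config.n_spots), dtype=bool)
    ring = []  # (cx, cy, mid-radius) per type
    for t in range(n):
        for _ in range(100):
            cx = rng.uniform(0.2 * cols, 0.8 * cols)
            cy = rng.uniform(0.2 * rows, 0.8 * rows)
            r_out = rng.uniform(0.35 * scale, 0.6 * scale)
            r_in = r_out * rng.uniform(0.0, 0.5)
            m = doughnut_mask(rows, cols, (cx, cy), r_in, r_out)
            if m.sum() >= 5:
                masks[t] = m
                ring.append((cx, cy, (r_in + r_out) / 2))
                break
        else:  # pragma: no cover - 100 draws on any sane grid always succeed
            raise RuntimeError("could not draw a non-empty doughnut pattern")
    n_high = min(config.n_high, n) or n
    uncovered = ~masks[:n_high].any(axis=0)
    if uncovered.any():
        xy = config.grid_xy()
        for s in np.flatnonzero(uncovered):
            d = [
                abs(np.hypot(xy[s, 0] - cx, xy[s, 1] - cy) - rmid)
                for cx, cy, rmid in ring[:n_high]
            ]
            masks[int(np.argmin(d)), s] = True
    return masks


def _gp_field(xy: np.ndarray, lengthscale: float, rng: np.random.Generator) -> np.ndarray:
    """One draw of a zero-mean GP with RBF kernel on the grid coordinates."""
    if np.isinf(lengthscale):
        return np.zeros(xy.shape[0])
    d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1)
    K = np.exp(-d2 / (2.0 * lengthscale**2))
    K[np.diag_indices_from(K)] += 1e-8
    L = np.linalg.cholesky(K)
    return L @ rng.standard_normal(xy.shape[0])


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def simulate_abundance(
    config: SimConfig,
    masks: np.ndarray | None = None,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw expected-abundance fields and integer cell counts per type.

    Per zone: sample a GP field on the grid, pass through softplus, restrict
    to the zone's pattern mask, rescale so the mean over occupied (in-mask)
    spots equals the type's density target, then draw counts ~ Poisson(field).

    Returns (fields, counts), both types × spots; counts are integers ≥ 0.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    if masks is None:
        masks = default_zone_masks(config, rng)
    masks = np.asarray(masks, dtype=bool)
    if masks.shape != (config.n_types, config.n_spots):
        raise ValueError("masks must be (n_types, n_spots)")
    if np.any(masks.sum(axis=1) == 0):
        raise ValueError("empty pattern mask for at least one cell type")

    xy = config.grid_xy()
    dens = config.densities()
    fields = np.zeros((config.n_types, config.n_spots))
    for t in range(config.n_types):
        f = _softplus(_gp_field(xy, config.gp_lengthscale, rng))
        f = f * masks[t]
        mean_occ = f[masks[t]].mean()
        if mean_occ <= 0:  # constant-zero GP draw; fall back to flat density
            f = masks[t] * dens[t]
        else:
            f = f * (dens[t] / mean_occ)
        fields[t] = f
    counts = rng.poisson(fields)
    return fields, counts


def synth_reference(
    n_genes: int = 200,
    n_types: int = 15,
    markers_per_type: int = 10,
    cells_per_type: int = 50,
    seed: int = 0,
    fold_change: float = 4.0,
    nb_dispersion: float = 2.0,
    base_range: tuple[float, float] = (0.05, 0.5),
) -> tuple[np.ndarray, np.ndarray, ReferenceSignature]:
    """Synthetic labeled single-cell counts plus the averaged signature.

    Stands in for an external scRNA-seq reference so the whole toolkit runs
    offline. Each type up-regulates a disjoint block of ``markers_per_type``
    genes by ``fold_change`` (≥ 4) over a shared baseline; cells are drawn
    negative-binomially around the type means. The defaults mimic the
    sparsity of real droplet scRNA-seq: baseline per-gene means below one
    count per cell (``base_range``), moderate marker contrast, and strong
    overdispersion, so per-spot deconvolution stays realistically noisy
    rather than trivially easy.

    Returns (cells genes × n_cells, labels, signature on the raw scale).
    """
    if markers_per_type * n_types > n_genes:
        raise ValueError("marker allocation infeasible: markers_per_type * n_types > n_genes")
    if fold_change < 4.0:
        raise ValueError("marker fold change must be >= 4")
    rng = np.random.default_rng(seed)
    base = rng.uniform(base_range[0], base_range[1], size=n_genes)
    means = np.tile(base[:, None], (1, n_types))
    for t in range(n_types):
        block = slice(t * markers_per_type, (t + 1) * markers_per_type)
        means[block, t] *= fold_change

    labels = np.repeat(np.arange(n_types), cells_per_type)
    r = nb_dispersion
    p = r / (r + means)  # NB success prob per gene/type
    cells = np.empty((n_genes, n_types * cells_per_type), dtype=np.int64)
    for t in range(n_types):
        cols = slice(t * cells_per_type, (t + 1) * cells_per_type)
        cells[:, cols] = rng.negative_binomial(
            r, p[:, t][:, None], size=(n_genes, cells_per_type)
        )

    sig = np.stack([cells[:, labels == t].mean(axis=1) for t in range(n_types)], axis=1)
    gene_ids = [f"g{i}" for i in range(n_genes)]
    type_ids = [f"type{t}" for t in range(n_types)]
    ref = ReferenceSignature(sig, gene_ids, type_ids, "raw")
    return cells, np.array([f"type{t}" for t in labels]), ref


def sample_expression(
    cell_counts: np.ndarray,
    reference_cells: np.ndarray,
    reference_labels: np.ndarray,
    type_order: list[str],
    seed: int = 0,
) -> np.ndarray:
    """Sum per-spot expression of cells drawn uniformly from the reference.

    For each spot and type, the required number of cells is drawn with
    replacement from that type's reference cells; their count vectors are
    summed. Returns a genes × spots matrix.
    """
    rng = np.random.default_rng(seed)
    counts = np.asarray(cell_counts)
    G = reference_cells.shape[0]
    labels = np.asarray(reference_labels)
    pools = {}
    for t in type_order:
        idx = np.flatnonzero(labels == t)
        if idx.size == 0:
            raise ValueError(f"cell type {t!r} absent from the reference")
        pools[t] = idx
    Y = np.zeros((G, counts.shape[1]))
    for ti, t in enumerate(type_order):
        pool = pools[t]
        for s in np.flatnonzero(counts[ti] > 0):
            draws = rng.choice(pool, size=int(counts[ti, s]), replace=True)
            Y[:, s] += reference_cells[:, draws].sum(axis=1)
    return Y


def _rook_transition(rows: int, cols: int) -> np.ndarray:
    """Row-stochastic matrix T: T[i, j] = 1/deg(i) for rook neighbors j."""
    n = rows * cols
    T = np.zeros((n, n))
    for r in range(rows):
        for c in range(cols):
            i = r * cols + c
            nbrs = []
            if r > 0:
                nbrs.append((r - 1) * cols + c)
            if r < rows - 1:
                nbrs.append((r + 1) * cols + c)
            if c > 0:
                nbrs.append(r * cols + c - 1)
            if c < cols - 1:
                nbrs.append(r * cols + c + 1)
            for j in nbrs:
                T[i, j] = 1.0 / len(nbrs)
    return T


def apply_diffusion(Y: np.ndarray, rows: int, cols: int, p: float) -> np.ndarray:
    """Lateral diffusion (spot bleeding) on the simulation grid.

    Each spot keeps a 1−p fraction of its own counts and shares p equally
    among its first-degree (rook) neighbors; boundary spots split p among
    their existing neighbors, so total counts are conserved exactly.
    """
    if not (0 <= p < 1):
        raise ValueError("p must be in [0, 1)")
    Y = np.asarray(Y, dtype=float)
    if Y.shape[1] != rows * cols:
        raise ValueError("Y columns must match the grid size")
    if p == 0:
        return Y.copy()
    T = _rook_transition(rows, cols)
    return (1.0 - p) * Y + p * (Y @ T)


def apply_gene_noise(
    Y: np.ndarray,
    shape: float = GAMMA_SHAPE,
    scale: float = GAMMA_SCALE,
    seed: int = 0,
) -> np.ndarray:
    """Multiplicative per-gene gamma noise (one multiplier per gene)."""
    if shape <= 0 or scale <= 0:
        raise ValueError("shape and scale must be > 0")
    Y = np.asarray(Y, dtype=float)
    rng = np.random.default_rng(seed)
    mult = rng.gamma(shape, scale, size=Y.shape[0])
    return Y * mult[:, None]


def simulate_scispace(
    reference_cells: np.ndarray,
    reference_labels: np.ndarray,
    spot_of_cell: np.ndarray,
    rows: int,
    cols: int,
    mean_cells: float = 10.0,
    dispersion: float = 2.0,
    max_umi: int = 5000,
    seed: int = 0,
) -> tuple[np.ndarray, SimTruth]:
    """Pool-and-resample simulation of barcoded single-cell ("sci-Space") data.

    Cells carry an approximate spot assignment (``spot_of_cell``). Per spot,
    a target cell count is drawn from a gamma-Poisson (negative binomial,
    mean ``mean_cells``, gamma shape ``dispersion``); cells are then resampled
    with replacement, choosing the spot's own pool or a uniformly chosen
    adjacent (rook) pool with probability ½ each. Spots whose summed profile
    exceeds ``max_umi`` total counts are thinned to exactly ``max_umi`` by
    multivariate-hypergeometric downsampling, which preserves relative gene
    proportions in expectation.

    Returns (genes × spots counts, truth with realized per-type cell counts).
    """
    rng = np.random.default_rng(seed)
    n_spots = rows * cols
    labels = np.asarray(reference_labels)
    types = sorted(set(labels.tolist()))
    tindex = {t: i for i, t in enumerate(types)}
    G = reference_cells.shape[0]

    pools = [np.flatnonzero(spot_of_cell == s) for s in range(n_spots)]
    nbrs = []
    for r in range(rows):
        for c in range(cols):
            nb = []
            if r > 0:
                nb.append((r - 1) * cols + c)
            if r < rows - 1:
                nb.append((r + 1) * cols + c)
            if c > 0:
                nb.append(r * cols + c - 1)
            if c < cols - 1:
                nb.append(r * cols + c + 1)
            nbrs.append(nb)

    lam = rng.gamma(dispersion, mean_cells / dispersion, size=n_spots)
    n_cells = rng.poisson(lam)

    Y = np.zeros((G, n_spots))
    type_counts = np.zeros((len(types), n_spots), dtype=np.int64)
    n_empty = 0
    for s in range(n_spots):
        for _ in range(int(n_cells[s])):
            if rng.random() < 0.5 or not nbrs[s]:
                pool = pools[s]
                if pool.size == 0:  # fall back to a neighbor pool
                    cand = [p_ for j in nbrs[s] if (p_ := pools[j]).size]
                    pool = cand[rng.integers(len(cand))] if cand else pool
            else:
                j = nbrs[s][rng.integers(len(nbrs[s]))]
                pool = pools[j] if pools[j].size else pools[s]
            if pool.size == 0:
                n_empty += 1
                continue
            cell = int(rng.choice(pool))
            Y[:, s] += reference_cells[:, cell]
            type_counts[tindex[labels[cell]], s] += 1
    if n_empty:
        warnings.warn(
            f"{n_empty} draw(s) hit spots with empty own and neighbor pools; "
            "affected columns stay (partially) zero",
            stacklevel=2,
        )

    # down-sample deep spots to exactly max_umi total counts
    for s in range(n_spots):
        tot = int(Y[:, s].sum())
        if tot > max_umi:
            Y[:, s] = rng.multivariate_hypergeometric(Y[:, s].astype(np.int64), max_umi)

    truth = SimTruth(
        cell_counts=type_counts,
        fields=None,
        noisy=Y,
        meta={
            "types": types,
            "mean_cells": mean_cells,
            "dispersion": dispersion,
            "max_umi": max_umi,
            "realized_cells_per_spot": n_cells,
        },
    )
    return Y, truth


def simulate_doughnut_dataset(
    config: SimConfig,
    n_genes: int = 150,
    markers_per_type: int = 4,
    cells_per_type: int = 80,
    apply_noise: bool = True,
) -> tuple[OmicsMatrix, SimTruth, ReferenceSignature, np.ndarray, np.ndarray]:
    """End-to-end doughnut benchmark dataset from a synthetic reference.

    Convenience composition of the individual steps: synthetic reference →
    zone patterns × GP abundance → Poisson counts → expression sampling →
    lateral diffusion → per-gene gamma noise. The reference is split in half:
    one half simulates the ST data, the other builds the deconvolution
    signature, so the signature is estimated from held-out cells.

    Returns (noisy counts, truth, held-out signature, reference cells,
    reference labels).
    """
    rng = np.random.default_rng(config.seed)
    cells, labels, _ = synth_reference(
        n_genes=n_genes,
        n_types=config.n_types,
        markers_per_type=markers_per_type,
        cells_per_type=2 * cells_per_type,
        seed=config.seed,
    )
    # split: even cells simulate, odd cells form the reference signature
    sim_idx = np.flatnonzero(np.arange(cells.shape[1]) % 2 == 0)
    ref_idx = np.flatnonzero(np.arange(cells.shape[1]) % 2 == 1)
    types = sorted(set(labels.tolist()))
    sig = np.stack(
        [cells[:, ref_idx][:, labels[ref_idx] == t].mean(axis=1) for t in types], axis=1
    )
    gene_ids = [f"g{i}" for i in range(n_genes)]
    ref = ReferenceSignature(sig, gene_ids, types, "raw")

    fields, counts = simulate_abundance(config, seed=int(rng.integers(2**31 - 1)))
    clean = sample_expression(
        counts, cells[:, sim_idx], labels[sim_idx], types, seed=int(rng.integers(2**31 - 1))
    )
    noisy = clean
    if config.diffusion_rate > 0:
        noisy = apply_diffusion(noisy, config.rows, config.cols, config.diffusion_rate)
    if apply_noise:
        noisy = apply_gene_noise(
            noisy, config.gamma_shape, config.gamma_scale, seed=int(rng.integers(2**31 - 1))
        )
    spot_ids = [f"s{i}" for i in range(config.n_spots)]
    Y = OmicsMatrix(noisy, gene_ids, spot_ids, "raw")
    truth = SimTruth(
        cell_counts=counts,
        fields=fields,
        clean=clean,
        noisy=noisy,
        meta={"config": config, "types": types},
    )
    return Y, truth, ref, cells, labels
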