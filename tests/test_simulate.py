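"""The spatial transcriptomics simulator: patterns, noise, and conservation."""

import numpy as np
import pytest
from scipy import stats

from smoothkit import (
    SimConfig,
    apply_diffusion,
    apply_gene_noise,
    doughnut_mask,
    sample_expression,
    select_marker_genes,
    simulate_abundance,
    simulate_doughnut_dataset,
    simulate_scispace,
    synth_reference,
)
from smoothkit.simulate import GAMMA_SCALE, GAMMA_SHAPE, default_zone_masks


class TestSimulateAbundance:
    def test_masked_out_type_has_zero_counts(self):
        cfg = SimConfig(rows=8, cols=8, n_high=1, n_low=1, seed=0)
        masks = np.ones((2, 64), bool)
        masks[1] = False
        with pytest.raises(ValueError, match="empty pattern"):
            simulate_abundance(cfg, masks=masks)
        # a type masked to a sub-region stays zero outside it
        masks[1, :4] = True
        fields, counts = simulate_abundance(cfg, masks=masks)
        assert counts[1, 4:].sum() == 0

    def test_high_density_mean_in_band(self):
        """Mean cells per occupied spot for high-density types ≈ 4 (10 seeds)."""
        cfg = SimConfig(rows=50, cols=50, n_high=5, n_low=10)
        vals = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            masks = default_zone_masks(cfg, rng)
            fields, counts = simulate_abundance(cfg, masks=masks, seed=seed)
            for t in range(cfg.n_high):
                vals.append(counts[t][masks[t]].mean())
        assert 3.6 <= np.mean(vals) <= 4.4

    def test_infinite_lengthscale_gives_iid_poisson(self):
        cfg = SimConfig(rows=30, cols=30, n_high=1, n_low=0, gp_lengthscale=np.inf, seed=1)
        masks = np.ones((1, 900), bool)
        _, counts = simulate_abundance(cfg, masks=masks)
        x = counts[0]
        # Poisson: variance ≈ mean
        assert x.var() / x.mean() == pytest.approx(1.0, abs=0.25)
        assert x.mean() == pytest.approx(4.0, abs=0.3)

    def test_coverage_patch_by_high_density_union(self):
        cfg = SimConfig(rows=20, cols=20, n_high=2, n_low=3, seed=4)
        masks = default_zone_masks(cfg, np.random.default_rng(4))
        assert masks[: cfg.n_high].any(axis=0).all()


class TestSampleExpression:
    def test_zero_cells_zero_matrix(self, rng):
        cells, labels, _ = synth_reference(n_genes=20, n_types=2, markers_per_type=3,
                                           cells_per_type=5, seed=0)
        Y = sample_expression(np.zeros((2, 6), int), cells, labels, ["type0", "type1"])
        assert not Y.any()

    def test_single_cell_draw_matches_a_reference_column(self):
        cells, labels, _ = synth_reference(n_genes=20, n_types=2, markers_per_type=3,
                                           cells_per_type=5, seed=0)
        counts = np.zeros((2, 3), int)
        counts[0, 1] = 1
        Y = sample_expression(counts, cells, labels, ["type0", "type1"], seed=5)
        pool = cells[:, labels == "type0"]
        assert any(np.array_equal(Y[:, 1], pool[:, j]) for j in range(pool.shape[1]))

    def test_expected_profile_matches_type_means(self):
        cells, labels, _ = synth_reference(n_genes=15, n_types=2, markers_per_type=3,
                                           cells_per_type=100, seed=1)
        counts = np.array([[3], [2]])
        means = {t: cells[:, labels == t].mean(axis=1) for t in ("type0", "type1")}
        expected = 3 * means["type0"] + 2 * means["type1"]
        draws = np.stack([
            sample_expression(counts, cells, labels, ["type0", "type1"], seed=s)[:, 0]
            for s in range(200)
        ])
        se = draws.std(axis=0, ddof=1) / np.sqrt(200)
        assert np.all(np.abs(draws.mean(axis=0) - expected) <= 3 * se + 1e-9)

    def test_missing_type_raises(self):
        cells, labels, _ = synth_reference(n_genes=10, n_types=2, markers_per_type=2,
                                           cells_per_type=5, seed=0)
        with pytest.raises(ValueError, match="absent"):
            sample_expression(np.ones((1, 2), int), cells, labels, ["ghost"])


class TestDiffusion:
    def test_p_zero_is_identity(self, rng):
        Y = rng.poisson(3.0, size=(5, 36)).astype(float)
        assert np.array_equal(apply_diffusion(Y, 6, 6, 0.0), Y)

    def test_half_retained_at_p_half(self, rng):
        Y = rng.poisson(5.0, size=(4, 25)).astype(float)
        Yd = apply_diffusion(Y, 5, 5, 0.5)
        assert np.all(Yd >= 0.5 * Y - 1e-12)

    def test_total_counts_conserved_exactly(self, rng):
        Y = rng.poisson(3.0, size=(6, 49)).astype(float)
        for p in (0.1, 0.5, 0.9):
            Yd = apply_diffusion(Y, 7, 7, p)
            assert Yd.sum() == pytest.approx(Y.sum(), rel=1e-12)
            assert Yd.sum(axis=1) == pytest.approx(Y.sum(axis=1), rel=1e-9)


class TestGeneNoise:
    def test_multiplier_mean_matches_gamma_mean(self):
        rng = np.random.default_rng(0)
        draws = rng.gamma(GAMMA_SHAPE, GAMMA_SCALE, size=100_000)
        assert draws.mean() == pytest.approx(GAMMA_SHAPE * GAMMA_SCALE, rel=0.01)
        # and through the API: one multiplier per gene, applied row-wise
        Y = np.ones((100_000, 1))
        noised = apply_gene_noise(Y, seed=0)
        assert noised.mean() == pytest.approx(0.4586 / 0.6992, rel=0.01)

    def test_zero_matrix_unchanged(self):
        Y = np.zeros((5, 9))
        assert not apply_gene_noise(Y, seed=1).any()

    def test_reproducible_given_seed(self, rng):
        Y = rng.random((6, 4))
        assert np.array_equal(apply_gene_noise(Y, seed=2), apply_gene_noise(Y, seed=2))


class TestSciSpace:
    @pytest.fixture(scope="class")
    def scispace_run(self):
        cells, labels, _ = synth_reference(n_genes=40, n_types=4, markers_per_type=5,
                                           cells_per_type=500, seed=0)
        rng = np.random.default_rng(0)
        spot_of_cell = rng.integers(2500, size=cells.shape[1])
        Y, truth = simulate_scispace(cells, labels, spot_of_cell, 50, 50, seed=0)
        return Y, truth

    def test_mean_cells_per_spot_near_ten(self, scispace_run):
        _, truth = scispace_run
        m = truth.meta["realized_cells_per_spot"].mean()
        assert m == pytest.approx(10.0, rel=0.05)

    def test_umi_cap_respected(self):
        # deep reference so the cap binds
        cells, labels, _ = synth_reference(n_genes=80, n_types=3, markers_per_type=5,
                                           cells_per_type=200, seed=1,
                                           base_range=(4.0, 12.0))
        rng = np.random.default_rng(1)
        spot_of_cell = rng.integers(100, size=cells.shape[1])
        Y, _ = simulate_scispace(cells, labels, spot_of_cell, 10, 10, seed=1)
        tot = Y.sum(axis=0)
        assert tot.max() <= 5000
        assert (tot == 5000).any()  # thinning actually triggered

    def test_thinning_preserves_gene_proportions(self):
        # 3-gene toy: one thinned draw is consistent with the original
        # per-gene proportions (hypergeometric thinning is unbiased)
        col = np.array([6000, 3000, 1000], dtype=np.int64)
        thinned = np.random.default_rng(3).multivariate_hypergeometric(col, 5000)
        expected = col / col.sum() * 5000
        chi2 = ((thinned - expected) ** 2 / expected).sum()
        assert stats.chi2.sf(chi2, df=2) > 0.01

    def test_truth_counts_match_sampled_cells(self, scispace_run):
        Y, truth = scispace_run
        assert truth.cell_counts.shape[1] == Y.shape[1]
        assert (truth.cell_counts >= 0).all()


class TestSynthReference:
    def test_marker_recovery_by_selection(self):
        cells, labels, _ = synth_reference(n_genes=200, n_types=15, markers_per_type=10,
                                           cells_per_type=50, seed=0)
        genes, _ = select_marker_genes(cells, [f"g{i}" for i in range(200)], labels, top_n=10)
        planted = {f"g{i}" for i in range(150)}
        assert len(planted & set(genes)) / 150 >= 0.9

    def test_single_cell_per_type_signature(self):
        cells, labels, ref = synth_reference(n_genes=30, n_types=2, markers_per_type=4,
                                             cells_per_type=1, seed=2)
        for j, t in enumerate(ref.cell_types):
            assert np.allclose(ref.values[:, j], cells[:, labels == t][:, 0])

    def test_byte_identical_given_seed(self):
        a = synth_reference(n_genes=50, n_types=3, markers_per_type=5, cells_per_type=10, seed=9)
        b = synth_reference(n_genes=50, n_types=3, markers_per_type=5, cells_per_type=10, seed=9)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])
        assert np.array_equal(a[2].values, b[2].values)

    def test_infeasible_marker_allocation_raises(self):
        with pytest.raises(ValueError, match="infeasible"):
            synth_reference(n_genes=10, n_types=4, markers_per_type=5)


def test_doughnut_dataset_pure_function_of_seed():
    cfg = SimConfig(rows=10, cols=10, n_high=2, n_low=2, seed=11)
    Y1, t1, r1, _, _ = simulate_doughnut_dataset(cfg, n_genes=40, cells_per_type=20)
    Y2, t2, r2, _, _ = simulate_doughnut_dataset(cfg, n_genes=40, cells_per_type=20)
    assert np.array_equal(Y1.values, Y2.values)
    assert np.array_equal(t1.cell_counts, t2.cell_counts)
    assert np.array_equal(r1.values, r2.values)


def test_doughnut_mask_geometry():
    m = doughnut_mask(10, 10, (5.0, 5.0), 2.0, 4.0).reshape(10, 10)
    assert not m[5, 5]          # center hole
    assert m[5, 8]              # inside the ring
    assert not m[0, 0]          # outside
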