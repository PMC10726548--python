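"""Cell-type deconvolution: losses, recovery, spatial regularization."""

import numpy as np
import pytest
from scipy.optimize import nnls as scipy_nnls

from smoothkit import (
    AbundanceMatrix,
    DeconvOptions,
    OmicsMatrix,
    ReferenceSignature,
    deconv_loss,
    deconvolve,
    select_marker_genes,
    spatial_loss,
)
from smoothkit.deconv import default_lambda


def make_instance(rng, G=30, C=3, S=25, noise=0.0):
    R = rng.uniform(0.0, 2.0, (G, C))
    X = rng.dirichlet(np.ones(C), size=S).T
    Y = R @ X + noise * rng.standard_normal((G, S))
    genes = [f"g{i}" for i in range(G)]
    spots = [f"s{i}" for i in range(S)]
    types = [f"c{i}" for i in range(C)]
    return (
        OmicsMatrix(np.clip(Y, 0, None), genes, spots, "raw"),
        ReferenceSignature(R, genes, types, "raw"),
        X,
    )


class TestDeconvLoss:
    def test_perfect_fit_zero_loss(self, rng):
        Ym, Rm, X = make_instance(rng)
        Y, R = Ym.values, Rm.values
        assert deconv_loss(Y, R, X, "NNLS") == pytest.approx(0.0, abs=1e-20)
        assert deconv_loss(Y, R, X, "DWLS") == pytest.approx(0.0, abs=1e-20)
        assert deconv_loss(Y, R, X, "LNR") == pytest.approx(0.0, abs=1e-18)
        # SVR's hinge term vanishes; only the ridge penalty on X remains
        opts = DeconvOptions()
        assert deconv_loss(Y, R, X, "SVR", opts) == pytest.approx(
            opts.svr_ridge * (X**2).sum(), rel=1e-12
        )

    def test_nnls_worked_two_gene_instance(self):
        # Y=(1,0) vs fitted (0,1): sum of squared residuals is 2
        Y = np.array([[1.0], [0.0]])
        R = np.array([[0.0], [1.0]])
        X = np.array([[1.0]])
        assert deconv_loss(Y, R, X, "NNLS") == pytest.approx(2.0)

    def test_dwls_weights_inverse_square_of_fitted_mean(self):
        from smoothkit.deconv import _dwls_weights

        R = np.array([[10.0], [1.0]])
        X = np.ones((1, 4))
        w = _dwls_weights(R, X, DeconvOptions())
        # gene with 10x fitted mean gets 100x smaller weight (before capping)
        assert w[1] / w[0] == pytest.approx(100.0)
        assert w.mean() == pytest.approx(1.0)

    def test_dwls_weight_cap(self):
        from smoothkit.deconv import _dwls_weights

        R = np.array([[1000.0], [0.01]])
        X = np.ones((1, 2))
        opts = DeconvOptions()
        w = _dwls_weights(R, X, opts)
        assert w.max() <= opts.dwls_cap_ratio

    def test_unknown_model_raises(self, rng):
        Ym, Rm, X = make_instance(rng)
        with pytest.raises(ValueError, match="model"):
            deconv_loss(Ym.values, Rm.values, X, "OLS")


class TestDeconvolve:
    @pytest.mark.parametrize("model", ["NNLS", "DWLS", "SVR", "LNR"])
    def test_noiseless_recovery(self, rng, model):
        Ym, Rm, X_true = make_instance(rng)
        ab = deconvolve(Ym, Rm, model=model)
        P = ab.proportions()
        for c in range(3):
            assert np.corrcoef(P[c], X_true[c])[0, 1] >= 0.99
        assert np.abs(P - X_true).max() <= 0.01 or model in ("SVR",)
        if model == "NNLS":
            assert np.abs(P - X_true).max() <= 0.01

    def test_single_cell_type_proportion_one(self, rng):
        Ym, Rm, _ = make_instance(rng, C=1)
        ab = deconvolve(Ym, Rm, model="DWLS")
        assert np.allclose(ab.proportions(), 1.0)

    def test_documented_lambda_defaults(self):
        assert default_lambda("NNLS") == 1.0
        assert default_lambda("SVR") == 1.0
        assert default_lambda("LNR") == 1.0
        assert default_lambda("DWLS") == 3.0

    def test_lambda_zero_matches_per_spot_nnls_oracle(self, rng):
        Ym, Rm, _ = make_instance(rng, G=10, C=3, S=20, noise=0.3)
        ab = deconvolve(Ym, Rm, model="NNLS")
        for s in range(20):
            oracle = scipy_nnls(Rm.values, Ym.values[:, s])[0]
            assert np.abs(ab.values[:, s] - oracle).max() < 1e-3

    def test_spatial_coherence_monotone_in_lambda(self, rng, grid10, prior10):
        G, C, S = 25, 3, 100
        R = rng.uniform(0, 2, (G, C))
        Xs = np.stack([np.clip(np.sin(grid10.xy[:, 0] / 3 + c), 0, None) for c in range(C)])
        Y = np.clip(R @ Xs + 0.5 * rng.standard_normal((G, S)), 0, None)
        Ym = OmicsMatrix(Y, [f"g{i}" for i in range(G)], [f"s{i}" for i in range(S)], "raw")
        Rm = ReferenceSignature(R, Ym.gene_ids, [f"c{i}" for i in range(C)], "raw")
        losses = []
        for lam in [0.0, 0.3, 1.0, 3.0, 10.0]:
            ab = deconvolve(Ym, Rm, "NNLS", prior=prior10 if lam > 0 else None, lambda_sp=lam)
            losses.append(spatial_loss(ab.values, prior10))
        assert all(a >= b - 1e-6 * max(abs(a), 1.0) for a, b in zip(losses, losses[1:]))

    def test_proportions_sum_to_one(self, rng):
        Ym, Rm, _ = make_instance(rng, noise=0.5)
        ab = deconvolve(Ym, Rm, "NNLS")
        assert np.allclose(ab.proportions().sum(axis=0), 1.0, atol=1e-6)

    def test_empty_gene_intersection_raises(self, rng):
        Ym, Rm, _ = make_instance(rng)
        Rbad = ReferenceSignature(Rm.values, [f"x{i}" for i in range(30)], Rm.cell_types, "raw")
        with pytest.raises(ValueError, match="intersection"):
            deconvolve(Ym, Rbad)

    def test_negative_lambda_raises(self, rng):
        Ym, Rm, _ = make_instance(rng)
        with pytest.raises(ValueError, match="lambda_sp"):
            deconvolve(Ym, Rm, lambda_sp=-1.0)

    def test_lnr_requires_raw_scale(self, rng):
        Ym, Rm, _ = make_instance(rng)
        with pytest.raises(ValueError, match="raw"):
            deconvolve(Ym.to_scale("log1p"), Rm.to_scale("log1p"), model="LNR")


class TestSelectMarkerGenes:
    def test_disjoint_marker_union_size(self, rng):
        m = 4
        prof = np.zeros((2 * m + 5, 40))
        labels = np.array(["A"] * 20 + ["B"] * 20)
        prof[:m, labels == "A"] = 10 + rng.random((m, 20))
        prof[m : 2 * m, labels == "B"] = 10 + rng.random((m, 20))
        prof[2 * m :, :] = 1.0
        genes, sig = select_marker_genes(prof, [f"g{i}" for i in range(2 * m + 5)], labels, top_n=m)
        assert len(genes) == 2 * m
        assert sig.values.shape == (2 * m, 2)

    def test_uniquely_expressed_gene_ranks_first(self):
        prof = np.ones((6, 10))
        labels = np.array(["A"] * 5 + ["B"] * 5)
        prof[2, labels == "A"] = 25.0  # unique A marker
        genes, _ = select_marker_genes(prof, [f"g{i}" for i in range(6)], labels, top_n=1)
        assert "g2" in genes

    def test_top_n_zero_raises(self, rng):
        prof = rng.random((5, 8))
        labels = np.array(["A"] * 4 + ["B"] * 4)
        with pytest.raises(ValueError, match="top_n"):
            select_marker_genes(prof, [f"g{i}" for i in range(5)], labels, top_n=0)

    def test_top_n_beyond_gene_count_warns(self, rng):
        prof = rng.random((5, 8)) + 0.1
        labels = np.array(["A"] * 4 + ["B"] * 4)
        with pytest.warns(UserWarning, match="top_n"):
            genes, _ = select_marker_genes(prof, [f"g{i}" for i in range(5)], labels, top_n=50)
        assert len(genes) == 5


def test_all_zero_abundance_column_warns_uniform():
    ab = AbundanceMatrix(np.array([[1.0, 0.0], [1.0, 0.0]]), ["a", "b"], ["s1", "s2"])
    with pytest.warns(UserWarning, match="uniform"):
        P = ab.proportions()
    assert np.allclose(P[:, 1], 0.5)
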