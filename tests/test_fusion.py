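"""KAN fusion: spline basis, edge functions, grid refinement, fusion head."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.interpolate import BSpline

from iopscreen.fusion import (
    FusionHead,
    KANFusionClassifier,
    KANLayer,
    bspline_basis,
    fuse,
    gap_pool,
    refine_grid,
    standardize_clinical,
)
from iopscreen.nn import Adam, Tensor


class TestBSplineBasis:
    def test_degree_zero_is_cell_indicator(self):
        grid = np.array([0.0, 1.0, 2.0, 3.0])
        B = bspline_basis(np.array([0.5, 1.5, 2.5]), grid, 0)
        assert np.array_equal(B, np.eye(3))

    @settings(max_examples=25, deadline=None)
    @given(
        degree=st.integers(0, 4),
        n_knots=st.integers(3, 9),
        seed=st.integers(0, 10_000),
    )
    def test_partition_of_unity_on_random_grids(self, degree, n_knots, seed):
        rng = np.random.default_rng(seed)
        grid = np.sort(rng.uniform(-5, 5, n_knots))
        grid += np.arange(n_knots) * 1e-3  # enforce strict increase
        x = rng.uniform(grid[0], grid[-1], 100)
        B = bspline_basis(x, grid, degree)
        assert (B >= -1e-12).all()
        assert np.abs(B.sum(axis=1) - 1).max() < 1e-10
        # local support: at most degree + 1 members active per point
        assert (B > 1e-12).sum(axis=1).max() <= degree + 1

    def test_matches_scipy_design_matrix(self, rng):
        grid = np.linspace(-1, 2, 7)
        deg = 3
        x = rng.uniform(-1, 2, 60)
        t = np.concatenate([[grid[0]] * deg, grid, [grid[-1]] * deg])
        oracle = BSpline.design_matrix(x, t, deg).toarray()
        assert np.abs(bspline_basis(x, grid, deg) - oracle).max() < 1e-10

    def test_out_of_domain_clamped(self):
        grid = np.linspace(0, 1, 5)
        B = bspline_basis(np.array([-2.0, 3.0]), grid, 3)
        assert np.allclose(B.sum(axis=1), 1.0)

    def test_derivative_matches_central_difference(self, rng):
        grid = np.linspace(0, 1, 6)
        x = rng.uniform(0.05, 0.95, 40)
        d = bspline_basis(x, grid, 3, derivative=True)
        eps = 1e-6
        dn = (bspline_basis(x + eps, grid, 3) - bspline_basis(x - eps, grid, 3)) / (
            2 * eps
        )
        assert np.abs(d - dn).max() < 1e-8


class TestKANLayer:
    def test_linear_in_outer_weights(self, rng):
        layer = KANLayer(3, 2, rng=rng)
        x = Tensor(rng.normal(size=(5, 3)))
        y1 = layer(x).data
        layer.lam.data *= 2.5
        assert np.allclose(layer(x).data, 2.5 * y1)

    def test_spline_encoding_identity_function(self, rng):
        layer = KANLayer(1, 1, n_knots=16, degree=3, domain=(0.0, 1.0), rng=rng)
        # least-squares fit of the identity on the basis
        xs = np.linspace(0, 1, 200)
        B = bspline_basis(xs, layer.grid, layer.degree)
        coef, *_ = np.linalg.lstsq(B, xs, rcond=None)
        layer.alpha.data[0, 0] = coef
        layer.lam.data[:] = 1.0
        out = layer(Tensor(xs[:, None])).data.ravel()
        assert np.abs(out - xs).max() < 1e-6

    def test_recovers_smooth_univariate_function(self, rng):
        layer = KANLayer(1, 1, n_knots=16, degree=3, domain=(0.0, 1.0), rng=rng)
        xs = rng.uniform(0, 1, (256, 1))
        ys = 4 * xs * (1 - xs)
        opt = Adam(layer.parameters(), lr=0.05)
        for _ in range(200):
            opt.zero_grad()
            loss = ((layer(Tensor(xs)) - Tensor(ys)) ** 2).mean()
            loss.backward()
            opt.step()
        gx = np.linspace(0, 1, 101)[:, None]
        rmse = float(np.sqrt(np.mean((layer(Tensor(gx)).data - 4 * gx * (1 - gx)) ** 2)))
        assert rmse < 0.05

    def test_input_gradient_matches_numeric(self, rng):
        layer = KANLayer(2, 3, n_knots=8, degree=3, rng=rng)
        x = Tensor(rng.uniform(-2, 2, size=(4, 2)), requires_grad=True)
        (layer(x) ** 2).sum().backward()
        eps = 1e-6
        ng = np.zeros_like(x.data)
        for i in range(4):
            for j in range(2):
                for s, sign in ((eps, 1), (-eps, -1)):
                    xp = x.data.copy()
                    xp[i, j] += s
                    ng[i, j] += sign * float(
                        (layer(Tensor(xp)) ** 2).sum().data
                    ) / (2 * eps)
        assert np.abs(x.grad - ng).max() < 1e-5


class TestGridRefinement:
    def test_constant_image_uniform_allocation(self):
        g = refine_grid(np.full((32, 32), 0.7), 32)
        assert np.all(g.allocations == 2)

    def test_budget_conserved_and_monotone(self, rng):
        for _ in range(10):
            img = rng.random((32, 32))
            g = refine_grid(img, 57)
            assert g.allocations.sum() == 57
            a, m = g.allocations.ravel(), g.gradient_means.ravel()
            order = np.argsort(m)
            assert np.all(np.diff(a[order]) >= -1)  # ties may flip by one knot

    def test_step_edge_region_receives_maximum(self):
        img = np.zeros((32, 32))
        img[:, 12] = 1.0  # sharp line inside region column 1
        g = refine_grid(img, 48)
        assert np.unravel_index(g.allocations.argmax(), g.allocations.shape)[1] == 1

    def test_budget_below_regions_rejected(self):
        with pytest.raises(ValueError):
            refine_grid(np.zeros((8, 8)), 3, regions=(2, 2))


class TestPoolingAndStandardization:
    def test_gap_examples(self):
        assert gap_pool(np.array([[1.0, 2.0], [3.0, 4.0]]))[0] == 2.5
        assert gap_pool(np.full((5, 7), 3.3))[0] == pytest.approx(3.3)
        a, b = np.random.default_rng(0).random((2, 4, 4, 3))
        assert np.allclose(gap_pool(a + b), gap_pool(a) + gap_pool(b))
        with pytest.raises(ValueError):
            gap_pool(np.zeros((0, 3)))

    def test_standardize_round_trip_and_zero_sigma(self, rng):
        table = rng.normal(5, 2, size=(100, 6))
        mu, sd = table.mean(0), table.std(0)
        z = standardize_clinical(table, mu, sd)
        assert np.abs(z.mean(0)).max() < 1e-6
        assert np.abs(z.std(0) - 1).max() < 1e-6
        assert np.allclose(standardize_clinical(mu, mu, sd), 0)
        with pytest.raises(ValueError, match="corneal_volume"):
            standardize_clinical(table, mu, np.array([1, 1, 0, 1, 1, 1.0]))


class TestFusion:
    def test_zero_clinical_weight_returns_image_branch(self, rng):
        f = rng.normal(size=8)
        c = rng.normal(size=8)
        assert np.array_equal(fuse(f, c, 1.0, 0.0), f)

    def test_equal_weights_convexity(self, rng):
        v = rng.normal(size=8)
        assert np.allclose(fuse(v, v, 0.5, 0.5), v)

    def test_width_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fuse(np.zeros(4), np.zeros(6), 0.5, 0.5)

    def test_modality_weight_gradients_nonzero(self, rng):
        head = FusionHead(5, 6, 8, rng)
        fi = Tensor(rng.normal(size=(10, 5)))
        xc = Tensor(rng.normal(size=(10, 6)))
        loss = (head(fi, xc) ** 2).mean()
        loss.backward()
        assert head.modality_logits.grad is not None
        # finite-difference check on the raw weights
        eps = 1e-6
        ng = np.zeros(2)
        for k in range(2):
            for s, sign in ((eps, 1), (-eps, -1)):
                head.modality_logits.data[k] += s
                ng[k] += sign * float((head(fi, xc) ** 2).mean().data) / (2 * eps)
                head.modality_logits.data[k] -= s
        assert np.abs(head.modality_logits.grad - ng).max() < 1e-6
        assert np.any(ng != 0)

    def test_classifier_keeps_weights_on_simplex(self, rng):
        X = np.hstack([rng.normal(size=(80, 10)), rng.normal(size=(80, 6))])
        y = (X[:, 0] + X[:, 10] > 0).astype(int)
        clf = KANFusionClassifier(epochs=15, random_state=0).fit(X, y)
        for w in clf.modality_weight_history_:
            assert np.all(w >= 0) and abs(w.sum() - 1) < 1e-9

    def test_classifier_learns_separable_multimodal_data(self, rng):
        n = 200
        Xi = rng.normal(size=(n, 10))
        Xc = rng.normal(size=(n, 6))
        y = (Xi[:, 0] + Xc[:, 0] > 0).astype(int)
        clf = KANFusionClassifier(epochs=40, random_state=1).fit(
            np.hstack([Xi, Xc]), y
        )
        assert (clf.predict(np.hstack([Xi, Xc])) == y).mean() > 0.9
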