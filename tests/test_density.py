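"""Copula density estimators (histogram fallback and spline flow) and
h-functions against analytic oracles."""

import numpy as np
import pytest

from copulamodules.density import (PairCopulaModel, fit_copula_fallback,
                                   fit_copula_flow, h_function)
from copulamodules.flow import RQSFlow
from copulamodules.parametric import (ParametricCopula, copula_h,
                                      density_parametric, sample_parametric)


class TestFallbackEstimator:
    def test_uniform_samples_mean_exactly_one(self):
        rng = np.random.default_rng(0)
        model = fit_copula_fallback(rng.random((20_000, 2)), G=100)
        assert model.grid.mean() == pytest.approx(1.0, abs=1e-12)

    def test_clayton_corner_in_top_percentile(self, clayton_sample_50k):
        model = fit_copula_fallback(clayton_sample_50k[:20_000], G=100)
        corner = model.grid[0, 0]
        assert corner >= np.quantile(model.grid, 0.99)

    def test_determinism(self):
        rng = np.random.default_rng(1)
        pairs = rng.random((2_000, 2))
        g1 = fit_copula_fallback(pairs, G=50).grid
        g2 = fit_copula_fallback(pairs, G=50).grid
        assert np.array_equal(g1, g2)

    def test_single_cell_mass_warns(self):
        pairs = np.full((50, 2), 0.5)
        with pytest.warns(RuntimeWarning):
            model = fit_copula_fallback(pairs, G=20, bandwidth=0.0)
        assert model.grid.max() == pytest.approx(20 * 20)  # near-delta

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_copula_fallback(np.random.default_rng(0).random((5, 2)))


class TestHFunction:
    def test_independence_model_h_is_identity_in_x(self):
        model = PairCopulaModel(kind="independence", G=50)
        x = np.array([0.1, 0.4, 0.9])
        assert np.allclose(model.h_forward(x, np.full(3, 0.3)), x)
        assert np.allclose(model.h_forward(x, np.full(3, 0.8)), x)

    def test_cdf_endpoints(self, clayton5):
        model = PairCopulaModel(kind="histogram_fallback", G=100,
                                _grid=density_parametric(clayton5, 100))
        eps = 1e-4
        y = np.array([0.2, 0.5, 0.9])
        assert np.all(model.h_forward(np.full(3, eps), y) < 0.01)
        assert np.all(model.h_forward(np.full(3, 1 - eps), y) > 0.99)

    def test_monotone_in_first_argument(self, clayton5):
        model = PairCopulaModel(kind="histogram_fallback", G=100,
                                _grid=density_parametric(clayton5, 100))
        x = np.linspace(0.01, 0.99, 60)
        h = model.h_forward(x, np.full_like(x, 0.37))
        assert np.all(np.diff(h) >= 0)

    def test_numeric_h_matches_closed_form_clayton(self, clayton5):
        """Numeric quadrature of the analytic Clayton grid reproduces the
        closed-form conditional CDF within 0.02 on a 9 x 9 probe grid."""
        model = PairCopulaModel(kind="histogram_fallback", G=100,
                                _grid=density_parametric(clayton5, 100))
        probes = np.linspace(0.1, 0.9, 9)
        xx, yy = np.meshgrid(probes, probes)
        numeric = model.h_forward(xx.ravel(), yy.ravel())
        closed = copula_h(clayton5, xx.ravel(), yy.ravel())
        assert np.max(np.abs(numeric - closed)) < 0.02

    def test_h_consistent_with_numeric_cdf_derivative(self, clayton5):
        """h(x,y) ~ [C(x, y+d) - C(x, y-d)]/(2d) for the model's own
        numeric CDF (computed by summing grid cells)."""
        G = 100
        grid = density_parametric(clayton5, G)
        model = PairCopulaModel(kind="histogram_fallback", G=G, _grid=grid)
        cell = 1.0 / G

        def numeric_cdf(x, y):
            i = int(x * G)
            j = int(y * G)
            return grid[:i, :j].sum() * cell * cell

        for x, y in [(0.3, 0.4), (0.6, 0.6), (0.2, 0.8)]:
            d = cell
            approx = (numeric_cdf(x, y + d) - numeric_cdf(x, y - d)) / (2 * d)
            h = float(model.h_forward(np.array([x]), np.array([y]))[0])
            assert h == pytest.approx(approx, abs=0.02)

    def test_domain_checks(self):
        model = PairCopulaModel(kind="independence")
        with pytest.raises(ValueError):
            h_function(model, np.array([0.0]), np.array([0.5]))


class TestFlowEstimator:
    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(0)
        uv = rng.random((30, 2))
        fl = RQSFlow(n_layers=2, n_basis=4, n_knots=4, seed=1)
        for i in range(2):
            fl.W[i] += rng.normal(0, 0.3, fl.W[i].shape)
            fl.b[i] += rng.normal(0, 0.3, fl.b[i].shape)
        loss, gW, gb = fl._loss_and_grads(uv)
        for i in range(2):
            for arr, g in ((fl.W[i], gW[i]), (fl.b[i], gb[i])):
                idx = tuple(rng.integers(0, s) for s in arr.shape)
                h = 1e-6
                old = arr[idx]
                arr[idx] = old + h
                lp = fl._loss_and_grads(uv)[0]
                arr[idx] = old - h
                lm = fl._loss_and_grads(uv)[0]
                arr[idx] = old
                fd = (lp - lm) / (2 * h)
                assert g[idx] == pytest.approx(fd, rel=1e-4, abs=1e-8)

    def test_small_sample_routes_to_fallback(self):
        rng = np.random.default_rng(2)
        model = fit_copula_flow(rng.random((50, 2)), G=20)
        assert model.kind == "histogram_fallback"

    def test_independence_fit_close_to_flat(self):
        rng = np.random.default_rng(3)
        space = {"n_layers": [2], "hidden_units": [32], "n_knots": [8]}
        model = fit_copula_flow(rng.random((3_000, 2)), search_space=space,
                                n_trials=1, seed=0, G=100, max_epochs=100)
        assert model.kind == "flow"
        mad = np.abs(model.grid - 1.0).mean()
        assert mad < 0.15

    def test_family_discrimination_and_margin_uniformity(self, clayton5,
                                                         frank6,
                                                         clayton_sample_50k):
        """A flow fitted on Clayton theta=5 samples is nearer (grid MSE) to
        the analytic Clayton density than to Frank theta=6, and its fitted
        copula has approximately uniform margins."""
        pairs = clayton_sample_50k[:20_000]
        space = {"n_layers": [2], "hidden_units": [32], "n_knots": [16]}
        model = fit_copula_flow(pairs, search_space=space, n_trials=1,
                                seed=1, G=100, max_epochs=150)
        assert model.kind == "flow"
        g = model.grid
        assert g.mean() == pytest.approx(1.0, abs=0.02)
        mse_c = np.mean((g - density_parametric(clayton5, 100)) ** 2)
        mse_f = np.mean((g - density_parametric(frank6, 100)) ** 2)
        assert mse_c < mse_f
        assert np.abs(g.mean(axis=0) - 1).mean() < 0.1
        assert np.abs(g.mean(axis=1) - 1).mean() < 0.1

    def test_fallback_and_flow_agree_on_family(self, frank6, clayton5,
                                               frank_sample_50k):
        pairs = frank_sample_50k[:8_000]
        fb = fit_copula_fallback(pairs, G=100)
        space = {"n_layers": [2], "hidden_units": [32], "n_knots": [8]}
        fl = fit_copula_flow(pairs, search_space=space, n_trials=1, seed=2,
                             G=100, max_epochs=100)
        tf = density_parametric(frank6, 100)
        tc = density_parametric(clayton5, 100)
        for model in (fb, fl):
            assert (np.mean((model.grid - tf) ** 2)
                    < np.mean((model.grid - tc) ** 2))

    def test_seeded_training_is_deterministic(self):
        uv = sample_parametric(ParametricCopula("frank", 6.0), 800, seed=5)
        m1 = fit_copula_flow(uv, n_trials=1, seed=9, G=30, max_epochs=30)
        m2 = fit_copula_flow(uv, n_trials=1, seed=9, G=30, max_epochs=30)
        assert np.array_equal(m1.grid, m2.grid)
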