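"""Weight construction, (weighted) multiplicative updates, speckled CV,
and module reporting."""

import numpy as np
import pytest

from copulamodules.margins import EmpiricalMargin, fit_empirical_margin
from copulamodules.wnmf import (build_weight_row, match_modules_to_truth, nmf,
                                sort_coefficients, speckled_cv, wnmf,
                                _speckle_masks)


@pytest.fixture(scope="module")
def poisson2_margin():
    return fit_empirical_margin(np.random.default_rng(0).poisson(2, 20_000))


class TestWeightRow:
    def test_uniform_like_margin_gives_flat_row(self):
        """If the (rescaled) quantile function is the identity the tail
        profile vanishes and the returned row is flat."""
        m = EmpiricalMargin(support=np.arange(100),
                            cdf_values=(np.arange(100) + 1) / 100.0,
                            cdf_left_values=np.arange(100) / 100.0)
        row = build_weight_row(m, m, G=50,
                               profile=lambda margin, g: np.zeros_like(g))
        assert np.all(row == 1.0)

    def test_symmetry_for_identical_margins(self, poisson2_margin):
        row = build_weight_row(poisson2_margin, poisson2_margin, G=64)
        assert np.allclose(row, row.T)
        assert np.allclose(row, np.rot90(row))

    def test_corners_outweigh_center(self, poisson2_margin):
        row = build_weight_row(poisson2_margin, poisson2_margin, G=100)
        corners = np.mean([row[:10, :10].mean(), row[:10, -10:].mean(),
                           row[-10:, :10].mean(), row[-10:, -10:].mean()])
        center = row[40:60, 40:60].mean()
        assert corners > center

    def test_strictly_positive_and_max_one(self, poisson2_margin):
        row = build_weight_row(poisson2_margin, poisson2_margin, G=100)
        assert row.min() > 0
        assert row.max() == pytest.approx(1.0)

    def test_degenerate_margin_flat_with_warning(self):
        m = fit_empirical_margin([4, 4, 4])
        with pytest.warns(RuntimeWarning):
            row = build_weight_row(m, m, G=32)
        assert np.all(row == 1.0)


class TestFactorization:
    def test_exact_rank_one_recovery(self):
        rng = np.random.default_rng(1)
        X = np.outer(rng.random(20) + 0.5, rng.random(40) + 0.5)
        res = nmf(X, 1, iters=500, seed=0)
        rel = np.linalg.norm(X - res.W @ res.H) / np.linalg.norm(X)
        assert rel < 1e-4

    def test_overcomplete_rank_near_zero_error(self):
        rng = np.random.default_rng(2)
        X = rng.random((8, 30))
        res = nmf(X, 8, iters=800, seed=0)
        assert res.objective[-1] < 1e-3 * np.sum(X * X)

    def test_nonnegativity_preserved(self):
        rng = np.random.default_rng(3)
        X = rng.random((15, 25))
        V = 0.5 + rng.random((15, 25))
        res = wnmf(X, V, 4, alpha1=0.1, alpha2=0.1, iters=100, seed=1)
        assert np.all(res.W >= 0) and np.all(res.H >= 0)

    def test_unweighted_objective_monotone(self):
        rng = np.random.default_rng(4)
        X = rng.random((20, 30))
        res = nmf(X, 3, iters=300, seed=2)
        diffs = np.diff(res.objective)
        assert np.all(diffs <= 1e-10 * np.abs(res.objective[:-1]) + 1e-12)

    def test_weighted_objective_monotone_after_burn_in(self):
        rng = np.random.default_rng(5)
        X = rng.random((20, 30))
        V = 0.2 + rng.random((20, 30))
        res = wnmf(X, V, 3, alpha1=0.05, alpha2=0.05, iters=300, seed=3)
        tail = res.objective[5:]
        assert np.all(np.diff(tail) <= 1e-8 * np.abs(tail[:-1]) + 1e-12)

    def test_wnmf_reduces_to_nmf(self):
        """With all-one weights and zero penalties the weighted updates are
        the plain Lee-Seung updates, iterate for iterate."""
        rng = np.random.default_rng(6)
        X = rng.random((25, 40))
        rn = nmf(X, 5, iters=120, seed=11)
        rw = wnmf(X, np.ones_like(X), 5, iters=120, seed=11)
        assert np.max(np.abs(rn.W - rw.W)) < 1e-10
        assert np.max(np.abs(rn.H - rw.H)) < 1e-10
        assert np.max(np.abs(rn.objective - rw.objective)) < 1e-8

    def test_l1_regularization_increases_sparsity(self):
        rng = np.random.default_rng(7)
        X = np.outer(rng.random(30), rng.random(60)) + 0.01 * rng.random((30, 60))
        V = np.ones_like(X)
        loose = wnmf(X, V, 6, alpha1=0.0, iters=300, seed=4)
        tight = wnmf(X, V, 6, alpha1=10.0 * X.mean(), iters=300, seed=4)
        frac = lambda H: np.mean(H < 1e-6)
        assert frac(tight.H) > frac(loose.H)

    def test_invalid_rank_rejected(self):
        X = np.random.default_rng(8).random((5, 10))
        with pytest.raises(ValueError):
            nmf(X, 6)


class TestSpeckledCV:
    def test_masks_disjoint_and_cover_expected_fraction(self):
        rng = np.random.default_rng(9)
        masks = _speckle_masks((40, 200), 5, 0.1, rng)
        held = np.zeros((40, 200), dtype=int)
        for m in masks:
            held += ~m
        assert held.max() <= 1  # each entry held out in at most one fold
        assert held.sum() == pytest.approx(5 * 0.1 * 40 * 200, rel=0.01)

    def test_recovers_planted_rank(self):
        """Noisy rank-3 positive matrix: mean validation error over ranks
        1..6 must be minimized at 3."""
        rng = np.random.default_rng(10)
        W0 = rng.random((60, 3)) + 0.5
        H0 = rng.random((3, 120)) + 0.5
        # zero-mean noise (a nonzero mean would itself be a rank-1
        # component), large enough that overfitting it is detectable
        X = W0 @ H0 + 0.3 * (rng.random((60, 120)) - 0.5)
        assert X.min() > 0
        rep = speckled_cv(X, None, ranks=range(1, 7), seed=0, iters=600,
                          weighted=False)
        assert rep.best_rank == 3

    def test_holdout_frac_validated(self):
        X = np.random.default_rng(11).random((10, 20))
        with pytest.raises(ValueError):
            speckled_cv(X, None, ranks=[2], holdout_frac=0.6)


class TestReporting:
    def test_identity_like_coefficients_group_by_factor(self):
        W = np.kron(np.eye(3), np.ones((4, 1))) * \
            np.linspace(1, 0.25, 12)[:, None]
        order = sort_coefficients(W)
        groups = np.argmax(W[order], axis=1)
        assert np.all(np.diff(groups) >= 0)  # grouped by dominant module

    def test_known_groups_recovered_under_noise(self):
        rng = np.random.default_rng(12)
        labels = np.repeat(np.arange(4), 25)
        W = 0.05 * rng.random((100, 4))
        W[np.arange(100), labels] += 1.0 + rng.random(100)
        order = sort_coefficients(W)
        recovered = np.argmax(W[order], axis=1)
        # within the sorted table, rows of one group are contiguous
        correct = sum(np.argmax(W[r]) == labels[r] for r in order)
        assert correct >= 95
        assert np.all(np.diff(recovered) >= 0)

    def test_zero_rows_sort_last_and_ties_stable(self):
        W = np.array([[0.0, 0.0], [1.0, 0.2], [0.0, 0.0], [1.0, 0.1]])
        order = list(sort_coefficients(W))
        assert order[-2:] == [0, 2]
        assert order[:2] == [1, 3]  # equal dominant values keep index order

    def test_exact_and_permuted_truth_matching(self):
        rng = np.random.default_rng(13)
        truths = [rng.random((8, 8)) + 0.2 for _ in range(3)]
        H = np.stack([t.ravel() for t in truths])
        perm = [2, 0, 1]
        assign, mse = match_modules_to_truth(H[perm], truths)
        assert np.allclose(mse, 0.0, atol=1e-12)
        assert list(assign) == [perm.index(j) for j in range(3)]

    def test_noise_level_reflected_in_mse(self):
        """Adding uniform noise of amplitude eps to mean-1 modules yields
        per-truth MSE close to the noise variance eps^2/3 (within x2),
        after the mean-1 rescaling both sides undergo."""
        rng = np.random.default_rng(14)
        eps = 0.05
        truths = [1.0 + 0.3 * rng.random((10, 10)) for _ in range(3)]
        H = np.stack([
            (t + eps * (2 * rng.random((10, 10)) - 1)).ravel()
            for t in truths])
        _, mse = match_modules_to_truth(H, truths)
        expected = eps**2 / 3.0
        assert np.all(mse < 2 * expected)
        assert np.all(mse > expected / 2)

    def test_k_mismatch_rejected(self):
        with pytest.raises(ValueError):
            match_modules_to_truth(np.ones((2, 16)), [np.ones((4, 4))] * 3)
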