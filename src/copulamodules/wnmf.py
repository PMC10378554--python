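"""Weighted non-negative matrix factorization of copula density matrices.

The input matrix X stacks vectorized G x G copula density grids, one row per
(possibly conditional) neuron pair.  NMF decomposes X ~ W H into
non-negative pair coefficients W (n_pairs x k) and copula modules H
(k x G^2), each module reshaping to a shared elementary dependence pattern
on the unit square.

Plain NMF misallocates overlapping tail regions because probability mass at
copula corners can differ by orders of magnitude between families.  The
weighted variant multiplies the squared reconstruction residual elementwise
by a weight matrix V built from the pair's count margins, so that errors in
tail regions are penalized more.  Multiplicative updates generalize the
Lee-Seung rules with V inside both numerator and denominator products and
L1/L2 penalty terms (alpha1, alpha2) added to the denominators.

Rank and regularization strengths are selected by speckled cross-validation:
each fold holds out a random scatter of matrix entries, treated as missing
during fitting (the holdout mask multiplies V), and scored by reconstruction
MSE on exactly those entries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.optimize import linear_sum_assignment

from .margins import EmpiricalMargin
from .parametric import grid_centers

__all__ = [
    "FactorizationResult",
    "SpeckledCVReport",
    "build_weight_row",
    "build_weight_matrix",
    "nmf",
    "wnmf",
    "speckled_cv",
    "sort_coefficients",
    "match_modules_to_truth",
]

_EPS = 1e-12  # denominator stabilizer


# ---------------------------------------------------------------------------
# weight matrix (tail emphasis from margin skewness)


def _profile_quantile_minus_uniform(margin: EmpiricalMargin, g: np.ndarray):
    """|F^-1(u) - u| in raw count units; vanishes iff the quantile function
    is the identity (a continuous-uniform-like margin)."""
    return np.abs(margin.quantile(g).astype(float) - g)


def _profile_rescaled(margin: EmpiricalMargin, g: np.ndarray):
    """Variant with the quantile rescaled to [0,1] by its max support."""
    q = margin.quantile(g).astype(float) / max(margin.max_support, 1)
    return np.abs(q - g)


_PROFILES = {
    "quantile_minus_uniform": _profile_quantile_minus_uniform,
    "rescaled": _profile_rescaled,
}


def build_weight_row(margin_x: EmpiricalMargin, margin_y: EmpiricalMargin,
                     G: int = 100, sigma: float = 5.0,
                     profile="quantile_minus_uniform",
                     baseline: float = 1e-3) -> np.ndarray:
    """Tail-emphasis weight matrix (G x G) for one neuron pair.

    The outer product of the two margins' tail profiles is summed with its
    90/180/270-degree rotations (so all four corners are weighted), smoothed
    with a Gaussian window of sd ``sigma`` bins, floored at ``baseline`` of
    the max so every weight is strictly positive, and normalized to max 1.
    The result is invariant under 90-degree rotation by construction.
    ``profile`` may be a key of the built-in profiles or a callable
    (margin, grid) -> values.
    """
    if G < 8:
        raise ValueError("G must be >= 8")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    prof = _PROFILES[profile] if isinstance(profile, str) else profile
    g = grid_centers(G)
    if len(margin_x.support) < 2 or len(margin_y.support) < 2:
        warnings.warn("degenerate margin; returning flat weight row",
                      RuntimeWarning)
        return np.ones((G, G))
    gx = np.asarray(prof(margin_x, g), dtype=float)
    gy = np.asarray(prof(margin_y, g), dtype=float)
    A = np.outer(gx, gy)
    R = A + np.rot90(A, 1) + np.rot90(A, 2) + np.rot90(A, 3)
    S = gaussian_filter(R, sigma=sigma, mode="reflect")
    m = S.max()
    if m <= 0:
        return np.ones((G, G))
    S = np.maximum(S, baseline * m)
    return S / S.max()


def build_weight_matrix(margin_pairs, G: int = 100, sigma: float = 5.0,
                        **kwargs) -> np.ndarray:
    """Stack weight rows for a list of (margin_x, margin_y) pairs -> n x G^2."""
    return np.stack([
        build_weight_row(mx, my, G=G, sigma=sigma, **kwargs).ravel()
        for mx, my in margin_pairs
    ])


# ---------------------------------------------------------------------------
# factorization


@dataclass
class FactorizationResult:
    W: np.ndarray
    H: np.ndarray
    objective: np.ndarray = field(repr=False, default=None)
    config: dict = field(default_factory=dict)


def _init_wh(X, k, rng):
    scale = np.sqrt(max(X.mean(), _EPS) / k)
    W = rng.random((X.shape[0], k)) * scale
    H = rng.random((k, X.shape[1])) * scale
    return W, H


def _init_nndsvda(X, k, svd=None):
    """Deterministic NNDSVD init with zeros filled by the matrix mean.

    Used inside cross-validation, where a single well-conditioned start per
    fold avoids the local-minima lottery of random inits without the cost
    of restarts.  ``svd`` may carry a precomputed (U, S, Vt) of X.
    """
    U, S, Vt = np.linalg.svd(X, full_matrices=False) if svd is None else svd
    W = np.zeros((X.shape[0], k))
    H = np.zeros((k, X.shape[1]))
    W[:, 0] = np.sqrt(S[0]) * np.abs(U[:, 0])
    H[0] = np.sqrt(S[0]) * np.abs(Vt[0])
    for j in range(1, k):
        u, v = U[:, j], Vt[j]
        up, un = np.maximum(u, 0), np.maximum(-u, 0)
        vp, vn = np.maximum(v, 0), np.maximum(-v, 0)
        pos = np.linalg.norm(up) * np.linalg.norm(vp)
        neg = np.linalg.norm(un) * np.linalg.norm(vn)
        if pos >= neg:
            uu, vv, sig = up, vp, pos
        else:
            uu, vv, sig = un, vn, neg
        if sig > 0:
            W[:, j] = np.sqrt(S[j] * sig) * uu / np.linalg.norm(uu)
            H[j] = np.sqrt(S[j] * sig) * vv / np.linalg.norm(vv)
    fill = max(X.mean(), _EPS)
    W[W <= 0] = fill
    H[H <= 0] = fill
    return W, H


def _objective(X, W, H, V, alpha1, alpha2):
    R = X - W @ H
    obj = float(np.sum(V * R * R))
    if alpha1:
        obj += alpha1 * (np.abs(W).sum() + np.abs(H).sum())
    if alpha2:
        obj += 0.5 * alpha2 * (np.sum(W * W) + np.sum(H * H))
    return obj


def _mu_factorize(X, V, k, alpha1, alpha2, iters, seed, record_objective=True,
                  init="random"):
    """Multiplicative updates; V=None means unweighted (all-ones weights)."""
    X = np.asarray(X, dtype=float)
    if np.any(X < 0):
        raise ValueError("X must be non-negative")
    if not 1 <= k <= min(X.shape):
        raise ValueError("k must satisfy 1 <= k <= min(X.shape)")
    Vw = np.ones_like(X) if V is None else np.asarray(V, dtype=float)
    if Vw.shape != X.shape:
        raise ValueError("V must have the same shape as X")
    if init == "random":
        W, H = _init_wh(X, k, np.random.default_rng(seed))
    elif init == "nndsvda":
        W, H = _init_nndsvda(X, k)
    elif isinstance(init, tuple):  # precomputed (W0, H0)
        W, H = init[0].copy(), init[1].copy()
    else:
        raise ValueError(f"unknown init {init!r}")
    VX = Vw * X
    trace = []
    WH = np.empty_like(X)  # reused buffer: allocation dominates cost otherwise
    for _ in range(iters):
        np.dot(W, H, out=WH)
        np.multiply(Vw, WH, out=WH)
        W *= (VX @ H.T) / (WH @ H.T + alpha1 + alpha2 * W + _EPS)
        np.dot(W, H, out=WH)
        np.multiply(Vw, WH, out=WH)
        H *= (W.T @ VX) / (W.T @ WH + alpha1 + alpha2 * H + _EPS)
        if record_objective:
            trace.append(_objective(X, W, H, Vw, alpha1, alpha2))
    return W, H, np.asarray(trace)


def nmf(X, k: int, iters: int = 200, seed: int = 0) -> FactorizationResult:
    """Unweighted NMF with Lee-Seung multiplicative updates (Frobenius)."""
    W, H, trace = _mu_factorize(X, None, k, 0.0, 0.0, iters, seed)
    return FactorizationResult(W=W, H=H, objective=trace,
                               config={"k": k, "iters": iters, "seed": seed,
                                       "weighted": False})


def wnmf(X, V, k: int, alpha1: float = 0.0, alpha2: float = 0.0,
         iters: int = 200, seed: int = 0, n_restarts: int = 1,
         ) -> FactorizationResult:
    """Weighted NMF; with V all-ones and zero alphas it reduces exactly to
    :func:`nmf` from the same seed.  ``n_restarts`` seeded inits keep the
    lowest final objective."""
    best = None
    seeds = [seed] if n_restarts <= 1 else [
        int(s.generate_state(1)[0] % (2**31 - 1))
        for s in np.random.SeedSequence(seed).spawn(n_restarts)]
    for s in seeds:
        W, H, trace = _mu_factorize(X, V, k, alpha1, alpha2, iters, s)
        if best is None or trace[-1] < best.objective[-1]:
            best = FactorizationResult(
                W=W, H=H, objective=trace,
                config={"k": k, "alpha1": alpha1, "alpha2": alpha2,
                        "iters": iters, "seed": s, "weighted": True})
    return best


# ---------------------------------------------------------------------------
# speckled cross-validation


@dataclass
class SpeckledCVReport:
    ranks: list
    alphas: list
    train_mse: np.ndarray  # (n_alphas, n_ranks, n_folds)
    val_mse: np.ndarray
    best_rank: int
    best_alpha: tuple
    holdout_frac: float
    seed: int

    def rank_curve(self) -> np.ndarray:
        """Mean validation MSE per rank, minimized over alpha settings."""
        return self.val_mse.mean(axis=2).min(axis=0)


def _speckle_masks(shape, n_folds, holdout_frac, rng, max_tries=20):
    """Disjoint random holdout masks; every entry held out in at most one
    fold and no row ever fully masked within a fold."""
    size = shape[0] * shape[1]
    per_fold = int(round(holdout_frac * size))
    if n_folds * per_fold > size:
        raise ValueError("folds x holdout_frac exceeds the matrix size")
    for _ in range(max_tries):
        perm = rng.permutation(size)
        masks = []
        ok = True
        for f in range(n_folds):
            held = perm[f * per_fold:(f + 1) * per_fold]
            mask = np.ones(size, dtype=bool)
            mask[held] = False
            mask = mask.reshape(shape)
            if np.any(~mask.any(axis=1)):
                ok = False
                break
            masks.append(mask)
        if ok:
            return masks
    raise RuntimeError("could not build speckle masks without empty rows")


def speckled_cv(X, V, ranks, n_folds: int = 5, holdout_frac: float = 0.1,
                alphas=((0.0, 0.0),), seed: int = 0, iters: int = 200,
                weighted: bool = True, score: str = "weighted",
                init: str = "nndsvda") -> SpeckledCVReport:
    """Rank (and alpha) selection by speckled cross-validation.

    Per fold a random scatter of entries is held out: the fit sees
    V * mask (or the bare mask for unweighted NMF), and the fold is scored
    by reconstruction error on exactly the held-out entries.

    ``score`` selects the error metric: ``"weighted"`` (default) scores
    with the same V-weighted squared loss the factorization minimizes
    (sum of V*(X-WH)^2 over scored entries, divided by the summed
    weights), which is the loss whose generalization CV should estimate;
    ``"unweighted"`` scores plain MSE.  For an unweighted fit the two
    coincide.
    """
    X = np.asarray(X, dtype=float)
    ranks = list(ranks)
    if not ranks:
        raise ValueError("ranks must be non-empty")
    if not 0.0 < holdout_frac < 0.5:
        raise ValueError("holdout_frac must be in (0, 0.5)")
    alphas = [tuple(a) for a in alphas]
    rng = np.random.default_rng(seed)
    masks = _speckle_masks(X.shape, n_folds, holdout_frac, rng)
    Vw = np.ones_like(X) if (V is None or not weighted) else np.asarray(V, float)
    if score not in ("weighted", "unweighted"):
        raise ValueError(f"unknown score {score!r}")
    Vs = Vw if score == "weighted" else np.ones_like(X)
    train_mse = np.zeros((len(alphas), len(ranks), n_folds))
    val_mse = np.zeros_like(train_mse)
    fit_seeds = rng.integers(2**31 - 1, size=(len(alphas), len(ranks), n_folds))
    if init == "nndsvda":
        svd = np.linalg.svd(X, full_matrices=False)
        inits = {k: _init_nndsvda(X, k, svd=svd) for k in ranks}
    else:
        inits = None
    for ai, (a1, a2) in enumerate(alphas):
        for ri, k in enumerate(ranks):
            for fi, mask in enumerate(masks):
                Veff = Vw * mask
                W, H, _ = _mu_factorize(X, Veff, k, a1, a2, iters,
                                        int(fit_seeds[ai, ri, fi]),
                                        record_objective=False,
                                        init=inits[k] if inits else init)
                R2 = Vs * (X - W @ H) ** 2
                train_mse[ai, ri, fi] = R2[mask].sum() / Vs[mask].sum()
                val_mse[ai, ri, fi] = R2[~mask].sum() / Vs[~mask].sum()
    mean_val = val_mse.mean(axis=2)  # (alphas, ranks)
    per_rank = mean_val.min(axis=0)
    ri_best = int(np.argmin(per_rank))
    ai_best = int(np.argmin(mean_val[:, ri_best]))
    return SpeckledCVReport(ranks=ranks, alphas=alphas, train_mse=train_mse,
                            val_mse=val_mse, best_rank=ranks[ri_best],
                            best_alpha=alphas[ai_best],
                            holdout_frac=holdout_frac, seed=seed)


# ---------------------------------------------------------------------------
# reporting helpers


def sort_coefficients(W) -> np.ndarray:
    """Row ordering: group rows by argmax module, descending coefficient
    within each group; all-zero rows go last in original order."""
    W = np.asarray(W, dtype=float)
    if np.any(W < 0):
        raise ValueError("W must be non-negative")
    rows = np.arange(W.shape[0])
    zero = W.sum(axis=1) == 0
    nz = rows[~zero]
    keys = [(int(np.argmax(W[r])), -float(W[r, np.argmax(W[r])]), int(r))
            for r in nz]
    ordered = [r for *_, r in sorted(keys)]
    return np.asarray(ordered + list(rows[zero]), dtype=int)


def match_modules_to_truth(H, truths) -> tuple[np.ndarray, np.ndarray]:
    """Optimal one-to-one matching of modules to ground-truth density grids.

    Modules and truths are rescaled to mean 1 (copula normalization) before
    computing MSE; the assignment minimizing total MSE is solved exactly.
    Returns (assignment, mse): assignment[j] is the module index matched to
    truth j, mse[j] the corresponding mean squared error.
    """
    H = np.asarray(H, dtype=float)
    truths = [np.asarray(t, dtype=float).ravel() for t in truths]
    if H.shape[0] != len(truths):
        raise ValueError("number of modules must equal number of truths")
    if any(t.size != H.shape[1] for t in truths):
        raise ValueError("truth grids must vectorize to H's column count")

    def _rescale(v):
        m = v.mean()
        return v / m if m > 0 else v

    Hn = np.stack([_rescale(h) for h in H])
    Tn = np.stack([_rescale(t) for t in truths])
    cost = np.mean((Tn[:, None, :] - Hn[None, :, :]) ** 2, axis=2)
    rows, cols = linear_sum_assignment(cost)
    assignment = np.empty(len(truths), dtype=int)
    mse = np.empty(len(truths))
    for r, c in zip(rows, cols):
        assignment[r] = c
        mse[r] = cost[r, c]
    return assignment, mse
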