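"""C-vine construction over pseudo-observations.

The joint density of d variables factorizes into d(d-1)/2 bivariate copulas
arranged in trees: tree 1 couples the root variable with every other
variable on the raw pseudo-observations; deeper trees couple conditional
pseudo-observations produced by h-functions of the previous tree's models.
The root sequence is chosen once by the sum-of-|Kendall tau| heuristic
(the variable most dependent on everything else becomes the first hub).
The simplifying assumption is adopted: conditional copulas do not depend on
the values of their conditioning variables, so all n observations are pooled
at every tree.

Before any density is fitted, each candidate edge is screened with a
two-sample two-dimensional Kolmogorov-Smirnov test (Fasano-Franceschini
statistic) against seeded uniform draws on the square; edges with p > alpha
are flagged independent and pass their arguments through unchanged
(h(x,y) = x).  This pruning is what keeps large vines tractable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import special

from .density import PairCopulaModel, fit_copula_fallback, fit_copula_flow
from .margins import EPS, kendall_tau

__all__ = [
    "VineEdge",
    "VineStructure",
    "count_pair_copulas",
    "order_variables",
    "ks2d_statistic",
    "independence_test",
    "fit_cvine",
]


def count_pair_copulas(d: int) -> int:
    """Number of pair copulas in a full vine over d variables: d(d-1)/2."""
    if d < 2:
        raise ValueError("need at least 2 variables")
    return d * (d - 1) // 2


def order_variables(u: np.ndarray) -> np.ndarray:
    """Root sequence: variables sorted by descending sum_j |tau(i, j)|.

    Ties (including identical columns) break by original index.
    """
    u = np.asarray(u, dtype=float)
    if u.ndim != 2 or u.shape[1] < 2:
        raise ValueError("need an n x d matrix with d >= 2")
    d = u.shape[1]
    sums = np.zeros(d)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for i in range(d):
            for j in range(i + 1, d):
                t = abs(kendall_tau(u[:, i], u[:, j]))
                sums[i] += t
                sums[j] += t
    return np.argsort(-sums, kind="stable")


# ---------------------------------------------------------------------------
# two-sample 2-D Kolmogorov-Smirnov (Fasano-Franceschini)


def _max_quadrant_diff(origins, a, b, chunk=256):
    """Max over origins and quadrants of |F_a - F_b| for quadrant fractions."""
    best = 0.0
    na, nb = len(a), len(b)
    for s in range(0, len(origins), chunk):
        o = origins[s:s + chunk]
        agx = a[None, :, 0] > o[:, None, 0]
        agy = a[None, :, 1] > o[:, None, 1]
        bgx = b[None, :, 0] > o[:, None, 0]
        bgy = b[None, :, 1] > o[:, None, 1]
        for qx, qy in ((1, 1), (0, 1), (0, 0), (1, 0)):
            fa = ((agx == qx) & (agy == qy)).sum(axis=1) / na
            fb = ((bgx == qx) & (bgy == qy)).sum(axis=1) / nb
            m = np.abs(fa - fb).max()
            if m > best:
                best = float(m)
    return best


def ks2d_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sample Fasano-Franceschini statistic: average of the max quadrant
    deviations taken with each sample's points as origins."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    d1 = _max_quadrant_diff(a, a, b)
    d2 = _max_quadrant_diff(b, a, b)
    return 0.5 * (d1 + d2)


def _ks2d_pvalue_asymptotic(d, a, b):
    na, nb = len(a), len(b)
    ra = np.corrcoef(a[:, 0], a[:, 1])[0, 1]
    rb = np.corrcoef(b[:, 0], b[:, 1])[0, 1]
    if not np.isfinite(ra):
        ra = 0.0
    if not np.isfinite(rb):
        rb = 0.0
    rr = np.sqrt(1.0 - 0.5 * (ra**2 + rb**2))
    sqen = np.sqrt(na * nb / (na + nb))
    lam = d * sqen / (1.0 + rr * (0.25 - 0.75 / sqen))
    return float(special.kolmogorov(lam))


@lru_cache(maxsize=8)
def _uniform_null_distribution(n: int, m: int, n_null: int = 500) -> tuple:
    """Monte-Carlo null of the two-sample FF statistic for uniform samples
    of sizes (n, m) on the unit square.  Deterministic (fixed internal seed)
    and cached, so the cost amortizes over the edges of a vine fit."""
    rng = np.random.default_rng(np.random.SeedSequence(202306))
    draws = np.empty(n_null)
    for i in range(n_null):
        draws[i] = ks2d_statistic(rng.random((n, 2)), rng.random((m, 2)))
    draws.sort()
    return tuple(draws)


def independence_test(pairs, alpha: float = 0.05, m_uniform: int | None = None,
                      seed: int = 0, reference: np.ndarray | None = None,
                      method: str = "montecarlo", n_permutations: int = 199,
                      ) -> tuple[float, bool]:
    """Test an empirical copula sample against the independence copula.

    The sample is compared with ``m_uniform`` seeded uniform draws on the
    square (or an explicit ``reference`` sample) using the two-sample 2-D KS
    statistic.  ``method`` selects the p-value computation:

    * ``"montecarlo"`` (default) — the statistic is referred to a cached
      Monte-Carlo null built from uniform-vs-uniform draws at the same
      sample sizes.  The pseudo-observations under test have uniform margins
      by construction, so this null is exact up to Monte-Carlo error and
      keeps the test calibrated at moderate n.
    * ``"asymptotic"`` — the Fasano-Franceschini large-sample approximation
      (fast, slightly anticonservative at moderate n).
    * ``"permutation"`` — pooled relabeling with ``n_permutations`` draws.

    Returns (p_value, is_independent) with is_independent = (p > alpha).
    """
    pairs = np.asarray(pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or len(pairs) < 20:
        raise ValueError("pairs must be n x 2 with n >= 20")
    rng = np.random.default_rng(seed)
    if reference is None:
        m = len(pairs) if m_uniform is None else int(m_uniform)
        reference = rng.random((m, 2))
    d = ks2d_statistic(pairs, reference)
    if method == "montecarlo":
        null = np.asarray(_uniform_null_distribution(len(pairs), len(reference)))
        p = (1 + int(np.sum(null >= d))) / (len(null) + 1)
    elif method == "asymptotic":
        p = _ks2d_pvalue_asymptotic(d, pairs, reference)
    elif method == "permutation":
        pooled = np.concatenate([pairs, reference])
        n1 = len(pairs)
        count = 0
        for _ in range(n_permutations):
            perm = rng.permutation(len(pooled))
            dp = ks2d_statistic(pooled[perm[:n1]], pooled[perm[n1:]])
            if dp >= d:
                count += 1
        p = (1 + count) / (n_permutations + 1)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(p), bool(p > alpha)


# ---------------------------------------------------------------------------
# C-vine fitting


@dataclass
class VineEdge:
    """One pair copula: (root, partner | conditioning)."""

    tree: int  # 1-based tree level
    root: int  # original variable index of the tree's hub
    partner: int
    conditioning: tuple
    independent: bool
    p_value: float
    model: PairCopulaModel


@dataclass
class VineStructure:
    """Fitted C-vine: root order, edges with models and independence flags."""

    order: np.ndarray
    edges: list = field(default_factory=list)
    d: int = 0
    n_obs: int = 0

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_independent(self) -> int:
        return sum(e.independent for e in self.edges)

    def nonindependent_edges(self) -> list:
        return [e for e in self.edges if not e.independent]


def fit_cvine(u: np.ndarray, estimator: str = "fallback", alpha: float = 0.05,
              seed: int = 0, G: int = 100, max_test_points: int = 2000,
              test_method: str = "montecarlo", fallback_kwargs: dict | None = None,
              flow_kwargs: dict | None = None, max_trees: int | None = None,
              ) -> VineStructure:
    """Sequential tree-by-tree C-vine fit with independence pruning.

    Tree 1 pairs the first root with every other variable on the raw
    pseudo-observations; for tree t > 1 the partner columns are replaced by
    conditional pseudo-observations h(partner | root) from tree t-1 models
    (independence edges pass through unchanged).  Every edge is independence
    -tested first; only non-independent edges get a fitted density.
    ``max_trees`` optionally truncates fitting to the first trees.
    """
    u = np.asarray(u, dtype=float)
    if u.ndim != 2 or u.shape[1] < 2:
        raise ValueError("need an n x d matrix with d >= 2")
    n, d = u.shape
    if n < 100:
        raise ValueError("need at least 100 observations")
    if estimator not in ("fallback", "flow"):
        raise ValueError("estimator must be 'fallback' or 'flow'")
    order = order_variables(u)
    cols = u[:, order].copy()
    structure = VineStructure(order=order, d=d, n_obs=n)
    seeds = np.random.SeedSequence(seed).spawn(d)
    n_trees = d - 1 if max_trees is None else min(max_trees, d - 1)
    for t in range(1, n_trees + 1):
        root_pos = t - 1
        root_var = int(order[root_pos])
        cond = tuple(int(v) for v in order[:root_pos])
        edge_seeds = seeds[t - 1].spawn(d - t)
        tree_models = {}
        for idx, j in enumerate(range(t, d)):
            pair = np.column_stack([cols[:, root_pos], cols[:, j]])
            ss = edge_seeds[idx]
            test_pair = pair
            if len(pair) > max_test_points:
                sub_rng = np.random.default_rng(ss.spawn(1)[0])
                sel = sub_rng.choice(len(pair), size=max_test_points, replace=False)
                test_pair = pair[sel]
            p, indep = independence_test(
                test_pair, alpha=alpha,
                seed=int(np.random.default_rng(ss).integers(2**31 - 1)),
                method=test_method)
            if indep:
                model = PairCopulaModel(kind="independence", G=G)
            elif estimator == "fallback":
                model = fit_copula_fallback(pair, G=G, **(fallback_kwargs or {}))
            else:
                model = fit_copula_flow(
                    pair, G=G,
                    seed=int(np.random.default_rng(ss).integers(2**31 - 1)),
                    **(flow_kwargs or {}))
            structure.edges.append(VineEdge(
                tree=t, root=root_var, partner=int(order[j]), conditioning=cond,
                independent=indep, p_value=p, model=model))
            tree_models[j] = model
        # conditional pseudo-observations for the next tree
        if t < n_trees:
            for j in range(t, d):
                model = tree_models[j]
                if model.kind == "independence":
                    continue  # h(x, y) = x: pass through unchanged
                h = model.h_backward(cols[:, j], cols[:, root_pos])
                if np.any((h <= 0) | (h >= 1)):
                    warnings.warn("conditional sample left (0,1); clipping",
                                  RuntimeWarning)
                cols[:, j] = np.clip(h, EPS, 1.0 - EPS)
    return structure
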