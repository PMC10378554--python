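"""Synthetic validation data: copula-density benchmarks and count populations.

The benchmark emulates the validation design used to compare WNMF with NMF:
pairs of Poisson-margin counts coupled by Clayton (theta=5) and Frank
(theta=6) copulas and their rotations, 20,000 pairs per copula by default.
Each pair sample is pushed through Poisson quantiles to counts, mapped back
to the unit square with the distributional transform, and its density is
estimated on a 100 x 100 grid; 20 such rows per family stack into matrices
of 40, 80 or 120 rows for the 2-, 4- and 6-copula cases.

``generate_population`` builds a trials x neurons count matrix whose listed
pairs are coupled through parametric copulas along a dependence forest
(sampled root-to-leaf via conditional inverses), giving an end-to-end
fixture for the full vine + factorization pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .density import fit_copula_fallback, fit_copula_flow
from .margins import distributional_transform, fit_empirical_margin
from .parametric import (ParametricCopula, conditional_sample,
                         density_parametric, sample_parametric)
from .wnmf import build_weight_row

__all__ = [
    "BenchmarkSpec",
    "BenchmarkData",
    "benchmark_families",
    "make_benchmark",
    "PopulationSpec",
    "generate_population",
]


def benchmark_families(case: int) -> list:
    """Family lists of the 2-, 4- and 6-copula validation cases."""
    frank = ParametricCopula("frank", 6.0)
    clayton = ParametricCopula("clayton", 5.0)
    fams = [frank, clayton]
    if case >= 4:
        fams += [ParametricCopula("frank", 6.0, rotation=90),
                 ParametricCopula("clayton", 5.0, rotation=90)]
    if case >= 6:
        fams += [ParametricCopula("clayton", 5.0, rotation=180),
                 ParametricCopula("clayton", 5.0, rotation=270)]
    if case not in (2, 4, 6):
        raise ValueError("case must be 2, 4 or 6")
    return fams


@dataclass(frozen=True)
class BenchmarkSpec:
    case: int = 6
    rows_per_family: int = 20
    samples_per_copula: int = 20_000
    grid_size: int = 100
    poisson_rate: float = 20.0
    seed: int = 0
    estimator: str = "fallback"

    @property
    def families(self) -> list:
        return benchmark_families(self.case)


@dataclass
class BenchmarkData:
    """Stacked density matrix with aligned weights, truths and labels."""

    X: np.ndarray  # n_rows x G^2 vectorized estimated densities
    V: np.ndarray  # n_rows x G^2 strictly positive weights
    truths: list = field(repr=False, default=None)  # one G x G grid per family
    truth_labels: list = None
    row_labels: list = None  # family label of each row
    G: int = 100


def _density_row(uv, spec: BenchmarkSpec, rng):
    """Counts -> empirical copula -> estimated density + weight row."""
    n = len(uv)
    counts_x = stats.poisson.ppf(uv[:, 0], spec.poisson_rate).astype(int)
    counts_y = stats.poisson.ppf(uv[:, 1], spec.poisson_rate).astype(int)
    mx = fit_empirical_margin(counts_x)
    my = fit_empirical_margin(counts_y)
    px = distributional_transform(counts_x, mx, rng.random(n))
    py = distributional_transform(counts_y, my, rng.random(n))
    pairs = np.column_stack([px, py])
    if spec.estimator == "fallback":
        model = fit_copula_fallback(pairs, G=spec.grid_size)
    else:
        model = fit_copula_flow(pairs, G=spec.grid_size,
                                seed=int(rng.integers(2**31 - 1)))
    w = build_weight_row(mx, my, G=spec.grid_size)
    return model.grid.ravel(), w.ravel()


def make_benchmark(spec: BenchmarkSpec) -> BenchmarkData:
    """Generate the stacked density matrix for one validation case.

    Deterministic given ``spec.seed``: per-row seeds are spawned from it.
    """
    fams = spec.families
    G = spec.grid_size
    rows, weights, labels = [], [], []
    seeds = np.random.SeedSequence(spec.seed).spawn(len(fams))
    for fam, fam_seed in zip(fams, seeds):
        row_seeds = fam_seed.spawn(spec.rows_per_family)
        for ss in row_seeds:
            rng = np.random.default_rng(ss)
            uv = sample_parametric(fam, spec.samples_per_copula,
                                   seed=int(rng.integers(2**31 - 1)))
            x, w = _density_row(uv, spec, rng)
            rows.append(x)
            weights.append(w)
            labels.append(fam.label)
    truths = [density_parametric(f, G) for f in fams]
    return BenchmarkData(X=np.stack(rows), V=np.stack(weights), truths=truths,
                         truth_labels=[f.label for f in fams],
                         row_labels=labels, G=G)


# ---------------------------------------------------------------------------
# synthetic neural population


@dataclass(frozen=True)
class PopulationSpec:
    """Hub-structured count population.

    ``edges`` lists (i, j, ParametricCopula) couplings; the edge set must be
    a forest (no cycles), which is what a C-vine with mostly-independent
    deeper trees can represent exactly.  Unlisted pairs are conditionally
    independent given the forest.  ``rates`` is a scalar Poisson rate or one
    rate per neuron.
    """

    d: int
    n_obs: int
    edges: tuple = ()
    rates: float = 2.0
    seed: int = 0


def _swap(c: ParametricCopula) -> ParametricCopula:
    """Copula of (V, U) when (U, V) ~ c; for exchangeable base families the
    90- and 270-degree rotations trade places."""
    if c.rotation in (90, 270):
        return ParametricCopula(c.family, c.theta, rotation=360 - c.rotation)
    return c


def generate_population(spec: PopulationSpec) -> np.ndarray:
    """Sample a trials x neurons count matrix with the specified couplings."""
    d, n = spec.d, spec.n_obs
    adj = {}
    for (i, j, cop) in spec.edges:
        if not (0 <= i < d and 0 <= j < d) or i == j:
            raise ValueError(f"invalid edge ({i}, {j})")
        adj.setdefault(i, []).append((j, cop, False))
        adj.setdefault(j, []).append((i, cop, True))
    rng = np.random.default_rng(spec.seed)
    u = np.empty((n, d))
    visited = np.zeros(d, dtype=bool)
    for start in range(d):
        if visited[start]:
            continue
        visited[start] = True
        u[:, start] = rng.random(n)
        queue = [(start, -1)]
        while queue:
            node, parent = queue.pop()
            for (child, cop, flipped) in adj.get(node, []):
                if visited[child]:
                    if child != parent:
                        raise ValueError(
                            "dependence graph contains a cycle; a forest is "
                            "required for the C-vine-consistent construction")
                    continue
                visited[child] = True
                eff = _swap(cop) if flipped else cop
                u[:, child] = conditional_sample(eff, u[:, node], rng.random(n))
                queue.append((child, node))
    rates = np.broadcast_to(np.asarray(spec.rates, dtype=float), (d,))
    counts = np.empty((n, d), dtype=np.int64)
    for j in range(d):
        counts[:, j] = stats.poisson.ppf(np.clip(u[:, j], 1e-12, 1 - 1e-12),
                                         rates[j]).astype(np.int64)
    return counts
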