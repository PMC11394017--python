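"""Euclidean distances between prey taxa and Kruskal non-metric MDS.

The ordination embeds prey taxa, described by their per-pellet abundance
in each survey, into two dimensions so that inter-point distances
reproduce the rank order of the input dissimilarities. The loss is
Kruskal's stress-1,

    stress = sqrt( Σ (D_ij − ĥ_ij)² / Σ D_ij² ),

where D are configuration distances and ĥ is the least-squares monotone
(isotonic) regression of D onto the rank order of the input distances
(pool-adjacent-violators, primary approach to ties). Minimization
alternates isotonic fits with Guttman-transform configuration updates,
with one start from classical metric scaling and the rest random. With
only two surveys the abundance profiles are literally points in the
plane, so a perfect (near-zero-stress) embedding exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .aggregate import AbundanceMatrix

__all__ = [
    "DistanceMatrix",
    "NMDSResult",
    "euclidean_distances",
    "monotone_fit",
    "nmds",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric non-negative dissimilarities with a zero diagonal."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.labels):
            raise ValueError("distance matrix must be square and match labels")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if (v < 0).any() or not np.allclose(np.diag(v), 0.0):
            raise ValueError("distances must be ≥ 0 with a zero diagonal")
        object.__setattr__(self, "values", v)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


@dataclass
class NMDSResult:
    """2-D configuration, Kruskal stress-1 and convergence diagnostics."""

    labels: tuple[str, ...]
    coordinates: np.ndarray
    stress: float
    n_starts: int
    converged: bool
    stress_history: list[float] = field(default_factory=list)


def euclidean_distances(abund: AbundanceMatrix) -> DistanceMatrix:
    """Pairwise Euclidean distances between taxon abundance profiles."""
    if len(abund.taxa) < 2:
        raise ValueError("need at least 2 taxa for a distance matrix")
    return DistanceMatrix(abund.taxa, squareform(pdist(abund.values)))


def monotone_fit(y: np.ndarray, weights: np.ndarray | None = None) -> np.ndarray:
    """Least-squares non-decreasing fit via pool-adjacent-violators.

    Returns the non-decreasing vector minimizing the (weighted) squared
    error to ``y``; the solution is piecewise constant with each level
    the weighted mean of its pool.
    """
    y = np.asarray(y, dtype=float)
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    # stacks of pool means, weights and sizes
    means: list[float] = []
    wsum: list[float] = []
    size: list[int] = []
    for yi, wi in zip(y, w):
        means.append(float(yi))
        wsum.append(float(wi))
        size.append(1)
        while len(means) > 1 and means[-2] > means[-1]:
            m2, w2, s2 = means.pop(), wsum.pop(), size.pop()
            m1, w1, s1 = means.pop(), wsum.pop(), size.pop()
            wt = w1 + w2
            means.append((m1 * w1 + m2 * w2) / wt)
            wsum.append(wt)
            size.append(s1 + s2)
    return np.repeat(means, size)


def _classical_scaling(d: np.ndarray, dims: int) -> np.ndarray:
    """Classical (Torgerson) metric scaling as a deterministic start."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    evals, evecs = np.linalg.eigh(b)
    idx = np.argsort(evals)[::-1][:dims]
    lam = np.clip(evals[idx], 0.0, None)
    return evecs[:, idx] * np.sqrt(lam)


def _disparities(d_cond: np.ndarray, config_d: np.ndarray) -> np.ndarray:
    # primary tie treatment: within blocks of tied input distances the
    # configuration distances may order freely, so sort ties by config_d
    order = np.lexsort((config_d, d_cond))
    fitted = monotone_fit(config_d[order])
    out = np.empty_like(config_d)
    out[order] = fitted
    return out


def _stress1(config_d: np.ndarray, disp: np.ndarray) -> float:
    denom = float((config_d**2).sum())
    if denom == 0.0:
        return 0.0
    return float(np.sqrt(((config_d - disp) ** 2).sum() / denom))


def _guttman_update(x: np.ndarray, config_d: np.ndarray, disp: np.ndarray) -> np.ndarray:
    n = x.shape[0]
    ratio = np.zeros_like(config_d)
    nz = config_d > 0
    ratio[nz] = disp[nz] / config_d[nz]
    b = -squareform(ratio, checks=False)
    np.fill_diagonal(b, -b.sum(axis=1))
    return (b @ x) / n


def nmds(
    d: DistanceMatrix,
    dims: int = 2,
    n_starts: int = 20,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int | None = None,
) -> NMDSResult:
    """Non-metric multidimensional scaling minimizing Kruskal stress-1.

    One start uses classical metric scaling (so the returned stress can
    never exceed that initialization's); the remaining ``n_starts − 1``
    use random Gaussian configurations. Within a start, an update that
    would increase stress is discarded and the start terminates, so the
    recorded stress history is non-increasing by construction.
    """
    d_cond = d.condensed()
    n = len(d.labels)
    rng = np.random.default_rng(seed)
    scale = d_cond.mean() if d_cond.size and d_cond.mean() > 0 else 1.0

    best: tuple[float, np.ndarray, list[float], bool] | None = None
    for start in range(max(1, n_starts)):
        x = (
            _classical_scaling(d.values, dims)
            if start == 0
            else rng.normal(scale=scale, size=(n, dims))
        )
        config_d = pdist(x)
        disp = _disparities(d_cond, config_d)
        s = _stress1(config_d, disp)
        history = [s]
        converged = False
        for _ in range(max_iter):
            if s == 0.0:
                converged = True
                break
            x_new = _guttman_update(x, config_d, disp)
            cd_new = pdist(x_new)
            disp_new = _disparities(d_cond, cd_new)
            s_new = _stress1(cd_new, disp_new)
            if s_new > s:
                converged = True  # stalled at a local minimum
                break
            x, config_d, disp = x_new, cd_new, disp_new
            improvement = s - s_new
            s = s_new
            history.append(s)
            if improvement < tol * max(s, tol):
                converged = True
                break
        if best is None or s < best[0]:
            best = (s, x, history, converged)

    stress, coords, history, converged = best
    return NMDSResult(
        labels=d.labels,
        coordinates=coords,
        stress=stress,
        n_starts=max(1, n_starts),
        converged=converged,
        stress_history=history,
    )
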