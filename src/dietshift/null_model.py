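"""Quantitative shuffle-and-swap null models and permutation inference.

The null models randomize a taxa × surveys count matrix while holding
fixed the features of the observed diet that are *not* under test:

* every variant preserves the number of unexploited resource categories
  in each survey (the zero pattern's margins) and the number of occupied
  cells;
* ``shuffle_samp`` (default) additionally preserves the multiset of
  observed non-zero cell values, permuting them over a freshly drawn
  occupancy pattern — so the grand total of prey individuals is conserved
  but per-survey totals may migrate between surveys;
* ``shuffle_both`` redistributes the grand total uniformly at random over
  the occupied cells (each receiving at least one individual);
* ``multinomial`` redraws each survey independently: which S_used taxa
  are occupied (uniformly) and a uniform composition of that survey's
  total N_j over them — hence per-survey totals are conserved exactly.

Inference is fully non-parametric: add-one empirical p-values
``(r + 1)/(n + 1)`` and a signed probit standardized effect size
``SES = sign × |Φ⁻¹(p/2)|``, appropriate when null distributions are
skewed; |SES| > 1.96 flags 5% two-sigma significance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.stats import norm

from .data_io import CountMatrix

__all__ = [
    "VARIANTS",
    "ALTERNATIVES",
    "NullConfig",
    "PermTestResult",
    "sample_incidence",
    "redistribute_quantities",
    "null_replicate",
    "null_distribution",
    "empirical_p",
    "probit_ses",
    "paired_permutation_test",
]

VARIANTS = ("shuffle_samp", "shuffle_both", "multinomial")
ALTERNATIVES = ("two_sided", "left", "right")


@dataclass(frozen=True)
class NullConfig:
    """Replicate count, randomization variant, seed and significance cutoff."""

    n_perm: int = 9999
    variant: str = "shuffle_samp"
    seed: int | None = None
    sig_threshold: float = 1.96
    n_swap_attempts: int = 10_000  # trial-swap chain length for > 2 surveys

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be ≥ 1")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got {self.variant!r}")


@dataclass(frozen=True)
class PermTestResult:
    """One permutation test: observed statistic, null summary, SES and p."""

    feature: str
    observed: float
    null_mean: float
    ses: float
    p: float
    alternative: str
    n_perm: int
    sig_threshold: float = 1.96

    @property
    def significant(self) -> bool:
        return abs(self.ses) > self.sig_threshold


# ---------------------------------------------------------------------------
# occupancy (incidence) randomization


def sample_incidence(counts: CountMatrix, rng: np.random.Generator,
                     n_swap_attempts: int = 10_000) -> np.ndarray:
    """Draw an occupancy pattern with the observed incidence margins.

    The draw is uniform over binary matrices sharing the observed
    per-survey used-taxon counts and per-taxon survey counts. With two
    surveys this is exact: taxa occupied in both surveys are fixed, and
    the single-survey taxa are repartitioned uniformly at random subject
    to the two per-survey totals. With more surveys a sequential 2×2
    checkerboard trial-swap chain is used.
    """
    inc = (counts.counts > 0)
    n_taxa, n_surv = inc.shape
    if n_surv == 2:
        out = inc.copy()
        row_occ = inc.sum(axis=1)
        singles = np.flatnonzero(row_occ == 1)
        if singles.size:
            # number of singleton taxa currently occupying the first survey
            r0 = int(inc[singles, 0].sum())
            pick = rng.choice(singles.size, size=r0, replace=False)
            first = np.zeros(singles.size, dtype=bool)
            first[pick] = True
            out[singles, 0] = first
            out[singles, 1] = ~first
        return out
    out = inc.copy()
    for _ in range(n_swap_attempts):
        i1, i2 = rng.integers(0, n_taxa, size=2)
        j1, j2 = rng.integers(0, n_surv, size=2)
        if i1 == i2 or j1 == j2:
            continue
        a, b, c, d = out[i1, j1], out[i1, j2], out[i2, j1], out[i2, j2]
        if a and d and not b and not c:
            out[i1, j1] = out[i2, j2] = False
            out[i1, j2] = out[i2, j1] = True
        elif b and c and not a and not d:
            out[i1, j2] = out[i2, j1] = False
            out[i1, j1] = out[i2, j2] = True
    return out


def _uniform_composition(total: int, parts: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform draw over compositions of `total` into `parts` parts, each ≥ 1."""
    if parts < 1 or total < parts:
        raise ValueError(f"cannot place {total} individuals into {parts} occupied cells")
    if parts == 1:
        return np.array([total], dtype=np.int64)
    cuts = np.sort(rng.choice(np.arange(1, total), size=parts - 1, replace=False))
    return np.diff(np.concatenate(([0], cuts, [total]))).astype(np.int64)


def redistribute_quantities(
    counts: CountMatrix,
    incidence: np.ndarray,
    variant: str,
    rng: np.random.Generator,
) -> CountMatrix:
    """Place quantities on an occupancy pattern.

    ``shuffle_samp`` permutes the observed multiset of non-zero cell
    values uniformly onto the occupied cells; ``shuffle_both``
    redistributes the grand total uniformly among them (each ≥ 1).
    """
    occupied = np.asarray(incidence, dtype=bool)
    vals = counts.counts[counts.counts > 0]
    if occupied.sum() != vals.size:
        raise ValueError(
            f"occupied-cell mismatch: incidence has {int(occupied.sum())}, "
            f"counts have {vals.size} non-zero cells"
        )
    new = np.zeros_like(counts.counts)
    if variant == "shuffle_samp":
        new[occupied] = rng.permutation(vals)
    elif variant == "shuffle_both":
        new[occupied] = _uniform_composition(int(vals.sum()), int(vals.size), rng)
    else:
        raise ValueError(f"unknown redistribution variant: {variant!r}")
    return CountMatrix(counts.taxa, counts.surveys, new, allow_zero_rows=True,
                       validate=False)


def null_replicate(counts: CountMatrix, config: NullConfig,
                   rng: np.random.Generator) -> CountMatrix:
    """One randomized matrix under the configured null variant."""
    if config.variant == "multinomial":
        new = np.zeros_like(counts.counts)
        totals = counts.column_totals()
        s_used = (counts.counts > 0).sum(axis=0)
        for j in range(len(counts.surveys)):
            support = rng.choice(counts.counts.shape[0], size=int(s_used[j]),
                                 replace=False)
            new[support, j] = _uniform_composition(int(totals[j]), int(s_used[j]), rng)
        return CountMatrix(counts.taxa, counts.surveys, new, allow_zero_rows=True,
                           validate=False)
    inc = sample_incidence(counts, rng, config.n_swap_attempts)
    return redistribute_quantities(counts, inc, config.variant, rng)


def null_distribution(
    counts: CountMatrix,
    statistic: Callable[[CountMatrix], float],
    config: NullConfig,
) -> np.ndarray:
    """Evaluate a statistic on ``n_perm`` independent null replicates."""
    rng = np.random.default_rng(config.seed)
    out = np.empty(config.n_perm, dtype=float)
    for k in range(config.n_perm):
        rep = null_replicate(counts, config, rng)
        try:
            out[k] = statistic(rep)
        except Exception as exc:
            raise RuntimeError(
                f"statistic failed on null replicate {k}:\n{rep.to_frame()}"
            ) from exc
    return out


# ---------------------------------------------------------------------------
# inference


def empirical_p(t_obs: float, null: np.ndarray, alternative: str) -> float:
    """Add-one empirical p-value, ties counted as at least as extreme.

    left: (#{T* ≤ T_obs} + 1)/(n + 1); right mirrored; two_sided compares
    absolute deviations from the null mean, which makes the minimum
    attainable p equal to 1/(n + 1) in every case.
    """
    null = np.asarray(null, dtype=float)
    if null.size == 0:
        raise ValueError("empty null distribution")
    n = null.size
    if alternative == "left":
        r = int((null <= t_obs).sum())
    elif alternative == "right":
        r = int((null >= t_obs).sum())
    elif alternative == "two_sided":
        center = null.mean()
        r = int((np.abs(null - center) >= abs(t_obs - center)).sum())
    else:
        raise ValueError(f"alternative must be one of {ALTERNATIVES}")
    return (r + 1) / (n + 1)


def probit_ses(p: float, direction: float) -> float:
    """Signed probit standardized effect size, SES = sign × |Φ⁻¹(p/2)|.

    ``direction`` is the sign of (observed − null mean); p = 1 gives 0.
    This non-parametric SES depends on the null only through the
    empirical p, so it is robust to skewed null distributions.
    """
    if not (0.0 < p <= 1.0):
        raise ValueError(f"p must be in (0, 1], got {p!r}")
    return float(np.sign(direction) * abs(norm.ppf(p / 2.0)))


def paired_permutation_test(
    counts: CountMatrix,
    statistic: Callable[[CountMatrix], float],
    config: NullConfig,
    alternative: str = "two_sided",
    label: str = "statistic",
) -> PermTestResult:
    """Full permutation test of a matrix statistic against the null model."""
    if alternative not in ALTERNATIVES:
        raise ValueError(f"alternative must be one of {ALTERNATIVES}")
    t_obs = float(statistic(counts))
    null = null_distribution(counts, statistic, config)
    null_mean = float(null.mean())
    p = empirical_p(t_obs, null, alternative)
    ses = probit_ses(p, t_obs - null_mean)
    return PermTestResult(
        feature=label,
        observed=t_obs,
        null_mean=null_mean,
        ses=ses,
        p=p,
        alternative=alternative,
        n_perm=config.n_perm,
        sig_threshold=config.sig_threshold,
    )
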