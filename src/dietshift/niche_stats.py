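"""Dietary statistics: Shannon entropy, Pielou evenness, Petraitis overlap.

All logarithms are natural. Pielou's J is base-invariant anyway, and the
Petraitis niche-overlap index has its cleanest form in nats:

    O_{A|B} = exp( Σ_{p_Ai>0} p_Ai ln p_Bi − Σ_{p_Ai>0} p_Ai ln p_Ai )
            = exp( −KL(p_A ‖ p_B) )

so O is 1 exactly when the two utilization distributions agree on A's
support, and 0 in the complete-separation limit (A uses a category B does
not). The single-number default is the geometric mean of the two directed
overlaps, which is symmetric in its arguments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .aggregate import AbundanceMatrix, per_pellet_abundance
from .data_io import CountMatrix, Survey

__all__ = [
    "DiversityResult",
    "OverlapResult",
    "shannon_entropy",
    "pielou_evenness",
    "evenness_difference",
    "petraitis_overlap",
    "guild_abundance_difference",
    "relative_abundance_change",
]

_PROP_TOL = 1e-9


@dataclass(frozen=True)
class DiversityResult:
    """Shannon entropy H (nats), used-taxon count and Pielou's J for a survey."""

    survey: str
    H: float
    S_used: int
    J: float


@dataclass(frozen=True)
class OverlapResult:
    """Directed Petraitis overlaps and the reported value for a chosen mode."""

    o_ab: float
    o_ba: float
    mode: str
    value: float


def _check_proportions(p: np.ndarray, name: str) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise ValueError(f"{name} has negative entries")
    if abs(p.sum() - 1.0) > _PROP_TOL:
        raise ValueError(f"{name} does not sum to 1 (sum = {p.sum()!r})")
    return p


def shannon_entropy(p: Sequence[float]) -> float:
    """Shannon entropy −Σ p ln p in nats; zero entries contribute nothing."""
    p = _check_proportions(np.asarray(p, dtype=float), "proportion vector")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def pielou_evenness(counts: Sequence[float]) -> float:
    """Pielou's evenness J = H / ln(S_used) over the taxa actually used.

    Unused (zero-count) taxa are excluded from both H and S_used, so J is
    a property of the realized diet spectrum. Invariant to rescaling all
    counts. Undefined when fewer than two taxa are used.
    """
    c = np.asarray(counts, dtype=float)
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    used = c[c > 0]
    if used.size <= 1:
        raise ValueError("evenness undefined for a single used taxon")
    p = used / used.sum()
    h = float(-(p * np.log(p)).sum())
    return h / float(np.log(used.size))


def diversity(counts: CountMatrix, survey_id: str) -> DiversityResult:
    """Bundle H, S_used and J for one survey column."""
    c = counts.column(survey_id).astype(float)
    s_used = int((c > 0).sum())
    p = c / c.sum()
    nz = p[p > 0]
    h = float(-(nz * np.log(nz)).sum())
    j = h / float(np.log(s_used)) if s_used >= 2 else float("nan")
    return DiversityResult(survey=str(survey_id), H=h, S_used=s_used, J=j)


def evenness_difference(counts: CountMatrix, later: str, earlier: str) -> float:
    """Paired evenness difference ΔJ = J(later) − J(earlier)."""
    return pielou_evenness(counts.column(later)) - pielou_evenness(counts.column(earlier))


def _directed_overlap(pa: np.ndarray, pb: np.ndarray) -> float:
    sup = pa > 0
    if (pb[sup] == 0).any():
        return 0.0  # complete-separation limit
    pa_s, pb_s = pa[sup], pb[sup]
    return float(np.exp((pa_s * np.log(pb_s)).sum() - (pa_s * np.log(pa_s)).sum()))


def petraitis_overlap(
    pA: Sequence[float],
    pB: Sequence[float],
    mode: str = "geometric_mean",
) -> OverlapResult:
    """Petraitis specific niche overlap between two utilization distributions.

    Parameters
    ----------
    pA, pB :
        Proportion vectors over the same taxon order, each summing to 1.
    mode :
        ``"A_on_B"`` reports O_{A|B}, ``"B_on_A"`` reports O_{B|A}, and
        ``"geometric_mean"`` (default) the symmetric geometric mean of the
        two directed overlaps.
    """
    pa = _check_proportions(np.asarray(pA, dtype=float), "pA")
    pb = _check_proportions(np.asarray(pB, dtype=float), "pB")
    if pa.shape != pb.shape:
        raise ValueError(f"mismatched lengths: {pa.shape} vs {pb.shape}")
    o_ab = _directed_overlap(pa, pb)
    o_ba = _directed_overlap(pb, pa)
    if mode == "A_on_B":
        value = o_ab
    elif mode == "B_on_A":
        value = o_ba
    elif mode == "geometric_mean":
        value = float(np.sqrt(o_ab * o_ba))
    else:
        raise ValueError(f"unknown overlap mode: {mode!r}")
    return OverlapResult(o_ab=o_ab, o_ba=o_ba, mode=mode, value=value)


def guild_abundance_difference(
    abund: AbundanceMatrix, guild: str, later: str, earlier: str
) -> float:
    """Paired per-pellet abundance difference for one feeding guild."""
    row = abund.row(guild)
    return float(row[abund.survey_index(later)] - row[abund.survey_index(earlier)])


def relative_abundance_change(
    counts: CountMatrix,
    surveys: Sequence[Survey],
    taxon: str,
    later: str,
    earlier: str,
) -> tuple[float, float]:
    """Change of one taxon between surveys, in two common senses.

    Returns ``(pp_change, pct_change)`` where ``pp_change`` is the change
    in within-survey proportion in percentage points,
    ``100 · (p_later − p_earlier)``, and ``pct_change`` is the relative
    change of per-pellet abundance in percent,
    ``100 · (a_later − a_earlier) / a_earlier``. Reports should label
    which sense they quote.
    """
    i = counts.taxon_index(taxon)
    jl, je = counts.survey_index(later), counts.survey_index(earlier)
    totals = counts.column_totals().astype(float)
    p_later = counts.counts[i, jl] / totals[jl]
    p_earlier = counts.counts[i, je] / totals[je]
    abund = per_pellet_abundance(counts, surveys)
    a_later = abund.values[i, jl]
    a_earlier = abund.values[i, je]
    if a_earlier == 0:
        raise ValueError(
            f"relative change undefined: {taxon!r} has zero abundance in {earlier!r}"
        )
    return (
        float(100.0 * (p_later - p_earlier)),
        float(100.0 * (a_later - a_earlier) / a_earlier),
    )
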