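"""Rank collapsing and normalization of prey counts.

Raw pellet identifications are often mixed-rank (species where the bones
allow, genus or family where they do not). Collapsing everything to one
rank (typically subfamily) via a flat item → group map removes taxonomic
nestedness before analysis. Two normalizations follow: per-pellet
abundance ``a_ij = n_ij / P_j``, which makes surveys with very different
pellet effort comparable, and within-survey proportions
``p_ij = n_ij / N_j``, consumed by evenness and overlap statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .data_io import CountMatrix, GuildMap, Survey, GUILDS

__all__ = [
    "AbundanceMatrix",
    "ProportionSet",
    "aggregate_to_subfamily",
    "per_pellet_abundance",
    "proportions",
    "aggregate_guilds",
]


@dataclass
class AbundanceMatrix:
    """Per-pellet abundances: prey individuals per pellet, taxa × surveys."""

    taxa: tuple[str, ...]
    surveys: tuple[str, ...]
    values: np.ndarray  # float, taxa × surveys

    def survey_index(self, survey_id: str) -> int:
        try:
            return self.surveys.index(str(survey_id))
        except ValueError:
            raise KeyError(f"unknown survey id: {survey_id!r}") from None

    def row(self, taxon: str) -> np.ndarray:
        try:
            return self.values[self.taxa.index(taxon)]
        except ValueError:
            raise KeyError(f"unknown taxon: {taxon!r}") from None


@dataclass
class ProportionSet:
    """Within-survey proportions ``p_ij = n_ij / N_j``; columns sum to 1."""

    taxa: tuple[str, ...]
    surveys: tuple[str, ...]
    values: np.ndarray

    def for_survey(self, survey_id: str) -> np.ndarray:
        try:
            return self.values[:, self.surveys.index(str(survey_id))]
        except ValueError:
            raise KeyError(f"unknown survey id: {survey_id!r}") from None


def aggregate_to_subfamily(raw: CountMatrix, mapping: Mapping[str, str]) -> CountMatrix:
    """Collapse mixed-rank prey items to their mapped group (e.g. subfamily).

    Counts are summed within each group per survey; output groups are
    ordered by first appearance among the raw items. Every raw label must
    have a map entry.
    """
    if len(mapping) == 0 and len(raw.taxa) > 0:
        raise ValueError("empty item → subfamily map for a non-empty matrix")
    groups: list[str] = []
    for item in raw.taxa:
        if item not in mapping:
            raise ValueError(f"item {item!r} has no subfamily mapping")
        g = mapping[item]
        if g not in groups:
            groups.append(g)
    counts = np.zeros((len(groups), len(raw.surveys)), dtype=np.int64)
    for i, item in enumerate(raw.taxa):
        counts[groups.index(mapping[item])] += raw.counts[i]
    return CountMatrix(groups, raw.surveys, counts)


def per_pellet_abundance(counts: CountMatrix, surveys: Sequence[Survey]) -> AbundanceMatrix:
    """Divide each survey's counts by that survey's pellet total ``P_j``."""
    by_id = {s.id: s.pellet_count for s in surveys}
    pellets = []
    for sid in counts.surveys:
        if sid not in by_id:
            raise ValueError(f"survey {sid!r} has no pellet_count in the metadata")
        pellets.append(by_id[sid])
    values = counts.counts / np.asarray(pellets, dtype=float)
    return AbundanceMatrix(counts.taxa, counts.surveys, values)


def proportions(counts: CountMatrix) -> ProportionSet:
    """Within-survey proportions ``p_ij = n_ij / N_j``."""
    totals = counts.column_totals()
    if (totals < 1).any():
        bad = [s for s, n in zip(counts.surveys, totals) if n < 1]
        raise ValueError(f"surveys with zero total count: {bad}")
    return ProportionSet(counts.taxa, counts.surveys, counts.counts / totals.astype(float))


def aggregate_guilds(counts: CountMatrix, guilds: GuildMap) -> CountMatrix:
    """Sum taxon counts into the three feeding guilds.

    The output always has exactly three rows in the fixed order
    insectivore, herbivore, omnivore; a guild with no exploited member is
    kept as a zero row so the per-guild tests always exist.
    """
    if len(guilds) == 0 and len(counts.taxa) > 0:
        raise ValueError("empty guild map for a non-empty matrix")
    out = np.zeros((len(GUILDS), len(counts.surveys)), dtype=np.int64)
    for i, taxon in enumerate(counts.taxa):
        out[GUILDS.index(guilds[taxon])] += counts.counts[i]
    return CountMatrix(GUILDS, counts.surveys, out, allow_zero_rows=True)
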