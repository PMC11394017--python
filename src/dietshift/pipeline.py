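"""End-to-end paired diet-shift analysis.

Orchestrates: optional rank aggregation → per-pellet abundances and
proportions → five permutation tests (evenness difference and niche
overlap on the taxon matrix; three guild abundance differences on the
guild matrix) → NMDS of taxa on Euclidean abundance distances → result
tables. Alternatives are fixed by design — two-sided for evenness and
the guild abundances, left-sided for overlap (the question being
whether the diets are *less* similar than randomly expected).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import data_io
from .aggregate import aggregate_guilds, aggregate_to_subfamily, per_pellet_abundance, proportions
from .data_io import CountMatrix, GuildMap, Survey, GUILDS
from .niche_stats import evenness_difference, petraitis_overlap
from .null_model import NullConfig, PermTestResult, paired_permutation_test
from .ordination import euclidean_distances, nmds

__all__ = [
    "FEATURE_LABELS",
    "PipelineConfig",
    "PipelineResult",
    "significance_flag",
    "analyze",
    "run_pipeline",
]

#: Fixed report rows, in order.
FEATURE_LABELS = (
    "Prey taxon evenness",
    "Food niche overlap",
    "Omnivorous prey",
    "Herbivorous prey",
    "Insectivorous prey",
)

_DEFAULT_ALTERNATIVES: dict[str, str] = {
    "Prey taxon evenness": "two_sided",
    "Food niche overlap": "left",
    "Omnivorous prey": "two_sided",
    "Herbivorous prey": "two_sided",
    "Insectivorous prey": "two_sided",
}

_GUILD_FOR_LABEL = {
    "Omnivorous prey": "omnivore",
    "Herbivorous prey": "herbivore",
    "Insectivorous prey": "insectivore",
}


def significance_flag(ses: float, threshold: float = 1.96) -> bool:
    """True iff the effect size lies outside the open interval (−t, +t)."""
    if not np.isfinite(ses):
        raise ValueError("ses must be finite")
    return abs(ses) > threshold


@dataclass
class PipelineConfig:
    """File paths and settings for a full pipeline run."""

    surveys_path: str | Path
    counts_path: str | Path
    guilds_path: str | Path
    earlier: str
    later: str
    subfamily_map_path: str | Path | None = None
    null: NullConfig = field(default_factory=NullConfig)
    nmds_starts: int = 20
    nmds_max_iter: int = 500
    nmds_tol: float = 1e-6
    out_dir: str | Path = "dietshift_out"

    def __post_init__(self) -> None:
        if str(self.earlier) == str(self.later):
            raise ValueError("earlier and later survey ids must differ")


@dataclass
class PipelineResult:
    """Bundle of test results, ordination and guild abundance summary."""

    results: list[PermTestResult]
    nmds: "object"
    guild_abundance: pd.DataFrame
    paths: dict[str, Path] = field(default_factory=dict)


#: Pipeline overlap statistic → petraitis_overlap mode. The directed
#: overlap of the later diet on the earlier baseline is the default: it
#: stays finite whenever the later survey's exploited taxa are nested in
#: the earlier survey's (the usual case when the follow-up sample is
#: smaller), whereas the symmetrized value collapses to 0 as soon as
#: either survey has an exclusive taxon.
OVERLAP_MODES = {
    "later_on_earlier": "A_on_B",
    "earlier_on_later": "B_on_A",
    "geometric_mean": "geometric_mean",
}


def _overlap_statistic(later_idx: int, earlier_idx: int, mode: str):
    petraitis_mode = OVERLAP_MODES[mode]

    def stat(cm: CountMatrix) -> float:
        c = cm.counts.astype(float)
        totals = c.sum(axis=0)
        p_l = c[:, later_idx] / totals[later_idx]
        p_e = c[:, earlier_idx] / totals[earlier_idx]
        return petraitis_overlap(p_l, p_e, petraitis_mode).value

    return stat


def analyze(
    surveys: Sequence[Survey],
    counts: CountMatrix,
    guilds: GuildMap,
    earlier: str,
    later: str,
    null: NullConfig | None = None,
    *,
    alternatives: Mapping[str, str] | None = None,
    overlap_mode: str = "later_on_earlier",
    randomize_guilds_from_taxa: bool = False,
    nmds_starts: int = 20,
    nmds_max_iter: int = 500,
    nmds_tol: float = 1e-6,
) -> PipelineResult:
    """Run the five permutation tests and the NMDS on in-memory data.

    A single master seed (``null.seed``) drives everything: per-feature
    replicate streams and the NMDS random starts are derived from it
    deterministically, so a run is bit-reproducible.
    """
    if str(earlier) == str(later):
        raise ValueError("earlier and later survey ids must differ")
    null = null or NullConfig()
    if overlap_mode not in OVERLAP_MODES:
        raise ValueError(f"overlap_mode must be one of {sorted(OVERLAP_MODES)}")
    alts = dict(_DEFAULT_ALTERNATIVES)
    if alternatives:
        unknown = set(alternatives) - set(FEATURE_LABELS)
        if unknown:
            raise ValueError(f"unknown feature labels: {sorted(unknown)}")
        alts.update(alternatives)

    master = np.random.default_rng(null.seed)
    child_seeds = master.integers(0, 2**31 - 1, size=len(FEATURE_LABELS) + 1)

    later_idx = counts.survey_index(later)
    earlier_idx = counts.survey_index(earlier)
    pellets = {s.id: s.pellet_count for s in surveys}
    for sid in counts.surveys:
        if sid not in pellets:
            raise ValueError(f"survey {sid!r} has no metadata row")
    p_later, p_earlier = float(pellets[later]), float(pellets[earlier])

    guild_counts = aggregate_guilds(counts, guilds)
    gi = {g: i for i, g in enumerate(guild_counts.taxa)}

    results: list[PermTestResult] = []
    for k, label in enumerate(FEATURE_LABELS):
        cfg = replace(null, seed=int(child_seeds[k]))
        if label == "Prey taxon evenness":
            target, stat = counts, (
                lambda cm: evenness_difference(cm, later, earlier)
            )
        elif label == "Food niche overlap":
            target, stat = counts, _overlap_statistic(later_idx, earlier_idx, overlap_mode)
        else:
            g = _GUILD_FOR_LABEL[label]
            if randomize_guilds_from_taxa:
                target = counts
                guild_rows = np.array([gi[guilds[t]] for t in counts.taxa])

                def stat(cm: CountMatrix, _g=g, _rows=guild_rows) -> float:
                    sums = np.zeros(3)
                    np.add.at(
                        sums, _rows,
                        cm.counts[:, later_idx] / p_later
                        - cm.counts[:, earlier_idx] / p_earlier,
                    )
                    return float(sums[gi[_g]])
            else:
                target = guild_counts

                def stat(cm: CountMatrix, _i=gi[g]) -> float:
                    return float(
                        cm.counts[_i, later_idx] / p_later
                        - cm.counts[_i, earlier_idx] / p_earlier
                    )
        results.append(
            paired_permutation_test(target, stat, cfg, alts[label], label)
        )

    abund = per_pellet_abundance(counts, surveys)
    ord_res = nmds(
        euclidean_distances(abund),
        n_starts=nmds_starts,
        max_iter=nmds_max_iter,
        tol=nmds_tol,
        seed=int(child_seeds[-1]),
    )

    guild_abund = per_pellet_abundance(guild_counts, surveys)
    summary = pd.DataFrame(
        {
            "guild": list(guild_counts.taxa),
            f"abundance_{earlier}": guild_abund.values[:, earlier_idx],
            f"abundance_{later}": guild_abund.values[:, later_idx],
            "difference": guild_abund.values[:, later_idx]
            - guild_abund.values[:, earlier_idx],
        }
    )
    return PipelineResult(results=results, nmds=ord_res, guild_abundance=summary)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Load inputs, run the analysis and write the result files.

    Writes ``results.tsv``, ``nmds_coords.csv``, ``guild_abundance.csv``
    and ``run.log`` into ``config.out_dir``.
    """
    surveys = data_io.read_surveys(config.surveys_path)
    ids = [s.id for s in surveys]
    for which, sid in (("earlier", config.earlier), ("later", config.later)):
        if str(sid) not in ids:
            raise ValueError(f"{which} survey {sid!r} not present in surveys file")
    counts = data_io.read_counts(config.counts_path, surveys)
    if config.subfamily_map_path is not None:
        counts = aggregate_to_subfamily(
            counts, data_io.read_subfamily_map(config.subfamily_map_path)
        )
    guilds = data_io.read_guild_map(config.guilds_path)

    result = analyze(
        surveys,
        counts,
        guilds,
        str(config.earlier),
        str(config.later),
        config.null,
        nmds_starts=config.nmds_starts,
        nmds_max_iter=config.nmds_max_iter,
        nmds_tol=config.nmds_tol,
    )

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "results": out / "results.tsv",
        "nmds": out / "nmds_coords.csv",
        "guilds": out / "guild_abundance.csv",
        "log": out / "run.log",
    }
    data_io.write_results_table(result.results, paths["results"])
    coords = pd.DataFrame(
        result.nmds.coordinates, columns=["nmds1", "nmds2"]
    ).assign(taxon=list(result.nmds.labels))[["taxon", "nmds1", "nmds2"]]
    coords.to_csv(paths["nmds"], index=False)
    result.guild_abundance.to_csv(paths["guilds"], index=False)
    paths["log"].write_text(
        "\n".join(
            [
                f"surveys: {config.surveys_path}",
                f"counts: {config.counts_path}",
                f"guilds: {config.guilds_path}",
                f"earlier: {config.earlier}",
                f"later: {config.later}",
                f"null_variant: {config.null.variant}",
                f"n_perm: {config.null.n_perm}",
                f"seed: {config.null.seed}",
                f"nmds_stress: {result.nmds.stress:.6e}",
                f"nmds_converged: {result.nmds.converged}",
            ]
        )
        + "\n",
        encoding="utf-8",
    )
    result.paths = paths
    return result
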