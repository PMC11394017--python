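"""Readers, writers and the core containers for paired pellet-survey data.

The central object is :class:`CountMatrix`, a dense taxa-by-surveys table of
integer prey counts (the resource-utilization matrix that the null models
randomize). Input files are tidy (long-format) CSV; results go out as TSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GUILDS",
    "Survey",
    "CountMatrix",
    "GuildMap",
    "read_surveys",
    "read_counts",
    "read_guild_map",
    "read_subfamily_map",
    "write_results_table",
]

#: The closed feeding-guild vocabulary for micromammal prey.
GUILDS = ("insectivore", "herbivore", "omnivore")


@dataclass(frozen=True)
class Survey:
    """One pellet-collection survey.

    Parameters
    ----------
    id :
        Short label, e.g. ``"2004"``. Unique within a study.
    year :
        Calendar year of collection.
    pellet_count :
        Number of pellets examined (``P_j``); the denominator of every
        per-pellet abundance. Must be at least 1.
    """

    id: str
    year: int
    pellet_count: int

    def __post_init__(self) -> None:
        if self.pellet_count < 1:
            raise ValueError("pellet_count must be ≥ 1")


class CountMatrix:
    """Dense taxa × surveys matrix of non-negative integer prey counts.

    Rows are prey taxa (resource categories), columns are surveys. Taxon
    rows that are zero in every survey are rejected — an entirely unused
    category is not part of the observed resource spectrum — unless
    ``allow_zero_rows`` is set (guild matrices keep empty guilds so that
    the three guild tests always exist).
    """

    def __init__(
        self,
        taxa: Sequence[str],
        surveys: Sequence[str],
        counts: np.ndarray,
        *,
        allow_zero_rows: bool = False,
        validate: bool = True,
    ) -> None:
        self.taxa: tuple[str, ...] = tuple(str(t) for t in taxa)
        self.surveys: tuple[str, ...] = tuple(str(s) for s in surveys)
        counts = np.asarray(counts)
        if validate:
            if counts.shape != (len(self.taxa), len(self.surveys)):
                raise ValueError(
                    f"counts shape {counts.shape} does not match "
                    f"{len(self.taxa)} taxa × {len(self.surveys)} surveys"
                )
            if len(set(self.taxa)) != len(self.taxa):
                raise ValueError("duplicate taxon labels")
            if len(set(self.surveys)) != len(self.surveys):
                raise ValueError("duplicate survey ids")
            if not np.issubdtype(counts.dtype, np.integer):
                rounded = np.rint(counts)
                if not np.array_equal(rounded, counts):
                    raise ValueError("counts must be integers")
                counts = rounded
            if (counts < 0).any():
                raise ValueError("counts must be non-negative")
            row_tot = counts.sum(axis=1)
            if not allow_zero_rows and (row_tot == 0).any():
                bad = [t for t, r in zip(self.taxa, row_tot) if r == 0]
                raise ValueError(f"all-zero taxon rows: {bad}")
            if (counts.sum(axis=0) < 1).any():
                bad = [s for s, c in zip(self.surveys, counts.sum(axis=0)) if c < 1]
                raise ValueError(f"surveys with zero total count: {bad}")
        self.counts: np.ndarray = counts.astype(np.int64, copy=False)

    # -- convenience views -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def column_totals(self) -> np.ndarray:
        """Total prey individuals per survey (``N_j``)."""
        return self.counts.sum(axis=0)

    def survey_index(self, survey_id: str) -> int:
        try:
            return self.surveys.index(str(survey_id))
        except ValueError:
            raise KeyError(f"unknown survey id: {survey_id!r}") from None

    def taxon_index(self, taxon: str) -> int:
        try:
            return self.taxa.index(taxon)
        except ValueError:
            raise KeyError(f"unknown taxon: {taxon!r}") from None

    def column(self, survey_id: str) -> np.ndarray:
        return self.counts[:, self.survey_index(survey_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.taxa), columns=list(self.surveys))

    def to_long_frame(self) -> pd.DataFrame:
        """Tidy long view with columns ``survey, taxon, count`` (zeros kept)."""
        rows = [
            (s, t, int(self.counts[i, j]))
            for j, s in enumerate(self.surveys)
            for i, t in enumerate(self.taxa)
        ]
        return pd.DataFrame(rows, columns=["survey", "taxon", "count"])

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"CountMatrix({len(self.taxa)} taxa × {len(self.surveys)} surveys)"


@dataclass
class GuildMap:
    """Mapping from taxon label to one of the three feeding guilds."""

    mapping: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cleaned: dict[str, str] = {}
        for taxon, guild in self.mapping.items():
            g = str(guild).strip().lower()
            if g not in GUILDS:
                raise ValueError(
                    f"unknown guild {guild!r} for taxon {taxon!r}; "
                    f"allowed guilds: {', '.join(GUILDS)}"
                )
            cleaned[str(taxon)] = g
        self.mapping = cleaned

    def __getitem__(self, taxon: str) -> str:
        try:
            return self.mapping[taxon]
        except KeyError:
            raise KeyError(f"taxon {taxon!r} has no guild assignment") from None

    def __contains__(self, taxon: str) -> bool:
        return taxon in self.mapping

    def __len__(self) -> int:
        return len(self.mapping)


# ---------------------------------------------------------------------------
# readers


def _read_csv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    return df


def _as_int(value: str, what: str) -> int:
    try:
        f = float(value)
    except ValueError:
        raise ValueError(f"{what} must be an integer, got {value!r}") from None
    if f != int(f):
        raise ValueError(f"{what} must be an integer, got {value!r}")
    return int(f)


def read_surveys(path: str | Path) -> list[Survey]:
    """Read a survey metadata table (``survey,year,pellets``).

    Returns one :class:`Survey` per row, preserving file order.
    """
    df = _read_csv(path, ["survey", "year", "pellets"])
    surveys: list[Survey] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        sid = str(row["survey"]).strip()
        if sid in seen:
            raise ValueError(f"duplicate survey id: {sid!r}")
        seen.add(sid)
        pellets = _as_int(row["pellets"], f"pellets for survey {sid!r}")
        if pellets < 1:
            raise ValueError("pellet_count must be ≥ 1")
        surveys.append(Survey(id=sid, year=_as_int(row["year"], "year"), pellet_count=pellets))
    return surveys


def read_counts(path: str | Path, surveys: Sequence[Survey]) -> CountMatrix:
    """Read long-format prey counts (``survey,taxon,count``) into a dense matrix.

    Absent (survey, taxon) pairs become zeros; duplicated pairs are an
    error rather than being silently summed, so the number of unexploited
    categories per survey is well defined. Taxa are ordered by first
    appearance in the file; survey order follows ``surveys``.
    """
    df = _read_csv(path, ["survey", "taxon", "count"])
    survey_ids = [s.id for s in surveys]
    known = set(survey_ids)

    taxa: list[str] = []
    cells: dict[tuple[str, str], int] = {}
    for _, row in df.iterrows():
        sid = str(row["survey"]).strip()
        taxon = str(row["taxon"]).strip()
        if sid not in known:
            raise ValueError(f"unknown survey id {sid!r} in counts file")
        n = _as_int(row["count"], f"count for ({sid}, {taxon})")
        if n < 0:
            raise ValueError(f"negative count for ({sid}, {taxon})")
        key = (taxon, sid)
        if key in cells:
            raise ValueError(f"duplicate (survey, taxon) pair: ({sid}, {taxon})")
        cells[key] = n
        if taxon not in taxa:
            taxa.append(taxon)

    counts = np.zeros((len(taxa), len(survey_ids)), dtype=np.int64)
    for (taxon, sid), n in cells.items():
        counts[taxa.index(taxon), survey_ids.index(sid)] = n
    zero_rows = [t for t, tot in zip(taxa, counts.sum(axis=1)) if tot == 0]
    if zero_rows:
        raise ValueError(f"all-zero taxon rows: {zero_rows}")
    return CountMatrix(taxa, survey_ids, counts)


def read_guild_map(path: str | Path) -> GuildMap:
    """Read a taxon → feeding-guild table (``taxon,guild``).

    Guild labels are validated case-insensitively against the closed
    vocabulary ``insectivore / herbivore / omnivore``.
    """
    df = _read_csv(path, ["taxon", "guild"])
    mapping: dict[str, str] = {}
    for _, row in df.iterrows():
        taxon = str(row["taxon"]).strip()
        if taxon in mapping:
            raise ValueError(f"duplicate taxon in guild map: {taxon!r}")
        mapping[taxon] = str(row["guild"]).strip()
    return GuildMap(mapping)


def read_subfamily_map(path: str | Path) -> dict[str, str]:
    """Read an optional raw-item → subfamily table (``item,subfamily``)."""
    df = _read_csv(path, ["item", "subfamily"])
    mapping: dict[str, str] = {}
    for _, row in df.iterrows():
        item = str(row["item"]).strip()
        if item in mapping:
            raise ValueError(f"duplicate item in subfamily map: {item!r}")
        mapping[item] = str(row["subfamily"]).strip()
    return mapping


# ---------------------------------------------------------------------------
# writers


def write_results_table(results: Iterable, path: str | Path) -> None:
    """Write permutation-test results as TSV.

    Columns: feature, observed, null_mean, ses, p, significant. Observed
    and null-mean differences print to 5 decimals, effect sizes to 3 and
    p-values to 4, matching the usual reporting precision for these
    statistics.
    """
    results = list(results)
    if not results:
        raise ValueError("nothing to write: empty results")
    path = Path(path)
    lines = ["feature\tobserved\tnull_mean\tses\tp\tsignificant"]
    for r in results:
        lines.append(
            f"{r.feature}\t{r.observed:.5f}\t{r.null_mean:.5f}"
            f"\t{r.ses:.3f}\t{r.p:.4f}\t{r.significant}"
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
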