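"""Occurrence records, decade occasions, and detection histories.

Dated species-occurrence records (one row per record: species, locality,
country, year) are the raw material of the decline analysis.  Localities are
treated as the "individuals" of a capture-recapture study: a locality's record
years are binned into decade occasions, and the resulting binary detection
history is the input to the Cormack-Jolly-Seber engine.
"""

from __future__ import annotations

import csv
import io
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OccurrenceRecord",
    "RecordSet",
    "OccasionGrid",
    "DetectionHistorySet",
    "SummaryCounts",
    "ConfigurationError",
    "DEFAULT_COLUMNS",
    "read_records",
    "filter_by_years",
    "count_species_records",
    "build_detection_histories",
    "summarize",
]

#: canonical column names of a RecordSet frame
DEFAULT_COLUMNS = ("species", "locality_id", "country", "year")

#: calendar years accepted as plausible observation dates
YEAR_BOUNDS = (1700, 2100)


class ConfigurationError(KeyError):
    """A configured column or option does not match the input."""


class OccurrenceRecord(NamedTuple):
    """A single dated (or undated) observation of a species at a locality."""

    species: str
    locality_id: str
    country: str
    year: int | None


class RecordSet:
    """An ordered collection of occurrence records.

    Thin wrapper around a :class:`pandas.DataFrame` with the canonical columns
    ``species``, ``locality_id``, ``country``, ``year`` (nullable integer).
    Undated records are kept for audit but excluded from all year-based
    analyses.
    """

    def __init__(self, frame: pd.DataFrame, provenance: str = ""):
        missing = [c for c in DEFAULT_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"record frame lacks columns {missing}")
        frame = frame.loc[:, list(DEFAULT_COLUMNS)].reset_index(drop=True)
        frame["species"] = frame["species"].astype(str)
        frame["locality_id"] = frame["locality_id"].astype(str)
        frame["country"] = frame["country"].astype(str)
        frame["year"] = pd.to_numeric(frame["year"], errors="coerce").astype("Int64")
        if len(frame):
            if (frame["species"].str.len() == 0).any():
                raise ValueError("empty species name in records")
            if (frame["locality_id"].str.len() == 0).any():
                raise ValueError("empty locality_id in records")
        lo, hi = YEAR_BOUNDS
        bad = frame["year"].notna() & ~frame["year"].between(lo, hi)
        if bad.any():
            warnings.warn(
                f"{int(bad.sum())} record(s) with year outside [{lo}, {hi}] "
                "treated as undated",
                stacklevel=2,
            )
            frame.loc[bad, "year"] = pd.NA
        self.frame = frame
        self.provenance = provenance

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.frame)

    def __iter__(self):
        for row in self.frame.itertuples(index=False):
            year = None if pd.isna(row.year) else int(row.year)
            yield OccurrenceRecord(row.species, row.locality_id, row.country, year)

    def __eq__(self, other) -> bool:
        if not isinstance(other, RecordSet):
            return NotImplemented
        return self.frame.equals(other.frame)

    def __repr__(self) -> str:
        return (
            f"<RecordSet n={len(self)} dated={self.n_dated} "
            f"localities={self.n_localities} provenance={self.provenance!r}>"
        )

    # -- derived counts -----------------------------------------------------
    @property
    def n_dated(self) -> int:
        return int(self.frame["year"].notna().sum())

    @property
    def n_undated(self) -> int:
        return len(self) - self.n_dated

    @property
    def n_localities(self) -> int:
        return int(self.frame["locality_id"].nunique())

    @property
    def species(self) -> list[str]:
        return sorted(self.frame["species"].unique())

    # -- construction / IO --------------------------------------------------
    @classmethod
    def from_records(
        cls, records: Iterable[OccurrenceRecord], provenance: str = ""
    ) -> "RecordSet":
        frame = pd.DataFrame(list(records), columns=list(DEFAULT_COLUMNS))
        return cls(frame, provenance=provenance)

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        out = {
            "provenance": self.provenance,
            "records": [
                {**r._asdict()} for r in self
            ],
        }
        Path(path).write_text(json.dumps(out, indent=1))

    def subset(self, mask) -> "RecordSet":
        return RecordSet(self.frame.loc[mask], provenance=self.provenance)


@dataclass(frozen=True)
class OccasionGrid:
    """Contiguous, equal-width year bins used as capture occasions.

    The default study window 1900-2019 with ``bin_width=10`` gives the twelve
    calendar decades 1900-1909, ..., 2010-2019, both bounds inclusive.
    """

    start_year: int
    end_year: int
    bin_width: int = 10

    def __post_init__(self):
        span = self.end_year - self.start_year + 1
        if span <= 0:
            raise ValueError("end_year must be >= start_year")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if span % self.bin_width:
            raise ValueError(
                f"window span {span} not divisible by bin_width {self.bin_width}"
            )

    @property
    def n_occasions(self) -> int:
        return (self.end_year - self.start_year + 1) // self.bin_width

    @property
    def occasions(self) -> list[tuple[int, int]]:
        w = self.bin_width
        return [
            (self.start_year + i * w, self.start_year + (i + 1) * w - 1)
            for i in range(self.n_occasions)
        ]

    @property
    def labels(self) -> list[str]:
        return [f"{lo}-{hi}" for lo, hi in self.occasions]

    def index_of(self, year: int) -> int:
        """0-based occasion index containing ``year``; raises if outside."""
        if not self.start_year <= year <= self.end_year:
            raise ValueError(f"year {year} outside grid {self.start_year}-{self.end_year}")
        return (year - self.start_year) // self.bin_width


#: the study's analysis window: 12 decade occasions, 1900-2019
DEFAULT_GRID = OccasionGrid(1900, 2019, 10)


@dataclass
class DetectionHistorySet:
    """Per-locality binary detection vectors over decade occasions.

    ``matrix`` is (n_histories, T) of 0/1; every row has at least one 1.
    ``strata`` optionally carries one label row per history (species, country).
    """

    occasions: OccasionGrid
    matrix: np.ndarray
    locality_ids: list[str]
    strata: pd.DataFrame | None = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        if self.matrix.ndim != 2:
            raise ValueError("history matrix must be 2-D")
        if self.matrix.shape[1] != self.occasions.n_occasions:
            raise ValueError("history length does not match occasion grid")
        if len(self.locality_ids) != self.matrix.shape[0]:
            raise ValueError("locality_ids misaligned with matrix")
        if self.matrix.shape[0] and not self.matrix.any(axis=1).all():
            raise ValueError("every detection history must contain a detection")

    @property
    def n_histories(self) -> int:
        return self.matrix.shape[0]

    @property
    def T(self) -> int:
        return self.occasions.n_occasions

    def for_stratum(self, **labels) -> "DetectionHistorySet":
        """Subset to histories whose stratum columns equal ``labels``."""
        if self.strata is None:
            raise ValueError("histories carry no strata")
        mask = np.ones(self.n_histories, dtype=bool)
        for col, val in labels.items():
            mask &= (self.strata[col] == val).to_numpy()
        return DetectionHistorySet(
            self.occasions,
            self.matrix[mask],
            [lid for lid, m in zip(self.locality_ids, mask) if m],
            self.strata.loc[mask].reset_index(drop=True),
        )

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(self.matrix, columns=self.occasions.labels)
        out.insert(0, "locality_id", self.locality_ids)
        if self.strata is not None:
            for i, col in enumerate(self.strata.columns):
                out.insert(1 + i, col, self.strata[col].to_numpy())
        return out


@dataclass
class SummaryCounts:
    """Record and locality tallies, overall and per species / country."""

    n_records: int
    n_dated_records: int
    n_localities: int
    per_species: pd.DataFrame  # index species; columns records, localities
    per_country: pd.DataFrame

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "n_records": self.n_records,
            "n_dated_records": self.n_dated_records,
            "n_localities": self.n_localities,
            "per_species": self.per_species.to_dict(orient="index"),
            "per_country": self.per_country.to_dict(orient="index"),
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


# ---------------------------------------------------------------------------
# operations


def _sniff_delimiter(sample: str) -> str:
    try:
        return csv.Sniffer().sniff(sample, delimiters=",;\t").delimiter
    except csv.Error:
        return ","


def read_records(
    source,
    column_map: Mapping[str, str] | None = None,
    delimiter: str | None = None,
    provenance: str = "",
) -> RecordSet:
    """Read a delimited-text table of occurrence records.

    Parameters
    ----------
    source
        Path or text stream with a header row.
    column_map
        Maps canonical field names (``species``, ``locality_id``, ``country``,
        ``year``) to the column names used in the file.  Defaults to identity.
    delimiter
        Field delimiter; auto-detected among comma / semicolon / tab if None.

    Unparseable year cells are stored as missing and the row is retained; a
    warning reports how many rows were affected.
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text(encoding="utf-8")
        if not provenance:
            provenance = str(source)
    else:
        text = source.read()
    if not text.strip():
        warnings.warn("empty occurrence file; returning empty RecordSet", stacklevel=2)
        return RecordSet(pd.DataFrame(columns=list(DEFAULT_COLUMNS)), provenance)

    if delimiter is None:
        delimiter = _sniff_delimiter(text.splitlines()[0])
    raw = pd.read_csv(io.StringIO(text), sep=delimiter, dtype=str, keep_default_na=False)

    cmap = dict(zip(DEFAULT_COLUMNS, DEFAULT_COLUMNS))
    if column_map:
        cmap.update(column_map)
    for canonical, name in cmap.items():
        if name not in raw.columns:
            raise ConfigurationError(
                f"mapped column {name!r} (for {canonical!r}) not found in header "
                f"{list(raw.columns)}"
            )
    frame = pd.DataFrame(
        {canonical: raw[name] for canonical, name in cmap.items()}
    )
    years = pd.to_numeric(frame["year"].replace("", None), errors="coerce")
    n_bad = int(years.isna().sum()) - int(frame["year"].replace("", None).isna().sum())
    if n_bad > 0:
        warnings.warn(
            f"{n_bad} unparseable year cell(s) stored as missing", stacklevel=2
        )
    frame["year"] = years
    rs = RecordSet(frame, provenance=provenance)
    assert len(rs) == len(raw), "row count must be preserved"
    return rs


def filter_by_years(rs: RecordSet, min_year: int, max_year: int) -> RecordSet:
    """Keep dated records with ``min_year <= year <= max_year`` (inclusive).

    Undated records are dropped: the analysis window is defined on observation
    dates only.
    """
    if min_year > max_year:
        raise ValueError(f"inverted year window [{min_year}, {max_year}]")
    y = rs.frame["year"]
    return rs.subset(y.notna() & y.between(min_year, max_year))


def count_species_records(rs: RecordSet, species: str) -> int:
    """Number of records whose species label matches ``species`` exactly."""
    return int((rs.frame["species"] == species).sum())


def build_detection_histories(
    rs: RecordSet,
    grid: OccasionGrid = DEFAULT_GRID,
    stratify_by: Sequence[str] | None = None,
) -> DetectionHistorySet:
    """Bin records into decade occasions, one binary history per locality.

    The occasion bit is 1 iff at least one record of that locality (within its
    stratum, if ``stratify_by`` is given) falls in the decade; multiple records
    in one decade collapse to a single detection.  All records must be dated
    and inside the grid span — apply :func:`filter_by_years` first.
    """
    frame = rs.frame
    undated = frame["year"].isna()
    outside = frame["year"].notna() & ~frame["year"].between(
        grid.start_year, grid.end_year
    )
    bad = undated | outside
    if bad.any():
        rows = frame.index[bad].tolist()
        raise ValueError(
            f"{int(bad.sum())} record(s) undated or outside grid "
            f"{grid.start_year}-{grid.end_year}: rows {rows[:20]}"
        )
    strat_cols = list(stratify_by) if stratify_by else []
    for col in strat_cols:
        if col not in frame.columns:
            raise ConfigurationError(f"unknown stratification column {col!r}")

    T = grid.n_occasions
    if not len(frame):
        strata = pd.DataFrame(columns=strat_cols) if strat_cols else None
        return DetectionHistorySet(grid, np.zeros((0, T), dtype=np.int8), [], strata)

    occ = ((frame["year"].astype(int) - grid.start_year) // grid.bin_width).to_numpy()
    keys = frame[strat_cols + ["locality_id"]].copy()
    keys["occ"] = occ
    # sort for record-order invariance
    groups = keys.drop_duplicates().sort_values(strat_cols + ["locality_id", "occ"])
    units = groups[strat_cols + ["locality_id"]].drop_duplicates()
    index = {tuple(u): i for i, u in enumerate(units.itertuples(index=False))}
    matrix = np.zeros((len(units), T), dtype=np.int8)
    for row in groups.itertuples(index=False):
        matrix[index[tuple(row)[:-1]], row.occ] = 1
    strata = (
        units[strat_cols].reset_index(drop=True) if strat_cols else None
    )
    return DetectionHistorySet(
        grid, matrix, units["locality_id"].tolist(), strata
    )


def summarize(rs: RecordSet) -> SummaryCounts:
    """Exact distinct-count tallies overall and per species / country.

    Total locality and dated-record counts are reported independently (no
    cross-tabulation is implied between them).
    """
    frame = rs.frame

    def _table(col: str) -> pd.DataFrame:
        if not len(frame):
            return pd.DataFrame(columns=["records", "localities"])
        out = frame.groupby(col).agg(
            records=("locality_id", "size"),
            localities=("locality_id", "nunique"),
        )
        out.index.name = col
        return out

    return SummaryCounts(
        n_records=len(frame),
        n_dated_records=rs.n_dated,
        n_localities=rs.n_localities,
        per_species=_table("species"),
        per_country=_table("country"),
    )
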