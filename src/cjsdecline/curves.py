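"""Cumulative-locality decline curves.

The naive (detection-uncorrected) view of decline: for each decade d, count
the localities with at least one record in d *or any later decade*.  Read
forward in time the curve can only fall, and its relative version (percent of
the earliest-decade count) summarises how much of the historically known range
is still confirmed.  The curve confounds true population loss with changes in
recording effort and with colonisation of new sites — correcting for those is
the job of the CJS engine.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .records import OccasionGrid, RecordSet, DEFAULT_GRID

__all__ = [
    "DeclineCurve",
    "cumulative_locality_curve",
    "relative_decline",
    "localities_confirmed_after",
]


@dataclass
class DeclineCurve:
    """Cumulative locality counts per decade, earliest decade first."""

    decades: list[str]
    cumulative_counts: np.ndarray
    relative_percent: np.ndarray | None = None
    stratum: str = "all"

    def __post_init__(self):
        c = np.asarray(self.cumulative_counts, dtype=float)
        if len(c) != len(self.decades):
            raise ValueError("counts misaligned with decade labels")
        if np.any(np.diff(c) > 0):
            raise ValueError("cumulative counts must be non-increasing in time")
        self.cumulative_counts = c

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "decade": self.decades,
                "stratum": self.stratum,
                "absolute": self.cumulative_counts.astype(int),
            }
        )
        if self.relative_percent is not None:
            out["relative"] = self.relative_percent
        return out

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def cumulative_locality_curve(
    rs: RecordSet, grid: OccasionGrid = DEFAULT_GRID, stratum: str = "all"
) -> DeclineCurve:
    """C(d) = number of distinct localities recorded in decade d or later.

    Equivalently: start from the localities of the most recent decade and,
    walking backwards, add every locality whose *last* record falls in each
    earlier decade.  Records outside the grid span are ignored.
    """
    frame = rs.frame
    dated = frame[frame["year"].notna()]
    dated = dated[dated["year"].between(grid.start_year, grid.end_year)]
    T = grid.n_occasions
    counts = np.zeros(T, dtype=int)
    if len(dated):
        last_occ = (
            (dated["year"].astype(int) - grid.start_year) // grid.bin_width
        ).groupby(dated["locality_id"].to_numpy()).max()
        added = np.bincount(last_occ.to_numpy(), minlength=T)
        # localities whose final record is in decade d or later
        counts = added[::-1].cumsum()[::-1]
    return DeclineCurve(grid.labels, counts, stratum=stratum)


def relative_decline(curve: DeclineCurve) -> DeclineCurve:
    """Fill ``relative_percent`` = 100 * C(d) / C(earliest decade)."""
    c0 = curve.cumulative_counts[0]
    if c0 <= 0:
        raise ValueError("relative decline undefined for an all-zero curve")
    return DeclineCurve(
        curve.decades,
        curve.cumulative_counts,
        relative_percent=100.0 * curve.cumulative_counts / c0,
        stratum=curve.stratum,
    )


def localities_confirmed_after(rs: RecordSet, year: int) -> int:
    """Distinct localities with at least one dated record strictly after ``year``."""
    frame = rs.frame
    recent = frame[frame["year"].notna() & (frame["year"] > year)]
    return int(recent["locality_id"].nunique())
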