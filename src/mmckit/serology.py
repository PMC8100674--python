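"""First-trimester serology expressed as multiples of the median (MoM).

PAPP-A and free beta-hCG concentrations vary strongly with gestational age, so
screening programmes normalise each measurement by the median concentration of
unaffected pregnancies at the same gestational day: MoM = raw / median(day).
The reference median table is an external input; medians between tabulated
days are linearly interpolated.

Samples conceived by assisted reproduction (ART) can be flagged and excluded,
since ART alters first-trimester marker levels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import MissingColumnError, NonPositiveError, OutOfWindowError

#: default screening window, days of amenorrhea (12 +/- 2 weeks)
SCREEN_WINDOW_DAYS = (70, 98)


class MedianTable:
    """Gestational-day -> median concentration lookup with interpolation."""

    def __init__(self, days, medians):
        days = np.asarray(days, dtype=float)
        medians = np.asarray(medians, dtype=float)
        if days.size < 2:
            raise ValueError("median table needs >=2 tabulated days")
        order = np.argsort(days)
        self.days = days[order]
        self.medians = medians[order]
        if np.any(self.medians <= 0):
            raise NonPositiveError("median table has non-positive medians")

    @classmethod
    def from_csv(cls, path: str | Path) -> "MedianTable":
        df = pd.read_csv(path)
        for c in ("gestational_day", "median"):
            if c not in df.columns:
                raise MissingColumnError(f"median table lacks column {c!r}")
        return cls(df["gestational_day"], df["median"])

    def median_at(self, gestational_day: float) -> float:
        d = float(gestational_day)
        if d < self.days[0] or d > self.days[-1]:
            raise OutOfWindowError(
                f"gestational day {d} outside table range "
                f"[{self.days[0]}, {self.days[-1]}]"
            )
        return float(np.interp(d, self.days, self.medians))


def synthetic_median_table(analyte: str = "PAPPA") -> MedianTable:
    """A smooth, monotone stand-in median table for testing only.

    Synthetic and non-clinical: real screening uses laboratory- and
    population-specific reference medians.  PAPP-A medians rise through the
    first trimester; free beta-hCG medians fall.
    """
    days = np.arange(SCREEN_WINDOW_DAYS[0], SCREEN_WINDOW_DAYS[1] + 1, dtype=float)
    if analyte.upper() == "PAPPA":
        medians = 1.0 * np.exp(0.035 * (days - days[0]))  # IU/L, rising
    else:
        medians = 80.0 * np.exp(-0.02 * (days - days[0]))  # IU/L, falling
    return MedianTable(days, medians)


def weeks_to_days(weeks: float) -> float:
    return weeks * 7.0


def compute_mom(raw: float, gestational_day: float, table: MedianTable) -> float:
    """MoM of one measurement: raw concentration over the same-day median."""
    if raw <= 0:
        raise NonPositiveError(f"non-positive concentration {raw}")
    return raw / table.median_at(gestational_day)


@dataclass
class ARTExclusion:
    records: pd.DataFrame
    n_excluded: int


def flag_art_exclusion(records: pd.DataFrame) -> ARTExclusion:
    """Drop ART-conceived records; reports how many were excluded."""
    if "art_conception" not in records.columns:
        raise MissingColumnError("records lack column 'art_conception'")
    mask = records["art_conception"].astype(bool)
    kept = records.loc[~mask].copy()
    if kept.empty and len(records):
        warnings.warn("all records were ART-conceived; nothing retained")
    return ARTExclusion(records=kept, n_excluded=int(mask.sum()))


SEROLOGY_COLUMNS = ["sample_id", "analyte", "raw", "gestational_day", "art_conception"]


def read_serology(
    path: str | Path,
    tables: Optional[dict[str, MedianTable]] = None,
) -> pd.DataFrame:
    """Read a serology CSV and append a ``mom`` column per record.

    ``tables`` maps analyte name (PAPPA, BHCG) to its median table; the
    synthetic non-clinical defaults are used when not given.
    """
    df = pd.read_csv(path)
    missing = [c for c in SEROLOGY_COLUMNS if c not in df.columns]
    if missing:
        raise MissingColumnError(f"serology file lacks columns {missing}")
    if tables is None:
        tables = {a: synthetic_median_table(a) for a in df["analyte"].unique()}
    df["mom"] = [
        compute_mom(r.raw, r.gestational_day, tables[r.analyte])
        for r in df.itertuples()
    ]
    return df


def mom_wide(serology: pd.DataFrame) -> pd.DataFrame:
    """Pivot long serology records to one row per sample with *_mom columns."""
    wide = serology.pivot_table(index="sample_id", columns="analyte",
                                values="mom", aggfunc="first")
    wide.columns = [f"{str(c).lower()}_mom" for c in wide.columns]
    art = serology.groupby("sample_id")["art_conception"].any()
    wide["art_conception"] = art
    return wide.reset_index()
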