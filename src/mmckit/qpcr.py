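"""Genome-equivalent qPCR quantification with explicit detection limits.

Microchimerism is quantified by allele-specific real-time PCR against a
log-linear standard curve.  One genome equivalent (gEq) — the DNA content of
one diploid cell — is fixed at 6.6 pg, wells are loaded at a nominal 20,000
gEq (132 ng) of host DNA, and each sample/compartment is tested in ten
replicate wells.  Quantities are reported as gEq of microchimeric cells per
million host cells (gEq/10^6): one positive genome in one well is 1/20,000 =
0.005% per well, 0.0005% across ten wells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .errors import (
    DegenerateCurveError,
    EmptyPlateError,
    MissingColumnError,
    NegativeMassError,
)

PG_PER_GEQ = 6.6  # DNA mass of one diploid genome equivalent, picograms
NOMINAL_HOST_GEQ_PER_WELL = 20_000.0
DEFAULT_N_REPLICATES = 10
DEFAULT_MAX_CYCLE = 45.0  # Cq beyond this is treated as no amplification
#: slope of an ideal 100%-efficiency curve: -1/log10(2) cycles per log10(gEq)
IDEAL_SLOPE = -1.0 / math.log10(2.0)

#: per-well positivity threshold on the estimated quantity.  The assay's
#: nominal sensitivity is one genome per well, but under realistic Cq noise a
#: single-template well quantifies symmetrically around 1 gEq; 0.5 gEq is the
#: midpoint cut that separates zero from one template without halving the
#: single-genome detection rate.  Configurable wherever it is consumed.
DEFAULT_WELL_THRESHOLD_GEQ = 0.5

HOST_ASSAY = "BGLOBIN"  # reference single-copy assay quantifying total input
COMPARTMENTS = ("WB", "PBMC", "CD3", "CD19", "CD66", "CD34")


@dataclass(frozen=True)
class StandardCurve:
    """Log-linear calibration: Cq = intercept + slope * log10(gEq)."""

    slope: float
    intercept: float  # Cq at 1 gEq
    pg_per_geq: float = PG_PER_GEQ
    r_squared: Optional[float] = None

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise ValueError("standard-curve slope must be negative")
        if self.pg_per_geq <= 0:
            raise ValueError("pg_per_geq must be positive")

    @property
    def efficiency(self) -> float:
        """Amplification efficiency; 1.0 means perfect doubling per cycle."""
        return 10.0 ** (-1.0 / self.slope) - 1.0

    def cq_of(self, geq: float) -> float:
        if geq <= 0:
            raise ValueError("Cq undefined for non-positive quantity")
        return self.intercept + self.slope * math.log10(geq)


DEFAULT_CURVE = StandardCurve(slope=IDEAL_SLOPE, intercept=35.0)


def mass_to_geq(mass_ng: float, pg_per_geq: float = PG_PER_GEQ) -> float:
    """Convert a DNA mass in ng to genome equivalents (132 ng -> 20,000 gEq)."""
    if mass_ng < 0:
        raise NegativeMassError(f"negative DNA mass: {mass_ng} ng")
    return mass_ng * 1000.0 / pg_per_geq


def geq_to_mass(geq: float, pg_per_geq: float = PG_PER_GEQ) -> float:
    """Inverse of :func:`mass_to_geq`; returns ng."""
    if geq < 0:
        raise NegativeMassError(f"negative quantity: {geq} gEq")
    return geq * pg_per_geq / 1000.0


def quantify_well(
    cq: Optional[float],
    curve: StandardCurve,
    max_cycle: float = DEFAULT_MAX_CYCLE,
) -> float:
    """Invert the standard curve for one well; null/late Cq means 0 gEq."""
    if cq is None or (isinstance(cq, float) and math.isnan(cq)) or cq > max_cycle:
        return 0.0
    return 10.0 ** ((cq - curve.intercept) / curve.slope)


def fit_standard_curve(points: Iterable[tuple[float, float]],
                       pg_per_geq: float = PG_PER_GEQ) -> StandardCurve:
    """Least-squares fit of Cq on log10(known gEq) over a dilution series.

    Parameters
    ----------
    points
        Iterable of ``(known_geq, cq)`` with all quantities > 0 and at least
        two distinct quantities.
    """
    pts = [(float(g), float(c)) for g, c in points]
    if len(pts) < 2:
        raise DegenerateCurveError("need at least two calibration points")
    if any(g <= 0 for g, _ in pts):
        raise ValueError("known quantities must be positive")
    if len({g for g, _ in pts}) < 2:
        raise DegenerateCurveError("all calibration quantities identical")
    x = np.log10([g for g, _ in pts])
    y = np.array([c for _, c in pts])
    fit = _sps.linregress(x, y)
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        pg_per_geq=pg_per_geq,
        r_squared=float(fit.rvalue) ** 2,
    )


def detection_limits(n_wells: int, host_geq_per_well: float) -> tuple[float, float]:
    """(per-well, combined) limit of detection as percent of host cells.

    One microchimeric genome among ``host_geq_per_well`` host genomes is the
    smallest detectable signal in one well; replicates divide the combined
    limit accordingly: (10 wells, 20,000 gEq) -> (0.005%, 0.0005%).
    """
    if n_wells < 1:
        raise ValueError("need at least one well")
    if host_geq_per_well <= 0:
        raise ValueError("host gEq per well must be positive")
    per_well = 1.0 / host_geq_per_well * 100.0
    return per_well, per_well / n_wells


def detection_probability(true_frequency: float, n_wells: int,
                          host_geq_per_well: float) -> float:
    """Probability that >=1 microchimeric genome is loaded across all wells.

    Rare microchimeric templates are Poisson-distributed into the reaction
    volume, so P(detect) = 1 - exp(-n_wells * host_geq_per_well * f).
    """
    if not 0.0 <= true_frequency <= 1.0:
        raise ValueError("true_frequency must be in [0, 1]")
    return -math.expm1(-n_wells * host_geq_per_well * true_frequency)


@dataclass
class QuantResult:
    """Per-sample, per-compartment microchimerism quantity with detection metadata."""

    sample_id: str
    compartment: str
    assay: Optional[str]
    target_geq_total: float
    host_geq_total: float
    mmc_per_million: float
    n_wells: int
    n_positive_wells: int
    per_well_lod_percent: float
    combined_lod_percent: float
    positive: bool

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def mmc_as_percent(mmc_per_million: float) -> float:
    """gEq/10^6 expressed as percent of host cells (3021 gEq/10^6 -> 0.3021%)."""
    return mmc_per_million / 1e6 * 100.0


def aggregate_replicates(
    well_geq: Sequence[float],
    host_geq_per_well: float,
    sample_id: str = "",
    compartment: str = "",
    assay: Optional[str] = None,
    positive_well_threshold_geq: float = DEFAULT_WELL_THRESHOLD_GEQ,
) -> QuantResult:
    """Combine replicate wells into one microchimerism quantity.

    ``mmc_per_million`` is the summed target gEq over the summed host gEq,
    scaled to a million host cells.  A well counts as positive when its
    estimated quantity reaches ``positive_well_threshold_geq``; a
    sample/compartment is positive when at least one well is.
    """
    wells = [float(w) for w in well_geq]
    if not wells:
        raise EmptyPlateError(f"no wells for {sample_id}/{compartment}")
    if host_geq_per_well <= 0:
        raise ValueError("host gEq per well must be positive")
    if any(w < 0 for w in wells):
        raise ValueError("negative well quantity")
    n = len(wells)
    target_total = float(sum(wells))
    host_total = n * host_geq_per_well
    per_well_lod, combined_lod = detection_limits(n, host_geq_per_well)
    n_pos = sum(w >= positive_well_threshold_geq for w in wells)
    return QuantResult(
        sample_id=sample_id,
        compartment=compartment,
        assay=assay,
        target_geq_total=target_total,
        host_geq_total=host_total,
        mmc_per_million=target_total / host_total * 1e6,
        n_wells=n,
        n_positive_wells=n_pos,
        per_well_lod_percent=per_well_lod,
        combined_lod_percent=combined_lod,
        positive=n_pos >= 1,
    )


PLATE_COLUMNS = ["sample_id", "compartment", "assay", "replicate", "cq"]


def read_plate(path: str | Path) -> pd.DataFrame:
    """Read a well-level plate CSV; empty cq means no amplification."""
    df = pd.read_csv(path)
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise MissingColumnError(f"plate file lacks columns {missing}")
    df["cq"] = pd.to_numeric(df["cq"], errors="coerce")
    if "host_geq_per_well" not in df.columns:
        df["host_geq_per_well"] = np.nan
    return df


def quantify_plate(
    plate: pd.DataFrame,
    curve: StandardCurve = DEFAULT_CURVE,
    positive_well_threshold_geq: float = DEFAULT_WELL_THRESHOLD_GEQ,
    max_cycle: float = DEFAULT_MAX_CYCLE,
    nominal_host_geq: float = NOMINAL_HOST_GEQ_PER_WELL,
) -> pd.DataFrame:
    """Quantify every (sample, compartment) group of target wells on a plate.

    Host input per well is taken from the reference single-copy (beta-globin)
    wells of the same sample/compartment when present, else from the
    ``host_geq_per_well`` column, else from the nominal 20,000 gEq.
    """
    results = []
    for (sid, comp), grp in plate.groupby(["sample_id", "compartment"], sort=True):
        host_rows = grp[grp["assay"] == HOST_ASSAY]
        target_rows = grp[grp["assay"] != HOST_ASSAY]
        if target_rows.empty:
            continue
        if not host_rows.empty:
            host = float(
                np.mean([quantify_well(c, curve, max_cycle) for c in host_rows["cq"]])
            )
        elif target_rows["host_geq_per_well"].notna().any():
            host = float(target_rows["host_geq_per_well"].dropna().iloc[0])
        else:
            host = nominal_host_geq
        assays = target_rows["assay"].unique()
        assay = assays[0] if len(assays) == 1 else "+".join(sorted(assays))
        geqs = [quantify_well(c, curve, max_cycle) for c in target_rows["cq"]]
        results.append(
            aggregate_replicates(
                geqs,
                host,
                sample_id=str(sid),
                compartment=str(comp),
                assay=assay,
                positive_well_threshold_geq=positive_well_threshold_geq,
            ).as_dict()
        )
    return pd.DataFrame(results)
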