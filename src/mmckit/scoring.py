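"""Per-sample chimerism positivity, mean total MMc and category calls.

A cord-blood sample is *positive* when maternal DNA is detected in at least
one tested compartment (whole blood or a sorted subset).  Its quantitative
score is the mean of the per-subset quantities over the subsets actually
tested, and samples are binned into four categories:

* ``negative`` — no compartment positive;
* ``slight``   — mean total MMc in (0, 10] gEq/10^6;
* ``moderate`` — mean in (10, 100);
* ``high``     — mean >= 100.

Whole blood is excluded from the mean-of-subsets score by default (it is a
mixture of the subsets, not a subset), but this is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .errors import NoCompartmentError

CATEGORIES = ("negative", "slight", "moderate", "high")
SUBSET_COMPARTMENTS = ("PBMC", "CD3", "CD19", "CD66", "CD34")
SLIGHT_MAX = 10.0
HIGH_MIN = 100.0


def mean_total_mmc(subset_quantities: Sequence[float]) -> float:
    """Mean gEq/10^6 over tested subsets (untested subsets are simply absent)."""
    vals = [float(v) for v in subset_quantities]
    if not vals:
        raise NoCompartmentError("no tested subset")
    if any(v < 0 for v in vals):
        raise ValueError("negative quantity")
    return sum(vals) / len(vals)


def categorize(
    mean_total: float,
    positive_any: bool,
    slight_max: float = SLIGHT_MAX,
    high_min: float = HIGH_MIN,
) -> str:
    """Four-level category from the mean score and the positivity call.

    The boundary values go with the closed bounds: exactly ``slight_max`` is
    slight, exactly ``high_min`` is high.  A sample called positive with a
    mean of 0 (e.g. a single sub-threshold detection) stays slight: the
    positivity call dominates.
    """
    if mean_total < 0:
        raise ValueError("mean_total must be >= 0")
    if not positive_any:
        return "negative"
    if mean_total >= high_min:
        return "high"
    if mean_total > slight_max:
        return "moderate"
    return "slight"


@dataclass
class ChimerismProfile:
    """Positivity and quantity summary of one cord-blood sample."""

    sample_id: str
    quantities: Mapping[str, float]  # tested compartments only, gEq/10^6
    positives: Mapping[str, bool]
    positive_any: bool
    positive_wb: Optional[bool]  # None when WB untested
    mean_total_mmc: float
    category: str


def build_profile(
    sample_id: str,
    quantities: Mapping[str, float],
    positives: Mapping[str, bool],
    include_wb_in_mean: bool = False,
) -> ChimerismProfile:
    """Assemble a profile from per-compartment quantification results.

    ``quantities``/``positives`` are keyed by compartment name and carry only
    tested compartments.
    """
    if not quantities:
        raise NoCompartmentError(f"sample {sample_id}: no tested compartment")
    positive_any = any(positives.values())
    positive_wb = positives.get("WB")
    mean_keys = [
        c for c in quantities
        if include_wb_in_mean or c != "WB"
    ]
    # WB-only sample: fall back to what was tested rather than refuse a score
    if not mean_keys:
        mean_keys = list(quantities)
    mean = mean_total_mmc([quantities[c] for c in mean_keys])
    return ChimerismProfile(
        sample_id=sample_id,
        quantities=dict(quantities),
        positives=dict(positives),
        positive_any=positive_any,
        positive_wb=positive_wb,
        mean_total_mmc=mean,
        category=categorize(mean, positive_any),
    )


def profiles_from_quant(quant: pd.DataFrame, include_wb_in_mean: bool = False) -> list[ChimerismProfile]:
    """Build one profile per sample from a quantification result table."""
    profiles = []
    for sid, grp in quant.groupby("sample_id", sort=True):
        q = dict(zip(grp["compartment"], grp["mmc_per_million"]))
        p = dict(zip(grp["compartment"], grp["positive"]))
        profiles.append(build_profile(str(sid), q, p, include_wb_in_mean))
    return profiles


def positivity_frequency(n_positive: int, n_tested: int) -> tuple[float, int]:
    """Frequency and the integer percent used for reporting (30/55 -> 55%)."""
    if n_tested < 1:
        raise ValueError("n_tested must be >= 1")
    freq = n_positive / n_tested
    return freq, round(freq * 100)


def cohort_summary(profiles: Iterable[ChimerismProfile]) -> pd.DataFrame:
    """Positivity frequencies overall, per compartment and per category.

    Per-compartment frequency is positives over the number *tested* in that
    compartment; percentages are rounded to integers for reporting.
    """
    profiles = list(profiles)
    if not profiles:
        raise NoCompartmentError("no profiles")
    rows = []
    n = len(profiles)
    n_pos = sum(p.positive_any for p in profiles)
    freq, pct = positivity_frequency(n_pos, n)
    rows.append({"group": "any_compartment", "n_positive": n_pos, "n_tested": n,
                 "frequency": freq, "percent": pct})
    compartments = sorted({c for p in profiles for c in p.quantities})
    for comp in compartments:
        tested = [p for p in profiles if comp in p.positives]
        pos = sum(p.positives[comp] for p in tested)
        freq, pct = positivity_frequency(pos, len(tested))
        rows.append({"group": comp, "n_positive": pos, "n_tested": len(tested),
                     "frequency": freq, "percent": pct})
    for cat in CATEGORIES:
        k = sum(p.category == cat for p in profiles)
        freq, pct = positivity_frequency(k, n)
        rows.append({"group": f"category:{cat}", "n_positive": k, "n_tested": n,
                     "frequency": freq, "percent": pct})
    return pd.DataFrame(rows)


PROFILE_COLUMNS = ["sample_id", "wb", "pbmc", "cd3", "cd19", "cd66", "cd34",
                   "positive_any", "mean_total_mmc", "category"]


def profiles_to_frame(profiles: Iterable[ChimerismProfile]) -> pd.DataFrame:
    """Profile table with one column per compartment (empty = untested)."""
    rows = []
    for p in profiles:
        row = {"sample_id": p.sample_id}
        for comp in ("WB",) + SUBSET_COMPARTMENTS:
            row[comp.lower()] = p.quantities.get(comp)
        row["positive_any"] = p.positive_any
        row["positive_wb"] = p.positive_wb
        row["mean_total_mmc"] = p.mean_total_mmc
        row["category"] = p.category
        rows.append(row)
    return pd.DataFrame(rows)
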