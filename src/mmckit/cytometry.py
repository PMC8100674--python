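"""Cord-blood immune-subset composition from flow-cytometry event counts.

The module converts gated event counts to percentages of CD45+ leukocytes,
applies the >95% purity gate used before sorted fractions enter chimerism
testing, and compares subset composition between microchimerism-positive and
-negative samples with per-subset Mann-Whitney tests.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyGroupError, MissingColumnError, ZeroDenominatorError
from .stats import benjamini_hochberg, mann_whitney

#: marker combinations reported per sample; CD45 is the leukocyte denominator
SUBSET_MARKERS = ("CD20", "CD3", "CD4", "CD8", "CD66", "CD16", "CD56",
                  "CD16_56", "CD3_16_56", "CD34")
DENOMINATOR = "CD45"
PURITY_THRESHOLD = 95.0


def subset_percentages(events: pd.DataFrame,
                       markers: Sequence[str] = SUBSET_MARKERS) -> pd.DataFrame:
    """Percent of CD45+ events for each marker combination, per sample.

    Flags rows where CD4 + CD8 exceeds CD3 (a gating inconsistency: both are
    T-cell subsets) in a ``cd4_cd8_consistent`` column.
    """
    if DENOMINATOR not in events.columns:
        raise MissingColumnError(f"composition table lacks {DENOMINATOR} column")
    present = [m for m in markers if m in events.columns]
    out = events[["sample_id"]].copy() if "sample_id" in events.columns else pd.DataFrame(index=events.index)
    denom = events[DENOMINATOR].astype(float)
    if (denom <= 0).any():
        bad = events.loc[denom <= 0]
        raise ZeroDenominatorError(f"non-positive CD45 events in rows {list(bad.index)}")
    for m in present:
        out[f"pct_{m}"] = events[m].astype(float) / denom * 100.0
    if {"CD3", "CD4", "CD8"} <= set(present):
        out["cd4_cd8_consistent"] = (
            events["CD4"].astype(float) + events["CD8"].astype(float)
            <= events["CD3"].astype(float) + 1e-9
        )
    return out


def purity_gate(purities: pd.DataFrame,
                threshold: float = PURITY_THRESHOLD) -> pd.DataFrame:
    """Pass/fail per sorted fraction; strictly greater than the threshold passes."""
    if "purity" not in purities.columns:
        raise MissingColumnError("purity table lacks 'purity' column")
    p = purities["purity"].astype(float)
    if ((p < 0) | (p > 100)).any():
        raise ValueError("purity must be within [0, 100]")
    out = purities.copy()
    out["pass"] = p > threshold
    out["reason"] = np.where(out["pass"], "", "purity-below-threshold")
    return out


def compare_composition(
    percentages: pd.DataFrame,
    group: Iterable[bool],
    alpha: float = 0.05,
    correction: str | None = None,
) -> pd.DataFrame:
    """Per-subset two-sided Mann-Whitney comparison of the two groups.

    ``group`` holds the MMc-positivity label per row.  Direction is the sign
    of (positive-group mean minus negative-group mean).  No multiple-testing
    correction is applied by default; ``correction="bh"`` adds
    Benjamini-Hochberg adjusted p-values and flags on those instead.
    """
    labels = np.asarray(list(group), dtype=bool)
    if labels.size != len(percentages):
        raise ValueError("group labels must match the number of rows")
    if labels.all() or (~labels).all():
        raise EmptyGroupError("both MMc groups must be non-empty")
    rows = []
    pct_cols = [c for c in percentages.columns if c.startswith("pct_")]
    for col in pct_cols:
        x = percentages.loc[labels, col].dropna().to_numpy(float)
        y = percentages.loc[~labels, col].dropna().to_numpy(float)
        if x.size == 0 or y.size == 0:
            continue
        res = mann_whitney(x, y)
        rows.append({
            "subset": col.removeprefix("pct_"),
            "n_positive": x.size,
            "n_negative": y.size,
            "mean_positive": float(np.mean(x)),
            "mean_negative": float(np.mean(y)),
            "direction": int(np.sign(np.mean(x) - np.mean(y))),
            "statistic": res.statistic,
            "p_value": res.p_value,
            "method": res.method,
        })
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    if correction == "bh":
        out["p_adjusted"] = benjamini_hochberg(out["p_value"].to_numpy())
        out["significant"] = out["p_adjusted"] < alpha
    else:
        out["significant"] = out["p_value"] < alpha
    return out
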