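"""Association statistics for chimerism cohorts.

The battery mirrors common practice in small observational cohorts:

* Mann-Whitney U for continuous covariates between MMc-positive and
  -negative samples — exact by enumeration for small, tie-free samples,
  normal approximation with tie correction otherwise;
* Pearson chi-square (no continuity correction) for 2x2 tables with adequate
  expected counts;
* Fisher's exact test for 2xK tables (K in {2, 3, 4}) by full enumeration of
  all tables with the observed margins, summing point probabilities no larger
  than the observed table's (the point-probability two-sided criterion);
* Spearman rank correlation, exact by permutation for n <= 9 without ties,
  t approximation otherwise.

These primitives are written out explicitly (rather than wrapping a stats
library) so that the exact small-sample conventions — enumeration criteria,
tie handling, two-sidedness — are pinned down and testable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, stdtr
from scipy.stats import chi2 as _chi2_dist
from scipy.stats import rankdata

from .errors import (
    EmptySampleError,
    EnumerationCapError,
    InsufficientPairsError,
    MissingColumnError,
    ZeroMarginError,
)

EXACT_MW_MAX_N = 12
EXACT_SPEARMAN_MAX_N = 9
FISHER_ENUMERATION_CAP = 200
#: relative tolerance for "probability not larger than the observed table's";
#: absorbs floating-point noise in genuinely tied point probabilities
_TIE_RTOL = 1e-9


@dataclass
class TestResult:
    statistic: Optional[float]
    p_value: float
    method: str
    n: tuple[int, ...]
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside (0, 1]")


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def _rank_sum_counts(n_total: int, n_x: int) -> np.ndarray:
    """counts[s] = number of size-n_x subsets of ranks 1..n_total with sum s.

    Classic shift/convolution recursion; the exact null distribution of the
    rank sum follows by dividing by C(n_total, n_x).
    """
    max_sum = n_x * (2 * n_total - n_x + 1) // 2
    counts = np.zeros((n_x + 1, max_sum + 1), dtype=float)
    counts[0, 0] = 1.0
    for rank in range(1, n_total + 1):
        for k in range(min(rank, n_x), 0, -1):
            counts[k, rank:] += counts[k - 1, :-rank or None]
    return counts[n_x]


def mann_whitney(x: Sequence[float], y: Sequence[float],
                 alternative: str = "two-sided") -> TestResult:
    """Mann-Whitney U test for two independent samples.

    Exact enumeration of the null distribution when n_x + n_y <= 12 with no
    ties; otherwise the normal approximation with tie correction and a 0.5
    continuity correction.  The two-sided exact p is twice the smaller tail,
    capped at 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise EmptySampleError("both samples must be non-empty")
    if alternative != "two-sided":
        raise ValueError("only the two-sided alternative is implemented")
    nx, ny = x.size, y.size
    n = nx + ny
    combined = np.concatenate([x, y])
    ranks = rankdata(combined)
    u_x = float(ranks[:nx].sum() - nx * (nx + 1) / 2.0)
    has_ties = np.unique(combined).size < n

    if n <= EXACT_MW_MAX_N and not has_ties:
        counts = _rank_sum_counts(n, nx)
        total = counts.sum()
        rank_sum = u_x + nx * (nx + 1) / 2.0
        s = int(round(rank_sum))
        lower = counts[: s + 1].sum() / total
        upper = counts[s:].sum() / total
        p = min(1.0, 2.0 * min(lower, upper))
        return TestResult(u_x, p, "mann-whitney-exact", (nx, ny))

    mu = nx * ny / 2.0
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts)).sum()) / (n * (n - 1))
    sigma2 = nx * ny / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:  # all values identical
        return TestResult(u_x, 1.0, "mann-whitney-normal", (nx, ny))
    diff = u_x - mu
    cc = 0.5 * np.sign(diff)  # continuity correction toward the mean
    z = (diff - cc) / math.sqrt(sigma2) if diff != 0 else 0.0
    p = min(1.0, 2.0 * float(_norm_sf(abs(z))))
    return TestResult(u_x, max(p, np.finfo(float).tiny),
                      "mann-whitney-normal", (nx, ny), {"z": z})


def _norm_sf(z: float) -> float:
    return 0.5 * math.erfc(z / math.sqrt(2.0))


# ---------------------------------------------------------------------------
# Pearson chi-square, 2x2
# ---------------------------------------------------------------------------

def chi_square_2x2(table) -> TestResult:
    """Pearson chi-square on a 2x2 table, df=1, no continuity correction."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("chi_square_2x2 needs a 2x2 table")
    if np.any(t < 0):
        raise ValueError("counts must be non-negative")
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    n = t.sum()
    if np.any(rows == 0) or np.any(cols == 0):
        raise ZeroMarginError("chi-square undefined with a zero margin")
    expected = np.outer(rows, cols) / n
    stat = float(((t - expected) ** 2 / expected).sum())
    p = float(_chi2_dist.sf(stat, df=1)) if stat > 0 else 1.0
    return TestResult(stat, p, "chi-square", tuple(int(r) for r in rows),
                      {"expected_min": float(expected.min())})


# ---------------------------------------------------------------------------
# Fisher exact, 2xK by enumeration
# ---------------------------------------------------------------------------

def _fisher_log_probs(col_totals: np.ndarray, r1: int,
                      lf: np.ndarray) -> np.ndarray:
    """Log point probabilities of all 2xK tables with the given margins.

    Enumerates the first-row count vectors (a_1..a_K) with 0 <= a_j <= c_j and
    sum r1; the last two columns are vectorised.  Probabilities follow the
    multivariate hypergeometric law: prod_j C(c_j, a_j) / C(n, r1).
    """
    c = np.asarray(col_totals, dtype=int)
    K = c.size

    def logbinom(nn: int, kk) -> np.ndarray:
        kk = np.asarray(kk)
        return lf[nn] - lf[kk] - lf[nn - kk]

    suffix = np.concatenate([np.cumsum(c[::-1])[::-1][1:], [0]])
    chunks: list[np.ndarray] = []

    def rec(j: int, rem: int, acc: float) -> None:
        if j == K - 2:
            lo = max(0, rem - int(c[K - 1]))
            hi = min(int(c[K - 2]), rem)
            if hi < lo:
                return
            a = np.arange(lo, hi + 1)
            chunks.append(acc + logbinom(int(c[K - 2]), a)
                          + logbinom(int(c[K - 1]), rem - a))
            return
        lo = max(0, rem - int(suffix[j]))
        hi = min(int(c[j]), rem)
        for a in range(lo, hi + 1):
            rec(j + 1, rem - a, acc + float(logbinom(int(c[j]), a)))

    if K == 1:
        chunks.append(np.zeros(1))
    else:
        rec(0, r1, 0.0)
    n = int(c.sum())
    denom = lf[n] - lf[r1] - lf[n - r1]
    return np.concatenate(chunks) - denom


def fisher_table_distribution(col_totals: Sequence[int], r1: int) -> np.ndarray:
    """Point probabilities of every 2xK table with the given margins.

    Exposed for diagnostics; the probabilities sum to 1.
    """
    c = np.asarray(col_totals, dtype=int)
    n = int(c.sum())
    lf = gammaln(np.arange(n + 1) + 1.0)
    return np.exp(_fisher_log_probs(c, r1, lf))


def fisher_exact_2xk(table, cap: int = FISHER_ENUMERATION_CAP) -> TestResult:
    """Exact two-sided Fisher test on a 2xK table by full enumeration.

    Sums the point probabilities of all tables with the observed margins that
    are no more probable than the observed table (the point-probability
    criterion, the convention of the classical 2xK exact calculators).
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] != 2:
        raise ValueError("table must be 2xK")
    if np.any(t < 0) or np.any(t != np.round(t)):
        raise ValueError("counts must be non-negative integers")
    t = t.astype(int)
    t = t[:, t.sum(axis=0) > 0]  # empty columns carry no information
    if t.shape[1] == 0 or t.sum() == 0:
        raise ZeroMarginError("empty table")
    n = int(t.sum())
    if n > cap:
        raise EnumerationCapError(f"table total {n} exceeds enumeration cap {cap}")
    c = t.sum(axis=0)
    r1 = int(t[0].sum())
    lf = gammaln(np.arange(n + 1) + 1.0)

    def logbinom(nn: int, kk: int) -> float:
        return float(lf[nn] - lf[kk] - lf[nn - kk])

    log_obs = sum(logbinom(int(cj), int(aj)) for cj, aj in zip(c, t[0]))
    log_obs -= logbinom(n, r1)
    probs = np.exp(_fisher_log_probs(c, r1, lf))
    p_obs = math.exp(log_obs)
    p = float(probs[probs <= p_obs * (1.0 + _TIE_RTOL)].sum())
    p = min(1.0, max(p, np.finfo(float).tiny))
    rows = tuple(int(r) for r in t.sum(axis=1))
    return TestResult(None, p, f"fisher-exact-2x{t.shape[1]}", rows,
                      {"point_probability": p_obs})


# ---------------------------------------------------------------------------
# Spearman rank correlation
# ---------------------------------------------------------------------------

def spearman(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Spearman rho with average ranks; exact permutation p for n <= 9.

    The exact path requires tie-free data (the d^2 shortcut formula holds
    only then); with ties or larger n, the two-sided p uses the
    t approximation with n-2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("paired samples must have equal length")
    n = x.size
    if n < 3:
        raise InsufficientPairsError("Spearman needs at least 3 pairs")
    rx = rankdata(x)
    ry = rankdata(y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        return TestResult(0.0, 1.0, "spearman-degenerate", (n,))
    rho = float(np.corrcoef(rx, ry)[0, 1])

    tie_free = np.unique(x).size == n and np.unique(y).size == n
    if n <= EXACT_SPEARMAN_MAX_N and tie_free:
        perms = np.array(list(permutations(range(1, n + 1))), dtype=float)
        d2 = ((perms - rx) ** 2).sum(axis=1)
        rho_null = 1.0 - 6.0 * d2 / (n * (n * n - 1))
        p = float(np.mean(np.abs(rho_null) >= abs(rho) - 1e-12))
        return TestResult(rho, p, "spearman-exact", (n,))

    denom = max(1.0 - rho * rho, np.finfo(float).tiny)
    t_stat = rho * math.sqrt((n - 2) / denom)
    p = 2.0 * float(stdtr(n - 2, -abs(t_stat)))
    p = min(1.0, max(p, np.finfo(float).tiny))
    return TestResult(rho, p, "spearman-t", (n,), {"t": t_stat})


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH-adjusted p-values (monotone step-up)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank_idx in range(m - 1, -1, -1):
        i = order[rank_idx]
        running = min(running, p[i] * m / (rank_idx + 1))
        adj[i] = running
    return adj


def categorical_association(
    values: pd.Series,
    status: pd.Series,
    small_cell_threshold: float = 5.0,
    cap: int = FISHER_ENUMERATION_CAP,
) -> TestResult:
    """Association between a categorical covariate and a binary status.

    2x2 tables with all expected counts >= the small-cell threshold use the
    chi-square test; small or wider tables use the exact Fisher test.
    """
    tab = pd.crosstab(status.astype(bool), values)
    t = tab.to_numpy()
    if t.shape[0] < 2 or t.shape[1] < 2:
        raise ZeroMarginError("covariate or status has a single level")
    if t.shape == (2, 2):
        rows, cols, n = t.sum(1), t.sum(0), t.sum()
        if np.any(rows == 0) or np.any(cols == 0):
            raise ZeroMarginError("zero margin")
        expected = np.outer(rows, cols) / n
        if expected.min() >= small_cell_threshold:
            return chi_square_2x2(t)
    return fisher_exact_2xk(t, cap=cap)


# ---------------------------------------------------------------------------
# the cohort battery
# ---------------------------------------------------------------------------

#: (report name, kind, needed columns); kind decides which primitive runs
_BATTERY_PLAN = [
    ("pappa_mom~positive_wb", "mw", ("pappa_mom", "positive_wb")),
    ("pappa_mom~positive_wb|no_art", "mw_noart", ("pappa_mom", "positive_wb", "art_conception")),
    ("bhcg_mom~positive_wb", "mw", ("bhcg_mom", "positive_wb")),
    ("weight_g~positive_any", "mw", ("weight_g", "positive_any")),
    ("gestation_weeks~positive_any", "mw", ("gestation_weeks", "positive_any")),
    ("center~positive_any", "cat", ("center", "positive_any")),
    ("delivery_mode~positive_any", "cat", ("delivery_mode", "positive_any")),
    ("same_day_processing~positive_any", "delay", ("processing_delay_h", "positive_any")),
    ("sex~positive_any", "cat", ("sex", "positive_any")),
    ("compat_A~positive_wb", "fisher", ("compat_A", "positive_wb")),
    ("compat_B~positive_wb", "fisher", ("compat_B", "positive_wb")),
    ("compat_DRB1~positive_wb", "fisher", ("compat_DRB1", "positive_wb")),
    ("compat_A_or_DRB1~category", "fisher2x4", ("compat_A_or_DRB1", "category")),
    ("pappa_mom~mean_total_mmc", "spearman", ("pappa_mom", "mean_total_mmc")),
]

CATEGORY_ORDER = ("negative", "slight", "moderate", "high")


def _mw_by_group(df: pd.DataFrame, value_col: str, group_col: str) -> TestResult:
    sub = df[[value_col, group_col]].dropna()
    g = sub[group_col].astype(bool)
    return mann_whitney(sub.loc[g, value_col], sub.loc[~g, value_col])


def association_battery(
    cohort: pd.DataFrame,
    small_cell_threshold: float = 5.0,
    cap: int = FISHER_ENUMERATION_CAP,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Run every cohort-level comparison the data supports.

    Comparisons whose columns are absent (e.g. serology was never collected)
    are reported as skipped rather than failing the whole battery; the status
    columns themselves are mandatory.
    """
    for required in ("positive_any",):
        if required not in cohort.columns:
            raise MissingColumnError(f"cohort table lacks {required!r}")
    rows = []
    for name, kind, cols in _BATTERY_PLAN:
        missing = [c for c in cols if c not in cohort.columns]
        if missing:
            rows.append({"comparison": name, "method": None, "statistic": None,
                         "p_value": None, "n": None, "significant": None,
                         "note": f"skipped: missing {','.join(missing)}"})
            continue
        try:
            if kind == "mw":
                res = _mw_by_group(cohort, cols[0], cols[1])
            elif kind == "mw_noart":
                kept = cohort.loc[~cohort["art_conception"].fillna(False).astype(bool)]
                res = _mw_by_group(kept, cols[0], cols[1])
            elif kind == "cat":
                sub = cohort[[cols[0], cols[1]]].dropna()
                res = categorical_association(sub[cols[0]], sub[cols[1]],
                                              small_cell_threshold, cap)
            elif kind == "delay":
                sub = cohort[["processing_delay_h", "positive_any"]].dropna()
                same_day = sub["processing_delay_h"].astype(float) < 24.0
                res = categorical_association(same_day, sub["positive_any"],
                                              small_cell_threshold, cap)
            elif kind == "fisher":
                sub = cohort[[cols[0], cols[1]]].dropna()
                tab = pd.crosstab(sub[cols[1]].astype(bool), sub[cols[0]].astype(bool))
                res = fisher_exact_2xk(tab.to_numpy(), cap=cap)
            elif kind == "fisher2x4":
                sub = cohort[[cols[0], cols[1]]].dropna()
                cats = pd.Categorical(sub[cols[1]], categories=CATEGORY_ORDER)
                tab = pd.crosstab(sub[cols[0]].astype(bool), cats)
                res = fisher_exact_2xk(tab.to_numpy(), cap=cap)
            elif kind == "spearman":
                sub = cohort[[cols[0], cols[1]]].dropna()
                res = spearman(sub[cols[0]], sub[cols[1]])
            else:  # pragma: no cover
                raise ValueError(kind)
        except (ZeroMarginError, EmptySampleError, InsufficientPairsError,
                EnumerationCapError) as exc:
            rows.append({"comparison": name, "method": None, "statistic": None,
                         "p_value": None, "n": None, "significant": None,
                         "note": f"skipped: {exc}"})
            continue
        rows.append({"comparison": name, "method": res.method,
                     "statistic": res.statistic, "p_value": res.p_value,
                     "n": sum(res.n), "significant": res.p_value < alpha,
                     "note": ""})
    return pd.DataFrame(rows)
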