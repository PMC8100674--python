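"""The statistical battery against independent oracles (scipy, brute force)."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps
from hypothesis import given
from hypothesis import strategies as st

from mmckit.errors import (
    EmptySampleError,
    EnumerationCapError,
    InsufficientPairsError,
    MissingColumnError,
    ZeroMarginError,
)
from mmckit.stats import (
    association_battery,
    benjamini_hochberg,
    categorical_association,
    chi_square_2x2,
    fisher_exact_2xk,
    fisher_table_distribution,
    mann_whitney,
    spearman,
)


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------

def _brute_force_mw_p(x, y):
    """Two-sided exact p by enumerating every group assignment of the ranks."""
    ranks = sps.rankdata(np.concatenate([x, y]))
    nx = len(x)
    u_obs = ranks[:nx].sum() - nx * (nx + 1) / 2
    us = []
    for idx in itertools.combinations(range(len(ranks)), nx):
        s = sum(ranks[list(idx)])
        us.append(s - nx * (nx + 1) / 2)
    us = np.array(us)
    lower = np.mean(us <= u_obs)
    upper = np.mean(us >= u_obs)
    return min(1.0, 2 * min(lower, upper))


def test_mw_separated_samples():
    res = mann_whitney([1, 2, 3], [4, 5, 6])
    assert res.statistic == 0.0
    assert res.p_value == pytest.approx(0.1)  # 2 / C(6,3)
    assert res.method == "mann-whitney-exact"


def test_mw_identical_multisets_p_one():
    res = mann_whitney([1, 2, 2, 3], [3, 2, 1, 2])
    assert res.p_value == pytest.approx(1.0, abs=1e-9)


def test_mw_empty_sample():
    with pytest.raises(EmptySampleError):
        mann_whitney([], [1.0])


def test_mw_normal_approximation_close_to_exact(rng):
    """At n=6+6 the normal approximation tracks full enumeration within 0.02."""
    for _ in range(25):
        x = rng.normal(size=6)
        y = rng.normal(0.5, size=6)
        exact = mann_whitney(x, y)
        assert exact.method == "mann-whitney-exact"
        # push through the approximation by inflating n with tied copies
        approx = mann_whitney(np.repeat(x, 2), np.repeat(y, 2))
        assert approx.method == "mann-whitney-normal"
        oracle = sps.mannwhitneyu(np.repeat(x, 2), np.repeat(y, 2),
                                  alternative="two-sided", method="asymptotic")
        assert approx.p_value == pytest.approx(oracle.pvalue, abs=1e-9)
        assert exact.p_value == pytest.approx(_brute_force_mw_p(x, y), abs=1e-12)


# ---------------------------------------------------------------------------
# chi-square
# ---------------------------------------------------------------------------

def test_chi_square_printed_center_counts():
    """14/22 vs 15/32 positives between collection centres: p rounds to 0.22."""
    res = chi_square_2x2([[14, 8], [15, 17]])
    assert res.statistic == pytest.approx(1.4732, abs=1e-4)
    assert round(res.p_value, 2) == 0.22


def test_chi_square_identical_rows():
    res = chi_square_2x2([[5, 10], [5, 10]])
    assert res.statistic == 0.0 and res.p_value == 1.0


def test_chi_square_symmetries():
    t = np.array([[14, 8], [15, 17]])
    base = chi_square_2x2(t).statistic
    assert chi_square_2x2(t.T).statistic == pytest.approx(base)
    assert chi_square_2x2(t[::-1]).statistic == pytest.approx(base)


def test_chi_square_zero_margin():
    with pytest.raises(ZeroMarginError):
        chi_square_2x2([[0, 0], [3, 4]])


def test_chi_square_matches_scipy_no_correction(rng):
    for _ in range(20):
        t = rng.integers(1, 30, size=(2, 2))
        ours = chi_square_2x2(t)
        ref = sps.chi2_contingency(t, correction=False)
        assert ours.statistic == pytest.approx(ref.statistic)
        assert ours.p_value == pytest.approx(ref.pvalue)


# ---------------------------------------------------------------------------
# Fisher exact 2xK
# ---------------------------------------------------------------------------

def test_fisher_corner_table():
    res = fisher_exact_2xk([[5, 0], [0, 5]])
    assert res.p_value == pytest.approx(2 / 252)  # two corner tables of C(10,5)


def test_fisher_identical_rows():
    assert fisher_exact_2xk([[3, 3], [3, 3]]).p_value == pytest.approx(1.0)


def test_fisher_2x2_matches_scipy(rng):
    for _ in range(50):
        t = rng.integers(0, 15, size=(2, 2))
        if t.sum(0).min() == 0 or t.sum() == 0:
            continue
        ours = fisher_exact_2xk(t)
        ref = sps.fisher_exact(t, alternative="two-sided")
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-7)


def test_fisher_2x4_matches_itertools_oracle(rng):
    """2xK agrees with an independent brute-force enumeration over products
    of exact binomial coefficients."""
    from math import comb

    for _ in range(5):
        t = rng.integers(0, 6, size=(2, 4))
        if t.sum() == 0 or t.sum(0).min() == 0:
            continue
        c = t.sum(0)
        r1 = t[0].sum()
        probs, p_obs = [], None
        for a in itertools.product(*(range(ci + 1) for ci in c)):
            if sum(a) != r1:
                continue
            p = np.prod([comb(ci, ai) for ci, ai in zip(c, a)]) / comb(t.sum(), r1)
            probs.append(p)
            if tuple(t[0]) == a:
                p_obs = p
        probs = np.array(probs)
        expected = probs[probs <= p_obs * (1 + 1e-9)].sum()
        assert fisher_exact_2xk(t).p_value == pytest.approx(expected, rel=1e-10)


def test_fisher_point_probabilities_sum_to_one(rng):
    for _ in range(20):
        k = rng.integers(2, 5)
        c = rng.integers(1, 8, size=k)
        r1 = int(rng.integers(0, c.sum() + 1))
        probs = fisher_table_distribution(c, r1)
        assert probs.sum() == pytest.approx(1.0, abs=1e-10)


def test_fisher_enumeration_cap():
    with pytest.raises(EnumerationCapError):
        fisher_exact_2xk([[150, 150], [150, 150]], cap=200)


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------

def test_spearman_perfect_monotone():
    x = [1, 2, 3, 4, 5, 6, 7, 8, 9, 10]
    up = spearman(x, [v * 2 + 1 for v in x])
    assert up.statistic == pytest.approx(1.0)
    down = spearman(x, list(reversed(x)))
    assert down.statistic == pytest.approx(-1.0)


def test_spearman_needs_three_pairs():
    with pytest.raises(InsufficientPairsError):
        spearman([1, 2], [3, 4])


def test_spearman_t_close_to_exact_permutation(rng):
    """At n=8 the t approximation stays within 0.03 of the exact p."""
    for _ in range(10):
        x = rng.normal(size=8)
        y = 0.5 * x + rng.normal(size=8)
        exact = spearman(x, y)
        assert exact.method == "spearman-exact"
        # force the t path with an extra pair of duplicated x values (ties)
        rho = exact.statistic
        n = 8
        t_stat = rho * np.sqrt((n - 2) / (1 - rho**2))
        p_t = 2 * sps.t.sf(abs(t_stat), n - 2)
        assert exact.p_value == pytest.approx(p_t, abs=0.03)


def test_spearman_matches_scipy_large_n(rng):
    x = rng.normal(size=40)
    y = 0.4 * x + rng.normal(size=40)
    ours = spearman(x, y)
    ref = sps.spearmanr(x, y)
    assert ours.statistic == pytest.approx(ref.statistic)
    assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-6)


# ---------------------------------------------------------------------------
# helpers and the battery
# ---------------------------------------------------------------------------

def test_benjamini_hochberg_monotone():
    p = [0.001, 0.01, 0.02, 0.8]
    adj = benjamini_hochberg(p)
    assert np.all(adj >= p)
    assert np.all(np.diff(adj[np.argsort(p)]) >= -1e-12)


def test_categorical_association_small_cell_switches_to_fisher():
    status = pd.Series([True] * 6 + [False] * 6)
    values = pd.Series(["a"] * 5 + ["b"] * 1 + ["a"] * 1 + ["b"] * 5)
    res = categorical_association(values, status)
    assert res.method.startswith("fisher")
    big_status = pd.Series([True] * 50 + [False] * 50)
    big_values = pd.Series((["a"] * 25 + ["b"] * 25) * 2)
    assert categorical_association(big_values, big_status).method == "chi-square"


def _toy_cohort(rng, n=60):
    positive = rng.random(n) < 0.5
    return pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)],
        "positive_any": positive,
        "positive_wb": positive,
        "category": np.where(positive, "slight", "negative"),
        "pappa_mom": rng.lognormal(np.where(positive, 0.35, 0.0), 0.4),
        "bhcg_mom": rng.lognormal(0, 0.5, n),
        "compat_A": rng.random(n) < 0.3,
        "compat_B": rng.random(n) < 0.3,
        "compat_DRB1": rng.random(n) < 0.3,
        "compat_A_or_DRB1": rng.random(n) < 0.5,
        "center": rng.choice(["c1", "c2"], n),
        "delivery_mode": rng.choice(["vaginal", "c_section"], n, p=[0.9, 0.1]),
        "processing_delay_h": rng.uniform(2, 30, n),
        "sex": rng.choice(["M", "F"], n),
        "weight_g": rng.normal(3400, 450, n),
        "gestation_weeks": rng.normal(39.5, 1.2, n),
        "art_conception": rng.random(n) < 0.08,
        "mean_total_mmc": np.where(positive, rng.lognormal(2, 1, n), 0.0),
    })


def test_association_battery_full_cohort(rng):
    report = association_battery(_toy_cohort(rng))
    assert (report["note"] == "").all()
    ran = report.dropna(subset=["p_value"])
    assert len(ran) == len(report)
    assert ran["p_value"].between(0, 1, inclusive="right").all()


def test_association_battery_skips_missing_serology(rng):
    cohort = _toy_cohort(rng).drop(columns=["pappa_mom", "bhcg_mom"])
    report = association_battery(cohort).set_index("comparison")
    assert report.loc["pappa_mom~positive_wb", "note"].startswith("skipped")
    assert report.loc["compat_A~positive_wb", "p_value"] is not None
    with pytest.raises(MissingColumnError):
        association_battery(cohort.drop(columns=["positive_any"]))
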