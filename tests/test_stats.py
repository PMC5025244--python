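"""Exactness and identities of the rank tests and summary statistics.

Each exact test is checked against an independent brute-force
enumeration oracle built from itertools, never from the implementation's
dynamic-programming path.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from dpmload import (
    covariate_r2,
    fisher_exact_right,
    mann_whitney_u,
    mean_relative_increase,
    spearman_rho,
    summarize_groups,
    wilcoxon_signed_rank,
)
from dpmload.classify import SampleSummary


# ---------------------------------------------------------------- oracles
def oracle_wilcoxon_two_sided(diffs):
    """Enumerate all 2^n sign assignments of the midranked |d|."""
    d = np.asarray([x for x in diffs if x != 0], dtype=float)
    n = d.size
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ge = le = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for s, r in zip(signs, ranks) if s)
        ge += w >= w_obs - 1e-12
        le += w <= w_obs + 1e-12
    total = 2**n
    return min(1.0, 2 * min(ge / total, le / total))


def oracle_mwu_two_sided(x, y):
    """Enumerate all C(nx+ny, nx) group labelings of the pooled data."""
    pooled = list(x) + list(y)
    nx = len(x)
    ranks = sps.rankdata(pooled)
    u_obs = ranks[:nx].sum() - nx * (nx + 1) / 2
    ge = le = total = 0
    for combo in itertools.combinations(range(len(pooled)), nx):
        u = sum(ranks[i] for i in combo) - nx * (nx + 1) / 2
        total += 1
        ge += u >= u_obs - 1e-12
        le += u <= u_obs + 1e-12
    return min(1.0, 2 * min(ge / total, le / total))


def oracle_spearman_two_sided(x, y):
    """Enumerate all n! permutations; two-sided on |rho|."""
    rho_obs = sps.spearmanr(x, y).statistic
    y = list(y)
    n = len(y)
    hits = total = 0
    for perm in itertools.permutations(y):
        r = sps.spearmanr(x, perm).statistic
        total += 1
        hits += abs(r) >= abs(rho_obs) - 1e-12
    return hits / total


def oracle_fisher_right(a, b, c, d):
    """Direct hypergeometric sum P(X >= a) with fixed margins."""
    row1, col1, total = a + b, a + c, a + b + c + d
    p = 0.0
    for k in range(a, min(row1, col1) + 1):
        if col1 - k > total - row1:
            continue
        p += (
            math.comb(row1, k)
            * math.comb(total - row1, col1 - k)
            / math.comb(total, col1)
        )
    return p


# ------------------------------------------------------ wilcoxon signed rank
def test_wilcoxon_all_zero_differences():
    res = wilcoxon_signed_rank([(1.0, 1.0)] * 5)
    assert res.p_value == 1.0
    assert "degenerate" in res.method_note


def test_wilcoxon_strictly_positive_exact():
    res = wilcoxon_signed_rank([(0, 1), (0, 2), (0, 3), (0, 4), (0, 5)])
    assert res.p_value == pytest.approx(1 / 16, abs=1e-12)
    one_sided = wilcoxon_signed_rank([(0, d) for d in (1, 2, 3, 4, 5)], alternative="greater")
    assert one_sided.p_value == pytest.approx(1 / 32, abs=1e-12)


@pytest.mark.parametrize("seed", range(8))
def test_wilcoxon_exact_matches_enumeration(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, 10))
    diffs = rng.choice([-3, -2, -1, 1, 2, 3, 5], size=n).astype(float)
    pairs = [(0.0, d) for d in diffs]
    res = wilcoxon_signed_rank(pairs)
    assert res.p_value == pytest.approx(oracle_wilcoxon_two_sided(diffs), abs=1e-9)


def test_wilcoxon_exact_vs_normal_approximation():
    rng = np.random.default_rng(42)
    for _ in range(10):
        diffs = rng.normal(0.3, 1.0, size=12)
        pairs = [(0.0, d) for d in diffs]
        exact = wilcoxon_signed_rank(pairs, exact_limit=25)
        approx = wilcoxon_signed_rank(pairs, exact_limit=1)
        assert abs(exact.p_value - approx.p_value) < 0.02


# ------------------------------------------------------------- mann-whitney
def test_mwu_worked_example():
    res = mann_whitney_u([1, 2], [3, 4])
    assert res.statistic == 0.0
    assert res.p_value == pytest.approx(2 / 6, abs=1e-12)


def test_mwu_identical_groups():
    res = mann_whitney_u([1, 2, 3], [1, 2, 3])
    assert res.p_value >= 0.99


def test_mwu_symmetry_identity():
    rng = np.random.default_rng(3)
    x, y = rng.normal(size=6), rng.normal(size=9)
    assert mann_whitney_u(x, y).statistic + mann_whitney_u(y, x).statistic == 6 * 9


@pytest.mark.parametrize("seed", range(8))
def test_mwu_exact_matches_enumeration(seed):
    rng = np.random.default_rng(100 + seed)
    nx, ny = int(rng.integers(2, 6)), int(rng.integers(2, 6))
    pooled = rng.permutation(np.arange(nx + ny, dtype=float) + rng.normal(0, 0.01, nx + ny))
    x, y = pooled[:nx], pooled[nx:]
    res = mann_whitney_u(x, y)
    assert "exact" in res.method_note
    assert res.p_value == pytest.approx(oracle_mwu_two_sided(x, y), abs=1e-9)


def test_mwu_exact_vs_normal_approximation():
    rng = np.random.default_rng(11)
    for _ in range(10):
        x = rng.normal(0, 1, size=8)
        y = rng.normal(0.5, 1, size=9)
        exact = mann_whitney_u(x, y, exact_limit=400)
        approx = mann_whitney_u(x, y, exact_limit=1)
        assert abs(exact.p_value - approx.p_value) < 0.02


# ----------------------------------------------------------------- spearman
def test_spearman_perfect_monotone():
    res = spearman_rho([1, 2, 3, 4], [10, 20, 30, 40])
    assert res.statistic == pytest.approx(1.0)


def test_spearman_hand_example():
    res = spearman_rho([1, 2, 3], [3, 1, 2])
    assert res.statistic == pytest.approx(-0.5)


def test_spearman_rank_invariance():
    rng = np.random.default_rng(5)
    x, y = rng.normal(size=10), rng.normal(size=10)
    a = spearman_rho(x, y)
    b = spearman_rho(sps.rankdata(x), sps.rankdata(y))
    assert a.statistic == pytest.approx(b.statistic)
    assert a.p_value == pytest.approx(b.p_value)


def test_spearman_constant_is_error():
    with pytest.raises(ValueError):
        spearman_rho([1, 1, 1], [1, 2, 3])


@pytest.mark.parametrize("seed", range(6))
def test_spearman_exact_matches_enumeration(seed):
    rng = np.random.default_rng(200 + seed)
    n = int(rng.integers(4, 7))
    x = rng.permutation(np.arange(n, dtype=float))
    y = rng.normal(size=n)
    res = spearman_rho(x, y)
    assert "exact" in res.method_note
    assert res.p_value == pytest.approx(oracle_spearman_two_sided(x, y), abs=1e-9)


# ------------------------------------------------------------------- fisher
def test_fisher_zero_cell():
    assert fisher_exact_right([[0, 4], [5, 6]]).p_value == pytest.approx(1.0)


def test_fisher_worked_example():
    assert fisher_exact_right([[3, 1], [1, 3]]).p_value == pytest.approx(17 / 70, abs=1e-12)


@pytest.mark.parametrize("seed", range(10))
def test_fisher_matches_hypergeometric_sum(seed):
    rng = np.random.default_rng(300 + seed)
    a, b, c, d = (int(v) for v in rng.integers(0, 12, size=4))
    if a + b + c + d == 0:
        a = 1
    assert fisher_exact_right([[a, b], [c, d]]).p_value == pytest.approx(
        oracle_fisher_right(a, b, c, d), abs=1e-9
    )


def test_fisher_point_probabilities_normalize():
    row1, col1, total = 4, 4, 8
    p = sum(
        math.comb(row1, k) * math.comb(total - row1, col1 - k) / math.comb(total, col1)
        for k in range(0, min(row1, col1) + 1)
    )
    assert p == pytest.approx(1.0, abs=1e-12)


# --------------------------------------------------- relative increase / R2
@pytest.mark.parametrize(
    "nt,t,expected",
    [(34.34, 36.78, 7.1), (29.76, 32.07, 7.8), (10.0, 10.0, 0.0)],
)
def test_mean_relative_increase_group_means(nt, t, expected):
    assert round(mean_relative_increase(nt, t), 1) == expected


def test_mean_relative_increase_per_patient():
    nt, t = [10.0, 20.0], [11.0, 24.0]
    assert mean_relative_increase(nt, t, basis="per_patient") == pytest.approx(15.0)
    with pytest.raises(ValueError):
        mean_relative_increase([0.0, 1.0], [1.0, 2.0], basis="per_patient")


def test_covariate_r2():
    x = np.arange(10.0)
    assert covariate_r2(x, 2 * x + 1) == pytest.approx(1.0)
    rng = np.random.default_rng(1)
    small = sum(covariate_r2(rng.normal(size=100), rng.normal(size=100)) < 0.1 for _ in range(20))
    assert small >= 18
    y = rng.normal(size=10)
    x2 = rng.normal(size=10)
    assert covariate_r2(x2, y) == pytest.approx(sps.pearsonr(x2, y).statistic ** 2)
    with pytest.raises(ValueError):
        covariate_r2([1, 1, 1], [1, 2, 3])


# ----------------------------------------------------------- group summary
def _summary(sid, patient, tissue, pct):
    return SampleSummary(
        sample_id=sid,
        patient_id=patient,
        tissue=tissue,
        n_total_exonic=100,
        n_dpm=int(pct),
        n_benign=0,
        n_synonymous=100 - int(pct),
        n_excluded_nonframeshift=0,
        n_unscored=0,
        pct_dpm=pct,
        pct_benign=0.0,
        pct_synonymous=100 - pct,
        pct_excluded_nonframeshift=0.0,
        pct_unscored=0.0,
    )


def test_summarize_groups_paired_direction_and_skips():
    summaries = []
    pairs = {}
    for i, (nt, t) in enumerate([(30.0, 33.0), (31.0, 35.0), (29.0, 30.5)]):
        p = f"P{i}"
        summaries += [_summary(f"{p}N", p, "non_tumour", nt), _summary(f"{p}T", p, "tumour", t)]
        pairs[p] = (f"{p}N", f"{p}T")
    lone = [_summary("Q1", "Q1", "cirrhotic", 28.0)]
    groups, tests = summarize_groups(
        {"WESX": (summaries, pairs), "WESY": (lone, {})}
    )
    nt_row = groups[(groups.dataset_id == "WESX") & (groups.tissue == "non_tumour")].iloc[0]
    assert nt_row["n"] == 3 and nt_row["mean"] == pytest.approx(30.0)
    lone_row = groups[groups.dataset_id == "WESY"].iloc[0]
    assert lone_row["sd"] is None or np.isnan(lone_row["sd"])
    paired = tests[tests.comparison.str.contains("paired")]
    assert len(paired) == 1
    # tumour uniformly higher: W+ is the maximal rank sum
    assert paired.iloc[0]["statistic"] == 6.0
    skipped = tests[tests.method_note.str.contains("skipped")]
    assert (skipped.n.str.contains("1")).all()


def test_summarize_groups_identical_groups_mwu():
    a = [_summary(f"A{i}", f"A{i}", "non_tumour", v) for i, v in enumerate([1.0, 2.0, 3.0])]
    b = [_summary(f"B{i}", f"B{i}", "non_tumour", v) for i, v in enumerate([1.0, 2.0, 3.0])]
    _, tests = summarize_groups({"D1": (a, {}), "D2": (b, {})})
    mwu = tests[tests.test == "mann_whitney_u"]
    assert (mwu.p_value >= 0.99).all()
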