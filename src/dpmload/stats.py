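"""Paired and unpaired rank statistics for mutation-burden comparisons.

The headline comparison is the paired Wilcoxon signed-rank test of a
per-sample normalized percentage (e.g. pct_dpm) between matched
non-tumour and tumour samples; the Mann-Whitney U test serves unpaired
groups and cross-dataset comparisons, Spearman's rho the monotone
association checks, and the right-tailed Fisher exact test the gene-set
enrichment gate.

Cohort sizes in this setting are small (tens of pairs), so all tests
use exact null distributions within configurable enumeration limits:

* signed-rank: exact distribution of W+ over all 2^n sign assignments,
  computed by dynamic programming over (doubled) midranks, for up to 25
  non-zero differences; normal approximation with tie and continuity
  corrections beyond that;
* Mann-Whitney: exact U distribution by the standard count recurrence
  when n_x * n_y <= 400 and the pooled data are tie-free;
* Spearman: full permutation enumeration for n <= 8, t-approximation
  otherwise.

Two-sided p-values are the default, with sidedness exposed.  Zero
differences are dropped (Wilcoxon's original rule); tied absolute
differences are mid-ranked.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats as sps

from .classify import SampleSummary

log = logging.getLogger(__name__)

ALTERNATIVES = ("two-sided", "greater", "less")

#: Default enumeration limits for exact null distributions.
WILCOXON_EXACT_LIMIT = 25
MANNWHITNEY_EXACT_LIMIT = 400
SPEARMAN_EXACT_LIMIT = 8


@dataclass(frozen=True)
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    n: tuple[int, ...]
    method_note: str

    def __post_init__(self) -> None:
        assert -1e-12 <= self.p_value <= 1 + 1e-12


@dataclass(frozen=True)
class GroupSummary:
    dataset_id: str
    tissue: str
    n: int
    mean: float
    sd: Optional[float]


def _two_sided_from_tails(cdf: float, sf: float) -> float:
    return min(1.0, 2.0 * min(cdf, sf))


def _signed_rank_null_counts(doubled_ranks: Sequence[int]) -> np.ndarray:
    """Counts of sign assignments per doubled-W+ value.

    Midranks are multiples of 0.5, so doubling makes them integers; the
    returned array c has c[w] = #{sign vectors with 2*W+ == w} and sums
    to 2^n.  Counts stay below 2^25 and are exact in float64.
    """
    total = sum(doubled_ranks)
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in doubled_ranks:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts += shifted
    return counts


def wilcoxon_signed_rank(
    pairs: Iterable[tuple[float, float]],
    alternative: str = "two-sided",
    exact_limit: int = WILCOXON_EXACT_LIMIT,
) -> TestResult:
    """Wilcoxon matched-pairs signed-rank test on (non_tumour, tumour) pairs.

    The statistic is W+, the rank sum of pairs where tumour > non-tumour.
    ``greater`` tests for an increase from the first to the second
    member of each pair.
    """
    if alternative not in ALTERNATIVES:
        raise ValueError(f"alternative must be one of {ALTERNATIVES}")
    pairs = list(pairs)
    if not pairs:
        raise ValueError("no pairs given")
    diffs = np.asarray([t - nt for nt, t in pairs], dtype=float)
    nonzero = diffs[diffs != 0]
    n = nonzero.size
    if n == 0:
        log.warning("all paired differences are zero; p = 1")
        return TestResult("wilcoxon_signed_rank", 0.0, 1.0, (len(pairs),), "degenerate: all zero")
    ranks = sps.rankdata(np.abs(nonzero))
    w_plus = float(ranks[nonzero > 0].sum())

    if n <= exact_limit:
        doubled = np.rint(2 * ranks).astype(int)
        counts = _signed_rank_null_counts(doubled)
        w2 = int(round(2 * w_plus))
        denom = 2.0**n
        cdf = counts[: w2 + 1].sum() / denom
        sf = counts[w2:].sum() / denom
        note = "exact (sign-assignment enumeration)"
    else:
        mu = n * (n + 1) / 4.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - ((tie_counts**3 - tie_counts).sum()) / 48.0
        sigma = np.sqrt(sigma2)
        # continuity correction toward the mean
        cdf = float(sps.norm.cdf((w_plus - mu + 0.5) / sigma))
        sf = float(sps.norm.sf((w_plus - mu - 0.5) / sigma))
        note = "normal approximation, tie + continuity corrected"

    if alternative == "two-sided":
        p = _two_sided_from_tails(cdf, sf)
    elif alternative == "greater":
        p = min(1.0, sf)
    else:
        p = min(1.0, cdf)
    return TestResult("wilcoxon_signed_rank", w_plus, p, (len(pairs),), note)


def _mwu_null_counts(nx: int, ny: int) -> np.ndarray:
    """Exact counts of labelings per U value (tie-free case).

    f(n, m, u) = f(n-1, m, u-m) + f(n, m-1, u); returned array sums to
    C(nx+ny, nx).
    """
    u_max = nx * ny
    f = np.zeros((nx + 1, ny + 1, u_max + 1))
    f[0, :, 0] = 1.0
    f[:, 0, 0] = 1.0
    for i in range(1, nx + 1):
        for j in range(1, ny + 1):
            f[i, j] = f[i, j - 1]
            f[i, j, j:] += f[i - 1, j, : u_max + 1 - j]
    return f[nx, ny]


def mann_whitney_u(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two-sided",
    exact_limit: int = MANNWHITNEY_EXACT_LIMIT,
) -> TestResult:
    """Mann-Whitney U test; U counts pairs where x beats y (ties half).

    Satisfies U(x, y) + U(y, x) = n_x * n_y.
    """
    if alternative not in ALTERNATIVES:
        raise ValueError(f"alternative must be one of {ALTERNATIVES}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    nx, ny = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u = float(ranks[:nx].sum() - nx * (nx + 1) / 2.0)
    has_ties = np.unique(pooled).size < pooled.size

    if nx * ny <= exact_limit and not has_ties:
        counts = _mwu_null_counts(nx, ny)
        denom = counts.sum()
        ui = int(round(u))
        cdf = counts[: ui + 1].sum() / denom
        sf = counts[ui:].sum() / denom
        note = "exact (labeling enumeration)"
    else:
        n = nx + ny
        mu = nx * ny / 2.0
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
        sigma = np.sqrt(nx * ny / 12.0 * ((n + 1) - tie_term))
        cdf = float(sps.norm.cdf((u - mu + 0.5) / sigma))
        sf = float(sps.norm.sf((u - mu - 0.5) / sigma))
        note = "normal approximation, tie + continuity corrected"

    if alternative == "two-sided":
        p = _two_sided_from_tails(cdf, sf)
    elif alternative == "greater":
        p = min(1.0, sf)
    else:
        p = min(1.0, cdf)
    return TestResult("mann_whitney_u", u, p, (nx, ny), note)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    return float(a @ b / np.sqrt((a @ a) * (b @ b)))


def spearman_rho(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two-sided",
    exact_limit: int = SPEARMAN_EXACT_LIMIT,
) -> TestResult:
    """Spearman rank correlation with exact permutation p for small n."""
    if alternative not in ALTERNATIVES:
        raise ValueError(f"alternative must be one of {ALTERNATIVES}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("rho undefined for a constant input vector")
    n = x.size
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = _pearson(rx, ry)

    if n <= exact_limit:
        eps = 1e-12
        ge = le = total = 0
        for perm in itertools.permutations(range(n)):
            r = _pearson(rx, ry[list(perm)])
            total += 1
            if r >= rho - eps:
                ge += 1
            if r <= rho + eps:
                le += 1
        cdf, sf = le / total, ge / total
        note = "exact (permutation enumeration)"
    else:
        if abs(rho) >= 1.0 - 1e-15:
            sf = 0.0 if rho > 0 else 1.0
            cdf = 1.0 - sf
        else:
            t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
            sf = float(sps.t.sf(t, df=n - 2))
            cdf = float(sps.t.cdf(t, df=n - 2))
        note = "t approximation"

    if alternative == "two-sided":
        p = _two_sided_from_tails(cdf, sf)
    elif alternative == "greater":
        p = min(1.0, sf)
    else:
        p = min(1.0, cdf)
    return TestResult("spearman_rho", rho, p, (n,), note)


def fisher_exact_right(table: Sequence[Sequence[int]]) -> TestResult:
    """Right-tailed Fisher exact test: P(X >= a) under fixed margins.

    ``table`` is [[a, b], [c, d]] with the enrichment cell top-left.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    total = a + b + c + d
    if total < 1:
        raise ValueError("grand total must be >= 1")
    # X ~ Hypergeometric(M=total, n=a+b successes, N=a+c draws)
    p = float(sps.hypergeom.sf(a - 1, total, a + b, a + c))
    return TestResult("fisher_exact_right", float(a), min(1.0, p), (total,), "exact hypergeometric tail")


def mean_relative_increase(
    nt, t, basis: str = "group_means"
) -> float:
    """Percent increase of tumour over non-tumour values.

    ``group_means``: 100 * (mean_t - mean_nt) / mean_nt.
    ``per_patient``: mean over patients of 100 * (t_i - nt_i) / nt_i.
    """
    nt = np.atleast_1d(np.asarray(nt, dtype=float))
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if basis == "group_means":
        mean_nt = nt.mean()
        if mean_nt <= 0:
            raise ValueError("non-tumour mean must be positive")
        return float(100.0 * (t.mean() - mean_nt) / mean_nt)
    if basis == "per_patient":
        if nt.size != t.size:
            raise ValueError("per_patient basis requires paired values")
        if np.any(nt <= 0):
            raise ValueError("non-tumour values must be positive")
        return float(np.mean(100.0 * (t - nt) / nt))
    raise ValueError(f"basis must be group_means or per_patient, got {basis!r}")


def covariate_r2(x: Sequence[float], y: Sequence[float]) -> float:
    """Ordinary least-squares R^2 of y on a single covariate x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.unique(x).size == 1:
        raise ValueError("constant covariate")
    if np.unique(y).size == 1:
        return 0.0
    return _pearson(x, y) ** 2


def summarize_groups(
    datasets: dict[str, tuple[list[SampleSummary], dict[str, tuple[str, str]]]],
    metric: str = "pct_dpm",
):
    """Group means/SDs and the paired + unpaired test battery.

    ``datasets`` maps dataset_id -> (per-sample summaries, NT/T pairs).
    Returns two pandas DataFrames: per-(dataset, tissue) group summaries
    and test results.  Paired Wilcoxon runs within each dataset that has
    pairs; unpaired Mann-Whitney runs between every pair of groups.
    Groups with a single sample report a mean with no SD and are
    excluded from tests (noted).
    """
    import pandas as pd

    groups: list[GroupSummary] = []
    values: dict[tuple[str, str], np.ndarray] = {}
    tests: list[dict] = []

    for dataset_id, (summaries, pairs) in datasets.items():
        by_tissue: dict[str, list[float]] = {}
        by_sample = {s.sample_id: s for s in summaries}
        for s in summaries:
            by_tissue.setdefault(s.tissue, []).append(getattr(s, metric))
        for tissue, vals in sorted(by_tissue.items()):
            arr = np.asarray(vals)
            groups.append(
                GroupSummary(
                    dataset_id=dataset_id,
                    tissue=tissue,
                    n=arr.size,
                    mean=float(arr.mean()),
                    sd=float(arr.std(ddof=1)) if arr.size > 1 else None,
                )
            )
            values[(dataset_id, tissue)] = arr
        if pairs:
            paired = [
                (getattr(by_sample[nt_id], metric), getattr(by_sample[t_id], metric))
                for nt_id, t_id in pairs.values()
                if nt_id in by_sample and t_id in by_sample
            ]
            if paired:
                res = wilcoxon_signed_rank(paired)
                tests.append(
                    {
                        "comparison": f"{dataset_id}: non_tumour vs tumour (paired)",
                        "test": res.test_name,
                        "statistic": res.statistic,
                        "p_value": res.p_value,
                        "n": str(res.n),
                        "method_note": res.method_note,
                    }
                )

    keys = sorted(values)
    for i, ka in enumerate(keys):
        for kb in keys[i + 1 :]:
            a, b = values[ka], values[kb]
            if a.size < 2 or b.size < 2:
                tests.append(
                    {
                        "comparison": f"{ka[0]}/{ka[1]} vs {kb[0]}/{kb[1]}",
                        "test": "mann_whitney_u",
                        "statistic": np.nan,
                        "p_value": np.nan,
                        "n": str((a.size, b.size)),
                        "method_note": "skipped: group with n < 2",
                    }
                )
                continue
            res = mann_whitney_u(a, b)
            tests.append(
                {
                    "comparison": f"{ka[0]}/{ka[1]} vs {kb[0]}/{kb[1]}",
                    "test": res.test_name,
                    "statistic": res.statistic,
                    "p_value": res.p_value,
                    "n": str(res.n),
                    "method_note": res.method_note,
                }
            )

    group_frame = pd.DataFrame([g.__dict__ for g in groups])
    test_frame = pd.DataFrame(
        tests, columns=["comparison", "test", "statistic", "p_value", "n", "method_note"]
    )
    return group_frame, test_frame
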