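"""Statistical procedures for the ambulance-vs-AED comparison and for
survey reliability.

* Shapiro–Wilk normality gatekeeper (Royston's approximation, via scipy).
* Paired Wilcoxon signed-rank test with an exact null (dynamic programming
  over the sign-flip distribution of the positive-rank sum) for small
  tie-free samples and a tie-corrected normal approximation otherwise; a
  z statistic is reported in both regimes.
* Descriptive summaries with Student-t or percentile-bootstrap confidence
  intervals for the mean.
* Cronbach's alpha for Likert-scale internal consistency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PairedComparison",
    "WilcoxonResult",
    "NormalityResult",
    "SummaryStats",
    "CronbachResult",
    "wilcoxon_signed_rank",
    "rank_sum_test",
    "signed_rank_null_cdf",
    "shapiro_wilk",
    "summarize_times",
    "cronbach_alpha",
    "read_likert_csv",
]


@dataclass
class PairedComparison:
    """Two equal-length paired vectors of response times (seconds).

    Entries must be finite: unreachable (+inf) points are excluded
    upstream, with the exclusion count reported alongside.
    """

    labels: tuple[str, str]
    a: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.a.shape != self.b.shape or self.a.ndim != 1 or len(self.a) < 1:
            raise ValueError("a and b must be equal-length 1-D vectors, n >= 1")
        if not (np.isfinite(self.a).all() and np.isfinite(self.b).all()):
            raise ValueError("paired vectors must be finite; exclude +inf upstream")


@dataclass
class WilcoxonResult:
    w_plus: float
    w_minus: float
    n_effective: int
    z: float
    p: float
    method: str  # exact | normal_approx
    n_zero: int = 0
    degenerate: bool = False


_NULL_CACHE: dict[int, np.ndarray] = {}


def signed_rank_null_cdf(n: int) -> np.ndarray:
    """Null distribution of the positive-rank sum W+ for n tie-free pairs.

    Returns counts[w] = number of the 2^n sign assignments with W+ = w,
    for w = 0 .. n(n+1)/2, built by dynamic programming (each rank is
    independently in the positive set or not). Cached per n; treat the
    returned array as read-only.
    """
    if n in _NULL_CACHE:
        return _NULL_CACHE[n]
    max_w = n * (n + 1) // 2
    counts = np.zeros(max_w + 1, dtype=float)
    counts[0] = 1.0
    for r in range(1, n + 1):
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:-r]
        counts = counts + shifted
    _NULL_CACHE[n] = counts
    return counts


def wilcoxon_signed_rank(
    pc: PairedComparison,
    exact_limit: int = 25,
    continuity: bool = False,
    zero_method: str = "wilcox",
) -> WilcoxonResult:
    """Paired Wilcoxon signed-rank test on differences d = a − b.

    Zero differences are dropped (Wilcoxon's convention; ``zero_method=
    "pratt"`` ranks them first and then discards their ranks). Absolute
    differences are ranked with midranks for ties. The two-sided p is
    exact — by enumeration of the sign-flip null — when the effective
    sample is tie-free, zero-free and no larger than ``exact_limit``;
    otherwise a tie-corrected normal approximation is used, optionally
    with a continuity correction. The z statistic is computed in both
    regimes (z > 0 means a tends to exceed b).
    """
    if zero_method not in ("wilcox", "pratt"):
        raise ValueError(f"unknown zero_method {zero_method!r}")
    d = pc.a - pc.b
    n_zero = int(np.sum(d == 0))
    if zero_method == "wilcox":
        d_ranked = d[d != 0]
        ranks = sps.rankdata(np.abs(d_ranked)) if len(d_ranked) else np.array([])
    else:  # pratt: rank zeros too, then drop their ranks
        ranks_all = sps.rankdata(np.abs(d))
        keep = d != 0
        d_ranked = d[keep]
        ranks = ranks_all[keep]
    n_eff = len(d_ranked)
    if n_eff == 0:
        return WilcoxonResult(0.0, 0.0, 0, 0.0, 1.0, "exact", n_zero, degenerate=True)

    w_plus = float(ranks[d_ranked > 0].sum())
    w_minus = float(ranks[d_ranked < 0].sum())

    # normal approximation pieces (used for z in every regime)
    if zero_method == "wilcox":
        mn = n_eff * (n_eff + 1) / 4.0
        var = n_eff * (n_eff + 1) * (2 * n_eff + 1) / 24.0
    else:
        m = len(d)
        mn = m * (m + 1) / 4.0 - n_zero * (n_zero + 1) / 4.0
        var = (
            m * (m + 1) * (2 * m + 1) / 24.0
            - n_zero * (n_zero + 1) * (2 * n_zero + 1) / 24.0
        )
    _, tie_counts = np.unique(np.abs(d_ranked), return_counts=True)
    var -= float(((tie_counts**3 - tie_counts) / 48.0).sum())
    has_ties = bool(np.any(tie_counts > 1))
    if var <= 0:
        return WilcoxonResult(
            w_plus, w_minus, n_eff, 0.0, 1.0, "normal_approx", n_zero, degenerate=True
        )
    dev = w_plus - mn
    cc = 0.5 * np.sign(dev) if continuity else 0.0
    z = float((dev - cc) / math.sqrt(var))

    exact_ok = (
        zero_method == "wilcox" and not has_ties and n_zero == 0 and n_eff <= exact_limit
    )
    if exact_ok:
        counts = signed_rank_null_cdf(n_eff)
        total = counts.sum()
        w_int = int(round(w_plus))
        p_low = counts[: w_int + 1].sum() / total
        p_high = counts[w_int:].sum() / total
        p = min(1.0, 2.0 * min(p_low, p_high))
        method = "exact"
    else:
        p = float(2.0 * sps.norm.sf(abs(z)))
        method = "normal_approx"
    return WilcoxonResult(w_plus, w_minus, n_eff, z, p, method, n_zero)


def rank_sum_test(pc: PairedComparison) -> tuple[float, float]:
    """Two-independent-sample Wilcoxon rank-sum (Mann–Whitney) variant,
    provided for sensitivity analysis when pairing is questioned.
    Returns (statistic, two-sided p)."""
    res = sps.mannwhitneyu(pc.a, pc.b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


@dataclass
class NormalityResult:
    w_statistic: float
    p: float
    n: int


def shapiro_wilk(x: np.ndarray) -> NormalityResult:
    """Shapiro–Wilk normality test (Royston's approximation).

    Valid for 3 ≤ n ≤ 5000; a constant sample has no defined W.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or not (3 <= len(x) <= 5000):
        raise ValueError("Shapiro-Wilk requires a 1-D sample with 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("zero variance: constant sample has no normality statistic")
    w, p = sps.shapiro(x)
    return NormalityResult(w_statistic=float(w), p=float(p), n=len(x))


@dataclass
class SummaryStats:
    n: int
    mean: float
    median: float
    sd: float
    ci_low: float
    ci_high: float
    ci_method: str
    level: float


def summarize_times(
    times: np.ndarray,
    ci_method: str = "t",
    level: float = 0.95,
    seed: int | None = None,
    n_boot: int = 10_000,
) -> SummaryStats:
    """Mean, median, sd and a CI for the mean (Student-t or percentile
    bootstrap). Requires at least two finite values."""
    x = np.asarray(times, dtype=float)
    if x.ndim != 1 or len(x) < 2 or not np.isfinite(x).all():
        raise ValueError("need >= 2 finite values")
    n = len(x)
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    if ci_method == "t":
        half = sps.t.ppf((1 + level) / 2.0, n - 1) * sd / math.sqrt(n)
        lo, hi = mean - half, mean + half
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, n, size=(n_boot, n))
        boot_means = x[idx].mean(axis=1)
        alpha = (1 - level) / 2.0
        lo, hi = np.quantile(boot_means, [alpha, 1 - alpha]).tolist()
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return SummaryStats(
        n=n,
        mean=mean,
        median=float(np.median(x)),
        sd=sd,
        ci_low=float(lo),
        ci_high=float(hi),
        ci_method=ci_method,
        level=level,
    )


@dataclass
class CronbachResult:
    alpha: float
    k_items: int
    n_respondents: int


def cronbach_alpha(m: np.ndarray | pd.DataFrame) -> CronbachResult:
    """Cronbach's alpha for a respondents × items matrix.

    alpha = k/(k−1) · (1 − Σ item variances / variance of total scores),
    with n−1 denominators throughout. The total-score variance must be
    positive.
    """
    x = np.asarray(m, dtype=float)
    if x.ndim != 2:
        raise ValueError("need a 2-D respondents x items matrix")
    n, k = x.shape
    if k < 2 or n < 2:
        raise ValueError("need >= 2 items and >= 2 respondents")
    if np.isnan(x).any():
        raise ValueError("missing cells are not supported")
    item_vars = x.var(axis=0, ddof=1)
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise ValueError("zero total-score variance")
    alpha = k / (k - 1) * (1.0 - item_vars.sum() / total_var)
    return CronbachResult(alpha=float(alpha), k_items=k, n_respondents=n)


def read_likert_csv(path: str | Path, min_v: int = 1, max_v: int = 7) -> pd.DataFrame:
    """Read a Likert matrix CSV: respondents as rows, items as columns,
    header row of item ids. Values must be integers in [min_v, max_v]."""
    df = pd.read_csv(path, comment="#")
    vals = df.to_numpy()
    if not np.issubdtype(vals.dtype, np.number) or np.any(vals != np.round(vals)):
        raise ValueError("Likert matrix must be integer-valued")
    if vals.min() < min_v or vals.max() > max_v:
        raise ValueError(f"Likert values must lie in [{min_v}, {max_v}]")
    return df
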