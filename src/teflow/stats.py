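"""Nonparametric group comparisons with Rosenthal effect sizes.

Distributions of transfer-entropy values are heavily skewed, so group
comparisons use rank-based tests: Kruskal-Wallis across settings, Wilcoxon
rank-sum / signed-rank for pairs, with normality screened beforehand by a
Monte-Carlo Lilliefors test.  Effect sizes follow Rosenthal's convention:

    Kruskal-Wallis:  r = sqrt(chi^2 / N)
    Wilcoxon:        r = W / sqrt(N)

where W is the *standardized* (z-like) Wilcoxon statistic and N the total
number of observations.  Magnitudes: small when |r| <= 0.3, medium when
0.3 < |r| < 0.5, large when |r| >= 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupTestResult",
    "lilliefors_mc",
    "kruskal_wallis_r",
    "wilcoxon_r",
    "classify_effect",
    "rosenthal_r_from_chi2",
    "rosenthal_r_from_w",
]


@dataclass(frozen=True)
class GroupTestResult:
    """Outcome of a rank-based group test.

    ``statistic`` is chi-square-distributed H for Kruskal-Wallis and the
    standardized W (z) for Wilcoxon tests; ``df`` mirrors the reporting
    convention (k-1, N-k) for Kruskal-Wallis and (N-2,) / (N-1,) for
    rank-sum / signed-rank.
    """

    test: str
    statistic: float
    df: tuple[int, ...]
    p: float
    effect_r: float
    magnitude: str
    n: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p-value {self.p} outside [0, 1]")

    def p_display(self) -> str:
        """Render tiny p-values as 'p < 0.001' rather than 0.00."""
        return "<0.001" if self.p < 0.001 else f"{self.p:.3f}"


def classify_effect(r: float) -> str:
    """Magnitude class of an effect size (|r| is used)."""
    if not np.isfinite(r):
        raise ValueError("effect size must be finite")
    a = abs(r)
    if a <= 0.3:
        return "small"
    if a < 0.5:
        return "medium"
    return "large"


def rosenthal_r_from_chi2(chi2: float, n: int) -> float:
    """r = sqrt(chi^2 / N) for a chi-square-distributed statistic."""
    if chi2 < 0 or n <= 0:
        raise ValueError("need chi2 >= 0 and n > 0")
    return float(np.sqrt(chi2 / n))


def rosenthal_r_from_w(w: float, n: int) -> float:
    """r = W / sqrt(N) for a standardized Wilcoxon statistic."""
    if n <= 0:
        raise ValueError("n must be positive")
    return float(w / np.sqrt(n))


def lilliefors_mc(
    sample: np.ndarray, B_mc: int = 2000, seed: int | np.random.Generator = 0
) -> GroupTestResult:
    """Lilliefors normality test with a Monte-Carlo null distribution.

    The statistic is the Kolmogorov-Smirnov distance between the sample and
    a normal with the sample's estimated mean and SD; because the
    parameters are estimated, the null distribution is obtained by
    simulating ``B_mc`` standard-normal samples of the same size and
    recomputing the statistic on each.
    """
    x = np.asarray(sample, dtype=float).ravel()
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(x) == 0.0:
        raise ValueError("constant sample: normality test undefined")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def lf_stat(v: np.ndarray) -> float:
        v = np.sort(v)
        z = (v - v.mean()) / v.std(ddof=1)
        cdf = sps.norm.cdf(z)
        i = np.arange(1, v.size + 1)
        return float(np.max(np.maximum(cdf - (i - 1) / v.size, i / v.size - cdf)))

    d_obs = lf_stat(x)
    null = np.empty(B_mc)
    draws = rng.standard_normal((B_mc, n))
    for b in range(B_mc):
        null[b] = lf_stat(draws[b])
    p = float((np.sum(null >= d_obs) + 1) / (B_mc + 1))
    r = 0.0
    return GroupTestResult(
        test="lilliefors_mc", statistic=d_obs, df=(n,), p=p,
        effect_r=r, magnitude=classify_effect(r), n=n,
    )


def kruskal_wallis_r(groups: list[np.ndarray]) -> GroupTestResult:
    """Kruskal-Wallis H (tie-corrected) with effect size r = sqrt(H / N)."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float).ravel() for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("empty group")
    h, p = sps.kruskal(*arrays)
    n = int(sum(a.size for a in arrays))
    k = len(arrays)
    r = rosenthal_r_from_chi2(float(h), n)
    return GroupTestResult(
        test="kruskal_wallis", statistic=float(h), df=(k - 1, n - k), p=float(p),
        effect_r=r, magnitude=classify_effect(r), n=n,
    )


def _ranksum_z(a: np.ndarray, b: np.ndarray) -> float:
    """Standardized rank-sum statistic with tie and continuity corrections."""
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    w = ranks[:n1].sum()
    mean_w = n1 * (n1 + n2 + 1) / 2.0
    n = n1 + n2
    # tie correction of the rank-sum variance
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1))
    var_w = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var_w <= 0:
        raise ValueError("zero rank variance (all values tied)")
    diff = w - mean_w
    cc = 0.5 * np.sign(diff) if diff != 0 else 0.0
    return float((diff - cc) / np.sqrt(var_w))


def _signed_rank_z(d: np.ndarray) -> float:
    """Standardized signed-rank statistic, positive for positive shifts.

    Zero differences are dropped (Wilcoxon's rule); the variance carries a
    tie correction and the statistic a 0.5 continuity correction.
    """
    d = d[d != 0]
    n = d.size
    ranks = sps.rankdata(np.abs(d))
    t_plus = ranks[d > 0].sum()
    mean_t = n * (n + 1) / 4.0
    var_t = n * (n + 1) * (2 * n + 1) / 24.0
    _, counts = np.unique(np.abs(d), return_counts=True)
    var_t -= np.sum(counts**3 - counts) / 48.0
    if var_t <= 0:
        raise ValueError("zero signed-rank variance (all magnitudes tied)")
    diff = t_plus - mean_t
    cc = 0.5 * np.sign(diff) if diff != 0 else 0.0
    return float((diff - cc) / np.sqrt(var_t))


def wilcoxon_r(
    sample_a: np.ndarray,
    sample_b: np.ndarray | None = None,
    mode: str = "ranksum",
    n_override: int | None = None,
) -> GroupTestResult:
    """Wilcoxon test reported as standardized W with r = W / sqrt(N).

    ``mode='ranksum'`` compares two independent samples (N = n1 + n2,
    df N-2); ``mode='signed_rank'`` tests paired differences — pass the
    differences as ``sample_a`` (or two paired samples), N = number of
    pairs, df N-1.  ``n_override`` substitutes the N entering the effect
    size when a protocol defines it differently from the raw count.
    """
    a = np.asarray(sample_a, dtype=float).ravel()
    if mode == "ranksum":
        if sample_b is None:
            raise ValueError("ranksum mode needs two samples")
        b = np.asarray(sample_b, dtype=float).ravel()
        if a.size == 0 or b.size == 0:
            raise ValueError("empty sample")
        z = _ranksum_z(a, b)
        n = a.size + b.size
        df = (n - 2,)
    elif mode == "signed_rank":
        d = a if sample_b is None else a - np.asarray(sample_b, dtype=float).ravel()
        if np.all(d == 0):
            raise ValueError("all paired differences are zero")
        z = _signed_rank_z(d)
        n = d.size
        df = (n - 1,)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    p = float(2.0 * sps.norm.sf(abs(z)))
    n_eff = n if n_override is None else int(n_override)
    r = rosenthal_r_from_w(z, n_eff)
    return GroupTestResult(
        test=mode, statistic=z, df=df, p=min(p, 1.0),
        effect_r=r, magnitude=classify_effect(r), n=n_eff,
    )
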