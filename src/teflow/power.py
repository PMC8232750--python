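"""Repeated-measures sensitivity analysis and effect-size conversions.

Sensitivity analysis answers: given the sample size, alpha and power, what
is the smallest effect a repeated-measures ANOVA (within factor) could have
detected?  The noncentral-F convention follows the G*Power "within factors"
dialog: with n subjects, g groups, m repeated measures and repeated-measure
correlation rho, the noncentrality is

    lambda = f^2 * n * m / (1 - rho)

with numerator df (m - 1) and error df (n - g)(m - 1) (nonsphericity
correction fixed at 1).  The conversion chain between ANOVA effect-size
scales is closed-form:

    eta^2 = f^2 / (1 + f^2),    d = 2 f,    r = d / sqrt(d^2 + 4).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy import stats as sps

__all__ = [
    "SensitivityResult",
    "convert_f",
    "repeated_measures_power",
    "min_detectable_f",
    "sensitivity_analysis",
]


@dataclass(frozen=True)
class SensitivityResult:
    """Smallest detectable effect and its equivalents on other scales."""

    f: float
    eta_squared: float
    cohens_d: float
    r_equiv: float
    alpha: float
    power: float
    n_total: int
    n_groups: int
    n_measurements: int
    rho: float

    def __post_init__(self) -> None:
        if not (0 <= self.eta_squared < 1):
            raise ValueError("eta_squared outside [0, 1)")
        expected = self.f**2 / (1 + self.f**2)
        if abs(self.eta_squared - expected) > 1e-9:
            raise ValueError("inconsistent eta_squared for f")


def convert_f(f: float) -> tuple[float, float, float]:
    """(eta^2, Cohen's d, equivalent r) for Cohen's f.

    f = 0.258 maps to eta^2 = 0.062, d = 0.516 and r = 0.2498 (full
    precision is carried; printed values are commonly truncated).
    """
    if f < 0:
        raise ValueError("f must be >= 0")
    eta2 = f**2 / (1.0 + f**2)
    d = 2.0 * f
    r = d / np.sqrt(d**2 + 4.0)
    return float(eta2), float(d), float(r)


def _dfs(n_total: int, n_groups: int, n_measurements: int) -> tuple[float, float]:
    df1 = n_measurements - 1
    df2 = (n_total - n_groups) * (n_measurements - 1)
    if df1 < 1 or df2 < 1:
        raise ValueError("degenerate design: non-positive degrees of freedom")
    return float(df1), float(df2)


def repeated_measures_power(
    f: float,
    alpha: float = 0.05,
    n_total: int = 20,
    n_groups: int = 2,
    n_measurements: int = 6,
    rho: float = 0.4,
) -> float:
    """Power of the within-factor repeated-measures F test at effect size f."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if not -1 < rho < 1:
        raise ValueError("rho must be in (-1, 1)")
    if f < 0:
        raise ValueError("f must be >= 0")
    df1, df2 = _dfs(n_total, n_groups, n_measurements)
    lam = f**2 * n_total * n_measurements / (1.0 - rho)
    f_crit = sps.f.ppf(1.0 - alpha, df1, df2)
    if lam == 0.0:
        return float(alpha)
    return float(sps.ncf.sf(f_crit, df1, df2, lam))


def min_detectable_f(
    alpha: float = 0.05,
    power: float = 0.8,
    n_total: int = 20,
    n_groups: int = 2,
    n_measurements: int = 6,
    rho: float = 0.4,
) -> float:
    """Root-find the f whose repeated-measures power equals the target.

    Monotone in f, so a bracketed Brent search suffices; power targets that
    cannot be reached below f = 10 raise.
    """
    if not 0 < power < 1:
        raise ValueError("power must be in (0, 1)")

    def gap(f: float) -> float:
        return repeated_measures_power(f, alpha, n_total, n_groups, n_measurements, rho) - power

    lo, hi = 1e-8, 10.0
    if gap(hi) < 0:
        raise ValueError("target power unattainable for any effect size f <= 10")
    return float(optimize.brentq(gap, lo, hi, xtol=1e-10))


def sensitivity_analysis(
    alpha: float = 0.05,
    power: float = 0.8,
    n_total: int = 20,
    n_groups: int = 2,
    n_measurements: int = 6,
    rho: float = 0.4,
) -> SensitivityResult:
    """Smallest detectable effect with its conversions, as one record."""
    f = min_detectable_f(alpha, power, n_total, n_groups, n_measurements, rho)
    eta2, d, r = convert_f(f)
    return SensitivityResult(
        f=f, eta_squared=eta2, cohens_d=d, r_equiv=r,
        alpha=alpha, power=power, n_total=n_total, n_groups=n_groups,
        n_measurements=n_measurements, rho=rho,
    )
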