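"""Inverse-variance-weighted group statistics and power analysis.

Each subject contributes an entropy-production mean ``H_i`` (bits) and
variance ``σ_i²``; the group mean weights subjects by ``1/σ_i²``::

    H̄ = Σ_i (H_i / σ_i²) / Σ_i (1 / σ_i²),    var(H̄) = 1 / Σ_i (1 / σ_i²)

with the 95% CI ``H̄ ± 1.96·√var(H̄)``.  Group differences are assessed with
a two-sample z-test, ``Z = (H̄₁ − H̄₂) / √(var₁ + var₂)`` and
``p = 2·Φ(−|Z|)``, reported with Hedges' g (pooled-SD standardized mean
difference with the small-sample correction ``J = 1 − 3/(4(n₁+n₂)−9)``).
The power routines implement the matching two-sided two-sample z-test for
means: ``power = Φ(d·√(n/2) − z_{1−α/2})``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

__all__ = [
    "GroupSummary",
    "TestResult",
    "weighted_group_mean",
    "summary_from_ci",
    "ci_to_variance",
    "two_sample_z",
    "hedges_g",
    "power_at_n",
    "power_n_per_group",
]

_Z95 = 1.96  # CI half-width multiplier, by convention


@dataclass(frozen=True)
class GroupSummary:
    """Inverse-variance-weighted group mean with its variance and 95% CI."""

    H_bar: float
    var_H_bar: float
    ci95: tuple[float, float]
    n: int


@dataclass(frozen=True)
class TestResult:
    Z: float
    p: float
    g: float | None = None


def weighted_group_mean(
    H: np.ndarray, sigma2: np.ndarray, n_min: int = 2
) -> GroupSummary:
    """Inverse-variance-weighted mean, variance and 95% CI of a group."""
    H = np.asarray(H, dtype=float)
    sigma2 = np.asarray(sigma2, dtype=float)
    if H.shape != sigma2.shape or H.ndim != 1:
        raise ValueError("H and sigma2 must be matching 1-D arrays")
    if H.size < n_min:
        raise ValueError(f"group must have at least {n_min} subjects")
    if np.any(sigma2 <= 0):
        raise ValueError("subject variances must be positive")
    w = 1.0 / sigma2
    h_bar = float((H * w).sum() / w.sum())
    var = float(1.0 / w.sum())
    half = _Z95 * np.sqrt(var)
    return GroupSummary(
        H_bar=h_bar, var_H_bar=var, ci95=(h_bar - half, h_bar + half), n=H.size
    )


def summary_from_ci(mean: float, ci_low: float, ci_high: float, n: int) -> GroupSummary:
    """Reconstruct a GroupSummary from a published mean and 95% CI."""
    return GroupSummary(
        H_bar=mean,
        var_H_bar=ci_to_variance(mean, ci_low, ci_high),
        ci95=(ci_low, ci_high),
        n=n,
    )


def ci_to_variance(mean: float, ci_low: float, ci_high: float) -> float:
    """Invert ``CI = mean ± 1.96·√var``: ``var = ((hi − lo) / (2·1.96))²``."""
    if not ci_low < mean < ci_high:
        raise ValueError("CI must bracket the mean")
    return float(((ci_high - ci_low) / (2.0 * _Z95)) ** 2)


def two_sample_z(g1: GroupSummary, g2: GroupSummary) -> TestResult:
    """Two-sided two-sample z-test on weighted group means."""
    var = g1.var_H_bar + g2.var_H_bar
    if var <= 0:
        raise ValueError("combined variance must be positive")
    z = (g1.H_bar - g2.H_bar) / np.sqrt(var)
    p = float(2.0 * norm.cdf(-abs(z)))
    return TestResult(Z=float(z), p=min(p, 1.0) if p > 0 else p)


def hedges_g(sample1: np.ndarray, sample2: np.ndarray) -> float:
    """Hedges' g: bias-corrected standardized mean difference.

    ``g = J · (mean₁ − mean₂) / s_pooled`` with the Bessel-corrected pooled
    SD and ``J = 1 − 3/(4(n₁+n₂) − 9)``.
    """
    x1 = np.asarray(sample1, dtype=float)
    x2 = np.asarray(sample2, dtype=float)
    n1, n2 = x1.size, x2.size
    if n1 < 2 or n2 < 2:
        raise ValueError("both samples need at least 2 observations")
    s2 = ((n1 - 1) * x1.var(ddof=1) + (n2 - 1) * x2.var(ddof=1)) / (n1 + n2 - 2)
    if s2 <= 0:
        raise ValueError("pooled SD is zero")
    J = 1.0 - 3.0 / (4.0 * (n1 + n2) - 9.0)
    return float(J * (x1.mean() - x2.mean()) / np.sqrt(s2))


def power_at_n(effect: float, alpha: float, n_per_group: int) -> float:
    """Power of the two-sided two-sample z-test at ``n_per_group`` subjects."""
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    z_crit = norm.ppf(1.0 - alpha / 2.0)
    return float(norm.cdf(effect * np.sqrt(n_per_group / 2.0) - z_crit))


def power_n_per_group(
    effect: float, alpha: float = 0.05, target_power: float = 0.8
) -> int:
    """Smallest per-group n with ``power_at_n(effect, alpha, n) >= target``."""
    if effect <= 0:
        raise ValueError("effect must be positive")
    if not 0 < target_power < 1:
        raise ValueError("target_power must be in (0, 1)")
    z_crit = norm.ppf(1.0 - alpha / 2.0)
    z_pow = norm.ppf(target_power)
    n = max(2, int(np.floor(2.0 * ((z_crit + z_pow) / effect) ** 2)))
    while power_at_n(effect, alpha, n) < target_power:
        n += 1
    while n > 2 and power_at_n(effect, alpha, n - 1) >= target_power:
        n -= 1
    return n
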