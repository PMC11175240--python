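"""A-priori sample size for a two-sided two-sample t-test.

Used to set the augmentation target: the smallest per-group n whose
noncentral-t power at the design effect size reaches the requested level.
With the study design (|d| >= 0.51, alpha = 0.05, power = 0.95, 1:1) this
yields approximately 100 subjects per class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class PowerSpec:
    """Design of the a-priori power analysis."""

    delta: float = 0.51          # standardized effect size (Cohen's d)
    alpha: float = 0.05          # two-sided significance level
    power: float = 0.95          # 1 - beta
    allocation: float = 1.0      # n2 / n1 ratio

    def validate(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0.0 < self.power < 1.0:
            raise ValueError("power must lie in (0, 1)")
        if self.delta <= 0:
            raise ValueError("delta must be > 0")
        if self.allocation <= 0:
            raise ValueError("allocation ratio must be > 0")


def achieved_power(n1: int, n2: int, delta: float, alpha: float = 0.05) -> float:
    """Exact (noncentral-t) power of the two-sided two-sample t-test."""
    df = n1 + n2 - 2
    if df < 1:
        return 0.0
    ncp = delta * np.sqrt(n1 * n2 / (n1 + n2))
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(stats.nct.sf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp))


def normal_approx_n(spec: PowerSpec) -> float:
    """Normal-approximation per-group n (cross-check for the exact search)."""
    za = stats.norm.ppf(1.0 - spec.alpha / 2.0)
    zb = stats.norm.ppf(spec.power)
    r = spec.allocation
    return (1.0 + 1.0 / r) * ((za + zb) / spec.delta) ** 2


def required_n_per_group(spec: PowerSpec | None = None,
                         max_n: int = 10**6, **kwargs) -> int:
    """Smallest per-group n (group 1) achieving the requested power.

    Group 2 size is ``round(allocation * n)``.  Keyword arguments build a
    :class:`PowerSpec` when none is given.
    """
    spec = spec or PowerSpec(**kwargs)
    spec.validate()
    n = max(2, int(np.floor(normal_approx_n(spec) * 0.5)))
    while n <= max_n:
        n2 = max(2, int(round(spec.allocation * n)))
        if achieved_power(n, n2, spec.delta, spec.alpha) >= spec.power:
            return n
        n += 1
    raise ValueError("requested power unreachable within the search limit")
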