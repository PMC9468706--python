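"""Analytic power for two-sample MR with a binary outcome.

Normal approximation: the SE of the causal log-OR estimate is

    se_b = 1 / sqrt(n_outcome * r2_exposure * cf * (1 - cf))

with cf the outcome case fraction and r2_exposure the variance of the
exposure explained by the instruments. Two-sided power at level alpha is
Phi(|log OR| / se_b - z_{1-alpha/2}); note that at OR = 1 this returns
Phi(-z) ~ alpha/2, the probability of rejecting in one tail.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["PowerQuery", "mr_power_binary", "minimum_detectable_or", "power_curve"]


@dataclass(frozen=True)
class PowerQuery:
    n_outcome: int
    case_fraction: float
    r2_exposure: float
    or_alt: float
    alpha: float = 0.05

    def __post_init__(self):
        if self.n_outcome < 1:
            raise ValueError(f"n_outcome must be positive, got {self.n_outcome}")
        if not (0 < self.case_fraction < 1):
            raise ValueError(f"case_fraction must be in (0,1), got {self.case_fraction}")
        if not (0 < self.r2_exposure < 1):
            raise ValueError(f"r2_exposure must be in (0,1), got {self.r2_exposure}")
        if self.or_alt <= 0:
            raise ValueError(f"or_alt must be > 0, got {self.or_alt}")
        if not (0 < self.alpha < 1):
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")


def _se_b(n_outcome: int, case_fraction: float, r2_exposure: float) -> float:
    return 1.0 / math.sqrt(
        n_outcome * r2_exposure * case_fraction * (1.0 - case_fraction)
    )


def mr_power_binary(q: PowerQuery) -> float:
    """Two-sided power to detect ``or_alt``; symmetric in OR <-> 1/OR."""
    se = _se_b(q.n_outcome, q.case_fraction, q.r2_exposure)
    z_crit = stats.norm.ppf(1.0 - q.alpha / 2.0)
    p = float(stats.norm.cdf(abs(math.log(q.or_alt)) / se - z_crit))
    # the exact value is strictly inside (0,1); keep the float there too
    return min(max(p, 5e-324), 1.0 - 1e-16)


def minimum_detectable_or(
    n_outcome: int,
    case_fraction: float,
    r2_exposure: float,
    alpha: float = 0.05,
    target_power: float = 0.8,
) -> float:
    """Smallest OR > 1 with power >= target_power (closed-form inverse).

    Round-trips through :func:`mr_power_binary` to ~1e-9.
    """
    if not (alpha < target_power < 1):
        raise ValueError(
            f"target_power must be in (alpha, 1), got {target_power} (alpha={alpha})"
        )
    se = _se_b(n_outcome, case_fraction, r2_exposure)
    z_crit = stats.norm.ppf(1.0 - alpha / 2.0)
    log_or = (z_crit + stats.norm.ppf(target_power)) * se
    if not math.isfinite(log_or):
        raise ValueError("target power unattainable with these inputs")
    return math.exp(log_or)


def power_curve(
    n_outcome: int,
    case_fraction: float,
    r2_exposure: float,
    or_grid,
    alpha: float = 0.05,
):
    """Power at each OR of the grid; returns an (or, power) array pair."""
    ors = np.asarray(or_grid, dtype=float)
    pw = np.array(
        [
            mr_power_binary(
                PowerQuery(n_outcome, case_fraction, r2_exposure, float(o), alpha)
            )
            for o in ors
        ]
    )
    return ors, pw
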