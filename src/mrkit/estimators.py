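"""Causal-effect estimators for two-sample MR on harmonized instruments.

All estimators work on the per-SNP (beta_exp, se_exp, beta_out, se_out)
quadruples of :class:`~mrkit.summary_io.HarmonizedInstrument`:

* :func:`wald_ratio` — single-SNP ratio estimate with a delta-method SE.
* :func:`ivw` — inverse-variance-weighted meta-analysis of the ratios,
  algebraically a zero-intercept weighted least-squares fit of outcome on
  exposure betas with weights 1/se_out^2. ``model="random_multiplicative"``
  inflates the SE by sqrt(max(Q/(L-1), 1)).
* :func:`mr_egger` — weighted regression with an unconstrained intercept;
  the intercept estimates directional pleiotropy. Exposure betas are
  oriented non-negative first (Egger is not orientation invariant), and
  inference is t-based with L-2 degrees of freedom with multiplicative
  residual inflation sqrt(max(RSS/(L-2), 1)).
* :func:`weighted_median` — interpolated 50% point of the
  inverse-variance-weighted ordered Wald ratios; SE by parametric
  bootstrap.
* :func:`weighted_mode` — argmax of a normal-kernel-smoothed, weighted
  density of the Wald ratios; SE by parametric bootstrap.

Point estimates are deterministic; bootstrap SEs are reproducible from
the recorded seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .summary_io import HarmonizedInstrument

__all__ = [
    "MREstimate",
    "wald_ratio",
    "ivw",
    "mr_egger",
    "weighted_median",
    "weighted_mode",
    "weighted_median_point",
    "weighted_mode_point",
    "f_statistic",
    "DEFAULT_SEED",
    "Z95",
]

#: default seed for bootstrap standard errors, recorded in estimates
DEFAULT_SEED = 20220830

Z95 = float(stats.norm.ppf(0.975))  # 1.959963984540054


@dataclass(frozen=True)
class MREstimate:
    """A causal (or intercept) estimate on the log-OR scale with its OR
    transform. ``pval`` is two-sided; the CI level is 95%."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snp: int
    seed: Optional[int] = None

    @property
    def or_(self) -> float:
        return math.exp(self.beta)

    @property
    def or_ci_low(self) -> float:
        return math.exp(self.ci_low)

    @property
    def or_ci_high(self) -> float:
        return math.exp(self.ci_high)

    def as_dict(self) -> dict:
        return {
            "method": self.method,
            "n_snp": self.n_snp,
            "beta": self.beta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "pval": self.pval,
            "or": self.or_,
            "or_ci_low": self.or_ci_low,
            "or_ci_high": self.or_ci_high,
            "seed": self.seed,
        }


def _normal_estimate(method, beta, se, n_snp, seed=None) -> MREstimate:
    z = beta / se if se > 0 else math.inf
    pval = min(1.0, float(2.0 * stats.norm.sf(abs(z)))) if se > 0 else 0.0
    pval = max(pval, float(np.nextafter(0, 1)))
    return MREstimate(
        method=method,
        beta=beta,
        se=se,
        ci_low=beta - Z95 * se,
        ci_high=beta + Z95 * se,
        pval=pval,
        n_snp=n_snp,
        seed=seed,
    )


def _t_estimate(method, beta, se, df, n_snp) -> MREstimate:
    tcrit = float(stats.t.ppf(0.975, df))
    pval = min(1.0, float(2.0 * stats.t.sf(abs(beta / se), df)))
    pval = max(pval, float(np.nextafter(0, 1)))
    return MREstimate(
        method=method,
        beta=beta,
        se=se,
        ci_low=beta - tcrit * se,
        ci_high=beta + tcrit * se,
        pval=pval,
        n_snp=n_snp,
    )


def _arrays(insts: Sequence[HarmonizedInstrument]):
    bx = np.array([i.beta_exp for i in insts], dtype=float)
    sx = np.array([i.se_exp for i in insts], dtype=float)
    by = np.array([i.beta_out for i in insts], dtype=float)
    sy = np.array([i.se_out for i in insts], dtype=float)
    return bx, sx, by, sy


def ratio_estimates(insts: Sequence[HarmonizedInstrument], second_order: bool = False):
    """Per-SNP Wald ratios and their delta-method SEs as arrays."""
    bx, sx, by, sy = _arrays(insts)
    if np.any(bx == 0):
        bad = [i.snp_id for i, b in zip(insts, bx) if b == 0]
        raise ZeroDivisionError(f"beta_exp is zero for {', '.join(bad)}")
    ratio = by / bx
    if second_order:
        se = np.sqrt(sy**2 / bx**2 + by**2 * sx**2 / bx**4)
    else:
        se = sy / np.abs(bx)
    return ratio, se


def wald_ratio(inst: HarmonizedInstrument, second_order: bool = False) -> MREstimate:
    """Single-SNP ratio estimate beta_out/beta_exp.

    SE is first-order delta method se_out/|beta_exp| by default;
    ``second_order=True`` adds the exposure-noise term.
    """
    ratio, se = ratio_estimates([inst], second_order=second_order)
    return _normal_estimate("wald", float(ratio[0]), float(se[0]), n_snp=1)


def ivw(
    insts: Sequence[HarmonizedInstrument],
    model: str = "random_multiplicative",
) -> MREstimate:
    """Inverse-variance-weighted combination of the per-SNP ratios.

    Equals the slope of a zero-intercept weighted least-squares fit of
    beta_out on beta_exp with weights 1/se_out^2. ``model="fixed"`` uses
    the plain WLS standard error; ``"random_multiplicative"`` multiplies
    it by sqrt(max(Q/(L-1), 1)) where Q is Cochran's Q at the fixed fit.
    """
    if model not in ("fixed", "random_multiplicative"):
        raise ValueError(f"unknown model {model!r}")
    if len(insts) == 0:
        raise ValueError("ivw requires at least one instrument")
    bx, _, by, sy = _arrays(insts)
    w = 1.0 / sy**2
    denom = float(np.sum(w * bx**2))
    beta = float(np.sum(w * bx * by)) / denom
    se = 1.0 / math.sqrt(denom)
    L = len(insts)
    method = "ivw_fe"
    if model == "random_multiplicative":
        if L == 1:
            warnings.warn(
                "random-effects IVW undefined for a single instrument; "
                "falling back to fixed",
                RuntimeWarning,
            )
        else:
            q = float(np.sum(w * (by - beta * bx) ** 2))
            se *= math.sqrt(max(q / (L - 1), 1.0))
            method = "ivw_re"
    return _normal_estimate(method, beta, se, n_snp=L)


def orient_exposure(
    insts: Sequence[HarmonizedInstrument],
) -> list[HarmonizedInstrument]:
    """Flip both betas of any instrument with beta_exp < 0, so that every
    exposure effect is non-negative (required by MR-Egger)."""
    out = []
    for i in insts:
        if i.beta_exp < 0:
            out.append(
                HarmonizedInstrument(
                    snp_id=i.snp_id,
                    beta_exp=-i.beta_exp,
                    se_exp=i.se_exp,
                    beta_out=-i.beta_out,
                    se_out=i.se_out,
                    eaf_exp=None if i.eaf_exp is None else 1 - i.eaf_exp,
                    eaf_out=None if i.eaf_out is None else 1 - i.eaf_out,
                    palindromic=i.palindromic,
                    flipped=not i.flipped,
                )
            )
        else:
            out.append(i)
    return out


def egger_fit(insts: Sequence[HarmonizedInstrument]):
    """Low-level weighted with-intercept fit on exposure-oriented betas.

    Returns (intercept, slope, se_intercept, se_slope, df, rss_w).
    """
    if len(insts) < 3:
        raise ValueError("mr_egger requires at least 3 instruments")
    oriented = orient_exposure(insts)
    bx, _, by, sy = _arrays(oriented)
    if np.ptp(bx) == 0:
        raise ValueError("mr_egger: zero variance in exposure betas (collinear)")
    w = 1.0 / sy**2
    X = np.column_stack([np.ones_like(bx), bx])
    xtwx = X.T @ (w[:, None] * X)
    xtwy = X.T @ (w * by)
    coef = np.linalg.solve(xtwx, xtwy)
    resid = by - X @ coef
    rss_w = float(np.sum(w * resid**2))
    L = len(insts)
    df = L - 2
    sigma2 = max(rss_w / df, 1.0)
    cov = sigma2 * np.linalg.inv(xtwx)
    return float(coef[0]), float(coef[1]), math.sqrt(cov[0, 0]), math.sqrt(cov[1, 1]), df, rss_w


def mr_egger(
    insts: Sequence[HarmonizedInstrument],
) -> Tuple[MREstimate, MREstimate]:
    """MR-Egger regression; returns (slope estimate, intercept estimate).

    The slope is the causal estimate; the intercept estimates the average
    directional pleiotropic effect. Inference uses t with L-2 df.
    """
    a, b, se_a, se_b, df, _ = egger_fit(insts)
    L = len(insts)
    slope = _t_estimate("egger_slope", b, se_b, df, n_snp=L)
    intercept = _t_estimate("egger_intercept", a, se_a, df, n_snp=L)
    return slope, intercept


def _weighted_median_point(ratio: np.ndarray, weight: np.ndarray) -> float:
    order = np.argsort(ratio, kind="stable")
    r = ratio[order]
    w = weight[order] / weight.sum()
    # mid-point cumulative weights; interpolate the 50% crossing
    s = np.cumsum(w) - 0.5 * w
    if 0.5 <= s[0]:
        return float(r[0])
    if 0.5 >= s[-1]:
        return float(r[-1])
    return float(np.interp(0.5, s, r))


def _bootstrap_se(
    insts: Sequence[HarmonizedInstrument],
    point_fn,
    n_boot: int,
    seed: int,
) -> float:
    """Parametric bootstrap: perturb betas by their SEs, recompute the
    point estimate, return the SD over replicates."""
    bx, sx, by, sy = _arrays(insts)
    rng = np.random.default_rng(seed)
    ests = np.empty(n_boot)
    for b in range(n_boot):
        bxb = bx + sx * rng.standard_normal(bx.size)
        byb = by + sy * rng.standard_normal(by.size)
        bxb = np.where(bxb == 0, np.finfo(float).tiny, bxb)
        ratio = byb / bxb
        se_ratio = sy / np.abs(bxb)
        ests[b] = point_fn(ratio, 1.0 / se_ratio**2)
    return float(np.std(ests, ddof=1))


def weighted_median(
    insts: Sequence[HarmonizedInstrument],
    n_boot: int = 1000,
    seed: int = DEFAULT_SEED,
) -> MREstimate:
    """Weighted-median estimator over the per-SNP Wald ratios.

    Consistent when >= 50% of the weight comes from valid instruments.
    The SE comes from ``n_boot`` parametric bootstrap replicates.
    """
    if len(insts) < 3:
        raise ValueError("weighted_median requires at least 3 instruments")
    if n_boot < 100:
        warnings.warn(
            f"n_boot={n_boot} is small; bootstrap SE will be noisy", RuntimeWarning
        )
    ratio, se_ratio = ratio_estimates(insts)
    weight = 1.0 / se_ratio**2
    beta = _weighted_median_point(ratio, weight)
    se = _bootstrap_se(insts, _weighted_median_point, n_boot, seed)
    return _normal_estimate("weighted_median", beta, se, n_snp=len(insts), seed=seed)


def _mode_bandwidth(ratio: np.ndarray, phi: float) -> float:
    sd = float(np.std(ratio, ddof=1))
    iqr = float(np.subtract(*np.percentile(ratio, [75, 25])))
    spread = min(sd, iqr / 1.349)
    return phi * 0.9 * spread * len(ratio) ** (-1 / 5)


def _weighted_mode_point(
    ratio: np.ndarray, weight: np.ndarray, phi: float = 1.0, n_grid: int = 2048
) -> float:
    h = _mode_bandwidth(ratio, phi)
    if h == 0 or not np.isfinite(h):
        return float(ratio[0])
    lo = ratio.min() - 3 * h
    hi = ratio.max() + 3 * h
    grid = np.linspace(lo, hi, n_grid)
    dens = np.zeros(n_grid)
    for r, w in zip(ratio, weight):
        dens += w * np.exp(-0.5 * ((grid - r) / h) ** 2)
    return float(grid[int(np.argmax(dens))])


def weighted_mode(
    insts: Sequence[HarmonizedInstrument],
    phi: float = 1.0,
    n_boot: int = 1000,
    seed: int = DEFAULT_SEED,
    n_grid: int = 2048,
) -> MREstimate:
    """Mode-based estimator: argmax of a normal-kernel density over the
    Wald ratios, each contributing mass proportional to its inverse
    variance. Bandwidth is ``phi * 0.9 * min(SD, IQR/1.349) * L^(-1/5)``.
    """
    if len(insts) < 3:
        raise ValueError("weighted_mode requires at least 3 instruments")
    if n_boot < 100:
        warnings.warn(
            f"n_boot={n_boot} is small; bootstrap SE will be noisy", RuntimeWarning
        )
    ratio, se_ratio = ratio_estimates(insts)
    weight = 1.0 / se_ratio**2
    beta = _weighted_mode_point(ratio, weight, phi=phi, n_grid=n_grid)
    se = _bootstrap_se(
        insts,
        lambda r, w: _weighted_mode_point(r, w, phi=phi, n_grid=n_grid),
        n_boot,
        seed,
    )
    return _normal_estimate("weighted_mode", beta, se, n_snp=len(insts), seed=seed)


def weighted_median_point(insts: Sequence[HarmonizedInstrument]) -> float:
    """Weighted-median point estimate only (no bootstrap)."""
    ratio, se_ratio = ratio_estimates(insts)
    return _weighted_median_point(ratio, 1.0 / se_ratio**2)


def weighted_mode_point(
    insts: Sequence[HarmonizedInstrument], phi: float = 1.0, n_grid: int = 2048
) -> float:
    """Weighted-mode point estimate only (no bootstrap)."""
    ratio, se_ratio = ratio_estimates(insts)
    return _weighted_mode_point(ratio, 1.0 / se_ratio**2, phi=phi, n_grid=n_grid)


def f_statistic(insts: Sequence[HarmonizedInstrument]):
    """Per-SNP instrument-strength F statistics (beta_exp/se_exp)^2 and
    their mean. Returns ``(per_snp_array, mean)``."""
    bx, sx, _, _ = _arrays(insts)
    f = (bx / sx) ** 2
    return f, float(f.mean())
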