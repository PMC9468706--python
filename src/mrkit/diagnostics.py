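"""Heterogeneity, pleiotropy, outlier and influence diagnostics.

Implements Cochran's Q at the IVW and Egger fits, the Egger intercept
test, leave-one-out IVW, funnel-plot data, and a simulation-based
global/outlier/distortion outlier analysis (PRESSO-style).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import (
    DEFAULT_SEED,
    MREstimate,
    _arrays,
    _normal_estimate,
    egger_fit,
    ivw,
    mr_egger,
    ratio_estimates,
)
from .summary_io import HarmonizedInstrument

__all__ = [
    "PressoResult",
    "DiagnosticsReport",
    "cochran_q",
    "egger_intercept_test",
    "leave_one_out",
    "funnel_data",
    "mr_presso",
    "build_report",
]


def cochran_q(insts: Sequence[HarmonizedInstrument], fit: str = "ivw"):
    """Cochran's Q heterogeneity statistic at the stated fit.

    Q = sum_j w_j (by_j - yhat_j)^2 with w_j = 1/se_out_j^2; yhat from
    the fixed-effects IVW slope (df = L-1) or the Egger regression line
    (df = L-2). Returns ``(q, df, p)`` with p from the chi-square upper
    tail.
    """
    L = len(insts)
    if fit == "ivw":
        if L < 2:
            raise ValueError("cochran_q(ivw) requires at least 2 instruments")
        bx, _, by, sy = _arrays(insts)
        beta = ivw(insts, model="fixed").beta
        w = 1.0 / sy**2
        q = float(np.sum(w * (by - beta * bx) ** 2))
        df = L - 1
    elif fit == "egger":
        if L < 3:
            raise ValueError("cochran_q(egger) requires at least 3 instruments")
        # rss_w from the egger fit is exactly the weighted residual sum
        _, _, _, _, df, q = egger_fit(insts)
    else:
        raise ValueError(f"unknown fit {fit!r}")
    p = float(stats.chi2.sf(q, df)) if df > 0 else float("nan")
    return q, df, p


def egger_intercept_test(insts: Sequence[HarmonizedInstrument]) -> MREstimate:
    """Directional-pleiotropy test: the MR-Egger intercept with t-based p."""
    _, intercept = mr_egger(insts)
    return intercept


def leave_one_out(insts: Sequence[HarmonizedInstrument]) -> pd.DataFrame:
    """Leave-one-out influence table.

    One row per excluded SNP with the random-effects IVW estimate on the
    remaining L-1 instruments, plus an ``ALL`` row for the full set.
    """
    L = len(insts)
    if L < 2:
        raise ValueError("leave_one_out requires at least 2 instruments")
    if L == 2:
        warnings.warn(
            "leave-one-out with 2 instruments reduces to single-SNP Wald ratios",
            RuntimeWarning,
        )
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for j in range(L):
            rest = [inst for k, inst in enumerate(insts) if k != j]
            est = ivw(rest, model="random_multiplicative")
            rows.append(
                {
                    "snp_id": insts[j].snp_id,
                    "beta": est.beta,
                    "se": est.se,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                    "pval": est.pval,
                    "n_snp": est.n_snp,
                }
            )
    full = ivw(insts, model="random_multiplicative")
    rows.append(
        {
            "snp_id": "ALL",
            "beta": full.beta,
            "se": full.se,
            "ci_low": full.ci_low,
            "ci_high": full.ci_high,
            "pval": full.pval,
            "n_snp": full.n_snp,
        }
    )
    return pd.DataFrame(rows)


def funnel_data(insts: Sequence[HarmonizedInstrument]) -> pd.DataFrame:
    """Per-SNP funnel coordinates: Wald ratio and 1/se(ratio)."""
    ratio, se_ratio = ratio_estimates(insts)
    return pd.DataFrame(
        {
            "snp_id": [i.snp_id for i in insts],
            "ratio": ratio,
            "precision": 1.0 / se_ratio,
        }
    )


@dataclass(frozen=True)
class PressoResult:
    """Outcome of the simulation-based outlier analysis."""

    global_rss_obs: float
    global_p: float
    outlier_pvals: dict  # snp_id -> Bonferroni-adjusted p
    outliers: list
    beta_raw: MREstimate
    beta_corrected: MREstimate
    distortion_p: Optional[float]
    n_sim: int
    seed: int

    def as_dict(self) -> dict:
        return {
            "global_rss_obs": self.global_rss_obs,
            "global_p": self.global_p,
            "outlier_pvals": self.outlier_pvals,
            "outliers": self.outliers,
            "beta_raw": self.beta_raw.as_dict(),
            "beta_corrected": self.beta_corrected.as_dict(),
            "distortion_p": self.distortion_p,
            "n_sim": self.n_sim,
            "seed": self.seed,
        }


def _loo_slopes(bx, by, w):
    """Leave-one-out fixed-effects IVW slopes, vectorized.

    Supports batched input: bx/by of shape (..., L) with w of shape (L,).
    """
    num = w * bx * by
    den = w * bx**2
    s_num = num.sum(axis=-1, keepdims=True)
    s_den = den.sum(axis=-1, keepdims=True)
    return (s_num - num) / (s_den - den)


def mr_presso(
    insts: Sequence[HarmonizedInstrument],
    n_sim: int = 1000,
    seed: int = DEFAULT_SEED,
    outlier_alpha: float = 0.05,
) -> PressoResult:
    """Simulation-based global heterogeneity, per-SNP outlier and
    distortion analysis.

    1. *Global test* — the observed weighted residual sum of squares of
       each SNP against its leave-one-out IVW fit is compared with the
       RSS distribution over ``n_sim`` parametric simulations under the
       no-pleiotropy model (betas redrawn from normal(fitted, se));
       ``global_p`` is the empirical upper-tail proportion with +1
       smoothing, so it is never 0.
    2. *Outlier test* — each SNP's simulated RSS distribution yields a
       per-SNP p-value, Bonferroni-corrected across the L SNPs; SNPs with
       adjusted p below ``outlier_alpha`` are flagged.
    3. *Distortion test* — the raw-vs-corrected IVW displacement is
       compared with the displacement distribution from removing the same
       number of random SNPs in each simulation. Absent when no outlier is
       flagged, in which case ``beta_corrected`` equals ``beta_raw``.

    Fully reproducible from ``(seed, n_sim)``.
    """
    L = len(insts)
    if L < 4:
        raise ValueError("mr_presso requires at least 4 instruments")
    bx, sx, by, sy = _arrays(insts)
    w = 1.0 / sy**2
    rng = np.random.default_rng(seed)

    loo = _loo_slopes(bx, by, w)
    rss_obs_j = w * (by - loo * bx) ** 2
    rss_obs = float(rss_obs_j.sum())

    # parametric simulations under the no-pleiotropy model: for SNP j the
    # fitted outcome mean is its leave-one-out slope times its exposure beta
    zx = rng.standard_normal((n_sim, L))
    zy = rng.standard_normal((n_sim, L))
    bx_sim = bx + sx * zx
    by_sim = loo * bx + sy * zy
    loo_sim = _loo_slopes(bx_sim, by_sim, w)
    rss_sim_j = w * (by_sim - loo_sim * bx_sim) ** 2
    rss_sim = rss_sim_j.sum(axis=1)

    global_p = (float(np.sum(rss_sim >= rss_obs)) + 1.0) / (n_sim + 1.0)

    p_raw = (np.sum(rss_sim_j >= rss_obs_j[None, :], axis=0) + 1.0) / (n_sim + 1.0)
    p_adj = np.minimum(1.0, p_raw * L)
    outlier_mask = p_adj < outlier_alpha
    ids = [i.snp_id for i in insts]
    outliers = [ids[j] for j in range(L) if outlier_mask[j]]
    outlier_pvals = {ids[j]: float(p_adj[j]) for j in range(L)}

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        beta_raw = ivw(insts, model="random_multiplicative")

    distortion_p: Optional[float] = None
    if outliers:
        kept = [i for i in insts if i.snp_id not in set(outliers)]
        if len(kept) == 0:
            raise ValueError("all instruments flagged as outliers")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            beta_corrected = ivw(kept, model="random_multiplicative")
        d_obs = abs(beta_raw.beta - beta_corrected.beta)
        # null displacement: remove the same number of random SNPs from
        # each simulated (outlier-free) data set
        k = len(outliers)
        slope_all = (w * bx_sim * by_sim).sum(axis=1) / (w * bx_sim**2).sum(axis=1)
        d_sim = np.empty(n_sim)
        for i in range(n_sim):
            drop = rng.choice(L, size=k, replace=False)
            keep = np.ones(L, dtype=bool)
            keep[drop] = False
            num = float(np.sum(w[keep] * bx_sim[i, keep] * by_sim[i, keep]))
            den = float(np.sum(w[keep] * bx_sim[i, keep] ** 2))
            d_sim[i] = abs(slope_all[i] - num / den)
        distortion_p = (float(np.sum(d_sim >= d_obs)) + 1.0) / (n_sim + 1.0)
    else:
        beta_corrected = beta_raw

    return PressoResult(
        global_rss_obs=rss_obs,
        global_p=global_p,
        outlier_pvals=outlier_pvals,
        outliers=outliers,
        beta_raw=beta_raw,
        beta_corrected=beta_corrected,
        distortion_p=distortion_p,
        n_sim=n_sim,
        seed=seed,
    )


@dataclass
class DiagnosticsReport:
    """Bundle of heterogeneity/pleiotropy/influence diagnostics for one
    harmonized instrument set."""

    q_ivw: tuple  # (q, df, p)
    q_egger: tuple
    egger_intercept: MREstimate
    loo_table: pd.DataFrame
    funnel_table: pd.DataFrame
    presso: Optional[PressoResult]

    def as_dict(self) -> dict:
        return {
            "q_ivw": {"q": self.q_ivw[0], "df": self.q_ivw[1], "p": self.q_ivw[2]},
            "q_egger": {
                "q": self.q_egger[0],
                "df": self.q_egger[1],
                "p": self.q_egger[2],
            },
            "egger_intercept": self.egger_intercept.as_dict(),
            "presso": None if self.presso is None else self.presso.as_dict(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.as_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def build_report(
    insts: Sequence[HarmonizedInstrument],
    n_sim: int = 1000,
    seed: int = DEFAULT_SEED,
    outlier_alpha: float = 0.05,
    run_presso: bool = True,
) -> DiagnosticsReport:
    """Compute the full diagnostics bundle on one instrument set."""
    presso = None
    if run_presso and len(insts) >= 4:
        presso = mr_presso(insts, n_sim=n_sim, seed=seed, outlier_alpha=outlier_alpha)
    return DiagnosticsReport(
        q_ivw=cochran_q(insts, "ivw"),
        q_egger=cochran_q(insts, "egger"),
        egger_intercept=egger_intercept_test(insts),
        loo_table=leave_one_out(insts),
        funnel_table=funnel_data(insts),
        presso=presso,
    )
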