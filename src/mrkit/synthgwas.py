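"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator draws, per SNP j (one stream, documented order):

1. minor-allele frequencies maf_j ~ Uniform(maf_range),
2. a bivariate-normal copula pair (z1, z2) with correlation
   ``inside_violation``; z1 maps to a uniform draw of the true exposure
   log-OR in ``log(exposure_or_range)``, z2 to the pleiotropic effect
   alpha_j ~ N(pleio_mean, pleio_sd^2) (applied to a Bernoulli
   ``pleio_frac`` subset),
3. alleles (ordered distinct pairs, palindromic pairs included),
4. observation noise for exposure then outcome betas.

True outcome effects are ``true_beta * bx_j + alpha_j``. Standard errors
use the binary-trait log-OR approximation
``se = 1/sqrt(2 * maf * (1 - maf) * n)`` — case fraction is absorbed into
an effective n. The LD matrix is block-diagonal with high within-block
r^2 and zero between blocks; block members are positioned within one
clumping window of each other, and blocks are placed far apart.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .instruments import LDMatrix
from .summary_io import SummaryStatRecord

__all__ = ["SimConfig", "SimTruth", "simulate_two_sample", "plant_outliers"]

_ALLELE_PAIRS = [
    (a, b) for a in "ACGT" for b in "ACGT" if a != b
]  # 12 ordered pairs, 4 of them palindromic


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters; defaults mirror the scale of the motivating
    analysis (43 instruments, exposure ORs 1.18-2.53, exposure n 14,267,
    outcome n 180,866)."""

    n_snps: int = 43
    n_exp: int = 14_267
    n_out: int = 180_866
    true_beta: float = 0.0
    maf_range: tuple = (0.1, 0.4)
    exposure_or_range: tuple = (1.18, 2.53)
    pleio_mean: float = 0.0
    pleio_sd: float = 0.0
    pleio_frac: float = 0.0
    inside_violation: float = 0.0
    n_ld_blocks: int = 5
    seed: int = 0

    def validate(self) -> "SimConfig":
        if self.n_snps < 1:
            raise ValueError(f"n_snps must be >= 1, got {self.n_snps}")
        if self.n_exp < 1 or self.n_out < 1:
            raise ValueError("sample sizes must be positive")
        lo, hi = self.maf_range
        if not (0 < lo <= hi < 0.5):
            raise ValueError(f"maf_range must satisfy 0 < lo <= hi < 0.5, got {self.maf_range}")
        olo, ohi = self.exposure_or_range
        if not (0 < olo <= ohi):
            raise ValueError(f"exposure_or_range must be ordered positive, got {self.exposure_or_range}")
        if not (0 <= self.pleio_frac <= 1):
            raise ValueError(f"pleio_frac must be in [0,1], got {self.pleio_frac}")
        if self.pleio_sd < 0:
            raise ValueError(f"pleio_sd must be >= 0, got {self.pleio_sd}")
        if abs(self.inside_violation) > 1:
            raise ValueError(f"|inside_violation| must be <= 1, got {self.inside_violation}")
        if self.n_ld_blocks < 1 or self.n_ld_blocks > self.n_snps:
            raise ValueError("n_ld_blocks must be in [1, n_snps]")
        return self


@dataclass
class SimTruth:
    """Ground truth behind one simulated data set."""

    true_beta: float
    alpha_j: np.ndarray
    bx_true: np.ndarray
    outlier_ids: list
    config: SimConfig
    seed: int

    def to_json(self, path) -> None:
        payload = {
            "true_beta": self.true_beta,
            "alpha_j": self.alpha_j.tolist(),
            "bx_true": self.bx_true.tolist(),
            "outlier_ids": list(self.outlier_ids),
            "config": asdict(self.config),
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")


# block placement: far enough apart to exceed any reasonable clumping
# window (50 Mb), block members 10 kb apart
_BLOCK_SPACING = 50_000_000
_SNP_SPACING = 10_000


def simulate_two_sample(cfg: SimConfig):
    """Generate one two-sample data set.

    Returns ``(exposure_records, outcome_records, ld, truth)``. All
    randomness comes from ``cfg.seed``; the same seed reproduces the
    tables exactly.
    """
    cfg.validate()
    n = cfg.n_snps
    rng = np.random.default_rng(cfg.seed)

    maf = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], n)

    rho = cfg.inside_violation
    z1 = rng.standard_normal(n)
    z2 = rho * z1 + np.sqrt(max(0.0, 1 - rho**2)) * rng.standard_normal(n)
    lo, hi = np.log(cfg.exposure_or_range[0]), np.log(cfg.exposure_or_range[1])
    bx_true = lo + (hi - lo) * stats.norm.cdf(z1)
    pleio_mask = rng.random(n) < cfg.pleio_frac
    alpha = np.where(pleio_mask, cfg.pleio_mean + cfg.pleio_sd * z2, 0.0)
    by_true = cfg.true_beta * bx_true + alpha

    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), n)

    se_x = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * cfg.n_exp)
    se_y = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * cfg.n_out)
    bx_obs = bx_true + se_x * rng.standard_normal(n)
    by_obs = by_true + se_y * rng.standard_normal(n)

    # block-diagonal LD; within-block r2 drawn high
    block = np.arange(n) % cfg.n_ld_blocks
    r2 = np.eye(n)
    for b in range(cfg.n_ld_blocks):
        members = np.flatnonzero(block == b)
        m = members.size
        if m < 2:
            continue
        iu, ju = np.triu_indices(m, k=1)
        vals = rng.uniform(0.6, 0.95, iu.size)
        r2[members[iu], members[ju]] = vals
        r2[members[ju], members[iu]] = vals

    px = 2.0 * stats.norm.sf(np.abs(bx_obs / se_x))
    py = 2.0 * stats.norm.sf(np.abs(by_obs / se_y))
    tiny = np.nextafter(0, 1)

    exposure, outcome = [], []
    snp_ids = []
    for j in range(n):
        b = int(block[j])
        rank = int(np.sum(block[: j + 1] == b)) - 1
        chrom = str(b % 22 + 1)
        pos = 1_000_000 + (b // 22) * _BLOCK_SPACING + rank * _SNP_SPACING
        ea, oa = _ALLELE_PAIRS[pair_idx[j]]
        snp_id = f"rs{j + 1:06d}"
        snp_ids.append(snp_id)
        exposure.append(
            SummaryStatRecord(
                snp_id=snp_id,
                chrom=chrom,
                pos=pos,
                effect_allele=ea,
                other_allele=oa,
                beta=float(bx_obs[j]),
                se=float(se_x[j]),
                eaf=float(maf[j]),
                pval=float(max(px[j], tiny)),
                n=cfg.n_exp,
            )
        )
        outcome.append(
            SummaryStatRecord(
                snp_id=snp_id,
                chrom=chrom,
                pos=pos,
                effect_allele=ea,
                other_allele=oa,
                beta=float(by_obs[j]),
                se=float(se_y[j]),
                eaf=float(maf[j]),
                pval=float(max(py[j], tiny)),
                n=cfg.n_out,
            )
        )

    ld = LDMatrix(snp_ids, r2)
    truth = SimTruth(
        true_beta=cfg.true_beta,
        alpha_j=alpha,
        bx_true=bx_true,
        outlier_ids=[],
        config=cfg,
        seed=cfg.seed,
    )
    return exposure, outcome, ld, truth


def plant_outliers(
    outcome: Sequence[SummaryStatRecord],
    truth: SimTruth,
    k: int,
    offset_sds: float,
    seed: int,
):
    """Shift k randomly chosen outcome betas by ``offset_sds`` of their
    own SE; returns the modified records and an updated truth with the
    planted ids recorded. ``k = 0`` is the identity."""
    n = len(outcome)
    if k >= n:
        raise ValueError(f"k={k} must be smaller than n_snps={n}")
    if k == 0:
        return list(outcome), truth
    rng = np.random.default_rng(seed)
    idx = rng.choice(n, size=k, replace=False)
    chosen = set(int(i) for i in idx)
    modified = []
    tiny = np.nextafter(0, 1)
    for j, rec in enumerate(outcome):
        if j in chosen:
            beta = rec.beta + offset_sds * rec.se
            pval = float(max(2.0 * stats.norm.sf(abs(beta / rec.se)), tiny))
            modified.append(replace(rec, beta=beta, pval=pval))
        else:
            modified.append(rec)
    new_truth = SimTruth(
        true_beta=truth.true_beta,
        alpha_j=truth.alpha_j,
        bx_true=truth.bx_true,
        outlier_ids=sorted(outcome[j].snp_id for j in chosen),
        config=truth.config,
        seed=truth.seed,
    )
    return modified, new_truth
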