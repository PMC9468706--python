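"""End-to-end analysis: instrument selection -> harmonization -> five
estimators -> diagnostics -> report bundle on disk.

Outputs (all deterministic given config + seed, byte-identical across
reruns):

* ``estimates.tsv``   — method x estimate table (OR, 95% CI, p, n_snp
  plus log-scale columns) in the conventional five-method layout.
* ``diagnostics.json``— Q statistics, Egger intercept test, PRESSO.
* ``loo.tsv``, ``funnel.tsv``, ``presso_outliers.tsv`` — figure-ready
  tables.
* ``harmonization_audit.tsv`` — every dropped SNP with its reason.
* ``manifest.json``   — package/library versions, seed, config hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import scipy
import yaml

from . import __version__
from .diagnostics import build_report
from .estimators import (
    DEFAULT_SEED,
    f_statistic,
    ivw,
    mr_egger,
    weighted_median,
    weighted_mode,
)
from .instruments import ClumpConfig, LDMatrix, clump, filter_significant
from .summary_io import harmonize, read_summary_table, write_audit

__all__ = ["AnalysisConfig", "run_analysis", "StageError"]

logger = logging.getLogger("mrkit")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class AnalysisConfig:
    exposure_path: str
    outcome_path: str
    out_dir: str
    outcome_name: str = "outcome"
    exposure_columns: dict = field(default_factory=dict)
    outcome_columns: dict = field(default_factory=dict)
    select_instruments: bool = True
    ld_matrix_path: Optional[str] = None
    clump: ClumpConfig = field(default_factory=ClumpConfig)
    palindromic_policy: str = "infer_by_eaf"
    eaf_window: float = 0.08
    n_boot: int = 1000
    phi: float = 1.0
    presso_n_sim: int = 1000
    presso_outlier_alpha: float = 0.05
    seed: int = DEFAULT_SEED

    @classmethod
    def from_dict(cls, raw: dict) -> "AnalysisConfig":
        clump_raw = raw.get("clump", {})
        est = raw.get("estimators", {})
        presso = raw.get("presso", {})
        pal = raw.get("palindromic", {})
        return cls(
            exposure_path=raw["exposure"],
            outcome_path=raw["outcome"],
            out_dir=raw["out_dir"],
            outcome_name=raw.get("outcome_name", "outcome"),
            exposure_columns=raw.get("exposure_columns") or {},
            outcome_columns=raw.get("outcome_columns") or {},
            select_instruments=bool(raw.get("select_instruments", True)),
            ld_matrix_path=raw.get("ld_matrix"),
            clump=ClumpConfig(
                p_threshold=float(clump_raw.get("p_threshold", 5e-8)),
                window_kb=int(clump_raw.get("window_kb", 10_000)),
                r2_threshold=float(clump_raw.get("r2_threshold", 0.001)),
            ),
            palindromic_policy=pal.get("policy", "infer_by_eaf"),
            eaf_window=float(pal.get("eaf_window", 0.08)),
            n_boot=int(est.get("n_boot", 1000)),
            phi=float(est.get("phi", 1.0)),
            presso_n_sim=int(presso.get("n_sim", 1000)),
            presso_outlier_alpha=float(presso.get("outlier_alpha", 0.05)),
            seed=int(raw.get("seed", DEFAULT_SEED)),
        )

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        base = Path(path).parent
        for key in ("exposure", "outcome", "out_dir", "ld_matrix"):
            if raw.get(key):
                raw[key] = str((base / raw[key]).resolve()) if not Path(raw[key]).is_absolute() else raw[key]
        return cls.from_dict(raw)

    def config_hash(self) -> str:
        payload = {
            "exposure": self.exposure_path,
            "outcome": self.outcome_path,
            "outcome_name": self.outcome_name,
            "exposure_columns": self.exposure_columns,
            "outcome_columns": self.outcome_columns,
            "select_instruments": self.select_instruments,
            "ld_matrix": self.ld_matrix_path,
            "clump": [self.clump.p_threshold, self.clump.window_kb, self.clump.r2_threshold],
            "palindromic": [self.palindromic_policy, self.eaf_window],
            "n_boot": self.n_boot,
            "phi": self.phi,
            "presso": [self.presso_n_sim, self.presso_outlier_alpha],
            "seed": self.seed,
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


_METHOD_LABELS = [
    ("egger", "MR Egger"),
    ("weighted_median", "Weighted median"),
    ("ivw", "Inverse variance weighted"),
    ("weighted_mode", "Weighted mode"),
    ("presso", "MR-PRESSO"),
]


def _estimate_row(outcome_name: str, label: str, est) -> dict:
    d = est.as_dict()
    return {
        "outcome": outcome_name,
        "method": label,
        "n_snp": d["n_snp"],
        "or": d["or"],
        "or_ci_low": d["or_ci_low"],
        "or_ci_high": d["or_ci_high"],
        "pval": d["pval"],
        "beta": d["beta"],
        "se": d["se"],
        "ci_low": d["ci_low"],
        "ci_high": d["ci_high"],
    }


def _write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def run_analysis(cfg: AnalysisConfig) -> dict:
    """Run the full analysis; returns a bundle of in-memory results and
    writes the report files under ``cfg.out_dir``."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    stage = "read_exposure"
    try:
        exposure = read_summary_table(cfg.exposure_path, cfg.exposure_columns)
        logger.info("read %d exposure records from %s", len(exposure), cfg.exposure_path)
        stage = "read_outcome"
        outcome = read_summary_table(cfg.outcome_path, cfg.outcome_columns)
        logger.info("read %d outcome records from %s", len(outcome), cfg.outcome_path)

        stage = "instrument_selection"
        if cfg.select_instruments:
            ld = LDMatrix.read(cfg.ld_matrix_path) if cfg.ld_matrix_path else None
            significant = filter_significant(exposure, cfg.clump.p_threshold)
            logger.info(
                "%d/%d exposure SNPs below p < %g",
                len(significant), len(exposure), cfg.clump.p_threshold,
            )
            selected = clump(significant, ld, cfg.clump)
            logger.info("%d SNPs retained after clumping", len(selected))
        else:
            selected = exposure

        stage = "harmonize"
        audit: list = []
        insts = harmonize(
            selected,
            outcome,
            palindromic_policy=cfg.palindromic_policy,
            eaf_window=cfg.eaf_window,
            audit=audit,
        )
        for snp_id, reason in audit:
            logger.info("dropped %s: %s", snp_id, reason)
        logger.info("%d instruments harmonized, %d dropped", len(insts), len(audit))
        write_audit(audit, out_dir / "harmonization_audit.tsv")
        if len(insts) < 3:
            raise ValueError(
                f"only {len(insts)} instruments after harmonization; need >= 3"
            )

        stage = "estimators"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            est_ivw = ivw(insts, model="random_multiplicative")
            est_egger, _ = mr_egger(insts)
            est_median = weighted_median(insts, n_boot=cfg.n_boot, seed=cfg.seed)
            est_mode = weighted_mode(insts, phi=cfg.phi, n_boot=cfg.n_boot, seed=cfg.seed)
        f_per_snp, f_mean = f_statistic(insts)

        stage = "diagnostics"
        report = build_report(
            insts,
            n_sim=cfg.presso_n_sim,
            seed=cfg.seed,
            outlier_alpha=cfg.presso_outlier_alpha,
        )
        # PRESSO row: corrected estimate when outliers exist, else the
        # headline IVW (the corrected estimate degenerates to it)
        est_presso = report.presso.beta_corrected if report.presso else est_ivw

        stage = "write_outputs"
        estimates = pd.DataFrame(
            [
                _estimate_row(cfg.outcome_name, "MR Egger", est_egger),
                _estimate_row(cfg.outcome_name, "Weighted median", est_median),
                _estimate_row(cfg.outcome_name, "Inverse variance weighted", est_ivw),
                _estimate_row(cfg.outcome_name, "Weighted mode", est_mode),
                _estimate_row(cfg.outcome_name, "MR-PRESSO", est_presso),
            ]
        )
        _write_tsv(estimates, out_dir / "estimates.tsv")
        _write_tsv(report.loo_table, out_dir / "loo.tsv")
        _write_tsv(report.funnel_table, out_dir / "funnel.tsv")
        if report.presso is not None:
            presso_tbl = pd.DataFrame(
                {
                    "snp_id": list(report.presso.outlier_pvals),
                    "p_adjusted": list(report.presso.outlier_pvals.values()),
                    "is_outlier": [
                        s in set(report.presso.outliers)
                        for s in report.presso.outlier_pvals
                    ],
                }
            )
            _write_tsv(presso_tbl, out_dir / "presso_outliers.tsv")
        report.to_json(out_dir / "diagnostics.json")

        manifest = {
            "mrkit_version": __version__,
            "numpy_version": np.__version__,
            "scipy_version": scipy.__version__,
            "pandas_version": pd.__version__,
            "seed": cfg.seed,
            "config_hash": cfg.config_hash(),
            "n_instruments": len(insts),
            "f_statistic_mean": f_mean,
            "f_statistic_min": float(f_per_snp.min()),
        }
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, exc) from exc

    return {
        "instruments": insts,
        "estimates": estimates,
        "diagnostics": report,
        "f_mean": f_mean,
        "out_dir": str(out_dir),
    }
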