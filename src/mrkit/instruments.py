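"""Instrument selection: genome-wide-significance filtering and greedy LD
clumping of exposure summary statistics."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .summary_io import SummaryStatRecord

__all__ = ["ClumpConfig", "LDMatrix", "filter_significant", "clump"]


@dataclass(frozen=True)
class ClumpConfig:
    """Thresholds for instrument selection.

    Defaults: p < 5e-8, 10 000 kb window, r^2 <= 0.001.
    """

    p_threshold: float = 5e-8
    window_kb: int = 10_000
    r2_threshold: float = 0.001

    def __post_init__(self):
        if not (0 < self.p_threshold < 1):
            raise ValueError(f"p_threshold must be in (0,1), got {self.p_threshold}")
        if self.window_kb <= 0:
            raise ValueError(f"window_kb must be > 0, got {self.window_kb}")
        if not (0 < self.r2_threshold < 1):
            raise ValueError(f"r2_threshold must be in (0,1), got {self.r2_threshold}")


class LDMatrix:
    """Symmetric matrix of squared correlations between SNPs.

    Values in [0, 1] with a unit diagonal. Pairs not covered by the
    matrix have no entry; callers decide how to treat them.
    """

    def __init__(self, snp_ids: Sequence[str], r2: np.ndarray):
        r2 = np.asarray(r2, dtype=float)
        n = len(snp_ids)
        if r2.shape != (n, n):
            raise ValueError(f"r2 shape {r2.shape} does not match {n} snp_ids")
        if not np.allclose(r2, r2.T, atol=1e-12):
            raise ValueError("r2 matrix is not symmetric")
        if not np.allclose(np.diag(r2), 1.0, atol=1e-12):
            raise ValueError("r2 diagonal must be 1")
        if r2.min() < -1e-12 or r2.max() > 1 + 1e-12:
            raise ValueError("r2 values must lie in [0, 1]")
        self.snp_ids = list(snp_ids)
        self.r2 = r2
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def get(self, a: str, b: str) -> Optional[float]:
        """r^2 between two SNPs, or None when either is not covered."""
        i = self._index.get(a)
        j = self._index.get(b)
        if i is None or j is None:
            return None
        return float(self.r2[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r2, index=self.snp_ids, columns=self.snp_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "LDMatrix":
        return cls(list(frame.index), frame.to_numpy(dtype=float))

    @classmethod
    def read(cls, path) -> "LDMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        return cls.from_frame(frame)

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", float_format="%.10g")


def filter_significant(
    records: Iterable[SummaryStatRecord], p_threshold: float = 5e-8
) -> list[SummaryStatRecord]:
    """Keep rows with pval strictly below the threshold, order preserved."""
    return [r for r in records if r.pval < p_threshold]


def clump(
    records: Sequence[SummaryStatRecord],
    ld: Optional[LDMatrix] = None,
    cfg: ClumpConfig = ClumpConfig(),
) -> list[SummaryStatRecord]:
    """Greedy LD clumping.

    Sort candidates by ascending p-value (ties broken by chrom, pos,
    snp_id for determinism), accept the best, and discard every remaining
    SNP on the same chromosome within ``cfg.window_kb`` whose r^2 with an
    accepted SNP exceeds ``cfg.r2_threshold``; repeat. A within-window
    pair with no LD entry (or ``ld is None``) is treated as exceeding the
    threshold — distance-based clumping when no panel is available.

    Returns accepted SNPs in acceptance order.
    """
    missing_pos = [r.snp_id for r in records if r.pos is None]
    if missing_pos:
        raise ValueError(f"records missing positions: {', '.join(missing_pos)}")

    window_bp = cfg.window_kb * 1000
    candidates = sorted(records, key=lambda r: (r.pval, r.chrom, r.pos, r.snp_id))
    accepted: list[SummaryStatRecord] = []
    for rec in candidates:
        conflict = False
        for kept in accepted:
            if kept.chrom != rec.chrom:
                continue
            if abs(kept.pos - rec.pos) > window_bp:
                continue
            r2 = ld.get(kept.snp_id, rec.snp_id) if ld is not None else None
            if r2 is None or r2 > cfg.r2_threshold:
                conflict = True
                break
        if not conflict:
            accepted.append(rec)
    return accepted
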