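import numpy as np
import pytest

from mrkit.summary_io import HarmonizedInstrument, SummaryStatRecord


def make_instrument(snp_id="rs1", bx=0.3, sx=0.02, by=0.03, sy=0.01, **kw):
    return HarmonizedInstrument(
        snp_id=snp_id, beta_exp=bx, se_exp=sx, beta_out=by, se_out=sy, **kw
    )


def make_instruments(bx, by, sy, sx=None, prefix="rs"):
    bx = np.asarray(bx, float)
    by = np.asarray(by, float)
    sy = np.asarray(sy, float)
    sx = np.full_like(bx, 1e-3) if sx is None else np.asarray(sx, float)
    return [
        make_instrument(f"{prefix}{j}", bx[j], sx[j], by[j], sy[j])
        for j in range(len(bx))
    ]


def random_instruments(rng, n=20, true_beta=0.1):
    """Instrument sets with realistic scales for oracle comparisons."""
    bx = rng.uniform(0.15, 0.9, n)
    sx = rng.uniform(0.005, 0.03, n)
    sy = rng.uniform(0.005, 0.05, n)
    by = true_beta * bx + sy * rng.standard_normal(n)
    return make_instruments(bx, by, sy, sx)


def make_record(snp_id="rs1", chrom="1", pos=1000, ea="A", oa="G", beta=0.2,
                se=0.05, eaf=0.3, pval=1e-9, n=10_000):
    return SummaryStatRecord(
        snp_id=snp_id, chrom=chrom, pos=pos, effect_allele=ea, other_allele=oa,
        beta=beta, se=se, eaf=eaf, pval=pval, n=n,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)
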