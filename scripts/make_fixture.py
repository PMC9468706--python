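"""Regenerate the committed pipeline fixture and its golden outputs.

Run from the repository root:

    python scripts/make_fixture.py

The fixture is a 31-instrument synthetic data set with a small negative
true effect; the golden files are the pipeline outputs of the first
verified run (checked against the WLS/bootstrap oracles in the test
suite). Both are committed as plain text and compared byte-for-byte by
tests/test_pipeline.py.
"""

import shutil
from pathlib import Path

from mrkit.pipeline import AnalysisConfig, run_analysis
from mrkit.summary_io import write_summary_table
from mrkit.synthgwas import SimConfig, simulate_two_sample

ROOT = Path(__file__).resolve().parent.parent
FIXTURE = ROOT / "tests" / "data" / "fixture"
GOLDEN = ROOT / "tests" / "data" / "golden"

CONFIG_YAML = """\
exposure: exposure.tsv
outcome: outcome.tsv
ld_matrix: ld.tsv
out_dir: out
outcome_name: depression
seed: 20220830
clump:
  p_threshold: 5.0e-8
  window_kb: 10000
  r2_threshold: 0.001
palindromic:
  policy: infer_by_eaf
  eaf_window: 0.08
estimators:
  n_boot: 500
  phi: 1.0
presso:
  n_sim: 1000
  outlier_alpha: 0.05
"""


def main():
    FIXTURE.mkdir(parents=True, exist_ok=True)
    cfg = SimConfig(
        n_snps=31,
        n_ld_blocks=31,  # all independent: clumping keeps every SNP
        true_beta=-0.005,
        seed=988022,
    )
    exposure, outcome, ld, truth = simulate_two_sample(cfg)
    write_summary_table(exposure, FIXTURE / "exposure.tsv")
    write_summary_table(outcome, FIXTURE / "outcome.tsv")
    ld.write(FIXTURE / "ld.tsv")
    truth.to_json(FIXTURE / "truth.json")
    (FIXTURE / "config.yaml").write_text(CONFIG_YAML)

    acfg = AnalysisConfig.from_yaml(FIXTURE / "config.yaml")
    bundle = run_analysis(acfg)
    if GOLDEN.exists():
        shutil.rmtree(GOLDEN)
    GOLDEN.mkdir(parents=True)
    out = Path(bundle["out_dir"])
    for name in ("estimates.tsv", "diagnostics.json", "loo.tsv", "funnel.tsv",
                 "presso_outliers.tsv", "harmonization_audit.tsv"):
        shutil.copy(out / name, GOLDEN / name)
    shutil.rmtree(out)
    print(f"fixture under {FIXTURE}, golden outputs under {GOLDEN}")


if __name__ == "__main__":
    main()
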