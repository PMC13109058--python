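#!/usr/bin/env python
"""Reconstruct allele-frequency and polygenic-score trajectories.

Fits epoch-wise selection coefficients (epochs 0-50, 50-100, 100-150
generations before present; Ne and a 28-year generation time as in the
trajectory model) to the selected site's present-day sample count with
the Wright-Fisher grid HMM, smooths its frequency trajectory, and
aggregates the trait SNPs' posterior-mean trajectories into
Z(t) = sum_i beta_i p_i(t).  Writes s_estimates.tsv, trajectory.tsv and
z.tsv under results/run/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import run_config

import pandas as pd

from polyhap.pipeline import run_pipeline
from polyhap.wf_trajectory import generations_to_years


def main() -> None:
    cfg = run_config()
    cfg.stages = ("trajectory",)
    run_pipeline(cfg)
    out = Path(cfg.outdir)
    s_est = pd.read_csv(out / "s_estimates.tsv", sep="\t")
    print("epoch-wise selection estimates at the selected site:")
    print(s_est.to_string(index=False))
    onset = cfg.sweep.onset_generation
    print(f"(true history: s = {cfg.sweep.s} switched on {onset} generations "
          f"= {generations_to_years(onset):.0f} years ago)")
    z = pd.read_csv(out / "z.tsv", sep="\t")
    print(f"\nZ(t) over {len(z)} generations: "
          f"Z(0) = {z['z'].iloc[0]:.4f}, "
          f"Z({int(z['time_generations'].iloc[-1])}) = {z['z'].iloc[-1]:.4f}")


if __name__ == "__main__":
    main()
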