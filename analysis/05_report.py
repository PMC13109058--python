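#!/usr/bin/env python
"""Render the report figures from the completed run.

EHH decay at the selected site, the chromosome-wide iHS scatter, and the
Z(t) time series with the settlement-window marker, plus the summary
table, under results/run/report/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import run_config

from polyhap.pipeline import run_pipeline


def main() -> None:
    cfg = run_config()
    cfg.stages = ("report",)
    manifest = run_pipeline(cfg)
    print("report files:")
    for f in manifest["report"]["files"]:
        print(f"  {Path(cfg.outdir) / 'report' / f}")


if __name__ == "__main__":
    main()
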