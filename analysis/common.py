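"""Shared configuration of the numbered analysis scripts.

One pipeline run over a synthetic sweep region emulating the study
design: a 22-diploid phased panel sampled from a population carrying one
strong-sweep locus, scanned with EHH/iHS, tested for polygenic
adaptation against a covariate-matched null, and summarized by
epoch-wise selection estimates and the polygenic-score trajectory Z(t).
All outputs land under results/run/.
"""

from pathlib import Path

from polyhap.pipeline import RunConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"


def run_config() -> RunConfig:
    return RunConfig.from_dict({
        "outdir": str(RESULTS / "run"),
        "seed": 1,
        "trait": "BMI",
        "epochs": [0, 50, 100, 150],
        "horizon": 150,
        "sim": {"n_diploids": 22, "region_length": 20_000_000,
                "n_sites": 250, "per_site_recomb": 1e-8, "Ne": 2000,
                "founder_daf_min": 0.2, "founder_daf_max": 0.8, "seed": 11},
        "sweep": {"selected_site_index": 125, "s": 0.1,
                  "onset_generation": 70},
        "arch": {"n_snps": 150, "n_causal": 30, "beta_sd": 0.05},
        "null": {"n_replicates": 10_000, "daf_bins": 3, "recomb_bins": 1,
                 "gerp_bins": 2, "seed": 13},
        "scan": {"n_bins": 10, "bin_mode": "count",
                 "max_extension_bp": 20_000_000},
    })
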