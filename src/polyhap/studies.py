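"""Simulation studies exercising the pipeline end to end.

Each function runs one self-contained study on synthetic data at fixed,
documented conditions (see docs/methods.md for the rationale behind the
problem sizes) and returns a plain dict of summary numbers.  They are the
workhorses behind the acceptance checks and the numbered analysis
scripts.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from polyhap.ehh_ihs import ScanConfig, scan_records, standardize_ihs
from polyhap.polyadapt import NullConfig, run_polyadapt
from polyhap.synthetic_data import (GwasArchitecture, SimConfig, SweepSpec,
                                    generate_gwas_table,
                                    generate_site_annotations,
                                    inject_polygenic_selection,
                                    simulate_neutral_genome,
                                    simulate_neutral_panel,
                                    simulate_sweep_panel,
                                    simulate_wf_trajectories, uniform_map)
from polyhap.wf_trajectory import Trajectory, estimate_epoch_s

logger = logging.getLogger(__name__)

# Sweep-region study conditions: a deep population (recent neutral
# coalescence rare), a 20 Mb region at the human-typical 1 cM/Mb with
# array-density SNPs from common standing variation, and the study's
# 22-diploid sample.
SWEEP_REGION = dict(n_diploids=22, region_length=20_000_000, n_sites=250,
                    per_site_recomb=1e-8, Ne=5000,
                    founder_daf_min=0.2, founder_daf_max=0.8)
SWEEP_SCAN = ScanConfig(n_bins=25, max_extension_bp=20_000_000)

# Genome-wide study conditions for the tiHS test: ten ~4 Mb regions of a
# few hundred diploids each — enough drift for haplotype structure while
# keeping ~2,000 scannable SNPs cheap to simulate.
GENOME = dict(n_diploids=22, region_length=4_000_000, n_sites=250,
              per_site_recomb=1e-8, Ne=500)
GENOME_REGIONS = 10
GENOME_DRIFT_GENERATIONS = 60


def _sub_seeds(seed: int, n: int, tag: int) -> list[int]:
    rng = np.random.default_rng([seed, tag])
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def build_neutral_genome(seed: int):
    """Neutral multi-region genome, its scan table and annotations."""
    cfg = SimConfig(seed=seed, **GENOME)
    regions = simulate_neutral_genome(cfg, n_regions=GENOME_REGIONS,
                                      n_generations=GENOME_DRIFT_GENERATIONS,
                                      seed=seed)
    sc = ScanConfig(n_bins=25)
    recs = pd.concat([scan_records(p, m, sc) for p, m in regions],
                     ignore_index=True)
    scan, _ = standardize_ihs(recs, n_bins=25)
    annot = generate_site_annotations([p for p, _ in regions],
                                      [m for _, m in regions],
                                      seed=_sub_seeds(seed, 1, 11)[0])
    return regions, scan, annot


def calibration_study(seed: int, n_traits: int = 12,
                      n_replicates: int = 10_000) -> dict:
    """Type-I calibration of the tiHS test on a fully neutral genome.

    ``n_traits`` pseudo-traits (random SNPs, random effects, uniform
    GWAS p-values) are tested at ``n_replicates`` resampling replicates;
    under the null the raw empirical p-values are uniform, so the number
    with p < 0.05 should fall inside the central 95% binomial band.
    """
    regions, scan, annot = build_neutral_genome(seed)
    panels = [p for p, _ in regions]
    arch = GwasArchitecture(n_snps=1500, n_causal=0, beta_sd=0.05,
                            p_assign_rule="uniform", effect_allele_rule=0.5)
    gwas_seeds = _sub_seeds(seed, n_traits, 21)
    traits = [(f"pseudo_{i}", generate_gwas_table(panels, arch, gwas_seeds[i],
                                                  trait=f"pseudo_{i}"))
              for i in range(n_traits)]
    cfg = NullConfig(n_replicates=n_replicates, daf_bins=5,
                     seed=_sub_seeds(seed, 1, 31)[0])
    table = run_polyadapt(traits, scan, annot, panels, cfg)
    hits = int((table["p"] < 0.05).sum())
    lo, hi = stats.binom.interval(0.95, len(table), 0.05)
    return {"n_traits": len(table), "raw_p": table["p"].tolist(),
            "hits_p_below_0.05": hits, "binom_lo": int(lo), "binom_hi": int(hi),
            "calibrated": bool(lo <= hits <= hi), "table": table}


def power_study(seed: int, n_runs: int = 20, n_replicates: int = 100_000,
                shift: float = 1.0) -> dict:
    """Power and direction of the tiHS test under polygenic selection.

    One neutral genome is scanned once; each run draws a fresh selected
    trait (100 causal SNPs whose trait-increasing derived alleles get a
    ``-shift`` siHS displacement — selection decreasing the trait) plus
    11 null pseudo-traits, and the full 12-trait test with BH adjustment
    is run at ``n_replicates``.  Success: the selected trait is called
    Decreasing with adjusted p < 0.05.
    """
    regions, scan, annot = build_neutral_genome(seed)
    panels = [p for p, _ in regions]
    null_arch = GwasArchitecture(n_snps=800, n_causal=0, beta_sd=0.05,
                                 p_assign_rule="uniform")
    sel_arch = GwasArchitecture(n_snps=800, n_causal=100, beta_sd=0.05,
                                p_assign_rule="suggestive_causal")
    run_seeds = _sub_seeds(seed, n_runs, 41)
    n_success = 0
    details = []
    for run, rs in enumerate(run_seeds):
        sub = _sub_seeds(rs, 13, 1)
        sel_gwas = generate_gwas_table(panels, sel_arch, sub[0],
                                       trait="selected")
        scan_run = inject_polygenic_selection(scan, sel_gwas, shift=shift)
        traits = [("selected", sel_gwas)]
        for i in range(11):
            traits.append((f"pseudo_{i}",
                           generate_gwas_table(panels, null_arch, sub[1 + i],
                                               trait=f"pseudo_{i}")))
        cfg = NullConfig(n_replicates=n_replicates, daf_bins=5, seed=sub[12])
        table = run_polyadapt(traits, scan_run, annot, panels, cfg)
        row = table[table["trait"] == "selected"].iloc[0]
        ok = (row["direction"] == "Decreasing") and (row["p_adjusted"] < 0.05)
        n_success += ok
        details.append({"run": run, "direction": row["direction"],
                        "p": row["p"], "p_adjusted": row["p_adjusted"],
                        "success": bool(ok)})
    return {"n_runs": n_runs, "n_success": n_success,
            "success_fraction": n_success / n_runs, "details": details}


def build_neutral_reference(seed: int, n_regions: int = 8) -> pd.DataFrame:
    """Large neutral reference scan used for genome-wide standardization."""
    seeds = _sub_seeds(seed, n_regions, 51)
    recs = []
    for r, s in enumerate(seeds):
        cfg = SimConfig(seed=s, **SWEEP_REGION)
        p = simulate_neutral_panel(cfg, n_generations=70, chrom=f"ref{r}")
        recs.append(scan_records(p, uniform_map(cfg), SWEEP_SCAN))
    return pd.concat(recs, ignore_index=True)


def sweep_detection_study(seed: int, n_replicates: int = 25, s: float = 0.1,
                          onset: int = 70) -> dict:
    """How often does the scan rank the selected site first in its region?

    Each replicate simulates a sweep region (s, onset as given),
    standardizes jointly with a shared neutral reference, and records the
    rank of the selected site among the region's |siHS| values (the
    comparison is over sites at minor allele frequency >= 0.05, the
    scan's low-frequency flag).
    """
    neutral = build_neutral_reference(seed)
    rep_seeds = _sub_seeds(seed, n_replicates, 61)
    hits = 0
    ranks = []
    sihs_values = []
    for rs in rep_seeds:
        cfg = SimConfig(seed=rs, **SWEEP_REGION)
        sweep = SweepSpec(selected_site_index=cfg.n_sites // 2, s=s,
                          onset_generation=onset)
        panel, _ = simulate_sweep_panel(cfg, sweep)
        recs = pd.concat([scan_records(panel, uniform_map(cfg), SWEEP_SCAN),
                          neutral], ignore_index=True)
        scan, _ = standardize_ihs(recs, n_bins=25)
        region = scan[scan["snp_id"].str.startswith("1_")]
        region = region[~region["flags"].str.contains("low_freq")]
        z = region["sihs"].abs().fillna(-1.0)
        sid = panel.site_ids[sweep.selected_site_index]
        sweep_z = float(region.loc[region["snp_id"] == sid, "sihs"]
                        .abs().iloc[0])
        rank = int((z > sweep_z).sum())
        ranks.append(rank)
        hits += rank == 0
        sihs_values.append(sweep_z)
    return {"n_replicates": n_replicates, "n_top": hits,
            "top_fraction": hits / n_replicates, "ranks": ranks,
            "top3_fraction": float(np.mean([r < 3 for r in ranks])),
            "sweep_abs_sihs": sihs_values}


def s_recovery_study(seed: int, n_replicates: int = 50, Ne: int = 10_000,
                     horizon: int = 100) -> dict:
    """Parameter recovery of the epoch selection coefficient from full paths.

    Neutral: 50 trajectories from p0 = 0.2 with s = 0; sweep: 50 from
    p0 = 0.05 with s = 0.013 (the trajectory-inference constants,
    Ne = 10,000).  Each path is fit by grid-search maximum likelihood over
    a single epoch covering the simulated horizon.
    """
    s_grid = np.round(np.arange(-0.05, 0.0505, 0.0005), 6)
    out = {}
    for label, tag, p0, s_true in (("neutral", 1, 0.2, 0.0),
                                   ("sweep", 2, 0.05, 0.013)):
        rng = np.random.default_rng([seed, 71, tag])
        freqs = simulate_wf_trajectories(p0, s_true, horizon, Ne,
                                         n_replicates, rng)
        est, better = [], 0
        for rep in range(n_replicates):
            traj = Trajectory(times=np.arange(horizon + 1), freq=freqs[rep])
            s_hat, surf = estimate_epoch_s(traj, [0, horizon], s_grid=s_grid,
                                           Ne=Ne)
            est.append(float(s_hat[0]))
            i_true = int(np.argmin(np.abs(s_grid - s_true)))
            better += surf[0, i_true] > surf[0, 0]  # vs s = -0.05
        est = np.asarray(est)
        out[label] = {
            "mean": float(np.nanmean(est)), "median": float(np.nanmedian(est)),
            "estimates": est.tolist(),
            "loglik_true_beats_minus05_fraction": better / n_replicates,
        }
    return out


def neutral_tail_fraction(seed: int) -> dict:
    """Fraction of |siHS| > 2 on a neutral genome (normal-tail behaviour)."""
    _, scan, _ = build_neutral_genome(seed)
    z = scan["sihs"].to_numpy(dtype=float)
    z = z[np.isfinite(z)]
    return {"n_sites": int(z.size),
            "fraction_abs_gt2": float(np.mean(np.abs(z) > 2))}
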