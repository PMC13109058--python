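"""Synthetic inputs with known ground truth for every pipeline stage.

The generator emulates the study design the pipeline targets: a small
phased panel of diploids (default 22, i.e. 44 haplotypes) drawn from a
population carrying one strong-sweep locus that arose as a single new
mutation ~100 generations ago (default s = 0.013), on top of standing
neutral variation, plus GWAS-like summary tables and the matching
covariates (DAF, local recombination rate, GERP-like conservation score)
needed by the polygenic-adaptation null.

Model choices (fixed here, surfaced in config where genuinely free):

* Selection acts deterministically on the expected frequency before
  binomial sampling — genic update p' = p(1+s)/(1+ps); in the diploid
  panel simulator, parents are drawn proportional to genotype fitness
  (1+s)^(2h) for heterozygotes and (1+s)^2 for derived homozygotes, which
  is multiplicative (genic) at h = 1/2.
* Recombination: per-gamete crossover count ~ Poisson(total map length in
  Morgans) with uniform breakpoint placement on the genetic scale.
* No recurrent mutation after time 0: all sites segregate from standing
  variation except the sweep allele, which arises exactly once at onset,
  so ancestral/derived polarization is exact by construction.
* Founder allele frequencies are a free choice (the real site-frequency
  spectrum is unknown at this scale); the default draws from a truncated
  neutral-like SFS with density proportional to 1/p on
  [daf_min, daf_max], selectable via ``founder_freq_dist``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from polyhap import hap_io
from polyhap.hap_io import GeneticMap, HaplotypePanel
from polyhap.wf_trajectory import (ConfigurationError, EpochSelectionModel,
                                   Trajectory, selection_update)

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))


class SweepLostError(RuntimeError):
    """Sweep allele was lost in every attempt up to the retry cap."""


@dataclass
class SimConfig:
    """Population and region parameters for the forward simulator.

    ``Ne`` is the simulated (effective) population size in diploids and
    defaults to the trajectory-inference constant 10,000; panel fixtures
    typically use a few hundred for tractable forward simulation.
    ``per_site_recomb`` is the recombination probability per bp per
    generation (Morgans/bp).
    """

    n_diploids: int = 22
    region_length: int = 1_000_000
    n_sites: int = 200
    per_site_recomb: float = 1e-8
    Ne: int = 10_000
    generation_time: float = 28.0
    seed: int = 0
    founder_freq_dist: str = "neutral_sfs"  # or "uniform"
    founder_daf_min: float = 0.05
    founder_daf_max: float = 0.95

    def __post_init__(self) -> None:
        if self.n_sites < 2:
            raise ConfigurationError("need at least 2 sites")
        if self.per_site_recomb < 0:
            raise ConfigurationError("recombination rate must be >= 0")
        if self.Ne < self.n_diploids:
            raise ConfigurationError("Ne must be >= sampled diploids")


@dataclass
class SweepSpec:
    """A single selected site: coefficient, onset, dominance.

    ``min_sample_carriers`` conditions the returned panel on the selected
    allele being observed at least that many times among the sampled
    haplotypes (and at most ``max_sample_carriers`` — near-fixed panels
    leave no ancestral haplotypes to contrast against).  This emulates the
    ascertainment of a known sweep locus segregating at appreciable
    frequency in the study panel; panels failing it are resimulated like
    outright losses.

    ``initial_frequency`` None means the allele arises once, on a single
    haplotype, at onset; a float starts it from standing variation at that
    frequency (weak selection on the 100-generation horizon can only reach
    appreciable frequency from standing variation).
    """

    selected_site_index: int = 100
    s: float = 0.013
    onset_generation: int = 100
    dominance: float = 0.5
    min_sample_carriers: int = 6
    max_sample_carriers: int | None = None
    initial_frequency: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.s < 1:
            raise ConfigurationError("require 0 <= s < 1")
        if self.onset_generation <= 0:
            raise ConfigurationError("onset must be > 0 generations ago")
        if not 0 <= self.dominance <= 1:
            raise ConfigurationError("dominance must lie in [0, 1]")


@dataclass
class GwasArchitecture:
    """Shape of a simulated GWAS summary table.

    ``effect_allele_rule`` is the probability that a record reports the
    derived allele as its effect allele (otherwise the ancestral base is
    reported with the sign of beta flipped, as real summary tables do).
    ``p_assign_rule``: "suggestive_causal" gives causal SNPs p ~
    U(1e-8, 0.05) and the rest p ~ U(0.05, 1); "uniform" gives everyone
    p ~ U(1e-8, 1).
    """

    n_snps: int = 200
    n_causal: int = 100
    beta_sd: float = 0.05
    p_assign_rule: str = "suggestive_causal"
    effect_allele_rule: float = 0.5

    def __post_init__(self) -> None:
        if self.n_causal > self.n_snps:
            raise ConfigurationError("n_causal cannot exceed n_snps")
        if not 0 <= self.effect_allele_rule <= 1:
            raise ConfigurationError("effect_allele_rule must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Single-locus trajectories

def simulate_wf_trajectories(p0: float, model: EpochSelectionModel | float,
                             n_generations: int, Ne: int,
                             n_replicates: int, rng: np.random.Generator
                             ) -> np.ndarray:
    """Vectorized WF trajectories; returns (n_replicates, n_generations+1).

    Column ``t`` is the frequency ``t`` generations before present; the
    simulation starts at ``p0`` at the oldest time and runs forward.
    """
    if isinstance(model, (int, float)):
        model = EpochSelectionModel.constant(float(model), n_generations, Ne=Ne)
    n = 2 * Ne
    out = np.empty((n_replicates, n_generations + 1))
    out[:, n_generations] = p0
    k = np.full(n_replicates, int(round(p0 * n)), dtype=np.int64)
    out[:, n_generations] = k / n
    for t in range(n_generations - 1, -1, -1):
        p_prime = selection_update(k / n, model.s_at(t))
        k = rng.binomial(n, p_prime)
        out[:, t] = k / n
    return out


def simulate_wf_trajectory(p0: float, epoch_s, cfg: SimConfig,
                           n_generations: int) -> Trajectory:
    """One WF trajectory under epoch-wise genic selection.

    ``epoch_s`` is a constant selection coefficient or an
    :class:`EpochSelectionModel`; for a model, the epoch boundaries must
    cover ``[0, n_generations]``.
    """
    if not 0 <= p0 <= 1:
        raise ValueError("p0 must lie in [0, 1]")
    if isinstance(epoch_s, EpochSelectionModel):
        if epoch_s.boundaries[-1] < n_generations:
            raise ConfigurationError(
                f"epoch boundaries end at {epoch_s.boundaries[-1]} but the "
                f"horizon is {n_generations} generations")
        model = epoch_s
    else:
        model = EpochSelectionModel.constant(float(epoch_s), n_generations,
                                             Ne=cfg.Ne,
                                             generation_time=cfg.generation_time)
    rng = np.random.default_rng(cfg.seed)
    freq = simulate_wf_trajectories(p0, model, n_generations, cfg.Ne, 1, rng)[0]
    return Trajectory(times=np.arange(n_generations + 1), freq=freq)


# ---------------------------------------------------------------------------
# Panel simulation

def _founder_freqs(cfg: SimConfig, n_sites: int,
                   rng: np.random.Generator) -> np.ndarray:
    lo, hi = cfg.founder_daf_min, cfg.founder_daf_max
    if cfg.founder_freq_dist == "uniform":
        return rng.uniform(lo, hi, size=n_sites)
    if cfg.founder_freq_dist == "neutral_sfs":
        # density ~ 1/p on [lo, hi]: inverse-CDF draw
        u = rng.random(n_sites)
        return lo * (hi / lo) ** u
    raise ConfigurationError(
        f"unknown founder_freq_dist {cfg.founder_freq_dist!r}")


def _site_positions(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    pos = rng.choice(np.arange(1, cfg.region_length + 1), size=cfg.n_sites,
                     replace=False)
    return np.sort(pos)


def uniform_map(cfg: SimConfig) -> GeneticMap:
    """Linear genetic map over the region at ``per_site_recomb`` Morgans/bp."""
    total_cm = cfg.region_length * cfg.per_site_recomb * 100.0
    return GeneticMap(np.array([1, cfg.region_length]),
                      np.array([0.0, total_cm]))


def _next_generation(pop: np.ndarray, fitness: np.ndarray,
                     positions_cm: np.ndarray, total_morgans: float,
                     rng: np.random.Generator) -> np.ndarray:
    """One generation of WF reproduction with recombination.

    ``pop`` is (2N, n_sites); parents drawn proportional to ``fitness``
    (per diploid, with replacement, selfing allowed); each gamete is a
    recombinant of one parent's two haplotypes.
    """
    n_dip = pop.shape[0] // 2
    n_gametes = 2 * n_dip
    probs = fitness / fitness.sum()
    parents = rng.choice(n_dip, size=n_gametes, p=probs)
    n_cross = rng.poisson(total_morgans, size=n_gametes)
    start = rng.integers(0, 2, size=n_gametes)
    child = np.empty_like(pop)
    plain = n_cross == 0
    child[plain] = pop[2 * parents[plain] + start[plain]]
    total_cm = total_morgans * 100.0
    single = np.nonzero(n_cross == 1)[0]
    if single.size:  # vectorized: one breakpoint per gamete is the common case
        bp = rng.uniform(0.0, total_cm, size=single.size)
        after = positions_cm[None, :] > bp[:, None]
        chooser = (start[single, None] + after) % 2
        a = pop[2 * parents[single]]
        b = pop[2 * parents[single] + 1]
        child[single] = np.where(chooser == 0, a, b)
    for g in np.nonzero(n_cross >= 2)[0]:
        bp = np.sort(rng.uniform(0.0, total_cm, size=n_cross[g]))
        switches = np.searchsorted(bp, positions_cm)
        chooser = (start[g] + switches) % 2
        a = pop[2 * parents[g]]
        b = pop[2 * parents[g] + 1]
        child[g] = np.where(chooser == 0, a, b)
    return child


def _random_bases(n_sites: int, rng: np.random.Generator):
    anc_idx = rng.integers(0, 4, size=n_sites)
    der_off = rng.integers(1, 4, size=n_sites)
    der_idx = (anc_idx + der_off) % 4
    return _BASES[anc_idx].astype(object), _BASES[der_idx].astype(object)


def simulate_sweep_panel(cfg: SimConfig, sweep: SweepSpec,
                         retry_cap: int = 1000
                         ) -> tuple[HaplotypePanel, Trajectory]:
    """Forward diploid WF simulation of a sweep region; returns the sampled
    phased panel (0 = ancestral, 1 = derived) and the true population
    frequency trajectory of the selected allele.

    The sweep allele arises on a single haplotype ``onset_generation``
    generations before present; runs in which it is lost before sampling
    are resimulated with a fresh stream up to ``retry_cap`` attempts.
    """
    if not 0 <= sweep.selected_site_index < cfg.n_sites:
        raise ConfigurationError("selected site outside the region")
    for attempt in range(retry_cap):
        rng = np.random.default_rng([cfg.seed, attempt])
        panel, traj = _simulate_panel_once(cfg, sweep, rng)
        if panel is not None:
            if attempt:
                logger.info("sweep retained after %d resimulations", attempt)
            return panel, traj
    raise SweepLostError(
        f"selected allele lost in all {retry_cap} attempts (s={sweep.s})")


def _simulate_panel_once(cfg: SimConfig, sweep: SweepSpec | None,
                         rng: np.random.Generator,
                         n_generations: int | None = None):
    positions = _site_positions(cfg, rng)
    gmap = uniform_map(cfg)
    positions_cm = np.asarray(gmap.interpolate_cm(positions), dtype=float)
    total_morgans = cfg.region_length * cfg.per_site_recomb

    freqs = _founder_freqs(cfg, cfg.n_sites, rng)
    n_hap = 2 * cfg.Ne
    pop = (rng.random((n_hap, cfg.n_sites)) < freqs).astype(np.uint8)

    horizon = sweep.onset_generation if sweep else int(n_generations)
    sel_j = sweep.selected_site_index if sweep else None
    if sweep is not None:
        pop[:, sel_j] = 0
        if sweep.initial_frequency is None:
            pop[rng.integers(0, n_hap), sel_j] = 1
        else:
            n_start = max(1, int(round(sweep.initial_frequency * n_hap)))
            pop[rng.choice(n_hap, size=n_start, replace=False), sel_j] = 1
        w_het = (1.0 + sweep.s) ** (2.0 * sweep.dominance)
        w_hom = (1.0 + sweep.s) ** 2.0

    traj = np.empty(horizon + 1)
    if sel_j is not None:
        traj[horizon] = pop[:, sel_j].mean()
    for t in range(horizon - 1, -1, -1):
        if sweep is not None:
            g = pop[0::2, sel_j].astype(np.int64) + pop[1::2, sel_j]
            fitness = np.where(g == 2, w_hom, np.where(g == 1, w_het, 1.0))
        else:
            fitness = np.ones(cfg.Ne)
        pop = _next_generation(pop, fitness, positions_cm, total_morgans, rng)
        if sel_j is not None:
            traj[t] = pop[:, sel_j].mean()
            if traj[t] == 0.0:
                return None, None  # sweep lost; caller retries

    sample = rng.choice(cfg.Ne, size=cfg.n_diploids, replace=False)
    hap_rows = np.empty(2 * cfg.n_diploids, dtype=np.int64)
    hap_rows[0::2] = 2 * sample
    hap_rows[1::2] = 2 * sample + 1
    alleles = pop[hap_rows]
    if sweep is not None:
        count = int(alleles[:, sel_j].sum())
        hi = (sweep.max_sample_carriers if sweep.max_sample_carriers is not None
              else 2 * cfg.n_diploids - 2)
        if not sweep.min_sample_carriers <= count <= hi:
            return None, None  # sweep unusable in the sample; caller retries

    anc, der = _random_bases(cfg.n_sites, rng)
    chrom = "1"
    site_ids = np.array([f"{chrom}_{p}" for p in positions], dtype=object)
    panel = HaplotypePanel(alleles, chrom, positions, positions_cm, site_ids,
                           anc_base=anc, der_base=der)
    trajectory = (Trajectory(times=np.arange(horizon + 1), freq=traj,
                             snp_id=str(site_ids[sel_j]))
                  if sel_j is not None else None)
    return panel, trajectory


def simulate_neutral_panel(cfg: SimConfig, n_generations: int = 60,
                           chrom: str = "1") -> HaplotypePanel:
    """Standing variation drifting neutrally for ``n_generations``."""
    rng = np.random.default_rng(cfg.seed)
    panel, _ = _simulate_panel_once(cfg, None, rng, n_generations=n_generations)
    if chrom != "1":
        panel = replace(panel, chrom=chrom,
                        site_ids=np.array([f"{chrom}_{p}"
                                           for p in panel.positions_bp],
                                          dtype=object))
    return panel


def simulate_neutral_genome(cfg: SimConfig, n_regions: int = 10,
                            n_generations: int = 60,
                            recomb_spread: float = 0.5,
                            seed: int | None = None
                            ) -> list[tuple[HaplotypePanel, GeneticMap]]:
    """Several independent neutral regions emulating a genome-wide panel.

    Per-region recombination rates are jittered log-normally around
    ``cfg.per_site_recomb`` (sd ``recomb_spread`` on the log scale) so the
    local-recombination matching covariate varies across the genome.
    """
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng([seed, 977])
    out = []
    for r in range(n_regions):
        rate = cfg.per_site_recomb * np.exp(
            rng.normal(0.0, recomb_spread))
        sub = replace(cfg, seed=int(rng.integers(0, 2**31 - 1)),
                      per_site_recomb=float(rate))
        panel = simulate_neutral_panel(sub, n_generations=n_generations,
                                       chrom=str(r + 1))
        out.append((panel, uniform_map(sub)))
    return out


# ---------------------------------------------------------------------------
# GWAS tables and annotations

def _as_pool(panel_pool) -> list[HaplotypePanel]:
    if isinstance(panel_pool, HaplotypePanel):
        return [panel_pool]
    return [p[0] if isinstance(p, tuple) else p for p in panel_pool]


def generate_gwas_table(panel_pool, arch: GwasArchitecture, seed: int,
                        trait: str = "trait") -> pd.DataFrame:
    """GWAS-like summary table over segregating panel sites.

    Effects are simulated per derived allele (truth kept in
    ``beta_derived_true``); with probability ``effect_allele_rule`` the
    record reports the derived base as effect allele, otherwise the
    ancestral base with the sign of beta flipped.  A ``causal`` flag marks
    the subset intended to carry signal for recovery tests.
    """
    panels = _as_pool(panel_pool)
    if not panels:
        raise ValueError("empty panel pool")
    ids, anc, der = [], [], []
    for p in panels:
        seg = p.segregating()
        ids.append(p.site_ids[seg])
        anc.append((p.anc_base if p.anc_base is not None
                    else np.array(["A"] * p.n_sites, dtype=object))[seg])
        der.append((p.der_base if p.der_base is not None
                    else np.array(["G"] * p.n_sites, dtype=object))[seg])
    ids = np.concatenate(ids)
    anc = np.concatenate(anc)
    der = np.concatenate(der)
    if arch.n_snps > ids.size:
        raise ValueError(f"requested {arch.n_snps} SNPs but only {ids.size} "
                         "segregating sites available")
    rng = np.random.default_rng(seed)
    pick = rng.choice(ids.size, size=arch.n_snps, replace=False)
    causal = np.zeros(arch.n_snps, dtype=bool)
    causal[rng.choice(arch.n_snps, size=arch.n_causal, replace=False)] = True
    beta_derived = rng.normal(0.0, arch.beta_sd, size=arch.n_snps)
    if arch.p_assign_rule == "suggestive_causal":
        p = np.where(causal, rng.uniform(1e-8, 0.05, size=arch.n_snps),
                     rng.uniform(0.05, 1.0, size=arch.n_snps))
    elif arch.p_assign_rule == "uniform":
        p = rng.uniform(1e-8, 1.0, size=arch.n_snps)
    else:
        raise ConfigurationError(f"unknown p_assign_rule {arch.p_assign_rule!r}")
    report_derived = rng.random(arch.n_snps) < arch.effect_allele_rule
    eff_allele = np.where(report_derived, der[pick], anc[pick])
    beta = np.where(report_derived, beta_derived, -beta_derived)
    df = pd.DataFrame({
        "snp_id": ids[pick], "effect_allele": eff_allele,
        "beta": beta, "p": p, "trait": trait,
        "causal": causal, "beta_derived_true": beta_derived,
    })
    return hap_io.validate_gwas_table(df)


def generate_site_annotations(panel_pool, gmaps, seed: int,
                              gerp_mean: float = 0.0, gerp_sd: float = 2.0,
                              window_bp: float = 100_000.0) -> pd.DataFrame:
    """Per-site matching covariates: DAF, local recomb rate, GERP-like score.

    DAF is counted from the panel; local recombination rate is the map
    slope (cM/Mb) in a window around the site; the conservation score is
    drawn from Normal(gerp_mean, gerp_sd).
    """
    panels = _as_pool(panel_pool)
    if isinstance(gmaps, GeneticMap):
        gmaps = [gmaps]
    if len(panels) != len(gmaps):
        raise ValueError("need one genetic map per panel")
    rng = np.random.default_rng(seed)
    frames = []
    for panel, gmap in zip(panels, gmaps):
        if (panel.positions_bp[0] < gmap.bp[0]
                or panel.positions_bp[-1] > gmap.bp[-1]):
            raise ValueError(f"panel {panel.chrom}: sites outside map range")
        rate = np.array([gmap.local_rate(b, window_bp)
                         for b in panel.positions_bp])
        frames.append(pd.DataFrame({
            "snp_id": panel.site_ids, "daf": panel.daf(),
            "recomb_rate": rate,
            "gerp": rng.normal(gerp_mean, gerp_sd, size=panel.n_sites),
        }))
    return hap_io.validate_annotations(pd.concat(frames, ignore_index=True))


def inject_polygenic_selection(scan: pd.DataFrame, gwas: pd.DataFrame,
                               shift: float = 1.0) -> pd.DataFrame:
    """Impose a polygenic-selection signal decreasing the trait.

    Causal trait-increasing derived alleles get their standardized iHS
    shifted by ``-shift`` (and trait-decreasing by ``+shift``): shorter
    haplotypes around trait-increasing alleles, the summary-statistic
    footprint of selection against the trait.  Returns a modified copy of
    the scan table.
    """
    out = scan.copy()
    causal = gwas.loc[gwas["causal"], ["snp_id", "beta_derived_true"]]
    delta = pd.Series(-shift * np.sign(causal["beta_derived_true"].to_numpy()),
                      index=causal["snp_id"].to_numpy())
    mask = out["snp_id"].isin(delta.index)
    out.loc[mask, "sihs"] = (out.loc[mask, "sihs"]
                             + delta[out.loc[mask, "snp_id"]].to_numpy())
    return out


# ---------------------------------------------------------------------------
# Fixture bundles

def write_fixture_bundle(outdir, cfg: SimConfig, sweep: SweepSpec,
                         arch: GwasArchitecture, trait: str = "BMI") -> dict:
    """Simulate a sweep region and write every pipeline input to ``outdir``.

    Files: phased VCF with ``AA`` tag, genetic-map text, GWAS TSV,
    annotation TSV, a truth TSV of per-site flags, and the true selected
    trajectory.  Byte-identical across runs with the same config.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    panel, traj = simulate_sweep_panel(cfg, sweep)
    gmap = uniform_map(cfg)
    rng = np.random.default_rng([cfg.seed, 4242])
    gwas = generate_gwas_table(panel, arch, seed=int(rng.integers(2**31 - 1)),
                               trait=trait)
    annot = generate_site_annotations(panel, gmap,
                                      seed=int(rng.integers(2**31 - 1)))
    ref_is_anc = rng.random(panel.n_sites) < 0.5

    paths = {k: outdir / v for k, v in {
        "vcf": "panel.vcf", "map": "map.txt", "gwas": f"gwas_{trait}.tsv",
        "annotations": "annotations.tsv", "truth_sites": "truth_sites.tsv",
        "truth_trajectory": "truth_trajectory.tsv"}.items()}
    try:
        hap_io.write_phased_vcf(panel, paths["vcf"], ref_is_ancestral=ref_is_anc)
        hap_io.write_genetic_map(gmap, paths["map"])
        hap_io.write_gwas_summary(gwas, paths["gwas"])
        hap_io.write_annotations(annot, paths["annotations"])
        truth = pd.DataFrame({
            "snp_id": panel.site_ids,
            "is_selected": [j == sweep.selected_site_index
                            for j in range(panel.n_sites)],
        }).merge(gwas[["snp_id", "causal", "beta_derived_true"]],
                 on="snp_id", how="left")
        truth["causal"] = truth["causal"].eq(True)
        truth.to_csv(paths["truth_sites"], sep="\t", index=False)
        pd.DataFrame({"time": traj.times, "freq": traj.freq}).to_csv(
            paths["truth_trajectory"], sep="\t", index=False)
    except OSError as exc:
        raise OSError(f"failed writing fixture bundle under {outdir}: {exc}"
                      ) from exc
    return {k: str(v) for k, v in paths.items()}
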