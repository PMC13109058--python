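"""Orchestration: simulate -> scan -> polyadapt -> trajectory -> report.

A single :class:`RunConfig` (plain YAML) drives the whole pipeline with
explicit per-stage seeds; rerunning an identical config reproduces
byte-identical tables.  Outputs land under ``outdir``:

* ``fixture/`` — the simulated input bundle (VCF, map, GWAS, annotations,
  truth tables)
* ``scan.tsv`` — the standardized iHS scan
* ``table1.tsv`` — the tiHS polygenic-adaptation summary (one row per trait)
* ``s_estimates.tsv`` / ``trajectory.tsv`` / ``z.tsv`` — epoch-wise
  selection estimates, the selected site's posterior trajectory, and the
  polygenic-score trajectory Z(t)
* ``manifest.json`` — inputs, seeds, versions and sha256 digests
* ``report/`` — EHH decay plot, iHS scatter, Z(t) series
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

import polyhap
from polyhap import hap_io
from polyhap.ehh_ihs import ScanConfig, compute_ehh, scan_chromosome
from polyhap.polyadapt import NullConfig, polarize_effects, run_polyadapt
from polyhap.synthetic_data import (GwasArchitecture, SimConfig, SweepSpec,
                                    write_fixture_bundle)
from polyhap.wf_trajectory import (EpochSelectionModel, WFHMMConfig,
                                   estimate_epoch_s, generations_to_years,
                                   ps_trajectory, trajectory_posterior)

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "scan", "polyadapt", "trajectory", "report")


class ConfigError(ValueError):
    """RunConfig failed validation."""


def _build(cls, data: dict, where: str):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"{where}: unknown key(s) {sorted(unknown)}")
    return cls(**data)


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    outdir: str
    seed: int = 0
    stages: tuple = ALL_STAGES
    trait: str = "BMI"
    epochs: tuple = (0, 50, 100, 150)
    horizon: int = 150
    min_retained: int = 10
    sim: SimConfig = field(default_factory=SimConfig)
    sweep: SweepSpec = field(default_factory=SweepSpec)
    arch: GwasArchitecture = field(default_factory=GwasArchitecture)
    null: NullConfig = field(default_factory=NullConfig)
    scan: ScanConfig = field(default_factory=ScanConfig)
    hmm: WFHMMConfig = field(default_factory=WFHMMConfig)

    def __post_init__(self) -> None:
        bad = set(self.stages) - set(ALL_STAGES)
        if bad:
            raise ConfigError(f"unknown stage(s) {sorted(bad)}")

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        sub = {"sim": SimConfig, "sweep": SweepSpec, "arch": GwasArchitecture,
               "null": NullConfig, "scan": ScanConfig, "hmm": WFHMMConfig}
        parsed = {}
        for key, sub_cls in sub.items():
            if key in data:
                parsed[key] = _build(sub_cls, data.pop(key) or {}, key)
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown key(s) {sorted(unknown)}")
        return cls(**data, **parsed)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stages"] = list(self.stages)
        d["epochs"] = list(self.epochs)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order; returns the run manifest.

    Every stochastic stage derives its stream from the config's explicit
    seeds, so identical configs reproduce identical outputs.  A stage
    failure aborts with the stage name; outputs of completed stages are
    preserved.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"config": config.to_dict(), "version": polyhap.__version__,
                "outputs": {}, "stages_run": []}
    state: dict = {}
    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        try:
            _STAGES[stage](config, outdir, state, manifest)
        except Exception as exc:
            _write_manifest(manifest, outdir)
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        manifest["stages_run"].append(stage)
    _write_manifest(manifest, outdir)
    return manifest


def _write_manifest(manifest: dict, outdir: Path) -> None:
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)


def _register(manifest: dict, name: str, path: Path, digest: bool = True):
    manifest["outputs"][name] = {"path": str(path)}
    if digest:
        manifest["outputs"][name]["sha256"] = _sha256(path)


def _stage_simulate(config: RunConfig, outdir: Path, state, manifest):
    fixture = outdir / "fixture"
    paths = write_fixture_bundle(fixture, config.sim, config.sweep,
                                 config.arch, trait=config.trait)
    for name, p in paths.items():
        _register(manifest, f"fixture_{name}", Path(p))
    state["paths"] = paths


def _load_fixture(config: RunConfig, outdir: Path, state):
    if "paths" not in state:
        fixture = outdir / "fixture"
        state["paths"] = {k: str(fixture / v) for k, v in {
            "vcf": "panel.vcf", "map": "map.txt",
            "gwas": f"gwas_{config.trait}.tsv",
            "annotations": "annotations.tsv",
            "truth_sites": "truth_sites.tsv",
            "truth_trajectory": "truth_trajectory.tsv"}.items()}
    p = state["paths"]
    if "panel" not in state:
        gmap = hap_io.read_genetic_map(p["map"])
        state["gmap"] = gmap
        state["panel"] = hap_io.read_phased_vcf(p["vcf"], gmap=gmap)
    return state


def _stage_scan(config: RunConfig, outdir: Path, state, manifest):
    _load_fixture(config, outdir, state)
    scan, bins = scan_chromosome(state["panel"], state["gmap"], config.scan)
    out = outdir / "scan.tsv"
    hap_io.write_scan_table(scan, out)
    state["scan"] = scan
    _register(manifest, "scan", out)


def _stage_polyadapt(config: RunConfig, outdir: Path, state, manifest):
    _load_fixture(config, outdir, state)
    if "scan" not in state:
        state["scan"] = hap_io.read_scan_table(outdir / "scan.tsv")
    gwas = hap_io.read_gwas_summary(state["paths"]["gwas"], trait=config.trait)
    annot = hap_io.read_annotations(state["paths"]["annotations"])
    truth = pd.read_csv(state["paths"]["truth_sites"], sep="\t")
    # the known selected candidate is excluded from the trait analysis
    exclusions = tuple(truth.loc[truth["is_selected"], "snp_id"])
    table = run_polyadapt([(config.trait, gwas)], state["scan"], annot,
                          state["panel"], config.null,
                          exclusions=exclusions,
                          min_retained=config.min_retained)
    out = outdir / "table1.tsv"
    table.to_csv(out, sep="\t", index=False)
    state["table1"] = table
    _register(manifest, "table1", out)


def _stage_trajectory(config: RunConfig, outdir: Path, state, manifest):
    _load_fixture(config, outdir, state)
    panel = state["panel"]
    gwas = hap_io.read_gwas_summary(state["paths"]["gwas"], trait=config.trait)
    gwas = polarize_effects(gwas, panel)
    n = panel.n_haplotypes
    s_grid = np.round(np.arange(-0.05, 0.0505, 0.0025), 6)
    boundaries = list(config.epochs)

    # epoch-wise s at the selected site: fit the true simulated frequency
    # path when the run produced one (the informative case), otherwise fall
    # back to the HMM marginal likelihood of the present-day sample count
    truth = pd.read_csv(state["paths"]["truth_sites"], sep="\t")
    sel_id = truth.loc[truth["is_selected"], "snp_id"].iloc[0]
    k_sel = int(panel.alleles[:, panel.site_index(sel_id)].sum())
    truth_traj_path = Path(state["paths"]["truth_trajectory"])
    if truth_traj_path.exists():
        from polyhap.wf_trajectory import Trajectory

        tt = pd.read_csv(truth_traj_path, sep="\t")
        path = Trajectory(times=tt["time"].to_numpy(),
                          freq=tt["freq"].to_numpy())
        wide_grid = np.round(np.arange(-0.15, 0.1505, 0.0025), 6)
        s_hat, _ = estimate_epoch_s(path, boundaries, config.hmm, wide_grid,
                                    Ne=config.sim.Ne)
    else:
        s_hat, _ = estimate_epoch_s((k_sel, n, config.horizon), boundaries,
                                    config.hmm, s_grid, Ne=config.sim.Ne)
    rows = [{"epoch_start": boundaries[i], "epoch_end": boundaries[i + 1],
             "s_hat": s_hat[i]} for i in range(len(s_hat))]
    s_out = outdir / "s_estimates.tsv"
    pd.DataFrame(rows).to_csv(s_out, sep="\t", index=False)
    _register(manifest, "s_estimates", s_out)

    model = EpochSelectionModel(tuple(boundaries),
                                tuple(np.nan_to_num(s_hat)),
                                Ne=config.sim.Ne,
                                generation_time=config.sim.generation_time)
    traj_sel = trajectory_posterior(k_sel, n, model, config.hmm,
                                    horizon=config.horizon, snp_id=sel_id)
    t_out = outdir / "trajectory.tsv"
    pd.DataFrame({"time": traj_sel.times, "freq": traj_sel.freq}).to_csv(
        t_out, sep="\t", index=False)
    _register(manifest, "trajectory", t_out)

    # Z(t) over the trait's suggestive SNPs under the neutral-epoch model
    sugg = gwas[(gwas["p"] < 0.05) & (gwas["snp_id"] != sel_id)]
    neutral = EpochSelectionModel(tuple(boundaries),
                                  (0.0,) * (len(boundaries) - 1),
                                  Ne=config.sim.Ne,
                                  generation_time=config.sim.generation_time)
    trajs, betas = [], []
    for row in sugg.itertuples(index=False):
        k = int(panel.alleles[:, panel.site_index(row.snp_id)].sum())
        trajs.append(trajectory_posterior(k, n, neutral, config.hmm,
                                          horizon=config.horizon,
                                          snp_id=row.snp_id))
        betas.append(row.beta_derived)
    ps = ps_trajectory(trajs, np.asarray(betas))
    z_out = outdir / "z.tsv"
    pd.DataFrame({
        "time_generations": ps.times,
        "time_years": generations_to_years(ps.times,
                                           config.sim.generation_time),
        "z": ps.z,
    }).to_csv(z_out, sep="\t", index=False)
    state["ps"] = ps
    _register(manifest, "z", z_out)


def _stage_report(config: RunConfig, outdir: Path, state, manifest):
    try:
        _load_fixture(config, outdir, state)
    except OSError:
        logger.warning("fixture not found; report will omit the EHH plot")
    render_report(manifest, config=config, state=state, outdir=outdir)


_STAGES = {"simulate": _stage_simulate, "scan": _stage_scan,
           "polyadapt": _stage_polyadapt, "trajectory": _stage_trajectory,
           "report": _stage_report}


def render_report(manifest: dict, config: RunConfig | None = None,
                  state: dict | None = None,
                  outdir: Path | None = None) -> list[str]:
    """Render figures/tables from a run's outputs; missing pieces are
    listed and skipped, the rest still rendered."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if outdir is None:
        outdir = Path(manifest["config"]["outdir"])
    report = outdir / "report"
    report.mkdir(parents=True, exist_ok=True)
    written, missing = [], []

    scan_path = outdir / "scan.tsv"
    if scan_path.exists():
        scan = hap_io.read_scan_table(scan_path)
        fig, ax = plt.subplots(figsize=(7, 3))
        ax.scatter(scan["pos"] / 1e6, scan["sihs"], s=8, alpha=0.7)
        ax.set_xlabel("position (Mb)")
        ax.set_ylabel("standardized iHS")
        fig.tight_layout()
        fig.savefig(report / "ihs_scatter.png", dpi=120)
        plt.close(fig)
        written.append("ihs_scatter.png")
    else:
        missing.append("scan.tsv")

    if config is not None and state and "panel" in state:
        panel, gmap = state["panel"], state["gmap"]
        truth = pd.read_csv(state["paths"]["truth_sites"], sep="\t")
        sel_id = truth.loc[truth["is_selected"], "snp_id"].iloc[0]
        core = panel.site_index(sel_id)
        fig, ax = plt.subplots(figsize=(6, 3.5))
        for cls, color in (("derived", "tab:red"), ("ancestral", "tab:blue")):
            try:
                c = compute_ehh(panel, core, cls, config.scan.truncation_ehh,
                                config.scan.max_extension_bp)
                ax.plot(c.offsets_bp / 1e6, c.ehh, color=color, label=cls)
            except ValueError:
                pass
        ax.set_xlabel("offset from core (Mb)")
        ax.set_ylabel("EHH")
        ax.legend()
        fig.tight_layout()
        fig.savefig(report / "ehh_decay.png", dpi=120)
        plt.close(fig)
        written.append("ehh_decay.png")

    z_path = outdir / "z.tsv"
    if z_path.exists():
        z = pd.read_csv(z_path, sep="\t")
        fig, ax = plt.subplots(figsize=(6, 3.5))
        ax.plot(z["time_generations"], z["z"])
        ax.axvspan(50, 100, alpha=0.15, color="tab:orange",
                   label="settlement window")
        ax.invert_xaxis()
        ax.set_xlabel("generations before present")
        ax.set_ylabel("population-average PS, Z(t)")
        ax.legend()
        fig.tight_layout()
        fig.savefig(report / "ps_trajectory.png", dpi=120)
        plt.close(fig)
        written.append("ps_trajectory.png")
    else:
        missing.append("z.tsv")

    t1 = outdir / "table1.tsv"
    if t1.exists():
        pd.read_csv(t1, sep="\t").to_csv(report / "summary_table.tsv",
                                         sep="\t", index=False)
        written.append("summary_table.tsv")
    else:
        missing.append("table1.tsv")
        (report / "summary_table.tsv").write_text(
            "# no trait results available\n")
    if missing:
        logger.warning("report rendered without: %s", ", ".join(missing))
    manifest.setdefault("report", {})["files"] = written
    return written
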