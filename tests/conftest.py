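import logging

import numpy as np
import pytest

from polyhap.hap_io import GeneticMap, HaplotypePanel

logging.getLogger("polyhap").setLevel(logging.ERROR)


def make_panel(alleles, positions=None, chrom="1", cm_per_mb=1.0):
    """Small literal panel: rows = haplotypes, columns = sites."""
    alleles = np.asarray(alleles, dtype=np.uint8)
    n_sites = alleles.shape[1]
    if positions is None:
        positions = (np.arange(n_sites) + 1) * 10_000
    positions = np.asarray(positions, dtype=np.int64)
    cm = positions / 1e6 * cm_per_mb
    ids = np.array([f"{chrom}_{p}" for p in positions], dtype=object)
    anc = np.array(["A"] * n_sites, dtype=object)
    der = np.array(["G"] * n_sites, dtype=object)
    return HaplotypePanel(alleles, chrom, positions, cm, ids,
                          anc_base=anc, der_base=der)


def make_map(length=10_000_000, cm_per_mb=1.0):
    return GeneticMap(np.array([1, length]),
                      np.array([0.0, length / 1e6 * cm_per_mb]))


@pytest.fixture
def flat_map():
    return make_map()


@pytest.fixture(scope="session")
def small_sweep_fixture():
    """A no-recombination sweep panel: derived core haplotypes identical."""
    from polyhap.synthetic_data import SimConfig, SweepSpec, simulate_sweep_panel

    cfg = SimConfig(n_diploids=22, region_length=1_000_000, n_sites=40,
                    per_site_recomb=0.0, Ne=300, seed=11)
    sweep = SweepSpec(selected_site_index=20, s=0.1, onset_generation=60,
                      max_sample_carriers=30)
    panel, traj = simulate_sweep_panel(cfg, sweep)
    return cfg, sweep, panel, traj
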