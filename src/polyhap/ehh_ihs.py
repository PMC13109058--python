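"""Extended haplotype homozygosity and the integrated haplotype score.

EHH at a signed offset from a core allele is the probability that two
randomly chosen carrier haplotypes are identical over the whole interval
from the core to that offset:

    EHH = sum_g C(n_g, 2) / C(n_c, 2)

over groups ``g`` of carriers identical from the core through the offset
site (``n_c`` carriers in total).  iHH is the trapezoidal integral of the
EHH decay curve against genetic distance (cM), summed over both sides of
the core; the unstandardized score is

    uiHS = ln(iHH_derived / iHH_ancestral),

standardized within derived-allele-frequency bins (default 25 equal-width
bins on (0,1), sample-SD denominator) so that large positive values flag
unusually extended derived haplotypes — the footprint of a recent sweep.
Two-sided normal tail probabilities 2(1 - Phi(|siHS|)) are attached for
reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from polyhap.hap_io import GeneticMap, HaplotypePanel

logger = logging.getLogger(__name__)


class EHHError(ValueError):
    """Core allele has too few carriers to define EHH."""


@dataclass
class ScanConfig:
    """Truncation, integration-scale and binning choices of the scan."""

    truncation_ehh: float = 0.05
    max_extension_bp: int = 1_000_000
    scale: str = "cM"        # integrate against "cM" or "bp" (Mb units)
    min_carriers: int = 2
    n_bins: int = 25
    bin_mode: str = "width"  # "width" (equal-width DAF) or "count" (quantile)
    low_freq_daf: float = 0.05  # cores below this DAF are flagged low_freq


@dataclass
class EHHCurve:
    """One EHH decay curve around a core allele.

    ``sites`` are panel site indices in ascending order (the core
    included); ``positions_bp``/``offsets_bp`` align with them, as does
    ``ehh``.  ``edge_left``/``edge_right`` record whether extension hit the
    panel edge before decaying below the truncation threshold.
    """

    core_site: int
    allele_class: str
    sites: np.ndarray
    positions_bp: np.ndarray
    offsets_bp: np.ndarray
    ehh: np.ndarray
    n_carriers: int
    edge_left: bool = False
    edge_right: bool = False

    def side(self, which: str) -> tuple[np.ndarray, np.ndarray]:
        """(positions_bp, ehh) from the core outward on one side."""
        at_core = int(np.nonzero(self.sites == self.core_site)[0][0])
        if which == "left":
            return (self.positions_bp[at_core::-1], self.ehh[at_core::-1])
        return (self.positions_bp[at_core:], self.ehh[at_core:])


def _ehh_walk(alleles: np.ndarray, carrier_rows: np.ndarray, core: int,
              positions: np.ndarray, step: int, truncation: float,
              max_ext: int) -> tuple[list[int], list[float], bool]:
    """Walk outward from the core, returning (site indices, EHH, edge hit)."""
    n_c = carrier_rows.size
    denom = n_c * (n_c - 1) / 2.0
    labels = np.zeros(n_c, dtype=np.int64)
    sites: list[int] = []
    ehhs: list[float] = []
    j = core + step
    n_sites = alleles.shape[1]
    while 0 <= j < n_sites and abs(int(positions[j]) - int(positions[core])) <= max_ext:
        labels = np.unique(labels * 2 + alleles[carrier_rows, j],
                           return_inverse=True)[1]
        counts = np.bincount(labels)
        ehh = float((counts * (counts - 1)).sum() / 2.0 / denom)
        sites.append(j)
        ehhs.append(ehh)
        if ehh < truncation:
            return sites, ehhs, False
        j += step
    # ran off the panel edge (or max extension) above the threshold
    edge = not (0 <= j < n_sites)
    return sites, ehhs, edge and (len(ehhs) == 0 or ehhs[-1] >= truncation)


def compute_ehh(panel: HaplotypePanel, core_site: int, allele_class: str,
                truncation_ehh: float = 0.05,
                max_extension_bp: int = 1_000_000) -> EHHCurve:
    """EHH decay curve for one core allele, extended independently per side
    until EHH < ``truncation_ehh`` (that terminal point is kept) or
    ``max_extension_bp`` is reached."""
    if allele_class not in ("ancestral", "derived"):
        raise ValueError("allele_class must be 'ancestral' or 'derived'")
    want = 1 if allele_class == "derived" else 0
    carriers = np.nonzero(panel.alleles[:, core_site] == want)[0]
    if carriers.size < 2:
        raise EHHError(f"site {core_site}: only {carriers.size} carriers of "
                       f"the {allele_class} allele")
    left_sites, left_ehh, edge_l = _ehh_walk(
        panel.alleles, carriers, core_site, panel.positions_bp, -1,
        truncation_ehh, max_extension_bp)
    right_sites, right_ehh, edge_r = _ehh_walk(
        panel.alleles, carriers, core_site, panel.positions_bp, +1,
        truncation_ehh, max_extension_bp)
    sites = np.array(left_sites[::-1] + [core_site] + right_sites)
    ehh = np.array(left_ehh[::-1] + [1.0] + right_ehh)
    pos = panel.positions_bp[sites]
    return EHHCurve(core_site=core_site, allele_class=allele_class,
                    sites=sites, positions_bp=pos,
                    offsets_bp=pos - panel.positions_bp[core_site],
                    ehh=ehh, n_carriers=int(carriers.size),
                    edge_left=edge_l, edge_right=edge_r)


def integrate_ihh(curve: EHHCurve, gmap: GeneticMap,
                  scale: str = "cM") -> float:
    """Trapezoidal integral of EHH against genetic distance, both sides.

    The terminal sub-threshold point of each side is included as the final
    trapezoid edge.  ``scale="bp"`` integrates against physical distance in
    Mb instead of the map.
    """
    if curve.sites.size < 1:
        raise ValueError("empty EHH curve")
    total = 0.0
    for which in ("left", "right"):
        pos, ehh = curve.side(which)
        if pos.size < 2:
            continue
        if scale == "cM":
            x = np.abs(np.asarray(gmap.interpolate_cm(pos), dtype=float)
                       - float(gmap.interpolate_cm(pos[0])))
        else:
            x = np.abs(pos - pos[0]) / 1e6
        total += float(np.trapezoid(ehh, x))
    return total


def compute_uihs(panel: HaplotypePanel, site: int, gmap: GeneticMap,
                 config: ScanConfig | None = None) -> dict:
    """Unstandardized iHS record for one site.

    Returns a dict with iHH for both allele classes, uiHS =
    ln(iHH_D/iHH_A) (NaN and a flag when either integral is zero), the
    site's DAF, and edge/low-frequency flags.
    """
    config = config or ScanConfig()
    counts = int(panel.alleles[:, site].sum())
    n = panel.n_haplotypes
    if counts == 0 or counts == n:
        raise EHHError(f"site {site} is monomorphic")
    if min(counts, n - counts) < config.min_carriers:
        raise EHHError(f"site {site}: fewer than {config.min_carriers} "
                       "carriers of one allele")
    flags = []
    curves = {}
    for cls in ("derived", "ancestral"):
        curves[cls] = compute_ehh(panel, site, cls, config.truncation_ehh,
                                  config.max_extension_bp)
    ihh_d = integrate_ihh(curves["derived"], gmap, config.scale)
    ihh_a = integrate_ihh(curves["ancestral"], gmap, config.scale)
    daf = counts / n
    if any(c.edge_left or c.edge_right for c in curves.values()):
        flags.append("edge")
    if min(daf, 1 - daf) < config.low_freq_daf:
        flags.append("low_freq")
    if ihh_d > 0 and ihh_a > 0:
        uihs = float(np.log(ihh_d / ihh_a))
    else:
        uihs = np.nan
        flags.append("zero_ihh")
    return {"snp_id": panel.site_ids[site], "pos": int(panel.positions_bp[site]),
            "daf": daf, "ihh_d": ihh_d, "ihh_a": ihh_a, "uihs": uihs,
            "flags": ",".join(flags)}


@dataclass
class StandardizationBins:
    """Frequency-bin summary used to standardize uiHS."""

    edges: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    count: np.ndarray


def standardize_ihs(records: pd.DataFrame, n_bins: int = 25,
                    mode: str = "width"
                    ) -> tuple[pd.DataFrame, StandardizationBins]:
    """Standardize uiHS within DAF bins: siHS = (uiHS - mean_bin)/sd_bin.

    Bins are equal-width on DAF in (0,1) by default (``mode="count"``
    uses equal-count quantile bins).  The sample (n-1) standard deviation
    is used.  Bins with fewer than 2 defined values, or zero variance,
    leave their records unstandardizable (siHS = NaN, flagged).
    """
    out = records.copy()
    uihs = out["uihs"].to_numpy(dtype=float)
    daf = out["daf"].to_numpy(dtype=float)
    defined = np.isfinite(uihs)
    if mode == "width":
        edges = np.linspace(0.0, 1.0, n_bins + 1)
    elif mode == "count":
        qs = np.linspace(0, 1, n_bins + 1)
        edges = np.unique(np.quantile(daf[defined], qs))
        edges[0], edges[-1] = 0.0, 1.0
    else:
        raise ValueError(f"unknown binning mode {mode!r}")
    bin_idx = np.clip(np.searchsorted(edges, daf, side="right") - 1,
                      0, len(edges) - 2)
    n_eff = len(edges) - 1
    mean = np.full(n_eff, np.nan)
    sd = np.full(n_eff, np.nan)
    count = np.zeros(n_eff, dtype=np.int64)
    sihs = np.full(uihs.size, np.nan)
    for b in range(n_eff):
        sel = defined & (bin_idx == b)
        count[b] = int(sel.sum())
        if count[b] < 2:
            if count[b]:
                logger.warning("bin %d has %d record(s); unstandardizable",
                               b, count[b])
            continue
        m = uihs[sel].mean()
        s = uihs[sel].std(ddof=1)
        mean[b], sd[b] = m, s
        if s == 0:
            logger.warning("bin %d has zero variance; records flagged", b)
            continue
        sihs[sel] = (uihs[sel] - m) / s
    out["bin"] = bin_idx
    out["sihs"] = sihs
    out["p_normal"] = ihs_normal_p(out["sihs"].to_numpy())
    return out, StandardizationBins(edges=edges, mean=mean, sd=sd, count=count)


def ihs_normal_p(sihs):
    """Two-sided standard-normal tail probability 2(1 - Phi(|siHS|))."""
    return 2.0 * norm.sf(np.abs(sihs))


def scan_records(panel: HaplotypePanel, gmap: GeneticMap,
                 config: ScanConfig | None = None) -> pd.DataFrame:
    """Unstandardized iHS records for every eligible site of one panel."""
    config = config or ScanConfig()
    rows = []
    n_skipped = 0
    for j in range(panel.n_sites):
        counts = int(panel.alleles[:, j].sum())
        if min(counts, panel.n_haplotypes - counts) < config.min_carriers:
            n_skipped += 1
            continue
        rows.append(compute_uihs(panel, j, gmap, config))
    logger.info("scan of %s: %d sites computed, %d skipped (carrier floor)",
                panel.chrom, len(rows), n_skipped)
    return pd.DataFrame(rows)


def scan_chromosome(panel: HaplotypePanel, gmap: GeneticMap,
                    config: ScanConfig | None = None
                    ) -> tuple[pd.DataFrame, StandardizationBins]:
    """Full single-chromosome scan: per-site uiHS, then bin standardization."""
    config = config or ScanConfig()
    recs = scan_records(panel, gmap, config)
    if len(recs) < 2 * config.n_bins:
        logger.warning("only %d eligible sites for %d bins; sparse bins "
                       "will be collapsed/flagged", len(recs), config.n_bins)
    return standardize_ihs(recs, n_bins=config.n_bins, mode=config.bin_mode)


def scan_genome(regions: list, config: ScanConfig | None = None
                ) -> tuple[pd.DataFrame, StandardizationBins]:
    """Scan several (panel, map) regions and standardize jointly genome-wide."""
    config = config or ScanConfig()
    recs = pd.concat([scan_records(p, m, config) for p, m in regions],
                     ignore_index=True)
    return standardize_ihs(recs, n_bins=config.n_bins, mode=config.bin_mode)
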