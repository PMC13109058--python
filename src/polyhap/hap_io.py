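"""Readers and writers for the standard formats the pipeline touches.

In-memory containers:

* :class:`HaplotypePanel` — phased binary haplotype matrix polarized to
  ancestral(0)/derived(1), with physical (bp) and genetic (cM) positions.
* :class:`GeneticMap` — piecewise-linear bp→cM map.
* GWAS summary tables and per-site annotation tables are plain pandas
  DataFrames validated on read (columns documented on the readers).

Coordinates are 1-based inclusive in files (VCF convention); internal arrays
are 0-indexed.  The conversion is confined to this module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GWAS_COLUMNS = ["snp_id", "effect_allele", "beta", "p"]
ANNOT_COLUMNS = ["snp_id", "daf", "recomb_rate", "gerp"]
SCAN_COLUMNS = [
    "snp_id", "pos", "daf", "ihh_d", "ihh_a", "uihs", "sihs", "bin", "p_normal",
]


class FormatError(ValueError):
    """A file violated the expected format or an invariant of its table."""


@dataclass
class GeneticMap:
    """Piecewise-linear genetic map: anchors of (bp, cM) pairs.

    bp strictly increasing, cM non-decreasing.  Interpolation is linear
    between anchors; beyond either end the terminal segment's slope is used
    to extrapolate.
    """

    bp: np.ndarray
    cm: np.ndarray

    def __post_init__(self) -> None:
        self.bp = np.asarray(self.bp, dtype=np.int64)
        self.cm = np.asarray(self.cm, dtype=float)
        if self.bp.size == 0:
            raise FormatError("genetic map has no anchors")
        if self.bp.size != self.cm.size:
            raise FormatError("bp and cM anchor arrays differ in length")
        if self.bp.size > 1:
            if np.any(np.diff(self.bp) <= 0):
                raise FormatError("map bp positions must be strictly increasing")
            if np.any(np.diff(self.cm) < 0):
                raise FormatError("map cM values must be non-decreasing")

    def interpolate_cm(self, bp) -> np.ndarray | float:
        """Map physical position(s) to cM (terminal-slope extrapolation)."""
        pos = np.atleast_1d(np.asarray(bp, dtype=float))
        if self.bp.size == 1:
            out = np.full(pos.shape, self.cm[0])
        else:
            out = np.interp(pos, self.bp.astype(float), self.cm)
            lo, hi = self.bp[0], self.bp[-1]
            slope_lo = (self.cm[1] - self.cm[0]) / (self.bp[1] - self.bp[0])
            slope_hi = (self.cm[-1] - self.cm[-2]) / (self.bp[-1] - self.bp[-2])
            below = pos < lo
            above = pos > hi
            out[below] = self.cm[0] + slope_lo * (pos[below] - lo)
            out[above] = self.cm[-1] + slope_hi * (pos[above] - hi)
        return out if np.ndim(bp) else float(out[0])

    def local_rate(self, bp: float, window_bp: float = 100_000.0) -> float:
        """Local recombination rate (cM/Mb) from the map slope in a window."""
        half = window_bp / 2.0
        c0 = self.interpolate_cm(bp - half)
        c1 = self.interpolate_cm(bp + half)
        return float((c1 - c0) / window_bp * 1e6)


def interpolate_cM(gmap: GeneticMap, bp):  # noqa: N802 - field convention
    """Functional alias for :meth:`GeneticMap.interpolate_cm`."""
    return gmap.interpolate_cm(bp)


@dataclass
class HaplotypePanel:
    """Phased binary haplotype matrix, 0 = ancestral, 1 = derived.

    Rows are haplotypes (two per diploid), columns are sites ordered by
    strictly increasing physical position.  ``positions_cm`` carries the
    genetic-map coordinate of each site; ``anc_base``/``der_base`` optionally
    carry the nucleotide identity of each allele so that GWAS effect alleles
    given as bases can be resolved.
    """

    alleles: np.ndarray
    chrom: str
    positions_bp: np.ndarray
    positions_cm: np.ndarray
    site_ids: np.ndarray
    anc_base: np.ndarray | None = None
    der_base: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.alleles = np.ascontiguousarray(self.alleles, dtype=np.uint8)
        self.positions_bp = np.asarray(self.positions_bp, dtype=np.int64)
        self.positions_cm = np.asarray(self.positions_cm, dtype=float)
        self.site_ids = np.asarray(self.site_ids, dtype=object)
        n_hap, n_sites = self.alleles.shape
        if n_hap % 2 != 0:
            raise FormatError("haplotype count must be even (phased diploids)")
        if not (len(self.positions_bp) == len(self.positions_cm)
                == len(self.site_ids) == n_sites):
            raise FormatError("site metadata lengths disagree with matrix")
        if n_sites > 1 and np.any(np.diff(self.positions_bp) <= 0):
            raise FormatError("positions must be strictly increasing")
        if self.alleles.max(initial=0) > 1:
            raise FormatError("alleles must be 0/1")
        if len(set(self.site_ids)) != n_sites:
            raise FormatError("site ids must be unique")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    def derived_counts(self) -> np.ndarray:
        return self.alleles.sum(axis=0).astype(np.int64)

    def daf(self) -> np.ndarray:
        """Derived allele frequency per site."""
        return self.derived_counts() / self.n_haplotypes

    def segregating(self) -> np.ndarray:
        """Boolean mask of segregating (non-monomorphic) sites."""
        c = self.derived_counts()
        return (c > 0) & (c < self.n_haplotypes)

    def site_index(self, snp_id: str) -> int:
        idx = np.nonzero(self.site_ids == snp_id)[0]
        if idx.size == 0:
            raise KeyError(f"site id {snp_id!r} not in panel")
        return int(idx[0])


# ---------------------------------------------------------------------------
# VCF

def read_phased_vcf(path: str, ancestral_source: str | dict = "AA",
                    gmap: GeneticMap | None = None) -> HaplotypePanel:
    """Read a phased biallelic-SNP VCF into a :class:`HaplotypePanel`.

    ``ancestral_source`` is either the name of an INFO tag holding the
    ancestral base (default ``AA``) or a dict mapping site id → ancestral
    base.  Genotypes are recoded so 1 = derived.  Sites whose ancestral
    state is missing or matches neither REF nor ALT are dropped (counted in
    the log); multi-allelic and indel records are skipped likewise.
    Unphased genotypes are an error naming the offending record.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    rows = []
    meta: list[tuple[str, int, str, str]] = []
    chrom = None
    n_dropped_aa = n_skipped_nonsnp = 0
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            n_skipped_nonsnp += 1
            continue
        if chrom is None:
            chrom = var.CHROM
        sid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        if isinstance(ancestral_source, dict):
            aa = ancestral_source.get(sid)
        else:
            aa = var.INFO.get(ancestral_source)
        if aa is not None:
            aa = str(aa).upper().strip()
        ref, alt = var.REF.upper(), var.ALT[0].upper()
        if aa not in (ref, alt):
            n_dropped_aa += 1
            logger.warning("site %s: ancestral allele %r matches neither "
                           "REF nor ALT; dropped", sid, aa)
            continue
        gts = var.genotype.array()
        if np.any(gts[:, -1] == 0):
            raise FormatError(f"unphased genotype at {var.CHROM}:{var.POS}")
        hap = gts[:, :-1].reshape(-1).astype(np.uint8)
        if aa == alt:  # ALT is ancestral: flip polarity
            hap = 1 - hap
            anc, der = alt, ref
        else:
            anc, der = ref, alt
        rows.append(hap)
        meta.append((sid, var.POS, anc, der))
    if n_skipped_nonsnp or n_dropped_aa:
        logger.info("read_phased_vcf: skipped %d non-biallelic-SNP records, "
                    "dropped %d with unusable ancestral state",
                    n_skipped_nonsnp, n_dropped_aa)
    if not rows:
        raise FormatError(f"no usable biallelic SNPs in {path}")
    alleles = np.stack(rows, axis=1)
    sids, pos, anc, der = (np.asarray([m[i] for m in meta], dtype=object)
                           for i in range(4))
    pos = pos.astype(np.int64)
    cm = gmap.interpolate_cm(pos) if gmap is not None else np.zeros(len(pos))
    return HaplotypePanel(alleles, chrom or "1", pos, np.asarray(cm, float),
                          sids, anc_base=anc, der_base=der)


def write_phased_vcf(panel: HaplotypePanel, path: str,
                     ref_is_ancestral: np.ndarray | None = None) -> None:
    """Write a panel as a phased VCF 4.2 with an ``AA=`` INFO tag.

    ``ref_is_ancestral`` (boolean per site, default all True) controls the
    REF/ALT orientation: where False, REF is the derived base and genotypes
    are written flipped, with the ``AA`` tag still naming the ancestral
    base — reading the file back re-polarizes to the same panel.
    """
    n_dip = panel.n_haplotypes // 2
    anc = panel.anc_base if panel.anc_base is not None else ["A"] * panel.n_sites
    der = panel.der_base if panel.der_base is not None else ["G"] * panel.n_sites
    if ref_is_ancestral is None:
        ref_is_ancestral = np.ones(panel.n_sites, dtype=bool)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,'
                 'Description="Ancestral Allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(f"##contig=<ID={panel.chrom}>\n")
        samples = "\t".join(f"S{i:03d}" for i in range(n_dip))
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
        for j in range(panel.n_sites):
            col = panel.alleles[:, j]
            if ref_is_ancestral[j]:
                ref, alt = anc[j], der[j]
            else:
                ref, alt = der[j], anc[j]
                col = 1 - col
            gts = "\t".join(f"{col[2*i]}|{col[2*i+1]}" for i in range(n_dip))
            fh.write(f"{panel.chrom}\t{panel.positions_bp[j]}\t"
                     f"{panel.site_ids[j]}\t{ref}\t{alt}\t.\tPASS\t"
                     f"AA={anc[j]}\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# Genetic map

def read_genetic_map(path: str) -> GeneticMap:
    """Read a two-column (bp, cM) whitespace-separated map file."""
    tab = pd.read_csv(path, sep=r"\s+", comment="#", header=None,
                      names=["bp", "cm"])
    return GeneticMap(tab["bp"].to_numpy(), tab["cm"].to_numpy())


def write_genetic_map(gmap: GeneticMap, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("# bp\tcM\n")
        for b, c in zip(gmap.bp, gmap.cm):
            fh.write(f"{b}\t{c:.8g}\n")


# ---------------------------------------------------------------------------
# Tables

def _require_columns(df: pd.DataFrame, cols: list[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{what}: missing columns {missing}; expected {cols}")


def validate_gwas_table(df: pd.DataFrame, trait: str | None = None) -> pd.DataFrame:
    """Validate a GWAS summary table (snp_id, effect_allele, beta, p)."""
    _require_columns(df, GWAS_COLUMNS, "GWAS table")
    if df["snp_id"].duplicated().any():
        dup = df.loc[df["snp_id"].duplicated(), "snp_id"].iloc[0]
        raise FormatError(f"GWAS table: duplicate snp_id {dup!r}")
    p = df["p"].to_numpy(dtype=float)
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise FormatError("GWAS table: p-values must lie in (0, 1]")
    if np.any(~np.isfinite(df["beta"].to_numpy(dtype=float))):
        raise FormatError("GWAS table: beta must be finite")
    out = df.copy()
    if trait is not None:
        out["trait"] = trait
    return out


def read_gwas_summary(path: str, trait: str | None = None) -> pd.DataFrame:
    return validate_gwas_table(pd.read_csv(path, sep="\t"), trait=trait)


def write_gwas_summary(df: pd.DataFrame, path: str) -> None:
    cols = GWAS_COLUMNS + [c for c in df.columns if c not in GWAS_COLUMNS]
    df[cols].to_csv(path, sep="\t", index=False)


def validate_annotations(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, ANNOT_COLUMNS, "annotation table")
    if df["snp_id"].duplicated().any():
        raise FormatError("annotation table: duplicate snp_id")
    daf = df["daf"].to_numpy(dtype=float)
    if np.any((daf < 0) | (daf > 1)):
        raise FormatError("annotation table: daf must lie in [0, 1]")
    return df


def read_annotations(path: str) -> pd.DataFrame:
    return validate_annotations(pd.read_csv(path, sep="\t"))


def write_annotations(df: pd.DataFrame, path: str) -> None:
    df[ANNOT_COLUMNS].to_csv(path, sep="\t", index=False)


def write_scan_table(records: pd.DataFrame, path: str) -> None:
    """Write an iHS scan table with a fixed column order."""
    _require_columns(records, SCAN_COLUMNS, "scan table")
    records[SCAN_COLUMNS].to_csv(path, sep="\t", index=False)


def read_scan_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, SCAN_COLUMNS, "scan table")
    return df
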