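"""Post-genotyping SNP filtering cascade for RAD data.

Stages, in order: locus call rate (keep loci genotyped in >= 70% of
individuals), individual missingness (drop individuals missing > 50% of
loci), minor allele count (keep MAC >= 3), HDPlot paralog removal
(heterozygosity > 0.55 or |read-ratio deviation| > 5), and thinning to the
single SNP with the highest minor allele frequency per RAD tag. Boundary
semantics follow the stage descriptions exactly: the call-rate and MAC
thresholds keep the boundary, the missingness and HDPlot thresholds remove
strictly beyond it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import DepthMatrix, GenotypeMatrix

log = logging.getLogger(__name__)

__all__ = [
    "FilterReport", "HDPlotStats", "filter_locus_call_rate",
    "filter_individual_missingness", "filter_mac", "hdplot",
    "filter_paralogs", "thin_one_snp_per_tag", "run_filter_cascade",
]


@dataclass
class FilterReport:
    """Ordered per-stage record of what each filter removed."""

    stages: list = field(default_factory=list)

    def add(self, name, thresholds, loci_before, loci_after, ind_before, ind_after):
        self.stages.append(dict(
            stage=name, thresholds=thresholds,
            loci_before=loci_before, loci_after=loci_after,
            loci_removed=loci_before - loci_after,
            individuals_before=ind_before, individuals_after=ind_after,
            individuals_removed=ind_before - ind_after,
        ))
        log.info("%s: loci %d -> %d, individuals %d -> %d",
                 name, loci_before, loci_after, ind_before, ind_after)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages)

    def extend(self, other: "FilterReport") -> None:
        self.stages.extend(other.stages)


@dataclass
class HDPlotStats:
    """Per-locus heterozygote proportion H and read-ratio deviation z-score D."""

    H: np.ndarray
    D: np.ndarray


def _report(name, thr, gm0, gm1):
    rep = FilterReport()
    rep.add(name, thr, gm0.n_loci, gm1.n_loci, gm0.n_individuals, gm1.n_individuals)
    return rep


def filter_locus_call_rate(gm: GenotypeMatrix, min_rate: float = 0.70,
                           depths: DepthMatrix | None = None):
    """Keep loci genotyped in at least ``min_rate`` of individuals (inclusive)."""
    rate = 1.0 - gm.missing_mask.mean(axis=0)
    keep = np.flatnonzero(rate >= min_rate)
    out = gm.subset(locus_idx=keep)
    dep = depths.subset(locus_idx=keep) if depths is not None else None
    return out, dep, _report("locus_call_rate", {"min_rate": min_rate}, gm, out)


def filter_individual_missingness(gm: GenotypeMatrix, max_missing: float = 0.50,
                                  depths: DepthMatrix | None = None):
    """Drop individuals missing strictly more than ``max_missing`` of loci."""
    miss = gm.missing_mask.mean(axis=1)
    keep = np.flatnonzero(miss <= max_missing)
    out = gm.subset(ind_idx=keep)
    dep = depths.subset(ind_idx=keep) if depths is not None else None
    return out, dep, _report("individual_missingness", {"max_missing": max_missing}, gm, out)


def minor_allele_counts(gm: GenotypeMatrix) -> np.ndarray:
    """Copy count of the rarer allele per locus (bi-allelic)."""
    d = gm.dosage()
    alt = np.nansum(d, axis=0)
    tot = 2.0 * (~np.isnan(d)).sum(axis=0)
    return np.minimum(alt, tot - alt)


def filter_mac(gm: GenotypeMatrix, min_mac: int = 3,
               depths: DepthMatrix | None = None):
    """Keep loci whose minor allele count is at least ``min_mac`` (inclusive)."""
    keep = np.flatnonzero(minor_allele_counts(gm) >= min_mac)
    out = gm.subset(locus_idx=keep)
    dep = depths.subset(locus_idx=keep) if depths is not None else None
    return out, dep, _report("minor_allele_count", {"min_mac": min_mac}, gm, out)


def hdplot(gm: GenotypeMatrix, depths: DepthMatrix | None) -> HDPlotStats:
    """Paralog diagnostics: H and the read-ratio deviation D.

    H is the proportion of genotyped individuals called heterozygous. D
    pools reads over heterozygous individuals at the locus: with A reads of
    the reference allele out of n total, D = (A - n/2) / sqrt(n/4), the
    z-score of a fair allele split. D is NaN where no heterozygote has
    reads (and everywhere when no depth matrix is available).
    """
    het = gm.het_mask()
    genotyped = (~gm.missing_mask).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        H = np.where(genotyped > 0, het.sum(axis=0) / genotyped, np.nan)
    D = np.full(gm.n_loci, np.nan)
    if depths is None:
        log.warning("hdplot: no depth matrix; D undefined, H-only filtering")
    else:
        A = np.where(het, depths.ref, 0).sum(axis=0).astype(float)
        n = np.where(het, depths.ref + depths.alt, 0).sum(axis=0).astype(float)
        ok = n > 0
        D[ok] = (A[ok] - n[ok] / 2.0) / np.sqrt(n[ok] / 4.0)
    return HDPlotStats(H=H, D=D)


def filter_paralogs(gm: GenotypeMatrix, stats: HDPlotStats,
                    h_max: float = 0.55, d_max: float = 5.0,
                    depths: DepthMatrix | None = None):
    """Remove putative paralogs: H > ``h_max`` or |D| > ``d_max``."""
    with np.errstate(invalid="ignore"):
        bad = (stats.H > h_max) | (np.abs(stats.D) > d_max)
    keep = np.flatnonzero(~np.nan_to_num(bad))
    out = gm.subset(locus_idx=keep)
    dep = depths.subset(locus_idx=keep) if depths is not None else None
    return out, dep, _report("hdplot_paralogs", {"h_max": h_max, "d_max": d_max}, gm, out)


def thin_one_snp_per_tag(gm: GenotypeMatrix, depths: DepthMatrix | None = None):
    """Keep one SNP per RAD tag: the highest-MAF SNP, ties to smallest locus_id."""
    d = gm.dosage()
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.nansum(d, axis=0) / (2.0 * (~np.isnan(d)).sum(axis=0))
    maf = np.minimum(p, 1.0 - p)
    df = pd.DataFrame({
        "idx": np.arange(gm.n_loci),
        "tag": gm.loci.df["tag_id"],
        "locus_id": gm.loci.df["locus_id"],
        "maf": np.nan_to_num(maf, nan=-1.0),
    })
    df = df.sort_values(["tag", "maf", "locus_id"],
                        ascending=[True, False, True], kind="stable")
    keep = np.sort(df.groupby("tag", sort=False).head(1)["idx"].to_numpy())
    out = gm.subset(locus_idx=keep)
    dep = depths.subset(locus_idx=keep) if depths is not None else None
    return out, dep, _report("thin_one_snp_per_tag", {}, gm, out)


def run_filter_cascade(
    gm: GenotypeMatrix,
    depths: DepthMatrix | None = None,
    min_rate: float = 0.70,
    max_missing: float = 0.50,
    min_mac: int = 3,
    h_max: float = 0.55,
    d_max: float = 5.0,
):
    """Apply the full cascade in order; returns ``(gm, depths, FilterReport)``.

    Each stage sees the output of the previous one, so e.g. minor allele
    counts are taken after low-call-rate loci and high-missingness
    individuals are gone.
    """
    report = FilterReport()
    gm, depths, r = filter_locus_call_rate(gm, min_rate, depths)
    report.extend(r)
    gm, depths, r = filter_individual_missingness(gm, max_missing, depths)
    report.extend(r)
    gm, depths, r = filter_mac(gm, min_mac, depths)
    report.extend(r)
    stats = hdplot(gm, depths)
    gm, depths, r = filter_paralogs(gm, stats, h_max, d_max, depths)
    report.extend(r)
    gm, depths, r = thin_one_snp_per_tag(gm, depths)
    report.extend(r)
    return gm, depths, report
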