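"""Kernel-smoothed genome scan along a linkage map, with bootstrap window
significance, plus a PCA-based per-locus outlier test with FDR control.

The scan slides 5-cM windows in 1-cM steps along each linkage group and
smooths a per-locus statistic (typically FST) with a Gaussian kernel
(sigma = width/4, hard-truncated at +-width/2). Window significance uses an
escalating bootstrap: the window's own positions and weights are kept while
statistic values are redrawn from the genome-wide pool (1,000 replicates,
escalated to 10,000 when the observed value exceeds the 90th percentile). A
window is significant when it exceeds the 99th percentile of its 10,000-
replicate null and holds at least two loci; overlapping or adjacent
significant windows merge into segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .genotypes import GenotypeMatrix

__all__ = [
    "WindowScanResult", "OutlierResult", "smooth_windows",
    "window_significance", "pca_outlier_scan", "scan_report",
]


@dataclass
class WindowScanResult:
    windows: pd.DataFrame               # one row per window
    weights: list = field(repr=False, default_factory=list)   # per-window locus weights
    locus_idx: list = field(repr=False, default_factory=list)  # per-window locus indices
    segments: pd.DataFrame | None = None


@dataclass
class OutlierResult:
    table: pd.DataFrame                 # locus_id, stat, p, q, outlier


def smooth_windows(
    per_locus_stat: np.ndarray,
    loci,
    width: float = 5.0,
    step: float = 1.0,
    sigma: float | None = None,
) -> WindowScanResult:
    """Gaussian-kernel smoothed windows over all mapped loci.

    ``loci`` is a LocusTable (or its DataFrame); loci without a map position
    or with a NaN statistic are ignored. Window centers run 0, step, 2*step,
    ... up to the last mapped locus of each linkage group. The smoothed
    value is sum(w_i F_i)/sum(w_i) over loci within +-width/2 of the center,
    w_i = exp(-d_i^2 / (2 sigma^2)).
    """
    df = loci.df if hasattr(loci, "df") else loci
    sigma = width / 4.0 if sigma is None else sigma
    stat = np.asarray(per_locus_stat, dtype=float)
    lg = df["linkage_group"].to_numpy(dtype=object)
    cm = pd.to_numeric(df["cM"], errors="coerce").to_numpy(dtype=float)
    usable = pd.notna(lg) & np.isfinite(cm) & np.isfinite(stat)
    rows, weights, lidx = [], [], []
    for group in pd.unique(lg[usable]):
        sel = np.flatnonzero(usable & (lg == group))
        pos = cm[sel]
        last = pos.max()
        centers = np.arange(0.0, np.floor(last / step) * step + step / 2, step)
        for c in centers:
            d = np.abs(pos - c)
            inside = d <= width / 2.0
            n_loc = int(inside.sum())
            if n_loc == 0:
                continue
            w = np.exp(-(d[inside] ** 2) / (2.0 * sigma**2))
            val = float((w * stat[sel[inside]]).sum() / w.sum())
            rows.append(dict(
                linkage_group=group, center_cM=float(c), n_loci=n_loc,
                smoothed=val,
            ))
            weights.append(w)
            lidx.append(sel[inside])
    win = pd.DataFrame(rows)
    return WindowScanResult(windows=win, weights=weights, locus_idx=lidx)


def window_significance(
    scan: WindowScanResult,
    pool: np.ndarray,
    seed=None,
    n_boot_1: int = 1000,
    n_boot_2: int = 10000,
    escalate_percentile: float = 0.90,
    sig_percentile: float = 0.99,
    min_loci: int = 2,
    step: float = 1.0,
    replace: bool = True,
) -> WindowScanResult:
    """Escalating bootstrap significance for each window.

    Null replicates keep the window's weights but draw statistic values
    from ``pool`` (the genome-wide per-locus statistics; NaNs dropped),
    with replacement by default. A window exceeding the
    ``escalate_percentile`` of its 1,000-replicate null is re-tested with
    10,000 replicates; significance requires exceeding the
    ``sig_percentile`` of the escalated null and at least ``min_loci``
    loci. Significant windows whose centers are within ``step`` on the same
    linkage group merge into segments.
    """
    rng = np.random.default_rng(seed)
    pool = np.asarray(pool, dtype=float)
    pool = pool[np.isfinite(pool)]
    win = scan.windows.copy()
    perc = np.full(len(win), np.nan)
    reps_used = np.zeros(len(win), dtype=int)
    sig = np.zeros(len(win), dtype=bool)
    obs = win["smoothed"].to_numpy()
    for i, w in enumerate(scan.weights):
        n = len(w)
        wsum = w.sum()

        def null_mean(B):
            if replace:
                draw = rng.choice(pool, size=(B, n), replace=True)
            else:
                draw = np.stack([
                    rng.choice(pool, size=n, replace=False) for _ in range(B)
                ])
            return draw @ w / wsum

        null = null_mean(n_boot_1)
        p1 = (null < obs[i]).mean()
        reps_used[i] = n_boot_1
        perc[i] = p1
        if p1 > escalate_percentile:
            null = null_mean(n_boot_2)
            perc[i] = (null < obs[i]).mean()
            reps_used[i] = n_boot_2
            sig[i] = (
                obs[i] > np.quantile(null, sig_percentile)
                and win["n_loci"].iloc[i] >= min_loci
            )
    win["percentile"] = perc
    win["n_boot"] = reps_used
    win["significant"] = sig
    segments = _merge_segments(win, scan.locus_idx, step)
    return WindowScanResult(
        windows=win, weights=scan.weights, locus_idx=scan.locus_idx,
        segments=segments,
    )


def _merge_segments(win: pd.DataFrame, locus_idx, step: float) -> pd.DataFrame:
    """Merge contiguous significant windows (centers <= step apart, same LG)."""
    rows = []
    sig = win[win["significant"]].sort_values(["linkage_group", "center_cM"])
    for group, sub in sig.groupby("linkage_group", sort=False):
        centers = sub["center_cM"].to_numpy()
        idx = sub.index.to_numpy()
        start = 0
        for i in range(1, len(centers) + 1):
            if i == len(centers) or centers[i] - centers[i - 1] > step + 1e-9:
                members = idx[start:i]
                loci_in = set()
                for j in members:
                    loci_in.update(locus_idx[win.index.get_loc(j)].tolist())
                rows.append(dict(
                    linkage_group=group,
                    start_cM=float(centers[start]) - 0.0,
                    end_cM=float(centers[i - 1]),
                    n_windows=len(members),
                    n_loci=len(loci_in),
                    peak=float(win.loc[members, "smoothed"].max()),
                ))
                start = i
    return pd.DataFrame(rows)


def pca_outlier_scan(
    gm: GenotypeMatrix, K: int, alpha: float = 0.05
) -> OutlierResult:
    """PCA-based per-locus outlier test (pcadapt-style).

    Each locus's (scaled) dosages are regressed on the first K principal-
    component score vectors; the vector of K z-scores is summarised by a
    Mahalanobis distance, scaled by the genomic inflation factor, and
    referred to chi-square(K). Benjamini-Hochberg FDR at ``alpha`` flags
    outliers.
    """
    from .ancestry import pca

    if K < 1:
        raise ValueError("K must be >= 1")
    scores, _ = pca(gm, n_components=K)
    u = scores / np.linalg.norm(scores, axis=0)      # orthonormal basis
    g, mask = _scaled_dosage(gm)
    n = g.shape[0]
    beta = u.T @ g                                   # (K, L)
    res2 = (g**2).sum(axis=0) - (beta**2).sum(axis=0)
    dof = max(n - K - 1, 1)
    sd = np.sqrt(np.maximum(res2, 1e-12) / dof)
    z = beta / sd[None, :]
    zc = z - z.mean(axis=1, keepdims=True)
    cov = np.cov(zc)
    if K == 1:
        d2 = (zc[0] ** 2) / float(cov)
    else:
        d2 = np.einsum("ki,kj,ji->i", zc, np.linalg.inv(cov), zc)
    lam = np.median(d2) / sps.chi2.ppf(0.5, K)
    pvals = sps.chi2.sf(d2 / lam, K)
    rej, qvals, *_ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    table = pd.DataFrame({
        "locus_id": gm.loci.locus_ids,
        "stat": d2,
        "p": pvals,
        "q": qvals,
        "outlier": rej,
    })
    return OutlierResult(table=table)


def _scaled_dosage(gm: GenotypeMatrix):
    d = gm.dosage()
    mask = ~np.isnan(d)
    cnt = np.maximum(mask.sum(axis=0), 1)
    p = np.nansum(d, axis=0) / (2.0 * cnt)
    x = np.where(mask, d, 2.0 * p) - 2.0 * p
    sd = np.sqrt(p * (1 - p))
    ok = sd > 0
    x[:, ok] /= sd[ok]
    x[:, ~ok] = 0.0
    return x, mask


def scan_report(results: dict[str, WindowScanResult]) -> pd.DataFrame:
    """Counts of significant windows per linkage group per comparison."""
    rows = []
    for name, res in results.items():
        sig = res.windows[res.windows["significant"]]
        counts = sig.groupby("linkage_group").size()
        for lg_name, cnt in counts.items():
            rows.append(dict(comparison=name, linkage_group=lg_name,
                             n_significant_windows=int(cnt)))
    return pd.DataFrame(rows)


def top_loci_table(
    gm: GenotypeMatrix, per_locus_stat: np.ndarray,
    linkage_group: str | None = None, n: int = 10,
) -> pd.DataFrame:
    """Per-group alternate-allele frequencies of the top-statistic loci.

    Restricting to one linkage group reproduces the usual close-up of a
    highly differentiated region: the ``n`` highest-FST loci with each
    group's allele frequency side by side.
    """
    stat = np.asarray(per_locus_stat, dtype=float)
    idx = np.arange(gm.n_loci)
    if linkage_group is not None:
        sel = gm.loci.linkage_groups == linkage_group
        idx = idx[sel]
    idx = idx[np.isfinite(stat[idx])]
    top = idx[np.argsort(-stat[idx], kind="stable")[:n]]
    dos = gm.dosage()
    rows = []
    for l in top:
        row = dict(
            locus_id=gm.loci.locus_ids[l],
            linkage_group=gm.loci.linkage_groups[l],
            cM=gm.loci.cm[l], stat=stat[l],
        )
        for pop in gm.pops():
            d = dos[gm.pop_indices(pop), l]
            row[f"freq_{pop}"] = float(np.nanmean(d) / 2.0)
        rows.append(row)
    return pd.DataFrame(rows)
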