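"""Diversity and differentiation statistics.

Implements the Weir & Cockerham (1984) variance-component estimator of FST
(theta), Nei's unbiased heterozygosities, the G_IS inbreeding coefficient,
Hedrick's standardized differentiation with the Meirmans-Hedrick small-sample
correction (G''ST), and a label-permutation test of pairwise differentiation.

Multilocus theta is combined as a ratio of sums of variance components over
loci and alleles, never as an average of per-locus ratios; negative per-locus
values are retained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

__all__ = [
    "FstResult", "wc_fst", "diversity_summary", "standardized_gst",
    "pairwise_differentiation", "permutation_differentiation_test",
]


@dataclass
class FstResult:
    theta: float                 # multilocus ratio-of-sums estimate
    per_locus: np.ndarray        # per-locus theta (NaN where excluded)
    n_loci_used: int
    n_excluded: int


def _group_indices(gm: GenotypeMatrix, groups) -> dict[str, np.ndarray]:
    if groups is None:
        return {p: gm.pop_indices(p) for p in gm.pops()}
    if isinstance(groups, dict):
        return {k: np.asarray(v) for k, v in groups.items()}
    return {p: gm.pop_indices(p) for p in groups}


def _biallelic_summaries(gm: GenotypeMatrix, idx_by_group):
    """Per-group, per-locus n (genotyped), alt-allele freq and het proportion."""
    dos = gm.dosage()
    het = gm.het_mask()
    ns, ps, hs = [], [], []
    for idx in idx_by_group.values():
        d = dos[idx]
        ok = ~np.isnan(d)
        n = ok.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.nansum(d, axis=0) / (2.0 * n)
            h = het[idx].sum(axis=0) / n
        ns.append(n)
        ps.append(p)
        hs.append(h)
    return np.array(ns), np.array(ps), np.array(hs)


def _theta_components(n, p, h):
    """Weir-Cockerham a, b, c for one allele, vectorized over loci.

    ``n``, ``p``, ``h`` have shape (r_groups, n_loci): sample sizes
    (individuals genotyped), allele frequency, and proportion of individuals
    heterozygous for the allele.
    """
    r = n.shape[0]
    nbar = n.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n**2).sum(axis=0) / (r * nbar)) / (r - 1)
        pbar = (n * p).sum(axis=0) / (r * nbar)
        s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n * h).sum(axis=0) / (r * nbar)
        inner = pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0
        a = nbar / nc * (s2 - inner / (nbar - 1))
        b = nbar / (nbar - 1) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2.0
    return a, b, c


def wc_fst(gm: GenotypeMatrix, groups=None, pair=None) -> FstResult:
    """Weir-Cockerham theta, per locus and multilocus (ratio of sums).

    ``groups`` selects/defines the populations (default: all pop labels);
    ``pair`` restricts to a 2-tuple of labels. Loci monomorphic across the
    included groups, or with fewer than two genotyped individuals in any
    group, are excluded from the sums.
    """
    if pair is not None:
        groups = list(pair)
    idx = _group_indices(gm, groups)
    if len(idx) < 2:
        raise ValueError("need at least two groups")
    if gm.is_biallelic:
        n, p, h = _biallelic_summaries(gm, idx)
        a, b, c = _theta_components(n, p, h)
        valid = (n >= 2).all(axis=0) & np.isfinite(a)
        # monomorphic across groups: every group fixed for the same allele
        mono = np.all(p == p[0], axis=0) & ((p[0] == 0) | (p[0] == 1))
        valid &= ~mono
        denom = a + b + c
        valid &= denom != 0
        per_locus = np.full(gm.n_loci, np.nan)
        with np.errstate(invalid="ignore", divide="ignore"):
            per_locus[valid] = a[valid] / denom[valid]
        theta = float(a[valid].sum() / denom[valid].sum()) if valid.any() else np.nan
        return FstResult(theta, per_locus, int(valid.sum()), int((~valid).sum()))
    return _wc_fst_general(gm, idx)


def _wc_fst_general(gm: GenotypeMatrix, idx) -> FstResult:
    """Per-allele variance components for loci with any allele count."""
    per_locus = np.full(gm.n_loci, np.nan)
    num_sum = den_sum = 0.0
    n_used = 0
    calls = gm.calls
    groups = list(idx.values())
    nall = gm.loci.n_alleles()
    for l in range(gm.n_loci):
        k = nall[l]
        n = np.zeros(len(groups))
        p = np.zeros((len(groups), k))
        h = np.zeros((len(groups), k))
        for gi, g in enumerate(groups):
            c = calls[g, l, :]
            ok = c[:, 0] >= 0
            n[gi] = ok.sum()
            if n[gi] == 0:
                continue
            cc = c[ok]
            cnt = np.bincount(cc.ravel(), minlength=k).astype(float)
            p[gi] = cnt / (2 * n[gi])
            het = cc[:, 0] != cc[:, 1]
            h[gi] = [(het & ((cc == al).sum(axis=1) == 1)).sum() / n[gi]
                     for al in range(k)]
        if (n < 2).any():
            continue
        pooled = (n[:, None] * p).sum(axis=0) / n.sum()
        if (pooled >= 1.0 - 1e-12).any():
            continue  # monomorphic across the included groups
        num = den = 0.0
        for al in range(k):
            a, b, c_ = _theta_components(
                n[:, None], p[:, al][:, None], h[:, al][:, None]
            )
            if np.isfinite(a[0]):
                num += a[0]
                den += (a + b + c_)[0]
        if den != 0:
            per_locus[l] = num / den
            num_sum += num
            den_sum += den
            n_used += 1
    theta = num_sum / den_sum if den_sum else np.nan
    return FstResult(float(theta), per_locus, n_used, gm.n_loci - n_used)


# ---------------------------------------------------------------------------
# diversity
# ---------------------------------------------------------------------------

def diversity_summary(gm: GenotypeMatrix, groups=None) -> pd.DataFrame:
    """Per-group N, A (% of all sampled alleles present), Ho, He and G_IS.

    He is Nei's unbiased expected heterozygosity 2n/(2n-1)(1 - sum p^2),
    averaged over loci; G_IS = 1 - mean(Ho)/mean(He) from the averaged
    components.
    """
    idx = _group_indices(gm, groups)
    calls = gm.calls
    nall = gm.loci.n_alleles()
    # which (locus, allele) combinations are observed anywhere
    total_alleles = 0
    observed_by_group = {g: 0 for g in idx}
    for l in range(gm.n_loci):
        c = calls[:, l, :]
        seen_all = np.unique(c[c >= 0])
        total_alleles += len(seen_all)
        for g, gi in idx.items():
            cg = c[gi]
            observed_by_group[g] += len(np.unique(cg[cg >= 0]))
    rows = []
    for g, gi in idx.items():
        cg = calls[gi]
        ok = cg[:, :, 0] >= 0
        n = ok.sum(axis=0).astype(float)
        het = (cg[:, :, 0] != cg[:, :, 1]) & ok
        with np.errstate(invalid="ignore", divide="ignore"):
            ho = np.where(n > 0, het.sum(axis=0) / n, np.nan)
        he = np.full(gm.n_loci, np.nan)
        for l in range(gm.n_loci):
            if n[l] == 0:
                continue
            cc = cg[ok[:, l], l, :]
            p = np.bincount(cc.ravel(), minlength=nall[l]) / (2 * n[l])
            corr = 2 * n[l] / (2 * n[l] - 1) if n[l] > 0.5 else np.nan
            he[l] = corr * (1 - (p**2).sum())
        ho_m = float(np.nanmean(ho))
        he_m = float(np.nanmean(he))
        gis = 1.0 - ho_m / he_m if he_m > 0 else np.nan
        rows.append(dict(
            group=g, N=len(gi),
            A_pct=100.0 * observed_by_group[g] / total_alleles if total_alleles else np.nan,
            Ho=ho_m, He=he_m, G_IS=gis,
        ))
    return pd.DataFrame(rows).set_index("group")


# ---------------------------------------------------------------------------
# standardized differentiation
# ---------------------------------------------------------------------------

def _nei_hs_ht(gm: GenotypeMatrix, idx):
    """Nei & Chesser unbiased within (Hs) and total (Ht) heterozygosity per locus."""
    calls = gm.calls
    nall = gm.loci.n_alleles()
    k = len(idx)
    groups = list(idx.values())
    hs = np.full(gm.n_loci, np.nan)
    ht = np.full(gm.n_loci, np.nan)
    for l in range(gm.n_loci):
        ns, sum_p2, pbar, ho = [], [], np.zeros(nall[l]), []
        skip = False
        for g in groups:
            c = calls[g, l, :]
            ok = c[:, 0] >= 0
            n = ok.sum()
            if n < 1:
                skip = True
                break
            cc = c[ok]
            p = np.bincount(cc.ravel(), minlength=nall[l]) / (2 * n)
            ns.append(n)
            sum_p2.append((p**2).sum())
            pbar += p / k
            ho.append((cc[:, 0] != cc[:, 1]).mean())
        if skip:
            continue
        ntilde = k / np.sum(1.0 / np.asarray(ns, dtype=float))
        ho_m = float(np.mean(ho))
        hs_l = ntilde / (ntilde - 1) * (1 - np.mean(sum_p2) - ho_m / (2 * ntilde))
        ht_l = 1 - (pbar**2).sum() + hs_l / (k * ntilde) - ho_m / (2 * k * ntilde)
        hs[l], ht[l] = hs_l, ht_l
    return hs, ht


def standardized_gst(gm: GenotypeMatrix, groups=None) -> float:
    """Hedrick's G''ST with the Meirmans-Hedrick small-sample correction.

    G''ST = k(H_T - H_S) / ((k H_T - H_S)(1 - H_S)), with H_S/H_T the
    unbiased within/total heterozygosities averaged over loci and k the
    number of groups compared.
    """
    idx = _group_indices(gm, groups)
    k = len(idx)
    if k < 2:
        raise ValueError("need at least two groups")
    hs, ht = _nei_hs_ht(gm, idx)
    ok = np.isfinite(hs) & np.isfinite(ht)
    HS, HT = float(hs[ok].mean()), float(ht[ok].mean())
    if HT <= 0 or HS >= 1:
        return 0.0
    return k * (HT - HS) / ((k * HT - HS) * (1 - HS))


def pairwise_differentiation(
    gm: GenotypeMatrix, groups=None, n_perm: int = 0, seed=None
) -> pd.DataFrame:
    """Pairwise multilocus theta, G''ST and (optionally) permutation p-values."""
    idx = _group_indices(gm, groups)
    names = list(idx)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            pair = {names[i]: idx[names[i]], names[j]: idx[names[j]]}
            theta = wc_fst(gm, groups=pair).theta
            gpp = standardized_gst(gm, groups=pair)
            p = (
                permutation_differentiation_test(
                    gm, (names[i], names[j]), n_perm=n_perm, seed=seed,
                    groups=pair,
                )
                if n_perm else np.nan
            )
            rows.append(dict(group1=names[i], group2=names[j],
                             fst=theta, g_dprime_st=gpp, p_value=p))
    return pd.DataFrame(rows)


def permutation_differentiation_test(
    gm: GenotypeMatrix, pair, n_perm: int = 10000, alpha: float = 0.01,
    seed=None, groups=None,
) -> float:
    """Permutation analog of an exact differentiation test.

    The statistic is the pair's multilocus theta; the null permutes
    individuals between the two groups. p = (1 + #{theta_perm >= theta_obs})
    / (1 + n_perm).
    """
    idx = _group_indices(gm, groups if groups is not None else list(pair))
    if len(idx) != 2:
        raise ValueError("permutation test is pairwise")
    ia, ib = list(idx.values())
    pool = np.concatenate([ia, ib])
    na = len(ia)
    obs = wc_fst(gm, groups={"a": ia, "b": ib}).theta
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pool)
        t = wc_fst(gm, groups={"a": perm[:na], "b": perm[na:]}).theta
        if t >= obs:
            count += 1
    return (1 + count) / (1 + n_perm)
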