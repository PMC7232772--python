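"""Leave-one-out home-likelihood population assignment.

For each individual and each candidate group, the home likelihood L_h is the
HWE probability of the individual's multilocus genotype given the group's
allele frequencies; the focal individual is removed from its own group's
frequency estimates (leave-one-out) before computing. Allele frequencies of
zero are replaced by 0.005 (frequencies renormalized afterwards). Assignment
is to the argmax group; a Monte-Carlo null of genotypes simulated under HWE
from each group's frequencies provides a per-group significance threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

log = logging.getLogger(__name__)

__all__ = [
    "AssignmentResult", "home_likelihood", "leave_one_out_assign",
    "assignment_significance",
]

ZERO_FREQ_FLOOR = 0.005


@dataclass
class AssignmentResult:
    log_likelihoods: pd.DataFrame   # individuals x groups
    assigned: pd.Series             # argmax group per individual
    self_assignment: pd.Series      # per-group % of members assigned home
    confusion: pd.DataFrame         # home group x assigned group counts


def _floor_freqs(p: np.ndarray) -> np.ndarray:
    """Apply the zero-frequency floor, then renormalize each locus."""
    q = np.maximum(p, ZERO_FREQ_FLOOR)
    return q / q.sum(axis=-1, keepdims=True)


def home_likelihood(calls: np.ndarray, freqs: list[np.ndarray]) -> float:
    """log L_h of one individual's calls given per-locus allele frequencies.

    ``calls`` is (n_loci, 2) allele indices (-1 missing); ``freqs`` a list of
    per-locus frequency vectors. Missing loci are skipped; zero frequencies
    are floored at 0.005 (with renormalization) before the HWE product.
    """
    ll = 0.0
    for l, f in enumerate(freqs):
        a, b = calls[l]
        if a < 0:
            continue
        f = _floor_freqs(np.asarray(f, dtype=float))
        if a == b:
            ll += np.log(f[a] ** 2)
        else:
            ll += np.log(2.0 * f[a] * f[b])
    return float(ll)


def _biallelic_loglik_matrix(dos, groups_idx, loo=True):
    """(n_ind, n_groups) home log-likelihoods from dosages with NaN missing."""
    n, L = dos.shape
    names = list(groups_idx)
    out = np.full((n, len(names)), np.nan)
    member = np.full(n, -1)
    for gi, g in enumerate(names):
        member[groups_idx[g]] = gi
    # per-group alt counts and called-individual counts per locus
    alt = np.vstack([np.nansum(dos[groups_idx[g]], axis=0) for g in names])
    cnt = np.vstack([(~np.isnan(dos[groups_idx[g]])).sum(axis=0) for g in names])
    for i in range(n):
        di = dos[i]
        ok = ~np.isnan(di)
        for gi in range(len(names)):
            a = alt[gi].copy()
            c = cnt[gi].astype(float).copy()
            if loo and member[i] == gi:
                a = a - np.where(ok, di, 0.0)
                c = c - ok
            with np.errstate(invalid="ignore", divide="ignore"):
                p = a / (2.0 * c)
            usable = ok & (c > 0)
            if not usable.any():
                continue
            pf = np.stack([1.0 - p, p], axis=-1)
            pf = _floor_freqs(np.nan_to_num(pf, nan=0.5))
            q = pf[:, 1]
            d = di
            term = np.where(
                d == 1, np.log(2.0 * q * (1 - q)),
                np.where(d == 2, 2.0 * np.log(q), 2.0 * np.log(1 - q)),
            )
            out[i, gi] = term[usable].sum()
    return out, names, member


def leave_one_out_assign(gm: GenotypeMatrix, groups=None) -> AssignmentResult:
    """Assign each individual to its maximum-home-likelihood group.

    The individual's own genotype is removed from its home group's allele
    frequencies before evaluating. Individuals whose home group would be
    emptied by the leave-one-out step are excluded with a warning.
    """
    from .stats import _group_indices

    idx = _group_indices(gm, groups)
    singletons = [g for g, v in idx.items() if len(v) < 2]
    if singletons:
        log.warning("leave_one_out_assign: dropping singleton groups %s", singletons)
        drop = set()
        for g in singletons:
            drop.update(idx[g].tolist())
            del idx[g]
    dos = gm.dosage()
    ll, names, member = _biallelic_loglik_matrix(dos, idx)
    sub = np.concatenate(list(idx.values()))
    rows = np.sort(sub)
    ids = [gm.individual_ids[i] for i in rows]
    lldf = pd.DataFrame(ll[rows], index=ids, columns=names)
    assigned = lldf.idxmax(axis=1).rename("assigned")
    home = pd.Series(
        [names[member[i]] for i in rows], index=ids, name="home"
    )
    conf = pd.crosstab(home, assigned).reindex(
        index=names, columns=names, fill_value=0
    )
    self_rate = pd.Series(
        {g: 100.0 * conf.loc[g, g] / max(conf.loc[g].sum(), 1) for g in names},
        name="self_assignment_pct",
    )
    return AssignmentResult(lldf, assigned, self_rate, conf)


def assignment_significance(
    gm: GenotypeMatrix, groups=None, n_reps: int = 1000,
    alpha: float = 0.002, seed=None,
) -> pd.DataFrame:
    """Monte-Carlo home-likelihood significance per individual.

    For each group, ``n_reps`` genotypes are simulated under HWE from the
    group's allele frequencies and scored against those frequencies; an
    individual whose leave-one-out home log-likelihood falls below the
    ``alpha`` quantile of its group's null is flagged.
    """
    from .stats import _group_indices

    rng = np.random.default_rng(seed)
    idx = _group_indices(gm, groups)
    idx = {g: v for g, v in idx.items() if len(v) >= 2}
    dos = gm.dosage()
    ll, names, member = _biallelic_loglik_matrix(dos, idx)
    rows = []
    for gi, g in enumerate(names):
        gidx = idx[g]
        sub = dos[gidx]
        cnt = (~np.isnan(sub)).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.nansum(sub, axis=0) / (2.0 * cnt)
        usable = cnt > 0
        p = p[usable]
        pf = _floor_freqs(np.stack([1.0 - p, p], axis=-1))[:, 1]
        sim = rng.binomial(2, pf, size=(n_reps, len(pf)))
        term = np.where(
            sim == 1, np.log(2.0 * pf * (1 - pf)),
            np.where(sim == 2, 2.0 * np.log(pf), 2.0 * np.log(1 - pf)),
        )
        null = term.sum(axis=1)
        thresh = np.quantile(null, alpha)
        for i in gidx:
            rows.append(dict(
                individual=gm.individual_ids[i], group=g,
                log_lh=ll[i, gi], threshold=thresh,
                flagged=bool(ll[i, gi] < thresh),
            ))
    return pd.DataFrame(rows)
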