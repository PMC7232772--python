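"""Shared data model: genotype matrices, locus tables, read-depth matrices.

Genotype calls are stored as ordered allele-index pairs (``(n_individuals,
n_loci, 2)`` int16, ``-1`` marking a missing call), which accommodates both
bi-allelic SNP data (allele 0 = reference, 1 = alternate) and multi-allelic
microsatellite-style data. Bi-allelic convenience accessors expose the usual
0/1/2 alternate-allele dosage coding.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING = -1

_LOCUS_COLUMNS = ["locus_id", "tag_id", "alleles", "linkage_group", "cM"]


class LocusTable:
    """Per-locus annotation: ids, RAD tag, allele symbols, map position.

    Backed by a :class:`pandas.DataFrame` with at least the columns
    ``locus_id`` (unique strings), ``tag_id``, ``alleles`` (list of allele
    symbols per locus), ``linkage_group`` (string or ``None``) and ``cM``
    (non-negative float, ``NaN`` when unplaced). Extra columns (e.g. VCF
    ``chrom``/``pos``) are carried through untouched.
    """

    def __init__(self, df: pd.DataFrame):
        df = df.reset_index(drop=True).copy()
        for col in _LOCUS_COLUMNS:
            if col not in df.columns:
                if col == "alleles":
                    df[col] = [["0", "1"] for _ in range(len(df))]
                elif col == "cM":
                    df[col] = np.nan
                else:
                    df[col] = None
        if df["locus_id"].duplicated().any():
            dupes = df.loc[df["locus_id"].duplicated(), "locus_id"].tolist()
            raise ValueError(f"duplicate locus ids: {dupes[:5]}")
        cm = pd.to_numeric(df["cM"], errors="coerce")
        has_cm = cm.notna()
        has_lg = df["linkage_group"].notna()
        if (has_cm & ~has_lg).any():
            raise ValueError("cM position given for loci without a linkage group")
        if (cm.dropna() < 0).any():
            raise ValueError("negative cM positions")
        df["cM"] = cm
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def locus_ids(self) -> list[str]:
        return self.df["locus_id"].tolist()

    @property
    def linkage_groups(self) -> np.ndarray:
        return self.df["linkage_group"].to_numpy(dtype=object)

    @property
    def cm(self) -> np.ndarray:
        return self.df["cM"].to_numpy(dtype=float)

    @property
    def mapped(self) -> np.ndarray:
        """Boolean mask of loci with a linkage-group placement."""
        return self.df["linkage_group"].notna().to_numpy() & self.df["cM"].notna().to_numpy()

    def n_alleles(self) -> np.ndarray:
        return np.array([len(a) for a in self.df["alleles"]], dtype=int)

    def subset(self, idx: Sequence[int] | np.ndarray) -> "LocusTable":
        return LocusTable(self.df.iloc[np.asarray(idx)].reset_index(drop=True))

    @classmethod
    def simple(
        cls,
        locus_ids: Iterable[str],
        tag_ids: Iterable[str] | None = None,
        linkage_groups: Iterable | None = None,
        cm: Iterable[float] | None = None,
    ) -> "LocusTable":
        locus_ids = list(locus_ids)
        df = pd.DataFrame({"locus_id": locus_ids})
        df["tag_id"] = list(tag_ids) if tag_ids is not None else locus_ids
        df["alleles"] = [["0", "1"] for _ in locus_ids]
        df["linkage_group"] = list(linkage_groups) if linkage_groups is not None else None
        df["cM"] = list(cm) if cm is not None else np.nan
        return cls(df)


@dataclass
class DepthMatrix:
    """Per-call allele-specific read depths (reference reads, alternate reads)."""

    ref: np.ndarray
    alt: np.ndarray

    def __post_init__(self):
        self.ref = np.asarray(self.ref)
        self.alt = np.asarray(self.alt)
        if self.ref.shape != self.alt.shape:
            raise ValueError("ref/alt depth shapes differ")
        if (self.ref < 0).any() or (self.alt < 0).any():
            raise ValueError("negative read depths")

    @property
    def total(self) -> np.ndarray:
        return self.ref + self.alt

    def subset(self, ind_idx=None, locus_idx=None) -> "DepthMatrix":
        ref, alt = self.ref, self.alt
        if ind_idx is not None:
            ref, alt = ref[np.asarray(ind_idx)], alt[np.asarray(ind_idx)]
        if locus_idx is not None:
            ref, alt = ref[:, np.asarray(locus_idx)], alt[:, np.asarray(locus_idx)]
        return DepthMatrix(ref, alt)


@dataclass
class GenotypeMatrix:
    """Individuals x loci genotype calls with population labels.

    ``calls[i, l] = (a, b)`` holds the two allele indices of individual ``i``
    at locus ``l`` (unordered; missing calls are ``(-1, -1)``).
    """

    individual_ids: list[str]
    pop_labels: list[str]
    loci: LocusTable
    calls: np.ndarray
    ancestry: np.ndarray | None = field(default=None, repr=False)
    ancestry_pops: list[str] | None = field(default=None, repr=False)

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int16)
        n, l = len(self.individual_ids), len(self.loci)
        if self.calls.shape != (n, l, 2):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{n} individuals x {l} loci"
            )
        if len(self.pop_labels) != n:
            raise ValueError("one pop label per individual required")
        half_missing = (self.calls == MISSING).sum(axis=2) == 1
        if half_missing.any():
            raise ValueError("half-missing genotype calls")
        nall = self.loci.n_alleles()
        if (self.calls.max(axis=(0, 2)) >= nall).any():
            raise ValueError("allele index exceeds declared allele count")

    # -- basic geometry ----------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def missing_mask(self) -> np.ndarray:
        """(n_individuals, n_loci) boolean mask, True where the call is missing."""
        return self.calls[:, :, 0] == MISSING

    @property
    def is_biallelic(self) -> bool:
        return bool((self.loci.n_alleles() == 2).all())

    def pops(self) -> list[str]:
        """Distinct population labels in order of first appearance."""
        return list(dict.fromkeys(self.pop_labels))

    def pop_indices(self, pop: str) -> np.ndarray:
        lab = np.asarray(self.pop_labels, dtype=object)
        return np.flatnonzero(lab == pop)

    # -- bi-allelic dosage view -------------------------------------------
    def dosage(self) -> np.ndarray:
        """Alternate-allele dosage (0/1/2) as float with NaN for missing calls.

        Only defined for bi-allelic data.
        """
        if not self.is_biallelic:
            raise ValueError("dosage coding requires bi-allelic loci")
        d = self.calls.sum(axis=2).astype(float)
        d[self.missing_mask] = np.nan
        return d

    def het_mask(self) -> np.ndarray:
        """True where the call is heterozygous (missing -> False)."""
        return (self.calls[:, :, 0] != self.calls[:, :, 1]) & ~self.missing_mask

    def allele_counts(self, ind_idx: np.ndarray | None = None) -> list[np.ndarray]:
        """Per-locus observed allele-copy counts (list of length-k arrays)."""
        calls = self.calls if ind_idx is None else self.calls[np.asarray(ind_idx)]
        nall = self.loci.n_alleles()
        out = []
        for l in range(self.n_loci):
            c = calls[:, l, :].ravel()
            c = c[c >= 0]
            out.append(np.bincount(c, minlength=nall[l]).astype(float))
        return out

    # -- construction / slicing -------------------------------------------
    @classmethod
    def from_dosage(
        cls,
        dosage: np.ndarray,
        individual_ids: Sequence[str] | None = None,
        pop_labels: Sequence[str] | None = None,
        loci: LocusTable | None = None,
        **kw,
    ) -> "GenotypeMatrix":
        """Build a bi-allelic matrix from a 0/1/2 dosage array (NaN = missing)."""
        dosage = np.asarray(dosage, dtype=float)
        n, l = dosage.shape
        if individual_ids is None:
            individual_ids = [f"ind{i:05d}" for i in range(n)]
        if pop_labels is None:
            pop_labels = ["pop1"] * n
        if loci is None:
            loci = LocusTable.simple([f"loc{j:06d}" for j in range(l)])
        miss = np.isnan(dosage)
        d = np.nan_to_num(dosage).astype(np.int16)
        calls = np.empty((n, l, 2), dtype=np.int16)
        calls[:, :, 0] = (d == 2).astype(np.int16)
        calls[:, :, 1] = (d >= 1).astype(np.int16)
        calls[miss] = MISSING
        return cls(list(individual_ids), list(pop_labels), loci, calls, **kw)

    def subset(self, ind_idx=None, locus_idx=None) -> "GenotypeMatrix":
        gm = self
        ids, labels, calls = gm.individual_ids, gm.pop_labels, gm.calls
        anc = gm.ancestry
        if ind_idx is not None:
            ind_idx = np.asarray(ind_idx)
            ids = [ids[i] for i in ind_idx]
            labels = [labels[i] for i in ind_idx]
            calls = calls[ind_idx]
            anc = anc[ind_idx] if anc is not None else None
        loci = gm.loci
        if locus_idx is not None:
            locus_idx = np.asarray(locus_idx)
            calls = calls[:, locus_idx]
            loci = loci.subset(locus_idx)
        return GenotypeMatrix(
            list(ids), list(labels), loci, calls.copy(),
            ancestry=None if anc is None else anc.copy(),
            ancestry_pops=_copy.copy(gm.ancestry_pops),
        )

    def with_labels(self, labels: Sequence[str]) -> "GenotypeMatrix":
        return GenotypeMatrix(
            list(self.individual_ids), list(labels), self.loci, self.calls.copy(),
            ancestry=self.ancestry, ancestry_pops=self.ancestry_pops,
        )
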