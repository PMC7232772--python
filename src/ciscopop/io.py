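"""Readers and writers for VCF, genepop, linkage-map and metadata tables.

Conventions
-----------
* VCF is 1-based per the standard; internal locus indices are 0-based.
* The RAD tag id of a SNP is parsed from the VCF ID column as the prefix
  before a ``:`` separator (configurable regex); loci without an ID get a
  synthetic ``chrom_pos`` id that doubles as tag id.
* Genepop files are written with 3-digit alleles; both 2- and 3-digit
  dialects are accepted on read. ``00``/``000`` alleles mark missing data.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import MISSING, DepthMatrix, GenotypeMatrix, LocusTable

log = logging.getLogger(__name__)

DEFAULT_TAG_REGEX = r"^([^:]+)"


@dataclass
class ReadReport:
    """Tally of records read and skipped by a reader."""

    n_records: int = 0
    n_kept: int = 0
    skipped: dict = field(default_factory=dict)
    n_masked_calls: int = 0

    def skip(self, reason: str, n: int = 1) -> None:
        self.skipped[reason] = self.skipped.get(reason, 0) + n


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path, tag_regex: str = DEFAULT_TAG_REGEX):
    """Read SNP genotypes (and AD depths when present) from a VCF file.

    Returns ``(GenotypeMatrix, DepthMatrix | None, ReadReport)``. Non-SNP
    records (indels, multi-allelic sites) are skipped and counted.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    report = ReadReport()
    pat = re.compile(tag_regex)

    rows, gts, refs, alts = [], [], [], []
    has_ad = False
    for var in vcf:
        report.n_records += 1
        if not var.is_snp or len(var.ALT) != 1:
            report.skip("non_snp")
            continue
        g = np.array(var.genotypes, dtype=np.int16)[:, :2]
        g[g < 0] = MISSING
        # a half-called genotype is treated as missing
        half = (g == MISSING).any(axis=1)
        g[half] = MISSING
        gts.append(g)
        vid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}"
        m = pat.search(vid)
        tag = m.group(1) if m else vid
        rows.append(
            dict(locus_id=vid, tag_id=tag, alleles=[var.REF, var.ALT[0]],
                 linkage_group=None, cM=np.nan, chrom=var.CHROM, pos=var.POS,
                 ref=var.REF, alt=var.ALT[0])
        )
        try:
            ad = var.format("AD")
        except KeyError:
            ad = None
        if ad is not None:
            has_ad = True
            ad = np.asarray(ad, dtype=np.int64)
            ad[ad < 0] = 0
            refs.append(ad[:, 0])
            alts.append(ad[:, 1] if ad.shape[1] > 1 else np.zeros(len(samples), dtype=np.int64))
        else:
            refs.append(np.zeros(len(samples), dtype=np.int64))
            alts.append(np.zeros(len(samples), dtype=np.int64))
    report.n_kept = len(rows)
    if report.skipped:
        log.info("read_vcf: skipped records %s", report.skipped)
    if not rows:
        raise ValueError(f"no usable SNP records in {path}")
    calls = np.stack(gts, axis=1)  # (n_ind, n_loci, 2)
    report.n_masked_calls = int((calls[:, :, 0] == MISSING).sum())
    loci = LocusTable(pd.DataFrame(rows))
    gm = GenotypeMatrix(samples, ["unassigned"] * len(samples), loci, calls)
    depths = DepthMatrix(np.stack(refs, axis=1), np.stack(alts, axis=1)) if has_ad else None
    return gm, depths, report


def write_vcf(gm: GenotypeMatrix, path, depths: DepthMatrix | None = None) -> None:
    """Write a bi-allelic GenotypeMatrix as an uncompressed VCF 4.2 file."""
    if not gm.is_biallelic:
        raise ValueError("write_vcf supports bi-allelic data only")
    df = gm.loci.df
    chrom = df["chrom"] if "chrom" in df else pd.Series(["un"] * len(df))
    pos = df["pos"] if "pos" in df else pd.Series(np.arange(1, len(df) + 1))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if depths is not None:
            fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.individual_ids) + "\n")
        fmt = "GT:AD" if depths is not None else "GT"
        calls = gm.calls
        bases = {"A", "C", "G", "T"}
        for l in range(gm.n_loci):
            alleles = df["alleles"].iloc[l]
            ref = str(df["ref"].iloc[l] if "ref" in df else alleles[0])
            alt = str(df["alt"].iloc[l] if "alt" in df else alleles[1])
            if ref not in bases or alt not in bases:
                ref, alt = "A", "C"      # symbolic alleles -> placeholder bases
            fields = [str(chrom.iloc[l] or "un"), str(int(pos.iloc[l])),
                      df["locus_id"].iloc[l], ref, alt, ".", "PASS", ".", fmt]
            for i in range(gm.n_individuals):
                a, b = calls[i, l]
                gt = "./." if a == MISSING else f"{a}/{b}"
                if depths is not None:
                    gt += f":{depths.ref[i, l]},{depths.alt[i, l]}"
                fields.append(gt)
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# genepop
# ---------------------------------------------------------------------------

def read_genepop(path):
    """Read a genepop file (2- or 3-digit alleles) into a GenotypeMatrix.

    Population labels are ``pop1..popN`` in POP-block order; the customary
    convention of naming a population after its last individual's id prefix
    is not assumed. Returns ``(GenotypeMatrix, ReadReport)``.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines:
        raise ValueError("empty genepop file")
    # line 1 = title; locus names follow, either one per line or comma-separated
    locus_names: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        part = [x.strip() for x in lines[i].split(",") if x.strip()]
        locus_names.extend(part)
        i += 1
    if i == len(lines):
        raise ValueError("genepop file has no POP block")
    n_loci = len(locus_names)
    report = ReadReport()

    ind_ids: list[str] = []
    pop_labels: list[str] = []
    raw_calls: list[list[str]] = []
    pop_no = 0
    while i < len(lines):
        if lines[i].strip().lower() == "pop":
            pop_no += 1
            i += 1
            continue
        line = lines[i].strip()
        i += 1
        if not line:
            continue
        if "," not in line:
            raise ValueError(f"genepop line {i}: missing ',' separator: {line!r}")
        name, geno = line.split(",", 1)
        toks = geno.split()
        if len(toks) != n_loci:
            raise ValueError(
                f"genepop line {i}: expected {n_loci} loci, found {len(toks)}"
            )
        ind_ids.append(name.strip())
        pop_labels.append(f"pop{pop_no}")
        raw_calls.append(toks)
        report.n_records += 1

    # determine allele width per file (4 or 6 digit genotypes)
    widths = {len(t) for row in raw_calls for t in row}
    if not widths <= {4, 6}:
        raise ValueError(f"unrecognized genepop genotype widths: {sorted(widths)}")
    if len(widths) > 1:
        raise ValueError("mixed 2- and 3-digit genotypes in one file")
    w = widths.pop() // 2

    n_ind = len(ind_ids)
    allele_syms: list[list[str]] = [[] for _ in range(n_loci)]
    calls = np.full((n_ind, n_loci, 2), MISSING, dtype=np.int16)
    for l in range(n_loci):
        seen: dict[str, int] = {}
        for ii in range(n_ind):
            tok = raw_calls[ii][l]
            a, b = tok[:w], tok[w:]
            pair = []
            for s in (a, b):
                if int(s) == 0:
                    pair = None
                    break
                if s not in seen:
                    seen[s] = len(seen)
                pair.append(seen[s])
            if pair is None:
                report.n_masked_calls += 1
                continue
            calls[ii, l] = sorted(pair)
        # stable allele order: sort symbols numerically, remap indices
        order = sorted(seen, key=lambda s: int(s))
        remap = np.full(max(len(seen), 1), 0, dtype=np.int16)
        for sym, old in seen.items():
            remap[old] = order.index(sym)
        ok = calls[:, l, 0] >= 0
        calls[ok, l, 0] = remap[calls[ok, l, 0]]
        calls[ok, l, 1] = remap[calls[ok, l, 1]]
        calls[ok, l] = np.sort(calls[ok, l], axis=1)
        allele_syms[l] = order if order else ["001", "002"]

    df = pd.DataFrame({"locus_id": locus_names})
    df["tag_id"] = locus_names
    df["alleles"] = allele_syms
    loci = LocusTable(df)
    gm = GenotypeMatrix(ind_ids, pop_labels, loci, calls)
    report.n_kept = n_ind
    return gm, report


def write_genepop(gm: GenotypeMatrix, path, title: str = "ciscopop export") -> None:
    """Write a GenotypeMatrix as a 3-digit genepop file (one POP block per label)."""
    df = gm.loci.df
    sym_tables = []
    for al in df["alleles"]:
        syms = [str(s) for s in al]
        if all(s.isdigit() and 1 <= int(s) <= 999 for s in syms) and len(set(syms)) == len(syms):
            sym_tables.append([f"{int(s):03d}" for s in syms])
        else:
            sym_tables.append([f"{k + 1:03d}" for k in range(len(syms))])
    with open(path, "w") as fh:
        fh.write(title + "\n")
        fh.write("\n".join(gm.loci.locus_ids) + "\n")
        for pop in gm.pops():
            fh.write("pop\n")
            for i in gm.pop_indices(pop):
                toks = []
                for l in range(gm.n_loci):
                    a, b = gm.calls[i, l]
                    if a == MISSING:
                        toks.append("000000")
                    else:
                        toks.append(sym_tables[l][a] + sym_tables[l][b])
                fh.write(f"{gm.individual_ids[i]} ,  " + " ".join(toks) + "\n")


# ---------------------------------------------------------------------------
# map / metadata tables
# ---------------------------------------------------------------------------

def read_map(path) -> pd.DataFrame:
    """Read a tab-separated linkage-map table (locus_id, linkage_group, cM)."""
    df = pd.read_csv(path, sep="\t", dtype={"locus_id": str, "linkage_group": str})
    missing = {"locus_id", "linkage_group", "cM"} - set(df.columns)
    if missing:
        raise ValueError(f"map table lacks columns: {sorted(missing)}")
    df["cM"] = pd.to_numeric(df["cM"], errors="coerce")
    df.loc[df["linkage_group"].isin(["", "NA", "nan"]), "linkage_group"] = None
    df.loc[df["linkage_group"].isna(), "cM"] = np.nan
    return df


def write_map(loci: LocusTable, path) -> None:
    loci.df[["locus_id", "linkage_group", "cM"]].to_csv(path, sep="\t", index=False)


def attach_map(gm: GenotypeMatrix, map_df: pd.DataFrame) -> GenotypeMatrix:
    """Attach linkage-group / cM positions to a GenotypeMatrix's loci.

    Loci absent from the map keep unknown placement.
    """
    df = gm.loci.df.drop(columns=["linkage_group", "cM"]).merge(
        map_df[["locus_id", "linkage_group", "cM"]], on="locus_id", how="left"
    )
    df["linkage_group"] = df["linkage_group"].where(df["linkage_group"].notna(), None)
    out = GenotypeMatrix(
        list(gm.individual_ids), list(gm.pop_labels), LocusTable(df), gm.calls.copy(),
        ancestry=gm.ancestry, ancestry_pops=gm.ancestry_pops,
    )
    return out


def read_metadata(path) -> pd.DataFrame:
    """Read a tab-separated sample table (individual_id, form)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"individual_id", "form"} - set(df.columns)
    if missing:
        raise ValueError(f"metadata lacks columns: {sorted(missing)}")
    return df


def attach_metadata(gm: GenotypeMatrix, meta: pd.DataFrame) -> GenotypeMatrix:
    """Assign population labels from a metadata table.

    An individual in the metadata that is absent from the genotype matrix is
    a hard error; matrix individuals without metadata keep their label.
    """
    known = set(gm.individual_ids)
    unknown = [i for i in meta["individual_id"] if i not in known]
    if unknown:
        raise ValueError(f"metadata names unknown individuals: {unknown[:5]}")
    lut = dict(zip(meta["individual_id"], meta["form"]))
    labels = [lut.get(i, lab) for i, lab in zip(gm.individual_ids, gm.pop_labels)]
    n_unlabelled = sum(1 for i in gm.individual_ids if i not in lut)
    if n_unlabelled:
        log.warning("attach_metadata: %d individuals without metadata", n_unlabelled)
    return gm.with_labels(labels)
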