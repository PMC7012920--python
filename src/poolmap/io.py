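"""Readers and writers for the pipeline's on-disk formats.

All tab-separated tables carry a single header line beginning with ``#``.
The minimal VCF writer emits v4.2 records with GT for the two parent
samples and AD for the two pool samples, so synthetic output can exercise
the same real-data entry points (parental variant filtering, pool allele
depths) as user-supplied calls.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .popsim import MarkerSet, F2Population

__all__ = [
    "write_tsv",
    "read_tsv",
    "write_marker_map",
    "read_marker_map",
    "write_genotypes",
    "write_phenotypes",
    "write_depth_table",
    "read_depth_table",
    "write_windows_bed",
    "write_vcf",
    "read_pool_depths_from_vcf",
    "filter_parent_variants",
]


# ---------------------------------------------------------------------------
# Generic hash-header TSVs
# ---------------------------------------------------------------------------

def write_tsv(df: pd.DataFrame, path) -> None:
    """Write a DataFrame as TSV with a single '#'-prefixed header line."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("#" + "\t".join(map(str, df.columns)) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False)


def read_tsv(path) -> pd.DataFrame:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith("#"):
            raise ValueError(f"{path}: expected '#'-prefixed header line")
        names = header.lstrip("#").split("\t")
        return pd.read_csv(fh, sep="\t", names=names)


def write_marker_map(marker_set: MarkerSet, path) -> None:
    write_tsv(marker_set.markers, path)


def read_marker_map(path, chrom_lengths: dict[str, int] | None = None) -> MarkerSet:
    markers = read_tsv(path)
    if chrom_lengths is None:
        chrom_lengths = {
            c: int(p) for c, p in markers.groupby("chrom", sort=False)["pos"].max().items()
        }
    return MarkerSet(tuple(chrom_lengths.items()), markers)


def write_genotypes(pop: F2Population, path) -> None:
    """Genotype matrix TSV: one row per marker, one column per individual,
    codes 0/1/2 for AA/AB/BB."""
    df = pd.DataFrame(
        pop.genotypes.T,
        columns=[f"ind{i:04d}" for i in range(pop.n_individuals)],
    )
    df.insert(0, "chrom", pop.marker_set.markers["chrom"].to_numpy())
    df.insert(1, "pos", pop.marker_set.markers["pos"].to_numpy())
    write_tsv(df, path)


def write_phenotypes(pop: F2Population, path) -> None:
    if pop.phenotypes is None:
        raise ValueError("phenotypes not assigned")
    df = pd.DataFrame(
        {
            "individual": [f"ind{i:04d}" for i in range(pop.n_individuals)],
            "phenotype": pop.phenotypes,
        }
    )
    write_tsv(df, path)


def write_depth_table(depths: pd.DataFrame, path) -> None:
    write_tsv(depths[["chrom", "pos", "pool", "count_a", "count_b"]], path)


def read_depth_table(path) -> pd.DataFrame:
    df = read_tsv(path)
    missing = {"chrom", "pos", "pool", "count_a", "count_b"} - set(df.columns)
    if missing:
        raise ValueError(f"depth table missing columns: {sorted(missing)}")
    return df


def write_windows_bed(windows: pd.DataFrame, path) -> None:
    """Window statistics as a BED-compatible TSV (0-based half-open
    chrom/start/end first, statistics after)."""
    out = windows.copy()
    out.insert(0, "chromStart", out.pop("start") - 1)
    out.insert(0, "chrom_", out.pop("chrom"))
    out.insert(2, "chromEnd", out.pop("end"))
    out = out.rename(columns={"chrom_": "chrom"})
    write_tsv(out, path)


# ---------------------------------------------------------------------------
# Minimal VCF
# ---------------------------------------------------------------------------

def write_vcf(
    marker_set: MarkerSet,
    depth_high: pd.DataFrame,
    depth_low: pd.DataFrame,
    path,
    parent_a: str = "parentA",
    parent_b: str = "parentB",
    qual: float = 60.0,
    parent_depth: int = 20,
) -> None:
    """Minimal VCF v4.2: parent GT columns (0/0 and 1/1 with per-sample DP)
    plus pool AD columns, REF = parent A's allele, ALT = parent B's."""
    path = Path(path)
    hi = depth_high.set_index(["chrom", "pos"])
    lo = depth_low.set_index(["chrom", "pos"])
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n'
        )
        for name, length in marker_set.chromosomes:
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            f"{parent_a}\t{parent_b}\tpool_high\tpool_low\n"
        )
        for row in marker_set.markers.itertuples(index=False):
            key = (row.chrom, row.pos)
            h = hi.loc[key]
            l = lo.loc[key]
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{row.allele_a}\t{row.allele_b}\t"
                f"{qual:g}\t.\t.\tGT:DP:AD\t"
                f"0/0:{parent_depth}:{parent_depth},0\t"
                f"1/1:{parent_depth}:0,{parent_depth}\t"
                f"./.:{int(h.count_a + h.count_b)}:{int(h.count_a)},{int(h.count_b)}\t"
                f"./.:{int(l.count_a + l.count_b)}:{int(l.count_a)},{int(l.count_b)}\n"
            )


def read_pool_depths_from_vcf(
    path, pool_high: str = "pool_high", pool_low: str = "pool_low"
) -> pd.DataFrame:
    """Long-format allele-depth table from the AD fields of two pool
    samples; REF counts map to parent A, ALT to parent B."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    for sample in (pool_high, pool_low):
        if sample not in vcf.samples:
            raise ValueError(f"sample {sample!r} missing from VCF (has {vcf.samples})")
    i_hi = vcf.samples.index(pool_high)
    i_lo = vcf.samples.index(pool_low)
    rows = []
    for rec in vcf:
        ad = rec.format("AD")
        if ad is None:
            continue
        for label, i in (("high", i_hi), ("low", i_lo)):
            rows.append(
                (rec.CHROM, rec.POS, label, int(ad[i][0]), int(ad[i][1]))
            )
    vcf.close()
    return pd.DataFrame(rows, columns=["chrom", "pos", "pool", "count_a", "count_b"])


def filter_parent_variants(
    path,
    parent_a: str = "parentA",
    parent_b: str = "parentB",
    min_qual: float = 10.0,
    min_depth: int = 5,
) -> pd.DataFrame:
    """Parental variant filtering for the real-data entry point.

    Flags (and drops from the retained set) records that are low quality
    (QUAL < ``min_qual``), low depth in either parent (DP < ``min_depth``,
    applied per parent sample), multi-allelic, heterozygous or missing in
    either parent, or monomorphic between the parents.  Retained sites are
    biallelic, homozygous in both parents, and polymorphic between them.

    Returns a DataFrame with one row per input record, per-rule boolean
    flags, and a ``retained`` column.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    for sample in (parent_a, parent_b):
        if sample not in vcf.samples:
            raise ValueError(f"parent sample {sample!r} missing from VCF")
    i_a = vcf.samples.index(parent_a)
    i_b = vcf.samples.index(parent_b)
    rows = []
    for rec in vcf:
        gts = rec.genotypes  # [allele1, allele2, phased]
        dp = rec.format("DP")
        dp_a = int(dp[i_a][0]) if dp is not None else 0
        dp_b = int(dp[i_b][0]) if dp is not None else 0
        g_a, g_b = gts[i_a][:2], gts[i_b][:2]
        low_qual = rec.QUAL is None or rec.QUAL < min_qual
        low_depth = dp_a < min_depth or dp_b < min_depth
        multi_allelic = len(rec.ALT) != 1
        het = (
            -1 in g_a or -1 in g_b or g_a[0] != g_a[1] or g_b[0] != g_b[1]
        )
        monomorphic = (not het) and g_a[0] == g_b[0]
        rows.append(
            {
                "chrom": rec.CHROM,
                "pos": rec.POS,
                "ref": rec.REF,
                "alt": ",".join(rec.ALT),
                "qual": rec.QUAL,
                "dp_a": dp_a,
                "dp_b": dp_b,
                "gt_a": "/".join(map(str, g_a)),
                "gt_b": "/".join(map(str, g_b)),
                "fail_qual": low_qual,
                "fail_depth": low_depth,
                "fail_multiallelic": multi_allelic,
                "fail_het": het,
                "fail_monomorphic": monomorphic,
                "retained": not (
                    low_qual or low_depth or multi_allelic or het or monomorphic
                ),
            }
        )
    vcf.close()
    return pd.DataFrame(rows)
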