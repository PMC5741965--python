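"""Text I/O dialects: BED (0-based half-open), TSV, JSON, minimal VCF writing.

VCF *parsing* lives in :mod:`hvrkit.ssv` (cyvcf2-backed); this module owns the
plain-text writers so that identical inputs always produce byte-identical
files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from hvrkit.layout import GenomeLayout

BED3 = ["chrom", "start", "end"]


def read_bed(path: str | Path, extra_cols: Sequence[str] = ()) -> pd.DataFrame:
    """Read a headerless BED file into chrom/start/end (+ named extras)."""
    names = BED3 + list(extra_cols)
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    except pd.errors.EmptyDataError:
        return pd.DataFrame({
            c: pd.Series(dtype="int64" if c in ("start", "end") else "object")
            for c in names})
    if df.shape[1] < 3:
        raise ValueError(f"{path}: BED needs >= 3 columns, found {df.shape[1]}")
    df = df.iloc[:, :len(names)]
    df.columns = names[:df.shape[1]]
    df["start"] = df["start"].astype("int64")
    df["end"] = df["end"].astype("int64")
    for col in names[df.shape[1]:]:
        df[col] = None
    return df


def write_bed(df: pd.DataFrame, path: str | Path, extra_cols: Sequence[str] = ()) -> None:
    cols = BED3 + [c for c in extra_cols if c in df.columns]
    df.to_csv(path, sep="\t", header=False, index=False, columns=cols)


def read_tsv(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        return pd.DataFrame()


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_vcf(
    df: pd.DataFrame,
    layout: GenomeLayout,
    sample: str,
    path: str | Path,
) -> None:
    """Write a minimal single-sample VCF.

    ``df`` columns: chrom, pos (1-based), ref, alt, zygosity ('hom'|'het').
    Heterozygous rows are written 0/1 (ref + alt allele) unless an ``alt2``
    column provides a second non-reference allele (written 1/2).
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=hvrkit\n")
        for chrom in layout:
            fh.write(f"##contig=<ID={chrom},length={layout[chrom]}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        has_alt2 = "alt2" in df.columns
        for row in df.itertuples(index=False):
            if row.zygosity == "hom":
                alt_field, gt = row.alt, "1/1"
            elif has_alt2 and isinstance(row.alt2, str) and row.alt2:
                alt_field, gt = f"{row.alt},{row.alt2}", "1/2"
            else:
                alt_field, gt = row.alt, "0/1"
            fh.write(f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{alt_field}\t.\tPASS\t.\tGT\t{gt}\n")
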