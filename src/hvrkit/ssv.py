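"""Strain-specific variant (SSV) calling.

An SSV for a query strain is a genomic position carrying at least one called
allele absent from the comparison baseline: the reference allele alone
(query-vs-reference) or the union of the reference allele and the control
strain's called alleles at that position (query-vs-control). Heterozygous
calls are retained; only single-nucleotide ACGT alleles are considered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

from hvrkit.layout import GenomeLayout

logger = logging.getLogger(__name__)

_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class VariantRecord:
    """A single-sample variant call at a 1-based position."""

    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alleles: frozenset[str]  # called alleles (may include ref for het calls)
    zygosity: str  # 'hom' | 'het'

    def __post_init__(self):
        if not self.alleles:
            raise ValueError(f"{self.chrom}:{self.pos}: empty allele set")
        if self.zygosity not in ("hom", "het"):
            raise ValueError(f"invalid zygosity {self.zygosity!r}")

    @property
    def is_snv(self) -> bool:
        return self.ref in _BASES and all(a in _BASES for a in self.alleles)


@dataclass
class SSVSet:
    """Strain-specific variant positions for one comparison.

    ``df`` columns: chrom, pos (0-based), novel (comma-joined novel alleles),
    zygosity.
    """

    label: str
    df: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["chrom", "pos", "novel", "zygosity"]))

    def __len__(self) -> int:
        return len(self.df)

    def positions(self) -> set[tuple[str, int]]:
        return set(zip(self.df["chrom"], self.df["pos"]))

    def to_bed(self, path: str | Path) -> None:
        out = pd.DataFrame({
            "chrom": self.df["chrom"],
            "start": self.df["pos"],
            "end": self.df["pos"] + 1,
            "novel": self.df["novel"],
            "zygosity": self.df["zygosity"],
        })
        out.to_csv(path, sep="\t", header=False, index=False)

    @classmethod
    def from_bed(cls, path: str | Path, label: str) -> "SSVSet":
        try:
            raw = pd.read_csv(
                path, sep="\t", header=None,
                names=["chrom", "start", "end", "novel", "zygosity"],
                dtype={"chrom": str})
        except pd.errors.EmptyDataError:
            return cls(label)
        df = pd.DataFrame({
            "chrom": raw["chrom"],
            "pos": raw["start"].astype("int64"),
            "novel": raw["novel"],
            "zygosity": raw["zygosity"],
        })
        return cls(label, df)


def read_variants(path: str | Path, layout: GenomeLayout | None = None) -> list[VariantRecord]:
    """Load single-sample SNV records from a VCF via cyvcf2.

    Non-SNV records (indels, non-ACGT alleles) are skipped with a counted
    warning; records whose contig is absent from ``layout`` raise.
    """
    from cyvcf2 import VCF

    records: list[VariantRecord] = []
    n_skipped = 0
    for v in VCF(str(path)):
        if layout is not None:
            if v.CHROM not in layout:
                raise ValueError(f"{path}: contig {v.CHROM!r} absent from genome layout")
            if not (1 <= v.POS <= layout[v.CHROM]):
                raise ValueError(f"{path}: position {v.CHROM}:{v.POS} beyond chromosome end")
        site_alleles = [v.REF] + list(v.ALT)
        gt = v.genotypes[0]
        called_idx = [i for i in gt[:-1] if i is not None and i >= 0]
        if not called_idx:
            n_skipped += 1
            continue
        called = frozenset(site_alleles[i] for i in called_idx)
        rec = VariantRecord(
            chrom=v.CHROM, pos=v.POS, ref=v.REF, alleles=called,
            zygosity="hom" if len(set(called_idx)) == 1 else "het",
        )
        if not rec.is_snv:
            n_skipped += 1
            continue
        records.append(rec)
    if n_skipped:
        logger.warning("%s: skipped %d non-SNV/uncalled records", path, n_skipped)
    return records


def _check_sorted(records: Iterable[VariantRecord]) -> Iterable[VariantRecord]:
    seen_chroms: list[str] = []
    last_pos = None
    for rec in records:
        if not seen_chroms or rec.chrom != seen_chroms[-1]:
            if rec.chrom in seen_chroms:
                raise ValueError(f"unsorted input: chromosome {rec.chrom} interleaved")
            seen_chroms.append(rec.chrom)
            last_pos = 0
        if rec.pos < last_pos:
            raise ValueError(f"unsorted input at {rec.chrom}:{rec.pos}")
        last_pos = rec.pos
        yield rec


def _build_ssvset(label: str, rows: list[tuple[str, int, str, str]]) -> SSVSet:
    df = pd.DataFrame(rows, columns=["chrom", "pos", "novel", "zygosity"])
    return SSVSet(label, df)


def call_ssvs_vs_reference(query: Iterable[VariantRecord], label: str = "query_vs_ref") -> SSVSet:
    """SSV at every position where the query carries an allele != reference."""
    rows = []
    n_ref_only = 0
    for rec in _check_sorted(query):
        novel = sorted(rec.alleles - {rec.ref})
        if novel:
            rows.append((rec.chrom, rec.pos - 1, ",".join(novel), rec.zygosity))
        else:
            n_ref_only += 1
    if n_ref_only:
        logger.info("%s: %d records carried only the reference allele", label, n_ref_only)
    return _build_ssvset(label, rows)


def call_ssvs_vs_control(
    query: Iterable[VariantRecord],
    control: Iterable[VariantRecord],
    label: str = "query_vs_control",
) -> SSVSet:
    """SSV at positions where the query carries an allele absent from both the
    reference and the control strain's called alleles.

    A position with no control record implies the control is homozygous
    reference there (baseline = reference allele only).
    """
    control_map: dict[tuple[str, int], VariantRecord] = {}
    for rec in _check_sorted(control):
        control_map[(rec.chrom, rec.pos)] = rec

    rows = []
    for rec in _check_sorted(query):
        baseline = {rec.ref}
        ctl = control_map.get((rec.chrom, rec.pos))
        if ctl is not None:
            if ctl.ref != rec.ref:
                raise ValueError(
                    f"conflicting reference allele at {rec.chrom}:{rec.pos}: "
                    f"query says {rec.ref!r}, control says {ctl.ref!r}")
            baseline |= ctl.alleles
        novel = sorted(rec.alleles - baseline)
        if novel:
            rows.append((rec.chrom, rec.pos - 1, ",".join(novel), rec.zygosity))
    return _build_ssvset(label, rows)
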