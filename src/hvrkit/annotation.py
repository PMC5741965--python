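"""Gene-level interpretation of SSVs in prioritised HVR subsets.

Covers expressed-gene filtering (FPKM strictly > 1), strand-aware one-to-one
promoter assignment (TSS inside the promoter or within 5 kb downstream of
it), a codon-table consequence classifier for coding SNVs, one-to-one
orthologue mapping and Fisher's exact disease/term enrichment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from scipy.stats import fisher_exact

from hvrkit.intervals import points_in_any
from hvrkit.ssv import SSVSet

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Consequence terms by decreasing severity; stop terms rank equal-highest.
SEVERITY = {
    "stop_gained": 3,
    "stop_lost": 3,
    "missense_variant": 2,
    "synonymous_variant": 1,
    "non_coding": 0,
}


def translate_codon(codon: str) -> str:
    """Single-codon translation under the standard code ('*' for stops)."""
    codon = codon.upper()
    if codon in standard_dna_table.stop_codons:
        return "*"
    return standard_dna_table.forward_table[codon]


@dataclass
class Transcript:
    transcript_id: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]  # genomic, ascending, half-open
    cds_seq: str  # translation order (mRNA sense)

    def __post_init__(self):
        total = sum(e - s for s, e in self.cds)
        if total % 3 != 0:
            raise ValueError(f"{self.transcript_id}: CDS length {total} not divisible by 3")
        if len(self.cds_seq) != total:
            raise ValueError(f"{self.transcript_id}: cds_seq length mismatch")
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise ValueError(f"{self.transcript_id}: overlapping/unsorted exons")


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str  # '+' | '-'
    tss: int  # 0-based position
    start: int
    end: int
    transcripts: list[Transcript] = field(default_factory=list)

    def cds_position(self, transcript: Transcript, pos: int) -> int | None:
        """Map a 0-based genomic position to a transcript CDS offset, or None."""
        offset = 0
        for s, e in transcript.cds:
            if s <= pos < e:
                ascending = offset + (pos - s)
                if self.strand == "+":
                    return ascending
                total = sum(ce - cs for cs, ce in transcript.cds)
                return total - 1 - ascending
            offset += e - s
        return None


def _parse_interval_list(text: str) -> list[tuple[int, int]]:
    if not isinstance(text, str) or not text:
        return []
    out = []
    for part in text.split(";"):
        s, e = part.split("-")
        out.append((int(s), int(e)))
    return out


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Load the gene-model TSV (one transcript per row, grouped by gene_id)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    genes: dict[str, GeneModel] = {}
    for row in df.itertuples(index=False):
        if row.gene_id not in genes:
            genes[row.gene_id] = GeneModel(
                gene_id=row.gene_id, chrom=row.chrom, strand=row.strand,
                tss=int(row.tss), start=int(row.start), end=int(row.end))
        genes[row.gene_id].transcripts.append(Transcript(
            transcript_id=row.transcript_id,
            exons=_parse_interval_list(row.exons),
            cds=_parse_interval_list(row.cds),
            cds_seq=row.cds_seq,
        ))
    return list(genes.values())


def write_gene_models(genes: Iterable[GeneModel], path: str | Path) -> None:
    rows = []
    for g in genes:
        for t in g.transcripts:
            rows.append({
                "gene_id": g.gene_id, "chrom": g.chrom, "strand": g.strand,
                "tss": g.tss, "start": g.start, "end": g.end,
                "transcript_id": t.transcript_id,
                "exons": ";".join(f"{s}-{e}" for s, e in t.exons),
                "cds": ";".join(f"{s}-{e}" for s, e in t.cds),
                "cds_seq": t.cds_seq,
            })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Expression

def expressed_genes(expression: pd.DataFrame, fpkm_min: float = 1.0) -> set[str]:
    """Genes with FPKM strictly greater than ``fpkm_min``."""
    if len(expression) == 0:
        return set()
    return set(expression.loc[expression["fpkm"] > fpkm_min, "gene_id"])


# ---------------------------------------------------------------------------
# Promoter assignment

def assign_promoters(
    promoters: pd.DataFrame,
    genes: pd.DataFrame,
    max_downstream: int = 5000,
    stranded: bool = True,
) -> pd.DataFrame:
    """One-to-one promoter-gene assignment.

    A candidate pair exists iff the gene's TSS lies inside the promoter
    interval, or within ``max_downstream`` bp past the promoter's 3' end in
    the gene's orientation (for '+': ``end <= tss < end + max_downstream``;
    mirrored for '-'). Candidate pairs involving a promoter or a gene with
    more than one candidate are dropped entirely.

    ``promoters``: chrom, start, end, promoter_id. ``genes``: gene_id, chrom,
    strand, tss. Returns promoter_id, gene_id, distance_class.
    """
    if len(promoters) and (promoters["start"] >= promoters["end"]).any():
        raise ValueError("zero-length promoter")
    pairs = []
    for chrom, proms in promoters.groupby("chrom", sort=False):
        sub_genes = genes[genes["chrom"] == chrom]
        if len(sub_genes) == 0:
            continue
        for prom in proms.itertuples(index=False):
            for gene in sub_genes.itertuples(index=False):
                tss = int(gene.tss)
                if prom.start <= tss < prom.end:
                    pairs.append((prom.promoter_id, gene.gene_id, "overlap"))
                    continue
                if stranded:
                    if gene.strand == "+":
                        hit = prom.end <= tss < prom.end + max_downstream
                    else:
                        hit = prom.start - max_downstream <= tss < prom.start
                else:
                    hit = (prom.end <= tss < prom.end + max_downstream
                           or prom.start - max_downstream <= tss < prom.start)
                if hit:
                    pairs.append((prom.promoter_id, gene.gene_id, "downstream"))
    df = pd.DataFrame(pairs, columns=["promoter_id", "gene_id", "distance_class"])
    # one-to-one: drop every pair whose promoter or gene is ambiguous
    prom_counts = df["promoter_id"].value_counts()
    gene_counts = df["gene_id"].value_counts()
    keep = df["promoter_id"].map(prom_counts).eq(1) & df["gene_id"].map(gene_counts).eq(1)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("promoter assignment: dropped %d ambiguous candidate pairs", dropped)
    return df[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Consequence classification

def classify_consequence(
    chrom: str,
    pos: int,  # 0-based
    alt: str,
    genes: Sequence[GeneModel],
    ref: str | None = None,
) -> dict:
    """Most severe coding consequence of a SNV across all transcripts.

    ``alt`` is the novel allele on the genome forward strand. When ``ref`` is
    given it is checked against the transcript CDS sequence. Returns a dict
    with ``term``, ``gene_id`` and per-transcript calls.
    """
    calls = []
    for gene in genes:
        if gene.chrom != chrom:
            continue
        for t in gene.transcripts:
            cds_pos = gene.cds_position(t, pos)
            if cds_pos is None:
                continue
            sense_alt = alt if gene.strand == "+" else alt.translate(_COMPLEMENT)
            sense_ref = t.cds_seq[cds_pos]
            if ref is not None:
                expect = ref if gene.strand == "+" else ref.translate(_COMPLEMENT)
                if expect != sense_ref:
                    raise ValueError(
                        f"{chrom}:{pos}: reference {ref!r} disagrees with CDS of "
                        f"{t.transcript_id} ({sense_ref!r} on sense strand)")
            if sense_alt == sense_ref:
                logger.info("%s:%d: variant allele equals reference, no-op", chrom, pos)
                continue
            codon_idx = cds_pos // 3
            within = cds_pos % 3
            codon = t.cds_seq[codon_idx * 3: codon_idx * 3 + 3]
            alt_codon = codon[:within] + sense_alt + codon[within + 1:]
            aa_ref, aa_alt = translate_codon(codon), translate_codon(alt_codon)
            if aa_ref == aa_alt:
                term = "synonymous_variant"
            elif aa_alt == "*":
                term = "stop_gained"
            elif aa_ref == "*":
                term = "stop_lost"
            else:
                term = "missense_variant"
            calls.append({"gene_id": gene.gene_id, "transcript_id": t.transcript_id,
                          "term": term})
    if not calls:
        return {"term": "non_coding", "gene_id": None, "calls": []}
    best = max(calls, key=lambda c: SEVERITY[c["term"]])
    return {"term": best["term"], "gene_id": best["gene_id"], "calls": calls}


def classify_ssvs(ssvs: SSVSet, genes: Sequence[GeneModel]) -> pd.DataFrame:
    """Most severe consequence per SSV (first novel allele per position)."""
    rows = []
    for row in ssvs.df.itertuples(index=False):
        alt = str(row.novel).split(",")[0]
        call = classify_consequence(row.chrom, int(row.pos), alt, genes)
        rows.append((row.chrom, int(row.pos), alt, call["term"], call["gene_id"]))
    return pd.DataFrame(rows, columns=["chrom", "pos", "alt", "term", "gene_id"])


# ---------------------------------------------------------------------------
# Candidate gene selection

def select_candidate_genes(
    subset_hvrs: pd.DataFrame,
    ssvs: SSVSet,
    genes: Sequence[GeneModel],
    promoter_assignments: pd.DataFrame,
    promoters: pd.DataFrame,
    expressed: set[str],
) -> dict:
    """Two candidate gene lists from a prioritised HVR subset.

    1. Expressed genes with >= 1 NSC-SSV (most severe consequence) inside a
       subset HVR. 2. Expressed genes whose one-to-one promoter carries >= 1
       SSV inside a subset HVR. Per-gene SSV counts are reported.
    """
    from hvrkit.conservation import NSC_TERMS

    in_subset = points_in_any(ssvs.df, subset_hvrs) if len(ssvs) else np.zeros(0, bool)
    sub_ssvs = SSVSet(ssvs.label, ssvs.df[in_subset].reset_index(drop=True))

    coding = classify_ssvs(sub_ssvs, genes)
    nsc = coding[coding["term"].isin(NSC_TERMS) & coding["gene_id"].notna()]
    nsc_counts = nsc.groupby("gene_id").size()
    coding_genes = pd.DataFrame({
        "gene_id": nsc_counts.index,
        "n_nsc_ssvs": nsc_counts.to_numpy(),
    })
    coding_genes = coding_genes[coding_genes["gene_id"].isin(expressed)].reset_index(drop=True)

    prom_by_id = promoters.set_index("promoter_id")
    rows = []
    for assign in promoter_assignments.itertuples(index=False):
        prom = prom_by_id.loc[assign.promoter_id]
        in_prom = (
            (sub_ssvs.df["chrom"] == prom["chrom"])
            & (sub_ssvs.df["pos"] >= prom["start"])
            & (sub_ssvs.df["pos"] < prom["end"])
        )
        n = int(in_prom.sum())
        if n > 0 and assign.gene_id in expressed:
            rows.append((assign.gene_id, assign.promoter_id, n))
    promoter_genes = pd.DataFrame(rows, columns=["gene_id", "promoter_id", "n_ssvs"])
    return {"coding": coding_genes, "promoter": promoter_genes}


# ---------------------------------------------------------------------------
# Orthology and disease enrichment

ORTHOLOGY_KEEP = frozenset({"one2one", "apparently_one2one"})


def orthologue_filter(rat_genes: Iterable[str], orthology: pd.DataFrame) -> dict[str, str]:
    """Map rat genes to human orthologues, keeping only one-to-one classes.

    Rows whose class is not one2one / apparently_one2one are dropped, as are
    residual many-to-many rows (duplicated rat or human ids). Rat genes
    without a surviving row are dropped and counted in the log.
    """
    ortho = orthology[orthology["class"].isin(ORTHOLOGY_KEEP)]
    ortho = ortho[~ortho["rat_id"].duplicated(keep=False)]
    ortho = ortho[~ortho["human_id"].duplicated(keep=False)]
    mapping = dict(zip(ortho["rat_id"], ortho["human_id"]))
    rat_genes = list(rat_genes)
    out = {g: mapping[g] for g in rat_genes if g in mapping}
    n_dropped = len(rat_genes) - len(out)
    if n_dropped:
        logger.info("orthologue filter: dropped %d genes without one-to-one orthologue",
                    n_dropped)
    return out


@dataclass
class DiseaseEnrichmentResult:
    disease_id: str
    a: int  # candidates with disease association
    b: int  # candidates without
    c: int  # non-candidate background with disease association
    d: int  # non-candidate background without
    odds_ratio: float  # ad / bc; inf when bc == 0
    p_two_sided: float
    p_greater: float

    @property
    def table(self) -> list[list[int]]:
        return [[self.a, self.b], [self.c, self.d]]

    @property
    def odds_ratio_defined(self) -> bool:
        return not (np.isinf(self.odds_ratio) or np.isnan(self.odds_ratio))

    def to_dict(self) -> dict:
        return {
            "disease_id": self.disease_id,
            "table": self.table,
            "odds_ratio": None if not self.odds_ratio_defined else self.odds_ratio,
            "p_two_sided": self.p_two_sided,
            "p_greater": self.p_greater,
        }


def fisher_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float, float]:
    """(odds ratio ad/bc, two-sided p, one-sided enrichment p)."""
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell count")
    with np.errstate(divide="ignore", invalid="ignore"):
        if b * c == 0:
            odds = np.inf if a * d > 0 else np.nan
        else:
            odds = (a * d) / (b * c)
    _, p_two = fisher_exact([[a, b], [c, d]], alternative="two-sided")
    _, p_greater = fisher_exact([[a, b], [c, d]], alternative="greater")
    return float(odds), float(p_two), float(p_greater)


def disease_enrichment(
    candidates: Iterable[str],
    background: Iterable[str],
    disease_map: pd.DataFrame,
    disease_id: str,
) -> DiseaseEnrichmentResult:
    """Fisher's exact test of disease association in candidates vs background.

    ``disease_map`` columns: disease_id, human_id. Candidates must be a
    subset of the background; the comparison group is background without the
    candidates.
    """
    candidates = set(candidates)
    background = set(background)
    if not background:
        raise ValueError("empty background gene set")
    if not candidates <= background:
        raise ValueError("candidate genes must be a subset of the background")
    disease_genes = set(disease_map.loc[disease_map["disease_id"] == disease_id, "human_id"])
    rest = background - candidates
    a = len(candidates & disease_genes)
    b = len(candidates) - a
    c = len(rest & disease_genes)
    d = len(rest) - c
    odds, p_two, p_greater = fisher_2x2(a, b, c, d)
    return DiseaseEnrichmentResult(disease_id, a, b, c, d, odds, p_two, p_greater)


def term_enrichment(
    candidates: Iterable[str],
    background: Iterable[str],
    gene_terms: pd.DataFrame,
    term: str,
) -> DiseaseEnrichmentResult:
    """Generic Fisher enrichment over a gene -> term table (columns term, gene_id)."""
    renamed = pd.DataFrame({"disease_id": gene_terms["term"], "human_id": gene_terms["gene_id"]})
    return disease_enrichment(candidates, background, renamed, term)
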