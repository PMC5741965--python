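"""Synthetic mosaic-genome datasets with planted structure.

Every downstream stage can be exercised offline: chromosomes are tiled with
alternating low-variability background and planted high-variability blocks
(window-aligned), per-window SSV counts are Poisson with ``lambda_high``
inside blocks and ``lambda_low`` elsewhere, blocks are owned either by one of
the query strains or shared with the control strain (shared variation is
emitted identically in control and all queries, so query-vs-control calling
removes it). TF peaks live inside blocks and are conserved (emitted
identically in >= 1 comparison species) with a per-block probability. Gene
models, promoters, expression with a planted DE set, GWAS points, unmappable
window runs and an orthology/disease map with a planted enrichment complete
the bundle. Identical seeds yield byte-identical files.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from hvrkit import io
from hvrkit.annotation import GeneModel, Transcript, write_gene_models
from hvrkit.layout import GenomeLayout

_BASES = np.array(list("ACGT"))
_STOP = {"TAA", "TAG", "TGA"}
_NONSTOP_CODONS = sorted(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOP
)

QUERY_STRAINS = ("Q1", "Q2", "Q3")
CONTROL_STRAIN = "CTRL"
SHARED_OWNER = "SHARED"


@dataclass
class SimulationConfig:
    seed: int = 0
    n_chromosomes: int = 5
    chrom_length_bp: int = 10_000_000
    window_bp: int = 10_000
    mean_high_block_windows: float = 50.0
    mean_low_block_windows: float = 100.0
    lambda_high: float = 15.0
    lambda_low: float = 0.5
    het_fraction: float = 0.05
    n_tf: int = 3
    n_other_species: int = 2
    peaks_per_high_block: float = 3.0
    conservation_prob: float = 0.8
    conservation_prob_by_block: dict = field(default_factory=dict)
    unmappable_fraction: float = 0.02
    n_genes: int = 200
    n_promoters: int = 150
    fpkm_lognormal_params: tuple = (1.0, 1.0)
    de_fraction: float = 0.1
    n_gwas_points: int = 100
    disease_gene_fraction_background: float = 0.11
    disease_odds_ratio: float = 2.5

    def validate(self) -> None:
        for name in ("het_fraction", "conservation_prob", "unmappable_fraction",
                     "de_fraction", "disease_gene_fraction_background"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_chromosomes", "chrom_length_bp", "window_bp", "n_tf",
                     "n_other_species", "n_genes", "n_promoters", "n_gwas_points"):
            if getattr(self, name) < 0 or (name in ("n_chromosomes", "chrom_length_bp",
                                                    "window_bp") and getattr(self, name) <= 0):
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        for name in ("mean_high_block_windows", "mean_low_block_windows",
                     "peaks_per_high_block", "disease_odds_ratio"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.lambda_high < 0 or self.lambda_low < 0:
            raise ValueError("rates must be non-negative")
        if self.lambda_high <= self.lambda_low and self.lambda_high > 0:
            warnings.warn("lambda_high <= lambda_low: bimodality not guaranteed",
                          stacklevel=2)


@dataclass
class GroundTruth:
    """What was actually written: block, peak, DE and disease plantings."""

    high_blocks: dict  # strain -> list of [chrom, start, end, block_id]
    shared_blocks: list  # blocks carried by control + all queries
    unmappable: list  # [chrom, start, end]
    peaks: dict  # factor -> list of {chrom,start,end,conserved,species,block_id}
    de_genes: dict  # strain -> sorted gene ids
    disease_enriched_genes: list  # rat gene ids of the planted enriched subset
    threshold_valley: tuple  # (low, high) interval the planted valley lies in

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = io.read_json(path)
        d["threshold_valley"] = tuple(d["threshold_valley"])
        return cls(**d)


@dataclass
class SimulatedBundle:
    config: SimulationConfig
    layout: GenomeLayout
    paths: dict  # logical name -> Path
    truth: GroundTruth


def _block_id(chrom: str, start: int, end: int) -> str:
    return f"{chrom}:{start}-{end}"


def _plant_blocks(cfg: SimulationConfig, layout: GenomeLayout,
                  rng: np.random.Generator) -> list[dict]:
    """Window-aligned blocks across the genome, each with an owner strain.

    Gaps are kept >= 2k+1 windows so triangular smoothing cannot bridge
    neighbouring blocks; block length is clipped at the 3-window run minimum.
    """
    owners = list(QUERY_STRAINS) + [SHARED_OWNER]
    min_gap = 8  # > 2*k + 1 for the default k=3
    blocks = []
    w = cfg.window_bp
    for chrom in layout:
        n_win = layout.n_windows(chrom, w)
        cursor = max(int(rng.geometric(1.0 / cfg.mean_low_block_windows)), min_gap)
        while cursor < n_win:
            length = max(int(rng.geometric(1.0 / cfg.mean_high_block_windows)), 3)
            if cursor + length > n_win - 1:
                break
            start, end = cursor * w, (cursor + length) * w
            owner = owners[int(rng.integers(len(owners)))]
            blocks.append({
                "chrom": chrom, "start": start, "end": end,
                "owner": owner, "block_id": _block_id(chrom, start, end),
            })
            cursor += length + max(int(rng.geometric(1.0 / cfg.mean_low_block_windows)),
                                   min_gap)
    return blocks


def _window_rate(cfg: SimulationConfig, owner_of_window: str | None, strain: str) -> float:
    if owner_of_window is None:
        return cfg.lambda_low
    return cfg.lambda_high if owner_of_window in (strain, SHARED_OWNER) else cfg.lambda_low


def _simulate_variants(cfg: SimulationConfig, layout: GenomeLayout, blocks: list[dict],
                       rng: np.random.Generator) -> dict[str, pd.DataFrame]:
    """Per-strain variant tables (chrom, pos 1-based, ref, alt, zygosity).

    Windows inside a block owned by strain s get Poisson(lambda_high) variants
    private to s; windows inside SHARED blocks get Poisson(lambda_high)
    variants present identically in the control and every query; all other
    windows get Poisson(lambda_low) private variants per query.
    """
    w = cfg.window_bp
    owner_by_window: dict[tuple[str, int], str] = {}
    for b in blocks:
        for widx in range(b["start"] // w, b["end"] // w):
            owner_by_window[(b["chrom"], widx)] = b["owner"]

    rows: dict[str, list] = {s: [] for s in (*QUERY_STRAINS, CONTROL_STRAIN)}
    for chrom in layout:
        n_win = layout.n_windows(chrom, w)
        for widx in range(n_win):
            wstart, wend = widx * w, min((widx + 1) * w, layout[chrom])
            owner = owner_by_window.get((chrom, widx))
            draws: list[tuple[str, int]] = []  # (recipient, count)
            if owner == SHARED_OWNER:
                draws.append((SHARED_OWNER, int(rng.poisson(cfg.lambda_high))))
                for q in QUERY_STRAINS:
                    draws.append((q, int(rng.poisson(cfg.lambda_low))))
            else:
                for q in QUERY_STRAINS:
                    draws.append((q, int(rng.poisson(_window_rate(cfg, owner, q)))))
            total = sum(n for _, n in draws)
            if total == 0:
                continue
            total = min(total, wend - wstart)
            positions = np.sort(rng.choice(wend - wstart, size=total, replace=False)) + wstart
            i = 0
            for recipient, n in draws:
                for pos in positions[i:i + n]:
                    ref, alt = rng.choice(4, size=2, replace=False)
                    zyg = "het" if rng.random() < cfg.het_fraction else "hom"
                    rec = (chrom, int(pos) + 1, _BASES[ref], _BASES[alt], zyg)
                    if recipient == SHARED_OWNER:
                        for s in (*QUERY_STRAINS, CONTROL_STRAIN):
                            rows[s].append(rec)
                    else:
                        rows[recipient].append(rec)
                i += n

    out = {}
    for strain, recs in rows.items():
        df = pd.DataFrame(recs, columns=["chrom", "pos", "ref", "alt", "zygosity"])
        out[strain] = df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    return out


def _plant_unmappable(cfg: SimulationConfig, layout: GenomeLayout, blocks: list[dict],
                      rng: np.random.Generator) -> tuple[pd.DataFrame, list]:
    """Window-stat track plus the planted UNMAP intervals.

    Unmappable runs avoid planted blocks (and their smoothing halo) so that
    segmentation recovery of the blocks is not confounded.
    """
    w = cfg.window_bp
    blocked: set[tuple[str, int]] = set()
    halo = 4
    for b in blocks:
        for widx in range(b["start"] // w - halo, b["end"] // w + halo):
            blocked.add((b["chrom"], widx))

    target = int(cfg.unmappable_fraction * sum(layout.n_windows(c, w) for c in layout))
    flagged: dict[str, set[int]] = {c: set() for c in layout}
    n_flagged = 0
    attempts = 0
    chroms = layout.chromosomes
    while n_flagged < target and attempts < 10_000:
        attempts += 1
        chrom = chroms[int(rng.integers(len(chroms)))]
        n_win = layout.n_windows(chrom, w)
        run = int(rng.integers(3, 7))
        start = int(rng.integers(0, max(n_win - run, 1)))
        widxs = range(start, min(start + run, n_win))
        if any((chrom, i) in blocked or i in flagged[chrom] for i in widxs):
            continue
        flagged[chrom].update(widxs)
        n_flagged += len(widxs)

    stat_rows, truth = [], []
    for chrom in layout:
        n_win = layout.n_windows(chrom, w)
        bad = flagged[chrom]
        for widx in range(n_win):
            if widx in bad:
                # alternate between the two failure modes
                mapq, cov = (10.0, 30.0) if widx % 2 == 0 else (60.0, 150.0)
            else:
                mapq, cov = 60.0, 30.0
            stat_rows.append((chrom, widx, mapq, cov))
        run_start = None
        for widx in range(n_win + 1):
            if widx in bad and run_start is None:
                run_start = widx
            elif widx not in bad and run_start is not None:
                truth.append([chrom, run_start * w, min(widx * w, layout[chrom])])
                run_start = None
    stats = pd.DataFrame(stat_rows,
                         columns=["chrom", "window_index", "mean_mapq", "mean_coverage"])
    return stats, truth


def _simulate_peaks(cfg: SimulationConfig, blocks: list[dict], layout: GenomeLayout,
                    rng: np.random.Generator) -> tuple[dict, dict]:
    """Rat + comparison-species peak tables per factor; truth records flags.

    Rat peaks are placed only inside planted blocks. A conserved rat peak is
    emitted identically in >= 1 comparison species; a non-conserved one has no
    same-factor overlap anywhere. Comparison species additionally carry decoy
    peaks in block-free territory.
    """
    factors = [f"TF{i + 1}" for i in range(cfg.n_tf)]
    species = [f"mus{i + 1}" for i in range(cfg.n_other_species)]
    peak_width = 400
    tables: dict[tuple[str, str], list] = {
        (f, sp): [] for f in factors for sp in ("rat", *species)
    }
    truth: dict[str, list] = {f: [] for f in factors}

    for factor in factors:
        for b in blocks:
            n = int(rng.poisson(cfg.peaks_per_high_block))
            if n == 0:
                continue
            space = (b["end"] - b["start"]) // max(n, 1)
            p_cons = cfg.conservation_prob_by_block.get(b["block_id"],
                                                        cfg.conservation_prob)
            for j in range(n):
                lo = b["start"] + j * space
                start = int(rng.integers(lo, max(lo + space - peak_width, lo + 1)))
                end = start + peak_width
                conserved = bool(rng.random() < p_cons)
                support = []
                if conserved and species:
                    mask = rng.random(len(species)) < 0.6
                    if not mask.any():
                        mask[int(rng.integers(len(species)))] = True
                    support = [sp for sp, m in zip(species, mask) if m]
                    for sp in support:
                        tables[(factor, sp)].append((b["chrom"], start, end))
                tables[(factor, "rat")].append((b["chrom"], start, end))
                truth[factor].append({
                    "chrom": b["chrom"], "start": start, "end": end,
                    "conserved": conserved, "species": support,
                    "block_id": b["block_id"],
                })
        # decoy peaks for comparison species, far from every block
        for sp in species:
            for chrom in layout:
                for _ in range(3):
                    start = int(rng.integers(0, layout[chrom] - peak_width))
                    if any(b["chrom"] == chrom
                           and start < b["end"] + peak_width and start + peak_width > b["start"] - peak_width
                           for b in blocks):
                        continue
                    tables[(factor, sp)].append((chrom, start, start + peak_width))

    frames = {}
    for key, recs in tables.items():
        df = pd.DataFrame(recs, columns=["chrom", "start", "end"])
        frames[key] = df.sort_values(["chrom", "start", "end"],
                                     kind="stable").reset_index(drop=True)
    return frames, truth


def _random_cds(n_codons: int, rng: np.random.Generator) -> str:
    idx = rng.integers(0, len(_NONSTOP_CODONS), size=n_codons - 1)
    return "".join(_NONSTOP_CODONS[i] for i in idx) + "TAA"


def _simulate_genes(cfg: SimulationConfig, layout: GenomeLayout, blocks: list[dict],
                    rng: np.random.Generator) -> tuple[list[GeneModel], pd.DataFrame]:
    """Gene models on a jittered grid (half steered into planted blocks) and
    their promoters. Genes are spaced widely so promoter assignment stays
    one-to-one by construction."""
    genes: list[GeneModel] = []
    promoters = []
    total_bp = layout.total_bp
    spacing = max(total_bp // max(cfg.n_genes, 1), 20_000)
    chroms = layout.chromosomes
    block_cycle = [b for b in blocks if (b["end"] - b["start"]) >= 20_000]
    for i in range(cfg.n_genes):
        if block_cycle and i % 2 == 0:
            b = block_cycle[(i // 2) % len(block_cycle)]
            chrom = b["chrom"]
            gstart = b["start"] + 3000 + (i % 3) * 4000
            if gstart + 2000 > b["end"]:
                gstart = b["start"] + 1000
        else:
            pos = (i * spacing + int(rng.integers(0, spacing // 2))) % total_bp
            ci = 0
            while pos >= layout[chroms[ci]]:
                pos -= layout[chroms[ci]]
                ci += 1
            chrom, gstart = chroms[ci], pos
        gstart = min(gstart, layout[chrom] - 3000)
        strand = "+" if rng.random() < 0.5 else "-"
        exons = [(gstart, gstart + 300), (gstart + 400, gstart + 700)]
        cds = exons  # 600 nt -> 200 codons
        gene_id = f"G{i:05d}"
        tss = gstart if strand == "+" else gstart + 700 - 1
        genes.append(GeneModel(
            gene_id=gene_id, chrom=chrom, strand=strand, tss=tss,
            start=gstart, end=gstart + 700,
            transcripts=[Transcript(
                transcript_id=f"{gene_id}.t1", exons=exons, cds=cds,
                cds_seq=_random_cds(200, rng))],
        ))
        if i < cfg.n_promoters:
            if strand == "+":
                pstart, pend = max(tss - 1500, 0), max(tss - 500, 1)
            else:
                pstart, pend = tss + 501, tss + 1501
            promoters.append((chrom, pstart, pend, f"P{i:05d}"))
    prom_df = pd.DataFrame(promoters, columns=["chrom", "start", "end", "promoter_id"])
    prom_df = prom_df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    return genes, prom_df


def simulate_disease_map(
    human_ids: list[str],
    enriched_ids: set[str],
    background_fraction: float,
    odds_ratio: float,
    rng: np.random.Generator,
    disease_id: str = "D:planted",
    control_disease_id: str = "D:control",
) -> pd.DataFrame:
    """Disease-gene map with a planted enrichment in ``enriched_ids``.

    Background genes are associated with probability ``background_fraction``;
    enriched genes with the probability implied by the odds ratio. A control
    disease with the uniform background rate is always included.
    """
    q = background_fraction
    p_enriched = odds_ratio * q / (1.0 - q + odds_ratio * q)
    rows = []
    for hid in human_ids:
        p = p_enriched if hid in enriched_ids else q
        if rng.random() < p:
            rows.append((disease_id, hid))
        if rng.random() < q:
            rows.append((control_disease_id, hid))
    return pd.DataFrame(rows, columns=["disease_id", "human_id"])


def simulate_dataset(config: SimulationConfig, outdir: str | Path) -> SimulatedBundle:
    """Write the full synthetic bundle to ``outdir`` and return its manifest."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    layout = GenomeLayout(
        [(f"chr{i + 1}", config.chrom_length_bp) for i in range(config.n_chromosomes)])
    paths: dict[str, Path] = {}

    paths["chrom_sizes"] = outdir / "chrom.sizes"
    layout.to_file(paths["chrom_sizes"])

    blocks = _plant_blocks(config, layout, rng)
    variants = _simulate_variants(config, layout, blocks, rng)
    for strain, df in variants.items():
        p = outdir / f"variants_{strain}.vcf"
        io.write_vcf(df, layout, strain, p)
        paths[f"vcf_{strain}"] = p

    window_stats, unmap_truth = _plant_unmappable(config, layout, blocks, rng)
    paths["window_stats"] = outdir / "window_stats.tsv"
    io.write_tsv(window_stats, paths["window_stats"])

    peak_frames, peak_truth = _simulate_peaks(config, blocks, layout, rng)
    for (factor, sp), df in peak_frames.items():
        p = outdir / f"peaks_{factor}_{sp}.bed"
        io.write_bed(df, p)
        paths[f"peaks_{factor}_{sp}"] = p

    genes, promoters = _simulate_genes(config, layout, blocks, rng)
    paths["genes"] = outdir / "genes.tsv"
    write_gene_models(genes, paths["genes"])
    paths["promoters"] = outdir / "promoters.bed"
    io.write_bed(promoters, paths["promoters"], extra_cols=["promoter_id"])

    mu, sigma = config.fpkm_lognormal_params
    expr_rows, de_truth = [], {}
    for strain in QUERY_STRAINS:
        de_ids = []
        for g in genes:
            fpkm = float(rng.lognormal(mu, sigma))
            de = bool(rng.random() < config.de_fraction)
            if de:
                de_ids.append(g.gene_id)
            expr_rows.append((g.gene_id, "liver", strain, round(fpkm, 4), int(de)))
        de_truth[strain] = de_ids
    paths["expression"] = outdir / "expression.tsv"
    io.write_tsv(pd.DataFrame(
        expr_rows, columns=["gene_id", "tissue", "strain", "fpkm", "de_flag"]),
        paths["expression"])

    gwas_rows = []
    for i in range(config.n_gwas_points):
        chrom = layout.chromosomes[int(rng.integers(len(layout)))]
        pos = int(rng.integers(0, layout[chrom]))
        gwas_rows.append((chrom, pos, pos + 1, f"rs{i:06d}"))
    gwas = pd.DataFrame(gwas_rows, columns=["chrom", "start", "end", "name"])
    gwas = gwas.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    paths["gwas"] = outdir / "gwas_points.bed"
    io.write_bed(gwas, paths["gwas"], extra_cols=["name"])

    ortho_rows = []
    for i, g in enumerate(genes):
        r = rng.random()
        klass = "one2one" if r < 0.9 else ("apparently_one2one" if r < 0.95 else "other")
        ortho_rows.append((g.gene_id, f"HUM{i:05d}", klass))
    orthology = pd.DataFrame(ortho_rows, columns=["rat_id", "human_id", "class"])
    paths["orthology"] = outdir / "orthology.tsv"
    io.write_tsv(orthology, paths["orthology"])

    # planted disease enrichment: genes lying inside planted blocks
    rat_to_human = dict(zip(orthology["rat_id"], orthology["human_id"]))
    in_block_rat = [
        g.gene_id for g in genes
        if any(b["chrom"] == g.chrom and b["start"] <= g.start < b["end"] for b in blocks)
    ]
    enriched_human = {rat_to_human[g] for g in in_block_rat}
    disease = simulate_disease_map(
        [rat_to_human[g.gene_id] for g in genes], enriched_human,
        config.disease_gene_fraction_background, config.disease_odds_ratio, rng)
    paths["disease"] = outdir / "disease.tsv"
    io.write_tsv(disease, paths["disease"])

    high_blocks = {
        strain: [[b["chrom"], b["start"], b["end"], b["block_id"]]
                 for b in blocks if b["owner"] == strain]
        for strain in QUERY_STRAINS
    }
    truth = GroundTruth(
        high_blocks=high_blocks,
        shared_blocks=[[b["chrom"], b["start"], b["end"], b["block_id"]]
                       for b in blocks if b["owner"] == SHARED_OWNER],
        unmappable=unmap_truth,
        peaks=peak_truth,
        de_genes=de_truth,
        disease_enriched_genes=sorted(in_block_rat),
        threshold_valley=(1.0, 10.0) if config.lambda_high > config.lambda_low else (0.0, 0.0),
    )
    paths["truth"] = outdir / "truth.json"
    io.write_json(truth.to_dict(), paths["truth"])

    return SimulatedBundle(config=config, layout=layout, paths=paths, truth=truth)
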