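"""End-to-end orchestration: configuration, validation, staged execution.

Stages: SSV calling -> windowing/smoothing -> threshold -> region calling ->
conservation/CE scoring -> HVR subsets -> permutation tests -> candidate
genes -> disease enrichment. Every stage writes re-loadable text outputs into
the configured output directory, and a machine-readable ``results.json``
aggregates the run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from hvrkit import annotation, conservation, io, permutation, segmentation, ssv
from hvrkit.layout import GenomeLayout

logger = logging.getLogger(__name__)

RESULTS_SCHEMA_VERSION = 1


class PipelineError(RuntimeError):
    """A stage failure; the message names the stage and the offending input."""


@dataclass
class PipelineConfig:
    chrom_sizes: str
    query_vcfs: dict  # strain -> path
    control_vcf: str
    outdir: str
    peaks: dict = field(default_factory=dict)  # factor -> {species -> path}
    rat_species: str = "rat"
    window_stats: str | None = None
    genes: str | None = None
    promoters: str | None = None
    expression: str | None = None
    orthology: str | None = None
    disease: str | None = None
    gwas: str | None = None

    window_bp: int = 10_000
    k: int = 3
    threshold_override: float | None = None
    threshold_fallback: float = segmentation.DEFAULT_THRESHOLD
    min_run: int = 3
    mapq_max: float = 30.0
    cov_min: float = 100.0
    max_gap: int = permutation.DEFAULT_MAX_GAP
    n_permutations: int = permutation.DEFAULT_N_PERMUTATIONS
    seed: int = 0
    ce_mode: str = "density_per_10kb"
    ce_thresholds: tuple = conservation.CE_THRESHOLDS
    ntf_levels: tuple = conservation.NTF_LEVELS
    fpkm_min: float = 1.0
    promoter_max_downstream: int = 5000
    disease_ids: tuple = ()
    permute_subsets: tuple | None = None  # None -> ALL + NTF subsets
    tissue: str = "liver"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def numeric_sanity(self) -> list[str]:
        errors = []
        for name in ("window_bp", "k", "min_run", "max_gap", "n_permutations",
                     "promoter_max_downstream"):
            if getattr(self, name) <= 0:
                errors.append(f"{name} must be positive, got {getattr(self, name)}")
        return errors

    def all_input_paths(self) -> dict[str, str]:
        paths = {"chrom_sizes": self.chrom_sizes, "control_vcf": self.control_vcf}
        for strain, p in self.query_vcfs.items():
            paths[f"query_vcf[{strain}]"] = p
        for factor, by_species in self.peaks.items():
            for species, p in by_species.items():
                paths[f"peaks[{factor}/{species}]"] = p
        for name in ("window_stats", "genes", "promoters", "expression",
                     "orthology", "disease", "gwas"):
            if getattr(self, name) is not None:
                paths[name] = getattr(self, name)
        return paths


def validate_inputs(config: PipelineConfig) -> dict:
    """Check path existence, coordinate-space consistency and sortedness.

    Returns {"errors": [...], "warnings": [...]}; errors make the pipeline
    refuse to run, warnings do not.
    """
    errors: list[str] = list(config.numeric_sanity())
    warnings_: list[str] = []
    for name, p in config.all_input_paths().items():
        if not Path(p).exists():
            errors.append(f"{name}: missing file {p}")
    if errors:
        return {"errors": errors, "warnings": warnings_}

    layout = GenomeLayout.from_file(config.chrom_sizes)
    from hvrkit.intervals import is_sorted

    for factor, by_species in config.peaks.items():
        for species, p in by_species.items():
            bed = io.read_bed(p)
            unknown = set(bed["chrom"]) - set(layout.chromosomes)
            if unknown:
                errors.append(f"peaks[{factor}/{species}]: unknown contigs {sorted(unknown)}")
                continue
            for chrom, sub in bed.groupby("chrom"):
                if (sub["end"] > layout[chrom]).any():
                    errors.append(
                        f"peaks[{factor}/{species}]: interval beyond end of {chrom}")
            if not is_sorted(bed):
                warnings_.append(f"peaks[{factor}/{species}]: not sorted, will auto-sort")

    for strain, p in list(config.query_vcfs.items()) + [("control", config.control_vcf)]:
        try:
            ssv.read_variants(p, layout)
        except ValueError as exc:
            errors.append(f"vcf[{strain}]: {exc}")
    return {"errors": errors, "warnings": warnings_}


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


@_stage("ssv_calling")
def _run_ssv(config: PipelineConfig, layout: GenomeLayout) -> dict[str, ssv.SSVSet]:
    control = ssv.read_variants(config.control_vcf, layout)
    out = {}
    for strain, path in sorted(config.query_vcfs.items()):
        query = ssv.read_variants(path, layout)
        out[strain] = ssv.call_ssvs_vs_control(query, control, label=f"{strain}_vs_control")
        logger.info("%s: %d SSVs", strain, len(out[strain]))
    return out


@_stage("segmentation")
def _run_segmentation(config: PipelineConfig, layout: GenomeLayout,
                      ssvs: dict[str, ssv.SSVSet], outdir: Path) -> dict:
    if config.window_stats:
        stats = io.read_tsv(config.window_stats)
        unmappable = segmentation.detect_unmappable(
            stats, layout, config.window_bp, config.mapq_max, config.cov_min,
            config.min_run)
    else:
        unmappable = segmentation.empty_regions()
    out = {}
    for strain, sset in ssvs.items():
        track = segmentation.count_ssvs_per_window(sset, layout, config.window_bp)
        track = segmentation.smooth_track(track, config.k)
        if config.threshold_override is not None:
            threshold = float(config.threshold_override)
        else:
            threshold = segmentation.find_threshold(
                track.all_smoothed(), fallback=config.threshold_fallback)
        regions = segmentation.call_regions(track, threshold, config.min_run, unmappable)
        summary = segmentation.summarize_comparison(sset, regions, layout)
        summary["threshold"] = threshold
        track.to_tsv(outdir / f"windows_{strain}.tsv")
        segmentation.write_regions(regions, outdir / f"regions_{strain}.bed")
        sset.to_bed(outdir / f"ssvs_{strain}.bed")
        out[strain] = {"track": track, "threshold": threshold,
                       "regions": regions, "summary": summary}
    return out


@_stage("conservation")
def _run_conservation(config: PipelineConfig, seg: dict, outdir: Path) -> dict:
    annotations = {}
    for factor, by_species in sorted(config.peaks.items()):
        rat = conservation.PeakSet.from_bed(by_species[config.rat_species], factor,
                                            config.rat_species)
        others = [conservation.PeakSet.from_bed(p, factor, spec)
                  for spec, p in sorted(by_species.items()) if spec != config.rat_species]
        ann = conservation.annotate_conservation(rat, others)
        ann.to_csv(outdir / f"conservation_{factor}.bed", sep="\t", header=False,
                   index=False, columns=["chrom", "start", "end", "conserved", "species"])
        annotations[factor] = ann

    out = {}
    for strain, stage in seg.items():
        hvrs = conservation.add_hvr_ids(stage["regions"])
        ce_tables = [
            conservation.compute_ce_table(hvrs, ann, factor, config.ce_mode)
            for factor, ann in annotations.items()
        ] if len(hvrs) else []
        if ce_tables:
            ce_all = pd.concat(ce_tables, ignore_index=True)
            io.write_tsv(ce_all, outdir / f"ce_{strain}.tsv")
            subsets = conservation.build_subsets(
                hvrs, ce_tables, config.ce_thresholds, config.ntf_levels)
        else:
            subsets = {"ALL": set(hvrs["hvr_id"]) if len(hvrs) else set()}
        membership = pd.DataFrame(
            [(k, hid) for k, ids in sorted(subsets.items()) for hid in sorted(ids)],
            columns=["subset", "hvr_id"])
        io.write_tsv(membership, outdir / f"subsets_{strain}.tsv")
        out[strain] = {"hvrs": hvrs, "subsets": subsets, "annotations": annotations}
    return out


def _subset_regions(hvrs: pd.DataFrame, ids: set[str]) -> pd.DataFrame:
    return hvrs[hvrs["hvr_id"].isin(ids)].reset_index(drop=True)


@_stage("permutation")
def _run_permutation(config: PipelineConfig, layout: GenomeLayout, cons: dict,
                     gene_models, outdir: Path) -> dict:
    elements = {}
    if gene_models:
        elements["genes"] = (pd.DataFrame(
            [(g.chrom, g.start, g.end) for g in gene_models],
            columns=["chrom", "start", "end"]), "n_elements_overlapping")
    if config.gwas:
        gwas = io.read_bed(config.gwas, extra_cols=["name"])
        elements["gwas"] = (gwas.assign(pos=gwas["start"]), "n_points_in")

    results = {}
    for strain, stage in cons.items():
        subset_keys = (list(config.permute_subsets) if config.permute_subsets is not None
                       else ["ALL"] + [k for k in stage["subsets"] if k.startswith("NTF")])
        results[strain] = {}
        for key in subset_keys:
            regions = _subset_regions(stage["hvrs"], stage["subsets"].get(key, set()))
            if len(regions) == 0:
                continue
            for elem_name, (elem_df, mode) in elements.items():
                res = permutation.permutation_test(
                    regions, elem_df, layout, mode=mode,
                    n_permutations=config.n_permutations,
                    seed=config.seed, max_gap=config.max_gap)
                res.to_json(outdir / f"permutation_{strain}_{key.replace('>', '')}_{elem_name}.json")
                results[strain][f"{key}|{elem_name}"] = res.to_dict()
    return results


@_stage("gene_annotation")
def _run_annotation(config: PipelineConfig, cons: dict, ssvs: dict, gene_models,
                    outdir: Path) -> dict:
    expression = io.read_tsv(config.expression) if config.expression else pd.DataFrame()
    promoters = (io.read_bed(config.promoters, extra_cols=["promoter_id"])
                 if config.promoters else pd.DataFrame(
                     columns=["chrom", "start", "end", "promoter_id"]))
    gene_df = pd.DataFrame(
        [(g.gene_id, g.chrom, g.strand, g.tss) for g in gene_models],
        columns=["gene_id", "chrom", "strand", "tss"])
    assignments = annotation.assign_promoters(
        promoters, gene_df, config.promoter_max_downstream)
    orthology = io.read_tsv(config.orthology) if config.orthology else pd.DataFrame(
        columns=["rat_id", "human_id", "class"])
    disease_map = io.read_tsv(config.disease) if config.disease else pd.DataFrame(
        columns=["disease_id", "human_id"])

    top_ntf = f"NTF>={max(config.ntf_levels)}"
    out = {}
    for strain, stage in cons.items():
        if len(expression):
            mask = (expression["strain"] == strain) & (expression["tissue"] == config.tissue)
            expressed = annotation.expressed_genes(expression[mask], config.fpkm_min)
        else:
            expressed = {g.gene_id for g in gene_models}
        subset = _subset_regions(stage["hvrs"], stage["subsets"].get(top_ntf, set()))
        candidates = annotation.select_candidate_genes(
            subset, ssvs[strain], gene_models, assignments, promoters, expressed)
        io.write_tsv(candidates["coding"], outdir / f"candidates_coding_{strain}.tsv")
        io.write_tsv(candidates["promoter"], outdir / f"candidates_promoter_{strain}.tsv")

        promoter_background_rat = sorted(
            expressed & set(assignments["gene_id"]))
        coding_background_rat = sorted(expressed)
        prom_bg_map = annotation.orthologue_filter(promoter_background_rat, orthology)
        coding_bg_map = annotation.orthologue_filter(coding_background_rat, orthology)

        disease_results = {}
        for disease_id in config.disease_ids:
            for list_name, cand_df, bg_map in (
                ("promoter", candidates["promoter"], prom_bg_map),
                ("coding", candidates["coding"], coding_bg_map),
            ):
                cand_human = {bg_map[g] for g in cand_df["gene_id"] if g in bg_map}
                if not bg_map:
                    continue
                res = annotation.disease_enrichment(
                    cand_human, set(bg_map.values()), disease_map, disease_id)
                disease_results[f"{disease_id}|{list_name}"] = res.to_dict()
        out[strain] = {
            "n_expressed": len(expressed),
            "candidates_coding": candidates["coding"].to_dict("records"),
            "candidates_promoter": candidates["promoter"].to_dict("records"),
            "disease_enrichment": disease_results,
        }
    return out


def run_full_analysis(config: PipelineConfig) -> dict:
    """Execute every stage; returns (and writes) the aggregated results."""
    report = validate_inputs(config)
    if report["errors"]:
        raise PipelineError("input validation failed: " + "; ".join(report["errors"]))
    for w in report["warnings"]:
        logger.warning("%s", w)

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    layout = GenomeLayout.from_file(config.chrom_sizes)

    ssvs = _run_ssv(config, layout)
    seg = _run_segmentation(config, layout, ssvs, outdir)
    cons = _run_conservation(config, seg, outdir)
    gene_models = annotation.read_gene_models(config.genes) if config.genes else []
    perm = _run_permutation(config, layout, cons, gene_models, outdir)
    annot = _run_annotation(config, cons, ssvs, gene_models, outdir)

    results = {
        "schema_version": RESULTS_SCHEMA_VERSION,
        "seed": config.seed,
        "summaries": {s: seg[s]["summary"] for s in seg},
        "subset_sizes": {
            s: {k: len(v) for k, v in sorted(cons[s]["subsets"].items())} for s in cons
        },
        "permutation": perm,
        "annotation": annot,
        "validation_warnings": report["warnings"],
    }
    io.write_json(results, outdir / "results.json")
    return results
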