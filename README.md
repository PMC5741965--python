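# hvrkit

Prioritisation of strain-specific haplotype blocks from genome variation and
cross-species regulatory conservation.

Given per-strain variant tables against a reference genome, `hvrkit`:

1. calls **strain-specific variants** (SSVs) for query-vs-reference and
   query-vs-control comparisons (an SSV carries an allele absent from both
   the reference and the control strain; heterozygous calls retained);
2. bins SSVs into non-overlapping 10 kb windows, applies a **triangular
   floating mean** (half-width k = 3, fixed denominator k²), finds the valley
   of the bimodal smoothed-density distribution, and calls **High/Low
   Variability Regions** (runs of ≥ 3 same-label windows; windows with mean
   MAPQ ≤ 30 or coverage ≥ 100 are masked as unmappable);
3. annotates TF peak **conservation** against comparison species (≥ 1 bp
   overlap with the same factor in ≥ 1 other species) and scores each HVR
   with a **Conservation Enrichment** score (conserved peaks per 10 kb, or
   the conserved fraction of peaks), building nested HVR subsets
   (w/TFBS, CE > 0…0.8, ≥ 1/2/3 factors with conserved peaks);
4. tests element enrichment in HVR subsets with a **cluster-preserving
   permutation test** (HVRs clustered within 1 Mb, clusters relocated
   genome-wide with internal offsets preserved, two-tailed empirical p with a
   floor of 1/(N+1));
5. interprets SSVs in the selected subsets at the gene level: FPKM > 1
   expression filter, strand-aware one-to-one promoter assignment (TSS inside
   or within 5 kb downstream of the promoter), codon-table consequence
   classification (synonymous / missense / stop gained / stop lost),
   one-to-one orthologue mapping and **Fisher's exact** disease enrichment.

A synthetic mosaic-genome generator (`hvrkit.simulate`) produces complete
toy input bundles — planted high-variability blocks with bimodal per-window
SSV densities, shared control haplotypes, peaks with a tunable conservation
probability, unmappable stretches, expression with a planted DE set, and a
disease map with a planted enrichment — so the whole pipeline runs and is
tested without any external data.

## CLI

```sh
hvrkit simulate --seed 1 --outdir sim/            # synthetic input bundle
hvrkit call-ssv --query sim/variants_Q1.vcf --control sim/variants_CTRL.vcf \
    --chrom-sizes sim/chrom.sizes --out q1.bed
hvrkit segment --ssv-bed q1.bed --chrom-sizes sim/chrom.sizes \
    --window-stats sim/window_stats.tsv --out-regions q1_regions.bed
hvrkit conserve --regions q1_regions.bed --factor TF1 \
    --rat-peaks sim/peaks_TF1_rat.bed \
    --other-peaks mus1 sim/peaks_TF1_mus1.bed --out ce.tsv
hvrkit permute --regions q1_regions.bed --elements sim/gwas_points.bed \
    --chrom-sizes sim/chrom.sizes --mode n_points_in --out perm.json
hvrkit annotate --ssv-bed q1.bed --genes sim/genes.tsv --out consequences.tsv
hvrkit run-all --config config.yaml                # everything, from YAML
hvrkit validate --config config.yaml               # input checks only
```

`run-all` writes per-stage TSV/BED intermediates plus a `results.json`
report; rerunning the same config is byte-identical. See
`hvrkit.pipeline.PipelineConfig` for the YAML schema (all keys are the
dataclass fields).

Conventions: every interval file is 0-based half-open BED; variant files are
minimal single-sample VCF (1-based positions, converted at the boundary).

## Tests

```sh
python -m pytest -q tests/
```

The suite pairs each operation with an independent brute-force oracle
(interval double loops, exhaustive codon substitution, hypergeometric
enumeration, seed-stream replay of the permutation null) and includes
stochastic calibration/recovery checks; the full run takes a few minutes,
dominated by the permutation-calibration test.

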