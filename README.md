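# oxbskit

Parallel bisulfite / oxidative-bisulfite (BS/oxBS) methylome analysis in
Python: simulation of paired tumor/normal WGBS + oxWGBS studies, spike-in
conversion QC, per-CpG β calling, joint 5mC/5hmC estimation by constrained
binomial maximum likelihood, differential (hydroxy)methylation region
calling, genomic-feature metaprofiles and enrichment, and integration of
promoter 5mC/5hmC direction patterns with gene expression (unidirectional
vs bidirectional modification, 5hmC-stratified fold changes, top-gene
signature scores).

## Modules

| module               | what it does |
|----------------------|--------------|
| `oxbskit.synthgen`   | toy annotation, true (p_m, p_h) methylome with implanted differential regions, binomial BS/oxBS read counts at Poisson depth, spike-in duplexes (C / 5mC / 5hmC / 5fC), negative-binomial expression coupled to promoter patterns |
| `oxbskit.qc`         | spike-in conversion rates and per-arm averages; library depth summaries |
| `oxbskit.calls`      | β = unconverted/total with a ≥10× coverage filter; context summaries; 10-kb genome bins |
| `oxbskit.mlml`       | closed-form constrained MLE of (p_m, p_h) from paired BS/oxBS counts, optional conversion-rate correction, occupancy summaries |
| `oxbskit.dmr`        | recursive binary segmentation of the group Δβ signal, Mann-Whitney region testing, BH FDR, DMR/DhMR threshold filters, promoter intersection |
| `oxbskit.annotate`   | feature labeling (promoter/UTR/exon/intron/CGI shore/shelf/…), 30-bin metaprofiles with flanks, observed/expected Fisher enrichment |
| `oxbskit.integrate`  | expression filtering, four-way promoter pattern classification, unidirectional/bidirectional comparisons (exact Mann-Whitney), \|Δβ\|-stratified log2FC, top-gene selection, signature scoring |
| `oxbskit.pipeline`   | `run_all`: simulate → qc → call → mlml → dmr → annotate → integrate from one config |

## CLI

```sh
oxbskit run-all --seed 1 --out out/            # full synthetic study + analysis
oxbskit simulate --seed 1 --out out/           # generation only (same artifacts)
oxbskit qc out/sim/T1.bs.spikes.tsv ... --out report.tsv
oxbskit call out/sim/T1.bs.counts.tsv --out beta.tsv
oxbskit mlml out/sim/T1.bs.counts.tsv out/sim/T1.ox.counts.tsv --correct --out mlml.tsv
oxbskit dmr matrix.tsv --modality m --tumor T1,T2,T3,T4 --normal N1,N2,N3,N4 --out dmr.tsv
```

`run-all` accepts a YAML config (see `oxbskit.pipeline.default_config()` for
the schema and defaults: chromosome sizes, gene counts, conversion rates,
depth, implant deltas, expression effect sizes).

## Conventions

- Coordinates are 0-based, half-open everywhere; CpG sites are
  strand-merged dyads (2 bp).
- DMR filters: |Δβ| > 0.2, > 10 CpGs, CpG density > 2 %, FDR < 0.001.
  DhMR filters: |Δβ| > 0.1, ≥ 5 CpGs, FDR < 0.05.
- Default conversion model: c_bs = 0.993, c_ox = 0.965, e_m = 0.035,
  c_f = 0.595 (BS) / 0.922 (oxBS).
- All tabular artifacts are plain TSV.
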