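# epihotspot

A tested, reusable pipeline for family-cohort differential DNA methylation
analysis from CpG count data (RRBS-style coverage files):

- **DMCpG calling** — per-CpG two-group test on methylated/unmethylated read
  counts (binomial-GLM likelihood-ratio test; Fisher's exact fallback for
  1-vs-1 designs), Benjamini–Hochberg correction, retained at q ≤ 0.01 and
  |Δmethylation| ≥ 30 percent points.
- **DMR tiling** — merging DMCpGs within ±500 bp, removal of mixed-sign
  (ambiguous) tiles, symmetric extension to a 100 bp minimum width.
- **Shared vs family-specific classification** across three differential
  runs (all samples, family A, family C), with cross-family CpG-coverage
  eligibility filtering, plus fibroblast↔iPSC persistence classes.
- **Genomic-context enrichment** — promoter/exon/intron/intergenic
  assignment, odds-ratio 2×2 tables with Fisher tests against arbitrary BED
  tracks (histone peaks, ChromHMM-style segments), signed TSS-distance bins,
  and basal-plus-extension (5 kb up / 1 kb down / ≤1 Mb distal) gene
  association.
- **Expression and nuclear-architecture integration** — DEG filtering and
  intersection, quadrant-count-ratio direction concordance, LAD
  redistribution (GoL/LoL/MoL) with cross-cell-type conservation,
  DEG-to-LAD distance statistics, and nearest-neighbor epimutation-hotspot
  proximity tests against matched random backgrounds (Wilcoxon rank-sum or
  binned one-tailed Fisher).
- **Synthetic data** — a seeded simulator producing multi-sample stranded
  coverage files with planted shared/family-specific DMRs of known
  location, sign, and effect size, plus consistent gene models, chromatin
  tracks, LAD tracks, and DEG tables.

A native genomic-interval engine (intersect / subtract / closest /
merge, BED3/BED6 I/O, 0-based half-open coordinates) underpins every
stage; all of its operations are validated against brute-force oracles.

## Run the test suite

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (oracle
equivalence, FDR control, planted-DMR parameter recovery, statistic
correctness, LAD algebra, hotspot-test calibration, end-to-end
determinism), one test per criterion.

## Command line

Generate a synthetic fixture tree:

```sh
epihotspot simulate --out fixtures/ --seed 1
```

Run the pipeline (stages: simulate, unite, dmcpg, tile, classify,
annotate, enrich, concordance, lads, hotspots, persistence, report):

```sh
epihotspot run --all --config cfg.yaml
epihotspot run --stage dmcpg --config cfg.yaml   # one stage
```

Minimal `cfg.yaml`:

```yaml
outdir: out
seed: 1
simulate:
  n_cpgs: 20000
  n_family_a: 30
  n_family_c: 30
  n_shared: 20
# thresholds default to: min_cov 5, diff_cutoff 30, q_cutoff 0.01,
# merge_gap 500, min_tile 100, deg_fdr 0.05, cardiac_p 0.05,
# lad_window 2000000; great: 5000/1000/1000000
```

Every stage writes a JSON manifest (input hashes, parameters, seed); a
re-run with unchanged inputs is a no-op unless `--force`. Identical
config + seed produce byte-identical output trees. Exit codes: 0 ok,
2 config error, 3 dependency error, 4 data error.

## Package layout

```
src/epihotspot/
  intervals.py    interval engine + BED I/O
  methio.py       coverage-file parsing, destranding, coverage filter, unite
  diffmeth.py     DMCpG calling, DMR tiling, tile classification
  annotation.py   promoters, feature assignment, OR enrichment, TSS bins, gene association
  integration.py  DEGs, QCR, LAD redistribution, proximity resampling
  simulate.py     seeded synthetic fixture generator with planted truth
  cli.py          stage-oriented pipeline with manifests
```
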