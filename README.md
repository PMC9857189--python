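# giscan

Copy-number analysis of shallow whole-genome sequencing of cell-free DNA,
built around control-referenced read-depth Z-scores:

- **Depth extraction** per 100 kb genome bin and per gene body, from a
  coordinate-sorted BAM, a bedGraph, or a binned TSV.
- **GC-bias correction** with a per-sample LOESS (tricube local polynomial,
  degree 2) fitted on bin depths; the same curve corrects gene-body depths.
- **Z-scores** against a healthy-control reference (per-feature mean/SD,
  SD floored at a 5% coefficient of variation); `z > 2` calls an
  amplification and `z < -2` a deletion (strict), with directional 0/1
  grouping against a packaged 33-gene ovarian-cancer panel (hg19).
- **Genome-wide instability (Gi) score** = sum of |z| over features, with a
  Wilcoxon rank-sum comparison between cohorts, plus in-silico
  downsampling concordance (binomial thinning).
- **Survival integration**: Kaplan–Meier, log-rank, per-gene univariate
  DFS/OS screens with small-arm eligibility rules, and a median-CA125 ×
  CNV four-subgroup analysis.
- **Synthetic cohorts**: negative-binomial GC-biased coverage with CNV
  segments diluted by tumor fraction (depth ratio `1 + tf·(copies−2)/2`),
  clinical outcomes with per-gene hazard ratios, and a deterministic
  fixture cohort whose per-gene carrier counts equal
  `round(frequency × n)` exactly.

## CLI

```bash
# simulate a cohort (YAML config optional; flags override)
giscan simulate --seed 43 --out cohort/

# deterministic fixture cohort (carrier counts from the panel frequencies)
giscan simulate --seed 17 --fixture --out fixture/

# normalize, build the control reference, score
giscan score --controls cohort/controls --patients cohort/patients \
             --gi-mode bins --out scored/

# per-gene DFS/OS screens + CA125 subgroup analysis (+ optional KM plots)
giscan survival --calls scored/cnv_calls.tsv --clinical cohort/clinical.csv \
                --out surv/ --plots

giscan report --score-dir scored/ --survival-dir surv/ --out report.txt
```

Every output table carries a header comment with the package version and a
config hash; each invocation writes a JSON run manifest.

## Python API

```python
import giscan as g

panel = g.load_gene_panel()                     # packaged 33-gene panel
cohort = g.simulate_cohort(g.SimConfig(seed=43), panel)
controls = [g.loess_gc_normalize(p) for p in cohort.controls]
ref = g.build_reference(controls)
zp = g.zscore(g.loess_gc_normalize(cohort.patients[0]), ref)
calls = g.calls_for_sample(zp, panel)
gi = g.gi_score(zp, kind="bin")
```

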