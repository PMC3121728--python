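# cghcohort

Cohort-scale analysis of 1-Mb array-CGH tumor profiles in a two-breed canine
cohort: per-case copy-number aberration (CNA) calling, genome-wide penetrance
and recurrence classification, microsatellite loss-of-heterozygosity (LOH)
scoring, per-region breed association with permutation family-wise error
control, and PCA-based population-substructure testing — together with a
synthetic cohort generator that reproduces the statistical structure the
analysis assumes, so every stage is testable without any external data.

## Layout

| Module | Role |
| --- | --- |
| `cghcohort.io_formats` | TSV readers/writers (clone map, ratio table, metadata, peak table, segments, regions, penetrance), `Config`, YAML config + run logs |
| `cghcohort.synthetic_data` | Fixture cohorts with exact-count planted CNAs, probe noise, flat profiles, background CNA model, and paired microsatellite genotypes |
| `cghcohort.cna_calling` | Moving-median smoothing, ratio thresholding, segment extraction, cohort count/size summaries |
| `cghcohort.penetrance` | Per-1-Mb-interval gain/loss penetrance, recurrence labels, region merging |
| `cghcohort.loh` | Allelic ratio / allelic imbalance, LOH calls, per-case region summaries |
| `cghcohort.association` | Fisher exact 2x2, breed-label permutation FWER cutoff, Mann-Whitney U, cohort epidemiology |
| `cghcohort.pca_substructure` | State-matrix PCA, scree, component-vs-covariate tests |
| `cghcohort.cli` | `cghcohort` command with `simulate`, `call`, `penetrance`, `loh`, `associate`, `pca`, `summarize` |

Coordinates are megabases, 0-based, half-open. Calling thresholds default to
tumor:reference ratios 1.15 (gain) and 0.85 (loss) applied on the log2 scale
to the smoothed profile; CNAs are *recurrent* at >= 30% penetrance and
*highly recurrent* at >= 50% among aberrant cases. LOH is called when
AI = AR(tumor)/AR(blood) is >= 1.5 or <= 0.67.

## CLI quick start

```sh
cghcohort simulate --fixture F1 --seed 42 --out scratch/f1
cghcohort call --ratios scratch/f1/ratios.tsv --map scratch/f1/map.tsv --out scratch/f1/segs.tsv
cghcohort penetrance --segs scratch/f1/segs.tsv --map scratch/f1/map.tsv --out scratch/f1/pen.tsv
cghcohort summarize --segs scratch/f1/segs.tsv --meta scratch/f1/meta.tsv --out scratch/f1/summary.tsv

cghcohort simulate --fixture F3 --seed 42 --out scratch/f3
cghcohort loh --peaks scratch/f3/peaks.tsv --out scratch/f3/ai.tsv
```

Every stage writes a YAML run log with the fully resolved configuration
(including the seed) next to its output.

## Fixtures

* **F1** — 104 cases (71 BMD / 33 FCR; 86 aberrant, 18 flat) with seven
  recurrent segments planted at exact combined-cohort carrier counts and a
  negative-binomial background CNA model.
* **F2** — 86 aberrant cases with 13 breed-differential loss regions
  (FCR 80% vs BMD 10% carriers) plus breed-balanced decoys.
* **F3** — 46 paired tumor/blood cases genotyped on a 7-marker panel, each
  with at least one informative marker planted beyond an LOH threshold, plus
  11 extra cases of which 6 carry LOH.
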