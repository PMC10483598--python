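# concord

Tooling for scoring concordance between paired tumor-tissue and circulating
tumor DNA (ctDNA) panel reports, and for quantifying the prognostic effect of
that concordance on overall survival.

The pipeline starts from called-alteration tables (one row per reported
aberration per assay per patient) plus a clinical table, and runs:

1. **Harmonization** (`concord.panels`) — resolves the date-appropriate
   comparable gene set between the tissue panel and the versioned ctDNA panel
   (53 genes / 3 amplification-eligible before 2015-02, 55 / 16 after),
   drops VUS/synonymous records, and restricts both assays' alterations to
   the shared universe.
2. **Concordance scoring** (`concord.concordance`) — per patient:
   *gene-level* concordance (same gene altered in both assays) and
   *mutation-level* concordance (identical locus: same normalized
   protein-change descriptor, or amplification in both); per cohort: a
   per-gene count table and conditional mutation-given-gene frequencies.
3. **Cohort statistics** (`concord.stats`) — Pearson correlations,
   chi-square independence tests with standardized residuals, and
   Kruskal–Wallis group comparisons over the per-patient frame.
4. **Survival models** (`concord.survival`) — Kaplan–Meier curves,
   univariate and multivariable Cox proportional-hazards fits (lifelines;
   Efron ties, Wald CIs), concordance-count threshold refits, time-gap
   sensitivity filters, and a leave-one-covariate-out diagnostic scan.
5. **Synthetic cohorts** (`concord.simulate`) — a seeded generator producing
   paired alteration/clinical/survival tables with known ground truth
   (per-patient shedding factor driving blood detection, per-gene
   locus-identity probabilities, blood-private alterations, Weibull
   proportional-hazards survival linear in the true mutual-gene count).
   `preset_paperlike()` is calibrated so a 433-patient cohort reproduces the
   published cohort's headline summary statistics.

## CLI

```sh
concord simulate  --preset paperlike --n 433 --seed 1 --out scratch/cohort
concord reproduce --config config.json --out scratch/results --seed 1
concord harmonize --config config.json --out scratch/harmonized.tsv
concord concordance|stats|survive --config config.json --out scratch/results
```

Exit codes: 0 success, 2 validation/configuration failure, 3 model-fit
failure. A run writes `gene_table.tsv`, `profiles.tsv`, `cohort_frame.tsv`,
`statistics.json`, `survival.json`, a forest-plot-ready `forest.tsv`, a
dropped-record log, and a `manifest.json` (version, config hash, seed).

`config.json` is a serialized `concord.io.RunConfig`, e.g.:

```json
{
 "alterations_path": "scratch/cohort/alterations.tsv",
 "clinical_path": "scratch/cohort/clinical.tsv",
 "survival_path": "scratch/cohort/survival.tsv",
 "out_dir": "scratch/results"
}
```

### Table schemas (tab-separated, UTF-8; CSV and XLSX also accepted)

* alterations: `patient_id  assay(tissue|ctdna)  gene  kind(point_mutation|
  indel|amplification|fusion|other)  locus  vaf_percent  characterized
  sample_date` — other layouts can be mapped with a `SchemaAdapter`
  (column renames plus kind/assay/characterized vocabulary maps).
* clinical: `patient_id  age_at_diagnosis  sex  tumor_type  tissue_date
  blood_date  [gap_months]  tmb  pct_ctdna`.
* survival: `patient_id  time_months  event`.

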