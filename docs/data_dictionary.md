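# Data dictionary

Column schemas for every interchange file.  All files are RFC-4180 CSV/TSV,
UTF-8, with a header row.

## cohort.csv (one row per subject)

| column | type | meaning |
|---|---|---|
| subject_id | string | unique subject identifier |
| family_id | string | shared by both twins of a pair; unique per case |
| zygosity | MZ / DZ / NA | NA for clinical cases |
| role | twin1 / twin2 / case | position within the family |
| sex | F / M | |
| age | years (float) | age at urine collection |
| aggression_score | float ≥ 0 | raw aggression scale score |
| t_score | float | 10·z + 50 within age/sex stratum |
| group | concordant_low / concordant_high / discordant_low / discordant_high / case / control / unlabeled | analysis-set assignment |
| density | float > 1 | urine specific gravity d_i |
| excl_chronic | bool | preexisting chronic condition flag |
| excl_medication | bool | current medication use flag |
| excl_vitamins | bool | vitamin supplement use flag |

Group semantics: `concordant_*` pairs form the discovery set, `discordant_*`
pairs the replication set, `case` + `control` the validation set.  `control`
pairs are concordant-low pairs reserved for validation and never enter
discovery.

## features_matrix.csv

Subjects in rows (index column `subject_id`), features in columns, raw
relative response ratios.  Cells censored below the limit of detection are
empty until imputation.

## features_metadata.csv (one row per feature)

| column | type | meaning |
|---|---|---|
| feature_id | string | metabolite / biomarker name |
| panel | amines / organic_acids / other | measurement platform |
| qc_rsd_target | percent | generator's target QC RSD (synthetic data) |
| lod | float or empty | limit of detection; empty = unknown |
| n_imputed | int | below-LOD cells imputed (written after preprocessing) |

## features_qc_replicates.csv

Pooled-QC replicate measurements: one row per replicate injection, one
column per feature.

## features_below_lod.csv

0/1 mask aligned with the matrix: 1 = value was censored below the LOD.

## ground_truth.json (synthetic data only)

`associated_features` (list), `effects` (per-feature log-scale slope on the
standardized liability), `beta_m` (true dilution slope), `log_baseline`,
`qc_rsd_target`, and the full generator `config`.

## Cascade report

Per-phase TSVs (`discovery_*.tsv`, `replication_*.tsv`, `validation_*.tsv`,
`sensitivity_*.tsv`) with columns `id`, `panel` (GEE phases), `n` /
`n_pairs`, `beta`/`mean_diff`, `se`/`t`, `df` (paired phases), `p`,
`fdr_p`, `scenario` (sensitivity only).  Effects are printed to 2 decimals
and p-values to 3 significant digits; `cascade_report.json` holds the same
records at full precision plus a provenance block (seed, configuration and
its hash, subject/feature counts, exclusion counts, caution-feature flags).
`twinmet/report_schema.json` documents the JSON layout.

## ACE pairs CSV (CLI `ace --pairs`)

| column | type |
|---|---|
| family_id | string |
| zygosity | MZ / DZ |
| phenotype1, phenotype2 | float |
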