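# gutmet

Family-aware microbiome–metabolome association pipeline with a synthetic
twin-cohort generator. Implements:

- **synthetic** — twin cohorts (MZ/DZ pairs + singletons), zero-inflated
  compositional species tables, pathway tables as weighted sums of
  contributing species, log-scale metabolite tables with planted feature
  effects, family covariance, run-day batches and planted mediated
  faecal–blood metabolite trios, with ground-truth labels.
- **preprocess** — zeros→missing, arcsine-sqrt, iterative Grubbs outlier
  filtering, standardization, PCA sample-outlier detection, run-day median
  scaling, log transform, rank-based inverse-normal transform.
- **pedigree** — expected-relatedness matrices (MZ = 1, DZ = 0.5).
- **association** — variance-component mixed model `y ~ N(Xβ, σ_g²K + σ_e²I)`
  fit by ML with a 1-D profile over the heritability fraction, per-pair
  likelihood-ratio tests (≥ 50 observations), Storey q-values, and
  covariate-sensitivity comparison.
- **sharing** — presence/absence sharing between unrelated pairs (paired
  Wilcoxon), prevalence bins, prevalence–redundancy correlation,
  species-contribution fractions, metabolome temporal stability with a
  random-pairing permutation null.
- **enrichment** — PAGE Z scores over metabolite super-pathways with
  permutation P values and BH adjustment.
- **dialogue** — co-association trios, the missingness-based presence
  correlation test with matched random pairs, log-ratio mixed-model P
  values, the P-gain statistic, and its empirically calibrated threshold
  (95th percentile of matched null P-gains).
- **linking** — compound-key joins from metabolites to pathways and the
  fraction of associations linked to producing/consuming pathways.
- **cli / pipeline** — TSV readers/writers with validation and an
  end-to-end orchestrator writing deterministic per-stage manifests.

## CLI

```sh
gutmet simulate --seed 1 --out-dir cohort/
gutmet preprocess --kind species --table cohort/species.tsv --out species_proc.tsv
gutmet associate --metabolites faecal_proc.tsv --features species_proc.tsv \
    --pedigree cohort/pedigree.tsv --covariates cohort/covariates.tsv \
    --min-n 50 --fdr 0.05 --out assoc.tsv
gutmet share --species cohort/species.tsv --pathways cohort/pathways.tsv \
    --pedigree cohort/pedigree.tsv --out-dir share/
gutmet enrich --associations assoc.tsv --annotation annotation.tsv --out enrich.tsv
gutmet dialogue --faecal-assoc fa.tsv --blood-assoc ba.tsv \
    --faecal faecal_proc.tsv --blood blood_proc.tsv --features species_proc.tsv \
    --pedigree cohort/pedigree.tsv --covariates cohort/covariates.tsv \
    --out-dir dialogue/
gutmet link --associations assoc.tsv --annotation annotation.tsv \
    --compound-map compound_map.tsv --out links.tsv
gutmet run --out-dir run/ --seed 1      # end-to-end on a synthetic cohort
```

All tables are TSV, UTF-8, `NA` for missing, samples as rows with a
`sample_id` first column.

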