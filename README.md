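# crcmeta

Multi-study case–control microbiome meta-analysis pipeline. Starting from
per-study count tables (samples × taxa/OTUs) with sample metadata, it
computes:

- **alpha diversity** — richness, Shannon diversity, Pielou evenness;
  Tukey ladder-of-powers normalization + Z-scoring; study-adjusted
  mixed-model tests of a disease-severity trend; median-split diversity
  odds ratios,
- **beta diversity** — Bray–Curtis dissimilarity and per-study one-way
  PERMANOVA (seeded permutations, within-subject strata for matched
  tissue),
- **biomarker odds ratios** — per-taxon median-dichotomized 2×2 odds
  ratios per study (Woolf interval, Haldane–Anscombe correction for zero
  cells, chi-square test), DerSimonian–Laird random-effects pooling across
  studies, and Benjamini–Hochberg selection of significant taxa,
- **classification** — random-forest models (500 trees,
  mtry = floor(√p)) per study under three feature regimes (significant-OR
  taxa, all taxa, OTUs), repeated stratified CV with pooled out-of-fold
  AUC, permutation mean-decrease-in-accuracy importances with cross-study
  Z-score ranking, a one-tailed paired *t* comparison of model families,
  and train-on-one-study / test-on-the-rest transfer matrices,
- **synthetic data** — a Dirichlet-multinomial multi-study generator with
  study-level composition effects, patchy (zero-inflated) case-enriched
  taxa and protective taxa, plus ground truth for parameter-recovery
  testing. Default fecal (8 cohorts) and tissue (7 cohorts) designs ship
  with the package.

## CLI

```sh
# generate a synthetic 8-cohort fecal collection (+ metadata + ground truth)
crcmeta simulate --out sim/ --seed 1 --site feces

# per-sample alpha metrics and per-study diversity OR table
crcmeta diversity --collection sim/ --min-total 1 --out diversity.tsv

# per-study Bray-Curtis PERMANOVA
crcmeta permanova --study sim/Baxter.tsv --metadata sim/metadata.tsv \
    --comparison carcinoma --permutations 999 --seed 1 --out permanova.tsv

# pooled median-dichotomized ORs with BH selection
crcmeta meta-or --collection sim/ --comparison carcinoma --alpha 0.05 \
    --out pooled_or.tsv

# per-study cross-validated random-forest AUCs
crcmeta classify --collection sim/ --regime all_taxa --folds 10 --out cv.tsv

# cross-study transfer matrix
crcmeta transfer --collection sim/ --regime sig_or_taxa --out transfer.tsv

# full pipeline from a YAML config
crcmeta run --config run.yaml
```

Input formats: plain TSV count tables (header of feature ids, first
column sample ids) or mothur `.shared`-dialect tables; metadata TSV with
columns `sample_id, diagnosis, site, subject_id, matched, region`
(optionally `study_id`). All matrices are samples-in-rows. Result TSVs
carry a commented provenance header with version and seed.

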