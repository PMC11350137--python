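# crossgain

Genomic prediction of the genetic parameters of biparental breeding
crosses — family mean, genetic variance, superior progeny mean and
between-trait genetic correlation — together with the phenotype-based
machinery needed to validate such predictions empirically.

Given inbred parents genotyped at mapped SNP markers and genome-wide
additive marker effects from RR-BLUP, the expected progeny parameters of a
cross are computed analytically: segregating loci contribute variance
through the expected recombinant-inbred-line disequilibrium
`D(c) = (1 - 2c)/(1 + 2c)`, with recombination fractions `c` derived from
map distances by Haldane's function. Validation follows a
leave-one-family-out cross-validation design: marker effects are trained
on all other families, predictions for the held-out family are compared
against "observed" parameters estimated from multi-environment plot
phenotypes with fixed-effect BLUEs and AI-REML variance components, and
agreement is summarized as Pearson predictive abilities with bootstrap
confidence intervals and a variance-prediction bias statistic.

Everything is exercised end-to-end on synthetic nested-association-mapping
(NAM) populations with known simulated truth — no external data needed.

## Modules

| module               | role |
|----------------------|------|
| `crossgain.simnam`   | synthetic NAM generator: Haldane meiosis, single-seed-descent RILs, pleiotropic QTL architectures, multi-environment phenotypes, true family parameters |
| `crossgain.blues`    | fixed-effect genotype BLUEs (OLS: genotype + environment + optional set-level check covariate) |
| `crossgain.rrblup`   | RR-BLUP marker effects; REML ridge parameter via spectral profile, exact mixed-model-equation solve |
| `crossgain.crosspred`| analytic cross predictions plus two independent oracles (exact multilocus enumeration, Monte-Carlo progeny simulation) |
| `crossgain.remlvc`   | AI-REML univariate/bivariate variance components, LRT, Cullis reliability, Fisher CIs, observed family statistics |
| `crossgain.validate` | leave-one-family-out cross-validation, predictive abilities, bootstrap CIs, variance bias |
| `crossgain.io` / `crossgain.cli` | plain-text formats (TSV/CSV/JSON) and the `crossgain` command-line pipeline |

## Command-line pipeline

```sh
# 1. simulate a NAM dataset with known truth
crossgain simulate --config sim.yaml --out data/ --seed 1

# 2. genotype BLUEs from plot phenotypes
crossgain blues --phenos data/phenos.csv --out data/blues.csv

# 3. train RR-BLUP marker effects
crossgain train --blues data/blues.csv --geno data/genotypes.tsv \
    --map data/map.csv --out-effects data/effects.csv --out-model data/model.json

# 4. predict parameters for arbitrary crosses
crossgain predict-crosses --effects data/effects.csv --model data/model.json \
    --map data/map.csv --geno data/genotypes.tsv --crosses crosses.csv \
    --p 0.10 --out-trait pred_trait.csv --out-pair pred_pair.csv

# 5. observed family parameters (AI-REML)
crossgain family-params --phenos data/phenos.csv --blues data/blues.csv \
    --out-trait family_estimates.csv --out-pair family_correlations.csv

# 6. leave-one-family-out cross-validation + report
crossgain crossval --dir data/ --out cv/ --seed 1
crossgain report --results cv/crossval_results.csv --out cv/pa.csv --seed 1
```

`sim.yaml` holds `SimConfig` fields (founders, families, RILs per family,
selfing generations, chromosomes, markers, QTL count, per-trait
heritabilities, QTL-effect correlations, environments, ...); all
randomness flows from `--seed` and outputs carry provenance comments.

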