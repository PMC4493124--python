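# ibmgs

Genomic selection analysis for **intermated biparental maize populations**
(IBM Syn4 / Syn10-style designs): population and trait simulation, genotype
imputation, LD and realized-kinship statistics, RR-BLUP breeding-value
prediction, and a seven-scenario cross-validation engine over marker-density ×
training-size grids.

## The problem

In genomic selection (GS), marker effects are estimated jointly in a
phenotyped *training population* and used to predict genomic estimated
breeding values (GEBVs) for genotyped-only candidates.  Prediction accuracy
depends on two confounded ingredients: the **realized genetic relationship**
between training and validation lines, and the **linkage disequilibrium (LD)**
between markers and QTL.  Two populations derived from the same founders but
with different intermating histories (a Syn4-like RIL population with high LD
and high kinship, and a Syn10-like DH population with an almost doubled
genetic map, lower LD and lower kinship) let these ingredients be separated by
crossing training and validation sources.  This package implements that whole
analysis as a reusable, tested pipeline, with a synthetic-data module that
reproduces the statistical structure of such populations so every step runs
end to end without restricted data.

## The model

Line-mean phenotypes are modeled as

```
y = μ1 + X g + e,     g_j ~ N(0, V_g / N_M),     e ~ N(0, V_e/r · I)
```

where `X` is the N_P × N_M matrix of homozygous allele-count codes
(`X_ij ∈ {0, 2}`), `g` the marker breeding values, and `r` the number of
plots per line.  Solving the mixed-model equations is a ridge regression with
shrinkage `λ = (V_e/r)/(V_g/N_M)` (RR-BLUP); for N_M > N_P the equivalent
observation-dimension (dual) solve is used.  Variance components come from a
one-way ANOVA of plot phenotypes (`V_e = MS_within`,
`V_g = (MS_between − MS_within)/r`).  Accuracy is reported as
`r_MP = cor(ŷ, y)` and on the genotypic scale as `r_MG = r_MP / h`, with
`h = √h²` on the line-mean basis.

Supporting statistics: pairwise LD as the squared genotype correlation `r²`
(identical to haplotype `r²` for inbred biallelic data), LD decay in 100-kb
physical bins, average LD between adjacent markers of a marker set (ALAM),
realized kinship as proportion identity-by-state, and expanded-map estimation
from adjacent-marker discordance via the inverse Haldane map function
`d = −½ ln(1 − 2c)`.

## Worked example

```python
import numpy as np, pandas as pd
from ibmgs import (GridSpec, PlotPhenotypes, alam, estimate_expanded_map,
                   estimate_variance_anova, kinship_matrix, run_grid,
                   summary_matrix)
from ibmgs.popsim import simulate_study

study = simulate_study(np.random.default_rng(42))   # 6611-marker dense panel
g4, g10 = study.genotypes["syn4"], study.genotypes["syn10"]
print("expanded map (cM): syn4 %.0f  syn10 %.0f" % (
    estimate_expanded_map(g4).total_length_cm(),
    estimate_expanded_map(g10).total_length_cm()))
print("adjacent-marker LD: syn4 %.3f  syn10 %.3f" % (alam(g4), alam(g10)))
print("mean kinship:       syn4 %.3f  syn10 %.3f" % (
    kinship_matrix(g4).mean_off_diagonal, kinship_matrix(g10).mean_off_diagonal))

plots = pd.concat(study.traits[p].plot_phenotypes.table for p in study.genotypes)
var = estimate_variance_anova(PlotPhenotypes(plots))
print("ANOVA: Vg=%.1f Ve=%.1f h2=%.2f" % (var.Vg, var.Ve, var.h2))

grid = GridSpec(marker_counts=(100, 800, None), training_sizes=(60, 180),
                n_repeats=20, seed=42)
table = run_grid([1, 2], grid, study.genotypes,
                 {p: study.line_means(p) for p in study.genotypes}, var)
print(summary_matrix(table, 2).round(2))
```

prints

```
expanded map (cM): syn4 6925  syn10 11197
adjacent-marker LD: syn4 0.961  syn10 0.936
mean kinship:       syn4 0.519  syn10 0.505
ANOVA: Vg=1053.3 Ve=982.0 h2=0.81
N_M  100   800   6611
N_P
60   0.60  0.68  0.71
180  0.71  0.81  0.84
```

The four-generation-intermated (syn4-like) panel shows the shorter realized
map, the higher adjacent-marker LD and the higher mean kinship; the accuracy
matrix for within-population prediction (scenario 2) rises with both training
size and marker density, and mean `r_MG` stays usable even at 100 markers —
the signature of prediction driven by genetic relationship.

A command-line interface mirrors the library:
`ibmgs simulate|impute|ld|kinship|fit|predict|run-scenarios` (each run writes
a `manifest.json` with the resolved parameters and seed).

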