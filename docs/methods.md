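# Methods

This note documents the models implemented in `ibmgs`, the defaults chosen
where the design was genuinely open, and what the synthetic data do and do
not emulate.

## Population simulation

**Genome.** Ten chromosomes with B73-like physical lengths (301…149 Mb,
≈2.055 Gb total) and a constant 0.83 cM/Mb, giving a base (F2-scale) genetic
map of ≈1,700 cM.  Markers are placed on a uniform bp grid per chromosome,
allocated proportionally to physical length; the dense panel has 6,611
markers and the Syn4-like low-density panel is an evenly thinned 1,339-marker
subset of it, so the two panels share physical coordinates by construction.

**Meiosis.** Crossover counts per chromosome are Poisson in the chromosome
length (Morgans) and positions are uniform on the genetic scale — the
Haldane model, no interference.  All distance ↔ recombination conversions use
`c = (1 − e^(−2d))/2` and its inverse.

**Pedigree.** Two fully homozygous founders (codes 0 and 2 everywhere) →
F1 → an F2 pool → `g` generations of random non-self mating (one offspring
per pairing, parents drawn with replacement) → terminal inbreeding:

* *Syn10-like*: 194 doubled haploids after `g = 10` intermating generations
  (one gamete per line, doubled);
* *Syn4-like*: 244 recombinant inbred lines after `g = 4`, selfed for 6
  generations and then continued by single-seed descent until fixation.
  Continuing SSD (rather than randomly assigning residual heterozygous loci)
  preserves linkage; per-locus resolution would add spurious marker
  discordance that visibly inflates the estimated map at 6,611-marker
  density.

Small-`c` theory gives expected map expansions of ≈×6 (Syn10-like DH; twelve
effective meioses of LD decay) and ≈×4 (Syn4-like selfed RIL), hence an
expansion ratio ≈1.5; simulated panels come out at ≈6,900 and ≈11,200 cM
(ratio ≈1.6).

**Intermating pool sizes** (the drift level) are not derivable from the
design description and act as the pedigree's only free knob.  Defaults are
400 (Syn10-like) and 60 (Syn4-like), chosen from the closed form
`E[IBS] ≈ 0.5 + 2·Var(p)`, `Var(p) ≈ 0.25(1 − (1 − 1/2N)^g)`, so that the
simulated populations reproduce the empirically observed ordering of mean
realized kinship (Syn4 above Syn10).  With equal pools the ordering would
invert, because drift variance — and with it mean identity-by-state — grows
with the number of intermating generations.  Custom designs default to a
pool of 200.

## Trait model

Seventeen QTL positions are drawn uniformly on the genetic map and
interleaved into the simulated loci but excluded from the marker panel, so
markers tag QTL only through LD.  Effects are standard normal, shared by both
populations (same founders, same biology), and rescaled once so the combined
438-line population has genetic variance exactly `V_g = 1022.71` (the
mixed-population estimate used throughout the analysis).  Plot residuals are
i.i.d. normal with `V_e = r·V_g·(1 − h²)/h²` at `h² = 0.80` and `r = 4`
plots per line, so the expected line-mean heritability matches the target.
When `simulate_trait` is given `target_Vg`, the rescaling is exact (sample
variance equals the target to numerical precision).

## Variance components and RR-BLUP

One-way ANOVA over lines: `V_e = MS_within`,
`V_g = max(0, (MS_between − MS_within)/r)` with `r` the harmonic-mean
replicate count, `h² = V_g/(V_g + V_e/r)` on the line-mean basis.  A single
replicate per line leaves `V_e` unidentifiable and raises an error.

RR-BLUP keeps the `{0, 2}` coding uncentered in the model; internally the
intercept is absorbed by column-centering, which is algebraically identical
to the mixed-model equations with an unpenalized mean.  Shrinkage is
`λ = (V_e/r)/(V_g/N_M)`: the residual variance of an `r`-plot line mean over
the per-marker effect variance.  For `N_M ≤ N_P` the marker-dimension
(primal) normal equations are solved; otherwise the observation-dimension
(dual/Woodbury) form `g = X_cᵀ(X_cX_cᵀ + λI)⁻¹y_c`.  Both paths agree to
1e-8 relative and match an independently coded dense mixed-model-equation
solve; predictions equal the genomic-relationship (gBLUP) formulation.
`r_MG = r_MP/√h²` is reported uncapped.

## Imputation

**Within panel.** A two-state (AA/BB) HMM per line and chromosome: uniform
initial distribution (biparental symmetry), transition probability
`(1 − e^(−2d))/2` per interval, symmetric emission error ε (default 0.01;
the generating data carry no genotyping error, so ε only regularizes).
Missing cells take the forward–backward posterior mode; observed cells are
never altered; an exact posterior tie (0.5) stays missing and is logged.
Distances should come from the panel's own *expanded* map
(`estimate_expanded_map`), which already absorbs the extra intermating
recombination; on a perfectly uniform base grid, symmetric flanking evidence
produces exact ties, which the data-estimated map breaks.

A hard information limit applies at low density: at the 1,339-marker panel's
≈5-cM expanded spacing, adjacent intervals recombine with `c ≈ 0.05`, so a
masked cell sees disagreeing flanks with probability ≈`2c(1−c)` ≈ 9%, and
those cells are near coin flips for *any* method.  The posterior-mode
decision sits on the Bayes floor (measured error equals `E[1 − max
posterior]` to a few tenths of a percent), ≈3–4% error at 10% random
masking; on the 6,611-marker panel the same experiment recovers ≈99.6%.

**Cross panel.** Dense-marker genotypes for sparsely genotyped lines are
copied from an exactly coinciding sparse marker, otherwise from agreeing
flanking markers, the physically nearer flank when they disagree, and the
single flank at chromosome ends; an exact distance tie between disagreeing
flanks yields missing (no rule is implied by the flanking logic itself).
At the 6,611/1,339 geometry this recovers ≈98.5% of hidden codes.

## LD, kinship, and maps

* `r²` is the squared Pearson correlation of code columns, computed on
  pairwise-complete rows; monomorphic columns give NA and are excluded from
  averages.  For complete panels the all-pairs matrix is computed by one
  standardized cross-product per chromosome.
* LD decay bins are half-open `[k·100 kb, (k+1)·100 kb)` on `|bp_a − bp_b|`,
  intra-chromosomal pairs only, unweighted means.
* ALAM averages `r²` over literal adjacent pairs of a marker set (an
  alternative reading — binned LD evaluated at the set's mean spacing — would
  give slightly different values; literal adjacency is implemented).
* The average adjacent genetic distance of a marker set is defined as total
  map length divided by `N_M` (not `N_M − 1`), matching the spacing
  arithmetic of evenly spread sets.
* Kinship is proportion identity-by-state on homozygous codes.  Absolute
  values are convention-dependent (centered or frequency-scaled estimators
  give different numbers); only orderings between populations are
  scientifically asserted here.
* Expanded maps convert adjacent-marker discordance directly to ĉ (correct
  for DH; for selfed RILs the back-transform `c = R/(2 − 2R)` is available
  behind a flag, off by default since realized maps are meant to absorb
  design effects), then to cM by the inverse Haldane function; intervals with
  ĉ ≥ 0.5 are capped (default 200 cM) and flagged.

## Scenario engine

The seven scenarios pair training/validation sources as
(syn10→syn10, syn4→syn4, syn10→syn4, syn4→syn10, mixed→mixed, mixed→syn10,
mixed→syn4).  Within-population scenarios validate on the left-out lines;
between-population scenarios validate on the *entire* other population (no
subsampling is implied, and using all lines maximizes precision); mixed
training draws `N_P/2` lines from each population and validates on the
pooled (scenario 5) or population-specific (6, 7) remainders.

Marker sets are stratified draws: the cumulative genome-wide cM axis is cut
into `N_M` equal strata, one marker drawn uniformly per non-empty stratum,
empty strata borrowing from the nearest stratum with unused markers.  Sets
are redrawn independently every repeat.  Per-repeat generators are seeded by
the tuple (master seed, scenario, N_P, N_M, repeat), so any cell reruns
bit-identically in isolation.  Repeats with fewer than three validation
lines are skipped and logged, never imputed.

The Bonferroni-adjusted LSD per scenario uses the one-way ANOVA of
repeat-level `r_MG` with the (N_P, N_M) cell as factor:
`LSD = t(1 − α′/2, df_error)·√(2·MSE/n)`, `α′ = α/C(k,2)`, harmonic-mean `n`
for unequal repeat counts.

## Problem sizes

The default grid is marker counts {100, 200, 400, 800, 1600, 3200, full},
training sizes 30–180 by 30, 100 repeats.  The bundled checks run the full
6,611/1,339-marker panels for imputation, LD, kinship, and map statistics,
and a scaled-down grid (N_M ∈ {100, 800, full}, N_P ∈ {30, 180}, 50 repeats
in the test suite, 20 in the acceptance script) for the accuracy trends —
sizes chosen to keep repeated end-to-end runs convenient while leaving the
directional contrasts far clear of sampling noise.

## What the generator does not emulate

No segregation distortion or selection, no genotyping error, no residual
heterozygosity in outputs, no crossover interference, no missing-data
pattern beyond the masking the tests inject, and an idealized evenly spaced
marker grid rather than empirically clustered bin markers.  Consequently:
passing tests demonstrate the statistical machinery (solvers, estimators,
experiment logic) and the qualitative population contrasts, not the absolute
accuracy levels of any real dataset; real-data `r²` and kinship values also
reflect ascertainment and estimator conventions the simulation deliberately
leaves out.  Accuracies here are higher than typically observed empirically
because the trait is purely additive and the genotypes error-free.
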