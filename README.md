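# metstab

Stability analysis for multi-environment trials (METs) of quantitative trait
panels. `metstab` is aimed at breeders and quantitative geneticists who
evaluate a set of genotypes in several environments under a randomized
complete block design (RCBD) and need to answer two questions per trait —
*which genotypes perform well?* and *which perform consistently?* — and one
question across a whole panel of traits (grain metabolite intensities, quality
traits, yield components): *which genotypes should be selected overall?*

## What it computes

For replicate-level observations `y_ijr` of genotype *i* in environment *j*,
block *r*:

* **Combined ANOVA and variance components.** Sources environment,
  block-within-environment, genotype, genotype x environment interaction
  (GEI) and residual; EMS estimators (σ²g = (MS_G − MS_GEI)/(RL),
  σ²ge = (MS_GEI − MS_res)/R) with a REML alternative, and broad-sense
  heritability H² = σ²g / (σ²g + σ²ge/L + σ²ε/(LR)) (single-environment
  version H² = σ²g / (σ²g + σ²ε/R)).
* **AMMI.** The additive-main-effects-and-multiplicative-interaction model
  `y_ij = μ + α_i + τ_j + Σ_k λ_k a_ik t_jk + ρ_ij`, fitted by marginal means
  plus SVD of the double-centred cell-mean matrix; per-axis GEI shares
  θ_k = 100 λ_k²/Σλ², Gollob-df axis F tests, AMMI1/AMMI2 biplot coordinates.
* **Thirteen AMMI stability indices** — ASTAB, ASI, ASV, AVAMGE, DA, DZ, EV,
  FA, MASI, MASV, SIPC, WAAS, ZA — with per-index genotype ranks and Spearman
  rank concordance among indices.
* **GGE.** SVD of the environment-centred matrix (genotype + GEI), axis
  shares of the G+GE sum of squares, and the which-won-where view: convex
  hull of genotype scores, sectors bounded by rays perpendicular to hull
  edges, environment-to-sector assignment and mega-environments with their
  winning genotypes; environment vector lengths and pairwise cosines.
* **BLUP-based indices.** A mixed model (environment and block fixed,
  genotype and GEI random, REML components) yields genotypic values
  `Gv_ij`; from these HMGV (harmonic mean), RPGV (relative performance),
  HMRPGV (harmonic mean of relative performance) and WAASB (weighted average
  of absolute IPCA scores of the BLUP interaction matrix).
* **WAASBY and MTSI.** Per trait, mean performance and WAASB stability are
  rescaled to 0–100 and blended with weights θ_Y, θ_S (default 50/50). The
  multi-trait stability index factor-analyses the genotype x trait WAASBY
  matrix (Kaiser retention, varimax rotation) and ranks genotypes by the
  Euclidean distance of their factor scores from the ideotype (per-trait
  maximum WAASBY); the smallest distance is the best overall genotype.
* **Preprocessing for metabolite panels.** Total-ion-count normalisation,
  log10 + Pareto scaling, per-feature one-way ANOVA screening with
  Bonferroni correction, and two-way ANOVA ranking of location-responsive
  features.
* **Synthetic MET generator** with exact, retrievable ground truth
  (additive effects, rank-k bilinear GEI with orthonormal score columns,
  RCBD block effects, Gaussian or heavy-tailed noise), used throughout the
  test suite as a parameter-recovery oracle.

## Worked example

```python
import metstab as ms

sim = ms.simulate_multitrait(3, seed=42)      # 11 genotypes x 5 envs x 3 reps
data = sim.dataset

fit = ms.AMMI.from_dataset(data, "trait_001").fit()
print(fit.summary())
```

```
AMMI fit — trait 'trait_001': 11 genotypes x 5 environments
grand mean 99.7457; GEI SS 107.0554; 4 axes, 4 retained
axis   lambda      theta%   F        p
PC1    7.1965      48.38    1.199    0.2912
PC2    5.3506      26.74    0.783    0.6559
PC3    3.9628      14.67    0.525    0.8532
PC4    3.3064      10.21    0.470    0.8541
```

The first interaction axis carries 48.4 % of the GEI sum of squares but is
not significant against the pooled replicate error (p = 0.29) — for this
simulated trait the interaction is weak relative to noise. Stability indices
and the GGE view follow the same fit:

```python
stab = ms.stability_indices(fit)
print(stab[["ASV", "WAAS", "MASI", "rank_WAAS"]].round(3).head(4))

gge = ms.GGE(data.cell_means("trait_001")).fit()
print(gge.summary())
print(gge.which_won_where().mega_environments)
```

```
            ASV   WAAS   MASI  rank_WAAS
genotype
G01       1.651  0.611  0.442        7.0
G02       0.772  0.333  0.206        2.0
G03       0.533  0.268  0.143        1.0
G04       1.856  0.912  0.496       10.0

GGE fit — trait 'trait_001' (11 genotypes x 5 environments, svp f=0.5)
axis   lambda      explained%
PC1    41.1820     94.55
PC2    6.6786      2.49
...
PC1+PC2 explain 97.04% of G+GE SS
  winner          environments
0    G06  (E1, E2, E3, E4, E5)
```

G03 is the most stable genotype by WAAS (rank 1); all five environments fall
in the sector of hull vertex G06, i.e. a single mega-environment won by G06
— consistent with the mixed model, whose best genotype by HMRPGV is also G06:

```python
blup = ms.METMixedModel(data, "trait_001").fit()
print(blup.summary())
```

```
Mixed-model fit — trait 'trait_001' (reml components)
sigma2_g=33.1045  sigma2_ge=0.0000  sigma2_e=9.4135
best genotype by HMRPGV: G06
```

The same toolchain runs from the shell:

```sh
$ metstab simulate -g 11 -e 5 -r 3 -t 54 -k 2 --seed 42 --out panel.csv
wrote panel.csv (11x5x3, 54 trait(s))
$ metstab run --input panel.csv --outdir results/
analysed 54 trait(s); selected: G09, G01
```

`results/` then holds one CSV per table (`anova_<trait>.csv`,
`stability_<trait>.csv`, `gge_megaenv_<trait>.csv`, `blup_indices_<trait>.csv`,
`heritability.csv`, `waasby.csv`, `mtsi.csv`, …) plus a `manifest.json`
recording the configuration. In `mtsi.csv` the two genotypes with the
smallest ideotype distance (here G09 with MTSI 1.87 and G01 with 3.19) carry
the `selected` flag.

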