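# Methods

This note records the models implemented in `metstab`, the assumptions they
make, the defaults and why they were chosen, and the places where the design
was genuinely open.

## Data model and design assumptions

All analyses assume a randomized complete block design replicated across
environments: every genotype appears once in each of R blocks within each of
L environments, and blocks are nested within environments and shared across
genotypes. Missing cells are an error, never imputed — the methods below
(marginal-mean decompositions, EMS estimators) are exact only on complete
balanced tables, and silently imputing trial data hides collection problems.
Labels are matched case-sensitively after whitespace stripping, again to
surface data errors rather than repair them.

## Synthetic trials

The generator draws from the cell-mean model

    y_ijr = mu + alpha_i + tau_j + sum_k lambda_k a_ik t_jk + b_jr + e_ijr

with alpha, tau centred, the score matrices `a` (G x k) and `t` (E x k)
orthonormal-columned and orthogonal to the ones vector, and lambda sorted
non-increasing — exactly the structure the AMMI SVD recovers, so recovery
tests compare like with like. Sign ambiguity is removed by forcing the first
element of each score column non-negative. Blocks are N(0, block_sd²) per
(environment, replicate) and shared across genotypes; residuals are i.i.d.
Gaussian, with an optional scaled Student-t alternative (df > 2, variance
held at error_sd²) for robustness checks.

Default conditions emulate a grain-metabolite MET: 11 genotypes, 5
environments, 3 replicates; grand mean 100 (arbitrary TIC-normalised
intensity units), environment effect SD 10, genotype effect SD 5,
singular-value scale 8 (|N(0,8)| draws), block SD 2, residual SD 3. The
environment-dominant variance ordering mirrors what multi-location
metabolite and yield trials typically show. Traits in a multi-trait panel
are independent by construction; real metabolite panels are correlated, so
multi-trait results on synthetic panels exercise the mechanics (factor
analysis, ideotype distance), not realistic trait covariance. Passing tests
therefore demonstrate correctness of the estimators, not field performance.

## ANOVA, variance components, heritability

The combined ANOVA partitions environment, block-within-environment,
genotype, GEI and residual. With GEI random, genotype is tested against the
GEI mean square and GEI against the residual; environment is tested against
block-within-environment (the replication stratum), blocks against the
residual. EMS estimators: σ²ε = MS_res, σ²ge = (MS_GEI − MS_res)/R,
σ²g = (MS_G − MS_GEI)/(R·L). Negative moment estimates are truncated to zero
with a `truncated` flag; the untruncated values are kept in
`VarianceComponents.raw` because truncation biases Monte-Carlo means upward
and calibration checks need the raw estimator.

The REML alternative fits the same model (environment and block fixed,
genotype and GEI random). statsmodels' MixedLM provides the starting point;
its general-purpose optimizer stops around 1e-4 relative precision, which is
too loose to exhibit the exact EMS/REML equivalence on balanced data, so the
restricted log-likelihood is then maximised directly (Nelder-Mead on log
variances, xatol 1e-12) using dense Cholesky evaluation of the exact
criterion. On balanced data with interior estimates this reproduces the EMS
closed forms to ~1e-8 relative; at the zero boundary the two estimators
legitimately differ. Whether environment should be fixed or random when
estimating σ²g is ambiguous in practice; both ANOVA-EMS (environment fixed)
and the REML route are exposed, EMS being the default for balanced tables.

Heritabilities are entry-mean based: H² = σ²g/(σ²g + σ²ε/R) per environment
and H² = σ²g/(σ²g + σ²ge/L + σ²ε/(LR)) combined, zero when σ²g = 0 and
clamped to [0, 1] by the upstream truncation.

## AMMI

Additive effects come from marginal means; the bilinear part is the SVD of
the double-centred matrix Z. The per-axis GEI share is θ_k = 100λ_k²/Σλ²; a
constant input matrix makes θ undefined and is returned as zeros with a
`degenerate` flag. Axis significance uses Gollob degrees of freedom
(G + E − 1 − 2k) with F against the pooled replicate-level residual — the
common default where no resampling scheme is specified; Gollob tests are
known to be liberal, which matters for the default choice of retained axes
(below) but not for the decomposition itself. Eigenvector signs follow the
rule "largest-magnitude genotype loading positive per axis" so biplots are
reproducible across platforms. Biplot scores use symmetric singular-value
partitioning (f = 0.5) for display; index formulas use whatever power of
lambda their source definition demands.

## Stability indices

The thirteen indices are implemented from their canonical literature
definitions (module docstring of `metstab.stability` lists each formula);
the scaled score s_in = sqrt(lambda_n)·gamma_in and the SS-proportion
theta_n enter ASI, MASI, WAAS, ZA with theta as a 0–1 proportion — the
scale of theta only rescales an index, it never reranks genotypes. The
default number of retained axes N′ is the count of Gollob-significant axes
at p < 0.05, floored at 2 (ASI and ASV are two-axis constructions) and
capped at p = min(G−1, E−1); it is overridable everywhere. With N′ < 2, ASI
and ASV are reported as NaN rather than silently zero. Homogeneity under
data scaling follows from each formula's lambda degree: sqrt(c) for the
score-based indices, c for ASTAB/DA/AVAMGE, c² for FA, invariance for
DZ/EV; the tests assert exactly these degrees.

## GGE and which-won-where

GGE removes the environment main effect only ("centering 2", no scaling)
and decomposes by SVD; genotype scores carry lambda^f, environment scores
lambda^(1−f), f = 0.5 by default. The which-won-where geometry is computed
in the rank-2 score plane, matching how the biplots are read: convex hull
of genotype points (Qhull), sector boundaries are rays from the origin
perpendicular to hull edges — equivalently, the winner for any direction d
is the hull vertex maximising d·v, which is how environments are assigned
(ties resolve to the first hull vertex in counter-clockwise order).
Environments sharing a winner form a mega-environment. Cosines between
environment score vectors approximate between-environment correlations. The
"favourable environment" flag projects each environment vector onto the
direction in score space along which genotype mean performance increases
(the score-space regression direction of mean performance); this is an
interpretive device, not a standard statistic, and is labelled as such.

## BLUP indices

Given REML components, random effects are the solution of Henderson's mixed
model equations, solved in the augmented least-squares form
min ‖y − Xβ − Zu‖² + u'Du (numerically preferable to forming normal
equations; D carries σ²ε/σ²g and σ²ε/σ²ge ridges). For balanced designs with
interior EMS estimates the components are taken from the closed forms
directly — they equal REML there — which keeps 50-trait panels fast; the
iterative fit is used otherwise and can be forced. Genotypic values
Gv_ij = fixed(j) + g̃_i + (ge)~_ij. HMGV, RPGV and HMRPGV follow the harmonic
/ relative-performance definitions with μ_j the observed environment mean;
rank 1 is the largest (best performer). Harmonic means require Gv > 0, so
these indices should run on a positive measurement scale (e.g.
TIC-normalised intensities, not log/Pareto scores); non-positive genotypic
values flag the genotype and exclude it from ranking rather than producing a
misleading number. WAASB applies the weighted-absolute-score average to the
SVD of the BLUP interaction matrix over all axes.

## WAASBY and MTSI

WAASBY rescales mean performance (higher better) and WAASB (lower better)
to 0–100 and blends them; the default weights are equal (50/50), the usual
choice when no economic weighting is available, and traits where smaller
values are desirable can invert the performance rescaling. A scale with no
spread cannot discriminate and is set to all-100 with a flag.

MTSI factor-analyses the genotype x trait WAASBY matrix: eigendecomposition
of the trait correlation matrix, Kaiser retention (eigenvalue ≥ 1, minimum
one factor), varimax rotation, regression scores S = Z R⁻¹ A (pseudo-inverse
when R is near-singular). The ideotype is the per-trait maximum WAASBY,
standardised and projected with the same coefficients; MTSI is the Euclidean
distance from the ideotype in factor space. Zero-variance traits are dropped
with a warning. The default selection fraction marks 2 of 11 genotypes
(rounded, at least one). Because factor scores depend on the retained-factor
subspace, MTSI values are comparable within one panel, not across panels
with different factor structures.

## Preprocessing

TIC normalisation rescales each sample row to sum 100 (idempotent). The
log10 + Pareto step centres each feature's log intensity and divides by the
square root of its standard deviation; zero-variance columns map to zeros.
Non-positive intensities are lifted by half the smallest positive value in
the matrix before the log (configurable off, in which case they are an
error) — the standard metabolomics offset policy. The screening ANOVA's
Bonferroni family is the set of features tested in the call; the two-way
ranking orders features by the environment main-effect p-value (most
variation across locations), configurable to the interaction term, with a
closed-form balanced path and a Type-II fallback for unbalanced designs.

## Numerical choices and problem sizes

Degenerate inputs are handled explicitly: constant matrices (θ flagged),
zero-variance features/traits (zeroed or dropped with notice), undefined
Spearman correlations on constant index vectors (NaN), boundary variance
components (truncated + flagged). Ranks use average ranking on ties.

Test and acceptance runs use the study-scale shapes directly (11 x 5 x 3,
54-trait panels, 2000-feature null calibrations, 200-seed Monte-Carlo at
G = 40) — all complete in seconds to a couple of minutes on one CPU, so no
down-scaling was needed.

## Known limitations

Unbalanced data are supported only through the REML/MixedLM path and the
Type-II ANOVA fallback; EMS paths refuse them. No spatial/row-column
adjustment, no confidence regions on biplots, no correlated-trait
simulation, no multi-trait mixed models, and plotting is limited to writing
coordinates — rendering is left to the caller.
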