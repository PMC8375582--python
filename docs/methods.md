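# Methods

`devgsa` relates gene-level association from GWAS summary statistics to
developmental-stage-specific brain gene expression within named gene sets.
This note documents the statistical models, the numerical choices behind
them, what the synthetic-data generator does and does not emulate, and the
design decisions taken where more than one reasonable construction existed.

## Gene-level association (SNP-wise mean model)

SNPs with minor allele frequency strictly greater than 1% (configurable)
are annotated to genes with strand-aware regulatory windows: 35 kb 5' and
10 kb 3' of the gene body, both ends inclusive, positions 1-based. On the
minus strand the 35 kb window therefore extends to the *right* of the gene.
A `--ignore-strand` option applies the larger window symmetrically.

For a gene with SNP p-values `p_1..p_k`, each p is converted to a 1-df
chi-square quantile `q_i = F^{-1}(1 - p_i)` and the gene statistic is
`mean(q_i)`. Under the null the SNP z-scores are multivariate normal with
the local LD correlation matrix `R`, so `k * stat` is distributed as
`sum_i lambda_i chi2_1`, the `lambda_i` being the eigenvalues of `R`
(floored at zero after estimation from the reference panel, with the
matrix re-projected to unit diagonal).

Tail probabilities of the quadratic form are computed by Imhof's inversion
integral. The integrand `sin(theta(u)) / (u rho(u))` oscillates at
asymptotic frequency `x/2`, so the integral is split: an ordinary adaptive
quadrature on `[0, 1]`, then QUADPACK Fourier quadrature (`weight="cos"` /
`"sin"`) on `[1, inf)` after expanding
`sin(phi - wu) = sin(phi)cos(wu) - cos(phi)sin(wu)`, where
`phi(u) = (1/2) sum_i arctan(lambda_i u)` tends to a constant. Absolute
tolerance 1e-9; the combined QUADPACK error estimate must stay below 1e-6
or the code falls back to a moment-matched gamma (Satterthwaite)
approximation, which is logged. Equal eigenvalues (including every
single-SNP gene) reduce to the central chi-square closed form and bypass
integration. Gene p-values are clamped to `[1e-300, 1]`.

Gene p-values become probit Z-scores `z = Phi^{-1}(1 - p)`, capped at
±8.2 (p = 1 maps to the lower cap; the cap value is roughly the probit of
the smallest p distinguishable from 1 in double precision). Z is the
response of every downstream regression.

Calibration evidence: with identity LD the p-values match the chi-square
closed form to 1e-6; against Monte-Carlo oracles of the weighted
chi-square tail the inversion agrees within MC noise both at p ~ 0.05
(plain MC) and p ~ 1e-4 (importance-sampled MC with exponential tilting —
plain MC at that depth has ~10% relative standard error, too noisy to test
a numerical integrator against). Under a global null with AR(1) LD blocks,
gene p-values are uniform (KS < 0.025 over 5000 genes).

## Competitive, conditional and interaction set regressions

The universe is every gene with a Z and complete covariates; genes missing
the brain-expression covariate are excluded and logged. The baseline
covariate is brain expression, `log2(mean RPKM + 0.5)` across all
expression samples; log gene length and log SNP count can be added.

* **Competitive test**: OLS of Z on [intercept, covariates, conditioning
  indicators, 0/1 set membership]; the membership coefficient's one-sided
  p (enrichment) is reported by default.
* **Conditional subset test**: the superset enters as a conditioning
  indicator, so the child coefficient measures signal beyond the parent.
  A child equal to its parent is perfectly collinear and returns a flagged
  degenerate result (beta 0, p 1) rather than an error.
* **Interaction test**: `Z ~ 1 + B + S1 + S2 + S1*S2` with `S2` a per-gene
  quantitative property (a stage's expression-score column); the product
  coefficient is two-tailed. Membership degeneracies (e.g. `S1` identically
  1, which duplicates the intercept and makes `S12 = S2`) are handled by
  keeping the product term and adding the other columns only where they
  enlarge the column space, so the model reduces to the corresponding
  simpler regression instead of failing.

Inference uses the t distribution with the regression's residual degrees
of freedom rather than the normal: on desk-scale synthetic universes the
difference is visible. Degeneracy is detected by exact rank comparison of
the design with and without the term column, plus a residual-variance
floor (a constant response yields beta 0, p 1, flagged).

Benjamini-Hochberg (step-up) and Bonferroni corrections wrap
`statsmodels.stats.multitest`. Bonferroni takes an explicit family size:
number of surviving independent sets times number of stages for the main
interaction scan, stages only for a forced scan of a disorder with no
FDR-significant sets.

### Stepwise independent-set selection

Loop: test every remaining candidate conditional on all previously
selected sets; drop candidates with one-sided p >= 0.05 (configurable);
select the survivor with the largest beta; repeat until none remain.
Ties on beta break by smaller p, then lexicographic name. Betas are
compared after rounding to 1e-9 (p to 1e-12): a candidate that is the
exact union of already-conditioned sets spans the same design as another
candidate and their fitted betas differ only by float noise; rounding
makes such mathematical ties fall through to the deterministic name
tie-break instead of a floating-point coin flip. Collinear candidates are
degenerate and dropped, which is what eliminates duplicate or
union-redundant sets.

## Developmental expression scores

Counts convert to RPKM against *gene-assigned* reads (the column sum of
the count matrix), `rpkm = counts / (length_kb * assigned_millions)`.

Samples are binned into 13 developmental stages spanning 8 postconceptual
weeks (pcw) to 100 years (early fetal 8-9 pcw through late adulthood
60-100 years). Ages are stored as signed years — prenatal samples encoded
as `(pcw - 40)/52` — but carry a unit tag so stage boundaries are applied
exactly in each stage's own unit. Printed integer bounds are inclusive;
membership uses `[lower, upper + 1)` in the stage's unit (closed at 100
years), so a 12.5-year-old falls in late childhood (6-12 years). Stages
with fewer than two samples are dropped along with their samples; fewer
than two surviving stages is fatal. An option removes listed duplicate
sample ids before scoring, for paired datasets sharing donors.

Per gene and per retained stage, expression (default `log2(RPKM + 0.5)`;
`transform="none"` for raw RPKM) is regressed on intercept, 5 genotype
PCs, sex, and a single binary this-stage-vs-rest indicator — one
independent fit per (gene, stage), not one model with 12 dummies. The
indicator's t-statistic is the score. Fits are vectorised across genes
(the design depends only on the stage) and verified against per-fit OLS
to 1e-8. Constant-expression genes get t = 0 in every column and a
degeneracy flag. Ordinary (not moderated) t-statistics are used.

Because the indicators are one-vs-rest, a gene's scores across stages are
anti-correlated by construction; on balanced designs the row mean of t is
near zero.

## Trajectory clustering

Per-gene stage means (raw RPKM by default; log on request) are
row-standardised with the sample SD (n-1); flat rows are dropped with a
warning. K-means uses scikit-learn's Lloyd algorithm with `init="random"`,
20 starts, 20 iterations, seeded; that implementation relocates empty
clusters internally, so the restart-on-empty branch cannot trigger and
the restart counter is always 0. Labels are canonicalised (descending
size, centroid order for ties), making the partition invariant to gene
order. The scree table reports total within-cluster SS over k = 1..10
(monotonicity enforced across k by cumulative minimum); the advisory
suggestion is the smallest k whose relative SS drop to k+1 falls below
10%, and is never applied automatically. Cluster enrichment runs the
competitive test per cluster, absolutely and conditional on the parent
set, with a flag for clusters below 5 genes.

## Effect-size contrasts

Two enrichment coefficients are compared with
`z = (b_a - b_b)/sqrt(se_a^2 + se_b^2)`, two-sided p. The test assumes
independent estimates, valid for nonoverlapping sets; an overlap guard
refuses (or on request warns about) overlapping inputs. Same-set
contrasts across two GWAS share a universe and are flagged
`dependent_universe` instead. Contrasting two disorders properly is done
by running the set regressions on case-vs-case summary statistics.

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
not the biology of any particular dataset:

* **Panel**: per gene, an AR(1) LD block (`rho` between adjacent SNPs,
  default 0.5) of continuous Gaussian dosages with mean `2*MAF` and
  variance `2*MAF*(1-MAF)`, MAF ~ U(0.05, 0.5) — imputed-dosage-like, so
  the empirical correlation equals `rho` exactly in expectation (discrete
  genotypes would attenuate it). Genes tile one synthetic chromosome at
  120 kb spacing, far wider than the annotation windows, so every SNP maps
  to exactly one gene.
* **GWAS**: per gene, SNP z-scores drawn MVN with the theoretical AR(1)
  correlation. Planted effects are stated on the probit-Z scale: an
  effect of tau means the gene's *median* probit Z is tau. The shared
  per-SNP mean shift achieving this is solved numerically per (k, rho) —
  the null quantile from the Imhof inversion, the noncentral median from
  a fixed, seeded draw set — because LD inflates the null SD and a naive
  `ncp = tau^2` split would deliver far less than the nominal effect.
  Effects are either constant per set or, with
  `effect_distribution="uniform"`, drawn U(0, 2*effect) per gene (same
  mean, heterogeneous).
* **Expression**: 13 stages (default 24 samples each, ~BrainSeq-scale
  total), ages uniform within each stage's own unit, random sex, 5
  standard-normal genotype PCs. Per gene: baseline log2-RPKM ~ N(4, 1),
  a trajectory archetype (rising, falling, fetal-peak, adult-peak by
  default; amplitude 1.5 log2 units), small sex and PC effects, Gaussian
  noise (SD 0.2). The interaction planting raises the target stage's
  expression by `coupling * effect_g` log2 units, coupling a gene's
  association strength to its preferential expression there. Counts are
  Poisson draws of `rpkm * length_kb * library_millions`
  (`deterministic_counts=True` skips the Poisson for exact
  constructions).

Two structural facts about the generator worth knowing. First, RPKM
normalisation is compositional: a trajectory component shared by *all*
genes cancels exactly against the library size, so single-archetype
constructions recover flat trajectories — constructions needing exact
recovery plant at least two archetypes. Second, with constant within-set
effects the interaction t-statistic is bounded by the within-set Z
contrast (about 2.6 at effect 0.5 in a 38-of-125 split) no matter how
strong the expression coupling; heterogeneous effects remove that bound.

What passing tests on these data do **not** show: robustness to real LD
(long-range, non-AR structure), allele-frequency-dependent architectures,
count overdispersion beyond Poisson, batch effects, or misannotation.
The generator exists to verify the statistical machinery against known
truth, not to certify performance on any real cohort.

### Reference study conditions ("paper-like" preset)

2,000 genes; a 125-gene parent set split into a 38-gene "calcium-like"
child, an 80-gene "potassium-like" child and a 7-gene remainder; eight
background sets of 100-200 genes with no signal; association effect 0.8
(median-Z) planted only in the calcium-like child; expression coupling
1.0 at early adulthood in the parent set. Panel n = 1000, 2-6 SNPs/gene,
rho = 0.5. The effect size follows from a power analysis: conditional on
the parent, the child test contrasts 38 against 87 genes (SE ~ 0.19 on
unit-variance Z), so 0.8 places the planted asymmetry's conditional t
near 4 and its recovery rate near 1 — a property of the conditions, not
of the replicate draw.

## Validation experiments and problem sizes

`devgsa.validation` packages the recurring planted-truth experiments used
by the test suite and by `scripts/acceptance.py`: weighted-chi-square
calibration (9 (k, rho) combinations, 1e6 draws each), competitive-test
type-I error (1000 null replicates, 2000 genes, 150-gene set),
interaction power (200 replicates, coupling 0.3 on a 125-gene set) and
type-I (500 replicates), stepwise recovery (100 replicates of the
A/B/union construction with effects 0.9/0.45, chosen so the first-round
ordering and second-round power are both near-certain), expression-score
agreement with per-fit statsmodels OLS (100 random fixtures),
archetype-recovery ARI (200 genes, noise SD 0.2), and the end-to-end
asymmetry (100 replicates of the reference conditions: the calcium-like
child conditionally significant, its within-parent complement not). These
sizes keep the full validation run in the tens of minutes on one core
while leaving the binomial error of every rate well inside its acceptance
band.

## Known limitations

* The weighted-chi-square null treats the panel-estimated LD as exact;
  no shrinkage or sample-size correction of `R` is applied.
* One-sided set tests assume enrichment (positive beta) is the only
  alternative of interest, as is conventional.
* The stepwise procedure is greedy; it approximates, not optimises, the
  smallest independent cover.
* No sex-chromosome handling, no SNP-id synonym resolution, no liftover;
  gene ids are matched verbatim across files.
* Cross-disorder contrasts of the same set are flagged, not corrected,
  for their shared universe.
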