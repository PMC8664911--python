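# Methods

`egiscape` implements a landscape-genomics chain for a widely distributed
insect pest sampled across a global climate gradient: quality-filter SNPs,
scan them for climate association with three complementary models, model
genetic turnover with generalized dissimilarity modelling (GDM), project the
genetic offset a future climate would impose, and fuse that offset with the
change in a CLIMEX-style ecoclimatic index (EI) into a single eco-genetic
index (EGI) per map cell. This note records the models, the defaults, and
the design decisions taken where the problem was genuinely open.

## Synthetic landscapes (`synthio`)

Real inputs (a worldwide resequencing panel plus WorldClim and CLIMEX
surfaces) are replaced by a seeded generator that reproduces the statistical
structure the analysis assumes:

* **Sites** lie on a latitudinal gradient (default 75 sites x 5 diploid
  individuals, mirroring the sampling design of worldwide insect panels).
* **Climate** follows a one-factor model: each of the 19 bioclimatic
  variables loads on (absolute) latitude, with correlated residuals chosen
  so user-specified variable pairs hit target Pearson correlations (default
  pairs 0.92 / 0.94 / 0.99 mimic the strongly collinear bioclim pairs of
  global data). Loadings are shrunk automatically when a requested pair
  correlation would be infeasible under the factor model. Temperature-like
  variables get deg-C-ish units (mean 15, sd 6), precipitation-like mm-ish
  (mean 1000, sd 300); the analysis itself is unit-agnostic.
* **Neutral loci** drift under a Balding-Nichols model: per-locus ancestral
  frequency uniform on [0.1, 0.9] (avoiding near-fixed loci that the MAF
  filter would mass-remove), per-site frequencies Beta-distributed with
  dispersion `fst_neutral` (default 0.10).
* **Adaptive loci** (default 50 of 500) follow logistic clines:
  p_site = expit(intercept + beta * z), with z the standardized driving
  climate variable (chosen uniformly at random per locus) and
  |beta| = `cline_strength` (default 2; the effect-size distribution of real
  clinal loci is unknown, so this is a documented constant, not an
  estimate). Ground truth is returned for recovery tests.
* **Genotypes** are Binomial(2, p_site) with independent missingness
  (default 2%). Loci sit on one chromosome at positions drawn without
  replacement from 1..60L, dense enough that some pairs share a 25-bp
  window and exercise thinning.
* **EI surfaces** come from a fixed Gaussian suitability bump in the
  temperature-like variable (optimum 15, width 12, scaled to 0-100),
  evaluated at current and future climate. The default future shift warms
  temperature variables by +2 and dries precipitation variables by -60,
  a 2050-style scenario; cells above the optimum lose suitability (DEI < 0)
  and cells below gain, so both signs occur.

Not emulated: spatially explicit migration / isolation-by-distance, linkage
disequilibrium beyond shared-window placement, and any mechanistic
phenology. Passing tests therefore demonstrate correctness of the
statistical machinery under the stated generative model, not performance on
real data with spatial autocorrelation or LD.

## Variant QC (`variant_qc`)

Dosage coding from VCF GT fields (any call containing "." is missing);
filters keep bi-allelic loci with pooled MAF >= 5% (strict "<" removes) and
missing fraction <= 10% (strict ">" removes). MAF is pooled across all
individuals since no per-population rule is defined. Window thinning keeps
at most one SNP per fixed 25-bp tile anchored at position 1 (whether the
original windowing was tiled or sliding is unstated; tiled is implemented);
within a tile the highest-MAF locus wins, ties to the lowest position, to
maximize information retained. All coordinates are 1-based closed intervals.

## Association scans (`gea`)

* **Logistic (presence/absence) scan.** For each observed genotype class at
  a locus, class membership is regressed on the individual's site climate
  value by a damped-Newton logistic fit; G = 2(l1 - l0) and the squared
  Wald ratio are both referred to chi-square(1), and a locus x variable is
  significant when either passes Bonferroni at family level alpha = 0.01
  over all (locus, variable, class) tests. Classes with fewer than 10
  members in either outcome group are not tested (chi-square tails are
  unreliable there); under (quasi-)separation (|beta| >= 15 or
  non-convergence) the Wald flag is marked unreliable and the G test alone
  decides. The scan assumes independent individuals: under strong shared
  drift within sites it is anticonservative by construction, which is one
  motivation for requiring multi-model consensus.
* **Latent-factor scan.** A deterministic spectral variant of the latent
  factor approach: per run, k factors are the top left singular vectors of
  the centred (mean-imputed) genotype matrix computed on a random 90% locus
  subsample; each locus is regressed on climate + factors, z-scores are
  recalibrated by genomic inflation (divide by sqrt(lambda),
  lambda = median(z^2)/0.456), and the median over 5 runs is thresholded at
  |z| > 4 together with p < 1e-5; Benjamini-Hochberg q-values are reported
  per variable. k is a required user choice (k = 3 in the examples); the
  MCMC machinery of the original method is intentionally not reproduced --
  the decision rule operates on the same statistics.
* **Bayes-factor scan.** Site allele frequencies are standardized as
  x_s = (p_s - pbar)/sqrt(pbar(1-pbar)); a population covariance Omega is
  estimated from every 200th locus (independent random offset per run,
  ridge 1e-6 * trace/P). Because desk-scale datasets have far fewer loci
  than the covariance needs, the effective stride is capped so at least
  ~3 loci per population remain in the subsample. The Bayes factor per
  locus x variable averages N(x; beta*e, Omega)/N(x; 0, Omega) over a
  21-point symmetric midpoint grid of slopes spanning +/-5 empirical
  regression standard deviations (a midpoint grid makes the plain mean a
  proper quadrature of the uniform slope prior); log10 BF is averaged over
  5 runs and thresholded at 1.5.
* **Consensus.** A locus joins a model's set if significant for any
  variable; the union set needs >= 1 model, the core set >= 2 of 3.

## Dissimilarity modelling (`gdm`)

Pairwise Weir-Cockerham (1984) theta is computed per population pair as
sum(a)/sum(a+b+c) over loci (populations need >= 5 individuals; negative
estimates clamp to 0) and the matrix is affinely rescaled to [0, 1].
Predictors are pruned greedily until all retained pairwise |r| < 0.8,
keeping within each collision the variable with the better score
(single-predictor explained deviance when supplied, else the lower index).

Each predictor is transformed by three order-2 monotone I-splines with
knots at the 0/50/100 percentiles (the conventional GDM default; the spline
count is not otherwise determined). The model
d_ij = 1 - exp(-(a0 + sum_pk a_pk |I_pk(x_i) - I_pk(x_j)|)) is fitted by
IRLS with a nonnegative-least-squares inner solve, minimizing binomial-type
deviance with unit weights (well-defined for the rescaled FST response);
explained deviance is 100 (1 - residual/null) with an intercept-only null.
Geographic distance -- plain Euclidean on (lon, lat) -- can enter as a raw
pairwise predictor with its own splines. Importance per predictor is the
fitted I-spline maximum (the coefficient sum), rescaled so the largest is 1.

Two screens separate climate signal from neutral spatial structure in
single-SNP fits: drop loci where geographic distance ranks in the top 3
predictors, and drop loci whose explained deviance falls below that of a
randomly drawn reference group's combined fit (the reference floor is
recomputed on each dataset; published floors are data-specific and not
portable). Transformed climate surfaces are summarized by PCA with the
first three components rescaled to [0, 1] as RGB channels.

## Vulnerability (`vulnerability`)

Genetic offset per grid cell is
go = 1 - exp(-sum_p |f_p(x_cur) - f_p(x_fut)|) with the intercept
deliberately excluded so zero climate change gives exactly zero offset (a
generic predict-style computation would include it). DEI = EI_F - EI_C and
the analysis mask is DEI < 0 (declining suitability). Both |DEI| and the
offset are affinely normalized to [0.1, 0.9]; by default the normalization
population is the masked cells only, since only those enter the index (the
alternative, all cells, is config-exposed). Larger |DEI| maps to larger
dei_i -- monotone in the magnitude of decline. The [0.1, 0.9] band is
load-bearing: it keeps every log finite and strictly negative downstream,
and inputs outside (0, 1) are rejected rather than clamped.

## Eco-genetic index (`egi`)

egi_i = dei_i^alpha * go_i^(1-alpha) (weighted geometric averaging). With
A_i = ln egi_i, D_i = ln dei_i, G_i = ln go_i, the deviation of the index
from each component is d_i = (-A)/(-D) + (-D)/(-A) - 2 (and t_i likewise
with G), nonnegative by the a/b + b/a >= 2 identity, and the objective
Y(alpha) = sum_i (d_i + t_i) is minimized over alpha in [0, 1]. On a single
cell the stationary point is closed-form: A* = -sqrt(D G), i.e.
alpha* = (A* - G)/(D - G), used as a test oracle; the objective is convex
in alpha, and swapping the two components maps alpha to 1 - alpha.

The optimizer is a canonical artificial bee colony: population 20 read as
10 food sources with 10 employed plus 10 onlooker bees; perturbation
v = x + phi (x - x_k) with phi ~ U(-1, 1), clamped to [0, 1]; roulette
fitness 1/(1 + Y); a source abandoned more than `limit` = 5 times is
re-seeded uniformly; acceptance is greedy so the best-Y trace is
nonincreasing; 30 iterations. A 1e-4 grid search acts as an independent
oracle (ties to the smaller alpha). If dei = go everywhere, Y is
identically 0 and the solver returns alpha = 0.5 with a degenerate flag.
Higher egi_i means the cell combines a larger suitability decline with a
larger required genetic change -- i.e. a more challenged population.

## Pipeline and reproducibility

All randomness derives from a single root seed through named substreams
(generation, latent runs, covariance subsampling, reference sampling, ABC),
so any stage can be re-run in isolation and identical config + seed gives
byte-identical artifacts. The manifest records input hashes, parameters,
and per-stage counts. Config files are flat YAML; unknown keys are errors.

## Problem sizes and numerical choices

Tests and the acceptance script run desk-scale profiles chosen to make the
statistical checks well-powered while staying light: 75 sites x 5
individuals with 500 loci for error-control and power studies (100 and 20
seeded replicates respectively), 60 populations x 2000 loci for FST
recovery, 200-cell problems for optimizer-oracle agreement, and a 20-30
site end-to-end profile. Error-control calibration uses weak drift
(fst_neutral = 0.01): the logistic scan's independence assumption is
violated by strong within-site drift by design, and the calibration
isolates the test machinery itself. IRLS uses deviance-based convergence
(relative 1e-9, step-halving on deviance increases, best iterate returned
with a flag on non-convergence); probabilities are clipped at 1e-10 in
deviance evaluations; the covariance ridge is 1e-6 * trace/P.

## Known limitations

No LD model, no spatial autocorrelation beyond latent factors, no
mechanistic suitability model (the EI bump stands in for a calibrated
phenology model), single-chromosome coordinates, and the logistic scan's
documented anticonservativeness under strong hierarchical structure. The
optimal weight alpha is data-dependent: values reported by the acceptance
script describe the synthetic landscape it generates, nothing more.
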