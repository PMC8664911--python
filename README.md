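# egiscape

Landscape-genomics toolkit for asking how a widely distributed species'
populations will cope with climate change, built around three questions:

1. **Which SNPs track climate?** Genome-wide genotype-environment
   association with three complementary decision rules (logistic
   presence/absence scan with G/Wald + Bonferroni; latent-factor scan with
   |z| > 4 and p < 1e-5 on inflation-recalibrated median z-scores;
   covariance-null Bayes factors with mean log10 BF > 1.5), combined into
   union (>= 1 model) and core (>= 2 models) candidate sets.
2. **How is climate-driven variation organized, and what would future
   climate demand?** Generalized dissimilarity modelling of pairwise
   Weir-Cockerham F_ST on monotone I-spline climate transforms,
   d = 1 - exp(-(a0 + sum |f_p(x_i) - f_p(x_j)|)), with geographic-distance
   and reference-deviance screens; the fitted model yields the **genetic
   offset** GO = 1 - exp(-sum_p |f_p(x_cur) - f_p(x_fut)|) per map cell.
3. **How does genetic vulnerability combine with habitat suitability?**
   With DEI = EI_F - EI_C the change in a 0-100 ecoclimatic index, and both
   |DEI| and GO normalized to [0.1, 0.9] over the declining (DEI < 0)
   cells, the **eco-genetic index** is the weighted geometric mean

       egi_i = dei_i^alpha * go_i^(1-alpha),

   where alpha minimizes the symmetric log-ratio deviation
   Y(alpha) = sum_i [(-ln egi_i)/(-ln dei_i) + (-ln dei_i)/(-ln egi_i) - 2
   + (same with go_i)], solved by an artificial bee colony search
   (population 20, 30 iterations, limit 5) and cross-checked against a
   brute-force grid oracle.

A first-class synthetic-data module generates seeded landscapes with the
structure the analysis assumes -- latitudinal climate gradients with
correlated bioclim variables, Balding-Nichols drift, planted allele-
frequency clines, missingness, future shifts, and suitability surfaces --
so the entire chain runs and is tested without any downloads.

## Worked example

```python
from pathlib import Path
from egiscape.pipeline import PipelineConfig, run_pipeline

manifest = run_pipeline(PipelineConfig(
    seed=1, outdir=Path("out"),
    synthetic=dict(n_sites=30, inds_per_site=5, n_neutral_loci=400,
                   n_adaptive_loci=30, cline_strength=3.0, grid_cells=300),
    scan=dict(k=3), gdm=dict(n_reference=60),
))
for stage, info in manifest["stages"].items():
    print(stage, info)
```

A run of this profile prints (numbers vary with the seed):

```
simulate {'individuals': 150, 'loci': 430, 'sites': 30, 'grid_cells': 300, 'adaptive_loci': 30}
qc       {'input_loci': 430, ..., 'after_thinning': 363}
scan     {'records': 6897, 'union': 44, 'core': 27, ...}
gdm      {'candidates': 44, 'screened': 19, 'fit_loci': 19, 'explained_deviance_pct': 68.3993, 'predictors': 16}
offset   {'cells': 300, 'masked_cells': 167}
egi      {'cells': 167, 'alpha': 0.673615, 'Y_min': 94.951902, 'degenerate': False}
```

Read: of 430 simulated SNPs, 363 survive the MAF < 5% / missing > 10% /
25-bp-window filters; 44 loci are climate-associated in at least one model
and 27 in at least two; after the geographic-distance and reference-
deviance screens, 19 loci feed the combined GDM (68.4% deviance
explained); 167 of 300 grid cells face declining suitability, and on those
cells the optimizer weights the suitability decline at alpha = 0.674
versus 0.326 for the genetic offset in the combined index. Every artifact
(filtered VCF, association TSV, GDM JSON, vulnerability and EGI tables,
manifest) lands in `out/`, and the same seed reproduces them byte for byte.

The same stages are available as a CLI (`egiscape run --config run.yaml`,
plus `simulate` / `qc` / `scan` / `offset` / `egi` subcommands).

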