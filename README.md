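# gypsodiv

Community-assembly analysis for perennial plant communities on gypsum soils
along aridity gradients: taxonomic, soil-affinity (gypsophily) and
phylogenetic diversity metrics with permutation null models, followed by
GLMs of every metric against temperature, precipitation, their interaction
and plant cover.

It is written for plant community ecologists working with the standard
survey artifacts: a plot×species cover matrix, a species-level gypsophily
index (GI, an ordinal soil-affinity score from 1 = avoids gypsum to 5 =
strict gypsophyte), a dated phylogeny of the species pool, and per-plot
climate/cover data.

## Metrics

Per plot, with `p_i` the relative abundance of species *i*:

* richness `S` and the inverse Simpson index `1 / Σ p_i²`;
* gypsophily range `GR = max(GI) − min(GI)` (the single-trait analogue of
  functional richness);
* community mean gypsophily `CMG = Σ GI_i p_i` (a community-weighted mean);
* gypsophily diversity `GD = Σ_{i,j} (GI_i − GI_j)² p_i p_j` (Rao quadratic
  entropy on the GI axis);
* standardized effect sizes `SES = (obs − mean_null) / sd_null` of GR and GD
  against 10 000 permutations of the species→GI assignment across the
  regional pool;
* phylogenetic species variability `PSV` (1 on a star phylogeny, → 0 with
  increasing relatedness), `PSR = PSV × S`, mean pairwise patristic distance
  `MPD`, and the net relatedness index
  `NRI = −(MPD − mean MPD_null) / sd MPD_null` against 999 independent-swap
  null assemblages (plot richness and species occupancy held fixed);
  positive NRI indicates phylogenetic clustering.

Each metric is then modelled by a GLM on `T` (mean maximum temperature of
the hottest month, °C), `P` (mean annual precipitation, mm), `T×P` and total
plant cover (%), with Poisson(log) for richness, quasi-Poisson(log) for CMG
and Gaussian(identity) otherwise. The report gives per-term Type-II
likelihood-ratio chi-squares, coefficient signs and significance stars, plus
a Pearson collinearity check between `T` and `P`.

A synthetic-data generator produces complete datasets with the survey's
structure (89 plots, a 111-species pool with 16 gypsophytes, T in
30.8–34.5 °C, MAP in 195–565 mm, cover in 11–52.2 %) and records the seeded
effects so that the full pipeline's recovery of them can be tested.

## Worked example

```python
from gypsodiv import (RunConfig, ScenarioConfig, NullModelConfig,
                      run_full_analysis)

cfg = RunConfig(
    scenario=ScenarioConfig(seed=42),
    null_config=NullModelConfig(n_rand_trait=1000, n_rand_phylo=199, seed=42),
    outdir="demo",
)
res = run_full_analysis(cfg)
print(res["metrics"].head(3).round(3))
```

```
          S  invSimpson   GR    CMG     GD  SES_GR  SES_GD    PSV     PSR      MPD    NRI
plot_id
plot001  24      14.822  3.0  3.495  2.496   0.110   1.020  0.770  18.491  154.094 -0.107
plot002  15      10.055  2.0  4.025  1.062  -3.178  -1.522  0.735  11.022  146.965  0.822
plot003  41      23.776  3.0  3.118  1.564     NaN  -1.414  0.746  30.572  149.131  1.481
```

Plot 2 sits near the hot end of the synthetic gradient: fewer species,
specialist-dominated (CMG ≈ 4), a narrowed gypsophily range whose SES of
−3.2 flags significant trait clustering. Plot 3's SES_GR is NA because a
41-species sample from the pool nearly always spans the full GI range, so
the null distribution of GR has zero spread. The model report for the same
run recovers the generator's seeded gradient structure:

```
 response       family  term  chi_square sign  p_value stars
diversity     gaussian     T     139.483    -    0.000   ***
diversity     gaussian     P     115.163    -    0.000   ***
       GR     gaussian     T      96.843    -    0.000   ***
      CMG quasipoisson     T      96.503    +    0.000   ***
```

i.e. taxonomic diversity declines toward hot and wet plots, the gypsophily
range narrows with temperature, and mean gypsophily rises with temperature.

The same analysis is available from a shell:

```sh
gypsodiv simulate --seed 42 --out inputs/
gypsodiv analyze --community inputs/community.csv --traits inputs/traits.csv \
    --tree inputs/tree.nwk --env inputs/environment.csv --out results/ \
    --seed 42 --fast
gypsodiv all --seed 42 --out run/   # both steps in one go
```

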