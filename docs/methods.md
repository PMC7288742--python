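# Methods

## Data model

The pipeline links four artifacts: a plot×species abundance matrix in cover
units (raw transect intercepts, percentages or proportions — relative
abundances are always recomputed per plot, so the input scale is
irrelevant), a species→GI trait table (GI ∈ [1, 5], ordinarily integer), a
rooted phylogeny with branch lengths in divergence-time units, and a
per-plot environment table (Tmax °C, MAP mm, cover %). Blank community
cells are absences (zero), not missing data: the presence/absence structure
drives the occupancy-based null model. Validation is strict and eager:
duplicate keys, negative abundances, empty plots, GI out of range, missing
branch lengths and any cross-file key mismatch abort with the offending
records named.

## Trait metrics and their null model

GR, CMG and GD are computed on the species present in a plot after dropping
zero-abundance columns; GD uses the identity
`GD = 2 Σ p_i (GI_i − CMG)²`, algebraically equal to the double sum
`Σ_{i,j} (GI_i − GI_j)² p_i p_j` over ordered pairs (the test suite fuzzes
this equivalence to 1e-12).

The SES null model permutes the species→GI assignment across the whole
regional pool once per randomization, holding the community matrix fixed,
and recomputes GR and GD per plot (default 10 000 randomizations). A
within-plot shuffle of abundances among the species present would leave GR
unchanged in every draw and make its SES degenerate; the pool-wide trait
shuffle is the standard functional-diversity null and is the scheme
implemented. Plots whose null distribution has zero spread (e.g. a plot so
rich it spans the full GI range in essentially every permutation, or a
constant-GI pool) report SES = NA rather than ±∞.

## Phylogenetic metrics

The phylogenetic correlation matrix is built from shared root-to-tip branch
length: `V_ab = (depth_a + depth_b − d_ab)/2`, `C_ab = V_ab/√(V_aa V_bb)`,
which reduces to the usual scaled variance-covariance matrix on ultrametric
trees and remains well defined on non-ultrametric ones. PSV is one minus
the mean off-diagonal of C over the plot's species; PSR is PSV × S. MPD is
presence-based (unweighted): the independent-swap null operates on
presence/absence with fixed occupancy, and weighting the observed MPD by
abundance would compare statistics across different spaces. Plots with
S < 2 yield NA for PSV, PSR, MPD and NRI and are dropped (with a logged
count) from the GLMs of those responses.

Each NRI null draw restarts the independent swap from the observed matrix
and attempts 10× (number of occupied cells) random 2×2 checkerboard flips,
giving serially independent randomizations rather than a thinned Markov
chain. Swaps preserve row and column sums exactly, so every null assemblage
has the observed plot richness and species occupancy rates. Implementations
of PSV and MPD were cross-checked against an independent
community-phylogenetics implementation on a fixed small tree; those values
are frozen in the test suite.

## Gradient models

Terms enter as T, P, T×P and cover, untransformed and uncentered by default
(a `center` flag mean-centers T and P before forming the interaction; this
changes the interpretation of main effects under interaction but not the
Type-II tests). Per-term chi-squares are Type-II likelihood-ratio tests
respecting marginality: main effects are tested within the model excluding
the interaction, the interaction and cover against the full model. For
Gaussian and quasi-Poisson fits the deviance difference is scaled by the
full-model Pearson dispersion; the quasi-Poisson dispersion is reported.
This scaled-deviance chi-square is mildly liberal relative to the exact F
test — with 89 plots and 84 residual df the nominal 5 % test rejects a true
null about 5.5 % of the time, which the calibration test brackets at
[3 %, 7 %]. Significance stars are a pure function of the p-value bands
(* 0.01<P<0.05, ** 0.001<P<0.01, *** P<0.001); no multiple-testing
correction is applied across the eight response models, matching the usual
presentation of such tables. The collinearity check reports the Pearson r
between T and P together with r², `t = r√(n−2)/√(1−r²)` and its two-sided
p-value.

A constant response (zero residual variance) is reported as "nothing to
explain": all term chi-squares are zero rather than 0/0. NRI may be
negative, so its spec is restricted to Gaussian/identity at construction.

## Synthetic data generator

The generator emulates a gypsum-outcrop survey at the study scale: 89
plots, a 111-species pool with 16 strict gypsophytes (GI 5) and the rest
spread evenly over GI 2–4 (GI 1 optional — plots sit on gypsum, so
gypsum-avoiding species are absent by default), Tmax ~ U(30.8, 34.5) °C,
MAP ~ U(195, 565) mm and cover ~ U(11, 52.2) % (an optional Gaussian copula
induces a mild T–P correlation). The pool phylogeny is a random ultrametric
coalescent-style tree scaled to depth 100; with `phylo_signal > 0` GI
classes are re-assigned by ranking a latent trait `signal × BM + noise`
(BM = standardized Brownian tip values), so related species share GI while
class counts stay fixed.

Communities are assembled by environmental filtering. Occurrence weights
are logistic in `beta_cmg_T × x_T × (GI − 3.5)` with x_T the min–max-scaled
temperature in [0, 1]: no filtering at the coolest plots, full-strength
selection for specialists at the hottest. The one-sided intensity is
deliberate — a signed score would select *against* specialists at the cool
end and depress GR at both ends of the gradient, whereas heat acting as the
stressor yields the target pattern of specialist dominance (CMG rising) and
range narrowing (GR falling) toward hot plots, with cool plots admitting
the full GI range. A per-plot richness budget
`round(20 × exp(−beta_div_T z_T − beta_div_P z_P))` (z = midpoint-scaled
gradient position in [−1, 1], clipped to ≥ 3 species) makes taxonomic
diversity decline toward hot and wet plots. Abundances of occurring species
are log-normal (σ = 0.8) renormalised to the plot's total cover.

Effect-size defaults (`beta_cmg_T = 4.0`, `beta_div_T = beta_div_P = 0.4`)
were fixed by a power analysis at the study's sample size (89 plots) so
that every seeded effect is recoverable by the GLM stage with the correct
sign and starred significance in ≥95 % of replicate datasets — the
generator's contract. All randomness flows from a single seed through
per-component child streams, so every output is bit-reproducible.

What the generator does *not* emulate: spatial autocorrelation between
plots, dispersal limitation, interannual climate variation, observation
error in cover estimates, and any direct phylogenetic filtering of
occurrence (phylogenetic community structure arises only through the
GI–tree association). Passing recovery tests therefore demonstrate that the
pipeline detects filtering on a single trait axis under these idealised
conditions, not that the models are robust to spatially or phylogenetically
autocorrelated noise in field data.

## Numerical choices

Relative abundances are renormalised to |Σp − 1| ≤ 1e-12. Null-model
variances are clipped at zero before the square root (round-off can produce
tiny negative values); SES and NRI with zero null spread are NA. The swap
algorithm warns and returns the input unchanged when no checkerboard exists
(e.g. a saturated matrix), making every downstream NRI NA. Reduced
replication (`--fast`: 200 trait / 99 phylo randomizations) is a documented
approximation for quick runs; defaults are 10 000 and 999.

## Known limitations

* The SES randomization scheme behind the trait nulls is a documented
  choice (pool-wide shuffle); alternative schemes can be plugged in but the
  abundance-shuffle reading of the source description is degenerate for GR.
* MPD/NRI are presence-based only; abundance-weighted MPD is not offered.
* Type-II tests are the only decomposition; sequential (Type-I) tables are
  verified equivalent on orthogonal designs in the test suite but not
  exposed.
* No spatial or phylogenetic autocorrelation structures in the GLMs.
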