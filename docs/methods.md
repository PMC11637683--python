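# Methods

`landla` simulates the evolution of local adaptation in a species whose
range spans a spatially heterogeneous selective environment, and measures
how the *spatial autocorrelation* of that environment shapes the strength,
variability and genetic architecture of the adaptation that evolves.  This
note records the model, the parameter choices, and the numerical and design
decisions behind the implementation.

## The model

**Landscape.**  The environment is a square grid of demes; deme *d* carries
a phenotypic optimum θ_d on [0, 1].  Landscapes are generated with the
midpoint-displacement (diamond–square) algorithm, whose roughness parameter
*h* scales the random displacement added at recursion level *l* by 2^(−lh).
Large *h* damps fine-scale noise and yields smooth, highly autocorrelated
surfaces; *h* ≤ 0 lets fine-scale noise dominate.  Each surface is min–max
rescaled to [0, 1] and rejected unless its mean lies in (0.4, 0.6), so the
distribution of optima is roughly equivalent across landscapes and only the
spatial arrangement differs.

Spatial autocorrelation is quantified with Moran's I under binary rook
adjacency (the 4 cardinal neighbours, weights 1, not row-standardized),
matching the migration topology of the simulator.  Because *h* has no
closed-form relation to Moran's I, a target I is reached in two stages:
bisection on *h* against the median achieved I of 5 probe surfaces, then
rejection sampling of surfaces until |I − target| ≤ tol (default 0.02,
1,000-attempt budget).  A map series spans targets evenly spaced over
[i_min, i_max] with spacing (i_max − i_min)/n_maps; the default series of
200 maps covers I from 0.05 to 0.95 in steps of 0.0045.  On small grids the
attainable ceiling drops — a perfectly linear gradient on a 7 × 7 grid has
I = 0.833 — so reduced-scale series stop at 0.85.

**Metapopulation.**  A 14 × 14 stepping-stone grid of demes, each holding
N = 100 diploids (19,600 in total), evolves with non-overlapping
Wright–Fisher generations: migration, then fitness-weighted reproduction
refilling every deme to exactly N offspring.  Both parents of an offspring
are drawn with replacement from the deme's post-migration pool with
probability proportional to fitness (selfing occurs at rate ~1/N, as in
standard Wright–Fisher practice).  The order migration-then-selection is a
fixed convention of this implementation.

**Migration.**  The migration rate *m* is interpreted *per deme pair*: an
individual emigrates across each of its deme's edges independently with
probability *m* (so an interior deme loses 4m of its residents per
generation, a corner deme 2m), and no migrant ever leaves the grid.  This is
the convention in which deme-pair migration rates are set in standard
Wright–Fisher metapopulation software, and it is the interpretation under
which the study's migration levels m = 0.07, 0.035, 0.0175 reproduce
population-wide neutral F_ST of about 0.02, 0.05 and 0.10 on the default
grid (the alternative reading — m as the total emigration probability split
among neighbours — gives F_ST roughly four times larger and is available as
`migration_mode="total"`).

**Selection.**  Fitness is Gaussian stabilizing selection toward the local
optimum: W = exp[−(α − θ_d)²/(2 V_s)] for one trait; with two traits the
squared deviations are summed and the exponent halved, making fitness the
average of the marginal log-fitnesses.  V_s (the width of the fitness
function; smaller = stronger selection) is a free parameter of the study
regimes, labelled only qualitatively in the source material.  Defaults:
V_s = 12.5 ("moderate", single-mutation selection coefficients weak
relative to drift at N = 100) and V_s = 2.5 ("strong").  With optima
confined to [0, 1], V_s = 2.5 bounds the home–away fitness differential at
1 − exp(−1/5) ≈ 0.18, which is resolvable above drift noise even in
reduced-scale runs; V_s = 12.5 bounds it at ≈ 0.04.

**Genetics.**  Each individual carries a continuous genome of length
L = 10 Mbp under the infinite-sites model.  Trait mutations arise at rate
μ = 10⁻¹⁰ per bp per gamete with effects drawn once from N(0, 1)
(independent across traits in the two-trait model) and act additively
(semidominant), giving a per-gamete mutational variance of
L·μ·E[γ²] = 0.001.  Crossovers occur at rate r = 10⁻⁷ per bp per meiosis at
uniform positions.  Genotypes are stored as a dense haplotype ×
polymorphism 0/1 matrix; lost mutations are dropped each generation and
mutations fixed metapopulation-wide are folded into a global phenotype
baseline (two copies per individual), which keeps the matrix small without
affecting any fitness difference.  Gamete assembly (crossover mosaic per
transmitted haplotype) is a compiled numba kernel; everything else is
vectorized numpy.  All randomness flows through one `numpy` Generator per
simulation, so a seed fully determines the outcome.

**Schedule.**  Metapopulations first evolve for 400 generations with θ = 0
everywhere (burn-in), then the optima switch to the landscape and evolution
continues for 100,000 generations, with the mean local adaptation logged at
a thinning interval to verify that it plateaus long before sampling.

## Statistics

**Home-vs-away local adaptation.**  Every individual's fitness is evaluated
at its home deme's optimum and at the optima of all other demes; its score
is home fitness minus the mean of the away fitnesses, and LA_d is the mean
score of deme *d*'s residents.  The landscape summaries are the mean of
LA_d over demes and its coefficient of variation (sd/mean, sample sd); the
CV is reported as undefined (NaN) when mean LA ≤ 0.

**Allele contributions (LA_rel).**  The contribution of polymorphism *l*
is measured by shuffling: its presence/absence vector over all 2N_total
haplotypes is permuted uniformly — erasing its covariance with the
landscape while preserving its global frequency, and hence its contribution
to range-wide additive variance — all phenotypes are recomputed, and mean
local adaptation is re-quantified as LA_l.  Then LA_rel,l = 1 − LA_l / LA.
Negative values mark locally maladaptive alleles; the values are not a
partition of 1 because stabilizing selection induces epistasis for fitness.
One shuffle per allele is the default (configurable); per-allele permutation
streams derive deterministically from a master seed.  Cumulative local
maladaptation — analogous to migration load — is the magnitude of the sum
of all negative LA_rel.  Locally adaptive alleles (LA_rel > 0) are classed
as large (> 0.10), intermediate (0.01–0.10) or small (< 0.01) contributors;
"proportion of LA explained" by a class divides its sum by the total over
positive alleles, a denominator this package fixes explicitly since the
classes must partition that total.

**Additive variance and heterogeneity.**  Per deme,
V_A,d = Σ 2 p_{i,d}(1 − p_{i,d}) γ_i² over segregating trait polymorphisms.
Local heterogeneity of an interior deme is the mean squared difference
between its optimum and those of its 4 cardinal neighbours; it is undefined
on the range edge.

**F_ST.**  Weir–Cockerham's θ from per-deme allele counts via the
variance-components (ANOVA) estimator for allele-count data, combining loci
as the ratio of summed components ("ratio of averages").  The neutral
calibration uses a frequency-based engine: per-deme frequencies of 200
unlinked biallelic loci are mixed each generation by the expected migration
matrix, nudged by symmetric per-allele mutation at 10⁻⁶ (which keeps loci
segregating indefinitely), and resampled binomially (2N draws per deme).
The run ends when multi-locus F_ST changes by < 1% between successive
1,000-generation windows.  This engine ignores linkage and hitchhiking —
appropriate for unlinked neutral markers — and equilibrates within a few
thousand generations.

**Allele ages.**  Age = sampling generation − origin generation.  The
effect-weighted mean age uses |γ| weights (robust to the occasional very
large squared effect; γ² is available by passing squared effects).

**Provenance trials.**  50 planting sites and 100 provenances are sampled
without replacement (independently, so a deme may serve as both).  The
fitness of a provenance at a site is the mean fitness of the provenance
deme's individuals at the site's optimum; environmental distance is
|θ_prov − θ_site|.  The transfer function is fitted as a linear mixed model
of fitness on distance with provenance-level random intercepts and slopes
(REML, via statsmodels); a two-stage fallback (per-provenance OLS, then
averaging) is used if the mixed fit fails and agrees in sign on well-posed
designs.  A negative fixed slope indicates local adaptation.

## Sweeps and reduced-scale runs

The pipeline executes a map series × migration × V_s × replicate grid; each
cell derives its seed from (master seed, map id, m, V_s, replicate), so
results are independent of execution order and any cell can be reproduced
alone.  Cell failures are logged and skipped.  Scatter summaries use
equal-width binned means with bootstrap confidence intervals rather than
LOESS — a plot-smoothing substitution, not a change of method.  Pooled
architecture contrasts ("high vs low autocorrelation") concatenate the
allele tables of the maps with the 50 highest and 50 lowest Moran's I in a
200-map series (quarter of the series at other sizes).

Full-scale simulations (196 demes × 100 diploids × 100,400 generations ×
200 maps) are expensive; the package therefore defines a `desk` preset used
by its own test suite: 7 × 7 grid, N = 50, 20 maps with I from 0.05 to
0.85, 200 burn-in + 2,500 main generations, 2–3 seeds per map, V_s = 2.5,
and a genome scaled down to L = 10⁵ bp with μ and r scaled up by the same
factor so the genome-wide totals (mutational variance L·μ·E[γ²] = 0.001 and
map length r·L = 1 crossover per gamete) are preserved.  Equilibration is
verified by the plateau of the logged LA trajectory rather than assumed.
At this scale the qualitative responses to spatial autocorrelation — mean
LA rising, its CV falling, cumulative maladaptation falling, allele ages
rising — are clearly detectable as rank correlations across maps.  Of the
allele-architecture contrast between weakly and highly autocorrelated
environments, the frequency half (adaptive alleles held at lower
frequencies under weak autocorrelation) is detectable as a rank test on
pooled allele tables, but the effect-size half (larger squared effects
under weak autocorrelation) is not reliably detectable at this scale: the
pools of locally adaptive alleles are dominated by young, rare mutations
whose effects are fresh draws from the same N(0, 1) in both pools, and the
selective sieve that retains only large-effect alleles against swamping
needs the full deme count and equilibration time to leave a marginal
signature.  The corresponding check is retained in the test suite at full
strictness and is expected to fail at reduced scale.

## What the generator does and does not emulate

The landscape module is the pipeline's synthetic-data stage.  It emulates
approximately normally distributed optima with controlled autocorrelation
and comparable means across maps; it does not emulate real climate rasters,
anisotropy, temporal environmental change, or geographic (great-circle)
distance metrics, and the simulator matches the granularity of dispersal to
that of the environment by construction.  Passing tests therefore
demonstrate the behaviour of the model under these idealized conditions,
not calibration to any empirical landscape or species.

## Numerical choices and limitations

- Positions (mutations and crossovers) are continuous uniform on [0, L);
  position collisions have probability zero (infinite sites).
- Moran's I raises on zero-variance grids; LA_rel raises when baseline mean
  LA is zero; F_ST raises when every locus is monomorphic or there are
  fewer than two demes; local heterogeneity raises on edge demes.  Degenerate
  inputs fail loudly rather than returning silent zeros.
- The midpoint-displacement calibration is stochastic; the bisection uses a
  median of 5 probes and 18 iterations, after which rejection sampling
  absorbs residual calibration error.  Roughness is searched on h ∈ [−2, 4],
  wide enough to cover the attainable I range at all supported sizes.
- The mean-LA trajectory is logged sparsely (default 50 points) to keep
  run-time dominated by the generation loop.
- Known limitations: no continuous-space dispersal, no dominance or
  epistatic mutation effects, no linkage-map structure, no tree-sequence
  recording (allele ages come from direct origin-time tracking), and the
  neutral F_ST engine treats loci as unlinked by construction.
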