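# Model and methods

`allochron` is an individual-based, forward-time simulator of allochronic
speciation, modelled on the corn and rice strains of the fall armyworm
(*Spodoptera frugiperda*): two sympatric populations of a nocturnal moth
that differ heritably in the time of night at which they mate.  The model
couples a mechanistic nightly mating market to a standard metapopulation
life cycle and asks under which conditions timing divergence survives.

## Life cycle

Generations are discrete and non-overlapping.  Each generation, in order:

1. **Migration.**  Each adult independently enters a migrant pool with
   probability `m` and is redistributed uniformly over accessible patches.
   Under the secondary-contact scenario the two halves of the
   metapopulation (corn-rich and rice-rich clusters of K/2 patches) keep
   separate pools until the contact generation.
2. **Settlement.**  Each female settles in her patch's corn habitat with
   probability `f_k` (otherwise rice) and will oviposit there.
3. **Mating season** (T nights; see below).
4. **Reproduction and soft selection.**  Exactly N juveniles per patch
   survive to adulthood, drawn by a weighted lottery with replacement:
   a uniformly chosen mated female and her clutch's sire produce a
   Mendelian offspring, accepted with probability proportional to

       S_k(tau, ell) = (1 - s_r)^(ell/2L) * (f_k/F_k) * exp(-c (tau - tau*_corn)^2)

   in the corn habitat (analogously with (1-f_k)/(1-F_k) and tau*_rice in
   rice), where `tau` is the offspring's juvenile timing, `ell` its number
   of sex-specifically regulated timing alleles, and `F_k` the realised
   corn fraction among settled females.  The f/F ratios implement
   within-habitat density dependence: expected recruitment through each
   habitat equals its frequency, regardless of settlement noise.

## Mating market

An adult's activity profile over the night (t in [0, 1]) is
`A(t; tau) = sqrt(Beta(t; 1 + a*tau, 1 + a*(1-tau)))`, normalised so that
`A^2` integrates to one; `a` sets profile narrowness.  A female i and
male j meet `Poisson(lambda_ij)` times per night with
`lambda_ij = eta * Int A(t; tau_i) A(t; tau_j) dt`, evaluated in closed
form via log-gamma identities; identically timed pairs meet `eta` times
per night on average.  Encounter times follow the normalised profile
product, a beta density centred on the pair's mean timing.  Encounters
are processed chronologically; a pair mates iff both are available.

Three systems govern availability.  Baseline (*S. frugiperda*): mating
occupies the rest of the night for both partners; mated females leave the
season, males return the next night.  Scramble: mating is instantaneous —
a female mates every male she meets in her night, one of whom (uniform)
sires the clutch.  Monogamy: as baseline but mated males also leave the
season.

Because a mating blocks both partners for the remainder of the night,
only each pair's *first* nightly encounter can change the outcome; the
implementation therefore samples per-pair first-encounter times (the
minimum of k beta variates, via the beta quantile function) instead of
all k events — an exact reduction, verified against an all-events
brute-force oracle in the test suite.  Within a set of pairs sharing one
encounter-time distribution only the order matters, so the quantile
transform is skipped there; pairs in disjoint components of the nightly
encounter graph are resolved independently.

## Genetics

Timing is encoded by L = 20 unlinked diploid loci with additive allelic
effects of ±delta, delta = 1/(4L), around 0.5, so phenotypes span [0, 1]
exactly.  Each allele also carries a cis-regulatory state: none, female-
limited, or male-limited; the regulated sex expresses the reversed sign
while juveniles and the other sex express the default.  Mutations per
allele per generation: allelic-state flips at `mu` (a flip replaces the
allele wholesale, reversing default and regulated sign together); with
regulatory evolution enabled, a further `2 mu` is split equally between
switch-on (to female- or male-limited, for unregulated alleles) and, for
regulated alleles, switch-off and default-reversal (which flips the
juvenile sign while leaving the adult pattern untouched).  The total
per-allele event rate is thus `3 mu` in every regulatory state.  The
exact partition within the `2 mu` regulatory budget is a design choice;
the total is the constraint the model fixes.  Twenty neutral diploid
loci (alleles 0/1, flipping at `mu`) track genome-wide differentiation;
founders are fixed for allele 0, so later differentiation reflects
accumulated isolation rather than initial conditions.

Founder genomes are deterministic: `round(2L*tau0)` plus alleles filled
homozygously locus by locus (one heterozygous locus if the count is odd),
no regulation.  Offspring sex is a fair coin.  The sqrt(N) patch-level
sex-ratio fluctuations this produces are not noise to be removed: males
re-enter the market nightly, so locally excess females are eventually
mated — by the earliest-active males, who accumulate extra clutches —
while under monogamy leftover risk falls on the locally excess sex of
either kind.  This asymmetry is the engine of directional sexual
selection for early male activity in the baseline system.  An
`exact_sex_balance` option removes the fluctuations (and with them most
sexual selection) as a control.

## Observables

- **rMF**: Pearson correlation of expressed adult timing between the
  partners of all matings in a census generation, pooled over patches.
- **Chronotype classes**: 1-D 2-means clustering of juvenile timing
  (10 restarts); the lower-centre cluster is "early".
- **FST**: Hudson's estimator between the early and late classes at the
  neutral panel, computed as a ratio of locus-summed components
  (Weir & Cockerham's theta available as an alternative).
- Per-context phenotype histograms (50 bins) and moments.

Undefined statistics (no matings, zero variance, monomorphic panel,
single cluster) are reported as missing rather than extrapolated.

## Parameters and defaults

K=100 patches, N=500 adults/patch, T=100 nights, eta=25, a=50, c=1,
tau*_corn=0, tau*_rice=1, s_r=0.05, m=0.01, L=20, mu=1e-5; corn-rich
patches have f_k=0.8, rice-rich 0.2.  Sympatric runs start monomorphic at
tau0=0.5; secondary-contact runs start the clusters at 0.1 / 0.9.

## Scaled-down presets

Full-scale runs (K*N = 50,000 individuals for thousands of generations)
are far beyond a desktop budget.  The `*-mini` presets shrink the
metapopulation (K=10, N=100) and the horizon (400 generations, contact at
generation 100) while preserving each scenario's parameter deltas.  Two
scaling choices matter and are deliberate:

- **Mutation rate.**  The mini presets raise `mu` so that the
  population-level mutational input per locus per generation, K*N*mu =
  0.5, matches the full-scale parameterisation (the standard rescaling
  for forward simulators).  At the paper-scale `mu` a mini population is
  mutation-limited and shows no evolutionary change on any feasible
  horizon.
- **Patch size and the monogamy contrast.**  Sexual selection from
  sex-ratio fluctuations scales like 1/sqrt(N) relative to ecological
  selection, so shrinking patches strengthens it artificially.  At N=100
  this residual overwhelms divergent selection even under monogamy,
  eroding the bimodality that the monogamous system is meant to retain;
  at N=500 (the standard per-patch size) monogamy retains separated
  chronotype clusters.  The mini presets keep N=100 for uniformity; the
  monogamy-retention comparison is therefore meaningful only at larger N,
  and is reported as such (see the test suite's documentation of this
  limit).  The grid preset (`fig3-mini`, K=4, N=50, 250 generations,
  contact at 50) is sized for many independent cells.

Passing mini-scale tests demonstrate that the implemented mechanisms
interact as described — collapse under first-male precedence, rescue by
sex-specific expression, no diversification without divergent selection,
FST eroded by migration — not that mini runs reproduce full-scale
quantitative values.

## Numerical choices

- Overlap integrals in log space (stable for a >= 100); lambda(tau, tau)
  reduces to eta exactly by construction.  Pair rates below 1e-12 are
  treated as zero.
- Additive phenotypes are computed as a single integer-sum division,
  `(2L + s)/(4L)`, so achievable values are exact floating-point
  rationals.
- The rejection sampler's bound is the larger habitat competition ratio
  (the cost and Gaussian factors never exceed one).
- Chronological ties in encounter times (measure zero) fall back to draw
  order, stable under a fixed seed.
- A patch whose season produces no mated female is left empty for that
  generation (refilled by migration) with a logged warning.
- Every generation draws from a child random stream of the root seed
  (`SeedSequence(seed, spawn_key=(generation,))`); grid cells derive
  independent root seeds from their coordinates, so cells are
  order-independent and runs are bit-reproducible for a fixed seed and
  package version.

## Limitations

- The synthetic scenarios explore the model's own dynamics; nothing here
  is fitted to field data, and real *S. frugiperda* populations add
  pheromone variation, seasonal structure, and non-equilibrium
  demography that the model abstracts away.
- Mini-scale runs inflate drift and fluctuation-driven sexual selection
  relative to full-scale runs, as discussed above.
- Habitat choice, hybrid-activity barriers, sex chromosomes, linkage and
  dominance are out of scope; the regulatory-mutation partition within
  the fixed 3*mu total is configurable rather than empirically anchored.
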