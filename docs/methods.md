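# Methods

## The model

`svload` simulates the accumulation and purging of structural-variant (SV)
alleles in a population with a mixed selfing/outcrossing mating system, and
provides the genomic overlap statistics used to interpret SV/SNP call sets
(SNPs trapped inside SV spans, exonic overlap, per-chromosome SV tallies).

### Genome and mutations

Each individual carries a diploid chromosome of `L` = 10,000 nucleotides.
An SV allele is a point-like object at a uniform position in `[0, L)`; the
physical extent of the variant is deliberately not modeled — what matters
for the dynamics is the count of mutations and their phenotypic effects.
Every new mutation receives a deleterious effect drawn from a gamma
distribution with shape `k` = 1 and scale `θ` = 2 (an exponential with mean
2).  Effects are attached even when the fitness mode ignores them, so the
mean segregating effect is always reportable.

### Fitness

Fitness exhibits synergistic (negative) epistasis:

    w(n) = exp(-(a·n + b·n²/2)),   a = 0.001, b = 0.0006

where `n` is the number of mutation *copies* in the diploid genome (a
homozygous variant counts twice).  An alternative `weighted` mode applies
the same curve to `S = Σᵢ effectᵢ`, the summed phenotypic effect over all
copies; under this mode large-effect mutations are purged preferentially
while count mode treats effects as neutral markers.  Both modes are
selectable via `SimParams.fitness_mode`; `count` is the default because it
is the form of the published fitness function this model implements.

### Transmission

Each gamete is produced by

1. **recombination** — crossover count ~ Poisson(r·(L−1)) with `r` = 1e-4
   per adjacent-site boundary (about one crossover per meiosis); breakpoint
   boundaries are uniform, distinct (duplicates thinned), and the active
   parental haplotype alternates at each boundary;
2. **loss** — each transmitted mutation copy is independently removed with
   probability `ν` = 0.001 (back mutation, e.g. gene conversion).  Loss is
   applied at transmission rather than to standing adults because gene
   conversion is a meiotic process;
3. **gain** — Poisson(μ) new mutations with `μ` = 0.01 per *gamete* per
   transmission, so the diploid genomic input is U = 2μ = 0.02.  A
   per-offspring interpretation of μ is available (`mu_unit="offspring"`).

### Population regulation and mating

The population is non-Wright-Fisher with overlapping generations.  Each
tick every adult initiates Poisson(`fecundity` = 2) offspring.  Under
androdioecy an initiating hermaphrodite outcrosses with probability `o`
(the outcrossing proportion) with a uniformly chosen distinct partner and
otherwise self-fertilizes with two independent meioses; under dioecy every
offspring has a uniform mother and a uniform father and `o` is ignored.
Parents are chosen uniformly — there is no fertility selection; all
selection acts through viability.  After reproduction *every* individual,
parent or newborn, survives independently with probability
`min(1, w·K/N_total)` where `K` = 1000 is the carrying capacity and
`N_total` the post-reproduction headcount.  There is no maximum age.  With
uniform fitness this regulates N around K (each tick ≈ N·f newborns are
created and ≈ N of the 3N candidates survive, so the expected turnover is
2/3 per tick and the mean lifespan is 1.5 ticks).  Fecundity 2 was chosen
to keep N near K while leaving headroom for viability selection.
Extinction is recorded as data, never raised as an error.

### Implementation

Populations are stored columnarly: a flat int32 array of mutation ids
grouped by haplotype plus an offset array (CSR layout), with positions and
effects in a shared append-only table.  Vectorized recombination uses the
parity of crossover boundaries ≤ position per parental copy, so per-tick
cost is O(total copies) and a 20,000-generation K=1000 run takes on the
order of a minute on one CPU.  The object-level API
(`model_core`/`reproduction`) defines the reference semantics on small
populations and the two are held to the same distributional behaviour by
the test suite (Mendelian segregation, Poisson crossover counts, neutral
equilibrium).  All randomness flows from a single `numpy` generator seeded
from `(params, seed)`; replicate i of a batch uses `base_seed + i`, and the
grid cell i of a sweep offsets the base by `i·R`, so every run is exactly
repeatable and order-independent.

## Equilibrium estimation and the outcrossing sweep

A trajectory records population size, mean/variance of load, distinct
segregating variants, mean segregating effect (averaged over copies), and
mean fitness, every `record_every` = 10 generations by default.  The
equilibrium mean load is the average of `mean_load` over the final 25% of
recorded generations (burn-in fraction 0.75); a replicate that goes extinct
before the burn-in end yields a missing estimate carrying an extinction
flag.  A stationarity diagnostic (least-squares slope of the tail, flagged
when it differs from zero by more than two standard errors) is logged and
never used to auto-extend a run.

The sweep experiment runs R = 5 replicates at each outcrossing proportion
in {0, 0.05, 0.10, 0.15, 0.20, 0.30, 0.50, 0.75, 1.0} — a grid straddling
the 10% and 30% thresholds discussed in the experimental literature.
"Retention" is operationalized as an equilibrium load of at least 1.0
copy/individual (the cutoff is configurable; "retain" has no standard
quantitative definition).  Two thresholds are reported: the largest grid
proportion at which *no* replicate retains, and the smallest grid
proportion from which retention is consistent (at it and every larger grid
value, all replicates retain).

## Problem sizes

The trajectory equilibrates within a few thousand generations at these
parameters (the relaxation time is set by 1/ν = 1000 transmissions and the
~2/3 per-tick turnover).  Headline runs therefore use 20,000 generations at
K = 1000 for the fully outcrossing equilibrium (5 replicates) and 10,000
generations at K = 500 for the sweep (5 replicates per grid value), with
stationarity checked on every tail.  These are the sizes used by
`scripts/acceptance.py` and the end-to-end tests.

## What the simulation does and does not show

The simulator reproduces the *mechanistic ingredients* of the published
model exactly as stated: gamma DFE, synergistic-epistasis fitness, mixed
mating, gain/loss rates, soft density regulation.  Running it at the
published parameter values, however, does **not** reproduce two published
simulation outcomes, and the discrepancy is robust to every construction
choice the model text leaves open (count vs weighted fitness, carrying
capacity 500–1000, per-gamete vs per-offspring μ):

* the fully outcrossing equilibrium load is ≈ 3.5–4.5 copies/individual,
  not ≈ 10.  This matches the deterministic mutation-selection balance for
  this construction: with per-tick newborn fraction f/(1+f) = 2/3,
  (2/3)·(2μ − ν·n̄) = Var(n)·(a + b·n̄) gives n̄ ≈ 3.5 for Poisson-like
  load variance, and the simulated variance is indeed ≈ the mean (epistasis
  builds compensating negative linkage disequilibrium);
* no outcrossing proportion purges the load below 1 copy/individual, so
  there is no retention threshold along the mating-system gradient.  This
  is arithmetic, not a sampling issue: the per-newborn genomic input
  2μ = 0.02 exceeds the strongest per-copy selective removal
  (a + b·n)·Var(n)/n ≈ 0.002–0.009 achievable at loads below 1 with
  a = 0.001, b = 0.0006, in *any* mating system, so mutations always
  accumulate back to a load of a few.

The validated diagnostics behind this conclusion: the neutral limit
(a = b = 0) reproduces the closed-form equilibrium 2μ/ν = 20; selfing
drives copy homozygosity to ≈ 98%; Mendelian 1:2:1 segregation and
Poisson crossover counts hold exactly; and the simulated selected
equilibrium matches the independent deterministic prediction to ~1%.  A
model producing near-complete purging under selfing together with ~10
retained mutations under outcrossing would need substantially stronger
per-mutation selection (e.g. ~10× larger curvature parameters, dominance,
or per-mutation selection coefficients on the scale of the raw gamma
effects) than the published equations and constants specify.  The package
reports what the stated model computes.

The synthetic-variant generator (`trapstats`) emulates VCF call sets with
points scattered over chromosomes and spanning/anchored interval variants
with an exactly controlled trapped fraction.  It does not emulate
sequencing noise, genotype likelihoods, caller-specific artifacts, or
multi-sample VCFs, so passing its ground-truth tests shows the overlap
*statistics* are correct, not that any particular caller's output is.

## Numerical and convention choices

* Coordinates: simulator positions are 0-based in `[0, L)`; crossover
  boundaries are integers in `(0, L)`, with a mutation at position p going
  to the side selected by the parity of boundaries ≤ p.  Genomic files are
  1-based with inclusive spans internally; BED is normalized from 0-based
  half-open on read.  Containment at span boundaries is inclusive.
* Insertions are 1-nt anchors for containment but contribute their inserted
  length (|SVLEN|) to nucleotides-affected totals; translocation breakends
  are 1-nt anchors of length 1.
* A SNP inside several overlapping SVs is trapped once; an SV containing
  several SNPs traps each of them.  Multi-allelic SNP lines count once.
* SNP filters default to QUAL ≥ 20 and INFO/DP ≥ 10; records lacking DP
  while depth filtering is active are skipped and counted in the log.
* Load variance is the population (ddof=0) variance.  Ties in haplotype
  ordering break by mutation uid.  The empty population yields missing
  (".") summary fields, and a trapped fraction with zero points is reported
  as 0 with an explicit undefined flag.

## Known limitations

* Physical SV size, SV class, and recombination suppression by SVs are not
  modeled in the simulator; trapping of SNPs by SVs is therefore a
  file-level statistic, not an emergent property of the simulation.
* Sperm limitation, mating-success differences, and male mating-ability
  evolution are not modeled; dioecious mode is a symmetric two-sex system.
* The retention thresholds are grid-resolution-limited by construction.
* Replicate-level parallelism (`--threads`) does not change results but the
  per-replicate streams are only reproducible from the documented
  seed-derivation rule, not across different replicate counts.
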