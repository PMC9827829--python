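# Methods

## Model

`traitlink` simulates discrete, non-overlapping generations of a diploid
population split over two habitats.  Genomes are a single pair of
homologous chromosomes of `L` loci; locus 0 carries the ecological trait
alleles A / A′ (codominant, three phenotypes), and loci `1..L-1` start in
an inert wild-type state and change only by mutation into
preference-for-AA, preference-for-A′A′, or explicitly neutral marker
states.  The trait locus is a "magic trait": it is both the target of
divergent viability selection (habitat 1 favours AA, habitat 2 favours
A′A′; all other phenotype–habitat combinations die with probability `s`
per generation, heterozygotes scaled by `het_selection_rel`) and the cue
used in mate choice.

Mate choice is by females.  A female's preference score `d` is the count
of preference-for-AA alleles minus preference-for-A′A′ alleles over both
chromosomes.  She accepts an AA male with probability
`1 / (1 + exp(-d * pf))`, an A′A′ male with the complement, and a
heterozygote male with the constant `het_mate_prob` (0.5).  Females take
turns in a fresh random order; each is paired with up to `max_pairings`
(10) males drawn uniformly — with replacement across her attempts — from
the unmated male pool of **both** habitats; an accepted male leaves the
pool (strict monogamy), and a female who exhausts her attempts does not
reproduce.  Each pair leaves four offspring (two of each sex) in the
mother's habitat, the parents die, each offspring inherits one uniformly
chosen chromosome from each parent, then undergoes `n_crossovers` (1)
uniform tail-swap crossovers and, with probability `mut_fraction` (1 %),
one mutation at a uniform non-trait locus on a uniform homolog, the new
state uniform over the three mutant types (overwriting the old state, so
back mutation exists).  After selection each habitat is culled uniformly
at random to `K` (5000).

### Assumptions worth stating

- Habitats are non-spatial; males are globally available during mate
  choice only, so gene flow between habitats is maximal.
- A rejected male returns to the pool and may be redrawn, even by the
  same female; this makes each of her pairings an independent trial.
- The female's own phenotype never enters the acceptance function —
  only her preference score; heterozygote females choose by the same rule.
- Offspring sexes are fixed at an even split, not Bernoulli.
- Selection is an independent Bernoulli death per maladapted individual,
  not deterministic culling of a fixed fraction.

## The mutation-rate anchor

The model's mutation regime is stated as "one percent of individuals per
generation, one locus each", equivalent to a per-locus rate of
`mut_fraction / (2 L)` = 5×10⁻⁵ per individual per generation.  Because
mutation acts on the offspring pool (~20 000 at defaults) rather than the
regulated population (10 000), "one percent" and "a fixed 100
individuals" differ by a factor of two in effective supply.  The package
defaults to the rate reading (`mut_anchor="pool"`: 1 % of the current
pool), which keeps the per-individual mutation probability — and the
5×10⁻⁵ per-locus rate — invariant to pool size and reproduces the
model's characteristic timescales; `mut_anchor="nominal"` provides the
fixed-count variant (`floor(mut_fraction * 2K)` per generation) for
comparison.  At the nominal population of 10 000 the two coincide at
exactly 100 mutated individuals per generation.

## Parameters

| name | default | units / meaning |
|---|---|---|
| `s` | 0.5 | death probability of a maladapted phenotype per generation; 0.5–0.8 keeps both homozygotes stably coexisting, lower or higher risks collapse of one phenotype |
| `pf` | 0.3 | logistic slope of mate acceptance per net preference allele; 2.4 makes a single allele excess give >0.9 acceptance |
| `K` | 5000 | carrying capacity per habitat |
| `L` | 100 | loci per chromosome (locus 0 = trait) |
| `mut_fraction` | 0.01 | fraction of individuals mutated per generation (= per-locus rate 5×10⁻⁵ at L=100) |
| `mut_anchor` | `"pool"` | what the fraction applies to (see above) |
| `max_pairings` | 10 | pairing attempts per female; caps the cost of choosiness |
| `n_offspring` | 4 | brood size per pair (2+2 by sex); keeps the pool above K before selection |
| `n_crossovers` | 1 | crossovers per offspring; 0 = no-recombination control |
| `het_mate_prob` | 0.5 | acceptance of heterozygote males |
| `het_selection_rel` | 1.0 | selection on heterozygotes relative to maladapted homozygotes |
| `generations` | 3000 | run length; assortment saturates well before this at all grid points |
| `seed` | 0 | seed of the single `numpy.random.Generator` driving a run |

## Measurements

- **Average preference distance**: per individual, the mean position of
  loci of one type (preference-for-AA, preference-for-A′A′, or neutral)
  over both chromosomes; averaged over individuals of a phenotype class
  (AA and A′A′ classes are reported; heterozygotes excluded).  Distance
  equals position index because the trait locus sits at position 0 and
  the adjacent locus at distance 1.  Uniformly placed loci have expected
  distance 50 at L=100 — the neutral null.  Per-type and pooled
  (`pref_any`) variants are available; individuals with no qualifying
  locus are excluded, and an empty class yields an explicit missing
  value (`NA` in TSV).
- **Matching-pair proportion**: fraction of realized mating pairs whose
  partners share a phenotype (all three phenotypes count, including
  heterozygote × heterozygote).
- **Preference loci per chromosome**: preference-type loci (both kinds)
  per chromosome, averaged over all `2n` chromosomes.
- **Position histogram**: per-position counts of preference loci,
  chromosomes classed by their own trait allele.
- **Sweep layer**: per (s, pf) combination the per-generation metric
  series is averaged over replicates; the minimum of the mean distance
  series over the run ("minimum average distance") measures realized
  physical linkage.  Combination-level minima are regressed on s and pf
  (OLS via statsmodels; partial F-tests, one observation per combination
  so 16 points give residual df 13, and df 12 with the s×pf
  interaction).  Replicate-level statistics at a focal generation feed a
  Pearson correlation between linkage and assortment
  (`scipy.stats.pearsonr`; df = n−2).

## Numerical and design choices

- All randomness flows from one seeded `numpy.random.Generator` per
  simulation; replicate `r` uses `base_seed + r`, and sweep combinations
  use disjoint seed blocks.  Reruns are bit-identical.
- The sequential mate-choice loop and the crossover tail swaps are numba
  kernels; the choice kernel consumes pre-drawn uniforms (a male index
  and an acceptance draw per pairing attempt) so the sequential logic
  stays deterministic and fast.  Unmated males are held in a swap-remove
  array, making each draw O(1).
- The logistic acceptance uses `scipy.special.expit`, which saturates to
  exact 0/1 for large `|d·pf|` instead of overflowing; the complement is
  computed as `1 - P_A` so the two probabilities sum to 1 exactly.
- Per-generation metrics use a single-pass kernel that tallies, per
  individual, count and position-sum of each mutant state; the readable
  numpy implementation (`avg_pref_distance`) is retained and the two are
  asserted equal in tests.
- Ties in the minimum of a distance series resolve to the earliest
  generation; missing entries (class or type absent) are skipped.
- Extinction (an emptied habitat, or no pair formed) terminates a run
  and is recorded; extinct replicates are excluded from replicate means
  with a warning.
- `min_avg_distance` on a truncated horizon equals the full-run value
  whenever the horizon covers the dip, since the series rises after it.

## What the generator emulates — and what it does not

The simulator *is* the study object here (no external data): runs are at
the stated study conditions (K = 5000, L = 100, the s × pf grid, 20–30
replicates) unless a test scales them down.  The model abstracts away
spatial structure, unequal migration, variable brood sizes, polygamy,
costs of choosiness beyond the pairing cap, and any real genetic map
(loci are evenly spaced; one crossover per meiosis).  Passing tests
therefore show the model's internal logic and statistics are right, not
that real genomes evolve linkage at these rates.

## Problem sizes in the shipped checks

Replicate counts and horizons in the test suite and in
`scripts/acceptance.py` are the package's own scaled study design: the
assortment-timing checks use 5–20 replicates (study: 20) on horizons
that cover the documented crossings; the correlation experiment uses
20–25 replicates (study: 30) to generation 700; the grid sweep runs 5
replicates per combination at K = 2000 to generation 1500, a scale at
which both homozygote phenotypes remain stably coexisting across the
whole grid (at K ≤ 1000 the high-s corner collapses too often for the
combination means to be meaningful).  The no-recombination example run
is full-size.

## Known limitations

- At small K (≲1000) drift destabilizes phenotype coexistence at the
  edges of the s grid; extinct replicates are excluded from means, which
  biases combination statistics if extinction is common.  Use K ≥ 2000
  for grid work.
- In the no-recombination control, assortment saturates earlier than
  with recombination, and the preference-locus count at a fixed early
  generation is correspondingly lower than in the matching
  recombination run (the count keeps growing roughly linearly after
  assortment is complete).
- The per-generation metrics cost one pass over the population per
  generation; recording can be thinned for very long runs if needed.
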