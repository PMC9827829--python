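"""One generation of the model, and multi-generation runs.

Each generation executes five stages in fixed order:

1. mate-pair formation (female choice via a logistic preference function),
2. reproduction (four offspring per pair, parents die),
3. offspring recombination and mutation,
4. ecological viability selection against locally maladapted phenotypes,
5. density-dependent regulation to the per-habitat carrying capacity.

Generations are discrete and non-overlapping.  All randomness flows from a
single ``numpy.random.Generator`` so a run is bit-reproducible from its
seed.  The only sequential part — females choosing one after another from
a shrinking pool of unmated males — is compiled with numba; every random
number it consumes is drawn from the generator up front.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.special import expit

from .core import (
    FEMALE,
    H1,
    H2,
    MALE,
    NEUTRAL,
    PHEN_AA,
    PHEN_APAP,
    PHEN_HET,
    PHENOTYPE_LABELS,
    PREF_A,
    PREF_APRIME,
    ExtinctionError,
    Individual,
    ModelParams,
    Population,
    initialize_population,
)
from . import metrics as _metrics


@dataclass
class MatingRecord:
    """Realized matings of one generation.

    Indices refer to the parent population the record was formed from.
    Monogamy holds: every individual appears at most once.
    """

    female_idx: np.ndarray
    male_idx: np.ndarray
    female_phen: np.ndarray
    male_phen: np.ndarray

    @property
    def n_pairs(self) -> int:
        return len(self.female_idx)

    def __len__(self) -> int:
        return self.n_pairs

    @classmethod
    def empty(cls) -> "MatingRecord":
        z = np.empty(0, dtype=np.int64)
        return cls(z, z.copy(), z.copy(), z.copy())


# --- preference scoring and the acceptance function -------------------------

def preference_scores(pop: Population) -> np.ndarray:
    """Preference score d for every individual.

    d = (# preference-for-AA alleles) - (# preference-for-A'A' alleles),
    counted over both chromosomes at positions 1..L-1.
    """
    sites = pop.genomes[:, :, 1:]
    return (
        (sites == PREF_A).sum(axis=(1, 2)).astype(np.int64)
        - (sites == PREF_APRIME).sum(axis=(1, 2)).astype(np.int64)
    )


def preference_score(individual: Individual) -> int:
    """Preference score d of a single individual."""
    sites = np.stack([individual.chrom1[1:], individual.chrom2[1:]])
    return int((sites == PREF_A).sum()) - int((sites == PREF_APRIME).sum())


def mate_probability(
    d: float,
    pf: float,
    male_phenotype: int | str,
    het_mate_prob: float = 0.5,
) -> float:
    """Probability that a female with preference score ``d`` accepts a male.

    For an AA male the probability is the logistic ``1 / (1 + exp(-d * pf))``;
    for an A'A' male its complement; for a heterozygote male the constant
    ``het_mate_prob``, independent of d.  Numerically saturates to 0/1 for
    large ``|d * pf|``.
    """
    if pf < 0:
        raise ValueError("pf must be >= 0")
    if isinstance(male_phenotype, str):
        male_phenotype = PHENOTYPE_LABELS.index(male_phenotype)
    p_a = float(expit(d * pf))
    if male_phenotype == PHEN_AA:
        return p_a
    if male_phenotype == PHEN_HET:
        return float(het_mate_prob)
    if male_phenotype == PHEN_APAP:
        return 1.0 - p_a
    raise ValueError(f"invalid male phenotype {male_phenotype}")


@njit(cache=True)
def _pairing_kernel(
    female_order,
    p_accept_aa,
    male_pool,
    phen,
    u_draw,
    u_accept,
    max_pairings,
    het_prob,
    out_female,
    out_male,
):  # pragma: no cover - exercised through form_mating_pairs
    n_pool = male_pool.shape[0]
    n_pairs = 0
    for i in range(female_order.shape[0]):
        if n_pool == 0:
            break
        f = female_order[i]
        base = i * max_pairings
        for t in range(max_pairings):
            if n_pool == 0:
                break
            j = int(u_draw[base + t] * n_pool)
            if j >= n_pool:
                j = n_pool - 1
            m = male_pool[j]
            g = phen[m]
            if g == 0:
                p = p_accept_aa[f]
            elif g == 1:
                p = het_prob
            else:
                p = 1.0 - p_accept_aa[f]
            if u_accept[base + t] < p:
                out_female[n_pairs] = f
                out_male[n_pairs] = m
                n_pairs += 1
                male_pool[j] = male_pool[n_pool - 1]
                n_pool -= 1
                break
    return n_pairs


def form_mating_pairs(
    pop: Population, params: ModelParams, rng: np.random.Generator
) -> MatingRecord:
    """Form monogamous mating pairs by sequential female choice.

    Females take turns in a fresh random order.  Each is paired with up to
    ``max_pairings`` males drawn uniformly (with replacement across her
    attempts) from the current unmated male pool of both habitats, and
    accepts each with :func:`mate_probability`.  An accepted male leaves
    the pool; a female who exhausts her attempts does not reproduce.
    """
    females = np.flatnonzero(pop.sex == FEMALE)
    males = np.flatnonzero(pop.sex == MALE).astype(np.int64)
    if len(females) == 0 or len(males) == 0:
        return MatingRecord.empty()

    phen = pop.phenotypes()
    p_accept_aa = expit(preference_scores(pop) * params.pf)

    order = rng.permutation(females).astype(np.int64)
    n_draws = len(females) * params.max_pairings
    u_draw = rng.random(n_draws)
    u_accept = rng.random(n_draws)

    cap = min(len(females), len(males))
    out_f = np.empty(cap, dtype=np.int64)
    out_m = np.empty(cap, dtype=np.int64)
    n_pairs = _pairing_kernel(
        order,
        p_accept_aa,
        males.copy(),
        phen,
        u_draw,
        u_accept,
        params.max_pairings,
        float(params.het_mate_prob),
        out_f,
        out_m,
    )
    f = out_f[:n_pairs].copy()
    m = out_m[:n_pairs].copy()
    return MatingRecord(f, m, phen[f], phen[m])


# --- reproduction, recombination, mutation, selection, regulation -----------

def reproduce(
    record: MatingRecord,
    pop: Population,
    params: ModelParams,
    rng: np.random.Generator,
) -> Population:
    """Produce the offspring pool; the parent generation dies.

    Each pair contributes ``n_offspring`` offspring with sexes fixed at an
    even split (female first when odd; 4 offspring = 2 + 2).  Every
    offspring receives one uniformly chosen chromosome from each parent,
    independently per offspring, and inherits its mother's habitat.
    """
    n_off = params.n_offspring
    n_pairs = record.n_pairs
    if n_pairs == 0:
        return Population(
            genomes=np.empty((0, 2, pop.L), dtype=np.uint8),
            sex=np.empty(0, dtype=np.uint8),
            habitat=np.empty(0, dtype=np.uint8),
            generation=pop.generation,
        )
    m = n_pairs * n_off
    mothers = np.repeat(record.female_idx, n_off)
    fathers = np.repeat(record.male_idx, n_off)
    mat_choice = rng.integers(0, 2, size=m)
    pat_choice = rng.integers(0, 2, size=m)
    genomes = np.empty((m, 2, pop.L), dtype=np.uint8)
    genomes[:, 0, :] = pop.genomes[mothers, mat_choice, :]
    genomes[:, 1, :] = pop.genomes[fathers, pat_choice, :]
    sex = np.tile((np.arange(n_off) % 2).astype(np.uint8), n_pairs)
    habitat = np.repeat(pop.habitat[record.female_idx], n_off)
    return Population(genomes=genomes, sex=sex, habitat=habitat, generation=pop.generation)


@njit(cache=True)
def _recombine_kernel(genomes, cuts):  # pragma: no cover - via recombine_offspring
    n, k = cuts.shape
    L = genomes.shape[2]
    for i in range(n):
        for j in range(k):
            for p in range(cuts[i, j], L):
                tmp = genomes[i, 0, p]
                genomes[i, 0, p] = genomes[i, 1, p]
                genomes[i, 1, p] = tmp


def recombine_offspring(
    pool: Population, params: ModelParams, rng: np.random.Generator
) -> Population:
    """Apply ``n_crossovers`` tail-swap crossovers to every offspring genome.

    Each breakpoint is drawn uniformly from the ``L - 1`` inter-locus gaps
    and the chromosome content strictly after it is exchanged between the
    two homologs; multiple crossovers compose as sequential independent
    tail swaps.  The per-locus allele pair of each individual is
    unchanged, so recombination never alters genotype or preference score.
    With ``n_crossovers = 0`` the pool is returned untouched.
    """
    k = params.n_crossovers
    n, L = pool.n, pool.L
    if k == 0 or n == 0:
        return pool
    cuts = rng.integers(1, L, size=(n, k))
    _recombine_kernel(pool.genomes, cuts)
    return pool


def mutate_offspring(
    pool: Population, params: ModelParams, rng: np.random.Generator
) -> Population:
    """Mutate one locus in each of a fraction of the offspring.

    ``floor(mut_fraction * pool_size)`` individuals (or a fixed
    ``floor(mut_fraction * 2K)`` when ``mut_anchor='nominal'``) are drawn
    without replacement; each
    receives one mutation at a uniform position in 1..L-1 on a uniformly
    chosen homolog.  The new state is uniform over {preference-for-AA,
    preference-for-A'A', neutral} and overwrites whatever was there, so
    repeat hits and back mutations are possible.  The trait locus is never
    mutated.
    """
    if params.mut_anchor == "nominal":
        n_mut = params.n_mutants
    else:
        n_mut = int(np.floor(params.mut_fraction * pool.n))
    if n_mut == 0:
        return pool
    if n_mut > pool.n:
        raise ValueError(
            f"cannot mutate {n_mut} individuals in a pool of {pool.n}"
        )
    idx = rng.choice(pool.n, size=n_mut, replace=False)
    hom = rng.integers(0, 2, size=n_mut)
    pos = rng.integers(1, pool.L, size=n_mut)
    state = rng.integers(PREF_A, NEUTRAL + 1, size=n_mut).astype(np.uint8)
    pool.genomes[idx, hom, pos] = state
    return pool


def apply_selection(
    pool: Population, params: ModelParams, rng: np.random.Generator
) -> Population:
    """Ecological viability selection.

    AA in habitat 1 and A'A' in habitat 2 always survive.  Every other
    (phenotype, habitat) combination dies independently with probability
    ``s`` (heterozygotes with ``s * het_selection_rel``).
    """
    if pool.n == 0:
        return pool
    phen = pool.phenotypes()
    adapted = ((phen == PHEN_AA) & (pool.habitat == H1)) | (
        (phen == PHEN_APAP) & (pool.habitat == H2)
    )
    p_death = np.where(
        adapted, 0.0, np.where(phen == PHEN_HET, params.s * params.het_selection_rel, params.s)
    )
    keep = rng.random(pool.n) >= p_death
    return pool.subset(keep)


def regulate_density(
    pool: Population, params: ModelParams, rng: np.random.Generator
) -> Population:
    """Cull each habitat uniformly at random down to the carrying capacity."""
    keep_parts = []
    over = False
    for hab in (H1, H2):
        idx = np.flatnonzero(pool.habitat == hab)
        if len(idx) > params.K:
            idx = rng.permutation(idx)[: params.K]
            over = True
        keep_parts.append(idx)
    if not over:
        return pool
    keep = np.sort(np.concatenate(keep_parts))
    return pool.subset(keep)


# --- generation step and full runs ------------------------------------------

def step_generation(
    pop: Population, params: ModelParams, rng: np.random.Generator
) -> tuple[Population, MatingRecord]:
    """Advance the population by one generation (the five stages in order)."""
    record = form_mating_pairs(pop, params, rng)
    if record.n_pairs == 0:
        raise ExtinctionError(pop.generation + 1, "no mating pairs formed")
    pool = reproduce(record, pop, params, rng)
    pool = recombine_offspring(pool, params, rng)
    pool = mutate_offspring(pool, params, rng)
    pool = apply_selection(pool, params, rng)
    pool = regulate_density(pool, params, rng)
    n1, n2 = pool.habitat_counts()
    if n1 == 0 or n2 == 0:
        raise ExtinctionError(pop.generation + 1, "habitat emptied")
    pool.generation = pop.generation + 1
    return pool, record


@dataclass
class SimulationResult:
    """Outcome of a multi-generation run.

    ``metrics`` holds one row per recorded generation (see
    :mod:`traitlink.metrics` for column definitions).  ``snapshots`` maps a
    generation number to a full copy of the population at that generation.
    ``extinct_at`` is the generation at which the population went extinct,
    or ``None`` if it survived the whole run.
    """

    params: ModelParams
    metrics: "object"  # pandas.DataFrame
    snapshots: dict = field(default_factory=dict)
    final_population: Population | None = None
    extinct_at: int | None = None


def run_simulation(
    params: ModelParams,
    rng: np.random.Generator | None = None,
    snapshot_generations: tuple[int, ...] = (),
    keep_final: bool = False,
) -> SimulationResult:
    """Run ``params.generations`` generations, recording metrics each one.

    Generation 0 is the initial population (its mating-pair columns are
    missing).  Extinction terminates the run early and is reported through
    ``extinct_at`` rather than raised.
    """
    import pandas as pd

    if rng is None:
        rng = np.random.default_rng(params.seed)
    snap_set = set(int(g) for g in snapshot_generations)
    pop = initialize_population(params, rng)
    rows = [_metrics.generation_metrics(pop, None)]
    snapshots: dict[int, Population] = {}
    if 0 in snap_set:
        snapshots[0] = pop.copy()
    extinct_at = None
    for _ in range(params.generations):
        try:
            pop, record = step_generation(pop, params, rng)
        except ExtinctionError as err:
            warnings.warn(str(err), stacklevel=2)
            extinct_at = err.generation
            break
        rows.append(_metrics.generation_metrics(pop, record))
        if pop.generation in snap_set:
            snapshots[pop.generation] = pop.copy()
    metrics = pd.DataFrame(rows).set_index("generation")
    return SimulationResult(
        params=params,
        metrics=metrics,
        snapshots=snapshots,
        final_population=pop if keep_final else None,
        extinct_at=extinct_at,
    )
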