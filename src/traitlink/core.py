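"""Core state: genomes, individuals, populations, and model parameters.

The simulated organism is diploid with a single pair of homologous
chromosomes of ``L`` loci (default 100).  Locus 0 is the ecological trait
locus — a "magic trait" that is both the target of divergent selection and
the mating cue.  It carries one of two codominant alleles, ``A`` or ``A'``,
so the three trait genotypes map onto three phenotypes (AA, AA', A'A').
The remaining ``L - 1`` loci start in an inert wild-type state and can be
hit by mutations that turn them into preference loci (preference for AA or
for A'A' mates) or explicitly neutral marker loci.

Genomes are stored as a single ``(n, 2, L)`` uint8 array per population.
Column 0 is interpreted in the trait-allele alphabet, columns ``1..L-1``
in the preference/neutral alphabet; the two code spaces deliberately reuse
small integers, so all per-locus statistics slice column 0 away first.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

# --- allele codes -----------------------------------------------------------
# trait locus (column 0)
ALLELE_A = 0
ALLELE_APRIME = 1
# non-trait loci (columns 1..L-1)
WILD = 0
PREF_A = 1
PREF_APRIME = 2
NEUTRAL = 3

# sexes and habitats
FEMALE = 0
MALE = 1
H1 = 0
H2 = 1

# trait phenotypes (sum of the two trait alleles)
PHEN_AA = 0
PHEN_HET = 1
PHEN_APAP = 2
PHENOTYPE_LABELS = ("AA", "AA'", "A'A'")

# text codes used by the snapshot format (see traitlink.io)
TRAIT_CHARS = {ALLELE_A: "A", ALLELE_APRIME: "B"}
SITE_CHARS = {WILD: "w", PREF_A: "p", PREF_APRIME: "q", NEUTRAL: "n"}


class ExtinctionError(RuntimeError):
    """Raised when a habitat empties or no mating pair can form."""

    def __init__(self, generation: int, message: str = "population extinct"):
        super().__init__(f"{message} at generation {generation}")
        self.generation = generation


@dataclass(frozen=True)
class ModelParams:
    """All free parameters of the model.

    Parameters
    ----------
    s
        Selection coefficient: per-generation death probability of an
        individual whose phenotype is maladapted in its habitat.
    pf
        Preference strength factor, the slope of the logistic mate
        acceptance function.  Larger values mean each additional
        preference allele shifts acceptance more strongly.
    K
        Carrying capacity per habitat (population is regulated to at most
        ``K`` individuals per habitat each generation).
    L
        Number of loci per chromosome, including the trait locus at
        position 0.
    mut_fraction
        Fraction of individuals receiving exactly one mutation per
        generation.  The default 0.01 corresponds to a per-locus mutation
        rate of ``mut_fraction / (2 L)`` = 5e-5 per individual per
        generation at L = 100, i.e. 100 mutated individuals per nominal
        population of 10 000.
    mut_anchor
        ``"pool"`` (default) mutates ``floor(mut_fraction * pool_size)``
        individuals of the current offspring pool, keeping the
        per-individual mutation probability at ``mut_fraction`` regardless
        of pool size; ``"nominal"`` mutates a fixed
        ``floor(mut_fraction * 2K)`` individuals per generation instead.
    max_pairings
        Maximum number of males a female is sequentially paired with
        before she forgoes reproduction.
    n_offspring
        Offspring per mating pair, with sexes fixed half female, half male
        (female first when odd).
    n_crossovers
        Crossover points per offspring genome; 0 disables recombination
        (the no-recombination control).
    het_mate_prob
        Constant acceptance probability for heterozygote (AA') males.
    het_selection_rel
        Selection strength against heterozygotes relative to the
        non-locally-adapted homozygote (1.0 = equally maladapted).
    generations
        Number of generations a simulation runs.
    seed
        Seed for the simulation's random generator.
    """

    s: float = 0.5
    pf: float = 0.3
    K: int = 5000
    L: int = 100
    mut_fraction: float = 0.01
    mut_anchor: str = "pool"
    max_pairings: int = 10
    n_offspring: int = 4
    n_crossovers: int = 1
    het_mate_prob: float = 0.5
    het_selection_rel: float = 1.0
    generations: int = 3000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.s <= 1.0:
            raise ValueError(f"s must be in [0, 1], got {self.s}")
        if self.pf < 0:
            raise ValueError(f"pf must be >= 0, got {self.pf}")
        if self.K < 2 or self.K % 2 != 0:
            raise ValueError(f"K must be a positive even integer, got {self.K}")
        if self.L < 2:
            raise ValueError(f"L must be >= 2, got {self.L}")
        if not 0.0 <= self.mut_fraction <= 1.0:
            raise ValueError(f"mut_fraction must be in [0, 1], got {self.mut_fraction}")
        if self.mut_anchor not in ("nominal", "pool"):
            raise ValueError(f"mut_anchor must be 'nominal' or 'pool', got {self.mut_anchor!r}")
        if self.max_pairings < 1:
            raise ValueError("max_pairings must be >= 1")
        if self.n_offspring < 1:
            raise ValueError("n_offspring must be >= 1")
        if self.n_crossovers < 0:
            raise ValueError("n_crossovers must be >= 0")
        if not 0.0 <= self.het_mate_prob <= 1.0:
            raise ValueError("het_mate_prob must be in [0, 1]")
        if self.het_selection_rel < 0 or self.s * self.het_selection_rel > 1.0:
            raise ValueError("het_selection_rel must be >= 0 with s * het_selection_rel <= 1")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")
        if not 0 <= int(self.seed) < 2**63:
            raise ValueError("seed must be a non-negative integer")

    @property
    def n_nominal(self) -> int:
        """Nominal total population size (both habitats at capacity)."""
        return 2 * self.K

    @property
    def n_mutants(self) -> int:
        """Mutated individuals per generation under the nominal anchor."""
        return int(np.floor(self.mut_fraction * self.n_nominal))

    def with_(self, **kwargs) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class Individual:
    """Read-only view of one individual (mostly for tests and small examples)."""

    chrom1: np.ndarray
    chrom2: np.ndarray
    sex: int
    habitat: int

    @property
    def trait_alleles(self) -> tuple[int, int]:
        return int(self.chrom1[0]), int(self.chrom2[0])


@dataclass
class Population:
    """Genotype state of all living individuals.

    Attributes
    ----------
    genomes
        uint8 array of shape ``(n, 2, L)``; axis 1 indexes the two
        homologous chromosomes.
    sex
        uint8 array, 0 = female, 1 = male.
    habitat
        uint8 array, 0 = habitat 1 (favours AA), 1 = habitat 2 (favours A'A').
    generation
        Non-negative generation counter.
    """

    genomes: np.ndarray
    sex: np.ndarray
    habitat: np.ndarray
    generation: int = 0

    def __post_init__(self) -> None:
        self.genomes = np.ascontiguousarray(self.genomes, dtype=np.uint8)
        self.sex = np.asarray(self.sex, dtype=np.uint8)
        self.habitat = np.asarray(self.habitat, dtype=np.uint8)
        n = self.genomes.shape[0]
        if self.genomes.ndim != 3 or self.genomes.shape[1] != 2:
            raise ValueError("genomes must have shape (n, 2, L)")
        if self.sex.shape != (n,) or self.habitat.shape != (n,):
            raise ValueError("sex and habitat must be 1-D arrays of length n")

    @property
    def n(self) -> int:
        return self.genomes.shape[0]

    @property
    def L(self) -> int:
        return self.genomes.shape[2]

    def phenotypes(self) -> np.ndarray:
        """Trait phenotype code per individual (0 = AA, 1 = AA', 2 = A'A')."""
        g = self.genomes
        return (g[:, 0, 0] + g[:, 1, 0]).astype(np.int64)

    def habitat_counts(self) -> tuple[int, int]:
        h = self.habitat
        return int(np.sum(h == H1)), int(np.sum(h == H2))

    def individual(self, i: int) -> Individual:
        return Individual(
            chrom1=self.genomes[i, 0].copy(),
            chrom2=self.genomes[i, 1].copy(),
            sex=int(self.sex[i]),
            habitat=int(self.habitat[i]),
        )

    def subset(self, idx: np.ndarray) -> "Population":
        return Population(
            genomes=self.genomes[idx],
            sex=self.sex[idx],
            habitat=self.habitat[idx],
            generation=self.generation,
        )

    def copy(self) -> "Population":
        return Population(
            genomes=self.genomes.copy(),
            sex=self.sex.copy(),
            habitat=self.habitat.copy(),
            generation=self.generation,
        )

    def equals(self, other: "Population") -> bool:
        return (
            self.generation == other.generation
            and self.genomes.shape == other.genomes.shape
            and np.array_equal(self.genomes, other.genomes)
            and np.array_equal(self.sex, other.sex)
            and np.array_equal(self.habitat, other.habitat)
        )


def phenotype(individual: Individual | tuple[int, int]) -> str:
    """Map the two trait alleles to a phenotype label.

    Accepts an :class:`Individual` or a raw ``(allele, allele)`` pair; the
    mapping is symmetric in allele order.
    """
    if isinstance(individual, Individual):
        a1, a2 = individual.trait_alleles
    else:
        a1, a2 = individual
    for a in (a1, a2):
        if a not in (ALLELE_A, ALLELE_APRIME):
            raise ValueError(f"invalid trait allele code {a}")
    return PHENOTYPE_LABELS[a1 + a2]


def initialize_population(params: ModelParams, rng: np.random.Generator) -> Population:
    """Build the founding population.

    Each habitat starts with exactly ``K`` individuals, half of each sex.
    Every chromosome draws its trait allele A / A' independently with
    probability one half (so trait alleles start at equal frequency and
    uncorrelated with habitat), and every non-trait locus starts wild type
    with no effect on mating.
    """
    K, L = params.K, params.L
    n = 2 * K
    genomes = np.zeros((n, 2, L), dtype=np.uint8)
    genomes[:, :, 0] = rng.integers(0, 2, size=(n, 2), dtype=np.uint8)
    half = K // 2
    sex = np.tile(np.concatenate([np.zeros(half, np.uint8), np.ones(half, np.uint8)]), 2)
    habitat = np.concatenate([np.zeros(K, np.uint8), np.ones(K, np.uint8)])
    return Population(genomes=genomes, sex=sex, habitat=habitat, generation=0)
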