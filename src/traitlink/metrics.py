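"""Population-level statistics.

Every function here is a pure function of a population and/or a mating
record — no randomness.  The central quantity is the *average preference
distance*: per individual, the mean position of the loci of a given type
(preference-for-AA, preference-for-A'A', or neutral) over both
chromosomes, averaged over the individuals of a phenotype class.  Because
the trait locus sits at position 0, a locus's position index is also its
distance from the trait locus; loci placed uniformly at random have
expected distance (L - 1 + 1) / 2 = 50 for L = 100, the neutral null.

Missing values (no qualifying loci, empty record) are NaN and are written
as ``NA`` in TSV output.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .core import (
    ALLELE_A,
    ALLELE_APRIME,
    NEUTRAL,
    PHEN_AA,
    PHEN_APAP,
    PHEN_HET,
    PREF_A,
    PREF_APRIME,
    Population,
)

#: names accepted by locus-type arguments
LOCUS_TYPES = {
    "pref_A": (PREF_A,),
    "pref_Ap": (PREF_APRIME,),
    "neutral": (NEUTRAL,),
    "pref_any": (PREF_A, PREF_APRIME),
}

#: phenotype classes used for the per-class distance statistics
PHENOTYPE_CLASSES = {"AA": PHEN_AA, "het": PHEN_HET, "ApAp": PHEN_APAP}

#: distance columns recorded every generation: (class, locus type)
DISTANCE_COLUMNS = [
    (cls, lt) for cls in ("AA", "ApAp") for lt in ("pref_A", "pref_Ap", "neutral")
]


def _resolve_type(locus_type) -> tuple[int, ...]:
    if isinstance(locus_type, str):
        try:
            return LOCUS_TYPES[locus_type]
        except KeyError:
            raise ValueError(f"unknown locus type {locus_type!r}") from None
    return (int(locus_type),)


def avg_pref_distance(pop: Population, locus_type, phenotype_class) -> float:
    """Mean distance of the given loci from the trait locus.

    Computed per individual of the given phenotype class as the mean
    position index of loci holding ``locus_type`` across both chromosomes,
    then averaged over those individuals.  Individuals carrying no such
    locus are excluded; NaN if none qualify.

    ``locus_type`` is ``"pref_A"``, ``"pref_Ap"``, ``"neutral"`` or
    ``"pref_any"`` (both preference types pooled); ``phenotype_class`` is
    ``"AA"``, ``"het"``, ``"ApAp"`` or a phenotype code.
    """
    codes = _resolve_type(locus_type)
    if isinstance(phenotype_class, str):
        phenotype_class = PHENOTYPE_CLASSES[phenotype_class]
    mask = pop.phenotypes() == phenotype_class
    if not mask.any():
        return float("nan")
    sites = pop.genomes[mask][:, :, 1:]
    hit = sites == codes[0]
    for c in codes[1:]:
        hit |= sites == c
    positions = np.arange(1, pop.L)
    count = hit.sum(axis=(1, 2))
    pos_sum = (hit * positions).sum(axis=(1, 2))
    has = count > 0
    if not has.any():
        return float("nan")
    return float(np.mean(pos_sum[has] / count[has]))


def matching_pair_proportion(record) -> float:
    """Fraction of mating pairs whose partners share the same phenotype.

    All three phenotypes count, including heterozygote x heterozygote
    pairs.  NaN for an empty record.
    """
    if record is None or record.n_pairs == 0:
        return float("nan")
    return float(np.mean(record.female_phen == record.male_phen))


def mean_pref_loci_per_chromosome(pop: Population) -> float:
    """Average count of preference loci (either type) per chromosome."""
    if pop.n == 0:
        return 0.0
    sites = pop.genomes[:, :, 1:]
    total = int(((sites == PREF_A) | (sites == PREF_APRIME)).sum())
    return total / (2 * pop.n)


def position_histogram(pop: Population, include_neutral: bool = False):
    """Count preference loci at each position, split by chromosome class.

    Chromosomes are classed by their own trait allele (A-bearing vs
    A'-bearing).  Returns a tidy DataFrame with columns ``chrom_class``
    ("A" or "Ap"), ``locus_type``, ``position`` (1..L-1) and ``count``.
    """
    import pandas as pd

    chroms = pop.genomes.reshape(2 * pop.n, pop.L)
    positions = np.arange(1, pop.L)
    types = ["pref_A", "pref_Ap"] + (["neutral"] if include_neutral else [])
    rows = []
    for cls_label, cls_code in (("A", ALLELE_A), ("Ap", ALLELE_APRIME)):
        sub = chroms[chroms[:, 0] == cls_code][:, 1:]
        for lt in types:
            code = LOCUS_TYPES[lt][0]
            counts = (sub == code).sum(axis=0) if len(sub) else np.zeros(pop.L - 1, int)
            rows.append(
                pd.DataFrame(
                    {
                        "chrom_class": cls_label,
                        "locus_type": lt,
                        "position": positions,
                        "count": counts.astype(np.int64),
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


@njit(cache=True)
def _site_stats(genomes):  # pragma: no cover - via generation_metrics
    """Per-individual count and position-sum of each non-wild site state.

    Returns (counts, possum), each (n, 3): column 0 = preference-for-AA,
    1 = preference-for-A'A', 2 = neutral, scanned over positions 1..L-1 of
    both chromosomes in one pass.
    """
    n = genomes.shape[0]
    L = genomes.shape[2]
    counts = np.zeros((n, 3), np.int64)
    possum = np.zeros((n, 3), np.int64)
    for i in range(n):
        for c in range(2):
            for p in range(1, L):
                a = genomes[i, c, p]
                if a != 0:
                    counts[i, a - 1] += 1
                    possum[i, a - 1] += p
    return counts, possum


def _class_mean_distance(counts, possum, class_mask, type_col) -> float:
    cnt = counts[class_mask, type_col]
    has = cnt > 0
    if not has.any():
        return float("nan")
    return float(np.mean(possum[class_mask, type_col][has] / cnt[has]))


def generation_metrics(pop: Population, record) -> dict:
    """One row of the per-generation metrics table.

    Columns: generation, per-habitat sizes, number of pairs, phenotype
    frequencies, matching-pair proportion, mean preference loci per
    chromosome, and the six per-class x per-type mean distances.
    """
    phen = pop.phenotypes()
    n = pop.n
    n1, n2 = pop.habitat_counts()
    counts, possum = _site_stats(pop.genomes)
    row = {
        "generation": pop.generation,
        "n_h1": n1,
        "n_h2": n2,
        "n_pairs": 0 if record is None else record.n_pairs,
        "freq_AA": float(np.mean(phen == PHEN_AA)) if n else float("nan"),
        "freq_het": float(np.mean(phen == PHEN_HET)) if n else float("nan"),
        "freq_ApAp": float(np.mean(phen == PHEN_APAP)) if n else float("nan"),
        "matching": matching_pair_proportion(record),
        "pref_per_chrom": (
            float(counts[:, :2].sum() / (2 * n)) if n else 0.0
        ),
    }
    type_cols = {"pref_A": 0, "pref_Ap": 1, "neutral": 2}
    class_masks = {"AA": phen == PHEN_AA, "ApAp": phen == PHEN_APAP}
    for cls, lt in DISTANCE_COLUMNS:
        row[f"dist_{cls}_{lt}"] = _class_mean_distance(
            counts, possum, class_masks[cls], type_cols[lt]
        )
    return row
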