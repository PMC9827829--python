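"""The five generation stages and whole-generation composition."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from traitlink import (
    FEMALE,
    MALE,
    NEUTRAL,
    PREF_A,
    PREF_APRIME,
    WILD,
    Individual,
    ModelParams,
    Population,
    apply_selection,
    form_mating_pairs,
    mate_probability,
    mutate_offspring,
    preference_score,
    preference_scores,
    recombine_offspring,
    regulate_density,
    reproduce,
    run_simulation,
    step_generation,
)
from traitlink.lifecycle import MatingRecord

from conftest import random_population


def make_pop(genomes, sex=None, habitat=None):
    genomes = np.asarray(genomes, dtype=np.uint8)
    n = genomes.shape[0]
    if sex is None:
        sex = np.zeros(n, np.uint8)
    if habitat is None:
        habitat = np.zeros(n, np.uint8)
    return Population(genomes=genomes, sex=np.asarray(sex, np.uint8),
                      habitat=np.asarray(habitat, np.uint8))


class TestPreferenceScore:
    def test_all_wild_genome_scores_zero(self):
        ind = Individual(np.zeros(10, np.uint8), np.zeros(10, np.uint8), 0, 0)
        assert preference_score(ind) == 0

    def test_counting(self):
        c1 = np.zeros(10, np.uint8)
        c1[[2, 5, 7]] = PREF_A
        c2 = np.zeros(10, np.uint8)
        c2[3] = PREF_APRIME
        assert preference_score(Individual(c1, c2, 0, 0)) == 2

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_matches_exhaustive_tally(self, seed):
        rng = np.random.default_rng(seed)
        pop = random_population(rng, n=20, L=15, pref_density=0.4)
        scores = preference_scores(pop)
        for i in range(pop.n):
            d = 0
            for c in range(2):
                for p in range(1, pop.L):
                    a = pop.genomes[i, c, p]
                    d += int(a == PREF_A) - int(a == PREF_APRIME)
            assert scores[i] == d == preference_score(pop.individual(i))


class TestMateProbability:
    def test_logistic_at_zero_is_half(self):
        for pf in (0.0, 0.3, 2.4, 50.0):
            assert mate_probability(0, pf, "AA") == pytest.approx(0.5)

    def test_strong_preference_bound(self):
        # one extra matching allele at pf = 2.4 gives > 0.9 acceptance
        p = mate_probability(1, 2.4, "AA")
        assert p == pytest.approx(1 / (1 + np.exp(-2.4)), rel=1e-12)
        assert p > 0.9

    def test_heterozygote_acceptance_constant(self):
        for d in (-5, 0, 5, 100):
            assert mate_probability(d, 2.4, "AA'") == 0.5
        assert mate_probability(3, 1.0, "AA'", het_mate_prob=0.7) == 0.7

    def test_independent_logistic_evaluation(self):
        assert mate_probability(-3, 0.3, "AA") == pytest.approx(1 / (1 + np.exp(0.9)))

    def test_complementarity_and_saturation(self):
        for d in range(-60, 61, 7):
            for pf in (0.0, 0.3, 2.4, 40.0):
                pa = mate_probability(d, pf, "AA")
                pap = mate_probability(d, pf, "A'A'")
                assert pa + pap == pytest.approx(1.0, abs=1e-15)
        # far in the tails: saturates without overflow
        assert mate_probability(2000, 2.4, "AA") == 1.0
        assert mate_probability(-2000, 2.4, "AA") == 0.0


class TestFormMatingPairs:
    def _choice_pop(self, n_females, n_males, L=4):
        genomes = np.zeros((n_females + n_males, 2, L), np.uint8)
        sex = np.array([FEMALE] * n_females + [MALE] * n_males, np.uint8)
        return make_pop(genomes, sex=sex)

    def test_indifferent_females_follow_geometric_trials(self):
        # all d = 0 against AA males: per-pairing acceptance is 0.5, so the
        # chance a female exhausts 10 pairings is 0.5^10 ~ 1e-3
        pop = self._choice_pop(20000, 40000)
        params = ModelParams(K=30000, pf=0.3)
        record = form_mating_pairs(pop, params, np.random.default_rng(0))
        unmated = 20000 - record.n_pairs
        expected = 20000 * 0.5**10  # ~19.5
        assert 5 <= unmated <= 45  # generous Poisson band around 19.5
        assert expected == pytest.approx(19.5, abs=0.1)

    def test_saturated_preference_mates_first_pairing(self):
        pop = self._choice_pop(50, 60)
        pop.genomes[:50, 0, 1] = PREF_A  # every female d = +1
        params = ModelParams(K=100, pf=50.0)
        record = form_mating_pairs(pop, params, np.random.default_rng(1))
        assert record.n_pairs == 50

    def test_empty_male_pool_gives_empty_record(self):
        pop = self._choice_pop(1, 0)
        record = form_mating_pairs(pop, ModelParams(K=2), np.random.default_rng(0))
        assert record.n_pairs == 0

    def test_monogamy(self, rng):
        pop = random_population(rng, n=400, L=5)
        record = form_mating_pairs(pop, ModelParams(K=200, pf=0.3), rng)
        assert len(np.unique(record.female_idx)) == record.n_pairs
        assert len(np.unique(record.male_idx)) == record.n_pairs
        assert (pop.sex[record.female_idx] == FEMALE).all()
        assert (pop.sex[record.male_idx] == MALE).all()


class TestReproduce:
    def test_four_offspring_two_of_each_sex(self, rng):
        pop = random_population(rng, n=100, L=5)
        females = np.flatnonzero(pop.sex == FEMALE)[:5]
        males = np.flatnonzero(pop.sex == MALE)[:5]
        record = MatingRecord(females, males, pop.phenotypes()[females],
                              pop.phenotypes()[males])
        pool = reproduce(record, pop, ModelParams(K=50), rng)
        assert pool.n == 20
        assert (pool.sex == FEMALE).sum() == 10
        assert (pool.sex == MALE).sum() == 10
        assert np.array_equal(pool.habitat, np.repeat(pop.habitat[females], 4))

    def test_homozygote_cross_yields_heterozygotes(self, rng):
        genomes = np.zeros((2, 2, 4), np.uint8)
        genomes[1, :, 0] = 1  # father A'A'
        pop = make_pop(genomes, sex=[FEMALE, MALE])
        record = MatingRecord(np.array([0]), np.array([1]),
                              np.array([0]), np.array([2]))
        pool = reproduce(record, pop, ModelParams(K=2), rng)
        assert (pool.phenotypes() == 1).all()

    def test_het_cross_segregates_one_two_one(self, rng):
        genomes = np.zeros((2, 2, 2), np.uint8)
        genomes[:, 1, 0] = 1  # both parents AA'
        pop = make_pop(genomes, sex=[FEMALE, MALE])
        record = MatingRecord(np.array([0]), np.array([1]),
                              np.array([1]), np.array([1]))
        params = ModelParams(K=2, n_offspring=4000)
        pool = reproduce(record, pop, params, rng)
        phen = pool.phenotypes()
        assert (phen == 0).mean() == pytest.approx(0.25, abs=0.03)
        assert (phen == 1).mean() == pytest.approx(0.5, abs=0.03)


class _FixedCutRNG:
    """Stands in for a Generator to force chosen crossover points."""

    def __init__(self, cuts):
        self._cuts = np.asarray(cuts)

    def integers(self, low, high, size=None):
        return self._cuts.reshape(size)


class TestRecombination:
    def test_tail_swap_example(self):
        # breakpoint after index 1: positions >= 2 exchanged
        genomes = np.array([[[0, PREF_A, WILD, WILD],
                             [1, WILD, WILD, NEUTRAL]]])
        pop = make_pop(genomes)
        recombine_offspring(pop, ModelParams(K=2, L=4), _FixedCutRNG([[2]]))
        assert pop.genomes[0, 0].tolist() == [0, PREF_A, WILD, NEUTRAL]
        assert pop.genomes[0, 1].tolist() == [1, WILD, WILD, WILD]

    def test_no_crossover_control_is_identity(self, rng):
        pop = random_population(rng, n=30, L=10)
        before = pop.genomes.copy()
        recombine_offspring(pop, ModelParams(K=30, n_crossovers=0), rng)
        assert np.array_equal(pop.genomes, before)

    @given(st.integers(0, 2**31 - 1), st.integers(1, 3))
    @settings(max_examples=40, deadline=None)
    def test_per_locus_allele_pairs_conserved(self, seed, k):
        rng = np.random.default_rng(seed)
        pop = random_population(rng, n=25, L=12, pref_density=0.3)
        before = np.sort(pop.genomes, axis=1)  # unordered per-locus pair
        d_before = preference_scores(pop)
        geno_before = pop.phenotypes()
        recombine_offspring(pop, ModelParams(K=30, n_crossovers=k), rng)
        assert np.array_equal(np.sort(pop.genomes, axis=1), before)
        assert np.array_equal(preference_scores(pop), d_before)
        assert np.array_equal(pop.phenotypes(), geno_before)


class TestMutation:
    def test_hits_one_percent_of_pool(self, rng):
        pop = make_pop(np.zeros((10000, 2, 100), np.uint8))
        before = pop.genomes.copy()
        mutate_offspring(pop, ModelParams(K=5000), rng)
        changed = (pop.genomes != before).any(axis=(1, 2))
        # wild-type start: every mutation event is visible, one per individual
        assert changed.sum() == 100
        per_ind = (pop.genomes != before).sum(axis=(1, 2))
        assert per_ind.max() == 1

    def test_nominal_anchor_is_fixed_count(self, rng):
        pop = make_pop(np.zeros((300, 2, 10), np.uint8))
        mutate_offspring(pop, ModelParams(K=100, mut_anchor="nominal"), rng)
        assert (pop.genomes != 0).sum() == 2  # floor(0.01 * 2K) = 2

    def test_trait_locus_never_mutated(self, rng):
        pop = make_pop(np.zeros((2000, 2, 10), np.uint8))
        for _ in range(50):
            mutate_offspring(pop, ModelParams(K=1000, L=10), rng)
        assert not pop.genomes[:, :, 0].any()

    def test_mutant_states_cover_all_three_types(self, rng):
        pop = make_pop(np.zeros((5000, 2, 10), np.uint8))
        for _ in range(20):
            mutate_offspring(pop, ModelParams(K=2500, L=10), rng)
        states = pop.genomes[:, :, 1:]
        found = {int(s) for s in np.unique(states)} - {WILD}
        assert found == {PREF_A, PREF_APRIME, NEUTRAL}

    def test_raises_when_count_exceeds_pool(self, rng):
        pop = make_pop(np.zeros((20, 2, 10), np.uint8))
        with pytest.raises(ValueError):
            mutate_offspring(
                pop, ModelParams(K=100, mut_fraction=1.0, mut_anchor="nominal"), rng
            )


class TestSelection:
    def _mixed_pool(self, rng, n=4000):
        pop = random_population(rng, n=n, L=3)
        return pop

    def test_no_selection_keeps_everyone(self, rng):
        pop = self._mixed_pool(rng)
        out = apply_selection(pop, ModelParams(K=5000, s=0.0), rng)
        assert out.n == pop.n

    def test_full_selection_keeps_only_locally_adapted(self, rng):
        pop = self._mixed_pool(rng)
        out = apply_selection(pop, ModelParams(K=5000, s=1.0), rng)
        phen = out.phenotypes()
        assert (((phen == 0) & (out.habitat == 0))
                | ((phen == 2) & (out.habitat == 1))).all()

    def test_half_selection_matches_binomial(self, rng):
        genomes = np.zeros((10000, 2, 3), np.uint8)
        genomes[:, :, 0] = 1  # all A'A' ...
        pop = make_pop(genomes)  # ... in habitat 1: all maladapted
        out = apply_selection(pop, ModelParams(K=5000, s=0.5), rng)
        # binomial(10000, 0.5): 5 sigma = 250
        assert abs(out.n - 5000) < 250

    def test_heterozygote_relative_selection(self, rng):
        genomes = np.zeros((20000, 2, 3), np.uint8)
        genomes[:, 1, 0] = 1  # all heterozygotes
        pop = make_pop(genomes)
        params = ModelParams(K=10000, s=0.5, het_selection_rel=0.5)
        out = apply_selection(pop, params, rng)
        assert abs(out.n - 15000) < 300  # die at s * rel = 0.25


class TestDensityRegulation:
    def test_caps_each_habitat_at_K(self, rng):
        pop = random_population(rng, n=6000, L=3)
        pop.habitat[:] = 0
        out = regulate_density(pop, ModelParams(K=5000), rng)
        assert out.n == 5000

    def test_under_capacity_keeps_all(self, rng):
        pop = random_population(rng, n=4000, L=3)
        out = regulate_density(pop, ModelParams(K=5000), rng)
        assert out.n == 4000

    def test_subsample_is_uniform(self):
        # each survivor kept with frequency K/n across seeds
        n, K, trials = 40, 30, 400
        kept = np.zeros(n)
        genomes = np.zeros((n, 2, 3), np.uint8)
        genomes[:, 0, 1] = np.arange(n) % 4  # give individuals identities
        for t in range(trials):
            pop = make_pop(genomes.copy())
            pop.habitat[:] = 0
            marker = np.arange(n, dtype=np.uint8)
            pop.genomes[:, 1, 2] = marker  # track identity through culling
            out = regulate_density(pop, ModelParams(K=K, L=3),
                                   np.random.default_rng(t))
            kept[out.genomes[:, 1, 2]] += 1
        freq = kept / trials
        assert np.all(np.abs(freq - K / n) < 0.12)  # ~5 sigma binomial band


class TestGenerationStep:
    def test_composition_contracts(self):
        params = ModelParams(K=500, L=20, s=0.5, pf=0.6, seed=0)
        rng = np.random.default_rng(0)
        pop = random_population(rng, n=1000, L=20)
        new, record = step_generation(pop, params, rng)
        assert new.generation == pop.generation + 1
        n1, n2 = new.habitat_counts()
        assert n1 <= params.K and n2 <= params.K
        assert record.n_pairs > 0

    def test_random_mating_when_preference_flat(self):
        # pf = 0: acceptance is 0.5 regardless of phenotype, so matching
        # equals the random-pairing expectation sum_p P(female p) P(male p)
        params = ModelParams(K=5000, L=10, pf=0.0, seed=3)
        rng = np.random.default_rng(3)
        pop = random_population(rng, n=10000, L=10, pref_density=0.1)
        record = form_mating_pairs(pop, params, rng)
        f = np.bincount(record.female_phen, minlength=3) / record.n_pairs
        m = np.bincount(record.male_phen, minlength=3) / record.n_pairs
        expected = float((f * m).sum())
        observed = float((record.female_phen == record.male_phen).mean())
        assert observed == pytest.approx(expected, abs=0.03)

    def test_trajectory_bit_identical_under_fixed_seed(self):
        params = ModelParams(K=200, L=20, generations=8, seed=11)
        a = run_simulation(params, keep_final=True)
        b = run_simulation(params, keep_final=True)
        assert a.metrics.equals(b.metrics)
        assert a.final_population.equals(b.final_population)

    def test_run_records_generation_zero_only_for_empty_run(self):
        params = ModelParams(K=100, L=10, generations=0, seed=1)
        res = run_simulation(params)
        assert list(res.metrics.index) == [0]
        assert np.isnan(res.metrics.loc[0, "matching"])

    def test_snapshots_collected_at_requested_generations(self):
        params = ModelParams(K=100, L=10, generations=4, seed=5)
        res = run_simulation(params, snapshot_generations=(0, 3))
        assert set(res.snapshots) == {0, 3}
        assert res.snapshots[3].generation == 3

    def test_heterozygotes_decline_under_defaults(self):
        # divergent selection with assortment drives the intermediate
        # phenotype toward loss and fixes each homozygote in its habitat
        params = ModelParams(K=500, L=20, s=0.7, pf=2.4, generations=60, seed=2)
        res = run_simulation(params, keep_final=True)
        first = res.metrics["freq_het"].iloc[0]
        last = res.metrics["freq_het"].iloc[-1]
        assert last < first / 3
        pop = res.final_population
        phen = pop.phenotypes()
        assert (phen[pop.habitat == 0] == 0).mean() > 0.8
        assert (phen[pop.habitat == 1] == 2).mean() > 0.8
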