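"""F-score, embedded pre-selection and the memetic algorithm operators."""

import math

import numpy as np
import pandas as pd
import pytest

from hexafib.feature_selection import (
    EmbeddedSVMSelector,
    FitnessUnsetError,
    Individual,
    MAConfig,
    MemeticFeatureSelector,
    embedded_preselect,
    f_score,
    init_population,
    local_search,
    mutate,
    mutation_count,
    rank_by_f_score,
    recombine_property_pool,
    run_memetic,
    select_best_half,
    svm_cv_fitness,
)
from hexafib.synthetic_data import PlantedDesign, generate_planted_matrix


def brute_force_f_score(values, labels):
    """Independent direct-formula oracle."""
    pos = [v for v, l in zip(values, labels) if l == 1]
    neg = [v for v, l in zip(values, labels) if l == 0]
    mean = sum(values) / len(values)
    mp, mn = sum(pos) / len(pos), sum(neg) / len(neg)
    num = (mp - mean) ** 2 + (mn - mean) ** 2
    vp = sum((v - mp) ** 2 for v in pos) / (len(pos) - 1)
    vn = sum((v - mn) ** 2 for v in neg) / (len(neg) - 1)
    return num / (vp + vn)


class TestFScore:
    def test_identical_class_means_score_zero(self):
        vals = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        labels = np.array([1, 1, 1, 0, 0, 0])
        assert f_score(vals, labels) == pytest.approx(0.0)

    def test_separated_tight_classes_score_large(self):
        vals = np.array([2.0, 2.0 + 1e-9, 0.0, 1e-9])
        labels = np.array([1, 1, 0, 0])
        assert f_score(vals, labels) > 1e6

    def test_constant_within_class_separation_is_inf(self):
        vals = np.array([2.0, 2.0, 0.0, 0.0])
        labels = np.array([1, 1, 0, 0])
        assert math.isinf(f_score(vals, labels))

    def test_example_matches_brute_force(self):
        vals = [1.0, 2.0, 3.0, 2.0, 3.0, 4.0]
        labels = [1, 1, 1, 0, 0, 0]
        assert f_score(np.array(vals), np.array(labels)) == pytest.approx(
            brute_force_f_score(vals, labels), abs=1e-12
        )

    def test_agrees_with_brute_force_on_random_instances(self, rng):
        """100 random small instances, 1e-9 agreement with the oracle."""
        for _ in range(100):
            n = int(rng.integers(4, 30))
            labels = np.array([1, 1, 0, 0] + list(rng.integers(0, 2, n)))
            vals = rng.normal(size=len(labels))
            assert f_score(vals, labels) == pytest.approx(
                brute_force_f_score(vals.tolist(), labels.tolist()), abs=1e-9
            )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            f_score(np.array([1.0, 2.0, 3.0]), np.array([1, 1, 1]))


@pytest.fixture(scope="module")
def planted_data():
    planted = tuple(f"SYN{i + 1:04d}" for i in range(3))
    design = PlantedDesign(pool_size=12, planted=planted, shift=3.0, seed=5)
    X, y = generate_planted_matrix(design, 80)
    return X, y, planted


class TestEmbeddedPreselect:
    def test_recovers_planted_signal_columns(self, planted_data):
        X, y, planted = planted_data
        assert sorted(embedded_preselect(X, y, k=3)) == sorted(planted)

    def test_k_equal_to_pool_keeps_everything(self, planted_data):
        X, y, _ = planted_data
        assert sorted(embedded_preselect(X, y, k=X.shape[1])) == sorted(X.columns)

    def test_duplicate_columns_tie_break_deterministically(self, planted_data):
        X, y, _ = planted_data
        dup = X.copy()
        dup["SYN0001B"] = dup["SYN0001"]
        first = embedded_preselect(dup, y, k=dup.shape[1])
        second = embedded_preselect(dup, y, k=dup.shape[1])
        assert first == second
        sel = EmbeddedSVMSelector(k=dup.shape[1]).fit(dup, y)
        w = dict(zip(dup.columns, sel.weights_))
        assert w["SYN0001"] == pytest.approx(w["SYN0001B"])

    def test_degenerate_labels_rejected(self, planted_data):
        X, _, _ = planted_data
        with pytest.raises(ValueError):
            embedded_preselect(X, np.ones(len(X)), k=2)

    def test_sklearn_selector_interface(self, planted_data):
        X, y, planted = planted_data
        sel = EmbeddedSVMSelector(k=3).fit(X, y)
        assert sel.support_.sum() == 3
        assert sel.transform(X).shape == (len(X), 3)


class TestSvmCvFitness:
    def test_separable_data_scores_high(self, planted_data):
        X, y, planted = planted_data
        fit = svm_cv_fitness(X[list(planted)], y, (10.0, 0.1), seed=0)
        assert fit >= 0.95

    def test_permuted_labels_score_near_chance(self, planted_data):
        X, y, planted = planted_data
        rng = np.random.default_rng(3)
        fit = svm_cv_fitness(X[list(planted)], rng.permutation(y), (10.0, 0.1), seed=0)
        assert 0.35 <= fit <= 0.65

    def test_deterministic_given_seed(self, planted_data):
        X, y, planted = planted_data
        a = svm_cv_fitness(X[list(planted)], y, (2.0, 0.5), seed=9)
        b = svm_cv_fitness(X[list(planted)], y, (2.0, 0.5), seed=9)
        assert a == b

    def test_too_few_samples_rejected(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0]})
        with pytest.raises(ValueError):
            svm_cv_fitness(X, np.array([1, 1, 0, 0]), (1.0, 1.0), folds=5)


def _config(pool_size=20, **kw):
    pool = tuple(f"P{i:03d}" for i in range(pool_size))
    defaults = dict(pop_size=4, subset_size=5, generations=10, seed=0)
    defaults.update(kw)
    return MAConfig(pool=pool, **defaults)


class TestPopulationOperators:
    def test_init_population_shape_and_membership(self):
        config = _config(pop_size=10, subset_size=5)
        pop = init_population(config)
        assert len(pop) == 10
        for ind in pop:
            assert len(ind.subset) == 5
            assert set(ind.subset) <= set(config.pool)
            assert ind.C > 0 and ind.gamma > 0

    def test_init_population_reproducible(self):
        config = _config(seed=123)
        a, b = init_population(config), init_population(config)
        assert [i.subset for i in a] == [i.subset for i in b]
        assert [i.C for i in a] == [i.C for i in b]

    def test_subset_size_equal_pool_forces_identical_subsets(self):
        config = _config(pool_size=5, subset_size=5)
        pop = init_population(config)
        assert len({i.subset for i in pop}) == 1

    def test_select_best_half_keeps_top_by_fitness(self):
        pop = [
            Individual(("a",), 1, 1, fitness=f)
            for f in (0.9, 0.5, 0.8, 0.6)
        ]
        kept = select_best_half(pop)
        assert [i.fitness for i in kept] == [0.9, 0.8]

    def test_select_best_half_stable_on_ties(self):
        pop = [Individual((f"p{i}",), 1, 1, fitness=0.5) for i in range(4)]
        kept = select_best_half(pop)
        assert [i.subset for i in kept] == [("p0",), ("p1",)]

    def test_select_requires_fitness(self):
        pop = [Individual(("a",), 1, 1)] * 4
        with pytest.raises(FitnessUnsetError):
            select_best_half(pop)

    def test_recombination_cardinality_and_closure(self, rng):
        parents = [
            Individual(tuple(f"P{i:03d}" for i in rng.choice(20, 8, replace=False)),
                       1.0, 1.0, fitness=0.5)
            for _ in range(5)
        ]
        offspring = recombine_property_pool(parents, 5, 8, rng)
        union = set().union(*(p.subset for p in parents))
        for o in offspring:
            assert len(o.subset) == 8
            assert set(o.subset) <= union

    def test_identical_parents_give_identical_offspring(self, rng):
        parent = Individual(tuple(f"P{i:03d}" for i in range(5)), 1.0, 1.0, fitness=0.9)
        offspring = recombine_property_pool([parent, parent], 3, 5, rng)
        assert all(o.subset == parent.subset for o in offspring)

    def test_frequent_parent_property_inherited_more_often(self):
        """A property carried by all parents beats a singleton property."""
        rng = np.random.default_rng(0)
        common, rare = "COMMON", "RARE"
        fillers = [f"F{i:02d}" for i in range(12)]
        parents = []
        for i in range(5):
            subset = [common] + fillers[2 * i : 2 * i + 2]
            if i == 0:
                subset.append(rare)
            else:
                subset.append(fillers[(2 * i + 2) % 12])
            parents.append(Individual(tuple(subset), 1.0, 1.0, fitness=0.5))
        n_common = n_rare = 0
        for _ in range(1000):
            (o,) = recombine_property_pool(parents, 1, 3, rng)
            n_common += common in o.subset
            n_rare += rare in o.subset
        assert n_common > n_rare

    def test_insufficient_parent_diversity_rejected(self, rng):
        parent = Individual(("P000", "P001"), 1.0, 1.0, fitness=0.5)
        with pytest.raises(ValueError):
            recombine_property_pool([parent], 1, 5, rng)


class TestMutationSchedule:
    def test_starts_at_s_times_m(self):
        assert mutation_count(0, 40, 0.2, 100) == 8

    def test_ends_at_one(self):
        assert mutation_count(100, 40, 0.2, 100) == 1

    @pytest.mark.parametrize("s,m,n_total", [(40, 0.2, 100), (40, 0.2, 30),
                                             (20, 0.5, 50), (60, 0.9, 10)])
    def test_non_increasing_and_at_least_one(self, s, m, n_total):
        values = [mutation_count(g, s, m, n_total) for g in range(n_total + 1)]
        assert all(v >= 1 for v in values)
        assert all(a >= b for a, b in zip(values, values[1:]))

    def test_domain_violations_rejected(self):
        with pytest.raises(ValueError):
            mutation_count(-1, 40, 0.2, 100)
        with pytest.raises(ValueError):
            mutation_count(0, 40, 1.5, 100)


class TestMutate:
    POOL = tuple(f"P{i:03d}" for i in range(20))

    def test_zero_mutations_leaves_subset_unchanged(self, rng):
        ind = Individual(self.POOL[:5], 1.0, 1.0)
        out = mutate(ind, 0, self.POOL, rng)
        assert out.subset == ind.subset

    def test_cardinality_preserved_under_full_swap(self, rng):
        ind = Individual(self.POOL[:5], 1.0, 1.0)
        out = mutate(ind, 5, self.POOL, rng)
        assert len(out.subset) == 5
        assert set(out.subset) <= set(self.POOL)

    def test_swapped_members_come_from_outside(self, rng):
        ind = Individual(self.POOL[:5], 1.0, 1.0)
        out = mutate(ind, 2, self.POOL, rng)
        assert len(set(out.subset) - set(ind.subset)) == 2

    def test_reproducible_for_fixed_seed(self):
        ind = Individual(self.POOL[:5], 1.0, 1.0)
        a = mutate(ind, 3, self.POOL, np.random.default_rng(4))
        b = mutate(ind, 3, self.POOL, np.random.default_rng(4))
        assert a.subset == b.subset and a.C == b.C

    def test_insufficient_nonmembers_swaps_available(self, rng):
        pool = self.POOL[:6]
        ind = Individual(pool[:5], 1.0, 1.0)
        out = mutate(ind, 5, pool, rng)
        assert len(out.subset) == 5


class TestLocalSearch:
    def test_unimprovable_offspring_returned_unchanged(self, planted_data):
        X, y, planted = planted_data
        rankings = rank_by_f_score(X, y)
        best = Individual(tuple(sorted(planted)), 10.0, 0.1)
        out = local_search(best, X, y, rankings, length=2, seed=0)
        assert out.subset == best.subset

    def test_pulls_top_ranked_feature_into_subset(self, planted_data):
        """Monte-Carlo: a planted feature left out of the offspring is
        recovered by Add/Delete in at least 90% of seeds."""
        X, y, planted = planted_data
        rankings = rank_by_f_score(X, y)
        noise = [c for c in X.columns if c not in planted]
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            subset = tuple(list(planted[:2]) + list(rng.choice(noise, 1)))
            out = local_search(
                Individual(subset, 10.0, 0.1), X, y, rankings, length=1, seed=0
            )
            hits += planted[2] in out.subset
        assert hits >= 9

    def test_cardinality_always_preserved(self, planted_data):
        X, y, planted = planted_data
        rankings = rank_by_f_score(X, y)
        subset = tuple(sorted(X.columns)[:5])
        out = local_search(Individual(subset, 1.0, 0.5), X, y, rankings,
                           length=8, seed=0)
        assert len(out.subset) == 5


@pytest.fixture(scope="module")
def ma_result(planted_data):
    X, y, planted = planted_data
    config = MAConfig(pool=tuple(X.columns), pop_size=4, subset_size=3,
                      generations=8, seed=1, patience=20)
    return run_memetic(X, y, config), config, planted


class TestRunMemetic:

    def test_best_fitness_non_decreasing(self, ma_result):
        (best, history), _, _ = ma_result
        fits = [r.best_fitness for r in history.records]
        assert all(a <= b for a, b in zip(fits, fits[1:]))

    def test_cardinality_invariant(self, ma_result):
        (best, history), config, _ = ma_result
        assert len(best.subset) == config.subset_size
        assert all(len(r.best_subset) == config.subset_size for r in history.records)

    def test_same_seed_identical_result(self, planted_data):
        X, y, _ = planted_data
        config = MAConfig(pool=tuple(X.columns), pop_size=4, subset_size=3,
                          generations=3, seed=2, patience=20)
        a, _ = run_memetic(X, y, config)
        b, _ = run_memetic(X, y, config)
        assert a.subset == b.subset and a.fitness == b.fitness

    def test_enriched_for_planted_features(self, ma_result):
        (best, _), config, planted = ma_result
        assert len(set(best.subset) & set(planted)) >= 2


class TestMemeticFeatureSelectorEstimator:
    def test_sklearn_interface_and_selection_json(self, planted_data):
        X, y, planted = planted_data
        sel = MemeticFeatureSelector(subset_size=3, pop_size=4, generations=3,
                                     random_state=0)
        sel.fit(X, y)
        assert sel.support_.sum() == 3
        assert sel.transform(X).shape == (len(X), 3)
        assert set(sel.history_.columns) >= {"generation", "best_fitness"}
        import json

        payload = json.loads(sel.to_json())
        assert len(payload["selected"]) == 3
        assert 0 <= payload["fitness"] <= 1
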