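"""Two-stage feature optimization.

Stage one is an embedded pre-selection: a linear-kernel SVM is fitted once
on all candidate per-property mean features and properties are ranked by
the magnitude of their weights; the top k (canonically 186) survive.

Stage two is a memetic algorithm (MA): a genetic algorithm over fixed-size
property subsets, hybridized with an F-score-guided Add/Delete local
search.  Each individual carries its own RBF-SVM hyperparameters (C,
gamma) as genes; fitness is stratified 5-fold cross-validated accuracy.
Per generation: evaluate, keep the best half, recombine through a shuffled
property pool (properties frequent among fit parents are drawn more
often), mutate with an exponentially decaying per-offspring swap count,
improve each offspring by local search, and replace the worst half.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import SVC

log = logging.getLogger(__name__)


class FitnessUnsetError(RuntimeError):
    """Selection requested before all individuals were evaluated."""


@dataclass
class Individual:
    """A candidate feature subset with its own SVM kernel parameters."""

    subset: tuple[str, ...]
    C: float
    gamma: float
    fitness: float | None = None

    def __post_init__(self) -> None:
        if len(set(self.subset)) != len(self.subset):
            raise ValueError("subset contains duplicate properties")
        if self.C <= 0 or self.gamma <= 0:
            raise ValueError("C and gamma must be positive")
        # canonical order makes runs seed-reproducible regardless of set ops
        object.__setattr__(self, "subset", tuple(sorted(self.subset)))


@dataclass(frozen=True)
class MAConfig:
    """Memetic-algorithm settings.

    ``subset_size`` is the fixed chromosome cardinality (40 properties
    canonically); ``mutation_value`` m sets the generation-zero mutation
    load s*m; ``local_search_length`` caps Add and Delete operations per
    improvement step.
    """

    pool: tuple[str, ...]
    pop_size: int = 10
    subset_size: int = 40
    generations: int = 100
    mutation_value: float = 0.2
    local_search_length: int = 8
    cv_folds: int = 5
    seed: int = 0
    patience: int = 15
    c_range: tuple[float, float] = (2.0**-5, 2.0**15)
    gamma_range: tuple[float, float] = (2.0**-15, 2.0**3)
    param_sigma: float = 0.1

    def __post_init__(self) -> None:
        if self.pop_size % 2 != 0:
            raise ValueError("pop_size must be even")
        if self.subset_size > len(self.pool):
            raise ValueError("subset_size exceeds pool size")
        if not (0 < self.mutation_value < 1):
            raise ValueError("mutation_value must lie in (0, 1)")
        if self.local_search_length < 1:
            raise ValueError("local_search_length must be >= 1")


@dataclass
class GenerationRecord:
    generation: int
    best_fitness: float
    mean_fitness: float
    n_mutations: int
    best_subset: tuple[str, ...]


@dataclass
class MAHistory:
    records: list[GenerationRecord] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "generation": [r.generation for r in self.records],
                "best_fitness": [r.best_fitness for r in self.records],
                "mean_fitness": [r.mean_fitness for r in self.records],
                "n_mutations": [r.n_mutations for r in self.records],
            }
        )


def f_score(values: np.ndarray, labels: np.ndarray) -> float:
    """Two-class F-score of one feature: separation over within-class spread.

    ((mean_pos - mean)^2 + (mean_neg - mean)^2) divided by the sum of the
    unbiased within-class variances.  A zero denominator with a nonzero
    numerator returns +inf (a constant-within-class feature separates the
    classes perfectly); 0/0 returns 0.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    pos = values[labels == 1]
    neg = values[labels == 0]
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("each class needs at least 2 samples for the F-score")
    grand = values.mean()
    num = (pos.mean() - grand) ** 2 + (neg.mean() - grand) ** 2
    den = pos.var(ddof=1) + neg.var(ddof=1)
    if den == 0.0:
        return math.inf if num > 0 else 0.0
    return float(num / den)


def rank_by_f_score(matrix: pd.DataFrame, labels: np.ndarray) -> dict[str, float]:
    """F-score per column; ties downstream break by accession order."""
    y = np.asarray(labels)
    return {c: f_score(matrix[c].to_numpy(), y) for c in matrix.columns}


def embedded_preselect(
    matrix: pd.DataFrame, labels: np.ndarray, k: int = 186
) -> list[str]:
    """Embedded SVM pre-selection: rank properties by linear-SVM |weight|.

    Fits one linear-kernel SVM on all candidate features and returns the
    top ``k`` accessions by absolute weight, ties broken by column order.
    """
    sel = EmbeddedSVMSelector(k=k)
    sel.fit(matrix, labels)
    return list(sel.selected_)


class EmbeddedSVMSelector(SelectorMixin, BaseEstimator):
    """Single-shot linear-SVM weight-magnitude feature ranking.

    Attributes (after fit): ``ranking_`` — all features best-first;
    ``selected_`` — the top ``k``; ``support_`` mask over input columns.
    """

    def __init__(self, k: int = 186, C: float = 1.0):
        self.k = k
        self.C = C

    def fit(self, X, y):
        X = pd.DataFrame(X)
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("labels are degenerate: need both classes")
        if self.k > X.shape[1]:
            raise ValueError(f"k={self.k} exceeds {X.shape[1]} features")
        svm = SVC(kernel="linear", C=self.C)
        svm.fit(X.to_numpy(), y)
        weights = np.abs(np.ravel(svm.coef_))
        # stable sort: descending weight, ascending original position
        order = np.lexsort((np.arange(len(weights)), -weights))
        names = [str(c) for c in X.columns]
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.weights_ = weights
        self.ranking_ = [names[i] for i in order]
        self.selected_ = self.ranking_[: self.k]
        keep = set(order[: self.k])
        self.support_ = np.array([i in keep for i in range(len(names))])
        return self

    def _get_support_mask(self):
        return self.support_


def svm_cv_fitness(
    matrix: pd.DataFrame | np.ndarray,
    labels: np.ndarray,
    params: tuple[float, float],
    folds: int = 5,
    seed: int = 0,
) -> float:
    """Mean stratified k-fold CV accuracy of an RBF-kernel SVM.

    Deterministic for fixed inputs and seed; this is the MA's fitness.
    """
    X = matrix.to_numpy() if isinstance(matrix, pd.DataFrame) else np.asarray(matrix)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < folds:
        raise ValueError(f"need at least {folds} samples per class for {folds}-fold CV")
    C, gamma = params
    clf = SVC(kernel="rbf", C=C, gamma=gamma)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = cross_val_score(clf, X, y, cv=cv, scoring="accuracy")
    return float(scores.mean())


def _draw_params(config: MAConfig, rng: np.random.Generator) -> tuple[float, float]:
    lo_c, hi_c = np.log(config.c_range)
    lo_g, hi_g = np.log(config.gamma_range)
    return float(np.exp(rng.uniform(lo_c, hi_c))), float(np.exp(rng.uniform(lo_g, hi_g)))


def init_population(config: MAConfig, rng: np.random.Generator | None = None) -> list[Individual]:
    """Random parents: uniform subsets of the pool, log-uniform (C, gamma)."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    pop = []
    for _ in range(config.pop_size):
        subset = tuple(
            rng.choice(len(config.pool), size=config.subset_size, replace=False)
        )
        C, gamma = _draw_params(config, rng)
        pop.append(Individual(tuple(config.pool[i] for i in subset), C=C, gamma=gamma))
    return pop


def select_best_half(population: list[Individual]) -> list[Individual]:
    """Top half by fitness; ties keep the lower-index individual (stable)."""
    if any(ind.fitness is None for ind in population):
        raise FitnessUnsetError("all individuals must be evaluated before selection")
    order = sorted(range(len(population)), key=lambda i: (-population[i].fitness, i))
    keep = sorted(order[: len(population) // 2])
    return [population[i] for i in keep]


def recombine_property_pool(
    parents: list[Individual],
    n_offspring: int,
    subset_size: int,
    rng: np.random.Generator,
) -> list[Individual]:
    """Property-pool recombination.

    The pool is the shuffled multiset union of the parents' subsets; each
    offspring draws properties one by one, keeping first occurrences and
    returning duplicates, until it holds ``subset_size`` distinct
    properties.  Properties shared by many fit parents are therefore more
    likely to be inherited.  Offspring (C, gamma) come from a uniformly
    chosen parent.
    """
    if not parents:
        raise ValueError("no parents to recombine")
    distinct = set().union(*(p.subset for p in parents))
    if len(distinct) < subset_size:
        raise ValueError(
            f"parents hold {len(distinct)} distinct properties; "
            f"cannot fill offspring of size {subset_size}"
        )
    multiset = [prop for p in parents for prop in p.subset]
    offspring = []
    for _ in range(n_offspring):
        pool = list(multiset)
        rng.shuffle(pool)
        held: list[str] = []
        seen: set[str] = set()
        i = 0
        while len(held) < subset_size:
            if i >= len(pool):  # duplicates put back: reshuffle the remainder
                pool = [p for p in pool if p not in seen]
                rng.shuffle(pool)
                i = 0
            prop = pool[i]
            i += 1
            if prop not in seen:
                seen.add(prop)
                held.append(prop)
        donor = parents[int(rng.integers(len(parents)))]
        offspring.append(Individual(tuple(held), C=donor.C, gamma=donor.gamma))
    return offspring


def mutation_count(n_g: int, s: int, m: float, n_total: int) -> int:
    """Mutations per offspring at generation n_g: exponential decay.

    N_M = max(1, round(s*m*exp(-lambda*n_g/N_G))) with lambda = ln(s*m),
    so the schedule starts at round(s*m) and reaches 1 at the final
    generation; it is non-increasing throughout.
    """
    if not (0 <= n_g <= n_total):
        raise ValueError("generation counter outside [0, N_G]")
    if not (0 < m < 1):
        raise ValueError("mutation value m must lie in (0, 1)")
    start = s * m
    if start <= 1:
        return 1
    lam = math.log(start)
    return max(1, round(start * math.exp(-lam * n_g / n_total)))


def mutate(
    individual: Individual,
    n_mutations: int,
    pool: tuple[str, ...],
    rng: np.random.Generator,
    param_sigma: float = 0.1,
) -> Individual:
    """Swap ``n_mutations`` subset members for uniformly chosen non-members.

    Cardinality is preserved; (C, gamma) are perturbed log-normally so
    kernel parameters co-evolve with the subset.  If fewer non-members
    exist than requested swaps, as many as available are swapped.
    """
    current = list(individual.subset)
    outside = sorted(set(pool) - set(current))
    n = min(n_mutations, len(outside), len(current))
    if n < n_mutations:
        log.warning("requested %d mutations, only %d possible", n_mutations, n)
    if n > 0:
        drop = rng.choice(len(current), size=n, replace=False)
        add = rng.choice(len(outside), size=n, replace=False)
        keep = [p for i, p in enumerate(current) if i not in set(drop.tolist())]
        current = keep + [outside[i] for i in add]
    C = individual.C * float(np.exp(rng.normal(0.0, param_sigma)))
    gamma = individual.gamma * float(np.exp(rng.normal(0.0, param_sigma)))
    return Individual(tuple(current), C=C, gamma=gamma, fitness=None)


def local_search(
    offspring: Individual,
    matrix: pd.DataFrame,
    labels: np.ndarray,
    rankings: dict[str, float],
    length: int = 8,
    cv_folds: int = 5,
    seed: int = 0,
) -> Individual:
    """F-score-guided Add/Delete improvement with strict acceptance.

    From the selected set S and excluded set E (both ranked by F-score,
    accession order breaking ties), up to ``length`` Add operations pull
    the best-ranked members of E in and up to ``length`` Delete operations
    push the worst-ranked members of S out; the merged candidate is
    trimmed/filled by rank back to the fixed cardinality.  The candidate
    replaces the offspring only if its CV fitness strictly improves.
    """
    size = len(offspring.subset)
    pool = sorted(rankings)
    in_set = set(offspring.subset)
    # rank best-first; ties by accession for reproducibility
    key = lambda p: (-rankings[p], p)
    S = sorted([p for p in pool if p in in_set], key=key)
    E = sorted([p for p in pool if p not in in_set], key=key)

    n_ops = min(length, len(E), len(S))
    adds = E[:n_ops]  # highest-ranked excluded
    dels = S[-n_ops:] if n_ops else []  # lowest-ranked selected

    candidate = (in_set | set(adds)) - set(dels)
    ranked = sorted(candidate, key=key)
    if len(ranked) > size:
        ranked = ranked[:size]
    else:
        fill = [p for p in E if p not in candidate]
        ranked += fill[: size - len(ranked)]
    improved = Individual(tuple(ranked), C=offspring.C, gamma=offspring.gamma)

    base = offspring.fitness
    if base is None:
        base = svm_cv_fitness(
            matrix[list(offspring.subset)], labels, (offspring.C, offspring.gamma),
            folds=cv_folds, seed=seed,
        )
        offspring = replace(offspring, fitness=base)
    new_fit = svm_cv_fitness(
        matrix[list(improved.subset)], labels, (improved.C, improved.gamma),
        folds=cv_folds, seed=seed,
    )
    if new_fit > base:
        return replace(improved, fitness=new_fit)
    return offspring


def run_memetic(
    matrix: pd.DataFrame,
    labels: np.ndarray,
    config: MAConfig,
) -> tuple[Individual, MAHistory]:
    """Full memetic loop; returns the fittest individual ever seen.

    Per generation: evaluate unevaluated individuals, log the elite,
    select the best half, recombine, mutate with the decaying schedule,
    improve offspring by local search, and replace the worst half.  Stops
    at ``config.generations`` or when the best fitness has not improved
    for ``config.patience`` generations.
    """
    missing = set(config.pool) - set(map(str, matrix.columns))
    if missing:
        raise ValueError(f"matrix lacks pool properties: {sorted(missing)[:5]} ...")
    y = np.asarray(labels)
    rng = np.random.default_rng(config.seed)
    rankings = rank_by_f_score(matrix[list(config.pool)], y)

    def evaluate(ind: Individual) -> Individual:
        if ind.fitness is not None:
            return ind
        fit = svm_cv_fitness(
            matrix[list(ind.subset)], y, (ind.C, ind.gamma),
            folds=config.cv_folds, seed=config.seed,
        )
        return replace(ind, fitness=fit)

    population = [evaluate(ind) for ind in init_population(config, rng)]
    history = MAHistory()
    best = max(population, key=lambda i: i.fitness)
    stale = 0

    for gen in range(config.generations):
        n_mut = mutation_count(
            gen, config.subset_size, config.mutation_value, config.generations
        )
        parents = select_best_half(population)
        offspring = recombine_property_pool(
            parents, len(population) - len(parents), config.subset_size, rng
        )
        offspring = [
            mutate(o, n_mut, config.pool, rng, config.param_sigma) for o in offspring
        ]
        offspring = [evaluate(o) for o in offspring]
        offspring = [
            local_search(
                o, matrix, y, rankings,
                length=config.local_search_length,
                cv_folds=config.cv_folds, seed=config.seed,
            )
            for o in offspring
        ]
        population = parents + offspring
        gen_best = max(population, key=lambda i: i.fitness)
        if gen_best.fitness > best.fitness:
            best = gen_best
            stale = 0
        else:
            stale += 1
        history.records.append(
            GenerationRecord(
                generation=gen,
                best_fitness=best.fitness,
                mean_fitness=float(np.mean([i.fitness for i in population])),
                n_mutations=n_mut,
                best_subset=best.subset,
            )
        )
        log.info(
            "generation %d: best=%.4f mean=%.4f N_M=%d",
            gen, best.fitness, history.records[-1].mean_fitness, n_mut,
        )
        if stale >= config.patience:
            log.info("early stop: best fitness flat for %d generations", stale)
            break
    return best, history


class MemeticFeatureSelector(SelectorMixin, BaseEstimator):
    """Sklearn-style selector wrapping the memetic algorithm.

    ``fit(X, y)`` runs the MA over the columns of X (the property pool);
    fitted attributes: ``best_individual_``, ``history_`` (DataFrame),
    ``selected_`` (accessions), ``support_``.
    """

    def __init__(
        self,
        subset_size: int = 40,
        pop_size: int = 10,
        generations: int = 100,
        mutation_value: float = 0.2,
        local_search_length: int = 8,
        cv_folds: int = 5,
        patience: int = 15,
        random_state: int = 0,
    ):
        self.subset_size = subset_size
        self.pop_size = pop_size
        self.generations = generations
        self.mutation_value = mutation_value
        self.local_search_length = local_search_length
        self.cv_folds = cv_folds
        self.patience = patience
        self.random_state = random_state

    def fit(self, X, y):
        X = pd.DataFrame(X)
        X.columns = [str(c) for c in X.columns]
        config = MAConfig(
            pool=tuple(X.columns),
            pop_size=self.pop_size,
            subset_size=self.subset_size,
            generations=self.generations,
            mutation_value=self.mutation_value,
            local_search_length=self.local_search_length,
            cv_folds=self.cv_folds,
            seed=self.random_state,
            patience=self.patience,
        )
        best, history = run_memetic(X, np.asarray(y), config)
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.best_individual_ = best
        self.history_ = history.to_frame()
        self.selected_ = list(best.subset)
        chosen = set(best.subset)
        self.support_ = np.array([c in chosen for c in X.columns])
        return self

    def _get_support_mask(self):
        return self.support_

    def to_json(self) -> str:
        ind = self.best_individual_
        return json.dumps(
            {
                "selected": list(ind.subset),
                "fitness": ind.fitness,
                "svm_params": {"C": ind.C, "gamma": ind.gamma},
            },
            indent=2,
        )
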