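"""Genetic-algorithm train/test partitioning with matched distributions.

Splits a cohort into train and test sets of fixed sizes while making the
two sides statistically equivalent: the fitness of a candidate membership
vector is the mean per-feature distribution distance (two-sample
Kolmogorov-Smirnov statistic for continuous features, total-variation
distance between category frequencies for categorical ones) plus the
absolute difference in CR prevalence.  Lower is better; a perfect split of
mirrored duplicates scores 0.

The GA itself uses tournament selection, uniform crossover followed by a
count repair that restores the train-set cardinality, swap mutation, and
elitism of one, so the best-ever fitness is monotone non-increasing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp

from .synthetic_data import Cohort, substream

__all__ = [
    "PartitionConfig",
    "Partition",
    "distribution_distance",
    "partition_fitness",
    "ga_partition",
    "random_partitions_fitness",
]


@dataclass(frozen=True)
class PartitionConfig:
    train_size: int = 191
    test_size: int = 100
    population_size: int = 100
    generations: int = 200
    tournament_size: int = 3
    crossover_rate: float = 0.9
    mutation_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.train_size < 1 or self.test_size < 1:
            raise ValueError("train and test sizes must be positive")
        for name in ("crossover_rate", "mutation_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]; got {rate}")
        if self.population_size < 2:
            raise ValueError("population_size must be at least 2")
        if self.tournament_size < 1:
            raise ValueError("tournament_size must be at least 1")


@dataclass
class Partition:
    membership: np.ndarray  # 1 = train, 0 = test
    fitness: float
    per_feature_distance: dict[str, float]
    history: np.ndarray  # best-ever fitness per generation


def distribution_distance(train_values, test_values, feature_kind: str) -> float:
    """Two-sample distance between the train and test marginals.

    Continuous features use the two-sample Kolmogorov-Smirnov statistic;
    categorical features the total-variation distance between category
    frequency vectors.  Both lie in [0, 1], 0 iff the empirical marginals
    coincide.
    """
    tr = np.asarray(train_values)
    te = np.asarray(test_values)
    if tr.size == 0 or te.size == 0:
        raise ValueError("both sides must be non-empty")
    if feature_kind == "continuous":
        return float(ks_2samp(tr.astype(float), te.astype(float)).statistic)
    if feature_kind == "categorical":
        levels = np.unique(np.concatenate([tr.astype(str), te.astype(str)]))
        p = np.array([(tr.astype(str) == lv).mean() for lv in levels])
        q = np.array([(te.astype(str) == lv).mean() for lv in levels])
        return float(0.5 * np.abs(p - q).sum())
    raise ValueError(f"unknown feature kind {feature_kind!r}")


def _feature_kinds(cohort: Cohort) -> dict[str, str]:
    kinds = {}
    for name in cohort.feature_names:
        col = cohort.data[name]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            kinds[name] = "categorical"
        else:
            kinds[name] = "continuous"
    return kinds


class _FitnessEngine:
    """Vectorised fitness evaluation for repeated membership queries.

    Continuous columns are pre-sorted once; a membership's KS statistic per
    column is then one gather + cumsum, evaluated only at the last
    occurrence of each distinct value (matching the exact two-sample KS
    definition under ties).  Categorical columns are pre-encoded as integer
    codes and compared through bincounts.
    """

    def __init__(self, cohort: Cohort, train_size: int, test_size: int) -> None:
        if train_size < 1 or test_size < 1:
            raise ValueError("both sides of the split must be non-empty")
        if train_size + test_size != cohort.n_patients:
            raise ValueError(
                f"train_size + test_size must equal the cohort size "
                f"({train_size} + {test_size} != {cohort.n_patients})"
            )
        self.n = cohort.n_patients
        self.n_train = train_size
        self.n_test = test_size
        kinds = _feature_kinds(cohort)
        self.cont_names = [f for f, k in kinds.items() if k == "continuous"]
        self.cat_names = [f for f, k in kinds.items() if k == "categorical"]
        self.n_features = len(kinds)

        cont = cohort.data[self.cont_names].to_numpy(dtype=float)
        self.cont_order = np.argsort(cont, axis=0, kind="stable")
        sorted_vals = np.take_along_axis(cont, self.cont_order, axis=0)
        # last occurrence of each distinct value in sorted order
        self.last_occ = np.ones_like(sorted_vals, dtype=bool)
        self.last_occ[:-1] = sorted_vals[:-1] != sorted_vals[1:]

        self.cat_codes = []
        for name in self.cat_names:
            codes, _ = pd.factorize(cohort.data[name].astype(str), sort=True)
            self.cat_codes.append(codes)
        self.cr = (cohort.data["rt_label"] == "CR").to_numpy()

    def feature_distances(self, membership: np.ndarray) -> dict[str, float]:
        m = np.asarray(membership)
        train_flag = np.take_along_axis(
            np.broadcast_to(m[:, None], self.cont_order.shape), self.cont_order, axis=0
        ).astype(np.float64)
        cum_tr = np.cumsum(train_flag, axis=0)
        pos = np.arange(1, self.n + 1, dtype=np.float64)[:, None]
        diff = np.abs(cum_tr / self.n_train - (pos - cum_tr) / self.n_test)
        diff[~self.last_occ] = 0.0
        ks = diff.max(axis=0)
        distances = dict(zip(self.cont_names, ks.tolist()))
        tr_mask = m.astype(bool)
        for name, codes in zip(self.cat_names, self.cat_codes):
            k = codes.max() + 1
            p = np.bincount(codes[tr_mask], minlength=k) / self.n_train
            q = np.bincount(codes[~tr_mask], minlength=k) / self.n_test
            distances[name] = float(0.5 * np.abs(p - q).sum())
        return distances

    def prevalence_gap(self, membership: np.ndarray) -> float:
        tr_mask = np.asarray(membership).astype(bool)
        return float(abs(self.cr[tr_mask].mean() - self.cr[~tr_mask].mean()))

    def fitness(self, membership: np.ndarray) -> float:
        self._check(membership)
        distances = self.feature_distances(membership)
        return float(np.mean(list(distances.values())) + self.prevalence_gap(membership))

    def _check(self, membership: np.ndarray) -> None:
        m = np.asarray(membership)
        if m.shape != (self.n,) or not np.isin(m, (0, 1)).all():
            raise ValueError("membership must be a binary vector over all patients")
        if int(m.sum()) != self.n_train:
            raise ValueError(
                f"membership must select exactly {self.n_train} training patients"
            )


def partition_fitness(
    cohort: Cohort, membership: Sequence[int], test_size: int | None = None
) -> float:
    """Fitness of a membership vector: mean feature distance + prevalence gap."""
    m = np.asarray(membership)
    n_train = int(m.sum())
    engine = _FitnessEngine(cohort, n_train, cohort.n_patients - n_train)
    return engine.fitness(m)


# ---------------------------------------------------------------------------
# genetic algorithm
# ---------------------------------------------------------------------------


def _repair(member: np.ndarray, n_train: int, rng: np.random.Generator) -> None:
    """Random flips restoring the train-set cardinality, in place."""
    excess = int(member.sum()) - n_train
    if excess > 0:
        ones = np.flatnonzero(member == 1)
        member[rng.choice(ones, size=excess, replace=False)] = 0
    elif excess < 0:
        zeros = np.flatnonzero(member == 0)
        member[rng.choice(zeros, size=-excess, replace=False)] = 1


def ga_partition(cohort: Cohort, config: PartitionConfig) -> Partition:
    """Evolve a distribution-matched train/test split.

    Fixed-cardinality membership vectors evolve under tournament selection,
    uniform crossover with count repair, swap mutation and single elitism;
    the best-ever individual is returned.  Deterministic given the seed.
    """
    engine = _FitnessEngine(cohort, config.train_size, config.test_size)
    rng = substream(config.seed, "partition_ga")
    n = cohort.n_patients

    def random_member() -> np.ndarray:
        m = np.zeros(n, dtype=np.int8)
        m[rng.choice(n, size=config.train_size, replace=False)] = 1
        return m

    population = [random_member() for _ in range(config.population_size)]
    fitnesses = np.array([engine.fitness(m) for m in population])
    best_idx = int(fitnesses.argmin())
    best = population[best_idx].copy()
    best_fit = float(fitnesses[best_idx])
    history = [best_fit]

    def tournament() -> np.ndarray:
        idx = rng.integers(0, config.population_size, size=config.tournament_size)
        return population[idx[fitnesses[idx].argmin()]]

    for _ in range(config.generations):
        new_pop = [best.copy()]  # elitism of 1
        while len(new_pop) < config.population_size:
            p1, p2 = tournament(), tournament()
            if rng.random() < config.crossover_rate:
                mask = rng.random(n) < 0.5
                child = np.where(mask, p1, p2).astype(np.int8)
                _repair(child, config.train_size, rng)
            else:
                child = p1.copy()
            if rng.random() < config.mutation_rate:
                ones = np.flatnonzero(child == 1)
                zeros = np.flatnonzero(child == 0)
                if ones.size and zeros.size:
                    child[rng.choice(ones)] = 0
                    child[rng.choice(zeros)] = 1
            new_pop.append(child)
        population = new_pop
        fitnesses = np.array([engine.fitness(m) for m in population])
        gen_best = int(fitnesses.argmin())
        if fitnesses[gen_best] < best_fit:
            best_fit = float(fitnesses[gen_best])
            best = population[gen_best].copy()
        history.append(best_fit)

    return Partition(
        membership=best.astype(int),
        fitness=best_fit,
        per_feature_distance=engine.feature_distances(best),
        history=np.array(history),
    )


def random_partitions_fitness(
    cohort: Cohort,
    train_size: int,
    test_size: int,
    n_draws: int,
    seed: int = 0,
) -> np.ndarray:
    """Fitness of ``n_draws`` uniformly random splits (a GA baseline)."""
    engine = _FitnessEngine(cohort, train_size, test_size)
    rng = substream(seed, "random_partitions")
    n = cohort.n_patients
    out = np.empty(n_draws)
    for i in range(n_draws):
        m = np.zeros(n, dtype=np.int8)
        m[rng.choice(n, size=train_size, replace=False)] = 1
        out[i] = engine.fitness(m)
    return out
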