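"""CHC genetic-algorithm feature selection maximising pooled OOB G mean.

Eshelman's CHC algorithm: half-uniform crossover (HUX) exchanging exactly
half the differing bits, incest prevention (parents mate only when their
Hamming distance is large enough), cross-generational elitist survival of
the best population_size individuals, and a cataclysmic restart seeded
from the best individual when the incest threshold is exhausted.  An
individual is a feature bitstring; its fitness is the pooled out-of-bag
G mean of forests trained on the selected columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import purf

logger = logging.getLogger(__name__)

__all__ = [
    "Individual",
    "GAConfig",
    "FitnessConfig",
    "hux_crossover",
    "evaluate_fitness",
    "run_chcga",
    "GAResult",
]


@dataclass(eq=False)
class Individual:
    """A candidate feature subset with its evaluated fitness.

    Identity (not value) equality, so survivor bookkeeping tracks object
    membership in the population.
    """

    bits: np.ndarray  # boolean, length = number of features
    fitness: float | None = None
    rf_seed: int = 0

    def key(self) -> bytes:
        return np.packbits(self.bits).tobytes()


@dataclass(frozen=True)
class FitnessConfig:
    """RF settings used to score a feature subset.

    ``n_forests`` forests are pooled per evaluation (smaller than a full
    grid search; a documented speed/fidelity trade-off), each with the
    dataset's optimal positive weight and mtry (capped at subset size).
    """

    number_trees: int = 100
    mtry: int = 10
    positive_weight: float = 1.0
    n_forests: int = 2
    min_node_size: int = 1


@dataclass
class GAConfig:
    population_size: int = 20
    divergence_rate: float = 0.35
    max_generations: int = 30
    max_restarts: int = 3
    fitness: FitnessConfig = field(default_factory=FitnessConfig)
    number_trees_sweep: tuple[int, ...] = ()  # empty -> fitness.number_trees
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2 or self.population_size % 2:
            raise ValueError("population_size must be even and >= 2")
        if not 0.0 < self.divergence_rate < 1.0:
            raise ValueError("divergence_rate must be in (0, 1)")


@dataclass
class GAResult:
    best_bits: np.ndarray
    best_fitness: float
    rf_seed: int
    number_trees: int
    selected_features: list[str]
    trace: pd.DataFrame  # generation, best, mean, d, restarts, number_trees


def hux_crossover(parent1: np.ndarray, parent2: np.ndarray, rng
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Half-uniform crossover: swap exactly floor(H/2) differing bits.

    The swapped positions are chosen uniformly at random among the H
    positions where the parents differ, so each child keeps the parental
    Hamming distance to the other child.
    """
    p1 = np.asarray(parent1, dtype=bool)
    p2 = np.asarray(parent2, dtype=bool)
    if p1.shape != p2.shape:
        raise ValueError("parents must have equal length")
    differing = np.flatnonzero(p1 != p2)
    child1, child2 = p1.copy(), p2.copy()
    n_swap = differing.size // 2
    if n_swap:
        swap = rng.choice(differing, size=n_swap, replace=False)
        child1[swap] = p2[swap]
        child2[swap] = p1[swap]
    return child1, child2


def evaluate_fitness(
    individual: Individual,
    table: pd.DataFrame,
    labels,
    fitness_config: FitnessConfig,
    _memo: dict | None = None,
) -> float:
    """Pooled OOB G mean of forests on the individual's feature columns.

    Memoised by (bitstring, rf_seed).  An empty subset scores 0 by
    convention (logged).
    """
    if _memo is not None:
        cached = _memo.get((individual.key(), individual.rf_seed))
        if cached is not None:
            individual.fitness = cached
            return cached
    k = int(individual.bits.sum())
    if k == 0:
        logger.warning("empty feature subset: fitness 0")
        individual.fitness = 0.0
        return 0.0
    columns = [c for c, b in zip(table.columns, individual.bits) if b]
    sub = table[columns]
    y = np.asarray(labels, dtype=int)
    seed_rng = np.random.default_rng(individual.rf_seed)
    tp = fn = tn = fp = 0
    for _ in range(fitness_config.n_forests):
        config = purf.RFConfig(
            number_trees=fitness_config.number_trees,
            mtry=min(fitness_config.mtry, k),
            positive_weight=fitness_config.positive_weight,
            seed=int(seed_rng.integers(0, 2**31 - 1)),
            min_node_size=fitness_config.min_node_size,
        )
        model = purf.train_forest(sub, y, config)
        cc = purf.confusion_from_predictions(
            purf.oob_similarity(model, sub), y
        )
        tp += cc.tp
        fn += cc.fn
        tn += cc.tn
        fp += cc.fp
    fitness = purf.ConfusionCounts(tp=tp, fn=fn, tn=tn, fp=fp).g_mean
    individual.fitness = fitness
    if _memo is not None:
        _memo[(individual.key(), individual.rf_seed)] = fitness
    return fitness


def _random_individual(n_features, rng, rf_seed) -> Individual:
    bits = rng.random(n_features) < 0.5
    if not bits.any():
        bits[rng.integers(0, n_features)] = True
    return Individual(bits=bits, rf_seed=rf_seed)


def _cataclysm(best: Individual, population_size, divergence_rate, rng
               ) -> list[Individual]:
    """Restart: keep the best, re-seed the rest by flipping a fraction of
    its bits."""
    n = best.bits.size
    n_flip = max(1, round(divergence_rate * n))
    fresh = [best]
    for _ in range(population_size - 1):
        bits = best.bits.copy()
        flip = rng.choice(n, size=n_flip, replace=False)
        bits[flip] = ~bits[flip]
        if not bits.any():
            bits[rng.integers(0, n)] = True
        fresh.append(Individual(bits=bits, rf_seed=best.rf_seed))
    return fresh


def _run_one_repetition(
    table, labels, config: GAConfig, number_trees: int,
    rf_seed: int, rng, memo,
) -> tuple[Individual, list[dict]]:
    n_features = table.shape[1]
    fitness_config = FitnessConfig(
        number_trees=number_trees,
        mtry=config.fitness.mtry,
        positive_weight=config.fitness.positive_weight,
        n_forests=config.fitness.n_forests,
        min_node_size=config.fitness.min_node_size,
    )

    def score(ind):
        return evaluate_fitness(ind, table, labels, fitness_config, memo)

    population = [
        _random_individual(n_features, rng, rf_seed)
        for _ in range(config.population_size)
    ]
    for ind in population:
        score(ind)
    population.sort(key=lambda i: i.fitness, reverse=True)
    best = population[0]
    d = n_features // 4  # initial incest threshold d0
    restarts = 0
    trace = []
    for generation in range(config.max_generations):
        order = rng.permutation(config.population_size)
        children = []
        for a, b in zip(order[::2], order[1::2]):
            p1, p2 = population[a], population[b]
            hamming = int((p1.bits != p2.bits).sum())
            if hamming / 2.0 <= d:
                continue  # incest prevention
            c1_bits, c2_bits = hux_crossover(p1.bits, p2.bits, rng)
            for bits in (c1_bits, c2_bits):
                if bits.any():
                    child = Individual(bits=bits, rf_seed=rf_seed)
                    score(child)
                    children.append(child)
        pool = population + children
        pool.sort(key=lambda i: i.fitness, reverse=True)
        survivors = pool[: config.population_size]
        child_survived = any(c in survivors for c in children)
        population = survivors
        if population[0].fitness > best.fitness:
            best = population[0]
        if not child_survived:
            d -= 1
        if d < 0:
            restarts += 1
            if restarts > config.max_restarts:
                trace.append({"generation": generation,
                              "best_fitness": best.fitness,
                              "mean_fitness": float(np.mean(
                                  [i.fitness for i in population])),
                              "d": d, "restarts": restarts,
                              "number_trees": number_trees})
                break
            population = _cataclysm(
                best, config.population_size, config.divergence_rate, rng
            )
            for ind in population[1:]:
                score(ind)
            d = round(config.divergence_rate
                      * (1.0 - config.divergence_rate) * n_features)
        trace.append({"generation": generation,
                      "best_fitness": best.fitness,
                      "mean_fitness": float(np.mean(
                          [i.fitness for i in population])),
                      "d": d, "restarts": restarts,
                      "number_trees": number_trees})
    return best, trace


def run_chcga(table: pd.DataFrame, labels, config: GAConfig) -> GAResult:
    """Run the CHC-GA for each forest size in the sweep; return the fittest.

    Each repetition draws its own RF seed from the master seed; the
    winner is reported together with that seed and its forest size,
    mirroring the optimal (feature subset, random seed) pair the final
    model is trained with.
    """
    rng = np.random.default_rng(config.seed)
    sweep = config.number_trees_sweep or (config.fitness.number_trees,)
    memo: dict = {}
    best: Individual | None = None
    best_trees = sweep[0]
    traces = []
    for number_trees in sweep:
        rf_seed = int(rng.integers(0, 2**31 - 1))
        winner, trace = _run_one_repetition(
            table, labels, config, number_trees, rf_seed, rng, memo
        )
        traces.extend(trace)
        if best is None or winner.fitness > best.fitness:
            best = winner
            best_trees = number_trees
    selected = [c for c, b in zip(table.columns, best.bits) if b]
    return GAResult(
        best_bits=best.bits,
        best_fitness=float(best.fitness),
        rf_seed=best.rf_seed,
        number_trees=best_trees,
        selected_features=selected,
        trace=pd.DataFrame(traces),
    )
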