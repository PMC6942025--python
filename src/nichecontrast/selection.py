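"""Weather-variable subset selection by genetic algorithm.

A chromosome is an inclusion bitmask over the candidate variables.  Its
fitness is the observation-weighted f1 of a classifier trained on the
included columns and evaluated under a stratified hold-out (default) or
k-fold protocol; the per-species subsampling cap is applied inside each
evaluation, before the split.  The empty subset scores -inf and can never
be selected.

Operators: tournament selection (size 2), uniform crossover, per-bit
mutation (default rate 1/n_candidates), elitism 1 — with elitism the
best-so-far fitness trace is monotone non-decreasing.

:func:`exhaustive_select` evaluates every nonempty subset with the same
fitness protocol and serves as the small-candidate-pool oracle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split

from .classifier import TrainingConfig, build_training_set, train
from .evaluation import weighted_f1
from .geodata_io import FeatureTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GAConfig:
    candidates: tuple[str, ...]
    population: int = 30
    generations: int = 25
    crossover_rate: float = 0.9
    mutation_rate: float | None = None  # default 1 / len(candidates)
    elitism: int = 1
    holdout_fraction: float = 0.25  # fitness protocol: stratified holdout
    k_folds: int | None = None  # set to use k-fold instead of holdout
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.candidates:
            raise ValueError("candidate list must be non-empty")
        if self.population < 2:
            raise ValueError("population must be >= 2")
        if self.generations < 1:
            raise ValueError("need at least 1 generation")
        for rate in (self.crossover_rate, self.mutation_rate):
            if rate is not None and not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.elitism < 0:
            raise ValueError("elitism must be nonnegative")
        if not 0.0 < self.holdout_fraction < 1.0:
            raise ValueError("holdout fraction must lie in (0, 1)")

    @property
    def effective_mutation_rate(self) -> float:
        return (self.mutation_rate if self.mutation_rate is not None
                else 1.0 / len(self.candidates))


class _FitnessEvaluator:
    """Caches subset fitness; the protocol seed is fixed per run, so a
    chromosome's fitness is a pure function of its bitmask."""

    def __init__(self, table: FeatureTable, tconfig: TrainingConfig,
                 gconfig: GAConfig):
        missing = [c for c in gconfig.candidates if c not in table.variables]
        if missing:
            raise ValueError(f"table lacks candidate columns {missing}")
        self.table = table
        self.tconfig = tconfig
        self.gconfig = gconfig
        self.cache: dict[tuple[str, ...], float] = {}
        self.n_evaluations = 0

    def __call__(self, mask: np.ndarray) -> float:
        subset = tuple(c for c, b in zip(self.gconfig.candidates, mask) if b)
        if not subset:
            return -np.inf
        if subset in self.cache:
            return self.cache[subset]
        fitness = self._evaluate(subset)
        self.cache[subset] = fitness
        self.n_evaluations += 1
        return fitness

    def _evaluate(self, subset: tuple[str, ...]) -> float:
        seed = self.gconfig.seed
        sub = FeatureTable(self.table.data, list(subset))
        capped = build_training_set(sub, seed=seed, config=self.tconfig)
        y = capped.data["label"].to_numpy()
        if self.gconfig.k_folds:
            scores = []
            skf = StratifiedKFold(n_splits=self.gconfig.k_folds)
            for tr, te in skf.split(capped.data, y):
                scores.append(self._fit_score(capped, tr, te))
            return float(np.mean(scores))
        idx = np.arange(len(capped.data))
        tr, te = train_test_split(
            idx, test_size=self.gconfig.holdout_fraction, stratify=y,
            random_state=seed % 2 ** 31)
        return self._fit_score(capped, tr, te)

    def _fit_score(self, table: FeatureTable, tr, te) -> float:
        train_part = table.subset(np.isin(np.arange(len(table)), tr))
        test_part = table.subset(np.isin(np.arange(len(table)), te))
        model = train(train_part, self.tconfig)
        predicted = model.predict_class(test_part)
        return weighted_f1(test_part.data["label"], predicted)


def ga_select(table: FeatureTable, tconfig: TrainingConfig,
              gconfig: GAConfig) -> tuple[list[str], list[float]]:
    """Evolve variable subsets; returns (best subset ever seen, trace).

    The trace holds the best-so-far fitness after each generation
    (non-decreasing when elitism >= 1).
    """
    evaluate = _FitnessEvaluator(table, tconfig, gconfig)
    n = len(gconfig.candidates)
    rng = np.random.default_rng(gconfig.seed)
    pop = rng.random((gconfig.population, n)) < 0.5
    if not pop.any() and gconfig.effective_mutation_rate == 0:
        raise ValueError("all-zero initial population with zero mutation "
                         "rate can never produce a nonempty subset")
    fitness = np.array([evaluate(ind) for ind in pop])

    best_mask = pop[int(np.argmax(fitness))].copy()
    best_fit = float(fitness.max())
    trace: list[float] = []
    p_mut = gconfig.effective_mutation_rate

    for _ in range(gconfig.generations):
        order = np.argsort(fitness)[::-1]
        elite = pop[order[:gconfig.elitism]].copy()
        children: list[np.ndarray] = []
        while len(children) < gconfig.population - gconfig.elitism:
            pa = _tournament(rng, fitness)
            pb = _tournament(rng, fitness)
            a, b = pop[pa].copy(), pop[pb].copy()
            if rng.random() < gconfig.crossover_rate:
                swap = rng.random(n) < 0.5
                a[swap], b[swap] = pop[pb][swap], pop[pa][swap]
            for child in (a, b):
                flip = rng.random(n) < p_mut
                child[flip] = ~child[flip]
                children.append(child)
        pop = np.vstack([elite, *children[:gconfig.population - gconfig.elitism]])
        fitness = np.array([evaluate(ind) for ind in pop])
        gen_best = int(np.argmax(fitness))
        if fitness[gen_best] > best_fit:
            best_fit = float(fitness[gen_best])
            best_mask = pop[gen_best].copy()
        trace.append(best_fit)

    subset = [c for c, b in zip(gconfig.candidates, best_mask) if b]
    logger.info("ga_select: best fitness %.4f with %d/%d variables "
                "(%d subset evaluations)", best_fit, len(subset), n,
                evaluate.n_evaluations)
    return subset, trace


def _tournament(rng: np.random.Generator, fitness: np.ndarray,
                size: int = 2) -> int:
    contenders = rng.integers(0, len(fitness), size=size)
    return int(contenders[np.argmax(fitness[contenders])])


def exhaustive_select(table: FeatureTable, tconfig: TrainingConfig,
                      gconfig: GAConfig) -> tuple[list[str], float]:
    """Evaluate every nonempty candidate subset; the oracle for ga_select.

    Refuses more than 12 candidates (4095 subsets).  Ties break toward the
    smaller, then lexicographically earlier, subset.
    """
    n = len(gconfig.candidates)
    if n > 12:
        raise ValueError(f"{n} candidates would need {2 ** n - 1} "
                         "evaluations; exhaustive search is capped at 12")
    evaluate = _FitnessEvaluator(table, tconfig, gconfig)
    best: tuple[float, int, tuple[str, ...]] | None = None
    for code in range(1, 2 ** n):
        mask = np.array([(code >> i) & 1 for i in range(n)], dtype=bool)
        fit = evaluate(mask)
        subset = tuple(c for c, b in zip(gconfig.candidates, mask) if b)
        key = (-fit, len(subset), subset)
        if best is None or key < best:
            best = key
    assert best is not None
    return list(best[2]), -best[0]
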