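"""Search over alanine-substitution masks under a fixed evaluation budget.

The genome is a binary mask over binding-site candidate residues; fitness is
the exploration-set ROC–AUC of the structure predicted from the correspondingly
perturbed MSA. Two strategies are provided:

* random search — i.i.d. masks with per-bit probability 0.5, evaluated until
  the budget is spent;
* a generational GA — tournament selection, uniform crossover, per-bit flip
  mutation, elitism — tuned so population × generations equals the same
  structure budget (default 1100 evaluations).

Duplicate masks hit a fitness cache and do not consume budget: the budget
counts unique predicted structures. An evaluator failure (rejected model,
backend crash) scores 0.0, the floor of the ROC–AUC range, and the run
continues.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .msa import MutationMask

__all__ = [
    "Individual",
    "GAConfig",
    "GenerationRecord",
    "Trajectory",
    "random_mask",
    "run_random_search",
    "run_ga",
    "evaluate_on_test",
]

log = logging.getLogger(__name__)

Evaluator = Callable[[MutationMask], float]


@dataclass
class Individual:
    mask: MutationMask
    fitness: float | None = None  # None = UNEVALUATED
    structure_ref: str = ""

    def __post_init__(self) -> None:
        if self.fitness is not None and not (0.0 <= self.fitness <= 1.0):
            raise ValueError("fitness must lie in [0, 1]")


@dataclass
class GAConfig:
    """GA hyperparameters; defaults spend the 1100-structure budget as 50 × 22."""

    population_size: int = 50
    n_generations: int = 22
    crossover_prob: float = 0.9
    per_bit_mutation_prob: float | None = None  # None → 1/mask_length
    tournament_size: int = 3
    n_elite: int = 1
    seed: int = 0
    budget: int = 1100

    def __post_init__(self) -> None:
        if self.population_size * self.n_generations > self.budget:
            raise ValueError("population_size × n_generations exceeds budget")
        if self.n_elite >= self.population_size:
            raise ValueError("n_elite must be smaller than population_size")


@dataclass
class GenerationRecord:
    generation: int
    best_fitness: float
    best_mask: str
    test_fitness: float | None = None


@dataclass
class Trajectory:
    """Per-generation records plus the overall best individual."""

    records: list[GenerationRecord] = field(default_factory=list)
    best: Individual | None = None
    n_evaluations: int = 0
    residue_indices: list[int] = field(default_factory=list)
    initial_masks: list[str] = field(default_factory=list)  # generation-0 genomes

    def best_fitness_curve(self) -> list[float]:
        return [r.best_fitness for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "generation": [r.generation for r in self.records],
                "best_fitness": [r.best_fitness for r in self.records],
                "best_mask": [r.best_mask for r in self.records],
                "test_fitness": [r.test_fitness for r in self.records],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def random_mask(
    length: int,
    residue_indices: Sequence[int] | None = None,
    p: float = 0.5,
    rng: np.random.Generator | None = None,
) -> MutationMask:
    """Draw each bit independently 1 with probability ``p``."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    rng = rng or np.random.default_rng()
    idx = list(residue_indices) if residue_indices is not None else list(range(1, length + 1))
    bits = (rng.random(length) < p).astype(int).tolist()
    return MutationMask(idx, bits)


class _CachedEvaluator:
    """Wraps the raw evaluator: failure → 0.0, duplicates → cache, budget counts misses."""

    def __init__(self, evaluator: Evaluator, use_cache: bool = True):
        self._evaluator = evaluator
        self._cache: dict[str, float] = {}
        self._use_cache = use_cache
        self.n_evaluations = 0

    def __call__(self, mask: MutationMask) -> float:
        key = mask.as_string()
        if self._use_cache and key in self._cache:
            return self._cache[key]
        self.n_evaluations += 1
        try:
            fitness = float(self._evaluator(mask))
        except Exception as exc:  # a dead structure scores the AUC floor
            log.warning("evaluator failed for mask %s: %s", key, exc)
            fitness = 0.0
        fitness = min(max(fitness, 0.0), 1.0)
        self._cache[key] = fitness
        return fitness


def run_random_search(
    evaluator: Evaluator,
    length: int,
    residue_indices: Sequence[int] | None = None,
    budget: int = 1100,
    p: float = 0.5,
    seed: int = 0,
    test_evaluator: Evaluator | None = None,
) -> Trajectory:
    """Evaluate exactly ``budget`` i.i.d. masks; track the running best.

    Each draw counts against the budget whether or not the mask repeats — the
    patterns are determined completely at random, with no memory.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    rng = np.random.default_rng(seed)
    # memoryless by definition: every draw is a fresh structure evaluation
    cached = _CachedEvaluator(evaluator, use_cache=False)
    idx = list(residue_indices) if residue_indices is not None else list(range(1, length + 1))
    traj = Trajectory(residue_indices=idx)
    best: Individual | None = None
    for step in range(budget):
        mask = random_mask(length, idx, p=p, rng=rng)
        fitness = cached(mask)
        if best is None or fitness > best.fitness:
            best = Individual(mask=mask, fitness=fitness, structure_ref=f"rs-{step}")
        traj.records.append(
            GenerationRecord(step, best.fitness, best.mask.as_string())
        )
    traj.best = best
    traj.n_evaluations = budget
    if test_evaluator is not None and best is not None:
        traj.records[-1].test_fitness = evaluate_on_test(best, test_evaluator)
    return traj


def _tournament(
    pop: list[Individual], k: int, rng: np.random.Generator
) -> Individual:
    picks = rng.integers(0, len(pop), size=k)
    return max((pop[i] for i in picks), key=lambda ind: ind.fitness)


def _uniform_crossover(
    a: MutationMask, b: MutationMask, rng: np.random.Generator
) -> tuple[MutationMask, MutationMask]:
    take_a = rng.random(len(a)) < 0.5
    c1 = [x if t else y for x, y, t in zip(a.bits, b.bits, take_a)]
    c2 = [y if t else x for x, y, t in zip(a.bits, b.bits, take_a)]
    return (
        MutationMask(list(a.residue_indices), c1),
        MutationMask(list(a.residue_indices), c2),
    )


def _mutate(mask: MutationMask, p: float, rng: np.random.Generator) -> MutationMask:
    flips = rng.random(len(mask)) < p
    bits = [b ^ 1 if f else b for b, f in zip(mask.bits, flips)]
    return MutationMask(list(mask.residue_indices), bits)


def _dump_checkpoint(
    path: Path,
    gen: int,
    population: list[Individual],
    traj: Trajectory,
    best: Individual | None,
    cache: dict[str, float],
    rng: np.random.Generator,
) -> None:
    state = {
        "next_generation": gen + 1,
        "population": [
            {"bits": ind.mask.as_string(), "fitness": ind.fitness, "ref": ind.structure_ref}
            for ind in population
        ],
        "records": [
            {
                "generation": r.generation,
                "best_fitness": r.best_fitness,
                "best_mask": r.best_mask,
                "test_fitness": r.test_fitness,
            }
            for r in traj.records
        ],
        "best": None
        if best is None
        else {"bits": best.mask.as_string(), "fitness": best.fitness, "ref": best.structure_ref},
        "cache": cache,
        "n_evaluations": traj.n_evaluations,
        "initial_masks": traj.initial_masks,
        "rng_state": rng.bit_generator.state,
    }
    tmp = path.with_suffix(".tmp")
    tmp.write_text(json.dumps(state))
    tmp.replace(path)


def run_ga(
    evaluator: Evaluator,
    length: int,
    config: GAConfig,
    residue_indices: Sequence[int] | None = None,
    test_evaluator: Evaluator | None = None,
    checkpoint_path: str | Path | None = None,
) -> Trajectory:
    """Generational GA over masks; elitism makes the best curve non-decreasing.

    Generation 0 is drawn i.i.d. at p = 0.5. Every later generation keeps the
    ``n_elite`` best unchanged and fills the rest by tournament selection,
    uniform crossover (probability ``crossover_prob``) and per-bit mutation
    (default rate 1/length). Unique-structure evaluations never exceed the
    budget; repeated masks are served from cache. When ``checkpoint_path`` is
    given, state is written after every generation and an interrupted run
    resumes from the last completed generation.
    """
    rng = np.random.default_rng(config.seed)
    cached = _CachedEvaluator(evaluator)
    idx = list(residue_indices) if residue_indices is not None else list(range(1, length + 1))
    mut_p = config.per_bit_mutation_prob if config.per_bit_mutation_prob is not None else 1.0 / length

    traj = Trajectory(residue_indices=idx)
    best: Individual | None = None
    start_gen = 0
    ckpt = Path(checkpoint_path) if checkpoint_path is not None else None
    if ckpt is not None and ckpt.exists():
        state = json.loads(ckpt.read_text())
        start_gen = state["next_generation"]
        population = [
            Individual(
                mask=MutationMask.from_string(idx, d["bits"]),
                fitness=d["fitness"],
                structure_ref=d["ref"],
            )
            for d in state["population"]
        ]
        traj.records = [GenerationRecord(**r) for r in state["records"]]
        if state["best"] is not None:
            best = Individual(
                mask=MutationMask.from_string(idx, state["best"]["bits"]),
                fitness=state["best"]["fitness"],
                structure_ref=state["best"]["ref"],
            )
        cached._cache.update(state["cache"])
        cached.n_evaluations = state["n_evaluations"]
        traj.n_evaluations = state["n_evaluations"]
        traj.initial_masks = state.get("initial_masks", [])
        rng.bit_generator.state = state["rng_state"]
    else:
        population = [
            Individual(mask=random_mask(length, idx, p=0.5, rng=rng))
            for _ in range(config.population_size)
        ]
        traj.initial_masks = [ind.mask.as_string() for ind in population]
    for gen in range(start_gen, config.n_generations):
        for i, ind in enumerate(population):
            if ind.fitness is None:
                ind.fitness = cached(ind.mask)
                ind.structure_ref = f"ga-g{gen}-i{i}"
        gen_best = max(population, key=lambda ind: ind.fitness)
        if best is None or gen_best.fitness > best.fitness:
            best = gen_best
        rec = GenerationRecord(gen, best.fitness, best.mask.as_string())
        if test_evaluator is not None:
            rec.test_fitness = evaluate_on_test(best, test_evaluator)
        traj.records.append(rec)

        if gen == config.n_generations - 1:
            if ckpt is not None:
                traj.n_evaluations = cached.n_evaluations
                _dump_checkpoint(ckpt, gen, population, traj, best, cached._cache, rng)
            break
        elites = sorted(population, key=lambda ind: -ind.fitness)[: config.n_elite]
        children: list[Individual] = [
            Individual(mask=e.mask, fitness=e.fitness, structure_ref=e.structure_ref)
            for e in elites
        ]
        while len(children) < config.population_size:
            p1 = _tournament(population, config.tournament_size, rng)
            p2 = _tournament(population, config.tournament_size, rng)
            if rng.random() < config.crossover_prob:
                c1, c2 = _uniform_crossover(p1.mask, p2.mask, rng)
            else:
                c1, c2 = p1.mask, p2.mask
            for child in (c1, c2):
                if len(children) < config.population_size:
                    children.append(Individual(mask=_mutate(child, mut_p, rng)))
        population = children
        if ckpt is not None:
            traj.n_evaluations = cached.n_evaluations
            _dump_checkpoint(ckpt, gen, population, traj, best, cached._cache, rng)

    traj.best = best
    traj.n_evaluations = cached.n_evaluations
    return traj


def evaluate_on_test(best: Individual, test_evaluator: Evaluator) -> float:
    """Score an already-evaluated individual against held-out ligands.

    Purely observational: the result never feeds back into the search.
    """
    if best.fitness is None:
        raise ValueError("individual is UNEVALUATED; run the search first")
    return float(test_evaluator(best.mask))
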