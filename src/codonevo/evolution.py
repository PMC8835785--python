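"""Generational evolutionary loop for populations of coding systems.

Each generation every individual's fitness is (re)evaluated — with a fresh
reading-mechanism draw per label in ``sampled`` mode, so the reading
distribution itself is under selection — then tournament selection with
elitism fills the next generation and non-elite offspring are mutated.

Mutation resamples whole probability rows from a Dirichlet centered on the
current row, ``Dirichlet(kappa * row + eps)``: this keeps rows on the
simplex without renormalization hacks, has a single interpretable strength
knob (``mutation_concentration``), and the small floor ``eps`` keeps the
support full so no assignment is ever irrevocably lost.

Selection is tournament (default size 4) plus one elite: tournament is
scale-free, which matters because log-fitness spans hundreds of log units
early in a run, where fitness-proportionate selection degenerates
numerically.

Randomness: the master seed spawns independent named streams (init,
reading draws, mutation, selection) so toggling one operator does not shift
another's draws; runs are bit-reproducible from the config alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy.special import xlogy

from .model_core import (
    Individual,
    N_CODONS,
    N_LABELS,
    N_MODELS,
    ReadingModel,
    neighbor_index_table,
    neighborhood_sizes,
)

__all__ = [
    "EvolutionConfig",
    "Population",
    "SimulationResult",
    "mutate",
    "select",
    "run_simulation",
    "TRAJECTORY_COLUMNS",
]

logger = logging.getLogger(__name__)

#: Additive Dirichlet floor keeping mutated rows fully supported.
MUTATION_EPS = 0.01

TRAJECTORY_COLUMNS = [
    "generation",
    "mean_log_fitness",
    "best_log_fitness",
    "mean_Hc",
    "mean_Hr",
    "expected_labels_M1",
    "expected_labels_M2",
    "expected_labels_M3",
]


@dataclass(frozen=True)
class EvolutionConfig:
    """Parameters of one simulation run.

    Defaults reproduce the reference protocol (1000 coding systems evolved
    for 100,000 generations); scaled-down runs override ``population_size``
    and ``generations``.
    """

    population_size: int = 1000
    generations: int = 100_000
    seed: int = 0
    mutation_row_prob: float = 0.02
    mutation_reading_prob: float = 0.3
    mutation_concentration: float = 200.0
    mutation_reading_concentration: float = 0.05
    tournament_size: int = 4
    elite_count: int = 1
    fitness_mode: str = "sampled"  # "sampled" | "expected"
    record_every: int = 100
    m1_position: int = 3  # 1-based codon position varied by M1

    def validate(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")
        if not 0 <= self.elite_count < self.population_size:
            raise ValueError("elite_count must be in [0, population_size)")
        if self.tournament_size < 1:
            raise ValueError("tournament_size must be >= 1")
        for name in ("mutation_row_prob", "mutation_reading_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.mutation_concentration <= 0:
            raise ValueError("mutation_concentration must be > 0")
        if self.mutation_reading_concentration <= 0:
            raise ValueError("mutation_reading_concentration must be > 0")
        if self.fitness_mode not in ("sampled", "expected"):
            raise ValueError(f"unknown fitness_mode {self.fitness_mode!r}")
        if self.record_every < 1:
            raise ValueError("record_every must be >= 1")
        if self.m1_position not in (1, 2, 3):
            raise ValueError("m1_position must be 1, 2 or 3")


@dataclass
class Population:
    """A population stored as stacked arrays for vectorized evaluation.

    ``codes`` has shape (n, 64, 21) and ``readings`` shape (n, 21, 3); every
    slice along the first axis is one individual's pair of row-stochastic
    matrices.
    """

    codes: np.ndarray
    readings: np.ndarray
    generation: int = 0

    @property
    def size(self) -> int:
        return self.codes.shape[0]

    @classmethod
    def random(cls, n: int, rng: np.random.Generator) -> "Population":
        g = rng.standard_gamma(1.0, size=(n, N_CODONS, N_LABELS))
        codes = g / g.sum(axis=2, keepdims=True)
        g = rng.standard_gamma(1.0, size=(n, N_LABELS, N_MODELS))
        readings = g / g.sum(axis=2, keepdims=True)
        return cls(codes, readings)

    def individual(self, i: int) -> Individual:
        return Individual(self.codes[i].copy(), self.readings[i].copy())

    @property
    def individuals(self) -> list[Individual]:
        return [self.individual(i) for i in range(self.size)]


@dataclass
class SimulationResult:
    """Trajectory, final population and the best coding system observed."""

    trajectory: pd.DataFrame
    population: Population
    best: Individual
    best_log_fitness: float
    config: EvolutionConfig = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# vectorized kernels

def _evaluate_population(
    codes: np.ndarray,
    readings: np.ndarray,
    mode: str,
    rng: Optional[np.random.Generator],
    m1_position: int,
) -> np.ndarray:
    """Log-fitness of every individual; one fresh reading draw in sampled mode."""
    n = codes.shape[0]
    sizes = neighborhood_sizes().astype(float)
    path = codes.argmax(axis=1)  # (n, 21); ties -> lowest codon index
    codes_t = np.transpose(codes, (0, 2, 1))  # (n, 21, 64) view
    # neighborhood sums S[j][i, l] = sum_{c' in N_j(path[i,l])} p[i, c', l]
    S = []
    for j in range(N_MODELS):
        table = neighbor_index_table(ReadingModel(j), m1_position)
        idx = table[path]  # (n, 21, |N_j|)
        S.append(np.take_along_axis(codes_t, idx, axis=2).sum(axis=2))
    if mode == "sampled":
        u = rng.random((n, N_LABELS))
        cum = np.cumsum(readings, axis=2)
        j = np.minimum((u[:, :, None] > cum).sum(axis=2), 2)
        r_sel = np.take_along_axis(readings, j[:, :, None], axis=2)[:, :, 0]
        S_stack = np.stack(S, axis=2)  # (n, 21, 3)
        S_sel = np.take_along_axis(S_stack, j[:, :, None], axis=2)[:, :, 0]
        terms = r_sel / sizes[j] * S_sel
    else:
        S_stack = np.stack(S, axis=2)
        terms = (readings * readings / sizes * S_stack).sum(axis=2)
    with np.errstate(divide="ignore"):
        return np.log(terms).sum(axis=1)


def _mutate_rows(
    matrices: np.ndarray, row_prob: float, kappa: float, rng: np.random.Generator
) -> None:
    """Resample a Bernoulli subset of rows from Dirichlet(kappa*row + eps), in place."""
    n, n_rows, _ = matrices.shape
    mask = rng.random((n, n_rows)) < row_prob
    if not mask.any():
        return
    rows = matrices[mask]
    g = rng.standard_gamma(kappa * rows + MUTATION_EPS)
    matrices[mask] = g / g.sum(axis=1, keepdims=True)


def _select_indices(
    log_fitness: np.ndarray, cfg: EvolutionConfig, rng: np.random.Generator
) -> tuple[np.ndarray, int]:
    """Indices of the next generation's parents: elites first, then winners.

    Tournament candidates are uniform with replacement; the first maximal
    candidate wins, which — because candidate positions are exchangeable —
    selects uniformly among tied entries.
    """
    n = log_fitness.shape[0]
    e = cfg.elite_count
    order = np.argsort(-log_fitness, kind="stable")
    elite = order[:e]
    if np.all(np.isneginf(log_fitness)):
        logger.warning(
            "all individuals at -inf log-fitness; selection degenerates to "
            "uniform random copying"
        )
    cand = rng.integers(0, n, size=(n - e, cfg.tournament_size))
    winners = cand[np.arange(n - e), np.argmax(log_fitness[cand], axis=1)]
    return np.concatenate([elite, winners]), e


def _population_entropies(codes: np.ndarray, readings: np.ndarray) -> tuple[float, float]:
    hc = -xlogy(codes, codes).sum(axis=(1, 2))
    hr = -xlogy(readings, readings).sum(axis=(1, 2))
    return float(hc.mean()), float(hr.mean())


# ---------------------------------------------------------------------------
# public single-individual operators (thin wrappers over the kernels)

def mutate(ind: Individual, cfg: EvolutionConfig, rng: np.random.Generator) -> Individual:
    """Mutated copy of one individual (row-resampling Dirichlet operator)."""
    cfg.validate()
    code = ind.code[None].copy()
    reading = ind.reading[None].copy()
    _mutate_rows(code, cfg.mutation_row_prob, cfg.mutation_concentration, rng)
    _mutate_rows(
        reading, cfg.mutation_reading_prob, cfg.mutation_reading_concentration, rng
    )
    return Individual(code[0], reading[0])


def select(
    pop: Population,
    log_fitnesses: np.ndarray,
    cfg: EvolutionConfig,
    rng: np.random.Generator,
) -> Population:
    """Next generation by elitism + tournament selection (copies, unmutated)."""
    cfg.validate()
    log_fitnesses = np.asarray(log_fitnesses, dtype=float)
    if log_fitnesses.shape != (pop.size,):
        raise ValueError("one log-fitness per individual required")
    idx, _ = _select_indices(log_fitnesses, cfg, rng)
    return Population(
        pop.codes[idx].copy(), pop.readings[idx].copy(), pop.generation + 1
    )


# ---------------------------------------------------------------------------
# the generational loop

def run_simulation(
    cfg: EvolutionConfig,
    progress: Optional[Callable[[int, float, float], None]] = None,
) -> SimulationResult:
    """Run the full mutation–selection loop described in the module docstring.

    Records a trajectory row at generation 0, every ``record_every``
    generations, and at the final generation.  ``progress``, if given, is
    called at each recorded generation with (generation, mean log-fitness,
    best log-fitness).  Fully reproducible from ``cfg`` alone.
    """
    cfg.validate()
    master = np.random.SeedSequence(cfg.seed)
    ss_init, ss_reading, ss_mutation, ss_selection = master.spawn(4)
    rng_init = np.random.Generator(np.random.PCG64(ss_init))
    rng_reading = np.random.Generator(np.random.PCG64(ss_reading))
    rng_mutation = np.random.Generator(np.random.PCG64(ss_mutation))
    rng_selection = np.random.Generator(np.random.PCG64(ss_selection))

    pop = Population.random(cfg.population_size, rng_init)
    log_f = _evaluate_population(
        pop.codes, pop.readings, cfg.fitness_mode, rng_reading, cfg.m1_position
    )

    best_i = int(np.argmax(log_f))
    best = pop.individual(best_i)
    best_log = float(log_f[best_i])
    best.fitness_cache = best_log

    records: list[tuple] = []

    def record(gen: int) -> None:
        hc, hr = _population_entropies(pop.codes, pop.readings)
        counts = pop.readings.sum(axis=1).mean(axis=0)  # mean E_j over population
        row = (
            gen,
            float(log_f.mean()),
            float(log_f.max()),
            hc,
            hr,
            float(counts[0]),
            float(counts[1]),
            float(counts[2]),
        )
        records.append(row)
        if progress is not None:
            progress(gen, row[1], row[2])

    record(0)
    for gen in range(1, cfg.generations + 1):
        idx, n_elite = _select_indices(log_f, cfg, rng_selection)
        pop = Population(pop.codes[idx].copy(), pop.readings[idx].copy(), gen)
        _mutate_rows(
            pop.codes[n_elite:],
            cfg.mutation_row_prob,
            cfg.mutation_concentration,
            rng_mutation,
        )
        _mutate_rows(
            pop.readings[n_elite:],
            cfg.mutation_reading_prob,
            cfg.mutation_reading_concentration,
            rng_mutation,
        )
        log_f = _evaluate_population(
            pop.codes, pop.readings, cfg.fitness_mode, rng_reading, cfg.m1_position
        )
        gen_best = int(np.argmax(log_f))
        if log_f[gen_best] > best_log:
            best_log = float(log_f[gen_best])
            best = pop.individual(gen_best)
            best.fitness_cache = best_log
        if gen % cfg.record_every == 0 or gen == cfg.generations:
            record(gen)

    trajectory = pd.DataFrame.from_records(records, columns=TRAJECTORY_COLUMNS)
    trajectory = trajectory.drop_duplicates(subset="generation", ignore_index=True)
    return SimulationResult(trajectory, pop, best, best_log, cfg)
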