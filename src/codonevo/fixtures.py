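"""Deterministic generators of small test inputs.

These constructions exercise edge cases of the model with closed-form
observables: maximum-entropy matrices, zero-entropy disjoint assignments
whose forced-M3 fitness is exactly ``0.1**21``, wobble-perfect toy codes
with restricted fitness exactly 1, and seeded random individuals.
"""

from __future__ import annotations

import numpy as np

from .model_core import (
    Individual,
    N_CODONS,
    N_LABELS,
    N_MODELS,
    ReadingModel,
    neighbor_index_table,
    random_individual,
)

__all__ = ["make_fixture", "FIXTURE_KINDS"]

FIXTURE_KINDS = ("uniform", "deterministic_disjoint", "m1_perfect_smallL", "random")


def _uniform() -> Individual:
    code = np.full((N_CODONS, N_LABELS), 1.0 / N_LABELS)
    reading = np.full((N_LABELS, N_MODELS), 1.0 / N_MODELS)
    return Individual(code, reading)


def _deterministic_disjoint() -> Individual:
    """Labels 0..20 deterministically on codons 0..20; zero total entropy.

    The remaining 43 codons are each assigned (with probability 1) to the
    lowest label whose path codon's M3 neighborhood they do *not* touch, so
    every label's neighborhood sum under any reading model is exactly the
    path codon's own probability.  Forced-M3 fitness is then (1/10)^21 and
    forced-M1 fitness (1/4)^21, exactly.
    """
    code = np.zeros((N_CODONS, N_LABELS))
    for l in range(N_LABELS):
        code[l, l] = 1.0
    m3 = neighbor_index_table(ReadingModel.M3)
    for c in range(N_LABELS, N_CODONS):
        for l in range(N_LABELS):
            if c not in m3[l]:
                code[c, l] = 1.0
                break
    reading = np.zeros((N_LABELS, N_MODELS))
    reading[:, ReadingModel.M1] = 1.0
    return Individual(code, reading)


def _m1_perfect_small() -> Individual:
    """Labels 0..2 each own a full wobble family with probability 1.

    Restricted to labels {0, 1, 2} with M1 reading forced, every factor of
    the fitness is (1/4) * 4 = 1, so the restricted fitness is exactly 1.
    Remaining codons are spread deterministically over the other labels.
    """
    code = np.zeros((N_CODONS, N_LABELS))
    for l in range(3):
        code[4 * l : 4 * l + 4, l] = 1.0
    for c in range(12, N_CODONS):
        code[c, 3 + (c - 12) % (N_LABELS - 3)] = 1.0
    reading = np.zeros((N_LABELS, N_MODELS))
    reading[:, ReadingModel.M1] = 1.0
    return Individual(code, reading)


def make_fixture(kind: str, seed: int = 0) -> Individual:
    """Build one of the named fixture individuals (seed matters for 'random')."""
    if kind == "uniform":
        return _uniform()
    if kind == "deterministic_disjoint":
        return _deterministic_disjoint()
    if kind == "m1_perfect_smallL":
        return _m1_perfect_small()
    if kind == "random":
        rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
        return random_individual(rng)
    raise ValueError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
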