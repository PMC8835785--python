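"""The coding-strength fitness F of a coding system.

F is a product over the 21 labels.  For label ``l`` with Bayes-path codon
``c_l``, reading mechanism ``j`` drawn from the label's reading-matrix row,
and neighborhood ``N_j(c_l)``, the factor is

    (r[l, j] / |N_j(c_l)|) * sum_{c' in N_j(c_l)} p[c', l]

i.e. the draw probability of the neighborhood times the average coding
probability of the label over that neighborhood.  Multiplying the 21
factors equals the literal sum over all combinations of one codon per label
(the neighborhoods index disjoint product dimensions), which
:func:`brute_force_fitness` verifies by exhaustive enumeration on small
label subsets.

All arithmetic is carried in log space: random starting systems have F of
order exp(-90), far below the underflow threshold of a naive product.  A
factor of exactly zero maps to ``log F = -inf``; such individuals are valid
and simply rank below every finite-fitness individual under selection.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .model_core import (
    Individual,
    N_LABELS,
    ReadingModel,
    bayes_path,
    neighbor_index_table,
)

__all__ = [
    "FitnessValue",
    "per_label_term",
    "fitness_sampled",
    "fitness_expected",
    "brute_force_fitness",
    "draw_reading_assignment",
]


@dataclass
class FitnessValue:
    """Log-fitness with its 21 per-label factors.

    ``log_f`` is the natural log of F and equals the sum of the logs of
    ``per_label_terms``; each term lies in [0, 1], so ``log_f <= 0``.
    ``assignment`` records the reading draw when one was made.
    """

    log_f: float
    per_label_terms: np.ndarray
    assignment: Optional[np.ndarray] = field(default=None)


def per_label_term(
    code: np.ndarray,
    label: int,
    ref_codon: int,
    model: ReadingModel,
    p_j: float,
) -> float:
    """One factor of F: ``(p_j / |N|) * sum over N_model(ref_codon) of p[c', label]``."""
    if not 0.0 <= p_j <= 1.0:
        raise ValueError(f"reading probability must be in [0, 1], got {p_j}")
    model = ReadingModel(model)
    nbrs = neighbor_index_table(model)[int(ref_codon)]
    s = float(np.asarray(code)[nbrs, int(label)].sum())
    return p_j / model.neighborhood_size * s


def draw_reading_assignment(
    reading: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw one reading mechanism per label from the reading-matrix rows."""
    u = rng.random(N_LABELS)
    cum = np.cumsum(np.asarray(reading, dtype=float), axis=1)
    return np.minimum((u[:, None] > cum).sum(axis=1), 2).astype(np.int64)


def _log_terms(terms: np.ndarray) -> float:
    with np.errstate(divide="ignore"):
        return float(np.sum(np.log(terms)))


def fitness_sampled(ind: Individual, rng: np.random.Generator) -> FitnessValue:
    """Paper-faithful stochastic fitness: one reading draw per label.

    The mechanism ``j_l`` for each label is drawn from the label's
    reading-matrix row; the factor then weights the neighborhood sum by the
    drawn mechanism's own probability ``r[l, j_l]``.
    """
    path = bayes_path(ind.code)
    j = draw_reading_assignment(ind.reading, rng)
    terms = np.empty(N_LABELS)
    for l in range(N_LABELS):
        terms[l] = per_label_term(
            ind.code, l, path[l], ReadingModel(j[l]), float(ind.reading[l, j[l]])
        )
    return FitnessValue(_log_terms(terms), terms, assignment=j)


def fitness_expected(ind: Individual) -> FitnessValue:
    """Deterministic variant: expectation of the sampled factor over the draw.

    Each label's factor becomes ``sum_j r[l,j] * (r[l,j] / |N_j|) * S_j``
    where ``S_j`` is the neighborhood sum under mechanism ``j``.  Because
    the sampled factor already carries the draw probability linearly, its
    expectation weights each mechanism by ``r[l,j]`` squared; this is a
    consequence of the sampled definition, not an extra modeling choice.
    """
    path = bayes_path(ind.code)
    terms = np.zeros(N_LABELS)
    for l in range(N_LABELS):
        for model in ReadingModel:
            r = float(ind.reading[l, model])
            terms[l] += r * per_label_term(ind.code, l, path[l], model, r)
    return FitnessValue(_log_terms(terms), terms)


def brute_force_fitness(
    code: np.ndarray,
    labels: Sequence[int],
    path: Sequence[int],
    models: Sequence[ReadingModel],
    reading_probs: Sequence[float],
) -> float:
    """Literal enumeration of F over all codon combinations (oracle).

    Enumerates every choice of one codon per label from the respective
    neighborhoods and sums the products ``p[c', l] * r / |N|``.  Restricted
    to at most 4 labels (<= 10^4 combinations) to guard against
    combinatorial explosion; the factorized implementations are the
    production path.
    """
    labels = list(labels)
    if len(labels) > 4:
        raise ValueError(f"brute force limited to <= 4 labels, got {len(labels)}")
    if not (len(labels) == len(path) == len(models) == len(reading_probs)):
        raise ValueError("labels, path, models and reading_probs must align")
    code = np.asarray(code, dtype=float)
    nbr_lists = [
        neighbor_index_table(ReadingModel(m))[int(c)] for m, c in zip(models, path)
    ]
    weights = [
        float(r) / ReadingModel(m).neighborhood_size
        for r, m in zip(reading_probs, models)
    ]
    total = 0.0
    for combo in itertools.product(*nbr_lists):
        prod = 1.0
        for lab, c_prime, w in zip(labels, combo, weights):
            prod *= code[c_prime, lab] * w
        total += prod
    return total


def restricted_log_fitness(
    code: np.ndarray,
    labels: Sequence[int],
    path: Sequence[int],
    models: Sequence[ReadingModel],
    reading_probs: Sequence[float],
) -> float:
    """Factorized log-fitness over an arbitrary label subset (test helper)."""
    terms = [
        per_label_term(code, lab, c, ReadingModel(m), float(r))
        for lab, c, m, r in zip(labels, path, models, reading_probs)
    ]
    with np.errstate(divide="ignore"):
        return float(np.sum(np.log(terms)))
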