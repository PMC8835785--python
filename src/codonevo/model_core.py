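"""Codon indexing, reading-system neighborhoods, and coding-system containers.

A coding system consists of two row-stochastic matrices:

* a 64 x 21 *code matrix* ``P`` whose entry ``p[c, l]`` is the probability
  that codon ``c`` encodes label ``l`` (20 amino-acid-like labels plus a
  stop-like label, all treated identically);
* a 21 x 3 *reading matrix* ``R`` whose entry ``r[l, j]`` is the probability
  that label ``l`` is read by mechanism ``Mj``.

Three reading mechanisms define codon neighborhoods around a reference codon:
M1 varies only the wobble (third) position, M2 varies exactly one of the two
non-wobble positions, and M3 varies exactly one of any of the three positions.
Neighborhoods always include the reference codon, so their sizes are fixed at
4, 7 and 10 respectively.
"""

from __future__ import annotations

import enum
import functools
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

__all__ = [
    "BASES",
    "N_CODONS",
    "N_LABELS",
    "N_MODELS",
    "ReadingModel",
    "Individual",
    "codon_index",
    "codon_triplet",
    "all_codons",
    "neighborhood",
    "neighbor_index_table",
    "neighborhood_sizes",
    "random_individual",
    "random_code_matrix",
    "random_reading_matrix",
    "bayes_path",
    "validate_code_matrix",
    "validate_reading_matrix",
    "DegenerateColumnError",
]

#: Fixed base order used for the codon <-> index bijection:
#: index = 16*b1 + 4*b2 + b3 with A=0, C=1, G=2, T=3.
BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

N_CODONS = 64
N_LABELS = 21
N_MODELS = 3

#: Row-sum tolerance for stochastic-matrix validation.
ROW_SUM_TOL = 1e-9


class ReadingModel(enum.IntEnum):
    """The three codon-reading mechanisms, ordered by neighborhood size."""

    M1 = 0  # wobble-like: varies only the third position; |N| = 4
    M2 = 1  # varies exactly one of the first two positions; |N| = 7
    M3 = 2  # varies exactly one of any position; |N| = 10

    @property
    def neighborhood_size(self) -> int:
        return (4, 7, 10)[self]


def neighborhood_sizes() -> np.ndarray:
    """Neighborhood sizes (4, 7, 10) indexed by reading model."""
    return np.array([4, 7, 10], dtype=np.int64)


class DegenerateColumnError(ValueError):
    """Raised when a code-matrix label column carries no probability mass."""


def codon_index(triplet: str) -> int:
    """Map a codon triplet to its integer index in ``[0, 63]``.

    The ordering is A=0, C=1, G=2, T=3 with index = 16*b1 + 4*b2 + b3.
    ``U`` is accepted as an alias of ``T``; case is ignored.
    """
    if not isinstance(triplet, str) or len(triplet) != 3:
        raise ValueError(f"codon must be a 3-base string, got {triplet!r}")
    t = triplet.upper().replace("U", "T")
    try:
        b1, b2, b3 = (_BASE_INDEX[ch] for ch in t)
    except KeyError:
        raise ValueError(f"invalid base in codon {triplet!r}") from None
    return 16 * b1 + 4 * b2 + b3


def codon_triplet(index: int) -> str:
    """Inverse of :func:`codon_index`: map an index in ``[0, 63]`` to ACGT."""
    index = int(index)
    if not 0 <= index < N_CODONS:
        raise ValueError(f"codon index must be in [0, 63], got {index}")
    return BASES[index // 16] + BASES[(index // 4) % 4] + BASES[index % 4]


def all_codons() -> list[str]:
    """All 64 codon triplets in index order."""
    return [codon_triplet(i) for i in range(N_CODONS)]


def _as_index(codon: Union[int, str]) -> int:
    return codon_index(codon) if isinstance(codon, str) else int(codon)


def neighborhood(
    codon: Union[int, str],
    model: ReadingModel,
    m1_position: int = 3,
) -> frozenset[str]:
    """Reading neighborhood of ``codon`` under ``model``, as triplets.

    The reference codon is always a member.  ``m1_position`` (1-based)
    selects which position M1 varies; M2 then varies the other two
    positions.  The default (third position) reproduces wobble-like
    reading; it is configurable because the mechanism definitions only fix
    *how many* positions are held, not which.
    """
    c = _as_index(codon)
    table = neighbor_index_table(ReadingModel(model), m1_position)
    return frozenset(codon_triplet(i) for i in table[c])


@functools.lru_cache(maxsize=None)
def neighbor_index_table(model: ReadingModel, m1_position: int = 3) -> np.ndarray:
    """Neighbor indices for every codon: shape ``(64, |N_model|)``.

    Row ``c`` lists the members of ``N_model(c)`` (reference codon first,
    then single-base variants in base order).  Cached per (model, position).
    """
    if m1_position not in (1, 2, 3):
        raise ValueError(f"m1_position must be 1, 2 or 3, got {m1_position}")
    model = ReadingModel(model)
    wobble = m1_position - 1
    if model is ReadingModel.M1:
        positions = [wobble]
    elif model is ReadingModel.M2:
        positions = [p for p in range(3) if p != wobble]
    else:
        positions = [0, 1, 2]

    rows = []
    for c in range(N_CODONS):
        digits = [c // 16, (c // 4) % 4, c % 4]
        members = [c]
        for p in positions:
            for b in range(4):
                if b != digits[p]:
                    d = digits.copy()
                    d[p] = b
                    members.append(16 * d[0] + 4 * d[1] + d[2])
        rows.append(members)
    table = np.asarray(rows, dtype=np.int64)
    table.setflags(write=False)
    return table


@dataclass
class Individual:
    """One coding system: a code matrix, a reading matrix, a cached fitness."""

    code: np.ndarray  # (64, 21) row-stochastic
    reading: np.ndarray  # (21, 3) row-stochastic
    fitness_cache: Optional[float] = None

    def copy(self) -> "Individual":
        return Individual(self.code.copy(), self.reading.copy(), self.fitness_cache)

    def validate(self) -> None:
        validate_code_matrix(self.code)
        validate_reading_matrix(self.reading)


def _validate_stochastic(m: np.ndarray, shape: tuple[int, int], what: str) -> None:
    m = np.asarray(m)
    if m.shape != shape:
        raise ValueError(f"{what} must have shape {shape}, got {m.shape}")
    if np.any(m < 0):
        bad = int(np.argwhere(m < 0)[0][0])
        raise ValueError(f"{what} has a negative entry in row {bad}")
    sums = m.sum(axis=1)
    off = np.abs(sums - 1.0)
    if np.any(off > ROW_SUM_TOL):
        bad = int(np.argmax(off))
        raise ValueError(
            f"{what} row {bad} sums to {sums[bad]:.12g}, not 1 within {ROW_SUM_TOL}"
        )


def validate_code_matrix(code: np.ndarray) -> None:
    _validate_stochastic(code, (N_CODONS, N_LABELS), "code matrix")


def validate_reading_matrix(reading: np.ndarray) -> None:
    _validate_stochastic(reading, (N_LABELS, N_MODELS), "reading matrix")


def random_code_matrix(rng: np.random.Generator) -> np.ndarray:
    """64 rows drawn from the flat Dirichlet over 21 labels."""
    g = rng.standard_gamma(1.0, size=(N_CODONS, N_LABELS))
    return g / g.sum(axis=1, keepdims=True)


def random_reading_matrix(rng: np.random.Generator) -> np.ndarray:
    """21 rows drawn from the flat Dirichlet over the 3 reading models."""
    g = rng.standard_gamma(1.0, size=(N_LABELS, N_MODELS))
    return g / g.sum(axis=1, keepdims=True)


def random_individual(rng: np.random.Generator) -> Individual:
    """A maximally ambiguous starting individual.

    Every code row and reading row is drawn from the flat Dirichlet (all
    concentration parameters 1), the maximum-entropy distribution on the
    simplex, emulating the high-entropy ambiguous assignments the model
    assumes at the outset.
    """
    return Individual(random_code_matrix(rng), random_reading_matrix(rng))


def bayes_path(code: np.ndarray) -> np.ndarray:
    """The most probable codon for each label, by Bayes' rule.

    With a uniform prior over codons the posterior P(c | l) is proportional
    to ``p[c, l]``, so the path codon for label ``l`` is the argmax of
    column ``l``; ties break to the lowest codon index.  Returns an int
    array of 21 codon indices (duplicates across labels are permitted).
    """
    code = np.asarray(code, dtype=float)
    if code.shape != (N_CODONS, N_LABELS):
        raise ValueError(f"code matrix must be 64x21, got {code.shape}")
    col_mass = code.sum(axis=0)
    if np.any(col_mass <= 0):
        label = int(np.argmax(col_mass <= 0))
        raise DegenerateColumnError(
            f"label column {label} carries no probability mass"
        )
    return np.argmax(code, axis=0)
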