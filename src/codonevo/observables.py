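"""Quality measures of coding systems: entropies, reading-type label counts,
codon-block extraction, and the standard-genetic-code reference spectrum.

The two entropies summarize how ambiguous a coding system still is:

* ``Hc = -sum_c sum_l p[c,l] ln p[c,l]`` over the 64 code rows, ranging from
  0 (every codon deterministically assigned) to ``64 ln 21``;
* ``Hr = -sum_l sum_j r[l,j] ln r[l,j]`` over the 21 reading rows, ranging
  from 0 to ``21 ln 3``.

Both are in nats (natural log).  Codon blocks are the high-confidence
assignments: ``block(l) = {c : p[c,l] > threshold}`` with a strict
inequality at the default threshold 0.8; with any threshold above 0.5 the
blocks are pairwise disjoint because a stochastic row can exceed 0.5 in at
most one column.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy.special import xlogy
from Bio.Data import CodonTable

from .model_core import (
    N_CODONS,
    N_LABELS,
    N_MODELS,
    codon_triplet,
    validate_code_matrix,
    validate_reading_matrix,
)

__all__ = [
    "BlockStructure",
    "code_entropy",
    "reading_entropy",
    "expected_label_counts",
    "extract_blocks",
    "block_size_distribution",
    "m1_consistency",
    "sgc_table",
    "sgc_block_spectrum",
    "MAX_CODE_ENTROPY",
    "MAX_READING_ENTROPY",
]

MAX_CODE_ENTROPY = N_CODONS * np.log(N_LABELS)
MAX_READING_ENTROPY = N_LABELS * np.log(N_MODELS)


def code_entropy(code: np.ndarray) -> float:
    """Shannon entropy of codon assignments, summed over the 64 rows (nats)."""
    validate_code_matrix(code)
    return float(-xlogy(code, code).sum())


def reading_entropy(reading: np.ndarray) -> float:
    """Shannon entropy of reading-system choices, summed over the 21 rows (nats)."""
    validate_reading_matrix(reading)
    return float(-xlogy(reading, reading).sum())


def expected_label_counts(reading: np.ndarray) -> np.ndarray:
    """Expected number of labels read by each mechanism: ``E_j = sum_l r[l,j]``.

    The three components always sum to 21 (one unit of expectation per
    label).  A fully homogeneous wobble-like system gives (21, 0, 0).
    """
    validate_reading_matrix(reading)
    return np.asarray(reading, dtype=float).sum(axis=0)


@dataclass
class BlockStructure:
    """Map label -> set of codon indices with coding probability above threshold."""

    blocks: dict[int, frozenset[int]]
    threshold: float = 0.8

    def non_empty(self) -> dict[int, frozenset[int]]:
        return {l: b for l, b in self.blocks.items() if b}

    def as_triplets(self) -> dict[int, list[str]]:
        """JSON-friendly view: label -> sorted codon triplets."""
        return {
            l: sorted(codon_triplet(c) for c in b) for l, b in self.blocks.items()
        }


def extract_blocks(code: np.ndarray, threshold: float = 0.8) -> BlockStructure:
    """Codon blocks at a strict probability threshold.

    A codon belongs to label ``l``'s block iff ``p[c,l] > threshold``
    (strictly), so a probability exactly at the threshold is excluded.
    Labels with no confident codon receive an empty block, which keeps
    early-simulation snapshots representable.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    validate_code_matrix(code)
    code = np.asarray(code, dtype=float)
    blocks = {
        l: frozenset(np.flatnonzero(code[:, l] > threshold).tolist())
        for l in range(N_LABELS)
    }
    return BlockStructure(blocks, threshold)


def block_size_distribution(blocks: BlockStructure) -> dict[int, int]:
    """Histogram of block sizes over the 21 labels (size-0 labels included)."""
    counts = Counter(len(b) for b in blocks.blocks.values())
    return dict(sorted(counts.items()))


def m1_consistency(blocks: BlockStructure) -> float:
    """Fraction of non-empty blocks contained in a single wobble neighborhood.

    A block fits one M1 neighborhood exactly when all its codons agree at
    the first two positions (indices sharing the same ``index // 4``
    quotient).  Returns 0.0 when every block is empty.
    """
    non_empty = blocks.non_empty()
    if not non_empty:
        return 0.0
    ok = sum(1 for b in non_empty.values() if len({c // 4 for c in b}) == 1)
    return ok / len(non_empty)


def sgc_table() -> dict[str, str]:
    """The standard genetic code: all 64 DNA codons -> amino acid or ``*`` (stop).

    Built from the canonical translation table (NCBI table 1).
    """
    table = CodonTable.unambiguous_dna_by_id[1]
    mapping = dict(table.forward_table)
    for stop in table.stop_codons:
        mapping[stop] = "*"
    assert len(mapping) == 64
    return mapping


def sgc_block_spectrum() -> dict:
    """Degeneracy spectrum of the standard genetic code.

    Classifies the 21 encoded items by codon-family size.  The three
    six-codon amino acids (Leu, Ser, Arg) are additionally reported as a
    four-codon plus a two-codon subgroup, the organization they show in the
    code table; the two three-codon items are one amino acid (Ile) and the
    stop signal.
    """
    table = sgc_table()
    per_item = Counter(table.values())
    by_size: dict[int, list[str]] = {}
    for item, n in per_item.items():
        by_size.setdefault(n, []).append(item)
    for items in by_size.values():
        items.sort()

    three = by_size.get(3, [])
    report = {
        "codons_per_item": dict(sorted(per_item.items())),
        "four_codon_aa": len([i for i in by_size.get(4, []) if i != "*"]),
        "two_codon_aa": len([i for i in by_size.get(2, []) if i != "*"]),
        "one_codon_aa": len([i for i in by_size.get(1, []) if i != "*"]),
        "six_codon_aa": len([i for i in by_size.get(6, []) if i != "*"]),
        "three_codon_items": sorted(three),
        "three_codon_note": "one amino acid plus the stop signal",
        "six_codon_organization": "each six-codon family = 4-codon + 2-codon subgroup",
        "total_codons": int(sum(per_item.values())),
    }
    return report
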