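"""Plain-text serialization of coding systems and run artifacts.

Code and reading matrices travel as TSV with a header row and a key column
(codon triplet, or label id) followed by probabilities written with 12
significant digits — enough for byte-stable round-trips at the validation
tolerance.  Summaries are JSON with sorted keys so identical runs produce
byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .model_core import (
    N_CODONS,
    N_LABELS,
    N_MODELS,
    all_codons,
    codon_index,
    validate_code_matrix,
    validate_reading_matrix,
)

__all__ = [
    "write_code_tsv",
    "read_code_tsv",
    "write_reading_tsv",
    "read_reading_tsv",
    "write_json",
]

PathLike = Union[str, Path]

LABEL_COLUMNS = [f"L{l:02d}" for l in range(N_LABELS)]
MODEL_COLUMNS = ["M1", "M2", "M3"]
FLOAT_FMT = "%.12g"


def _write_matrix(path: PathLike, keys, matrix: np.ndarray, key_name: str, columns) -> None:
    df = pd.DataFrame(np.asarray(matrix, dtype=float), columns=columns)
    df.insert(0, key_name, keys)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def write_code_tsv(path: PathLike, code: np.ndarray) -> None:
    """Write a 64x21 code matrix; first column is the codon triplet."""
    validate_code_matrix(code)
    _write_matrix(path, all_codons(), code, "codon", LABEL_COLUMNS)


def read_code_tsv(path: PathLike) -> np.ndarray:
    """Read a code matrix written by :func:`write_code_tsv` (any codon order)."""
    df = pd.read_csv(path, sep="\t")
    if "codon" not in df.columns or list(df.columns[1:]) != LABEL_COLUMNS:
        raise ValueError(f"{path}: not a code-matrix TSV (bad header)")
    if len(df) != N_CODONS:
        raise ValueError(f"{path}: expected {N_CODONS} codon rows, got {len(df)}")
    code = np.zeros((N_CODONS, N_LABELS))
    code[[codon_index(t) for t in df["codon"]]] = df[LABEL_COLUMNS].to_numpy(float)
    validate_code_matrix(code)
    return code


def write_reading_tsv(path: PathLike, reading: np.ndarray) -> None:
    """Write a 21x3 reading matrix; first column is the label id."""
    validate_reading_matrix(reading)
    _write_matrix(path, list(range(N_LABELS)), reading, "label", MODEL_COLUMNS)


def read_reading_tsv(path: PathLike) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    if "label" not in df.columns or list(df.columns[1:]) != MODEL_COLUMNS:
        raise ValueError(f"{path}: not a reading-matrix TSV (bad header)")
    if len(df) != N_LABELS:
        raise ValueError(f"{path}: expected {N_LABELS} label rows, got {len(df)}")
    reading = np.zeros((N_LABELS, N_MODELS))
    reading[df["label"].to_numpy(int)] = df[MODEL_COLUMNS].to_numpy(float)
    validate_reading_matrix(reading)
    return reading


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        seq = sorted(obj) if isinstance(obj, (set, frozenset)) else obj
        return [_jsonable(v) for v in seq]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_json(path: PathLike, payload: dict) -> None:
    """Deterministic JSON dump (sorted keys, trailing newline)."""
    Path(path).write_text(
        json.dumps(_jsonable(payload), indent=2, sort_keys=True, allow_nan=True)
        + "\n"
    )
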