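"""Declarative run configuration: a single flat YAML mapping.

Every key is optional and falls back to a documented default; unknown keys
are rejected so typos cannot silently change a run.  The effective
configuration is echoed verbatim into the run summary.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import yaml

from .evolution import EvolutionConfig

__all__ = ["RunConfig", "load_run_config"]


@dataclass(frozen=True)
class RunConfig:
    """EvolutionConfig plus output location and observables options."""

    evolution: EvolutionConfig
    output_directory: str = "codonevo_run"
    block_threshold: float = 0.8

    def validate(self) -> None:
        self.evolution.validate()
        if not 0.0 < self.block_threshold <= 1.0:
            raise ValueError("block_threshold must be in (0, 1]")

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self.evolution)
        d["output_directory"] = self.output_directory
        d["block_threshold"] = self.block_threshold
        return d


_EVOLUTION_KEYS = {f.name for f in dataclasses.fields(EvolutionConfig)}
_EXTRA_KEYS = {"output_directory", "block_threshold"}


def load_run_config(
    path: Optional[Union[str, Path]] = None, **overrides
) -> RunConfig:
    """Load a YAML run config, apply keyword overrides, validate.

    ``path=None`` yields the all-defaults configuration.  Overrides with
    value ``None`` are ignored (convenient for CLI options left unset).
    """
    raw: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"{path}: config must be a flat YAML mapping")
        raw.update(loaded)
    for k, v in overrides.items():
        if v is not None:
            raw[k] = v

    unknown = set(raw) - _EVOLUTION_KEYS - _EXTRA_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")

    evo = EvolutionConfig(**{k: raw[k] for k in _EVOLUTION_KEYS if k in raw})
    cfg = RunConfig(
        evolution=evo,
        **{k: raw[k] for k in _EXTRA_KEYS if k in raw},
    )
    cfg.validate()
    return cfg
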