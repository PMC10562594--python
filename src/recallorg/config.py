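"""Run configuration: YAML-backed settings shared by all CLI stages."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .listgen import ListSpec
from .simulate import SimParams
from .types import ValidationError

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run needs, seed included.

    Each randomized stage receives its own sub-seed derived from the
    master seed via ``numpy.random.SeedSequence.spawn``, so stages never
    share a stream.
    """

    seed: int = 0
    sim: SimParams = field(default_factory=SimParams)
    list_spec: ListSpec = field(default_factory=ListSpec)
    max_edit_distance: int = 1
    semantic_possible: str = "available"
    n_perm: int = 10_000
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.semantic_possible not in ("available", "all"):
            raise ValidationError(
                f"semantic_possible={self.semantic_possible!r} "
                "(expected 'available' or 'all')"
            )
        if not 0 < self.alpha < 1:
            raise ValidationError(f"alpha={self.alpha} outside (0, 1)")

    def stage_seeds(self) -> dict[str, int]:
        """Deterministic per-stage sub-seeds from the master seed."""
        children = np.random.SeedSequence(self.seed).spawn(3)
        return {
            stage: int(child.generate_state(1)[0])
            for stage, child in zip(("simulate", "score", "analyze"), children)
        }

    @classmethod
    def from_yaml(cls, path: Path | str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimParams(**raw.pop("sim", {}))
        list_spec = ListSpec(**raw.pop("list_spec", {}))
        return cls(sim=sim, list_spec=list_spec, **raw)

    def to_yaml(self, path: Path | str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)
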