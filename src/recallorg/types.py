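"""Core domain types for free-recall organization analysis.

The analysis pipeline revolves around four kinds of objects:

* :class:`StudyList` — an ordered word list with 1-based serial positions
  and (optionally) designated high-similarity pair assignments.
* :class:`SimilarityMatrix` — symmetric pairwise semantic similarity
  (cosine-style values in ``[0, 1]``) over a vocabulary.
* :class:`RecallSequence` — one subject-by-condition recall transcript,
  optionally annotated with per-response classifications.
* :class:`SubjectMeasures` — the per-subject, per-condition scalar
  measures that feed the statistics stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CONDITIONS",
    "LABELS",
    "StudyList",
    "SimilarityMatrix",
    "Resolution",
    "RecallSequence",
    "SubjectMeasures",
    "measures_frame",
    "ValidationError",
]

#: Recognized experimental conditions.
CONDITIONS = ("same_context", "different_context", "control")

#: Recognized response classifications.
LABELS = ("correct", "repetition", "ELI", "PLI")


class ValidationError(ValueError):
    """Raised when an input object violates a structural invariant."""


@dataclass(frozen=True)
class StudyList:
    """An ordered study list.

    Serial positions are implicit in ``items`` order and are 1-based:
    ``items[0]`` occupies serial position 1.

    Parameters
    ----------
    list_id
        Identifier of the list.
    items
        Ordered, unique word strings.
    pair_assignment
        Optional mapping from item to a designated high-similarity pair
        identifier. Each pair id must be shared by exactly two items.
    """

    list_id: str
    items: tuple[str, ...]
    pair_assignment: Optional[Mapping[str, int]] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", tuple(self.items))
        if len(self.items) == 0:
            raise ValidationError(f"list {self.list_id!r}: empty item sequence")
        if len(set(self.items)) != len(self.items):
            seen: set[str] = set()
            for w in self.items:
                if w in seen:
                    raise ValidationError(
                        f"list {self.list_id!r}: duplicate word {w!r}"
                    )
                seen.add(w)
        if self.pair_assignment is not None:
            unknown = set(self.pair_assignment) - set(self.items)
            if unknown:
                raise ValidationError(
                    f"list {self.list_id!r}: pair assignment references "
                    f"non-list words {sorted(unknown)}"
                )
            counts: dict[int, int] = {}
            for pid in self.pair_assignment.values():
                counts[pid] = counts.get(pid, 0) + 1
            bad = {pid: c for pid, c in counts.items() if c != 2}
            if bad:
                raise ValidationError(
                    f"list {self.list_id!r}: pair ids without exactly two "
                    f"members: {sorted(bad)}"
                )

    @property
    def L(self) -> int:
        """List length."""
        return len(self.items)

    def position_of(self, word: str) -> int:
        """1-based serial position of ``word``."""
        return self.items.index(word) + 1

    def word_at(self, position: int) -> str:
        """Word at 1-based serial ``position``."""
        if not 1 <= position <= self.L:
            raise IndexError(f"serial position {position} outside 1..{self.L}")
        return self.items[position - 1]

    def pairs(self) -> list[tuple[str, str]]:
        """Designated pairs as sorted 2-tuples (empty if unassigned)."""
        if self.pair_assignment is None:
            return []
        by_id: dict[int, list[str]] = {}
        for w in self.items:  # deterministic order
            pid = self.pair_assignment.get(w)
            if pid is not None:
                by_id.setdefault(pid, []).append(w)
        return [tuple(sorted(ws)) for _, ws in sorted(by_id.items())]  # type: ignore[misc]


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric pairwise semantic similarity over a vocabulary.

    Values lie in ``[0, 1]`` with a unit diagonal.
    """

    vocabulary: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "vocabulary", tuple(self.vocabulary))
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        n = len(self.vocabulary)
        if len(set(self.vocabulary)) != n:
            raise ValidationError("similarity matrix: duplicate vocabulary word")
        if vals.shape != (n, n):
            raise ValidationError(
                f"similarity matrix: shape {vals.shape} does not match "
                f"vocabulary size {n}"
            )
        if np.any(vals < 0) or np.any(vals > 1):
            bad = vals[(vals < 0) | (vals > 1)].flat[0]
            raise ValidationError(
                f"similarity matrix: value {bad} outside [0, 1]"
            )
        if not np.allclose(vals, vals.T, atol=1e-9):
            raise ValidationError("similarity matrix: not symmetric")
        if not np.allclose(np.diag(vals), 1.0, atol=1e-9):
            raise ValidationError("similarity matrix: diagonal must be 1")
        object.__setattr__(
            self, "_index", {w: i for i, w in enumerate(self.vocabulary)}
        )

    def index(self, word: str) -> int:
        try:
            return self._index[word]  # type: ignore[attr-defined]
        except KeyError:
            raise KeyError(f"word {word!r} not in similarity vocabulary") from None

    def similarity(self, a: str, b: str) -> float:
        """Similarity between two vocabulary words."""
        return float(self.values[self.index(a), self.index(b)])

    def covers(self, words: Iterable[str]) -> bool:
        return set(words) <= set(self.vocabulary)


@dataclass(frozen=True)
class Resolution:
    """Classification of one raw recall response.

    ``label`` is one of ``correct`` (with the study serial position),
    ``repetition`` (already-credited current-list word), ``PLI`` (word
    from a different session list) or ``ELI`` (extra-list intrusion).
    """

    label: str
    position: Optional[int] = None

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValidationError(f"unknown response label {self.label!r}")
        if self.label in ("correct", "repetition") and self.position is None:
            raise ValidationError(f"label {self.label!r} requires a position")


@dataclass(frozen=True)
class RecallSequence:
    """One subject-by-condition recall transcript.

    ``responses`` holds the raw typed strings in output order;
    ``resolved`` (when populated) holds one :class:`Resolution` per
    response. ``list_id`` names the just-studied list, when known.
    """

    subject_id: str
    condition: str
    condition_order: int
    responses: tuple[str, ...]
    resolved: Optional[tuple[Resolution, ...]] = None
    list_id: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "responses", tuple(self.responses))
        if self.condition not in CONDITIONS:
            raise ValidationError(
                f"subject {self.subject_id!r}: unknown condition "
                f"{self.condition!r} (expected one of {CONDITIONS})"
            )
        if self.resolved is not None:
            object.__setattr__(self, "resolved", tuple(self.resolved))
            if len(self.resolved) != len(self.responses):
                raise ValidationError(
                    f"subject {self.subject_id!r}: {len(self.resolved)} "
                    f"resolutions for {len(self.responses)} responses"
                )
            credited: set[int] = set()
            for res in self.resolved:
                if res.label == "correct":
                    if res.position in credited:
                        raise ValidationError(
                            f"subject {self.subject_id!r}: serial position "
                            f"{res.position} credited as correct twice"
                        )
                    credited.add(res.position)  # type: ignore[arg-type]

    @property
    def is_resolved(self) -> bool:
        return self.resolved is not None

    def with_resolutions(self, resolved: Sequence[Resolution]) -> "RecallSequence":
        return replace(self, resolved=tuple(resolved))

    def correct_positions(self) -> list[int]:
        """Serial positions of first-time correct recalls, in output order."""
        if self.resolved is None:
            raise ValueError("sequence is not resolved")
        return [r.position for r in self.resolved if r.label == "correct"]  # type: ignore[misc]

    def count(self, label: str) -> int:
        if self.resolved is None:
            raise ValueError("sequence is not resolved")
        return sum(1 for r in self.resolved if r.label == label)


@dataclass(frozen=True)
class SubjectMeasures:
    """Per-subject, per-condition scalar measures.

    ``temporal_factor`` / ``semantic_factor`` are NaN when fewer than
    two scorable transitions exist. ``spc`` is a length-``L`` 0/1
    vector of per-position recall indicators; ``pfr_position`` is the
    serial position of the first correct recall (None if no correct
    recall).
    """

    subject_id: str
    condition: str
    condition_order: int
    n_correct: int
    temporal_factor: float
    semantic_factor: float
    n_eli: int
    n_pli: int
    n_repetition: int
    spc: np.ndarray = field(repr=False)
    pfr_position: Optional[int]

    def __post_init__(self) -> None:
        spc = np.asarray(self.spc, dtype=float)
        object.__setattr__(self, "spc", spc)
        if self.n_correct > spc.size:
            raise ValidationError(
                f"subject {self.subject_id!r}: n_correct {self.n_correct} "
                f"exceeds list length {spc.size}"
            )


def measures_frame(measures: Iterable[SubjectMeasures]) -> pd.DataFrame:
    """Tabulate :class:`SubjectMeasures` (one row per subject-condition)."""
    rows = []
    for m in measures:
        rows.append(
            {
                "subject_id": m.subject_id,
                "condition": m.condition,
                "condition_order": m.condition_order,
                "n_correct": m.n_correct,
                "temporal_factor": m.temporal_factor,
                "semantic_factor": m.semantic_factor,
                "n_ELI": m.n_eli,
                "n_PLI": m.n_pli,
                "n_repetition": m.n_repetition,
                "pfr_position": m.pfr_position,
            }
        )
    return pd.DataFrame(rows)
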