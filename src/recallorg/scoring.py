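"""Recall-dynamics measures.

Implements the transition-level machinery shared by all organization
scores:

* signed lags and lag conditional-response probabilities (lag-CRP),
  where each lag's probability is the number of times it occurred
  divided by the number of times it was possible;
* rank-based Temporal and Semantic Factor scores — each valid
  transition is scored ``(R - 1) / (N - 1)`` where ``N`` counts the
  possible transitions and ``R`` is the (average-tie Spearman) rank of
  the actual transition, ranked so that the most temporally contiguous
  or most semantically similar candidate receives the highest rank;
  0.5 is chance-level organization;
* serial-position and probability-of-first-recall curves;
* adjacent/remote lag-direction summaries.

Transitions into or out of intrusions and repetitions are invalid and
contribute to neither actual nor possible tallies. The possible-target
set at each transition excludes every already-credited serial position.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
from scipy.stats import rankdata

from .types import (
    RecallSequence,
    SimilarityMatrix,
    StudyList,
    SubjectMeasures,
    ValidationError,
)

__all__ = [
    "TransitionRecord",
    "CRPCurve",
    "FactorScore",
    "extract_transitions",
    "lag_crp",
    "average_crp",
    "transition_factor",
    "chance_level",
    "adjacent_remote_summary",
    "serial_position_curve",
    "probability_of_first_recall",
    "score_sequence",
    "score_cohort",
]

FactorKind = Literal["temporal", "semantic"]


@dataclass(frozen=True)
class TransitionRecord:
    """One recall-to-recall step.

    ``valid`` is False when either endpoint is not a first-time correct
    recall; lag and possible targets are then undefined (None/empty).
    """

    from_position: Optional[int]
    to_position: Optional[int]
    lag: Optional[int]
    possible_targets: frozenset[int]
    valid: bool

    def __post_init__(self) -> None:
        if self.valid:
            assert self.lag is not None and self.lag != 0
            assert self.to_position in self.possible_targets
            assert self.from_position not in self.possible_targets


@dataclass(frozen=True)
class CRPCurve:
    """Per-lag actual/possible transition counts for one sequence set.

    Lags run over ``-(L-1) .. (L-1)`` excluding 0. ``crp`` is NaN where
    a lag was never possible.
    """

    L: int
    actual: np.ndarray
    possible: np.ndarray

    @property
    def lags(self) -> np.ndarray:
        side = np.arange(1, self.L)
        return np.concatenate((-side[::-1], side))

    def _idx(self, lag: int) -> int:
        if lag == 0 or abs(lag) > self.L - 1:
            raise IndexError(f"lag {lag} outside +/-1..{self.L - 1}")
        return lag + self.L - 1 if lag < 0 else lag + self.L - 2

    def actual_at(self, lag: int) -> int:
        return int(self.actual[self._idx(lag)])

    def possible_at(self, lag: int) -> int:
        return int(self.possible[self._idx(lag)])

    @property
    def crp(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(
                self.possible > 0, self.actual / np.maximum(self.possible, 1), np.nan
            )

    def crp_at(self, lag: int) -> float:
        return float(self.crp[self._idx(lag)])


@dataclass(frozen=True)
class FactorScore:
    """Per-transition percentile-rank scores and their mean."""

    kind: FactorKind
    scores: tuple[float, ...]

    @property
    def mean(self) -> float:
        """Mean over scorable transitions; NaN when there are none."""
        if not self.scores:
            return math.nan
        return float(np.mean(self.scores))

    @property
    def n_transitions(self) -> int:
        return len(self.scores)


def extract_transitions(seq: RecallSequence, L: int) -> list[TransitionRecord]:
    """Build one record per consecutive response pair.

    A record is valid only when both endpoints are first-time correct
    recalls; an intrusion or repetition invalidates the transitions both
    into and out of it. At a valid transition the possible targets are
    all serial positions except those already credited (including the
    just-recalled position).
    """
    if seq.resolved is None:
        raise ValueError("sequence must be resolved before transition extraction")
    records: list[TransitionRecord] = []
    credited: set[int] = set()
    all_positions = set(range(1, L + 1))
    for prev, nxt in zip(seq.resolved, seq.resolved[1:]):
        if prev.label == "correct":
            credited.add(prev.position)  # type: ignore[arg-type]
        if prev.label == "correct" and nxt.label == "correct":
            possible = frozenset(all_positions - credited)
            records.append(
                TransitionRecord(
                    from_position=prev.position,
                    to_position=nxt.position,
                    lag=nxt.position - prev.position,  # type: ignore[operator]
                    possible_targets=possible,
                    valid=True,
                )
            )
        else:
            records.append(
                TransitionRecord(
                    from_position=prev.position if prev.label == "correct" else None,
                    to_position=nxt.position if nxt.label == "correct" else None,
                    lag=None,
                    possible_targets=frozenset(),
                    valid=False,
                )
            )
    return records


def lag_crp(transitions: Iterable[TransitionRecord], L: int) -> CRPCurve:
    """Tally actual and possible transition counts per signed lag."""
    actual = np.zeros(2 * (L - 1), dtype=int)
    possible = np.zeros(2 * (L - 1), dtype=int)
    curve = CRPCurve(L=L, actual=actual, possible=possible)
    for t in transitions:
        if not t.valid:
            continue
        actual[curve._idx(t.lag)] += 1  # type: ignore[arg-type]
        for target in t.possible_targets:
            possible[curve._idx(target - t.from_position)] += 1  # type: ignore[operator]
    return curve


def average_crp(curves: Sequence[CRPCurve]) -> np.ndarray:
    """Pointwise mean of per-subject CRP curves over defined values."""
    if not curves:
        raise ValueError("no curves to average")
    stacked = np.vstack([c.crp for c in curves])
    with np.errstate(invalid="ignore"):
        return np.nanmean(stacked, axis=0)


def _candidate_keys(
    t: TransitionRecord,
    kind: FactorKind,
    study: Optional[StudyList],
    sim: Optional[SimilarityMatrix],
    candidates: Sequence[int],
) -> np.ndarray:
    if kind == "temporal":
        return -np.abs(np.asarray(candidates) - t.from_position)
    if sim is None or study is None:
        raise ValidationError(
            "semantic factor requires a study list and similarity matrix"
        )
    prev_word = study.word_at(t.from_position)  # type: ignore[arg-type]
    return np.array(
        [sim.similarity(prev_word, study.word_at(p)) for p in candidates]
    )


def transition_factor(
    transitions: Iterable[TransitionRecord],
    kind: FactorKind,
    study: Optional[StudyList] = None,
    sim: Optional[SimilarityMatrix] = None,
    semantic_possible: Literal["available", "all"] = "available",
) -> FactorScore:
    """Score each valid transition as the percentile rank of its target.

    For each valid transition with at least two possible targets, all
    candidates are ranked by the key (negative absolute lag for
    ``temporal``; similarity to the just-recalled word for ``semantic``)
    in ascending order, so the best candidate holds the highest rank;
    ties receive average ranks. The transition scores
    ``(R - 1) / (N - 1)``. Transitions with a single possible target are
    excluded.

    ``semantic_possible="all"`` ranks the semantic target within every
    other list word regardless of recall history (an alternative reading
    of the possible-transition set); the default restricts candidates to
    still-available words, mirroring the temporal score.
    """
    if kind not in ("temporal", "semantic"):
        raise ValidationError(f"unknown factor kind {kind!r}")
    scores: list[float] = []
    for t in transitions:
        if not t.valid:
            continue
        if kind == "semantic" and semantic_possible == "all":
            if study is None:
                raise ValidationError("semantic_possible='all' requires study list")
            candidates = sorted(
                set(range(1, study.L + 1)) - {t.from_position}
            )
        else:
            candidates = sorted(t.possible_targets)
        n = len(candidates)
        if n < 2:
            continue
        keys = _candidate_keys(t, kind, study, sim, candidates)
        ranks = rankdata(keys, method="average")
        r = float(ranks[candidates.index(t.to_position)])
        scores.append((r - 1.0) / (n - 1.0))
    return FactorScore(kind=kind, scores=tuple(scores))


def chance_level() -> float:
    """Factor score expected under organization-free (random) recall."""
    return 0.5


def adjacent_remote_summary(
    curve: CRPCurve, remote_max: int = 16
) -> dict[str, float]:
    """Mean CRP for {forward, backward} x {adjacent, remote} lag groups.

    Adjacent pools absolute lags 1-2; remote pools absolute lags 3 up to
    ``remote_max`` (larger lags are excluded from the contrast).
    Undefined lags are skipped; a group with no defined lag is NaN.
    """

    def pool(lags: Iterable[int]) -> float:
        vals = [
            curve.crp_at(lag)
            for lag in lags
            if abs(lag) <= curve.L - 1 and not math.isnan(curve.crp_at(lag))
        ]
        return float(np.mean(vals)) if vals else math.nan

    hi = min(remote_max, curve.L - 1)
    return {
        "forward_adjacent": pool([1, 2]),
        "forward_remote": pool(range(3, hi + 1)),
        "backward_adjacent": pool([-1, -2]),
        "backward_remote": pool(range(-hi, -2)),
    }


def serial_position_curve(
    measures: Sequence[SubjectMeasures], L: int, n_bins: int = 4
) -> tuple[np.ndarray, np.ndarray]:
    """Per-position recall probability and equal-width bin means.

    Returns ``(per_position, bin_means)`` where ``per_position[k]`` is
    the fraction of subjects recalling serial position ``k + 1`` and
    bins partition positions into ``n_bins`` contiguous groups.
    """
    if L % n_bins != 0:
        raise ValidationError(f"L={L} not divisible by n_bins={n_bins}")
    if not measures:
        raise ValueError("no measures supplied")
    spc = np.vstack([m.spc for m in measures])
    if spc.shape[1] != L:
        raise ValidationError(
            f"spc vectors of length {spc.shape[1]} do not match L={L}"
        )
    per_position = spc.mean(axis=0)
    bin_means = per_position.reshape(n_bins, L // n_bins).mean(axis=1)
    return per_position, bin_means


def probability_of_first_recall(
    measures: Sequence[SubjectMeasures], L: int
) -> np.ndarray:
    """Normalized histogram of first-correct-recall positions.

    Subjects with no correct recall are excluded; the result sums to 1
    (all-NaN when no subject recalled anything).
    """
    counts = np.zeros(L)
    for m in measures:
        if m.pfr_position is not None:
            counts[m.pfr_position - 1] += 1
    total = counts.sum()
    if total == 0:
        return np.full(L, math.nan)
    return counts / total


def score_sequence(
    seq: RecallSequence,
    study: StudyList,
    sim: Optional[SimilarityMatrix] = None,
    semantic_possible: Literal["available", "all"] = "available",
) -> SubjectMeasures:
    """Compute all per-subject measures for one resolved transcript."""
    if seq.resolved is None:
        raise ValueError("sequence must be resolved before scoring")
    L = study.L
    transitions = extract_transitions(seq, L)
    tf = transition_factor(transitions, "temporal").mean
    if sim is not None:
        sf = transition_factor(
            transitions, "semantic", study=study, sim=sim,
            semantic_possible=semantic_possible,
        ).mean
    else:
        sf = math.nan
    positions = seq.correct_positions()
    spc = np.zeros(L)
    for p in positions:
        spc[p - 1] = 1.0
    return SubjectMeasures(
        subject_id=seq.subject_id,
        condition=seq.condition,
        condition_order=seq.condition_order,
        n_correct=len(positions),
        temporal_factor=tf,
        semantic_factor=sf,
        n_eli=seq.count("ELI"),
        n_pli=seq.count("PLI"),
        n_repetition=seq.count("repetition"),
        spc=spc,
        pfr_position=positions[0] if positions else None,
    )


def score_cohort(
    sequences: Sequence[RecallSequence],
    lists: Sequence[StudyList],
    sim: Optional[SimilarityMatrix] = None,
    session_lists: Optional[Sequence[StudyList]] = None,
    max_edit_distance: int = 1,
    semantic_possible: Literal["available", "all"] = "available",
) -> tuple[list[SubjectMeasures], dict[str, CRPCurve]]:
    """Resolve (if needed) and score a whole cohort of transcripts.

    Each transcript is matched to its study list by ``list_id``; when a
    transcript carries no list id and a single list is supplied, that
    list is used. Returns the per-subject measures and one pooled
    per-condition CRP curve built from per-transition tallies.
    """
    from .classify import resolve_responses

    by_id = {sl.list_id: sl for sl in lists}
    session = session_lists if session_lists is not None else lists
    measures: list[SubjectMeasures] = []
    cond_transitions: dict[str, list[TransitionRecord]] = {}
    L_by_cond: dict[str, int] = {}
    for seq in sequences:
        if seq.list_id is not None:
            if seq.list_id not in by_id:
                raise ValidationError(
                    f"subject {seq.subject_id!r}: unknown list {seq.list_id!r}"
                )
            study = by_id[seq.list_id]
        elif len(lists) == 1:
            study = lists[0]
        else:
            raise ValidationError(
                f"subject {seq.subject_id!r}: transcript names no list and "
                f"{len(lists)} lists were supplied"
            )
        if seq.resolved is None:
            seq = resolve_responses(
                seq, study, session, max_edit_distance=max_edit_distance
            )
        measures.append(
            score_sequence(seq, study, sim=sim, semantic_possible=semantic_possible)
        )
        cond_transitions.setdefault(seq.condition, []).extend(
            extract_transitions(seq, study.L)
        )
        L_by_cond[seq.condition] = study.L
    curves = {
        cond: lag_crp(trans, L_by_cond[cond])
        for cond, trans in cond_transitions.items()
    }
    return measures, curves
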