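"""Synthetic recall-process generator.

A deliberately minimal cue-mixture sampler: after a recency-weighted
first recall, each next candidate is drawn with weight

    w(i) ∝ (1 - λ) · exp(-|Δpos| / τ) · (φ if forward else 1)
           + λ · similarity(prev, i)

over still-unrecalled items, where λ trades contextual (temporal)
against semantic cuing. Sampled items fail recovery with probability ρ
(a retrieval attempt without output); intrusion tokens are emitted with
probability ε per output; recall halts at a per-output stop probability
or when the simulated 90-second recall window (1.5 s per output event)
is exhausted. Two within-subject conditions differ only in (λ, ρ).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import io as rio
from .listgen import ListSpec, order_list, select_pairs
from .types import RecallSequence, SimilarityMatrix, StudyList, ValidationError

__all__ = [
    "SimParams",
    "SyntheticCohort",
    "generate_similarity",
    "simulate_recall",
    "simulate_study",
    "write_cohort",
]

#: 90 s recall window at 1.5 s per output event.
MAX_OUTPUTS = 60


@dataclass(frozen=True)
class SimParams:
    """Generator parameters; condition-dependent fields carry suffixes."""

    L: int = 32
    n_pairs: int = 16
    n_subjects: int = 141
    p_stop: float = 0.07
    tau: float = 1.5
    phi: float = 1.5
    lam_same: float = 0.15
    lam_diff: float = 0.45
    rho_same: float = 0.05
    rho_diff: float = 0.10
    epsilon: float = 0.02
    p_repeat: float = 0.01
    n_orderings: int = 4
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        for name in (
            "p_stop", "lam_same", "lam_diff", "rho_same", "rho_diff",
            "epsilon", "p_repeat",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name}={v} outside [0, 1]")
        if self.tau <= 0:
            raise ValidationError(f"tau={self.tau} must be positive")
        if self.phi < 1:
            raise ValidationError(f"phi={self.phi} must be >= 1")
        if 2 * self.n_pairs > self.L:
            raise ValidationError("2*n_pairs exceeds L")

    def lam(self, condition: str) -> float:
        return self.lam_same if condition == "same_context" else self.lam_diff

    def rho(self, condition: str) -> float:
        return self.rho_same if condition == "same_context" else self.rho_diff


@dataclass
class SyntheticCohort:
    """A full simulated study plus its ground truth."""

    study_lists: list[StudyList]
    similarity: SimilarityMatrix
    recalls: list[RecallSequence]
    params: SimParams
    truth: dict = field(default_factory=dict)


def _background_block(rng: np.random.Generator, n: int) -> np.ndarray:
    """|N(0.1, 0.05)| values truncated (by rejection) to [0, 0.3]."""
    out = np.abs(rng.normal(0.1, 0.05, size=n))
    while True:
        bad = out > 0.3
        if not bad.any():
            return out
        out[bad] = np.abs(rng.normal(0.1, 0.05, size=int(bad.sum())))


def generate_similarity(
    L: int = 32,
    n_pairs: int = 16,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    prefix: str = "w",
) -> SimilarityMatrix:
    """Synthetic similarity matrix with separated value ranges.

    ``n_pairs`` designated pairs (a random disjoint pairing of items)
    get similarities uniform in [0.7, 0.95]; every other off-diagonal
    entry is background noise in [0, 0.3]; the diagonal is 1. The
    designated pairs are therefore exactly recoverable by greedy
    above-0.7 selection.
    """
    if 2 * n_pairs > L:
        raise ValidationError("2*n_pairs exceeds L")
    if rng is None:
        rng = np.random.default_rng(seed)
    width = max(2, len(str(L)))
    vocab = tuple(f"{prefix}{i:0{width}d}" for i in range(1, L + 1))
    vals = np.zeros((L, L))
    iu = np.triu_indices(L, k=1)
    vals[iu] = _background_block(rng, len(iu[0]))
    perm = rng.permutation(L)
    for k in range(n_pairs):
        i, j = int(perm[2 * k]), int(perm[2 * k + 1])
        vals[min(i, j), max(i, j)] = rng.uniform(0.7, 0.95)
    vals = vals + vals.T
    np.fill_diagonal(vals, 1.0)
    return SimilarityMatrix(vocabulary=vocab, values=vals)


def simulate_recall(
    study: StudyList,
    sim: SimilarityMatrix,
    p: SimParams,
    condition: str,
    rng: Optional[np.random.Generator] = None,
    subject_id: str = "s1",
    condition_order: int = 1,
) -> RecallSequence:
    """Draw one raw transcript from the cue-mixture process."""
    if rng is None:
        rng = np.random.default_rng(p.seed)
    L = study.L
    lam, rho = p.lam(condition), p.rho(condition)
    positions = np.arange(1, L + 1)
    sim_idx = np.array([sim.index(w) for w in study.items])
    sim_block = sim.values[np.ix_(sim_idx, sim_idx)]  # position-ordered

    recalled: list[int] = []
    recalled_set: set[int] = set()
    responses: list[str] = []
    prev: Optional[int] = None
    n_intrusions = 0

    while len(responses) < MAX_OUTPUTS:
        if rng.random() < p.p_stop:
            break
        if rng.random() < p.epsilon:
            n_intrusions += 1
            responses.append(f"zzq{n_intrusions:03d}")
            continue
        if recalled and rng.random() < p.p_repeat:
            pos = int(rng.choice(recalled))
            responses.append(study.word_at(pos))
            continue
        available = np.array([q for q in positions if q not in recalled_set])
        if available.size == 0:
            # list exhausted: only intrusions/repetitions can still occur
            if p.epsilon == 0 and (p.p_repeat == 0 or not recalled):
                break
            continue
        if prev is None:
            weights = np.exp((available - L) / p.tau)
        else:
            delta = available - prev
            temporal = np.exp(-np.abs(delta) / p.tau)
            temporal[delta > 0] *= p.phi
            semantic = sim_block[prev - 1, available - 1]
            weights = (1 - lam) * temporal + lam * semantic
        total = weights.sum()
        if total <= 0:
            break
        pos = int(rng.choice(available, p=weights / total))
        if rng.random() < rho:
            continue  # recovery failure: attempt without output
        recalled.append(pos)
        recalled_set.add(pos)
        prev = pos
        responses.append(study.word_at(pos))
    return RecallSequence(
        subject_id=subject_id,
        condition=condition,
        condition_order=condition_order,
        responses=tuple(responses),
        list_id=study.list_id,
    )


def simulate_study(p: SimParams) -> SyntheticCohort:
    """Simulate a full two-condition within-subject study.

    Each subject studies one list per condition (two distinct lists,
    drawn from a shared vocabulary of designated-pair structure) under
    one of ``n_orderings`` ordering schemes, with condition order
    counterbalanced across subjects (balanced to within one subject).
    """
    rng = np.random.default_rng(p.seed)
    n_lists = 2
    sim = generate_similarity(
        L=n_lists * p.L, n_pairs=n_lists * p.n_pairs, rng=rng
    )
    spec = ListSpec(L=p.L, n_pairs=p.n_pairs, n_orderings=p.n_orderings)
    all_pairs = select_pairs(
        sim,
        ListSpec(L=n_lists * p.L, n_pairs=n_lists * p.n_pairs),
        rng=rng,
    )
    used = {w for pr in all_pairs for w in pr}
    free = [w for w in sim.vocabulary if w not in used]
    n_fillers = p.L - 2 * p.n_pairs
    study_lists: list[StudyList] = []
    lists_by_block: list[list[StudyList]] = []
    for k in range(n_lists):
        pairs = all_pairs[k * p.n_pairs : (k + 1) * p.n_pairs]
        fillers = free[k * n_fillers : (k + 1) * n_fillers]
        assignment = {w: i for i, pr in enumerate(pairs) for w in pr}
        block = [
            StudyList(
                list_id=f"L{k + 1}.o{s + 1}",
                items=order,
                pair_assignment=assignment,
            )
            for s, order in enumerate(order_list(pairs, fillers, spec, rng=rng))
        ]
        study_lists.extend(block)
        lists_by_block.append(block)

    recalls: list[RecallSequence] = []
    for s in range(p.n_subjects):
        subject_id = f"sub{s + 1:04d}"
        same_first = s % 2 == 0
        conditions = (
            ("same_context", "different_context")
            if same_first
            else ("different_context", "same_context")
        )
        order_flag = 1 if same_first else 2
        for block_idx, condition in enumerate(conditions):
            study = lists_by_block[block_idx][int(rng.integers(p.n_orderings))]
            recalls.append(
                simulate_recall(
                    study,
                    sim,
                    p,
                    condition,
                    rng=rng,
                    subject_id=subject_id,
                    condition_order=order_flag,
                )
            )
    truth = {
        "lam": {"same_context": p.lam_same, "different_context": p.lam_diff},
        "rho": {"same_context": p.rho_same, "different_context": p.rho_diff},
        "tau": p.tau,
        "phi": p.phi,
        "p_stop": p.p_stop,
        "epsilon": p.epsilon,
        "p_repeat": p.p_repeat,
        "n_subjects": p.n_subjects,
        "seed": p.seed,
    }
    return SyntheticCohort(
        study_lists=study_lists,
        similarity=sim,
        recalls=recalls,
        params=p,
        truth=truth,
    )


def write_cohort(cohort: SyntheticCohort, outdir: Path | str) -> dict[str, Path]:
    """Write a cohort to the standard CSV dialects plus a truth YAML."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "lists": outdir / "study_lists.csv",
        "similarity": outdir / "similarity.csv",
        "recalls": outdir / "recalls.csv",
        "truth": outdir / "truth.yaml",
    }
    rio.write_study_lists(cohort.study_lists, paths["lists"])
    rio.write_similarity_matrix(cohort.similarity, paths["similarity"])
    rio.write_recalls(cohort.recalls, paths["recalls"])
    with open(paths["truth"], "w") as fh:
        yaml.safe_dump(cohort.truth, fh, sort_keys=True)
    return paths
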