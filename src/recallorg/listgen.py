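"""Constrained study-list construction.

Builds lists containing designated high-similarity word pairs
(similarity above a threshold) arranged so that members of a pair are
never adjacent, under one or more seed-reproducible ordering schemes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np

from .types import SimilarityMatrix, StudyList, ValidationError

__all__ = ["ListSpec", "select_pairs", "order_list", "make_lists"]

_MAX_REPAIR_STEPS = 10_000


@dataclass(frozen=True)
class ListSpec:
    """Parameters of list construction."""

    L: int = 32
    n_pairs: int = 16
    sim_threshold: float = 0.7
    n_orderings: int = 4
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if 2 * self.n_pairs > self.L:
            raise ValidationError(
                f"2*n_pairs = {2 * self.n_pairs} exceeds list length {self.L}"
            )
        if not 0 < self.sim_threshold < 1:
            raise ValidationError(
                f"sim_threshold {self.sim_threshold} outside (0, 1)"
            )
        if self.n_orderings < 1:
            raise ValidationError("n_orderings must be >= 1")


def _max_disjoint_pairs(eligible: Iterable[tuple[str, str]]) -> int:
    g = nx.Graph()
    g.add_edges_from(eligible)
    return len(nx.max_weight_matching(g, maxcardinality=True))


def select_pairs(
    sim: SimilarityMatrix,
    spec: ListSpec,
    rng: Optional[np.random.Generator] = None,
) -> list[tuple[str, str]]:
    """Select ``n_pairs`` disjoint word pairs with similarity above threshold.

    Selection is greedy in descending similarity; ties are broken by a
    seed-controlled shuffle so the result is reproducible under
    ``spec.seed`` (or an explicit ``rng``).

    Raises
    ------
    ValidationError
        If fewer than ``n_pairs`` disjoint above-threshold pairs exist;
        the message reports the maximum achievable count.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    words = sim.vocabulary
    eligible = [
        (float(sim.values[i, j]), words[i], words[j])
        for i in range(len(words))
        for j in range(i + 1, len(words))
        if sim.values[i, j] > spec.sim_threshold
    ]
    rng.shuffle(eligible)  # seed-controlled tie order
    eligible.sort(key=lambda t: -t[0])

    used: set[str] = set()
    chosen: list[tuple[str, str]] = []
    for _, a, b in eligible:
        if a in used or b in used:
            continue
        chosen.append((a, b))
        used.update((a, b))
        if len(chosen) == spec.n_pairs:
            return chosen
    feasible = _max_disjoint_pairs((a, b) for _, a, b in eligible)
    raise ValidationError(
        f"feasible pairs: {feasible} < {spec.n_pairs} "
        f"(similarity threshold {spec.sim_threshold})"
    )


def _violations(
    order: Sequence[str],
    pair_of: dict[str, int],
    strict_block: Optional[set[frozenset[str]]] = None,
) -> list[int]:
    """Indices i where order[i] and order[i+1] are forbidden neighbours."""
    bad = []
    for i in range(len(order) - 1):
        a, b = order[i], order[i + 1]
        if pair_of.get(a) is not None and pair_of.get(a) == pair_of.get(b):
            bad.append(i)
        elif strict_block is not None and frozenset((a, b)) in strict_block:
            bad.append(i)
    return bad


def order_list(
    pairs: Sequence[tuple[str, str]],
    fillers: Sequence[str],
    spec: ListSpec,
    rng: Optional[np.random.Generator] = None,
    sim: Optional[SimilarityMatrix] = None,
    strict: bool = False,
) -> list[tuple[str, ...]]:
    """Produce ``n_orderings`` permutations with no adjacent pair members.

    Each ordering is a seed-controlled shuffle followed by local repair:
    one member of a violating adjacency is swapped with a random other
    position until no violation remains (or an error after 10,000 repair
    steps). With ``strict=True`` any adjacent pair of words whose
    similarity exceeds ``spec.sim_threshold`` is also forbidden (requires
    ``sim``).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    words = [w for p in pairs for w in p] + list(fillers)
    if len(set(words)) != len(words):
        raise ValidationError("pairs and fillers overlap")
    if len(words) != spec.L:
        raise ValidationError(
            f"pairs and fillers supply {len(words)} words, expected L={spec.L}"
        )
    pair_of = {w: i for i, p in enumerate(pairs) for w in p}
    strict_block: Optional[set[frozenset[str]]] = None
    if strict:
        if sim is None:
            raise ValidationError("strict mode requires a similarity matrix")
        strict_block = {
            frozenset((a, b))
            for i, a in enumerate(words)
            for b in words[i + 1 :]
            if sim.similarity(a, b) > spec.sim_threshold
        }

    orderings: list[tuple[str, ...]] = []
    for _ in range(spec.n_orderings):
        order = list(words)
        rng.shuffle(order)
        steps = 0
        while True:
            bad = _violations(order, pair_of, strict_block)
            if not bad:
                break
            if steps >= _MAX_REPAIR_STEPS:
                raise ValidationError(
                    "could not construct a non-adjacent ordering "
                    f"after {_MAX_REPAIR_STEPS} repair steps"
                )
            i = int(rng.choice(bad))
            j = int(rng.integers(len(order)))
            order[i + 1], order[j] = order[j], order[i + 1]
            steps += 1
        assert not _violations(order, pair_of, strict_block)
        orderings.append(tuple(order))
    return orderings


def make_lists(
    sim: SimilarityMatrix,
    spec: ListSpec,
    n_lists: int = 1,
    rng: Optional[np.random.Generator] = None,
    strict: bool = False,
) -> list[StudyList]:
    """Build ``n_lists`` study lists (each with ``n_orderings`` schemes).

    Pairs are selected disjointly across all lists; fillers are drawn
    from the unused vocabulary. List ids are ``L{k}.o{s}`` for list k,
    ordering scheme s.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    total_spec = ListSpec(
        L=spec.L,
        n_pairs=spec.n_pairs * n_lists,
        sim_threshold=spec.sim_threshold,
        n_orderings=spec.n_orderings,
        seed=spec.seed,
    ) if spec.n_pairs * n_lists * 2 <= spec.L else None
    if total_spec is not None:
        all_pairs = select_pairs(sim, total_spec, rng=rng)
    else:
        # more pair slots than one list holds: select against a widened spec
        widened = ListSpec(
            L=2 * spec.n_pairs * n_lists,
            n_pairs=spec.n_pairs * n_lists,
            sim_threshold=spec.sim_threshold,
            n_orderings=spec.n_orderings,
            seed=spec.seed,
        )
        all_pairs = select_pairs(sim, widened, rng=rng)
    used = {w for p in all_pairs for w in p}
    free = [w for w in sim.vocabulary if w not in used]
    n_fillers = spec.L - 2 * spec.n_pairs
    if n_lists * n_fillers > len(free):
        raise ValidationError(
            f"vocabulary provides {len(free)} fillers, "
            f"{n_lists * n_fillers} needed"
        )
    lists: list[StudyList] = []
    for k in range(n_lists):
        pairs = all_pairs[k * spec.n_pairs : (k + 1) * spec.n_pairs]
        fillers = free[k * n_fillers : (k + 1) * n_fillers]
        assignment = {w: i for i, p in enumerate(pairs) for w in p}
        for s, order in enumerate(
            order_list(pairs, fillers, spec, rng=rng, sim=sim, strict=strict)
        ):
            lists.append(
                StudyList(
                    list_id=f"L{k + 1}.o{s + 1}",
                    items=order,
                    pair_assignment=assignment,
                )
            )
    return lists
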