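"""Independent brute-force reference implementations used by the tests.

Everything here deliberately avoids the package's scoring code paths:
ranks are assigned by counting comparisons, tallies use plain dicts,
and transition replay is written from the behavioural rules alone.
"""

from __future__ import annotations


def brute_rank(values: list[float], idx: int) -> float:
    """Average (fractional) rank of values[idx], ascending, by counting."""
    v = values[idx]
    less = sum(1 for x in values if x < v)
    equal = sum(1 for x in values if x == v)
    return less + (equal + 1) / 2.0


def brute_replay(resolved: list[tuple[str, int | None]], L: int):
    """Replay a resolved transcript into (from, to, possible) triples.

    ``resolved`` holds (label, position) pairs; only consecutive
    first-time-correct pairs form valid transitions. Possible targets
    are every not-yet-recalled position other than the just-recalled
    one.
    """
    transitions = []
    recalled: list[int] = []
    for (lab_a, pos_a), (lab_b, pos_b) in zip(resolved, resolved[1:]):
        if lab_a == "correct":
            recalled.append(pos_a)
        if lab_a == "correct" and lab_b == "correct":
            possible = [
                q for q in range(1, L + 1) if q not in recalled
            ]
            transitions.append((pos_a, pos_b, possible))
    return transitions


def brute_factor(
    resolved: list[tuple[str, int | None]],
    L: int,
    key,
) -> list[float]:
    """Per-transition (R-1)/(N-1) scores with ``key(from, candidate)``.

    Higher key = better candidate = higher rank. Transitions with fewer
    than two possible targets are skipped.
    """
    scores = []
    for frm, to, possible in brute_replay(resolved, L):
        if len(possible) < 2:
            continue
        vals = [key(frm, q) for q in possible]
        r = brute_rank(vals, possible.index(to))
        scores.append((r - 1.0) / (len(possible) - 1.0))
    return scores


def brute_crp(resolved: list[tuple[str, int | None]], L: int):
    """(actual, possible) per-lag tallies as plain dicts."""
    actual: dict[int, int] = {}
    possible: dict[int, int] = {}
    for frm, to, poss in brute_replay(resolved, L):
        actual[to - frm] = actual.get(to - frm, 0) + 1
        for q in poss:
            possible[q - frm] = possible.get(q - frm, 0) + 1
    return actual, possible
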