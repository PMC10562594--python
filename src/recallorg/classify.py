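"""Classification of raw typed responses.

Responses are matched against the known word pool by restricted
Damerau-Levenshtein distance (transpositions of adjacent characters
count as one edit), after case-folding and whitespace trimming. A
response matching exactly one current-list word within the threshold is
credited as correct (or repetition, if already credited); matching a
word studied on a *different* session list yields a prior-list
intrusion (PLI); everything else — including ambiguous ties between
candidates at equal distance — is an extra-list intrusion (ELI).
"""

from __future__ import annotations

from typing import Iterable, Sequence

from .types import RecallSequence, Resolution, StudyList

__all__ = ["damerau_levenshtein", "resolve_responses"]


def damerau_levenshtein(a: str, b: str) -> int:
    """Restricted Damerau-Levenshtein (optimal string alignment) distance.

    Counts insertions, deletions, substitutions and transpositions of
    adjacent characters, each as one edit.
    """
    la, lb = len(a), len(b)
    if la == 0:
        return lb
    if lb == 0:
        return la
    prev2: list[int] = []
    prev = list(range(lb + 1))
    for i in range(1, la + 1):
        cur = [i] + [0] * lb
        for j in range(1, lb + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost)
            if (
                i > 1
                and j > 1
                and a[i - 1] == b[j - 2]
                and a[i - 2] == b[j - 1]
            ):
                cur[j] = min(cur[j], prev2[j - 2] + 1)
        prev2, prev = prev, cur
    return prev[lb]


def _fold(word: str) -> str:
    return word.strip().casefold()


def _best_matches(
    response: str, vocabulary: Sequence[str], max_dist: int
) -> tuple[int, list[str]]:
    """Words at minimal distance from ``response`` (if within threshold)."""
    best = max_dist + 1
    matches: list[str] = []
    for word in vocabulary:
        d = damerau_levenshtein(response, _fold(word))
        if d < best:
            best = d
            matches = [word]
        elif d == best:
            matches.append(word)
    return best, matches


def resolve_responses(
    raw: RecallSequence,
    study: StudyList,
    session_lists: Iterable[StudyList] = (),
    max_edit_distance: int = 1,
) -> RecallSequence:
    """Classify each raw response against the session word pool.

    Parameters
    ----------
    raw
        Transcript with raw responses (any existing resolutions are
        recomputed, making the operation idempotent).
    study
        The just-studied list; its words are the targets for correct
        recalls.
    session_lists
        All lists shown in the session (the current list may be
        included; it is skipped when looking for prior-list words).
    max_edit_distance
        Maximum Damerau-Levenshtein distance for a match (default 1;
        0 reduces to exact case-folded membership).

    Returns
    -------
    RecallSequence
        Copy of ``raw`` with the ``resolved`` field populated. Every
        response receives exactly one label.
    """
    current = set(study.items)
    other_words: list[str] = []
    seen: set[str] = set()
    for sl in session_lists:
        if sl.list_id == study.list_id:
            continue
        for w in sl.items:
            if w not in current and w not in seen:
                other_words.append(w)
                seen.add(w)
    current_exact = {_fold(w): w for w in study.items}
    other_exact = {_fold(w) for w in other_words}

    credited: set[int] = set()
    resolutions: list[Resolution] = []
    for response in raw.responses:
        folded = _fold(response)
        if folded in current_exact:  # fast path; distance 0 is always unique
            pos = study.position_of(current_exact[folded])
            if pos in credited:
                resolutions.append(Resolution("repetition", pos))
            else:
                credited.add(pos)
                resolutions.append(Resolution("correct", pos))
            continue
        dist, matches = _best_matches(folded, study.items, max_edit_distance)
        if dist <= max_edit_distance:
            if len(matches) == 1:
                pos = study.position_of(matches[0])
                if pos in credited:
                    resolutions.append(Resolution("repetition", pos))
                else:
                    credited.add(pos)
                    resolutions.append(Resolution("correct", pos))
            else:  # ambiguous: no guess
                resolutions.append(Resolution("ELI"))
            continue
        if folded in other_exact:
            resolutions.append(Resolution("PLI"))
            continue
        dist, matches = _best_matches(folded, other_words, max_edit_distance)
        if dist <= max_edit_distance and len(matches) == 1:
            resolutions.append(Resolution("PLI"))
        else:
            resolutions.append(Resolution("ELI"))
    return raw.with_resolutions(resolutions)
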