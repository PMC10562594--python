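from __future__ import annotations

import numpy as np
import pytest

from recallorg.types import RecallSequence, Resolution, StudyList


@pytest.fixture
def words32() -> tuple[str, ...]:
    return tuple(f"w{i:02d}" for i in range(1, 33))


@pytest.fixture
def study32(words32) -> StudyList:
    return StudyList(list_id="L1", items=words32)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230926)


def resolved_sequence(
    positions: list[int | str],
    subject_id: str = "s1",
    condition: str = "same_context",
) -> RecallSequence:
    """Build a resolved transcript from serial positions / label strings.

    Entries may be ints (first occurrence -> correct, later -> repetition)
    or the strings "ELI"/"PLI".
    """
    resolutions: list[Resolution] = []
    seen: set[int] = set()
    for p in positions:
        if p == "ELI":
            resolutions.append(Resolution("ELI"))
        elif p == "PLI":
            resolutions.append(Resolution("PLI"))
        elif p in seen:
            resolutions.append(Resolution("repetition", p))
        else:
            seen.add(p)  # type: ignore[arg-type]
            resolutions.append(Resolution("correct", p))
    return RecallSequence(
        subject_id=subject_id,
        condition=condition,
        condition_order=1,
        responses=tuple(f"r{i}" for i in range(len(positions))),
        resolved=tuple(resolutions),
    )
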