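"""Readers and writers for the plain-CSV artifact formats.

Dialects (all UTF-8):

* study lists — ``list_id,serial_position,word`` (optional ``pair_id``);
* similarity matrix — square CSV, first row/column are the vocabulary;
* recall transcripts — ``subject_id,condition,condition_order,
  output_position,response`` (optional ``list_id``).
"""

from __future__ import annotations

import os
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .types import (
    RecallSequence,
    SimilarityMatrix,
    StudyList,
    ValidationError,
)

__all__ = [
    "read_study_lists",
    "write_study_lists",
    "read_similarity_matrix",
    "write_similarity_matrix",
    "read_recalls",
    "write_recalls",
]

_SYMMETRY_TOL = 1e-9


def read_study_lists(path: os.PathLike | str) -> list[StudyList]:
    """Read study lists from CSV, validating serial positions.

    Serial positions must be exactly ``1..L`` per list, with no gaps or
    duplicates; words must be unique within a list.
    """
    df = pd.read_csv(path, dtype={"list_id": str, "word": str})
    required = {"list_id", "serial_position", "word"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"study-list file missing columns {sorted(missing)}")
    has_pairs = "pair_id" in df.columns
    lists: list[StudyList] = []
    for list_id, grp in df.groupby("list_id", sort=False):
        positions = grp["serial_position"].astype(int).to_numpy()
        L = len(positions)
        seen: set[int] = set()
        for p in positions:
            if p in seen:
                raise ValidationError(
                    f"list {list_id!r}: duplicate serial position {p}"
                )
            seen.add(p)
        for p in range(1, L + 1):
            if p not in seen:
                raise ValidationError(
                    f"list {list_id!r}: serial-position gap at {p}"
                )
        grp = grp.sort_values("serial_position")
        items = tuple(grp["word"].astype(str))
        pair_assignment = None
        if has_pairs:
            pairs = {
                w: int(pid)
                for w, pid in zip(grp["word"], grp["pair_id"])
                if pd.notna(pid)
            }
            pair_assignment = pairs or None
        lists.append(
            StudyList(list_id=str(list_id), items=items, pair_assignment=pair_assignment)
        )
    return lists


def write_study_lists(lists: Iterable[StudyList], path: os.PathLike | str) -> None:
    rows = []
    for sl in lists:
        pa = sl.pair_assignment or {}
        for pos, word in enumerate(sl.items, start=1):
            rows.append(
                {
                    "list_id": sl.list_id,
                    "serial_position": pos,
                    "word": word,
                    "pair_id": pa.get(word, ""),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_similarity_matrix(path: os.PathLike | str) -> SimilarityMatrix:
    """Read a square similarity CSV (first row/column = vocabulary).

    Near-symmetric inputs (within 1e-9) are symmetrized by averaging;
    larger asymmetries are an error. The diagonal is forced to 1.
    """
    df = pd.read_csv(path, index_col=0)
    rows = [str(w) for w in df.index]
    cols = [str(w) for w in df.columns]
    if rows != cols:
        raise ValidationError(
            "similarity matrix: row and column vocabularies differ"
        )
    vals = df.to_numpy(dtype=float)
    if vals.shape[0] != vals.shape[1]:
        raise ValidationError("similarity matrix: not square")
    if np.any(vals < 0) or np.any(vals > 1):
        bad = vals[(vals < 0) | (vals > 1)].flat[0]
        raise ValidationError(f"similarity matrix: value {bad} outside [0, 1]")
    if not np.allclose(vals, vals.T, atol=_SYMMETRY_TOL):
        raise ValidationError("similarity matrix: asymmetric beyond tolerance")
    vals = (vals + vals.T) / 2.0
    np.fill_diagonal(vals, 1.0)
    return SimilarityMatrix(vocabulary=tuple(rows), values=vals)


def write_similarity_matrix(
    sim: SimilarityMatrix, path: os.PathLike | str, float_format: str = "%.17g"
) -> None:
    df = pd.DataFrame(sim.values, index=sim.vocabulary, columns=sim.vocabulary)
    df.to_csv(path, float_format=float_format)


def read_recalls(path: os.PathLike | str) -> list[RecallSequence]:
    """Read recall transcripts grouped by subject and condition.

    Responses are ordered by ``output_position`` within each group.
    An optional ``list_id`` column records which list was just studied.
    """
    df = pd.read_csv(
        path,
        dtype={"subject_id": str, "condition": str, "response": str},
        keep_default_na=False,
    )
    required = {
        "subject_id",
        "condition",
        "condition_order",
        "output_position",
        "response",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"recall file missing columns {sorted(missing)}")
    has_list = "list_id" in df.columns
    sequences: list[RecallSequence] = []
    for (subject, condition), grp in df.groupby(
        ["subject_id", "condition"], sort=False
    ):
        grp = grp.sort_values("output_position")
        orders = set(grp["condition_order"].astype(int))
        if len(orders) != 1:
            raise ValidationError(
                f"subject {subject!r} condition {condition!r}: "
                "inconsistent condition_order"
            )
        list_id: Optional[str] = None
        if has_list:
            ids = {str(x) for x in grp["list_id"] if str(x)}
            if len(ids) > 1:
                raise ValidationError(
                    f"subject {subject!r} condition {condition!r}: "
                    "inconsistent list_id"
                )
            list_id = ids.pop() if ids else None
        sequences.append(
            RecallSequence(
                subject_id=str(subject),
                condition=str(condition),
                condition_order=orders.pop(),
                # empty strings are placeholders for zero-recall transcripts
                responses=tuple(str(r) for r in grp["response"] if str(r)),
                list_id=list_id,
            )
        )
    return sequences


def write_recalls(
    sequences: Iterable[RecallSequence], path: os.PathLike | str
) -> None:
    rows = []
    for seq in sequences:
        # a zero-recall transcript still gets one (empty-response) row so
        # the subject-condition cell survives a round trip
        for pos, resp in enumerate(seq.responses, start=1) if seq.responses else [
            (1, "")
        ]:
            rows.append(
                {
                    "subject_id": seq.subject_id,
                    "condition": seq.condition,
                    "condition_order": seq.condition_order,
                    "output_position": pos,
                    "response": resp,
                    "list_id": seq.list_id or "",
                }
            )
    pd.DataFrame(
        rows,
        columns=[
            "subject_id",
            "condition",
            "condition_order",
            "output_position",
            "response",
            "list_id",
        ],
    ).to_csv(path, index=False)
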