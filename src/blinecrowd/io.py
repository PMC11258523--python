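"""Readers and writers for the tab-delimited interchange formats.

Three formats flow between pipeline stages:

* opinion log — ``user_id  clip_id  label  event_index`` plus optional
  ``qscore_at_submission  eligible`` columns filled by a contest replay;
* clip manifest — ``clip_id  patient_id  split  [reference_label]`` plus any
  extra columns, which round-trip untouched;
* expert label table — ``clip_id`` plus one column per expert id.

Labels are stored as the canonical uppercase tokens; synonyms are rejected.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence, Union

import pandas as pd

from .errors import FormatError, IntegrityError, OrderingError, ParseError
from .labels import BLineClass, Clip, Opinion, Split

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

_OPINION_COLUMNS = ["user_id", "clip_id", "label", "event_index"]
_OPINION_OPT_COLUMNS = ["qscore_at_submission", "eligible"]
_MANIFEST_COLUMNS = ["clip_id", "patient_id", "split"]


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{what} is missing required column {col!r}")


def _parse_label(token: object, row: int, column: str) -> BLineClass:
    try:
        return BLineClass.parse(str(token))
    except ValueError as exc:
        raise ParseError(f"row {row}, column {column!r}: {exc}") from None


def read_opinion_log(path: PathLike) -> list[Opinion]:
    """Read an opinion log, returning opinions sorted by event_index."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, _OPINION_COLUMNS, "opinion log")
    has_qscore = "qscore_at_submission" in df.columns
    has_eligible = "eligible" in df.columns

    opinions: list[Opinion] = []
    seen: set[int] = set()
    for row, rec in enumerate(df.itertuples(index=False), start=1):
        label = _parse_label(rec.label, row, "label")
        try:
            event_index = int(rec.event_index)
        except ValueError:
            raise ParseError(
                f"row {row}, column 'event_index': not an integer: {rec.event_index!r}"
            ) from None
        if event_index in seen:
            raise IntegrityError(f"duplicate event_index {event_index} at row {row}")
        seen.add(event_index)
        qscore = None
        if has_qscore and rec.qscore_at_submission != "":
            qscore = float(rec.qscore_at_submission)
        eligible = False
        if has_eligible and rec.eligible != "":
            eligible = rec.eligible == "true"
        opinions.append(
            Opinion(
                user_id=str(rec.user_id),
                clip_id=str(rec.clip_id),
                label=label,
                event_index=event_index,
                qscore_at_submission=qscore,
                eligible=eligible,
            )
        )
    opinions.sort(key=lambda o: o.event_index)
    return opinions


def write_opinion_log(opinions: Sequence[Opinion], path: PathLike) -> None:
    """Write an opinion log; input must already be sorted by event_index."""
    indices = [o.event_index for o in opinions]
    if indices != sorted(indices):
        raise OrderingError("opinions must be sorted by event_index before writing")
    rows = []
    for o in opinions:
        rows.append(
            {
                "user_id": o.user_id,
                "clip_id": o.clip_id,
                "label": o.label.name,
                "event_index": o.event_index,
                "qscore_at_submission": ""
                if o.qscore_at_submission is None
                else repr(o.qscore_at_submission),
                "eligible": "true" if o.eligible else "false",
            }
        )
    df = pd.DataFrame(rows, columns=_OPINION_COLUMNS + _OPINION_OPT_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_clip_manifest(path: PathLike) -> dict[str, Clip]:
    """Read a clip manifest into a map clip_id -> Clip.

    TRAINING/TEST rows must carry a reference_label; a label on an UNLABELED
    row is ignored with a logged warning. Extra columns are preserved in
    ``Clip.extra``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, _MANIFEST_COLUMNS, "clip manifest")
    has_ref = "reference_label" in df.columns
    extra_cols = [
        c for c in df.columns if c not in _MANIFEST_COLUMNS + ["reference_label"]
    ]

    clips: dict[str, Clip] = {}
    for row, rec in enumerate(df.itertuples(index=False), start=1):
        clip_id = str(rec.clip_id)
        if clip_id in clips:
            raise IntegrityError(f"duplicate clip_id {clip_id!r} at row {row}")
        try:
            split = Split(str(rec.split))
        except ValueError:
            raise ParseError(
                f"row {row}, column 'split': unknown split {rec.split!r}"
            ) from None
        ref_token = getattr(rec, "reference_label", "") if has_ref else ""
        reference_label = None
        if ref_token != "":
            reference_label = _parse_label(ref_token, row, "reference_label")
        if split in (Split.TRAINING, Split.TEST) and reference_label is None:
            raise FormatError(
                f"row {row}: {split.value} clip {clip_id!r} has no reference_label"
            )
        if split is Split.UNLABELED and reference_label is not None:
            logger.warning(
                "row %d: UNLABELED clip %s has a reference_label; ignoring it",
                row,
                clip_id,
            )
            reference_label = None
        extra = {c: getattr(rec, c) for c in extra_cols}
        clips[clip_id] = Clip(
            clip_id=clip_id,
            patient_id=str(rec.patient_id),
            split=split,
            reference_label=reference_label,
            extra=extra,
        )
    return clips


def write_clip_manifest(clips: Mapping[str, Clip], path: PathLike) -> None:
    """Write a clip manifest (stable clip_id order, extras preserved)."""
    extra_cols: list[str] = []
    for clip in clips.values():
        for c in clip.extra:
            if c not in extra_cols:
                extra_cols.append(c)
    rows = []
    for clip_id in sorted(clips):
        clip = clips[clip_id]
        row = {
            "clip_id": clip.clip_id,
            "patient_id": clip.patient_id,
            "split": clip.split.value,
            "reference_label": ""
            if clip.reference_label is None
            else clip.reference_label.name,
        }
        for c in extra_cols:
            row[c] = clip.extra.get(c, "")
        rows.append(row)
    df = pd.DataFrame(rows, columns=_MANIFEST_COLUMNS + ["reference_label"] + extra_cols)
    df.to_csv(path, sep="\t", index=False)


def read_expert_labels(path: PathLike) -> dict[str, dict[str, BLineClass]]:
    """Read an expert label table into a map expert_id -> (clip_id -> class)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, ["clip_id"], "expert label table")
    expert_ids = [c for c in df.columns if c != "clip_id"]
    if not expert_ids:
        raise FormatError("expert label table has no expert columns")
    table: dict[str, dict[str, BLineClass]] = {e: {} for e in expert_ids}
    seen: set[str] = set()
    for row, rec in enumerate(df.itertuples(index=False), start=1):
        clip_id = str(rec.clip_id)
        if clip_id in seen:
            raise IntegrityError(f"duplicate clip_id {clip_id!r} at row {row}")
        seen.add(clip_id)
        for e in expert_ids:
            table[e][clip_id] = _parse_label(getattr(rec, e), row, e)
    return table


def write_expert_labels(
    table: Mapping[str, Mapping[str, BLineClass]], path: PathLike
) -> None:
    """Write an expert label table (experts as columns, clips as rows)."""
    expert_ids = sorted(table)
    clip_ids = sorted({c for labels in table.values() for c in labels})
    rows = []
    for clip_id in clip_ids:
        row = {"clip_id": clip_id}
        for e in expert_ids:
            label = table[e].get(clip_id)
            row[e] = "" if label is None else label.name
        rows.append(row)
    df = pd.DataFrame(rows, columns=["clip_id"] + expert_ids)
    df.to_csv(path, sep="\t", index=False)
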