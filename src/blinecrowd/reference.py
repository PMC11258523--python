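"""Expert reference standards: full-consensus and leave-one-out majorities.

The reference label of a clip is the majority of the expert opinions, with
ties broken uniformly at random. Beyond the single 6-expert consensus, a
leave-one-out family is built — one 5-expert standard per excluded expert —
so each expert can be scored against a reference their own opinion did not
influence. Tie-breaking for each standard draws from a seed derived
deterministically from (base seed, excluded expert), so recomputing one
standard never shifts another's ties.
"""

from __future__ import annotations

import enum
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import numpy as np
import pandas as pd

from .errors import CoverageError, FormatError
from .labels import CLASSES, BLineClass


class StandardSource(enum.Enum):
    FULL_CONSENSUS = "FULL_CONSENSUS"
    LEAVE_ONE_OUT = "LEAVE_ONE_OUT"


@dataclass(frozen=True)
class ReferenceStandard:
    """A clip -> class map produced by (possibly partial) expert majority."""

    labels: Mapping[str, BLineClass]
    source: StandardSource
    excluded_expert: Optional[str]
    rng_seed: int

    def __post_init__(self) -> None:
        if self.source is StandardSource.FULL_CONSENSUS and self.excluded_expert:
            raise ValueError("FULL_CONSENSUS must not name an excluded expert")
        if self.source is StandardSource.LEAVE_ONE_OUT and not self.excluded_expert:
            raise ValueError("LEAVE_ONE_OUT must name exactly one excluded expert")


@dataclass(frozen=True)
class LeaveOneOutSet:
    """One 5-expert standard per excluded expert."""

    standards: Mapping[str, ReferenceStandard]

    def __post_init__(self) -> None:
        for expert, std in self.standards.items():
            if std.excluded_expert != expert:
                raise ValueError(
                    f"standard keyed {expert!r} excludes {std.excluded_expert!r}"
                )


def majority_label(
    votes: Iterable[BLineClass], rng: np.random.Generator
) -> BLineClass:
    """Majority class of a vote multiset; ties broken uniformly from ``rng``."""
    counts = {cls: 0 for cls in CLASSES}
    n = 0
    for v in votes:
        counts[v] += 1
        n += 1
    if n == 0:
        raise ValueError("majority_label requires a nonempty vote multiset")
    best = max(counts.values())
    leaders = [cls for cls in CLASSES if counts[cls] == best]
    if len(leaders) == 1:
        return leaders[0]
    return leaders[rng.integers(len(leaders))]


def _check_coverage(
    expert_opinions: Mapping[str, Mapping[str, BLineClass]],
) -> list[str]:
    if not expert_opinions:
        raise ValueError("at least one expert is required")
    clip_sets = {e: set(m) for e, m in expert_opinions.items()}
    all_clips = set().union(*clip_sets.values())
    for expert, clips in clip_sets.items():
        missing = all_clips - clips
        if missing:
            clip = sorted(missing)[0]
            raise CoverageError(
                f"expert {expert!r} has no opinion on clip {clip!r}"
            )
    return sorted(all_clips)


def _expert_seed(rng_seed: int, excluded_expert: str) -> list[int]:
    # crc32 gives a stable cross-session integer from the expert id
    return [rng_seed, zlib.crc32(excluded_expert.encode("utf-8"))]


def build_full_consensus(
    expert_opinions: Mapping[str, Mapping[str, BLineClass]], rng_seed: int
) -> ReferenceStandard:
    """Majority-rule consensus of all experts, one label per clip."""
    clip_ids = _check_coverage(expert_opinions)
    rng = np.random.default_rng([rng_seed])
    labels = {
        clip: majority_label(
            (expert_opinions[e][clip] for e in sorted(expert_opinions)), rng
        )
        for clip in clip_ids
    }
    return ReferenceStandard(
        labels=labels,
        source=StandardSource.FULL_CONSENSUS,
        excluded_expert=None,
        rng_seed=rng_seed,
    )


def build_leave_one_out(
    expert_opinions: Mapping[str, Mapping[str, BLineClass]], rng_seed: int
) -> LeaveOneOutSet:
    """One majority standard per excluded expert, independently tie-broken."""
    if len(expert_opinions) < 3:
        raise ValueError("leave-one-out standards need at least 3 experts")
    clip_ids = _check_coverage(expert_opinions)
    standards: dict[str, ReferenceStandard] = {}
    for excluded in sorted(expert_opinions):
        rng = np.random.default_rng(_expert_seed(rng_seed, excluded))
        others = [e for e in sorted(expert_opinions) if e != excluded]
        labels = {
            clip: majority_label((expert_opinions[e][clip] for e in others), rng)
            for clip in clip_ids
        }
        standards[excluded] = ReferenceStandard(
            labels=labels,
            source=StandardSource.LEAVE_ONE_OUT,
            excluded_expert=excluded,
            rng_seed=rng_seed,
        )
    return LeaveOneOutSet(standards=standards)


def write_reference_standard(
    standard: ReferenceStandard, path: Union[str, Path]
) -> None:
    rows = [
        {
            "clip_id": clip,
            "label": standard.labels[clip].name,
            "source": standard.source.value,
            "excluded_expert": standard.excluded_expert or "",
        }
        for clip in sorted(standard.labels)
    ]
    pd.DataFrame(rows, columns=["clip_id", "label", "source", "excluded_expert"]).to_csv(
        path, sep="\t", index=False
    )


def read_reference_standard(path: Union[str, Path]) -> ReferenceStandard:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("clip_id", "label", "source"):
        if col not in df.columns:
            raise FormatError(f"reference standard is missing column {col!r}")
    labels = {
        str(rec.clip_id): BLineClass.parse(str(rec.label))
        for rec in df.itertuples(index=False)
    }
    source = StandardSource(str(df["source"].iloc[0]))
    excluded = None
    if "excluded_expert" in df.columns:
        token = str(df["excluded_expert"].iloc[0])
        excluded = token or None
    return ReferenceStandard(
        labels=labels, source=source, excluded_expert=excluded, rng_seed=0
    )
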