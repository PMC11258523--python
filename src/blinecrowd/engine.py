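"""Event-ordered replay of a gamified labeling contest.

Each submitted opinion is processed in global event order:

1. the user's quality score (Qscore) — trailing mean correctness over their
   last 50 opinions on feedback clips, zero until they have 25 — is stamped on
   the opinion *before* any state update, and the opinion is eligible iff that
   stamped score meets the 80% threshold;
2. if the clip currently has a feedback label (a training clip, or an
   initially unlabeled clip already promoted to crowd consensus), a
   correctness entry is appended to the user's history;
3. if the clip is unlabeled and not yet decided, an eligible opinion
   overwrites that user's pending vote (most-recent-per-user deduplication)
   and the stopping rule is checked: consensus is reached on a 3-vote lead
   between the top two classes, or at 15 tallied opinions with the majority
   taken and ties broken randomly. A decided clip immediately becomes a
   feedback clip and its label is frozen.

Ineligible opinions are stamped and logged but never enter a tally, even if
the user's Qscore later rises.
"""

from __future__ import annotations

import copy
import enum
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .errors import OrderingError
from .labels import CLASSES, BLineClass, Clip, Opinion, Split, UserState


class EngineConfig(BaseModel):
    """Contest mechanics: quality scoring window and consensus stopping rule."""

    qscore_window: int = Field(default=50, gt=0)
    qscore_min_history: int = Field(default=25, gt=0)
    eligibility_threshold: float = Field(default=0.80, gt=0.0, le=1.0)
    consensus_lead: int = Field(default=3, gt=0)
    consensus_cap: int = Field(default=15, gt=0)
    rng_seed: int = 0

    @model_validator(mode="after")
    def _lead_le_cap(self) -> "EngineConfig":
        if self.consensus_lead > self.consensus_cap:
            raise ValueError("consensus_lead must not exceed consensus_cap")
        return self


class StopReason(enum.Enum):
    LEAD = "LEAD"
    CAP = "CAP"
    EXHAUSTED = "EXHAUSTED"


@dataclass(frozen=True)
class ConsensusResult:
    """Crowd consensus for one clip, with the tally that produced it."""

    clip_id: str
    label: BLineClass
    vote_counts: Mapping[BLineClass, int]
    n_opinions_used: int
    stop_reason: StopReason
    tie_broken: bool


@dataclass
class ContestState:
    """Mutable replay state; ``annotated_log`` echoes every opinion stamped."""

    users: dict[str, UserState] = field(default_factory=dict)
    clips: dict[str, Clip] = field(default_factory=dict)
    pending_votes: dict[str, dict[str, BLineClass]] = field(default_factory=dict)
    consensus: dict[str, ConsensusResult] = field(default_factory=dict)
    annotated_log: list[Opinion] = field(default_factory=list)
    last_event_index: int = -1


def current_qscore(state: UserState, config: EngineConfig) -> float:
    """The user's quality score under the configured window/minimum."""
    return state.qscore(
        window=config.qscore_window, min_history=config.qscore_min_history
    )


def check_consensus(
    votes: Mapping[str, BLineClass],
    config: EngineConfig,
    rng: np.random.Generator,
) -> Optional[ConsensusResult]:
    """Apply the stopping rule to a deduplicated tally; None if undecided.

    Clip id on the returned result is left empty for the caller to fill.
    """
    counts = {cls: 0 for cls in CLASSES}
    for label in votes.values():
        counts[label] += 1
    n = len(votes)
    ordered = sorted(counts.values(), reverse=True)
    lead = ordered[0] - ordered[1]
    if lead >= config.consensus_lead:
        leader = next(cls for cls in CLASSES if counts[cls] == ordered[0])
        return ConsensusResult(
            clip_id="",
            label=leader,
            vote_counts=dict(counts),
            n_opinions_used=n,
            stop_reason=StopReason.LEAD,
            tie_broken=False,
        )
    if n >= config.consensus_cap:
        leaders = [cls for cls in CLASSES if counts[cls] == ordered[0]]
        tie = len(leaders) > 1
        label = leaders[rng.integers(len(leaders))] if tie else leaders[0]
        return ConsensusResult(
            clip_id="",
            label=label,
            vote_counts=dict(counts),
            n_opinions_used=n,
            stop_reason=StopReason.CAP,
            tie_broken=tie,
        )
    return None


def process_opinion(
    state: ContestState,
    opinion: Opinion,
    config: EngineConfig,
    rng: np.random.Generator,
) -> ContestState:
    """Process one opinion in event order, mutating and returning ``state``."""
    if opinion.event_index <= state.last_event_index:
        raise OrderingError(
            f"event_index {opinion.event_index} not greater than "
            f"last processed {state.last_event_index}"
        )
    state.last_event_index = opinion.event_index
    clip = state.clips[opinion.clip_id]
    user = state.users.setdefault(opinion.user_id, UserState(opinion.user_id))

    # Stamp BEFORE updating history: an opinion never affects its own eligibility.
    qscore = current_qscore(user, config)
    eligible = qscore >= config.eligibility_threshold
    stamped = replace(opinion, qscore_at_submission=qscore, eligible=eligible)
    state.annotated_log.append(stamped)

    feedback_label = clip.current_feedback_label
    if feedback_label is not None:
        user.feedback_history.append(opinion.label == feedback_label)

    if (
        clip.split is Split.UNLABELED
        and clip.clip_id not in state.consensus
        and eligible
    ):
        tally = state.pending_votes.setdefault(clip.clip_id, {})
        tally[opinion.user_id] = opinion.label
        result = check_consensus(tally, config, rng)
        if result is not None:
            result = replace(result, clip_id=clip.clip_id)
            state.consensus[clip.clip_id] = result
            clip.feedback_label = result.label  # frozen: promotion is permanent
    return state


def replay_contest(
    opinions: Sequence[Opinion],
    clips: Mapping[str, Clip],
    config: EngineConfig,
) -> ContestState:
    """Replay a full opinion log against fresh copies of the clips."""
    state = ContestState(clips={cid: copy.deepcopy(c) for cid, c in clips.items()})
    rng = np.random.default_rng([config.rng_seed, 1])
    for opinion in opinions:
        process_opinion(state, opinion, config, rng)
    return state


def finalize_exhausted(
    state: ContestState, rng: np.random.Generator
) -> ContestState:
    """Assign majority labels to clips whose tallies never hit a stopping rule."""
    for clip_id in sorted(state.pending_votes):
        if clip_id in state.consensus:
            continue
        tally = state.pending_votes[clip_id]
        if not tally:
            continue
        counts = {cls: 0 for cls in CLASSES}
        for label in tally.values():
            counts[label] += 1
        best = max(counts.values())
        leaders = [cls for cls in CLASSES if counts[cls] == best]
        tie = len(leaders) > 1
        label = leaders[rng.integers(len(leaders))] if tie else leaders[0]
        result = ConsensusResult(
            clip_id=clip_id,
            label=label,
            vote_counts=counts,
            n_opinions_used=len(tally),
            stop_reason=StopReason.EXHAUSTED,
            tie_broken=tie,
        )
        state.consensus[clip_id] = result
        state.clips[clip_id].feedback_label = label
    return state


def eligible_vote_pools(
    annotated_log: Sequence[Opinion], clip_set: set[str]
) -> dict[str, list[tuple[str, BLineClass]]]:
    """Per-clip pools of eligible opinions, deduplicated to most recent per user.

    This is the vote pool the crowd label of a test clip is computed from (test
    clips never pass through the stopping rule), and the pool the opinion
    subsampling analysis draws from. Pool order follows event order of each
    user's latest eligible opinion.
    """
    latest: dict[str, dict[str, tuple[int, BLineClass]]] = {c: {} for c in clip_set}
    for op in annotated_log:
        if not op.eligible or op.clip_id not in latest:
            continue
        latest[op.clip_id][op.user_id] = (op.event_index, op.label)
    pools: dict[str, list[tuple[str, BLineClass]]] = {}
    for clip_id, by_user in latest.items():
        ordered = sorted(by_user.items(), key=lambda kv: kv[1][0])
        pools[clip_id] = [(user, label) for user, (_, label) in ordered]
    return pools
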