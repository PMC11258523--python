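"""Domain types for crowd-labeled lung-ultrasound B-line classification.

The label space is a three-way ordinal classification of a lung POCUS clip:
no B-lines, one or more discrete B-lines, or confluent B-lines, ordered by
severity. Every record the pipeline touches — an opinion submitted by a
labeler, a clip with its split assignment, a labeler's rolling quality
state — is defined here.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional


class BLineClass(enum.Enum):
    """The three B-line severity classes, ordered NO_BLINES < DISCRETE < CONFLUENT."""

    NO_BLINES = 0
    DISCRETE = 1
    CONFLUENT = 2

    @property
    def severity_rank(self) -> int:
        return self.value

    @classmethod
    def parse(cls, token: str) -> "BLineClass":
        """Parse a canonical uppercase token; synonyms are rejected, not coerced."""
        try:
            return cls[token]
        except KeyError:
            raise ValueError(f"unknown B-line class token: {token!r}") from None


#: Canonical class order used for stable file columns and tie-break draws.
CLASSES: tuple[BLineClass, BLineClass, BLineClass] = (
    BLineClass.NO_BLINES,
    BLineClass.DISCRETE,
    BLineClass.CONFLUENT,
)


class Split(enum.Enum):
    TRAINING = "TRAINING"
    TEST = "TEST"
    UNLABELED = "UNLABELED"


@dataclass
class Clip:
    """One ultrasound clip in the contest.

    ``reference_label`` is the expert-consensus label (TRAINING/TEST clips only);
    ``feedback_label`` is the label revealed to users after they submit an
    opinion — the reference label for TRAINING clips, or the promoted crowd
    consensus label for an initially UNLABELED clip. Extra manifest columns are
    preserved in ``extra`` but ignored by computation.
    """

    clip_id: str
    patient_id: str
    split: Split
    reference_label: Optional[BLineClass] = None
    feedback_label: Optional[BLineClass] = None
    extra: dict = field(default_factory=dict)

    @property
    def is_feedback(self) -> bool:
        """True when an opinion on this clip is graded and revealed to the user."""
        return self.split is Split.TRAINING or (
            self.split is Split.UNLABELED and self.feedback_label is not None
        )

    @property
    def current_feedback_label(self) -> Optional[BLineClass]:
        """The label used to grade opinions right now, or None for nonfeedback clips."""
        if self.split is Split.TRAINING:
            return self.reference_label
        if self.split is Split.UNLABELED:
            return self.feedback_label
        return None


@dataclass(frozen=True)
class Opinion:
    """One labeling event: a user's submitted class for a clip.

    ``event_index`` is the authoritative global submission order (the
    interchange format carries no timestamps). ``qscore_at_submission`` is the
    user's quality score stamped at the moment of submission, or ``None`` when
    the log has not been annotated by a contest replay; ``eligible`` records
    whether the opinion passed the quality filter at that moment.
    """

    user_id: str
    clip_id: str
    label: BLineClass
    event_index: int
    qscore_at_submission: Optional[float] = None
    eligible: bool = False


@dataclass
class UserState:
    """A labeler's rolling feedback-correctness history.

    ``feedback_history`` holds one boolean per opinion the user gave on a clip
    that had a feedback label at submission time (True = matched it). The
    quality score derived from it is computed by the contest engine.
    """

    user_id: str
    is_expert: bool = False
    medical_experience: Optional[bool] = None
    feedback_history: list[bool] = field(default_factory=list)

    def qscore(self, window: int = 50, min_history: int = 25) -> float:
        """Trailing mean correctness over the last ``window`` feedback opinions.

        Zero until the user has at least ``min_history`` feedback opinions.
        """
        n = len(self.feedback_history)
        if n < min_history:
            return 0.0
        tail = self.feedback_history[-window:]
        return sum(tail) / len(tail)
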