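"""Synthetic crowd generator for end-to-end pipeline testing.

No public opinion log or ultrasound clips exist for this task, so the
simulator produces the three interchange artifacts — clip manifest, expert
label table, opinion log — with the statistical structure the analysis
assumes:

* clip true classes drawn from the test-set prevalence (default 70/18/12),
  with an "ambiguous" subset on which every rater's accuracy drops by a
  shared multiplicative factor (this induces correlated crowd/expert
  disagreement on the same clips);
* six static experts with heterogeneous accuracies (default spread 0.77-0.91);
* crowd labelers whose accuracy rises from a starting level toward a
  personal asymptote (mean 0.80) along an exponential-approach curve
  a(t) = a_inf - (a_inf - a0) * exp(-lambda * t), where t counts feedback
  clips seen;
* labeling errors biased toward the severity-adjacent class (discrete
  B-lines sit between the other two classes, so most confusions involve it);
* a contest event stream in which each user alternates feedback clips
  (sampled stratified-equally over the three currently available feedback
  classes) and nonfeedback clips, processed live through the contest engine
  so that promoted clips join the feedback pool exactly as in a real contest.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .engine import ContestState, EngineConfig, process_opinion
from .labels import CLASSES, BLineClass, Clip, Opinion, Split
from .reference import ReferenceStandard, build_full_consensus

__all__ = [
    "SimulationConfig",
    "LabelerProfile",
    "SimulatedDataset",
    "generate_clips",
    "generate_profiles",
    "sample_opinion",
    "simulate_experts",
    "simulate_contest",
    "simulate_dataset",
    "latent_pool_accuracy",
]


class SimulationConfig(BaseModel):
    """Study-scale knobs for the synthetic crowd (desk-sized defaults)."""

    n_clips_training: int = Field(default=200, gt=0)
    n_clips_test: int = Field(default=200, gt=0)
    n_clips_unlabeled: int = Field(default=200, ge=0)
    class_priors: tuple[float, float, float] = (0.70, 0.18, 0.12)
    ambiguity_fraction: float = Field(default=0.15, ge=0.0, le=1.0)
    hard_clip_confusability: float = Field(default=0.40, ge=0.0, lt=1.0)
    n_experts: int = Field(default=6, ge=1)
    expert_accuracies: tuple[float, ...] = (0.77, 0.81, 0.85, 0.87, 0.88, 0.91)
    n_users: int = Field(default=100, ge=0)
    user_initial_accuracy_mean: float = Field(default=0.55, gt=1 / 3, le=1.0)
    user_initial_accuracy_sd: float = Field(default=0.08, ge=0.0)
    user_asymptote_mean: float = Field(default=0.80, gt=1 / 3, le=1.0)
    user_asymptote_sd: float = Field(default=0.10, ge=0.0)
    learning_rate: float = Field(default=0.03, ge=0.0)
    opinions_per_user_mean: float = Field(default=200.0, gt=0.0)
    opinions_per_user_dispersion: float = Field(default=0.5, ge=0.0)
    #: Rank correlation between a user's opinion volume and their skill
    #: asymptote: performance-based prizes keep skilled users playing, so the
    #: heaviest contributors are the strongest labelers.
    engagement_skill_correlation: float = Field(default=0.6, ge=-1.0, le=1.0)
    adjacent_confusion_bias: float = Field(default=0.8, ge=0.0, le=1.0)
    clips_per_patient: int = Field(default=12, gt=0)
    rng_seed: int = 0

    @model_validator(mode="after")
    def _validate(self) -> "SimulationConfig":
        if abs(sum(self.class_priors) - 1.0) > 1e-9:
            raise ValueError("class_priors must sum to 1")
        if any(p < 0 for p in self.class_priors):
            raise ValueError("class_priors must be nonnegative")
        if any(not (1 / 3 < a <= 1.0) for a in self.expert_accuracies):
            raise ValueError("expert accuracies must lie in (1/3, 1]")
        return self


@dataclass(frozen=True)
class LabelerProfile:
    """A rater's accuracy trajectory over feedback clips seen."""

    user_id: str
    initial_accuracy: float
    asymptote_accuracy: float
    learning_rate: float

    def accuracy_at(self, t: int) -> float:
        a0, ainf = self.initial_accuracy, self.asymptote_accuracy
        return ainf - (ainf - a0) * math.exp(-self.learning_rate * t)

    def confusion_row(
        self, true_class: BLineClass, t: int, adjacent_bias: float
    ) -> dict[BLineClass, float]:
        """Probability of each reported class given the true class."""
        a = self.accuracy_at(t)
        row = {cls: 0.0 for cls in CLASSES}
        row[true_class] = a
        others = [c for c in CLASSES if c is not true_class]
        adjacent = [
            c for c in others if abs(c.severity_rank - true_class.severity_rank) == 1
        ]
        err = 1.0 - a
        for c in others:
            row[c] += err * (1 - adjacent_bias) / len(others)
        for c in adjacent:
            row[c] += err * adjacent_bias / len(adjacent)
        return row


@dataclass
class SimulatedDataset:
    """All artifacts of one simulated contest, plus the latent ground truth."""

    config: SimulationConfig
    clips: dict[str, Clip]
    true_labels: dict[str, BLineClass]
    hard_clips: set[str]
    expert_table: dict[str, dict[str, BLineClass]]
    reference: ReferenceStandard
    profiles: list[LabelerProfile]
    opinions: list[Opinion]  # raw (unannotated) event-ordered log
    state: ContestState = field(repr=False, default=None)  # live-replay state


def generate_clips(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[dict[str, Clip], dict[str, BLineClass], set[str]]:
    """Draw clips with latent classes and difficulty; splits never share patients."""
    clips: dict[str, Clip] = {}
    true_labels: dict[str, BLineClass] = {}
    hard: set[str] = set()
    counts = {
        Split.TRAINING: config.n_clips_training,
        Split.TEST: config.n_clips_test,
        Split.UNLABELED: config.n_clips_unlabeled,
    }
    for split, n in counts.items():
        tag = split.value[:2].lower()
        for i in range(n):
            clip_id = f"{tag}{i:05d}"
            patient_id = f"pt_{tag}_{i // config.clips_per_patient:04d}"
            cls = CLASSES[rng.choice(3, p=config.class_priors)]
            clips[clip_id] = Clip(clip_id=clip_id, patient_id=patient_id, split=split)
            true_labels[clip_id] = cls
            if rng.random() < config.ambiguity_fraction:
                hard.add(clip_id)
    return clips, true_labels, hard


def generate_profiles(
    config: SimulationConfig, rng: np.random.Generator
) -> list[LabelerProfile]:
    """Draw per-user initial and asymptote accuracies (clipped to (1/3, 1])."""
    profiles = []
    for i in range(config.n_users):
        a0 = float(
            np.clip(
                rng.normal(
                    config.user_initial_accuracy_mean, config.user_initial_accuracy_sd
                ),
                0.34,
                1.0,
            )
        )
        ainf = float(
            np.clip(
                rng.normal(config.user_asymptote_mean, config.user_asymptote_sd),
                a0,
                1.0,
            )
        )
        profiles.append(
            LabelerProfile(
                user_id=f"user_{i:04d}",
                initial_accuracy=a0,
                asymptote_accuracy=ainf,
                learning_rate=config.learning_rate,
            )
        )
    return profiles


def sample_opinion(
    profile: LabelerProfile,
    true_class: BLineClass,
    t: int,
    rng: np.random.Generator,
    *,
    hard: bool = False,
    hard_clip_confusability: float = 0.40,
    adjacent_confusion_bias: float = 0.8,
) -> BLineClass:
    """Draw one noisy opinion from the rater's confusion model at time t."""
    a = profile.accuracy_at(t)
    if hard:
        a *= 1.0 - hard_clip_confusability
    if rng.random() < a:
        return true_class
    others = [c for c in CLASSES if c is not true_class]
    adjacent = [
        c for c in others if abs(c.severity_rank - true_class.severity_rank) == 1
    ]
    if rng.random() < adjacent_confusion_bias:
        pool = adjacent
    else:
        pool = others
    return pool[rng.integers(len(pool))]


def simulate_experts(
    config: SimulationConfig,
    clips: dict[str, Clip],
    true_labels: dict[str, BLineClass],
    hard_clips: set[str],
    rng: np.random.Generator,
) -> dict[str, dict[str, BLineClass]]:
    """One static opinion per expert per training/test clip."""
    table: dict[str, dict[str, BLineClass]] = {}
    for i in range(config.n_experts):
        acc = config.expert_accuracies[i % len(config.expert_accuracies)]
        profile = LabelerProfile(
            user_id=f"expert_{i + 1}",
            initial_accuracy=acc,
            asymptote_accuracy=acc,
            learning_rate=0.0,
        )
        opinions: dict[str, BLineClass] = {}
        for clip_id in sorted(clips):
            clip = clips[clip_id]
            if clip.split is Split.UNLABELED:
                continue
            opinions[clip_id] = sample_opinion(
                profile,
                true_labels[clip_id],
                0,
                rng,
                hard=clip_id in hard_clips,
                hard_clip_confusability=config.hard_clip_confusability,
                adjacent_confusion_bias=config.adjacent_confusion_bias,
            )
        table[profile.user_id] = opinions
    return table


def simulate_contest(
    config: SimulationConfig,
    clips: dict[str, Clip],
    true_labels: dict[str, BLineClass],
    hard_clips: set[str],
    profiles: Sequence[LabelerProfile],
    rng: np.random.Generator,
    engine_config: Optional[EngineConfig] = None,
) -> tuple[list[Opinion], ContestState]:
    """Generate an event-ordered opinion stream, replayed live through the engine.

    Each user alternates feedback and nonfeedback clips. Feedback clips are
    stratified equally over the three classes of currently available feedback
    labels (uniform fallback when a class pool is empty); nonfeedback clips
    are uniform over test clips and still-undecided unlabeled clips. A user's
    learning clock advances by one per feedback clip seen.
    """
    if engine_config is None:
        engine_config = EngineConfig(rng_seed=config.rng_seed)
    state = ContestState(clips={cid: Clip(**_clip_kwargs(c)) for cid, c in clips.items()})
    engine_rng = np.random.default_rng([engine_config.rng_seed, 1])

    feedback_pool: dict[BLineClass, list[str]] = {cls: [] for cls in CLASSES}
    for clip_id, clip in state.clips.items():
        if clip.split is Split.TRAINING:
            feedback_pool[clip.reference_label].append(clip_id)
    for pool in feedback_pool.values():
        pool.sort()
    nonfeedback: list[str] = sorted(
        cid
        for cid, c in state.clips.items()
        if c.split in (Split.TEST, Split.UNLABELED)
    )
    promoted: set[str] = set()

    quotas = _draw_quotas(config, rng, profiles)
    active = [i for i, q in enumerate(quotas) if q > 0]
    wants_feedback = [True] * len(profiles)
    clock = [0] * len(profiles)
    raw_log: list[Opinion] = []
    event_index = 0

    while active:
        pos = int(rng.integers(len(active)))
        ui = active[pos]
        profile = profiles[ui]

        clip_id = None
        if wants_feedback[ui]:
            classes = [cls for cls in CLASSES if feedback_pool[cls]]
            if classes:
                cls = classes[int(rng.integers(len(classes)))]
                pool = feedback_pool[cls]
                clip_id = pool[int(rng.integers(len(pool)))]
        if clip_id is None:
            # nonfeedback turn (or empty feedback pool): lazy-drop promoted clips
            while nonfeedback:
                j = int(rng.integers(len(nonfeedback)))
                cand = nonfeedback[j]
                if cand in promoted:
                    nonfeedback[j] = nonfeedback[-1]
                    nonfeedback.pop()
                    continue
                clip_id = cand
                break
            if clip_id is None:  # everything promoted: fall back to test clips
                test_ids = [
                    cid for cid, c in state.clips.items() if c.split is Split.TEST
                ]
                clip_id = test_ids[int(rng.integers(len(test_ids)))]
        wants_feedback[ui] = not wants_feedback[ui]

        clip = state.clips[clip_id]
        is_feedback_now = clip.is_feedback
        label = sample_opinion(
            profile,
            true_labels[clip_id],
            clock[ui],
            rng,
            hard=clip_id in hard_clips,
            hard_clip_confusability=config.hard_clip_confusability,
            adjacent_confusion_bias=config.adjacent_confusion_bias,
        )
        opinion = Opinion(
            user_id=profile.user_id,
            clip_id=clip_id,
            label=label,
            event_index=event_index,
        )
        event_index += 1
        raw_log.append(opinion)
        process_opinion(state, opinion, engine_config, engine_rng)
        if is_feedback_now:
            clock[ui] += 1
        if clip_id in state.consensus and clip_id not in promoted:
            promoted.add(clip_id)
            feedback_pool[state.consensus[clip_id].label].append(clip_id)

        quotas[ui] -= 1
        if quotas[ui] == 0:
            active[pos] = active[-1]
            active.pop()
    return raw_log, state


def _clip_kwargs(c: Clip) -> dict:
    return dict(
        clip_id=c.clip_id,
        patient_id=c.patient_id,
        split=c.split,
        reference_label=c.reference_label,
        feedback_label=c.feedback_label,
        extra=dict(c.extra),
    )


def _draw_quotas(
    config: SimulationConfig,
    rng: np.random.Generator,
    profiles: Sequence[LabelerProfile],
) -> list[int]:
    """Per-user opinion counts: lognormal, rank-coupled to skill.

    A Gaussian copula links each user's volume to their asymptote accuracy
    with the configured engagement-skill correlation.
    """
    n = config.n_users
    if n == 0:
        return []
    sigma = config.opinions_per_user_dispersion
    mu = math.log(config.opinions_per_user_mean) - sigma**2 / 2
    asymptotes = np.array([p.asymptote_accuracy for p in profiles])
    ranks = asymptotes.argsort().argsort()
    from scipy.stats import norm

    z_skill = norm.ppf((ranks + 0.5) / n)
    rho = config.engagement_skill_correlation
    z = rho * z_skill + math.sqrt(1 - rho**2) * rng.standard_normal(n)
    draws = np.exp(mu + sigma * z)
    return [max(1, int(round(d))) for d in draws]


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Full generation: clips, experts, reference labels, contest stream.

    Reference labels on training/test clips are the simulated experts'
    majority-rule consensus (ties broken randomly), exactly as the evaluation
    pipeline would construct them from the emitted expert table.
    """
    rng_clips = np.random.default_rng([config.rng_seed, 11])
    rng_experts = np.random.default_rng([config.rng_seed, 12])
    rng_users = np.random.default_rng([config.rng_seed, 13])
    rng_contest = np.random.default_rng([config.rng_seed, 14])

    clips, true_labels, hard = generate_clips(config, rng_clips)
    expert_table = simulate_experts(config, clips, true_labels, hard, rng_experts)
    reference = build_full_consensus(expert_table, rng_seed=config.rng_seed)
    for clip_id, label in reference.labels.items():
        clips[clip_id].reference_label = label
    profiles = generate_profiles(config, rng_users)
    opinions, state = simulate_contest(
        config, clips, true_labels, hard, profiles, rng_contest
    )
    return SimulatedDataset(
        config=config,
        clips=clips,
        true_labels=true_labels,
        hard_clips=hard,
        expert_table=expert_table,
        reference=reference,
        profiles=profiles,
        opinions=opinions,
        state=state,
    )


def latent_pool_accuracy(
    annotated_log: Sequence[Opinion],
    true_labels: dict[str, BLineClass],
    only_eligible: bool,
) -> float:
    """Fraction of (optionally quality-filtered) opinions matching latent truth."""
    hits = total = 0
    for op in annotated_log:
        if only_eligible and not op.eligible:
            continue
        total += 1
        hits += op.label == true_labels[op.clip_id]
    if total == 0:
        raise ValueError("no opinions in the requested pool")
    return hits / total
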