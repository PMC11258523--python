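"""Concordance and agreement statistics for crowd and expert labels.

Concordance is the percentage of labels matching a reference standard over a
clip set; it is reported overall, per reference class, and balanced (the
unweighted mean of the per-class values, which removes class-prevalence
effects). Leave-one-out variants score the crowd against all six 5-expert
standards and each expert against the standard that excludes them. Vote-split
ROC curves treat the crowd's per-class vote fraction as a score for
predicting the expert-consensus class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .errors import (
    CoverageError,
    DegenerateInputError,
    NormalizationError,
    PairingError,
)
from .labels import CLASSES, BLineClass
from .reference import LeaveOneOutSet, ReferenceStandard


@dataclass(frozen=True)
class ConcordanceReport:
    overall: float  # percentage
    per_class: Mapping[BLineClass, float]  # percentage, keyed by reference class
    balanced: float  # percentage: unweighted mean of per_class
    n_clips: int
    per_clip: Mapping[str, float]  # match fraction in [0, 1]


@dataclass(frozen=True)
class ExpertSummary:
    per_expert: Mapping[str, float]  # percentage
    mean: float
    sd: float  # sample SD (n-1)
    se: float  # sample SD / sqrt(n)


@dataclass(frozen=True)
class ROCResult:
    target_class: BLineClass
    points: tuple[tuple[float, float], ...]  # (FPR, TPR), sorted, incl. (0,0),(1,1)
    auc: float


def _summarize(per_clip: Mapping[str, float], classes_of: Mapping[str, BLineClass]):
    values = np.array([per_clip[c] for c in per_clip], dtype=float)
    overall = 100.0 * values.mean()
    per_class: dict[BLineClass, float] = {}
    for cls in CLASSES:
        members = [c for c in per_clip if classes_of[c] is cls]
        if members:
            per_class[cls] = 100.0 * float(np.mean([per_clip[c] for c in members]))
    balanced = float(np.mean(list(per_class.values())))
    return overall, per_class, balanced


def concordance(
    labels: Mapping[str, BLineClass],
    reference: ReferenceStandard,
    clip_set: set[str],
) -> ConcordanceReport:
    """Percent of labels matching the reference, overall / per class / balanced."""
    if not clip_set:
        raise ValueError("concordance over an empty clip set is undefined")
    missing = clip_set - set(labels)
    if missing:
        raise CoverageError(f"no label for clip {sorted(missing)[0]!r}")
    missing_ref = clip_set - set(reference.labels)
    if missing_ref:
        raise CoverageError(f"reference has no label for {sorted(missing_ref)[0]!r}")
    per_clip = {
        c: 1.0 if labels[c] == reference.labels[c] else 0.0 for c in sorted(clip_set)
    }
    classes_of = {c: reference.labels[c] for c in clip_set}
    overall, per_class, balanced = _summarize(per_clip, classes_of)
    return ConcordanceReport(
        overall=overall,
        per_class=per_class,
        balanced=balanced,
        n_clips=len(clip_set),
        per_clip=per_clip,
    )


def summarize_expert_concordances(
    values: Sequence[float], expert_ids: Optional[Sequence[str]] = None
) -> ExpertSummary:
    """Mean, sample SD and SE of a set of per-expert concordance percentages."""
    if len(values) < 2:
        raise ValueError("need at least 2 expert concordances to summarize")
    arr = np.asarray(values, dtype=float)
    sd = float(arr.std(ddof=1))
    ids = list(expert_ids) if expert_ids is not None else [
        f"expert_{i + 1}" for i in range(len(values))
    ]
    return ExpertSummary(
        per_expert=dict(zip(ids, map(float, arr))),
        mean=float(arr.mean()),
        sd=sd,
        se=sd / math.sqrt(len(arr)),
    )


def loo_crowd_concordance(
    crowd_labels: Mapping[str, BLineClass],
    loo: LeaveOneOutSet,
    clip_set: set[str],
) -> ConcordanceReport:
    """Crowd concordance against the leave-one-out standards.

    Per clip: the fraction of the six 5-expert standards the crowd label
    matches; overall is the mean of those fractions. Per-class values average,
    over the standards, the per-class concordance under that standard's own
    labels.
    """
    missing = clip_set - set(crowd_labels)
    if missing:
        raise CoverageError(f"no crowd label for clip {sorted(missing)[0]!r}")
    standards = list(loo.standards.values())
    per_clip: dict[str, float] = {}
    for clip in sorted(clip_set):
        matches = sum(1 for std in standards if crowd_labels[clip] == std.labels[clip])
        per_clip[clip] = matches / len(standards)
    overall = 100.0 * float(np.mean(list(per_clip.values())))
    per_class: dict[BLineClass, float] = {}
    for cls in CLASSES:
        vals = []
        for std in standards:
            members = [c for c in clip_set if std.labels[c] is cls]
            if members:
                vals.append(
                    np.mean([crowd_labels[c] == std.labels[c] for c in members])
                )
        if vals:
            per_class[cls] = 100.0 * float(np.mean(vals))
    balanced = float(np.mean(list(per_class.values())))
    return ConcordanceReport(
        overall=overall,
        per_class=per_class,
        balanced=balanced,
        n_clips=len(clip_set),
        per_clip=per_clip,
    )


def loo_expert_concordance(
    expert_opinions: Mapping[str, Mapping[str, BLineClass]],
    loo: LeaveOneOutSet,
    clip_set: set[str],
) -> ExpertSummary:
    """Each expert scored against the standard that excludes their own opinion."""
    per_expert: dict[str, float] = {}
    for expert in sorted(expert_opinions):
        if expert not in loo.standards:
            raise PairingError(f"no leave-one-out standard excludes {expert!r}")
        std = loo.standards[expert]
        matches = sum(
            1 for c in clip_set if expert_opinions[expert][c] == std.labels[c]
        )
        per_expert[expert] = 100.0 * matches / len(clip_set)
    values = list(per_expert.values())
    summary = summarize_expert_concordances(values, expert_ids=list(per_expert))
    return summary


def vote_proportion_roc(
    vote_fractions: Mapping[str, Mapping[BLineClass, float]],
    reference: ReferenceStandard,
    target: BLineClass,
    tolerance: float = 1e-6,
) -> ROCResult:
    """One-vs-rest ROC of the target class's vote fraction vs the reference."""
    clip_ids = sorted(vote_fractions)
    for clip in clip_ids:
        total = sum(vote_fractions[clip].values())
        if abs(total - 1.0) > tolerance:
            raise NormalizationError(
                f"vote fractions for clip {clip!r} sum to {total}, not 1"
            )
    y_true = np.array([reference.labels[c] is target for c in clip_ids], dtype=int)
    scores = np.array(
        [vote_fractions[c].get(target, 0.0) for c in clip_ids], dtype=float
    )
    fpr, tpr, _ = _sk_roc_curve(y_true, scores, drop_intermediate=False)
    points = tuple(zip(map(float, fpr), map(float, tpr)))
    return ROCResult(target_class=target, points=points, auc=float(_sk_auc(fpr, tpr)))


def paired_concordance_test(
    per_case_crowd: Sequence[float], per_case_expert_mean: Sequence[float]
) -> tuple[float, float]:
    """Paired t test on per-case crowd-vs-expert concordance differences."""
    a = np.asarray(per_case_crowd, dtype=float)
    b = np.asarray(per_case_expert_mean, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("inputs must be equal-length sequences of length >= 2")
    diffs = a - b
    if np.all(np.abs(diffs) < 1e-12):
        return 0.0, 1.0
    if np.ptp(diffs) < 1e-9:  # constant nonzero difference
        raise DegenerateInputError(
            "zero-variance nonzero differences: paired t is undefined"
        )
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


def agreement_correlation(
    crowd_agreement: Mapping[str, float], expert_agreement: Mapping[str, float]
) -> tuple[float, float]:
    """Pearson correlation of per-clip internal crowd vs expert agreement."""
    if set(crowd_agreement) != set(expert_agreement):
        raise CoverageError("crowd and expert agreement maps cover different clips")
    clips = sorted(crowd_agreement)
    a = np.array([crowd_agreement[c] for c in clips])
    b = np.array([expert_agreement[c] for c in clips])
    if a.std() == 0 or b.std() == 0:
        raise DegenerateInputError("constant agreement values: r is undefined")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)


def agreement_rank_test(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U with tie-corrected normal approximation."""
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be nonempty")
    res = stats.mannwhitneyu(
        group_a, group_b, alternative="two-sided", method="asymptotic"
    )
    return float(res.statistic), float(res.pvalue)


def internal_agreement(labels: Sequence[BLineClass]) -> float:
    """Fraction of a group's opinions on one clip that chose the modal class."""
    if not labels:
        raise ValueError("internal agreement of an empty opinion set is undefined")
    counts = {cls: 0 for cls in CLASSES}
    for lab in labels:
        counts[lab] += 1
    return max(counts.values()) / len(labels)
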