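"""End-to-end evaluation: references, replay, metrics, secondary analyses.

``evaluate_contest`` mirrors the full analysis of a finished contest: build
the full and leave-one-out expert reference standards, replay the opinion
log through the contest engine to stamp quality scores and eligibility,
derive crowd test-set labels from the eligible vote pools, and compute the
concordance, paired-test, ROC, agreement, subsampling and learning-curve
results as one JSON-ready report.
"""

from __future__ import annotations

import logging
from typing import Mapping, Optional, Sequence

import numpy as np

from .engine import EngineConfig, eligible_vote_pools, replay_contest
from .errors import DegenerateInputError
from .labels import CLASSES, BLineClass, Clip, Opinion, Split
from .metrics import (
    ConcordanceReport,
    agreement_correlation,
    agreement_rank_test,
    concordance,
    internal_agreement,
    loo_crowd_concordance,
    loo_expert_concordance,
    paired_concordance_test,
    summarize_expert_concordances,
    vote_proportion_roc,
)
from .reference import build_full_consensus, build_leave_one_out, majority_label
from .secondary import build_subsample_curve, identify_skilled_users, learning_curve

logger = logging.getLogger(__name__)


def _report_block(report: ConcordanceReport) -> dict:
    return {
        "overall_pct": report.overall,
        "per_class_pct": {cls.name: report.per_class.get(cls) for cls in CLASSES},
        "balanced_pct": report.balanced,
        "n_clips": report.n_clips,
    }


def crowd_test_labels(
    pools: Mapping[str, Sequence[tuple[str, BLineClass]]],
    rng: np.random.Generator,
) -> dict[str, BLineClass]:
    """Majority of each clip's eligible deduplicated votes, ties broken randomly."""
    labels: dict[str, BLineClass] = {}
    for clip_id in sorted(pools):
        votes = [label for _, label in pools[clip_id]]
        if votes:
            labels[clip_id] = majority_label(votes, rng)
    return labels


def vote_fractions(
    pools: Mapping[str, Sequence[tuple[str, BLineClass]]],
) -> dict[str, dict[BLineClass, float]]:
    fractions: dict[str, dict[BLineClass, float]] = {}
    for clip_id, pool in pools.items():
        if not pool:
            continue
        counts = {cls: 0 for cls in CLASSES}
        for _, label in pool:
            counts[label] += 1
        n = len(pool)
        fractions[clip_id] = {cls: counts[cls] / n for cls in CLASSES}
    return fractions


def evaluate_contest(
    opinions: Sequence[Opinion],
    clips: Mapping[str, Clip],
    expert_table: Mapping[str, Mapping[str, BLineClass]],
    engine_config: Optional[EngineConfig] = None,
    seed: int = 0,
    k_values: Sequence[int] = tuple(range(1, 16)),
    n_mc: int = 1000,
    skilled_threshold: float = 0.80,
    learning_window: int = 25,
) -> dict:
    """Run the complete evaluation and return a nested, JSON-ready report."""
    if engine_config is None:
        engine_config = EngineConfig(rng_seed=seed)
    test_set = {cid for cid, c in clips.items() if c.split is Split.TEST}

    full = build_full_consensus(expert_table, rng_seed=seed)
    loo = build_leave_one_out(expert_table, rng_seed=seed)

    state = replay_contest(opinions, clips, engine_config)
    pools = eligible_vote_pools(state.annotated_log, test_set)
    covered = {c for c in test_set if pools[c]}
    if not covered:
        raise ValueError(
            "no test clip has any eligible opinions; the contest is too small "
            "or the quality threshold admits no users"
        )
    if covered != test_set:
        logger.warning(
            "%d test clips have no eligible opinions and are excluded",
            len(test_set) - len(covered),
        )

    rng = np.random.default_rng([seed, 21])
    crowd_labels = crowd_test_labels(pools, rng)
    crowd = concordance(crowd_labels, full, covered)

    per_expert = {
        e: concordance(expert_table[e], full, covered) for e in sorted(expert_table)
    }
    expert_summary = summarize_expert_concordances(
        [per_expert[e].overall for e in sorted(per_expert)],
        expert_ids=sorted(per_expert),
    )
    expert_per_class = {
        cls.name: float(
            np.mean(
                [
                    per_expert[e].per_class[cls]
                    for e in per_expert
                    if cls in per_expert[e].per_class
                ]
            )
        )
        for cls in CLASSES
        if any(cls in per_expert[e].per_class for e in per_expert)
    }

    crowd_loo = loo_crowd_concordance(crowd_labels, loo, covered)
    expert_loo = loo_expert_concordance(expert_table, loo, covered)

    # Paired tests: per-case crowd indicator vs fraction of experts correct.
    case_ids = sorted(covered)
    crowd_cases = [crowd.per_clip[c] for c in case_ids]
    expert_cases = [
        float(np.mean([expert_table[e][c] == full.labels[c] for e in expert_table]))
        for c in case_ids
    ]
    loo_crowd_cases = [crowd_loo.per_clip[c] for c in case_ids]
    loo_expert_cases = [
        float(
            np.mean(
                [
                    expert_table[e][c] == loo.standards[e].labels[c]
                    for e in expert_table
                ]
            )
        )
        for c in case_ids
    ]

    def _paired(a, b):
        try:
            t, p = paired_concordance_test(a, b)
            return {"t": t, "p": p}
        except DegenerateInputError:
            return {"t": None, "p": None}

    fractions = vote_fractions(pools)
    roc = {
        cls.name: vote_proportion_roc(fractions, full, cls) for cls in CLASSES
    }

    # Internal agreement: ALL crowd opinions on a clip vs the 6 expert opinions.
    all_by_clip: dict[str, list[BLineClass]] = {c: [] for c in covered}
    for op in state.annotated_log:
        if op.clip_id in all_by_clip:
            all_by_clip[op.clip_id].append(op.label)
    crowd_agree = {
        c: internal_agreement(v) for c, v in all_by_clip.items() if v
    }
    expert_agree = {
        c: internal_agreement([expert_table[e][c] for e in expert_table])
        for c in crowd_agree
    }
    try:
        r, r_p = agreement_correlation(crowd_agree, expert_agree)
    except DegenerateInputError:
        r, r_p = None, None
    matched = [c for c in crowd_agree if crowd.per_clip[c] == 1.0]
    unmatched = [c for c in crowd_agree if crowd.per_clip[c] == 0.0]
    if matched and unmatched:
        u_stat, u_p = agreement_rank_test(
            [expert_agree[c] for c in matched], [expert_agree[c] for c in unmatched]
        )
        expert_agree_matched = 100.0 * float(np.mean([expert_agree[c] for c in matched]))
        expert_agree_unmatched = 100.0 * float(
            np.mean([expert_agree[c] for c in unmatched])
        )
    else:
        u_stat = u_p = expert_agree_matched = expert_agree_unmatched = None
    high_agree = [c for c in crowd_agree if crowd_agree[c] >= 0.80]
    high_agree_concordance = (
        100.0 * float(np.mean([crowd.per_clip[c] for c in high_agree]))
        if high_agree
        else None
    )

    curve = build_subsample_curve(
        {c: pools[c] for c in covered}, full, k_values, n_mc=n_mc, rng_seed=seed
    )

    skilled = identify_skilled_users(
        state.annotated_log, test_set, threshold=skilled_threshold
    )
    curves = {}
    try:
        curves["all_crowd"] = learning_curve(
            state.annotated_log, full, covered, window=learning_window
        )
    except ValueError:
        pass
    if skilled:
        try:
            curves["skilled_crowd"] = learning_curve(
                state.annotated_log, full, covered, users=skilled, window=learning_window
            )
        except ValueError:
            pass

    promoted = list(state.consensus.values())
    n_eligible = sum(1 for op in state.annotated_log if op.eligible)

    return {
        "n_opinions": len(state.annotated_log),
        "n_eligible_opinions": n_eligible,
        "n_users": len(state.users),
        "n_skilled_users": len(skilled),
        "n_test_clips": len(test_set),
        "n_test_clips_covered": len(covered),
        "crowd": _report_block(crowd),
        "experts": {
            "per_expert_pct": expert_summary.per_expert,
            "mean_pct": expert_summary.mean,
            "sd_pct": expert_summary.sd,
            "se_pct": expert_summary.se,
            "per_class_pct": expert_per_class,
        },
        "crowd_loo": _report_block(crowd_loo),
        "experts_loo": {
            "per_expert_pct": expert_loo.per_expert,
            "mean_pct": expert_loo.mean,
            "sd_pct": expert_loo.sd,
            "se_pct": expert_loo.se,
        },
        "paired_test_full": _paired(crowd_cases, expert_cases),
        "paired_test_loo": _paired(loo_crowd_cases, loo_expert_cases),
        "roc": {
            name: {"auc": res.auc, "points": list(res.points)}
            for name, res in roc.items()
        },
        "agreement": {
            "pearson_r": r,
            "pearson_p": r_p,
            "mannwhitney_u": u_stat,
            "mannwhitney_p": u_p,
            "expert_agreement_matched_pct": expert_agree_matched,
            "expert_agreement_unmatched_pct": expert_agree_unmatched,
            "high_crowd_agreement_concordance_pct": high_agree_concordance,
        },
        "subsample_curve": {
            "k": list(curve.k_values),
            "mean_pct": list(curve.mean_concordance),
            "se_pct": list(curve.se),
            "full_pool_pct": curve.full_pool_concordance,
            "knee_k": curve.knee_k,
            "knee_margin_pct": curve.knee_margin,
            "n_mc": curve.n_mc,
        },
        "learning_curves": {
            name: {
                "x": list(c.x),
                "mean_pct": list(c.mean_concordance),
                "se_pct": list(c.se),
                "n_users": list(c.n_users),
                "window": c.window,
            }
            for name, c in curves.items()
        },
        "consensus": {
            "n_promoted": len(promoted),
            "mean_opinions_used": float(
                np.mean([c.n_opinions_used for c in promoted])
            )
            if promoted
            else None,
            "stop_reasons": {
                reason: sum(1 for c in promoted if c.stop_reason.value == reason)
                for reason in ("LEAD", "CAP", "EXHAUSTED")
            },
        },
    }
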