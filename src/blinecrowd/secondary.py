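"""Secondary analyses: opinion subsampling, learning curves, skilled users.

The subsampling analysis estimates the concordance the crowd labels would
have had with fewer opinions per clip: for each count k it repeatedly draws k
eligible opinions per clip without replacement, takes the majority (ties
broken randomly) and scores the resulting labels against the reference;
1000 Monte-Carlo replicates per clip by default. Learning curves track each
labeler's trailing-window concordance over their successive test-set
opinions, averaged across labelers at each ordinal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .labels import BLineClass, Opinion
from .reference import ReferenceStandard

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SubsampleCurve:
    k_values: tuple[int, ...]
    mean_concordance: tuple[float, ...]  # percentage per k
    se: tuple[float, ...]  # Monte-Carlo SE per k
    n_mc: int
    rng_seed: int
    full_pool_concordance: float  # percentage using every eligible opinion
    knee_k: Optional[int]  # smallest k within the margin of the full pool
    knee_margin: float  # percentage points


@dataclass(frozen=True)
class LearningCurve:
    x: tuple[int, ...]  # opinion ordinal (test-set cases seen)
    mean_concordance: tuple[float, ...]  # percentage
    se: tuple[float, ...]
    n_users: tuple[int, ...]
    window: int


def _dedup_most_recent(
    opinions: Sequence[tuple[str, BLineClass]],
) -> list[BLineClass]:
    """Keep each user's last opinion, preserving order of last occurrence."""
    latest: dict[str, int] = {}
    for i, (user, _) in enumerate(opinions):
        latest[user] = i
    keep = sorted(latest.values())
    return [opinions[i][1] for i in keep]


def _mc_concordance(
    pools: Mapping[str, Sequence[tuple[str, BLineClass]]],
    reference: ReferenceStandard,
    k: int,
    n_mc: int,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Mean/SE over replicates of across-clip concordance at subsample size k."""
    correct = np.zeros((n_mc, 0), dtype=float)
    columns = []
    for clip_id in sorted(pools):
        labels = _dedup_most_recent(pools[clip_id])
        if not labels:
            logger.warning("clip %s has no eligible opinions; excluded", clip_id)
            continue
        codes = np.array([lab.value for lab in labels])
        n = len(codes)
        kk = min(k, n)
        # Random k-subsets without replacement: first kk columns of random permutations.
        idx = rng.random((n_mc, n)).argsort(axis=1)[:, :kk]
        onehot = np.eye(3)[codes]  # (n, 3)
        counts = onehot[idx].sum(axis=1)  # (n_mc, 3)
        # Uniform random tie-break: jitter < 1 never reorders distinct counts.
        jitter = rng.random((n_mc, 3)) * 0.5
        winner = (counts + jitter).argmax(axis=1)
        ref_code = reference.labels[clip_id].value
        columns.append(winner == ref_code)
    if not columns:
        raise ValueError("no clip has any eligible opinions")
    correct = np.column_stack(columns).astype(float)
    per_replicate = correct.mean(axis=1)
    mean = 100.0 * float(per_replicate.mean())
    se = 100.0 * float(per_replicate.std(ddof=1) / np.sqrt(n_mc)) if n_mc > 1 else 0.0
    return mean, se


def subsample_concordance(
    eligible_opinions: Mapping[str, Sequence[tuple[str, BLineClass]]],
    reference: ReferenceStandard,
    k: int,
    n_mc: int = 1000,
    rng_seed: int = 0,
) -> tuple[float, float]:
    """Estimated concordance (mean %, MC SE) had only k opinions been collected."""
    if k < 1:
        raise ValueError("k must be at least 1")
    rng = np.random.default_rng([rng_seed, k])
    return _mc_concordance(eligible_opinions, reference, k, n_mc, rng)


def build_subsample_curve(
    eligible_opinions: Mapping[str, Sequence[tuple[str, BLineClass]]],
    reference: ReferenceStandard,
    k_values: Sequence[int],
    n_mc: int = 1000,
    rng_seed: int = 0,
    knee_margin: float = 1.0,
) -> SubsampleCurve:
    """Concordance-vs-k curve plus the smallest k near the full-pool concordance."""
    ks = list(k_values)
    if ks != sorted(ks) or len(set(ks)) != len(ks):
        raise ValueError("k_values must be strictly increasing")
    means: list[float] = []
    ses: list[float] = []
    for k in ks:
        m, s = subsample_concordance(eligible_opinions, reference, k, n_mc, rng_seed)
        means.append(m)
        ses.append(s)
    max_pool = max(
        (len(_dedup_most_recent(v)) for v in eligible_opinions.values()), default=0
    )
    full_mean, _ = subsample_concordance(
        eligible_opinions, reference, max(max_pool, 1), n_mc, rng_seed
    )
    knee = next((k for k, m in zip(ks, means) if m >= full_mean - knee_margin), None)
    return SubsampleCurve(
        k_values=tuple(ks),
        mean_concordance=tuple(means),
        se=tuple(ses),
        n_mc=n_mc,
        rng_seed=rng_seed,
        full_pool_concordance=full_mean,
        knee_k=knee,
        knee_margin=knee_margin,
    )


def learning_curve(
    annotated_log: Sequence[Opinion],
    reference: ReferenceStandard,
    test_set: set[str],
    users: Optional[set[str]] = None,
    window: int = 25,
    min_users: int = 5,
) -> LearningCurve:
    """Trailing-window concordance vs number of test-set cases seen.

    For each labeler, their i-th opinion on a test-set clip contributes the
    mean correctness of their last ``window`` test-set opinions up to and
    including it; point i of the curve averages this over all labelers with at
    least i test-set opinions. Points supported by fewer than ``min_users``
    labelers are dropped. All opinions count, including repeat sightings.
    """
    series: dict[str, list[float]] = {}
    correct_hist: dict[str, list[bool]] = {}
    for op in annotated_log:
        if op.clip_id not in test_set:
            continue
        if users is not None and op.user_id not in users:
            continue
        hist = correct_hist.setdefault(op.user_id, [])
        hist.append(op.label == reference.labels[op.clip_id])
        tail = hist[-window:]
        series.setdefault(op.user_id, []).append(sum(tail) / len(tail))
    if not series:
        raise ValueError("no opinions on test-set clips for the requested cohort")
    max_len = max(len(s) for s in series.values())
    xs, means, ses, ns = [], [], [], []
    for i in range(1, max_len + 1):
        vals = [s[i - 1] for s in series.values() if len(s) >= i]
        if len(vals) < min_users:
            break
        arr = np.asarray(vals)
        xs.append(i)
        means.append(100.0 * float(arr.mean()))
        ses.append(
            100.0 * float(arr.std(ddof=1) / np.sqrt(len(arr))) if len(arr) > 1 else 0.0
        )
        ns.append(len(arr))
    return LearningCurve(
        x=tuple(xs),
        mean_concordance=tuple(means),
        se=tuple(ses),
        n_users=tuple(ns),
        window=window,
    )


def identify_skilled_users(
    annotated_log: Sequence[Opinion],
    test_set: set[str],
    threshold: float = 0.80,
) -> set[str]:
    """Users with >= 1 test-set opinion stamped at or above the quality threshold."""
    skilled: set[str] = set()
    for op in annotated_log:
        if (
            op.clip_id in test_set
            and op.qscore_at_submission is not None
            and op.qscore_at_submission >= threshold
        ):
            skilled.add(op.user_id)
    return skilled
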