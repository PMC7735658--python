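"""Time-to-last-mention survival contrasts between treatment groups.

For every (user, symptom) pair with at least one tagged post, the event
time is the day of the user's LAST mention of that symptom inside the
84-day window. Users who never mention a symptom contribute nothing to that
symptom's analysis.

Central interpretive assumption: there is NO censoring. Every last mention
is treated as an observed cessation event; subject-header data cannot show
whether a user kept posting about the symptom after the window. The
Kaplan-Meier product-limit estimate therefore coincides with the empirical
survivor function S(t) = #(T > t)/n.

Group contrasts use the standard two-sample log-rank test (hypergeometric
tie handling, 1 df) and the mean interquartile difference: the mean of the
25/50/75% event-time quartile differences, in days. Negative values mean
the comparison group ceases mentions EARLIER than the reference.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from lifelines.statistics import logrank_test

from forumlisten.reporting import significance_tier
from forumlisten.taxonomy import SYMPTOM_GROUPS, TaggedPost

QUARTILES = (0.25, 0.5, 0.75)


@dataclass(frozen=True)
class LastMentionRecord:
    user_id: str
    treatment_group: str
    symptom: str
    last_day: int


@dataclass(frozen=True)
class SurvivalCurve:
    """Step survivor function over integer event days; reaches 0 (no censoring)."""

    event_times: np.ndarray  # ascending unique event days
    survival: np.ndarray  # S(t) just after each event time
    n: int

    def at(self, t: float) -> float:
        """S(t) = P(T > t)."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def last_mentions(tagged_posts: Iterable[TaggedPost]) -> list[LastMentionRecord]:
    """Latest mention day per (user, symptom); one record per mentioned symptom."""
    latest: dict[tuple[str, str], int] = {}
    group: dict[str, str] = {}
    for tp in tagged_posts:
        uid = tp.post.user_id
        group.setdefault(uid, tp.post.treatment_group)
        for symptom in tp.mentioned_groups:
            key = (uid, symptom)
            day = tp.post.days_postop
            if key not in latest or day > latest[key]:
                latest[key] = day
    return [
        LastMentionRecord(uid, group[uid], symptom, day)
        for (uid, symptom), day in sorted(latest.items())
    ]


def km_estimate(times: Sequence[int]) -> SurvivalCurve:
    """Product-limit estimate; with all events observed this equals #(T > t)/n."""
    times = np.asarray(times)
    if times.size == 0:
        raise ValueError("cannot estimate a survival curve from zero event times")
    uniq, counts = np.unique(times, return_counts=True)
    n = times.size
    at_risk = n - np.concatenate(([0], np.cumsum(counts[:-1])))
    surv = np.cumprod(1.0 - counts / at_risk)
    return SurvivalCurve(event_times=uniq, survival=surv, n=int(n))


def log_rank(times_a: Sequence[int], times_b: Sequence[int]) -> tuple[float, float]:
    """Two-sample log-rank chi-square (1 df); all observations are events."""
    ta, tb = np.asarray(times_a), np.asarray(times_b)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("log-rank requires both groups non-empty")
    res = logrank_test(ta, tb, event_observed_A=np.ones(ta.size), event_observed_B=np.ones(tb.size))
    return float(res.test_statistic), float(res.p_value)


def quartile_time(curve: SurvivalCurve, q: float) -> int:
    """Smallest event time t with S(t) <= 1 - q (the q-th event-time quantile)."""
    if not 0 < q < 1:
        raise ValueError(f"q must be in (0,1), got {q}")
    target = 1.0 - q
    for t, s in zip(curve.event_times, curve.survival):
        # tolerance absorbs product-limit float noise at exact-quantile ties
        if s <= target + 1e-9:
            return int(t)
    return int(curve.event_times[-1])  # curve reaches 0, so unreachable


def mean_interquartile_difference(curve_group: SurvivalCurve, curve_reference: SurvivalCurve) -> float:
    """Mean of the 25/50/75% quartile-time differences (group minus reference)."""
    diffs = [quartile_time(curve_group, q) - quartile_time(curve_reference, q) for q in QUARTILES]
    return float(np.mean(diffs))


@dataclass(frozen=True)
class SurvivalRow:
    symptom: str
    group: str
    n_group: int
    n_ref: int
    mid_days: float | None  # mean interquartile difference, full precision
    logrank_stat: float | None
    p: float | None
    sig_tier: str
    direction: str  # earlier_cessation | later_cessation | no_shift | insufficient_data


def survival_report(
    records: Sequence[LastMentionRecord],
    reference_group: str = "abdominal",
    comparison_groups: Sequence[str] = ("vaginal", "laparoscopic"),
    min_group_size: int = 2,
) -> list[SurvivalRow]:
    """Per-(symptom, group) mean interquartile difference and log-rank p.

    Symptoms with fewer than ``min_group_size`` records in either group get
    an insufficient-data row rather than an error; a missing reference
    group is fatal.
    """
    by_group_symptom: dict[tuple[str, str], list[int]] = defaultdict(list)
    groups_present = set()
    for rec in records:
        groups_present.add(rec.treatment_group)
        by_group_symptom[(rec.treatment_group, rec.symptom)].append(rec.last_day)
    if reference_group not in groups_present:
        raise ValueError(f"reference group {reference_group!r} absent from records")
    if not (groups_present & set(comparison_groups)):
        raise ValueError("no comparison group present in records")

    rows: list[SurvivalRow] = []
    for symptom in SYMPTOM_GROUPS:
        ref_times = by_group_symptom.get((reference_group, symptom), [])
        for group in comparison_groups:
            grp_times = by_group_symptom.get((group, symptom), [])
            if len(grp_times) < min_group_size or len(ref_times) < min_group_size:
                rows.append(
                    SurvivalRow(symptom, group, len(grp_times), len(ref_times),
                                None, None, None, "na", "insufficient_data")
                )
                continue
            mid = mean_interquartile_difference(km_estimate(grp_times), km_estimate(ref_times))
            stat, p = log_rank(grp_times, ref_times)
            direction = "earlier_cessation" if mid < 0 else ("later_cessation" if mid > 0 else "no_shift")
            rows.append(
                SurvivalRow(symptom, group, len(grp_times), len(ref_times),
                            mid, stat, p, significance_tier(p), direction)
            )
    return rows
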