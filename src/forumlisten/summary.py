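"""Conversation-volume histograms, weekly symptom shares, cohort descriptives.

All percentages are derived from the integer counts stored next to them via
:func:`forumlisten.reporting.pct` (half-up, 2 decimals), so every displayed
number is re-derivable from the stored counts.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from forumlisten.ingest import OVARY_STATUSES, TREATMENT_GROUPS, UserProfile
from forumlisten.reporting import pct, round_half_up
from forumlisten.taxonomy import SYMPTOM_GROUPS, TaggedPost

#: Stratum labels: number of symptom groups a post subject mentions.
STRATA = ("0", "1", "2", "3+")


@dataclass(frozen=True)
class VolumeHistogram:
    axis: str  # "day" or "week"
    bins: np.ndarray
    counts: np.ndarray
    strata: np.ndarray  # shape (len(bins), 4): mention-count strata 0/1/2/3+

    def as_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.strata, columns=[f"mentions_{s}" for s in STRATA])
        df.insert(0, self.axis, self.bins)
        df.insert(1, "posts", self.counts)
        return df


def _stratum(k: int) -> int:
    return min(k, 3)


def post_volume_histogram(tagged_posts: Iterable[TaggedPost], axis: str = "day") -> VolumeHistogram:
    """Post counts per day (0-84) or week (1-12), stratified by mention count.

    On the week axis the single-day week-13 bin (day 84) is merged into
    week 12.
    """
    if axis == "day":
        bins = np.arange(0, 85)
    elif axis == "week":
        bins = np.arange(1, 13)
    else:
        raise ValueError(f"axis must be 'day' or 'week', got {axis!r}")
    strata = np.zeros((bins.size, 4), dtype=np.int64)
    for tp in tagged_posts:
        if axis == "day":
            idx = tp.post.days_postop
        else:
            idx = min(tp.post.week_postop, 12) - 1
        strata[idx, _stratum(len(tp.mentioned_groups))] += 1
    return VolumeHistogram(axis=axis, bins=bins, counts=strata.sum(axis=1), strata=strata)


def symptom_week_distribution(tagged_posts: Iterable[TaggedPost]) -> pd.DataFrame:
    """Each symptom's share of all mentions, per week (rows sum to 1).

    Weeks with zero mentions get NaN rows (undefined shares, not zeros).
    Day 84 is merged into week 12.
    """
    counts = np.zeros((12, len(SYMPTOM_GROUPS)), dtype=np.int64)
    col = {s: j for j, s in enumerate(SYMPTOM_GROUPS)}
    for tp in tagged_posts:
        w = min(tp.post.week_postop, 12) - 1
        for symptom in tp.mentioned_groups:
            counts[w, col[symptom]] += 1
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        shares = np.where(totals > 0, counts / totals, np.nan)
    return pd.DataFrame(shares, index=pd.RangeIndex(1, 13, name="week"), columns=SYMPTOM_GROUPS)


@dataclass(frozen=True)
class CohortSummary:
    """Descriptive statistics of the tagged cohort; counts are exact integers."""

    n_users: int
    n_posts: int
    n_posts_with_symptom: int
    pct_posts_with_symptom: float
    pct_posts_without_symptom: float
    n_posts_first3weeks: int
    pct_posts_first3weeks: float
    group_counts: dict[str, int]
    group_pcts: dict[str, float]
    ovary_counts: dict[str, int]
    ovary_pcts: dict[str, float]
    post_day_median: float
    post_day_mean: float
    post_day_sd: float
    posts_per_user_median: float
    posts_per_user_mean: float
    posts_per_user_sd: float
    total_symptom_mentions: int
    symptom_mention_counts: dict[str, int]
    symptom_mention_shares: dict[str, float]  # of all mentions, sums to ~100
    symptom_post_pcts: dict[str, float]  # of posts mentioning >=1 symptom

    def as_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)


def cohort_summary(
    tagged_posts: Sequence[TaggedPost],
    profiles: Mapping[str, UserProfile] | None = None,
) -> CohortSummary:
    """Descriptive summary of the analysis cohort.

    User-level attributes (treatment group, ovary status) come from the
    cohort posts themselves; ``profiles`` is accepted for interface parity
    but group/ovary tallies are computed over cohort users only. A
    "symptom mention" counts once per (post, distinct group) pair. Users
    counted in group/ovary breakdowns are those mentioning >= 1 symptom;
    posts-per-user statistics use all cohort posts and users. The
    first-3-weeks bin is days 0-20 inclusive.
    """
    if not tagged_posts:
        raise ValueError("cohort_summary requires a nonempty cohort")

    user_group: dict[str, str] = {}
    user_ovary: dict[str, str] = {}
    user_posts: Counter = Counter()
    mentioners: set[str] = set()
    days: list[int] = []
    mention_counts: Counter = Counter()
    n_with = 0
    n_first3 = 0
    for tp in tagged_posts:
        uid = tp.post.user_id
        user_group.setdefault(uid, tp.post.treatment_group)
        user_ovary.setdefault(uid, tp.post.ovary_status)
        user_posts[uid] += 1
        days.append(tp.post.days_postop)
        if tp.mentioned_groups:
            n_with += 1
            mentioners.add(uid)
            for s in tp.mentioned_groups:
                mention_counts[s] += 1
        if tp.post.days_postop <= 20:
            n_first3 += 1

    n_posts = len(tagged_posts)
    group_counts = {g: 0 for g in TREATMENT_GROUPS}
    ovary_counts = {o: 0 for o in OVARY_STATUSES}
    for uid in mentioners:
        group_counts[user_group[uid]] += 1
        ovary_counts[user_ovary[uid]] += 1
    n_mentioners = len(mentioners)

    days_arr = np.asarray(days, dtype=float)
    ppu = np.asarray(list(user_posts.values()), dtype=float)
    total_mentions = sum(mention_counts.values())

    def _share_pct(counts: Mapping[str, int], denom: int) -> dict[str, float]:
        if denom == 0:
            return {k: math.nan for k in counts}
        return {k: pct(v, denom) for k, v in counts.items()}

    return CohortSummary(
        n_users=len(user_posts),
        n_posts=n_posts,
        n_posts_with_symptom=n_with,
        pct_posts_with_symptom=pct(n_with, n_posts),
        pct_posts_without_symptom=pct(n_posts - n_with, n_posts),
        n_posts_first3weeks=n_first3,
        pct_posts_first3weeks=pct(n_first3, n_posts),
        group_counts=group_counts,
        group_pcts=_share_pct(group_counts, n_mentioners),
        ovary_counts=ovary_counts,
        ovary_pcts=_share_pct(ovary_counts, n_mentioners),
        post_day_median=float(np.median(days_arr)),
        post_day_mean=round_half_up(days_arr.mean(), 2),
        post_day_sd=round_half_up(days_arr.std(ddof=1), 2) if n_posts > 1 else 0.0,
        posts_per_user_median=float(np.median(ppu)),
        posts_per_user_mean=round_half_up(ppu.mean(), 2),
        posts_per_user_sd=round_half_up(ppu.std(ddof=1), 2) if ppu.size > 1 else 0.0,
        total_symptom_mentions=total_mentions,
        symptom_mention_counts={s: mention_counts.get(s, 0) for s in SYMPTOM_GROUPS},
        symptom_mention_shares=_share_pct({s: mention_counts.get(s, 0) for s in SYMPTOM_GROUPS}, total_mentions)
        if total_mentions
        else {s: math.nan for s in SYMPTOM_GROUPS},
        symptom_post_pcts=_share_pct({s: mention_counts.get(s, 0) for s in SYMPTOM_GROUPS}, n_with)
        if n_with
        else {s: math.nan for s in SYMPTOM_GROUPS},
    )
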