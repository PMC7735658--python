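"""Per-user symptom-mention proportions compared across treatment groups.

Tagged posts are aggregated to one record per user (the union of symptom
groups across their posts). For each symptom, each minimally invasive
group's mention proportion is contrasted with the abdominal reference via a
Pearson chi-square test of homogeneity on the 2x2 table (1 df, no
continuity correction).

Sign convention throughout: positive percentage difference means the
comparison group mentions the symptom MORE than the reference group.

Denominators default to users who mention at least one taxonomy symptom;
pass ``denominator="all"`` to use every cohort user instead.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from forumlisten.reporting import significance_tier
from forumlisten.taxonomy import SYMPTOM_GROUPS, TaggedPost

COMPARISON_GROUPS = ("vaginal", "laparoscopic")


@dataclass(frozen=True)
class UserSymptomProfile:
    user_id: str
    treatment_group: str
    mentioned: frozenset[str]


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float | None
    p: float | None
    degenerate: bool = False


@dataclass(frozen=True)
class MentionComparison:
    """One (symptom, group) row of the mention-frequency table."""

    symptom: str
    group: str
    n_group: int
    k_group: int
    n_ref: int
    k_ref: int
    p_group: float
    p_ref: float
    abs_pct_diff: float  # percentage points, positive = group mentions more
    chi2: float | None
    p: float | None
    sig_tier: str


def aggregate_user_mentions(tagged_posts: Iterable[TaggedPost]) -> list[UserSymptomProfile]:
    """One record per user: the union of mentioned groups over their posts."""
    mentioned: dict[str, set[str]] = defaultdict(set)
    group: dict[str, str] = {}
    order: list[str] = []
    for tp in tagged_posts:
        uid = tp.post.user_id
        if uid not in group:
            group[uid] = tp.post.treatment_group
            order.append(uid)
        mentioned[uid].update(tp.mentioned_groups)
    return [UserSymptomProfile(uid, group[uid], frozenset(mentioned[uid])) for uid in order]


def mention_contingency(
    profiles: Sequence[UserSymptomProfile],
    symptom: str,
    group: str,
    reference_group: str = "abdominal",
) -> np.ndarray:
    """2x2 table [[k_group, n_group-k_group], [k_ref, n_ref-k_ref]]."""
    g = [p for p in profiles if p.treatment_group == group]
    r = [p for p in profiles if p.treatment_group == reference_group]
    if not g:
        raise ValueError(f"group {group!r} is empty")
    if not r:
        raise ValueError(f"reference group {reference_group!r} is empty")
    kg = sum(symptom in p.mentioned for p in g)
    kr = sum(symptom in p.mentioned for p in r)
    return np.array([[kg, len(g) - kg], [kr, len(r) - kr]], dtype=np.int64)


def chi_square_homogeneity(table: np.ndarray) -> ChiSquareResult:
    """Pearson chi-square on a 2x2 table, 1 df, no continuity correction.

    A zero row or column margin makes the test undefined; a degenerate
    marker is returned rather than an exception.
    """
    table = np.asarray(table)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("expected a non-negative 2x2 table")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return ChiSquareResult(None, None, degenerate=True)
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return ChiSquareResult(float(stat), float(p), degenerate=False)


def mention_frequency_report(
    profiles: Sequence[UserSymptomProfile],
    reference_group: str = "abdominal",
    denominator: str = "mentioners",
    holm: bool = False,
) -> list[MentionComparison]:
    """Mention-proportion contrast table: 12 symptoms x 2 comparison groups.

    Both comparison groups are contrasted against the same reference
    proportion. ``holm=True`` applies a Holm step-down adjustment across
    the 24 raw p-values (off by default).
    """
    if denominator not in ("mentioners", "all"):
        raise ValueError(f"denominator must be 'mentioners' or 'all', got {denominator!r}")
    universe = [p for p in profiles if p.mentioned] if denominator == "mentioners" else list(profiles)
    present = {p.treatment_group for p in universe}
    missing = {reference_group, *COMPARISON_GROUPS} - present
    if missing:
        raise ValueError(f"missing treatment group(s) in profiles: {sorted(missing)}")

    rows: list[MentionComparison] = []
    for symptom in SYMPTOM_GROUPS:
        for group in COMPARISON_GROUPS:
            table = mention_contingency(universe, symptom, group, reference_group)
            kg, ng = int(table[0, 0]), int(table[0].sum())
            kr, nr = int(table[1, 0]), int(table[1].sum())
            res = chi_square_homogeneity(table)
            pg, pr = kg / ng, kr / nr
            rows.append(
                MentionComparison(
                    symptom=symptom,
                    group=group,
                    n_group=ng,
                    k_group=kg,
                    n_ref=nr,
                    k_ref=kr,
                    p_group=pg,
                    p_ref=pr,
                    abs_pct_diff=(pg - pr) * 100.0,
                    chi2=res.statistic,
                    p=res.p,
                    sig_tier="degenerate" if res.degenerate else significance_tier(res.p),
                )
            )
    if holm:
        rows = _holm_adjust(rows)
    return rows


def _holm_adjust(rows: list[MentionComparison]) -> list[MentionComparison]:
    from dataclasses import replace

    testable = [(i, r.p) for i, r in enumerate(rows) if r.p is not None]
    m = len(testable)
    order = sorted(range(m), key=lambda j: testable[j][1])
    adjusted = [None] * m
    running = 0.0
    for rank, j in enumerate(order):
        running = max(running, min(1.0, (m - rank) * testable[j][1]))
        adjusted[j] = running
    out = list(rows)
    for (i, _), padj in zip(testable, adjusted):
        out[i] = replace(rows[i], p=padj, sig_tier=significance_tier(padj))
    return out
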