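"""Log-likelihood n-gram comparison of two subject-header corpora.

For each n-gram the G-type log-likelihood statistic contrasts the term's
relative frequency in a comparison corpus against a base corpus:

    e1 = c(a+b)/(c+d),  e2 = d(a+b)/(c+d)
    LL = 2 * [ a*ln(a/e1) + b*ln(b/e2) ]

with a, b the term's counts and c, d the corpora's total n-gram counts for
the given n; zero-count terms contribute 0 to the sum. LL is referred to a
chi-square distribution with 1 df, so LL >= 3.84 corresponds to p <= .05
and LL >= 10.83 to p <= .001.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy import stats

from forumlisten.taxonomy import tokenize

NGram = tuple[str, ...]


def extract_ngrams(tokens: Sequence[str], n: int) -> list[NGram]:
    """All contiguous length-n windows within one subject's tokens.

    Windows never span subjects; a subject shorter than n yields none.
    """
    if n not in (1, 2, 3):
        raise ValueError(f"n must be 1, 2 or 3, got {n}")
    return [tuple(tokens[i : i + n]) for i in range(len(tokens) - n + 1)]


def log_likelihood(a: int, b: int, c: int, d: int) -> float:
    """Dunning-style log-likelihood for one term's counts in two corpora.

    ``a``/``b`` are the term's counts in corpora of total size ``c``/``d``.
    Symmetric under swapping (a, c) <-> (b, d); 0 iff a/c == b/d.
    """
    if a < 0 or b < 0:
        raise ValueError("term counts must be non-negative")
    if a + b < 1:
        raise ValueError("term must occur at least once in the pooled corpora")
    if c < max(a, 1) or d < max(b, 1):
        raise ValueError("corpus sizes must be >= 1 and >= the term counts")
    e1 = c * (a + b) / (c + d)
    e2 = d * (a + b) / (c + d)
    ll = 0.0
    if a > 0:
        ll += a * math.log(a / e1)
    if b > 0:
        ll += b * math.log(b / e2)
    # guard tiny negative float noise on near-equal frequencies
    return max(2.0 * ll, 0.0)


@dataclass(frozen=True)
class NGramCounts:
    """n-gram occurrence counts for one corpus."""

    n: int
    counts: Counter
    total: int


@dataclass(frozen=True)
class TermComparison:
    """One term's two-corpus contrast, ranked by log-likelihood."""

    term: NGram
    a: int  # count in comparison corpus
    b: int  # count in base corpus
    e1: float
    e2: float
    ll: float
    p: float
    direction: str  # over_in_comparison | over_in_base | equal


def count_ngrams(subjects: Iterable[str], n: int) -> NGramCounts:
    """Tokenize subjects and count their n-grams (windows never span subjects)."""
    counts: Counter = Counter()
    for subj in subjects:
        counts.update(extract_ngrams(tokenize(subj), n))
    return NGramCounts(n=n, counts=counts, total=sum(counts.values()))


def compare_corpora(
    base_subjects: Sequence[str],
    comparison_subjects: Sequence[str],
    n: int,
    min_count: int = 5,
) -> list[TermComparison]:
    """Rank pooled n-grams by log-likelihood, comparison vs base corpus.

    Terms with pooled count below ``min_count`` are dropped. Sorted by LL
    descending, ties broken lexicographically by term.
    """
    base = count_ngrams(base_subjects, n)
    comp = count_ngrams(comparison_subjects, n)
    if base.total == 0:
        raise ValueError("base corpus is empty after tokenization")
    if comp.total == 0:
        raise ValueError("comparison corpus is empty after tokenization")

    c, d = comp.total, base.total
    rows: list[TermComparison] = []
    for term in set(base.counts) | set(comp.counts):
        a = comp.counts.get(term, 0)
        b = base.counts.get(term, 0)
        if a + b < min_count:
            continue
        ll = log_likelihood(a, b, c, d)
        e1 = c * (a + b) / (c + d)
        e2 = d * (a + b) / (c + d)
        if a * d > b * c:
            direction = "over_in_comparison"
        elif a * d < b * c:
            direction = "over_in_base"
        else:
            direction = "equal"
        p = float(stats.chi2.sf(ll, df=1)) if ll > 0 else 1.0
        rows.append(TermComparison(term, a, b, e1, e2, ll, p, direction))
    rows.sort(key=lambda r: (-r.ll, r.term))
    return rows
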