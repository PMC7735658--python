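"""Symptom keyword taxonomy and subject-header tagging.

Twelve fixed symptom groups, each holding a set of keywords (a keyword is a
sequence of one or more lowercase tokens). A post subject is tagged with a
group iff any of the group's keywords occurs as a contiguous run of whole
tokens in the tokenized subject — never by substring.

Tokenization is deliberately minimal: lowercase, split on any
non-alphanumeric character, drop empties. Morphological variants, slang and
misspellings are handled by enumerating them as keywords, not by stemming.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from forumlisten.ingest import CohortPost

#: The twelve symptom group names, fixed vocabulary.
SYMPTOM_GROUPS = (
    "pain",
    "sleep_and_fatigue",
    "hormones_and_emotions",
    "digestion",
    "swelling",
    "bleeding",
    "urination",
    "intimacy",
    "odd_sensations",
    "drugs",
    "fever_and_infection",
    "family",
)

Keyword = tuple[str, ...]

_TOKEN_RE = re.compile(r"[a-z0-9]+")


def tokenize(text: str) -> list[str]:
    """Lowercase and split on any non-alphanumeric character.

    Digits survive as tokens; empty fragments are dropped; deterministic.
    """
    return _TOKEN_RE.findall(text.lower())


@dataclass(frozen=True)
class SymptomTaxonomy:
    """Mapping from the 12 group names to frozensets of keyword token tuples."""

    groups: dict[str, frozenset[Keyword]]
    # first-token index for fast contiguous matching; rebuilt on construction
    _index: dict[str, list[tuple[str, Keyword]]] = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self):
        if set(self.groups) != set(SYMPTOM_GROUPS):
            missing = set(SYMPTOM_GROUPS) - set(self.groups)
            extra = set(self.groups) - set(SYMPTOM_GROUPS)
            raise ValueError(
                f"taxonomy must define exactly the 12 symptom groups; "
                f"missing={sorted(missing)} unknown={sorted(extra)}"
            )
        seen: dict[Keyword, str] = {}
        for name, kws in self.groups.items():
            for kw in kws:
                if len(kw) == 0 or any(t == "" or re.search(r"\s", t) for t in kw):
                    raise ValueError(f"invalid keyword {kw!r} in group {name!r}")
                if kw in seen and seen[kw] != name:
                    raise ValueError(
                        f"keyword {' '.join(kw)!r} assigned to both "
                        f"{seen[kw]!r} and {name!r}"
                    )
                seen[kw] = name
        index: dict[str, list[tuple[str, Keyword]]] = {}
        for name in SYMPTOM_GROUPS:
            for kw in self.groups[name]:
                index.setdefault(kw[0], []).append((name, kw))
        object.__setattr__(self, "_index", index)

    @property
    def all_tokens(self) -> frozenset[str]:
        """Every token used by any keyword (for vocabulary-collision checks)."""
        return frozenset(t for kws in self.groups.values() for kw in kws for t in kw)

    def keywords(self, group: str) -> frozenset[Keyword]:
        return self.groups[group]


def _build(groups: dict[str, Iterable[str]]) -> SymptomTaxonomy:
    parsed: dict[str, frozenset[Keyword]] = {}
    for name, kws in groups.items():
        tuples = set()
        for kw in kws:
            toks = tuple(tokenize(kw))
            if not toks:
                raise ValueError(f"keyword {kw!r} in group {name!r} tokenizes to nothing")
            tuples.add(toks)
        parsed[name] = frozenset(tuples)
    return SymptomTaxonomy(groups=parsed)


def default_taxonomy() -> SymptomTaxonomy:
    """The curated default taxonomy shipped as package data.

    A configuration artifact, not ground truth: real analyses should pass
    their own reviewed keyword file. Deliberately excludes context-free
    procedural terms (e.g. "catheter") that occur unassociated with a
    symptom.
    """
    ref = resources.files("forumlisten.data").joinpath("default_taxonomy.json")
    return _build(json.loads(ref.read_text(encoding="utf-8")))


def load_taxonomy(path: str | Path) -> SymptomTaxonomy:
    """Load a ``{group_name: [keyword, ...]}`` JSON taxonomy file.

    Unknown group names and keywords duplicated across groups are fatal.
    """
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"taxonomy file {path} must be a JSON object")
    return _build(raw)


def tag_subject(tokens: Sequence[str], taxonomy: SymptomTaxonomy) -> set[str]:
    """Symptom groups whose keywords occur as contiguous whole-token runs."""
    found: set[str] = set()
    index = taxonomy._index
    n = len(tokens)
    for i, tok in enumerate(tokens):
        for name, kw in index.get(tok, ()):
            if name in found:
                continue
            k = len(kw)
            if i + k <= n and tuple(tokens[i : i + k]) == kw:
                found.add(name)
    return found


@dataclass(frozen=True)
class TaggedPost:
    """A cohort post plus the set of symptom groups its subject mentions."""

    post: CohortPost
    mentioned_groups: frozenset[str]


def tag_cohort(
    cohort_posts: Iterable[CohortPost], taxonomy: SymptomTaxonomy
) -> list[TaggedPost]:
    """Tag every cohort post's subject against the taxonomy."""
    return [
        TaggedPost(post=p, mentioned_groups=frozenset(tag_subject(tokenize(p.subject), taxonomy)))
        for p in cohort_posts
    ]


def keyword_in_context(keyword: str, cohort_posts: Iterable[CohortPost]) -> list[str]:
    """Pull all subjects containing the keyword, for manual curation.

    Multi-token keywords match only contiguous occurrences.
    """
    kw = tuple(tokenize(keyword))
    if not kw:
        raise ValueError(f"keyword {keyword!r} tokenizes to nothing")
    k = len(kw)
    out = []
    for p in cohort_posts:
        toks = tokenize(p.subject)
        if any(tuple(toks[i : i + k]) == kw for i in range(len(toks) - k + 1)):
            out.append(p.subject)
    return out
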