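"""Cohort construction from raw forum exports.

Reads post and profile records, maps self-declared hysterectomy type codes
onto the three surgical-approach treatment groups, and applies the
inclusion/exclusion filters that define the analysis cohort:

1. only thread-initiating posts are kept;
2. the posting user must have declared both a hysterectomy type and a
   surgery date;
3. the type code must map to one of the three treatment groups
   (single-incision codes are excluded);
4. the post must fall within the closed 0--84 day postoperative window
   (surgery day = day 0).

Attrition is logged per rule, in rule order.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from datetime import date, datetime
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

#: Marker returned by :func:`map_treatment_group` for codes excluded from analysis.
EXCLUDED = "excluded"

TREATMENT_GROUPS = ("abdominal", "vaginal", "laparoscopic")

OVARY_STATUSES = ("kept_at_least_one", "both_removed", "unknown")

# Forum type-code vocabulary -> treatment group. Single-incision
# laparoscopic codes (SILS / LESS) are excluded outright.
_GROUP_BY_CODE: dict[str, str] = {
    "TAH": "abdominal",
    "SAH": "abdominal",
    "TAH/SAH": "abdominal",
    "TAH-SAH": "abdominal",
    "TVH": "vaginal",
    "LAVH": "vaginal",
    "TLH": "laparoscopic",
    "LSH": "laparoscopic",
    "DVH": "laparoscopic",
    "SILS": EXCLUDED,
    "LESS": EXCLUDED,
}

POST_COLUMNS = ("user_id", "thread_id", "is_thread_initial", "subject", "posted_at")
PROFILE_COLUMNS = ("user_id", "hysterectomy_type", "surgery_date", "ovary_status")

#: Attrition rule names, in the order the filters are applied.
FILTER_RULES = ("not_thread_initial", "undeclared_profile", "excluded_type", "outside_window")


@dataclass(frozen=True)
class RawPost:
    """One unfiltered forum post record."""

    user_id: str
    thread_id: str
    is_thread_initial: bool
    subject: str
    posted_at: datetime


@dataclass(frozen=True)
class UserProfile:
    """Structured self-declared profile data for one user."""

    user_id: str
    hysterectomy_type: str | None
    surgery_date: date | None
    ovary_status: str = "unknown"


@dataclass(frozen=True)
class CohortPost:
    """A filtered, thread-initiating post inside the analysis window."""

    user_id: str
    treatment_group: str
    ovary_status: str
    subject: str
    days_postop: int

    @property
    def week_postop(self) -> int:
        """1-based week index; day 84 alone lands in week 13."""
        return self.days_postop // 7 + 1


@dataclass
class AttritionLog:
    """Per-rule removal counts, in filter order."""

    total_in: int = 0
    total_out: int = 0
    removed: dict[str, int] = field(default_factory=lambda: {r: 0 for r in FILTER_RULES})

    def as_dict(self) -> dict:
        return {"total_in": self.total_in, "total_out": self.total_out, "removed": dict(self.removed)}


def map_treatment_group(type_code: str) -> str:
    """Map a declared hysterectomy type code to a treatment group.

    Total function: unknown codes return the excluded marker (with a
    warning) rather than raising.
    """
    code = (type_code or "").strip().upper()
    group = _GROUP_BY_CODE.get(code)
    if group is None:
        logger.warning("unknown hysterectomy type code %r; excluding", type_code)
        return EXCLUDED
    return group


def days_postop(posted_at: datetime | date, surgery_date: date) -> int:
    """Whole-day difference post date minus surgery date (surgery day = 0).

    Negative when the post precedes surgery; callers filter, this does not.
    """
    post_date = posted_at.date() if isinstance(posted_at, datetime) else posted_at
    return (post_date - surgery_date).days


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    s = str(value).strip().lower()
    if s in ("true", "1", "t", "yes"):
        return True
    if s in ("false", "0", "f", "no"):
        return False
    raise ValueError(f"not a boolean: {value!r}")


def _parse_timestamp(value) -> datetime:
    if isinstance(value, datetime):
        return value
    return datetime.fromisoformat(str(value).strip())


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("csv", "jsonl"):
            raise ValueError(f"unsupported format {fmt!r}; expected 'csv' or 'jsonl'")
        return fmt
    return "jsonl" if path.suffix.lower() in (".jsonl", ".ndjson", ".json") else "csv"


def _iter_records(path: Path, fmt: str) -> Iterable[dict]:
    if fmt == "csv":
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                return
            missing = [c for c in POST_COLUMNS if c not in reader.fieldnames]
            if missing:
                raise ValueError(f"post file {path} is missing required column(s): {', '.join(missing)}")
            yield from reader
    else:
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if line:
                    yield json.loads(line)


def read_posts(path: str | Path, format: str | None = None) -> list[RawPost]:
    """Read raw post records from a CSV or JSON-lines file.

    Malformed rows (missing user/thread ids, unparseable timestamp or
    boolean) are logged and counted, never silently dropped. A null
    subject is treated as malformed; an empty-string subject is legal.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"post file not found: {path}")
    fmt = _infer_format(path, format)

    posts: list[RawPost] = []
    n_rejected = 0
    for i, rec in enumerate(_iter_records(path, fmt)):
        try:
            subject = rec["subject"]
            if subject is None:
                raise ValueError("null subject")
            posted_raw = rec.get("posted_at")
            if posted_raw is None or str(posted_raw).strip() == "":
                raise ValueError("missing posted_at")
            posts.append(
                RawPost(
                    user_id=str(rec["user_id"]),
                    thread_id=str(rec["thread_id"]),
                    is_thread_initial=_parse_bool(rec["is_thread_initial"]),
                    subject=str(subject),
                    posted_at=_parse_timestamp(posted_raw),
                )
            )
        except KeyError as exc:
            raise ValueError(f"post file {path} is missing required column: {exc.args[0]}") from exc
        except (ValueError, TypeError) as exc:
            n_rejected += 1
            logger.warning("rejected malformed post row %d: %s", i, exc)
    if n_rejected:
        logger.warning("rejected %d malformed post row(s) from %s", n_rejected, path)
    return posts


def read_profiles(path: str | Path) -> dict[str, UserProfile]:
    """Read user profiles from CSV, keyed by user id.

    Duplicate ids keep the first occurrence (warned). Blank type or date
    fields become ``None``; blank/unrecognized ovary status becomes
    ``"unknown"``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"profile file not found: {path}")
    profiles: dict[str, UserProfile] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            return profiles
        missing = [c for c in PROFILE_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise ValueError(f"profile file {path} is missing required column(s): {', '.join(missing)}")
        for rec in reader:
            uid = str(rec["user_id"])
            if uid in profiles:
                logger.warning("duplicate profile for user %s; keeping first", uid)
                continue
            htype = (rec.get("hysterectomy_type") or "").strip() or None
            sdate_raw = (rec.get("surgery_date") or "").strip()
            sdate = date.fromisoformat(sdate_raw) if sdate_raw else None
            ostat = (rec.get("ovary_status") or "").strip()
            if ostat not in OVARY_STATUSES:
                ostat = "unknown"
            profiles[uid] = UserProfile(uid, htype, sdate, ostat)
    return profiles


def build_cohort(
    posts: Sequence[RawPost],
    profiles: Mapping[str, UserProfile],
    window_days: tuple[int, int] = (0, 84),
) -> tuple[list[CohortPost], AttritionLog]:
    """Apply the four inclusion filters, in order, and log attrition.

    Ovary status is carried through but never used as a filter.
    """
    lo, hi = window_days
    if not (0 <= lo <= hi):
        raise ValueError(f"invalid window {window_days}; need 0 <= lo <= hi")

    log = AttritionLog(total_in=len(posts))
    cohort: list[CohortPost] = []
    for post in posts:
        if not post.is_thread_initial:
            log.removed["not_thread_initial"] += 1
            continue
        prof = profiles.get(post.user_id)
        if prof is None or prof.hysterectomy_type is None or prof.surgery_date is None:
            log.removed["undeclared_profile"] += 1
            continue
        group = map_treatment_group(prof.hysterectomy_type)
        if group == EXCLUDED:
            log.removed["excluded_type"] += 1
            continue
        day = days_postop(post.posted_at, prof.surgery_date)
        if not (lo <= day <= hi):
            log.removed["outside_window"] += 1
            continue
        cohort.append(
            CohortPost(
                user_id=post.user_id,
                treatment_group=group,
                ovary_status=prof.ovary_status,
                subject=post.subject,
                days_postop=day,
            )
        )
    log.total_out = len(cohort)
    if not cohort:
        logger.warning("cohort is empty after filtering (%d posts in)", len(posts))
    logger.info("cohort filter attrition: %s", log.as_dict())
    return cohort, log
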