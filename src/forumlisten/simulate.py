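"""Synthetic forum-cohort generator.

Emits profile and post files in the ingest schema with the statistical
structure the analysis pipeline assumes, so every stage is testable without
any real forum data:

* three-way treatment-group split (default 40/32/28%),
* right-skewed posting times on days 0-84 (gamma, fit to a target
  median/mean at config-build time),
* zero-truncated negative-binomial posts per user (fit to target mean/sd),
* per (group, symptom) mention probabilities and exponential cessation
  times: a post can mention a symptom only while its day is at or below
  the user's drawn cessation time for that symptom,
* subjects assembled as token bags: filler words (guaranteed disjoint from
  the taxonomy vocabulary) interleaved with embedded keywords, so planted
  per-post symptom sets are recoverable exactly by the tagger.

Optionally injects known filter violations (reply posts, missing surgery
dates, excluded type codes, out-of-window posts) at configured rates so
ingest attrition accounting can be validated against ground truth.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from datetime import date, timedelta
from pathlib import Path
import numpy as np
import pandas as pd
from scipy import optimize, stats

from forumlisten.ingest import TREATMENT_GROUPS, OVARY_STATUSES
from forumlisten.taxonomy import SYMPTOM_GROUPS, SymptomTaxonomy, default_taxonomy

_CODES_BY_GROUP = {
    "abdominal": ("TAH", "SAH", "TAH/SAH"),
    "vaginal": ("TVH", "LAVH"),
    "laparoscopic": ("TLH", "LSH", "DVH"),
}

#: Subject filler vocabulary; must stay disjoint from taxonomy keyword tokens.
DEFAULT_FILLER = (
    "question", "about", "week", "weeks", "post", "op", "update", "today",
    "advice", "anyone", "else", "normal", "at", "after", "my", "still",
    "when", "back", "work", "home", "first", "time", "help", "please",
    "wondering", "experience", "recovery", "doing", "well", "day",
)

VIOLATION_KINDS = ("reply", "missing_date", "sils_user", "preop", "postwindow")


@dataclass(frozen=True)
class SymptomParams:
    """Generative parameters for one (treatment group, symptom) cell."""

    mention_prob: float  # per-post mention probability while day <= cessation
    cessation_mean: float | None = None  # exponential mean (days); None = never ceases
    cessation_shift: float = 0.0  # additive shift on drawn cessation times


@dataclass
class SimConfig:
    """Full generative parameterization of a synthetic forum cohort."""

    seed: int
    n_users: int
    group_probs: dict[str, float] = field(
        default_factory=lambda: {"abdominal": 0.40, "vaginal": 0.32, "laparoscopic": 0.28}
    )
    ovary_probs: dict[str, float] = field(
        default_factory=lambda: {"kept_at_least_one": 0.56, "both_removed": 0.37, "unknown": 0.07}
    )
    posts_per_user: dict = field(default_factory=lambda: {"dist": "ztnb", "mean": 2.42, "sd": 3.10})
    post_time: dict = field(default_factory=lambda: {"dist": "gamma", "median": 19.0, "mean": 23.8})
    symptom_model: dict[str, dict[str, SymptomParams]] = field(default_factory=dict)
    filler_vocabulary: tuple[str, ...] = DEFAULT_FILLER
    violations: dict[str, float] = field(default_factory=dict)
    start_date: str = "2015-01-01"
    fit_report: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.n_users < 1:
            raise ValueError("n_users must be >= 1")
        for name, probs, keys in (
            ("group_probs", self.group_probs, TREATMENT_GROUPS),
            ("ovary_probs", self.ovary_probs, OVARY_STATUSES),
        ):
            if set(probs) != set(keys):
                raise ValueError(f"{name} must have keys {keys}")
            vals = list(probs.values())
            if any(not 0 <= v <= 1 for v in vals) or abs(sum(vals) - 1.0) > 1e-9:
                raise ValueError(f"{name} must be probabilities summing to 1")
        if not self.symptom_model:
            self.symptom_model = default_symptom_model()
        for symptom, per_group in self.symptom_model.items():
            if symptom not in SYMPTOM_GROUPS:
                raise ValueError(f"unknown symptom {symptom!r} in symptom_model")
            for group, params in per_group.items():
                if group not in TREATMENT_GROUPS:
                    raise ValueError(f"unknown group {group!r} in symptom_model[{symptom!r}]")
                if not 0.0 <= params.mention_prob <= 1.0:
                    raise ValueError(f"mention_prob out of [0,1] for ({symptom}, {group})")
                if params.cessation_mean is not None and params.cessation_mean <= 0:
                    raise ValueError(f"cessation_mean must be positive for ({symptom}, {group})")
        for kind, rate in self.violations.items():
            if kind not in VIOLATION_KINDS:
                raise ValueError(f"unknown violation kind {kind!r}")
            if not 0 <= rate <= 1:
                raise ValueError(f"violation rate for {kind!r} out of [0,1]")
        if sum(self.violations.get(k, 0.0) for k in ("reply", "preop", "postwindow")) > 1:
            raise ValueError("post-level violation rates sum to more than 1")
        self._fit_distributions()

    # -- distribution fitting -------------------------------------------------

    def _fit_distributions(self):
        ppu = self.posts_per_user
        if ppu["dist"] == "ztnb":
            r, p = fit_zero_truncated_nb(ppu["mean"], ppu["sd"])
            ppu["r"], ppu["p"] = r, p
            mu, sd = _ztnb_moments(r, p)
            self.fit_report["posts_per_user"] = {
                "target_mean": ppu["mean"], "target_sd": ppu["sd"],
                "achieved_mean": mu, "achieved_sd": sd,
            }
        elif ppu["dist"] == "fixed":
            if ppu.get("k", 0) < 1:
                raise ValueError("fixed posts_per_user requires k >= 1")
        else:
            raise ValueError(f"unsupported posts_per_user dist {ppu['dist']!r}")

        pt = self.post_time
        if pt["dist"] == "gamma":
            shape, scale = fit_gamma_median_mean(pt["median"], pt["mean"])
            pt["shape"], pt["scale"] = shape, scale
            med, mean = _truncated_floored_gamma_moments(shape, scale)
            self.fit_report["post_time"] = {
                "target_median": pt["median"], "target_mean": pt["mean"],
                "achieved_median_after_truncation": med,
                "achieved_mean_after_truncation": mean,
            }
        elif pt["dist"] != "uniform":
            raise ValueError(f"unsupported post_time dist {pt['dist']!r}")

    # -- (de)serialization ----------------------------------------------------

    def to_json(self) -> str:
        d = asdict(self)
        d["filler_vocabulary"] = list(self.filler_vocabulary)
        d["schema_version"] = 1
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimConfig":
        d = json.loads(text)
        d.pop("schema_version", None)
        d.pop("fit_report", None)
        sm = {
            s: {g: SymptomParams(**pp) for g, pp in per_group.items()}
            for s, per_group in d.pop("symptom_model", {}).items()
        }
        ppu = d.get("posts_per_user", {})
        ppu.pop("r", None), ppu.pop("p", None)
        pt = d.get("post_time", {})
        pt.pop("shape", None), pt.pop("scale", None)
        d["filler_vocabulary"] = tuple(d.get("filler_vocabulary", DEFAULT_FILLER))
        return cls(symptom_model=sm, **d)


def default_symptom_model() -> dict[str, dict[str, SymptomParams]]:
    """Mild group-dependent per-post probabilities and cessation scales.

    Per-post probabilities are loosely proportional to the relative mention
    volumes of the symptom groups; minimally invasive groups get slightly
    shorter cessation scales.
    """
    base = {
        "pain": 0.18, "bleeding": 0.11, "hormones_and_emotions": 0.07,
        "sleep_and_fatigue": 0.05, "digestion": 0.05, "swelling": 0.04,
        "urination": 0.035, "intimacy": 0.03, "odd_sensations": 0.03,
        "drugs": 0.025, "fever_and_infection": 0.02, "family": 0.02,
    }
    cess = {"abdominal": 45.0, "vaginal": 38.0, "laparoscopic": 36.0}
    return {
        s: {g: SymptomParams(mention_prob=p, cessation_mean=cess[g]) for g in TREATMENT_GROUPS}
        for s, p in base.items()
    }


def fit_gamma_median_mean(median: float, mean: float, hi: int = 84) -> tuple[float, float]:
    """Gamma (shape, scale) whose [0, hi]-truncated, floored-to-day law hits
    the target integer-day median and mean.

    The continuous truncated median is steered to ``median + 0.5`` so that
    flooring lands the day-valued median on ``median`` itself.
    """
    if not 0 < median < mean:
        raise ValueError("gamma fit requires 0 < median < mean (right skew)")

    def resid(x):
        shape, scale = math.exp(x[0]), math.exp(x[1])
        f_hi = stats.gamma.cdf(hi + 1, shape, scale=scale)
        cont_median = stats.gamma.ppf(0.5 * f_hi, shape, scale=scale)
        _, floored_mean = _truncated_floored_gamma_moments(shape, scale, hi=hi)
        return [floored_mean - mean, cont_median - (median + 0.5)]

    x0 = [math.log(2.0), math.log(mean / 2.0)]
    sol = optimize.root(resid, x0=x0, method="hybr")
    if not sol.success:
        raise ValueError(f"could not fit gamma to median={median}, mean={mean}")
    return float(math.exp(sol.x[0])), float(math.exp(sol.x[1]))


def _truncated_floored_gamma_moments(shape: float, scale: float, hi: int = 84) -> tuple[float, float]:
    edges = np.arange(hi + 2, dtype=float)
    cdf = stats.gamma.cdf(edges, shape, scale=scale)
    pmf = np.diff(cdf) / cdf[-1]
    days = np.arange(hi + 1)
    cum = np.cumsum(pmf)
    median = float(days[np.searchsorted(cum, 0.5)])
    return median, float((days * pmf).sum())


def _ztnb_moments(r: float, p: float) -> tuple[float, float]:
    mu = r * (1 - p) / p
    denom = -math.expm1(r * math.log(p))  # 1 - P(X=0), cancellation-safe
    mt = mu / denom
    vt = (mu / p + mu * mu) / denom - mt * mt
    return float(mt), float(math.sqrt(max(vt, 0.0)))


def fit_zero_truncated_nb(mean: float, sd: float) -> tuple[float, float]:
    """(r, p) of the underlying NB whose zero-truncation targets mean and sd.

    The mean is matched exactly; the sd is matched as closely as the family
    allows (at low means the zero-truncated NB has a bounded sd, so some
    target pairs are infeasible). Achieved moments land in the config's
    ``fit_report``.
    """
    if mean <= 1 or sd <= 0:
        raise ValueError("zero-truncated NB needs mean > 1 and sd > 0")

    def p_for_mean(r: float) -> float:
        return optimize.brentq(
            lambda p: _ztnb_moments(r, p)[0] - mean, 1e-12, 1 - 1e-12, xtol=1e-14
        )

    def sd_err(log_r: float) -> float:
        r = math.exp(log_r)
        try:
            p = p_for_mean(r)
        except ValueError:
            return 1e12
        return (_ztnb_moments(r, p)[1] - sd) ** 2

    res = optimize.minimize_scalar(sd_err, bounds=(-8.0, 6.0), method="bounded")
    r = float(math.exp(res.x))
    return r, float(p_for_mean(r))


# -- generation ---------------------------------------------------------------


@dataclass
class SimResult:
    posts: pd.DataFrame
    profiles: pd.DataFrame
    truth: pd.DataFrame  # per post: planted symptom set and violation kind
    config: SimConfig
    paths: dict[str, Path] = field(default_factory=dict)


def _draw_posts_per_user(rng: np.random.Generator, cfg: dict, size: int) -> np.ndarray:
    if cfg["dist"] == "fixed":
        return np.full(size, int(cfg["k"]))
    r, p = cfg["r"], cfg["p"]
    out = np.zeros(size, dtype=np.int64)
    todo = np.arange(size)
    while todo.size:
        draw = rng.negative_binomial(r, p, size=todo.size)
        ok = draw > 0
        out[todo[ok]] = draw[ok]
        todo = todo[~ok]
    return out


def _draw_days(rng: np.random.Generator, cfg: dict, size: int) -> np.ndarray:
    if cfg["dist"] == "uniform":
        return rng.integers(0, 85, size=size)
    out = np.zeros(size, dtype=np.int64)
    todo = np.arange(size)
    while todo.size:
        draw = np.floor(rng.gamma(cfg["shape"], cfg["scale"], size=todo.size)).astype(np.int64)
        ok = draw <= 84
        out[todo[ok]] = draw[ok]
        todo = todo[~ok]
    return out


def simulate_cohort(
    config: SimConfig,
    taxonomy: SymptomTaxonomy | None = None,
    out_dir: str | Path | None = None,
) -> SimResult:
    """Generate profile/post tables (and optionally files) for one cohort.

    Deterministic given ``config.seed``. Subjects embed one keyword per
    planted symptom, always separated by filler tokens, so the tagger
    recovers planted symptom sets exactly for any valid taxonomy.
    """
    taxonomy = taxonomy or default_taxonomy()
    overlap = set(config.filler_vocabulary) & set(taxonomy.all_tokens)
    if overlap:
        raise ValueError(f"filler vocabulary collides with taxonomy tokens: {sorted(overlap)}")

    rng = np.random.default_rng(config.seed)
    n = config.n_users
    start = date.fromisoformat(config.start_date)

    groups = rng.choice(TREATMENT_GROUPS, size=n, p=[config.group_probs[g] for g in TREATMENT_GROUPS])
    ovaries = rng.choice(OVARY_STATUSES, size=n, p=[config.ovary_probs[o] for o in OVARY_STATUSES])
    surgery_offsets = rng.integers(0, 365, size=n)
    n_posts = _draw_posts_per_user(rng, config.posts_per_user, n)

    v = config.violations
    sils_users = rng.random(n) < v.get("sils_user", 0.0)
    missing_date_users = rng.random(n) < v.get("missing_date", 0.0)

    # sorted keyword lists per group for deterministic sampling; only embed
    # keywords that tag back to exactly their own group, so planted per-post
    # symptom sets are recoverable verbatim for any taxonomy
    from forumlisten.taxonomy import tag_subject

    kw_lists = {}
    for g in SYMPTOM_GROUPS:
        safe = [kw for kw in sorted(taxonomy.keywords(g)) if tag_subject(list(kw), taxonomy) == {g}]
        if not safe:
            raise ValueError(f"group {g!r} has no unambiguous keyword to embed")
        kw_lists[g] = safe
    filler = config.filler_vocabulary

    prof_rows = []
    post_rows = []
    truth_rows = []
    post_i = 0
    for i in range(n):
        uid = f"u{i:06d}"
        group = str(groups[i])
        sdate = start + timedelta(days=int(surgery_offsets[i]))
        code = "SILS" if sils_users[i] else _CODES_BY_GROUP[group][rng.integers(0, len(_CODES_BY_GROUP[group]))]
        prof_rows.append(
            {
                "user_id": uid,
                "hysterectomy_type": code,
                "surgery_date": "" if missing_date_users[i] else sdate.isoformat(),
                "ovary_status": str(ovaries[i]),
            }
        )

        cessation = {}
        for s in SYMPTOM_GROUPS:
            params = config.symptom_model.get(s, {}).get(group)
            if params is None or params.cessation_mean is None:
                cessation[s] = math.inf
            else:
                cessation[s] = max(0.0, rng.exponential(params.cessation_mean) + params.cessation_shift)

        days = np.sort(_draw_days(rng, config.post_time, int(n_posts[i])))
        for day in days:
            day = int(day)
            violation = ""
            u = rng.random()
            acc = 0.0
            for kind in ("reply", "preop", "postwindow"):
                acc += v.get(kind, 0.0)
                if u < acc:
                    violation = kind
                    break
            if violation == "preop":
                day = -int(rng.integers(1, 30))
            elif violation == "postwindow":
                day = 85 + int(rng.integers(0, 30))

            planted = []
            for s in SYMPTOM_GROUPS:
                params = config.symptom_model.get(s, {}).get(group)
                if params is None or params.mention_prob == 0.0:
                    continue
                if day <= cessation[s] and rng.random() < params.mention_prob:
                    planted.append(s)

            tokens = [str(filler[rng.integers(0, len(filler))])]
            for s in planted:
                kws = kw_lists[s]
                tokens.extend(kws[rng.integers(0, len(kws))])
                tokens.append(str(filler[rng.integers(0, len(filler))]))
            subject = " ".join(tokens)

            tid = f"t{post_i:07d}"
            hour = int(rng.integers(6, 23))
            post_rows.append(
                {
                    "user_id": uid,
                    "thread_id": tid,
                    "is_thread_initial": violation != "reply",
                    "subject": subject,
                    "posted_at": f"{(sdate + timedelta(days=day)).isoformat()}T{hour:02d}:00:00",
                }
            )
            # attribute the violation the same way the ingest filter order will
            if violation == "reply":
                attributed = "reply"
            elif missing_date_users[i]:
                attributed = "missing_date"
            elif sils_users[i]:
                attributed = "sils_user"
            else:
                attributed = violation
            truth_rows.append(
                {
                    "thread_id": tid,
                    "user_id": uid,
                    "treatment_group": group,
                    "day": day,
                    "planted": ";".join(planted),
                    "violation": attributed,
                }
            )
            post_i += 1

    posts = pd.DataFrame(post_rows)
    profiles = pd.DataFrame(prof_rows)
    truth = pd.DataFrame(truth_rows)
    result = SimResult(posts=posts, profiles=profiles, truth=truth, config=config)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "posts": out_dir / "posts.csv",
            "profiles": out_dir / "profiles.csv",
            "truth": out_dir / "truth.csv",
            "config": out_dir / "sim_config.json",
        }
        posts.to_csv(paths["posts"], index=False, lineterminator="\n")
        profiles.to_csv(paths["profiles"], index=False, lineterminator="\n")
        truth.to_csv(paths["truth"], index=False, lineterminator="\n")
        paths["config"].write_text(config.to_json(), encoding="utf-8")
        result.paths = paths
    return result


# -- recovery validation ------------------------------------------------------


def planted_user_mention_prob(config: SimConfig, symptom: str, group: str) -> float | None:
    """Per-user mention probability implied by the config, when analytic.

    Only defined for fixed posts-per-user with no cessation (infinite
    cessation mean); otherwise returns None.
    """
    params = config.symptom_model.get(symptom, {}).get(group)
    if params is None:
        return 0.0
    if config.posts_per_user["dist"] != "fixed" or params.cessation_mean is not None:
        return None
    k = int(config.posts_per_user["k"])
    return 1.0 - (1.0 - params.mention_prob) ** k


def run_pipeline_on_sim(result: SimResult, taxonomy: SymptomTaxonomy | None = None):
    """simulate -> ingest -> tag, via the real pipeline entry points."""
    from forumlisten.ingest import RawPost, UserProfile, build_cohort
    from forumlisten.taxonomy import tag_cohort
    from datetime import datetime

    posts = [
        RawPost(
            user_id=r.user_id,
            thread_id=r.thread_id,
            is_thread_initial=bool(r.is_thread_initial),
            subject=r.subject,
            posted_at=datetime.fromisoformat(r.posted_at),
        )
        for r in result.posts.itertuples()
    ]
    profiles = {
        r.user_id: UserProfile(
            user_id=r.user_id,
            hysterectomy_type=r.hysterectomy_type or None,
            surgery_date=date.fromisoformat(r.surgery_date) if r.surgery_date else None,
            ovary_status=r.ovary_status,
        )
        for r in result.profiles.itertuples()
    }
    cohort, attrition = build_cohort(posts, profiles)
    tagged = tag_cohort(cohort, taxonomy or default_taxonomy())
    return tagged, attrition


def validate_recovery(
    config: SimConfig,
    n_replicates: int = 20,
    base_seed: int | None = None,
    alpha: float = 0.05,
    taxonomy: SymptomTaxonomy | None = None,
) -> dict:
    """Replicate-level recovery report for the full simulate->analyse loop.

    For every (symptom, comparison group) cell, reports the mean estimated
    mention percentage-point difference and chi-square rejection rate, and
    the mean interquartile survival difference and log-rank rejection rate,
    against the generating parameters.
    """
    from dataclasses import replace as dc_replace

    from forumlisten.mention_stats import aggregate_user_mentions, mention_frequency_report
    from forumlisten.survival import last_mentions, survival_report

    base_seed = config.seed if base_seed is None else base_seed
    mention_acc: dict[tuple[str, str], list] = {}
    surv_acc: dict[tuple[str, str], list] = {}
    for rep in range(n_replicates):
        cfg = dc_replace_config(config, seed=base_seed + rep)
        tagged, _ = run_pipeline_on_sim(simulate_cohort(cfg, taxonomy=taxonomy), taxonomy=taxonomy)
        profiles = aggregate_user_mentions(tagged)
        for row in mention_frequency_report(profiles):
            mention_acc.setdefault((row.symptom, row.group), []).append(
                (row.abs_pct_diff, row.p is not None and row.p < alpha)
            )
        for row in survival_report(last_mentions(tagged)):
            if row.mid_days is not None:
                surv_acc.setdefault((row.symptom, row.group), []).append(
                    (row.mid_days, row.p < alpha)
                )

    report = {"n_replicates": n_replicates, "alpha": alpha, "mention": {}, "survival": {}}
    for (symptom, group), vals in sorted(mention_acc.items()):
        diffs = [v[0] for v in vals]
        planted_g = planted_user_mention_prob(config, symptom, group)
        planted_r = planted_user_mention_prob(config, symptom, "abdominal")
        planted = None if planted_g is None or planted_r is None else (planted_g - planted_r) * 100
        report["mention"][f"{symptom}|{group}"] = {
            "planted_diff_pp": planted,
            "mean_estimated_diff_pp": float(np.mean(diffs)),
            "rejection_rate": float(np.mean([v[1] for v in vals])),
        }
    for (symptom, group), vals in sorted(surv_acc.items()):
        pg = config.symptom_model.get(symptom, {}).get(group)
        pr = config.symptom_model.get(symptom, {}).get("abdominal")
        planted_shift = None
        if pg and pr and pg.cessation_mean == pr.cessation_mean:
            planted_shift = pg.cessation_shift - pr.cessation_shift
        report["survival"][f"{symptom}|{group}"] = {
            "planted_shift_days": planted_shift,
            "mean_mid_days": float(np.mean([v[0] for v in vals])),
            "rejection_rate": float(np.mean([v[1] for v in vals])),
        }
    return report


def dc_replace_config(config: SimConfig, **kwargs) -> SimConfig:
    """Copy a SimConfig with fields replaced (fresh validation/fit)."""
    d = json.loads(config.to_json())
    d.pop("schema_version", None)
    d.pop("fit_report", None)
    sm = {
        s: {g: SymptomParams(**pp) for g, pp in per_group.items()}
        for s, per_group in d.pop("symptom_model", {}).items()
    }
    ppu = d.get("posts_per_user", {})
    ppu.pop("r", None), ppu.pop("p", None)
    pt = d.get("post_time", {})
    pt.pop("shape", None), pt.pop("scale", None)
    d["filler_vocabulary"] = tuple(d["filler_vocabulary"])
    d.update(kwargs)
    return SimConfig(symptom_model=kwargs.get("symptom_model", sm), **{k: v for k, v in d.items() if k != "symptom_model"})
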