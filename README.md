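# forumlisten

Social-media listening analytics for postoperative recovery forums.

`forumlisten` turns thread-initiating forum posts (subject headers only)
plus structured user profiles (surgery type, surgery date, ovary status)
into a reproducible analysis of what patients talk about during the first
12 weeks of hysterectomy recovery, and how that differs by surgical
approach (abdominal vs vaginal vs laparoscopic):

| Stage | Module | What it does |
|---|---|---|
| ingest | `forumlisten.ingest` | maps type codes to treatment groups, applies inclusion filters (thread-initiating, declared type+date, day 0–84 window), logs per-rule attrition |
| taxonomy | `forumlisten.taxonomy` | 12-group symptom keyword taxonomy; tokenizes subjects; tags posts by whole-token contiguous keyword match |
| termfreq | `forumlisten.termfreq` | n-gram (n = 1–3) extraction and Dunning log-likelihood corpus comparison with chi-square(1 df) significance |
| mentions | `forumlisten.mention_stats` | per-user symptom-mention indicators; 2×2 chi-square homogeneity contrasts of each minimally invasive group vs abdominal |
| survival | `forumlisten.survival` | per-user time-to-last-mention per symptom; Kaplan–Meier curves, log-rank tests, mean interquartile differences |
| summary | `forumlisten.summary` | volume histograms (day/week, stratified by mention count), weekly symptom shares, cohort descriptives |
| simulate | `forumlisten.simulate` | synthetic forum generator (group split, right-skewed post times, per-group mention/cessation models, injectable filter violations) with ground-truth output |
| cli | `forumlisten.cli` | `listen` CLI and end-to-end `run` orchestration with manifest |

**Central interpretive assumption** (documented in `forumlisten.survival`):
there is no censoring — every user's last mention inside the 84-day window
is treated as an observed cessation event, so the KM estimate equals the
empirical survivor function.

The shipped default taxonomy is a configuration artifact, not ground
truth; real analyses should supply a reviewed taxonomy JSON
(`{group_name: [keyword, ...]}`).

## CLI

All stages are subcommands of `listen` (see `listen <cmd> --help`):

```sh
# generate a synthetic cohort (posts.csv, profiles.csv, truth.csv, sim_config.json)
listen simulate --seed 1 --n-users 2000 --out-dir data/

# stage by stage
listen ingest  --posts data/posts.csv --profiles data/profiles.csv --out cohort.csv
listen tag     --cohort cohort.csv --out tagged.csv            # add --taxonomy my.json to override
listen mentions --tagged tagged.csv --out mentions.csv
listen survive  --tagged tagged.csv --out survival.csv --curves-out curves.csv
listen termfreq --base tagged_abdominal.csv --comparison tagged_vaginal.csv -n 3 --out tf.csv
listen summary  --tagged tagged.csv --out summary.json
listen volume   --tagged tagged.csv --axis week --out volume.csv
listen kwic     --keyword "spotting" --cohort cohort.csv       # curation helper

# or everything at once, with a manifest of input digests
listen run --config run.json
```

`run.json` minimally contains `{"posts": ..., "profiles": ..., "out_dir": ...}`;
optional keys: `taxonomy`, `window`, `min_count`, `alpha_tiers`, `seed`,
`denominator` (`"mentioners"` or `"all"`).

## Conventions

* Surgery day is day 0; the analysis window is the closed interval
  [0, 84] days; "first 3 weeks" is days 0–20.
* Weeks are 1-based (`week = day // 7 + 1`); reporting merges the 1-day
  week-13 bin (day 84) into week 12.
* Percentages are rounded half-up to 2 decimals and always re-derivable
  from the integer counts stored alongside them.
* Sign conventions: positive mention difference = comparison group
  mentions more; negative interquartile difference = comparison group
  ceases mentions earlier.
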