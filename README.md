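# polyrisk

A scoring engine for a weighted environmental polyrisk instrument, plus a
Monte-Carlo simulator of the score distribution in a synthetic general
population and the between-group statistics used to compare cohorts.

The instrument is a fixed registry of 16 factor groups (22 underlying
operationalised factors; logically dependent exposures such as immigration
generation × origin are folded into single scored groups). Each group offers
mutually exclusive exposure levels carrying half-point weights on a
`10 * log10(odds ratio)` scale. A respondent's total score is the sum of one
weight per group, and maps to a relative risk via `RR = 10 ** (total / 10)`.

## Modules

- `polyrisk.factor_model` — the instrument: groups, levels, weights,
  evidence classes, validation, OR-to-points conversion, YAML/JSON overrides.
- `polyrisk.scoring` — raw questionnaire responses → exposure profiles →
  scored totals with per-group contributions, relative risks, and cohort
  summaries (quartile ranges, threshold proportions).
- `polyrisk.population_sim` — synthetic-population simulation from a
  per-group prevalence configuration, analytic mean/SD oracle, and an
  adjusted Jarque–Bera normality test (exact small-sample moment
  corrections, chi-square(2) reference).
- `polyrisk.group_stats` — Welch t-test (raw data or summary statistics),
  two-sided Fisher's exact test (probability-mass rule), one-way ANOVA with
  Tukey–Kramer HSD, Pearson correlation.
- `polyrisk.io` / `polyrisk.cli` — CSV readers/writers, synthetic fixture
  cohorts, and the `pps` command-line tool.

**Important:** the shipped default prevalence configuration uses round
illustrative values. It is *not* a set of population estimates; summaries
computed from it are not comparable to any published cohort. Supply your own
prevalences (YAML/JSON keyed by group then level) for substantive use.

## CLI

```sh
# score a responses CSV (booleans yes/no, categorical codes in snake case)
pps score --responses cohort.csv --out report.json

# simulate a synthetic population (seed is mandatory)
pps simulate --n 1000000 --seed 7 --prevalence prev.yaml \
    --out sim.json --histogram hist.csv

# between-group comparisons
pps compare --summaries two_groups.json      # Welch t from {n, mean, sd}
pps compare --table 4,11,30,36               # Fisher's exact on a 2x2
pps compare --groups long.csv                # ANOVA + Tukey (value,group)

# generate a synthetic responses CSV
pps fixtures --n 100 --seed 3 --out cohort.csv
```

Every JSON report embeds a `meta` block (schema version, registry checksum,
seed, n) sufficient to re-run the command bit-identically. Numbers are
stored at full precision; `*_display` fields carry the conventional rounding
(relative risks and means/SDs to 2 decimals, percentages to 1).

## Responses CSV data dictionary

Columns: `respondent_id`, `age`, `sex` (male/female/other), `paternal_age`,
`ethnicity` (white/black_caribbean/other), `ethnic_density`
(low/medium/high, ignored for white), `immigration`
(none/first_generation/second_generation), `origin`
(north_africa/other/not_applicable), plus twelve yes/no items:
`childhood_trauma`, `non_right_handedness`, `pollution`, `urbanicity`,
`winter_spring_birth`, `low_paternal_ses`, `parental_smi`,
`adult_life_events`, `daily_smoker`, `heavy_cannabis`, `hearing_problems`,
`trait_anhedonia`. Blank cells mean missing; the missing-data policy is
`strict` (error), `reference` (impute baseline, warn) or `exclude` (drop
from summaries).
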