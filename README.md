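# dronetrack

Reconstruction and analysis of honeybee drone hive-entrance activity from
two-sensor RFID read streams.

A hive entrance fitted with two RFID antennas (`A` inside, `B` outside, or
vice versa — the labels are opaque) records one line per tag detection. From
that raw stream, `dronetrack`:

1. **detects crossings** — a departure is the read triple `(A, B, B)`, an
   arrival `(B, A, A)`, each timestamped at its middle read; the complete
   departure-then-arrival series is the five-read overlap `A,B,B,A,A`
   (the trailing `B` of the departure doubles as the head of the arrival);
2. **builds spans** — outside spans (departure → arrival) and inside spans
   (arrival → departure), with censoring for records that start/end
   mid-span and for broken same-kind event pairs;
3. **classifies behavior** by duration: exit/entry (≤ 3 min), orientation
   "short missions" (3–10 min), scouting (10 min – 10 h), extended
   absences (> 10 h, with a days-away count), inside resting (> 30 min),
   and departed drones (final unreturned departures);
4. **summarizes activity** per drone (flight counts, morning/afternoon
   departures), per hour (24 × duration-class profile), and per day
   (zero-filled daily series), plus departure-time groups, a cohort report
   (never-detected / single-read percentages) and an unusual-activity
   filter (long morning flights returning at the afternoon peak);
5. **tests** observation series (Mann–Whitney U, min convention), flight
   count distributions (chi-square GOF) and weather effects (Pearson r of
   daily flights vs temperature / precipitation).

Because raw reader logs are not bundled, an **agent-based simulator**
generates realistic entrance traffic (200 drones over a 45-day window by
default) together with exact ground truth, including detection-failure
modes: never-detected tags, single-read tags, per-read dropout and
spurious duplicate reads.

## Test

```sh
python -m pytest -q tests/
```

The suite includes property tests (hypothesis), an exhaustive
matcher-vs-oracle equivalence check over all 510 sensor sequences of
length ≤ 8, full-scale noiseless end-to-end recovery, and 20-seed
parameter-recovery checks. It runs in well under a minute.

## CLI

```sh
dronetrack run-all --seed 1 --out run/          # full pipeline
dronetrack simulate --seed 1 --out sim/         # reads + truth + weather
dronetrack detect sim/reads.csv --out events.csv
dronetrack classify events.csv --out spans.csv
dronetrack summarize spans.csv --out summaries/
dronetrack compare --sample1 a.csv --sample2 b.csv
dronetrack compare --daily run/daily.csv --weather run/weather.csv
```

All stages accept a TOML config (`--config`) with `[simulate]`,
`[detect]`, `[classify]`, `[summarize]` and `[stats]` sections; defaults
reproduce the standard analysis (3/10-min and 10-h outside thresholds,
30-min resting threshold, noon morning cutoff, four departure-time group
windows). `run-all` writes every artifact plus `run_log.json` with a
config hash and per-stage counts; outputs are byte-identical for a fixed
seed.

## Layout

| module | responsibility |
| --- | --- |
| `dronetrack.rfid_io` | CSV read/write, dialects, validation, canonical ordering |
| `dronetrack.detect` | crossing-grammar matcher, match report, morning predicate |
| `dronetrack.behavior` | span construction, censoring, duration classification |
| `dronetrack.summary` | per-drone/hourly/daily aggregation, cohort report, groups |
| `dronetrack.stats` | Mann–Whitney U, chi-square GOF, weather correlations |
| `dronetrack.synthetic` | agent-based traffic + weather simulator with ground truth |
| `dronetrack.pipeline` / `dronetrack.cli` | orchestration, config, console entry point |
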